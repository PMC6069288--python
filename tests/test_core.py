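"""Shortest paths, GRGT extraction, and canonical pattern keys."""

import itertools
import random

import networkx as nx
import pytest

from grgt.candidates import TripletCandidate
from grgt.core import (PatternGraph, canonical_key, extract_grgt,
                       mention_head, shortest_path)
from grgt.depgraph import SentenceGraph, Token, TypedDependency
from grgt.lexicon import Mention
from grgt.synthdata import builtin_fixtures


def random_sentence_graph(rng, n_max=12, sid="r", tree=False):
    n = rng.randint(2, n_max)
    labels = ["nsubj", "dobj", "prep_of", "amod", "nn", "conj_and"]
    edges = set()
    if tree:
        for v in range(2, n + 1):
            u = rng.randint(1, v - 1)
            edges.add((u, v))
    else:
        m = rng.randint(1, n * (n - 1) // 2)
        pairs = list(itertools.combinations(range(1, n + 1), 2))
        rng.shuffle(pairs)
        edges.update(pairs[:m])
    tokens = [Token(i, f"w{i}") for i in range(1, n + 1)]
    deps = [TypedDependency(u, v, rng.choice(labels))
            for u, v in sorted(edges)]
    return SentenceGraph(sid, "x", tokens, deps)


# ---------------------------------------------------------------------------
# shortest_path


def test_path_par3alpha_to_interact_passes_through_domain(fixtures_by_id):
    g = fixtures_by_id["fig2"].graph
    # token 6 = PAR3alpha, 4 = domain, 10 = interact
    assert shortest_path(g, 6, 10) == [6, 4, 10]


def test_identical_endpoints_give_single_node_path(fixtures_by_id):
    g = fixtures_by_id["fig2"].graph
    assert shortest_path(g, 4, 4) == [4]


def test_disconnected_pair_gives_empty_path():
    tokens = [Token(i, f"w{i}") for i in range(1, 5)]
    deps = [TypedDependency(1, 2, "nsubj"), TypedDependency(3, 4, "dobj")]
    g = SentenceGraph("s", "x", tokens, deps)
    assert shortest_path(g, 1, 4) == []


def test_punct_edges_do_not_carry_paths():
    """A path that would shortcut through a punctuation edge is not taken;
    with no other route the pair is disconnected."""
    tokens = [Token(i, f"w{i}") for i in range(1, 4)]
    deps = [TypedDependency(1, 2, "punct"), TypedDependency(2, 3, "nsubj")]
    g = SentenceGraph("s", "x", tokens, deps)
    assert shortest_path(g, 1, 3) == []
    assert shortest_path(g, 1, 3, exclude_labels=frozenset()) == [1, 2, 3]


def test_path_length_equals_bfs_distance_on_random_graphs():
    """Minimum-hop contract: path length agrees with networkx BFS distance
    for every connected pair of 1000 random graphs (<= 12 nodes); the
    returned sequence is the lexicographically smallest one."""
    rng = random.Random(20240901)
    for _ in range(1000):
        g = random_sentence_graph(rng)
        nxg = g.to_networkx()
        dist = dict(nx.all_pairs_shortest_path_length(nxg))
        for a in range(1, len(g.tokens) + 1):
            for b in range(1, len(g.tokens) + 1):
                path = shortest_path(g, a, b,
                                     exclude_labels=frozenset())
                if b in dist.get(a, {}):
                    assert len(path) - 1 == dist[a][b]
                    all_paths = list(nx.all_shortest_paths(nxg, a, b))
                    assert path == min(all_paths)
                else:
                    assert path == []


# ---------------------------------------------------------------------------
# extract_grgt


def triplet_for(g, p1_tok, p2_tok, i_tok, inorm="interact"):
    sid = g.sentence_id
    return TripletCandidate(
        sid, Mention(sid, p1_tok, p1_tok, "protein", f"X{p1_tok}"),
        Mention(sid, p2_tok, p2_tok, "protein", f"X{p2_tok}"),
        Mention(sid, i_tok, i_tok, "interaction", inorm))


def test_fig2_grgt_is_domain_plus_terminals(fixtures_by_id):
    fig2 = fixtures_by_id["fig2"]
    p = extract_grgt(fig2.graph, fig2.triplets[0])
    roles = sorted((n.role, n.word) for n in p.nodes)
    assert roles == [("INT", "interact"), ("LEX", "domain"), ("P1", None),
                     ("P2", None)]
    assert sorted(p.token_of_node) == [4, 6, 10, 12]


def test_mutually_adjacent_triplet_gives_three_node_pattern():
    tokens = [Token(i, f"w{i}") for i in range(1, 4)]
    deps = [TypedDependency(2, 1, "nsubj"), TypedDependency(2, 3, "dobj"),
            TypedDependency(1, 3, "conj_and")]
    g = SentenceGraph("s", "x", tokens, deps)
    p = extract_grgt(g, triplet_for(g, 1, 3, 2))
    assert p.n_nodes == 3
    assert {n.role for n in p.nodes} == {"P1", "P2", "INT"}


def test_disconnected_triplet_is_unextractable():
    tokens = [Token(i, f"w{i}") for i in range(1, 5)]
    deps = [TypedDependency(1, 2, "nsubj"), TypedDependency(3, 4, "dobj")]
    g = SentenceGraph("s", "x", tokens, deps)
    assert extract_grgt(g, triplet_for(g, 1, 4, 2)) is None


def test_grgt_on_trees_equals_steiner_tree_of_terminals():
    """On trees the union of pairwise shortest paths is the minimal
    connecting subtree; compare node sets against brute force."""
    rng = random.Random(77)
    for _ in range(300):
        g = random_sentence_graph(rng, n_max=10, tree=True)
        n = len(g.tokens)
        if n < 3:
            continue
        terms = rng.sample(range(1, n + 1), 3)
        nxg = g.to_networkx()
        # brute-force Steiner tree on a tree: union of unique tree paths
        expected = set()
        for a, b in itertools.combinations(terms, 2):
            expected.update(nx.shortest_path(nxg, a, b))
        p = extract_grgt(g, triplet_for(g, min(terms[0], terms[1]),
                                        max(terms[0], terms[1]), terms[2]))
        assert p is not None
        assert set(p.token_of_node) == expected


def test_multi_token_mention_head_is_span_token_linked_outside():
    # "protein kinase A binds B": span 1-3, head = token governed from outside
    tokens = [Token(1, "protein"), Token(2, "kinase"), Token(3, "A"),
              Token(4, "binds"), Token(5, "B")]
    deps = [TypedDependency(3, 1, "nn"), TypedDependency(3, 2, "nn"),
            TypedDependency(4, 3, "nsubj"), TypedDependency(4, 5, "dobj")]
    g = SentenceGraph("s", "x", tokens, deps)
    m = Mention("s", 1, 3, "protein", "protein kinase A")
    assert mention_head(g, m) == 3


# ---------------------------------------------------------------------------
# canonical keys


def grgt_of(cs, idx=0):
    return extract_grgt(cs.graph, cs.triplets[idx])


@pytest.fixture(scope="module")
def worked(lex):
    by_id = {cs.sentence_id: cs for cs in builtin_fixtures()}
    return {
        "domain": grgt_of(by_id["train-domain"]),
        "motif": grgt_of(by_id["probe-motif-interact"]),
        "associate": grgt_of(by_id["probe-motif-associate"]),
    }


def test_renaming_proteins_leaves_level1_key_unchanged(fixtures_by_id, lex):
    """Protein nodes carry no word, so a pattern with altered protein
    names is the same pattern."""
    fig2 = fixtures_by_id["fig2"]
    renamed = SentenceGraph(
        "renamed", fig2.graph.text,
        [Token(t.index, "Q1" if t.form == "PAR3alpha" else
               ("Q2" if t.form == "PAR6" else t.form),
               "Q1" if t.lemma == "PAR3alpha" else
               ("Q2" if t.lemma == "PAR6" else t.lemma))
         for t in fig2.graph.tokens],
        list(fig2.graph.dependencies))
    t = triplet_for(renamed, 6, 12, 10)
    k1 = canonical_key(extract_grgt(fig2.graph, fig2.triplets[0]), 1, lex)
    k2 = canonical_key(extract_grgt(renamed, t), 1, lex)
    assert k1 == k2


def test_lex_word_variation_splits_level1_merges_level2(worked, lex):
    dom, mot = worked["domain"], worked["motif"]
    assert canonical_key(dom, 1, lex) != canonical_key(mot, 1, lex)
    assert canonical_key(dom, 2, lex) == canonical_key(mot, 2, lex)


def test_interaction_word_variation_splits_level2_merges_level3(worked, lex):
    mot, ass = worked["motif"], worked["associate"]
    assert canonical_key(mot, 2, lex) != canonical_key(ass, 2, lex)
    assert canonical_key(mot, 3, lex) == canonical_key(ass, 3, lex)


def test_level4_reduces_edge_labels(worked, lex, hierarchy):
    dom = worked["domain"]
    k3 = canonical_key(dom, 3, lex, hierarchy)
    k4 = canonical_key(dom, 4, lex, hierarchy, reduce_steps=1)
    assert "nsubj" in k3.key
    assert "nsubj" not in k4.key
    assert "subj" in k4.key


def test_direction_matters_by_default_but_can_be_ignored(lex):
    """A inhibits B vs B inhibits A: same undirected shape, different
    stored directions on the role nodes."""
    tokens = [Token(1, "A"), Token(2, "inhibits", "inhibit"), Token(3, "B")]
    deps_fwd = [TypedDependency(2, 1, "nsubj"), TypedDependency(2, 3, "dobj")]
    deps_rev = [TypedDependency(2, 3, "nsubj"), TypedDependency(2, 1, "dobj")]
    g1 = SentenceGraph("s1", "x", tokens, deps_fwd)
    g2 = SentenceGraph("s2", "x", tokens, deps_rev)
    p1 = extract_grgt(g1, triplet_for(g1, 1, 3, 2, "inhibit"))
    p2 = extract_grgt(g2, triplet_for(g2, 1, 3, 2, "inhibit"))
    assert canonical_key(p1, 1, lex) != canonical_key(p2, 1, lex)


def test_key_is_stable_under_storage_order_shuffling(worked, lex):
    """100 random permutations of node and edge storage order never change
    any level's key."""
    base = worked["domain"]
    keys = {lv: canonical_key(base, lv, lex) for lv in (1, 2, 3)}
    rng = random.Random(5)
    for _ in range(100):
        perm = list(range(base.n_nodes))
        rng.shuffle(perm)
        nodes = [None] * base.n_nodes
        for old, new in enumerate(perm):
            nodes[new] = base.nodes[old]
        edges = [(perm[g], perm[d], lab) for g, d, lab in base.edges]
        rng.shuffle(edges)
        shuffled = PatternGraph(nodes=nodes, edges=edges, level=1)
        for lv in (1, 2, 3):
            assert canonical_key(shuffled, lv, lex) == keys[lv]


def test_level_key_refinement_on_synthetic_corpus(small_corpus, lex):
    """Equal level-k keys imply equal level-(k+1) keys: generalization
    only ever merges pattern classes, never splits them."""
    keys = []
    for cs in small_corpus:
        for t in cs.triplets:
            p = extract_grgt(cs.graph, t)
            assert p is not None
            keys.append({lv: canonical_key(p, lv, lex).key
                         for lv in (1, 2, 3, 4)})
    for ka, kb in itertools.combinations(keys, 2):
        for lv in (1, 2, 3):
            if ka[lv] == kb[lv]:
                assert ka[lv + 1] == kb[lv + 1]


def test_grgt_is_connected_and_within_sentence(small_corpus):
    for cs in small_corpus:
        for t in cs.triplets:
            p = extract_grgt(cs.graph, t)
            g = nx.Graph()
            g.add_nodes_from(range(p.n_nodes))
            g.add_edges_from((u, v) for u, v, _ in p.edges)
            assert nx.is_connected(g)
            sent_pairs = {frozenset((d.governor, d.dependent))
                          for d in cs.graph.dependencies}
            for u, v, lab in p.edges:
                tu, tv = p.token_of_node[u], p.token_of_node[v]
                assert frozenset((tu, tv)) in sent_pairs
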