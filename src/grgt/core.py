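"""GRGT extraction and pattern canonicalization.

The grammatical relationship graph for a triplet (GRGT) is the union of
the three pairwise shortest paths — in the undirected view of the
sentence's typed-dependency graph — among the two protein heads and the
interaction-word token.  It is the minimal grammatical context linking
the triplet, and it is the entire feature the classifier uses.

A GRGT is abstracted at increasing generalization levels:

1. exact — every intermediate (LEX) word and the interaction word kept;
2. relaxed — LEX words wildcarded, structure and labels kept;
3. grouped — additionally the interaction word replaced by its
   interaction-word group, so grammatically interchangeable verbs match;
4. hierarchy-reduced (optional, off by default) — additionally every
   edge label coarsened through the dependency-label hierarchy.

Two triplets whose GRGTs are isomorphic under this abstraction get the
same canonical key string, which is what training counts and prediction
matches on.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .candidates import TripletCandidate
from .depgraph import LabelHierarchy, SentenceGraph, reduce_label
from .lexicon import Lexicon, Mention

__all__ = [
    "PatternNode",
    "PatternGraph",
    "PatternKey",
    "shortest_path",
    "extract_grgt",
    "canonical_key",
]

#: dependency labels whose edges are kept in the graph but never used for
#: path finding (punctuation carries no grammatical linkage).
PATH_EXCLUDED_LABELS: frozenset[str] = frozenset({"punct"})


@dataclass(frozen=True)
class PatternNode:
    """A role-abstracted node: P1/P2 (proteins), INT (interaction word),
    or LEX (any other word on a connecting path, with its lemma)."""

    role: str  # "P1" | "P2" | "INT" | "LEX"
    word: Optional[str] = None  # lemma for LEX/INT; None for P1/P2


@dataclass
class PatternGraph:
    """The GRGT: role-abstracted nodes plus typed, directed edges.

    ``edges`` hold node list indices ``(gov, dep, label)`` with the stored
    governor -> dependent direction of the source dependency.
    """

    nodes: list[PatternNode]
    edges: list[tuple[int, int, str]]
    level: int = 1
    token_of_node: list[int] = field(default_factory=list)  # provenance

    def node_index(self, role: str) -> int:
        for i, n in enumerate(self.nodes):
            if n.role == role:
                return i
        raise KeyError(role)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class PatternKey:
    """Canonical, position-independent serialization of a PatternGraph."""

    level: int
    key: str


# ---------------------------------------------------------------------------
# Shortest paths


def _adjacency(g: SentenceGraph,
               exclude_labels: frozenset[str]) -> dict[int, list[int]]:
    adj: dict[int, list[int]] = {t.index: [] for t in g.tokens}
    for d in g.dependencies:
        if d.label in exclude_labels:
            continue
        adj[d.governor].append(d.dependent)
        adj[d.dependent].append(d.governor)
    for lst in adj.values():
        lst.sort()
    return adj


def shortest_path(g: SentenceGraph, a: int, b: int,
                  exclude_labels: frozenset[str] = PATH_EXCLUDED_LABELS
                  ) -> list[int]:
    """Minimum-hop undirected path from token ``a`` to token ``b``.

    All non-excluded edges have unit weight, so Dijkstra reduces to
    breadth-first search.  Among equal-length paths the one whose token
    index sequence is lexicographically smallest is returned, which makes
    extracted patterns reproducible.  Returns ``[]`` when the tokens are
    disconnected; ``[a]`` when ``a == b``.
    """
    n = len(g.tokens)
    if not (1 <= a <= n and 1 <= b <= n):
        raise ValueError(f"token index out of range: {a}, {b}")
    if a == b:
        return [a]
    adj = _adjacency(g, exclude_labels)
    # distances from b, then greedy walk from a choosing the smallest
    # neighbor index one step closer: lexicographic minimum over all
    # minimum-hop paths.
    dist = {b: 0}
    queue = deque([b])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    if a not in dist:
        return []
    path = [a]
    cur = a
    while cur != b:
        cur = min(v for v in adj[cur] if dist.get(v, -1) == dist[cur] - 1)
        path.append(cur)
    return path


# ---------------------------------------------------------------------------
# GRGT extraction


def mention_head(g: SentenceGraph, m: Mention) -> int:
    """Head token of a mention span.

    Single-token spans are their own head.  For multi-token spans the head
    is the token governed from outside the span (or, failing that, one
    with any edge leaving the span); ties break to the smallest index.
    """
    if m.token_start == m.token_end:
        return m.token_start
    span = set(range(m.token_start, m.token_end + 1))
    governed_from_outside = []
    touching_outside = []
    for d in g.dependencies:
        if d.dependent in span and d.governor not in span:
            governed_from_outside.append(d.dependent)
        if d.governor in span and d.dependent not in span:
            touching_outside.append(d.governor)
    for pool in (governed_from_outside, touching_outside):
        if pool:
            return min(pool)
    return m.token_end


def extract_grgt(g: SentenceGraph, t: TripletCandidate,
                 exclude_labels: frozenset[str] = PATH_EXCLUDED_LABELS
                 ) -> Optional[PatternGraph]:
    """Union of the three pairwise shortest paths among (p1 head, p2 head,
    interaction token), with roles P1/P2/INT on the terminals and LEX on
    every other path token.

    Returns ``None`` (the "unextractable" signal) when any pair is
    disconnected or the three head tokens are not distinct; callers treat
    such triplets as unmatched, hence classified false.
    """
    h1 = mention_head(g, t.p1)
    h2 = mention_head(g, t.p2)
    hi = mention_head(g, t.iword)
    if len({h1, h2, hi}) != 3:
        return None
    paths = [shortest_path(g, x, y, exclude_labels)
             for x, y in ((h1, h2), (h1, hi), (h2, hi))]
    if any(not p for p in paths):
        return None
    keep_tokens: set[int] = set()
    keep_pairs: set[frozenset[int]] = set()
    for p in paths:
        keep_tokens.update(p)
        for u, v in zip(p, p[1:]):
            keep_pairs.add(frozenset((u, v)))
    role_of = {h1: "P1", h2: "P2", hi: "INT"}
    order = sorted(keep_tokens)
    idx_of = {tok: i for i, tok in enumerate(order)}
    nodes: list[PatternNode] = []
    for tok in order:
        role = role_of.get(tok, "LEX")
        if role == "INT":
            word = t.iword.norm
        elif role == "LEX":
            word = g.token(tok).lemma.lower()
        else:
            word = None
        nodes.append(PatternNode(role, word))
    edges: list[tuple[int, int, str]] = []
    for d in g.dependencies:
        if frozenset((d.governor, d.dependent)) in keep_pairs:
            edges.append((idx_of[d.governor], idx_of[d.dependent], d.label))
    edges.sort()
    return PatternGraph(nodes=nodes, edges=edges, level=1,
                        token_of_node=order)


# ---------------------------------------------------------------------------
# Canonical keys


def _abstract(p: PatternGraph, level: int, lex: Lexicon,
              hierarchy: Optional[LabelHierarchy],
              reduce_steps: int) -> tuple[list[PatternNode],
                                          list[tuple[int, int, str]]]:
    """Apply the generalization level to node words and edge labels."""
    nodes = []
    for n in p.nodes:
        word = n.word
        if n.role == "LEX" and level >= 2:
            word = "*"
        elif n.role == "INT" and level >= 3:
            word = lex.interaction_words.get(n.word, f"~{n.word}")
        nodes.append(PatternNode(n.role, word))
    edges = p.edges
    if level >= 4:
        h = hierarchy if hierarchy is not None else LabelHierarchy()
        edges = [(g_, d_, reduce_label(lab, h, reduce_steps))
                 for g_, d_, lab in edges]
    return nodes, list(edges)


def _node_sig(n: PatternNode) -> str:
    return f"{n.role}:{n.word if n.word is not None else ''}"


def _serialize(order: Sequence[int], nodes: list[PatternNode],
               edges: list[tuple[int, int, str]], directed: bool) -> str:
    pos = {n: i for i, n in enumerate(order)}
    node_part = ";".join(_node_sig(nodes[n]) for n in order)
    edge_reprs = []
    for gov, dep, lab in edges:
        i, j = pos[gov], pos[dep]
        if directed:
            arrow = ">" if i < j else "<"
            edge_reprs.append(f"{min(i, j)}-{lab}{arrow}-{max(i, j)}")
        else:
            edge_reprs.append(f"{min(i, j)}-{lab}-{max(i, j)}")
    return node_part + "||" + ",".join(sorted(edge_reprs))


def _canonical_orderings(nodes: list[PatternNode],
                         edges: list[tuple[int, int, str]],
                         start: int, directed: bool,
                         cap: int = 5000) -> list[list[int]]:
    """All BFS visit orders from ``start`` with neighbors sorted by
    (edge label, direction, role, word); genuinely tied neighbors branch
    into permutations.  Capped; beyond the cap remaining ties break by
    node index (sound for key stability only in pathological graphs far
    larger than any path union)."""
    adj: dict[int, list[tuple[str, str, int]]] = {i: [] for i in range(len(nodes))}
    for gov, dep, lab in edges:
        d_out = ">" if directed else "-"
        d_in = "<" if directed else "-"
        adj[gov].append((lab, d_out, dep))
        adj[dep].append((lab, d_in, gov))

    results: list[list[int]] = []

    def expand(order: list[int], frontier_pos: int) -> None:
        if len(results) >= cap:
            return
        if frontier_pos == len(order) and len(order) == len(nodes):
            results.append(order)
            return
        if frontier_pos >= len(order):
            return  # disconnected remainder; caller guarantees connected
        current = order[frontier_pos]
        placed = set(order)
        nbrs = [(lab, d, v) for lab, d, v in adj[current] if v not in placed]
        if not nbrs:
            expand(order, frontier_pos + 1)
            return
        # group by (label, direction, node signature); permute within groups
        keyed = sorted(nbrs, key=lambda x: (x[0], x[1], _node_sig(nodes[x[2]])))
        groups: list[list[int]] = []
        prev = None
        for lab, d, v in keyed:
            sig = (lab, d, _node_sig(nodes[v]))
            if sig != prev:
                groups.append([])
                prev = sig
            groups[-1].append(v)
        for combo in itertools.product(
                *(itertools.permutations(grp) for grp in groups)):
            if len(results) >= cap:
                return
            flat = [v for grp in combo for v in grp]
            # a neighbor may appear via two parallel labels? edges are unique
            # per pair, so flat has no duplicates.
            expand(order + flat, frontier_pos + 1)

    expand([start], 0)
    return results


def canonical_key(p: PatternGraph, level: int, lex: Lexicon,
                  hierarchy: Optional[LabelHierarchy] = None,
                  reduce_steps: int = 1,
                  directed: bool = True) -> PatternKey:
    """Canonical string key of a pattern at a generalization level.

    The key is the lexicographically smallest serialization over all
    breadth-first visit orders rooted at the INT node, with neighbors
    ordered by (edge label, stored direction, node role, node word).
    Isomorphic patterns — same structure, labels, role placement and
    level-visible words — therefore share a key, and the key never
    depends on node or edge storage order or on absolute token positions.
    """
    if level not in (1, 2, 3, 4):
        raise ValueError(f"level must be 1..4, got {level}")
    nodes, edges = _abstract(p, level, lex, hierarchy, reduce_steps)
    start = p.node_index("INT")
    orders = _canonical_orderings(nodes, edges, start, directed)
    if not orders:  # cap exhausted before any full order: deterministic fall-back
        orders = [sorted(range(len(nodes)))]
    key = min(_serialize(o, nodes, edges, directed) for o in orders)
    return PatternKey(level, f"L{level}|{key}")


def pattern_keys(p: PatternGraph, levels: Sequence[int], lex: Lexicon,
                 hierarchy: Optional[LabelHierarchy] = None,
                 reduce_steps: int = 1,
                 directed: bool = True) -> dict[int, str]:
    """Key strings for several levels at once (helper for training)."""
    return {lv: canonical_key(p, lv, lex, hierarchy, reduce_steps,
                              directed).key
            for lv in levels}
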