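"""Training counts, the decision-tree cascade, and model serialization."""

from collections import Counter, defaultdict

import pytest

from grgt.core import extract_grgt, pattern_keys
from grgt.model import (PatternModel, predict_triplet, train_model)
from grgt.synthdata import (GeneratorConfig, builtin_fixtures,
                            generate_corpus, instantiate_template,
                            DEFAULT_TEMPLATES)


def corpus_pairs(corpus):
    return [(cs.graph, t) for cs in corpus for t in cs.triplets]


@pytest.fixture(scope="module")
def worked_model(lex):
    """Model trained on the single true example 'domain of P1 interact
    with P2'."""
    by_id = {cs.sentence_id: cs for cs in builtin_fixtures()}
    train = by_id["train-domain"]
    return train_model([(train.graph, train.triplets[0])], lex=lex), by_id


def test_probability_is_true_proportion(lex):
    """One pattern observed in 3 triplets of which 2 true -> 2/3."""
    tpl = DEFAULT_TEMPLATES[0]  # simple_active
    sents = [instantiate_template(tpl, f"s{i}", [f"A{i}", f"B{i}"],
                                  "bind", [flip])
             for i, flip in enumerate([False, False, True])]
    m = train_model(corpus_pairs(sents), lex=lex)
    entries = m.entries[1]
    assert len(entries) == 1
    (e,) = entries.values()
    assert (e.n_true, e.n_total) == (2, 3)
    assert e.probability == pytest.approx(2 / 3)


def test_empty_corpus_gives_valid_empty_model(lex):
    m = train_model([], lex=lex)
    assert m.n_trained == 0
    assert all(not m.entries[lv] for lv in m.levels)


def test_unlabeled_triplet_is_training_error(lex):
    by_id = {cs.sentence_id: cs for cs in builtin_fixtures()}
    probe = by_id["probe-motif-interact"]  # gold unknown
    with pytest.raises(ValueError, match="unlabeled"):
        train_model([(probe.graph, probe.triplets[0])], lex=lex)


def test_entry_counts_match_brute_force_recount(lex):
    """Seed-42 synthetic corpus: model counts equal an independent
    recount over the generated records, at every level."""
    corpus = generate_corpus(GeneratorConfig(n_sentences=150, seed=42,
                                             pattern_noise=0.1), lex)
    m = train_model(corpus_pairs(corpus), lex=lex)
    recount = {lv: defaultdict(lambda: [0, 0]) for lv in (1, 2, 3)}
    n_seen = 0
    for cs in corpus:
        for t in cs.triplets:
            p = extract_grgt(cs.graph, t)
            keys = pattern_keys(p, (1, 2, 3), lex)
            n_seen += 1
            for lv in (1, 2, 3):
                rec = recount[lv][keys[lv]]
                rec[1] += 1
                rec[0] += int(t.gold_label)
    assert m.n_trained == n_seen
    for lv in (1, 2, 3):
        assert set(m.entries[lv]) == set(recount[lv])
        for key, (nt, ntot) in recount[lv].items():
            e = m.entries[lv][key]
            assert (e.n_true, e.n_total) == (nt, ntot)
    # count conservation: totals at each level sum to extractable triplets
    for lv in (1, 2, 3):
        assert sum(e.n_total for e in m.entries[lv].values()) == \
            m.n_trained


def test_cascade_level1_match_on_renamed_proteins(worked_model, lex):
    m, by_id = worked_model
    tpl = next(t for t in DEFAULT_TEMPLATES if t.name == "domain_prep")
    # same structure as the training example, different protein names
    probe = instantiate_template(tpl, "p", ["CaM", "RAF1"], "interact")
    pred = predict_triplet(m, probe.graph, probe.triplets[0], lex)
    assert pred.matched_level == 1
    assert pred.probability == 1.0
    assert pred.predicted_label is True


def test_cascade_level2_on_lex_word_change(worked_model, lex):
    m, by_id = worked_model
    probe = by_id["probe-motif-interact"]
    pred = predict_triplet(m, probe.graph, probe.triplets[0], lex)
    assert pred.matched_level == 2
    assert pred.probability == 1.0


def test_cascade_level3_on_same_group_interaction_word(worked_model, lex):
    m, by_id = worked_model
    probe = by_id["probe-motif-associate"]
    pred = predict_triplet(m, probe.graph, probe.triplets[0], lex)
    assert pred.matched_level == 3
    assert pred.probability == 1.0


def test_no_match_means_false_with_probability_zero(worked_model, lex):
    m, _ = worked_model
    # different structure AND an interaction word from a different group
    tpl = next(t for t in DEFAULT_TEMPLATES if t.name == "simple_active")
    probe = instantiate_template(tpl, "p", ["CaM", "RAF1"], "inhibit")
    pred = predict_triplet(m, probe.graph, probe.triplets[0], lex)
    assert pred.matched_level is None
    assert pred.probability == 0.0
    assert pred.predicted_label is False


def test_self_consistency_on_training_corpus(small_corpus, lex):
    """Every training triplet, predicted with its own full model, matches
    at level 1 with exactly the level-1 entry probability."""
    m = train_model(corpus_pairs(small_corpus), lex=lex)
    for cs in small_corpus:
        for t in cs.triplets:
            pred = predict_triplet(m, cs.graph, t, lex)
            assert pred.matched_level == 1
            p = extract_grgt(cs.graph, t)
            key = pattern_keys(p, (1,), lex)[1]
            assert pred.probability == m.entries[1][key].probability


def test_cascade_monotone_in_level_list(small_corpus, lex):
    """Enlarging the level list never shrinks the matched set."""
    by_id = {cs.sentence_id: cs for cs in builtin_fixtures()}
    train = by_id["train-domain"]
    probes = [(cs.graph, t) for cs in small_corpus for t in cs.triplets]
    matched_prev: set[int] = set()
    for levels in ((1,), (1, 2), (1, 2, 3)):
        m = train_model([(train.graph, train.triplets[0])], levels=levels,
                        lex=lex)
        matched = {i for i, (g, t) in enumerate(probes)
                   if predict_triplet(m, g, t, lex).matched_level
                   is not None}
        assert matched >= matched_prev
        matched_prev = matched


def test_direction_by_majority_vote_ties_unknown(lex):
    tpl = DEFAULT_TEMPLATES[0]
    fwd = [instantiate_template(tpl, f"f{i}", [f"A{i}", f"B{i}"], "bind")
           for i in range(2)]
    m = train_model(corpus_pairs(fwd), lex=lex)
    probe = instantiate_template(tpl, "p", ["CaM", "RAF1"], "bind")
    pred = predict_triplet(m, probe.graph, probe.triplets[0], lex)
    assert pred.predicted_direction == "p1_to_p2"
    # force a tie by manual tally
    (entry,) = m.entries[1].values()
    entry.direction_tally = Counter({"p1_to_p2": 1, "p2_to_p1": 1})
    pred = predict_triplet(m, probe.graph, probe.triplets[0], lex)
    assert pred.predicted_direction == "unknown"


def test_lexicon_fingerprint_mismatch_is_rejected(worked_model, lex, tmp_path):
    m, by_id = worked_model
    probe = by_id["probe-motif-interact"]
    other = type(lex)(protein_names={"X"}, interaction_words={"y": "g"})
    with pytest.raises(ValueError, match="fingerprint"):
        predict_triplet(m, probe.graph, probe.triplets[0], other)
    # explicit override allowed
    predict_triplet(m, probe.graph, probe.triplets[0], lex,
                    check_lexicon=False)


def test_model_file_round_trip_is_bit_exact(small_corpus, lex, tmp_path):
    m = train_model(corpus_pairs(small_corpus), lex=lex)
    p1, p2 = tmp_path / "m1.txt", tmp_path / "m2.txt"
    m.save(p1)
    back = PatternModel.load(p1)
    back.save(p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert back.levels == m.levels
    for lv in m.levels:
        assert set(back.entries[lv]) == set(m.entries[lv])
        for k in m.entries[lv]:
            a, b = m.entries[lv][k], back.entries[lv][k]
            assert (a.n_true, a.n_total, a.direction_tally) == \
                (b.n_true, b.n_total, b.direction_tally)


def test_probabilities_always_in_unit_interval(small_corpus, lex):
    m = train_model(corpus_pairs(small_corpus), lex=lex)
    for lv in m.levels:
        for e in m.entries[lv].values():
            assert 0.0 <= e.probability <= 1.0
            assert 0 <= e.n_true <= e.n_total
            assert e.n_total >= 1
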