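"""Synthetic parsed corpora and built-in worked-example fixtures.

Real PPI corpora require an external dependency parser and curated
dictionaries; this module removes both from the test surface.  Sentence
*templates* carry hand-authored Stanford-style dependency skeletons with
protein and interaction-word slots, so instantiating a template yields a
sentence whose parse is valid by construction.  The template set spans
active, passive, prepositional-attachment, nominalization, negation,
coordination, relative-clause and complement-clause shapes; negation and
multi-protein templates supply realistic gold-false triplets.

Two instantiations of one template with different protein names have
identical level-1 pattern keys (protein nodes carry no word), which is
the property the whole pattern-matching method rests on.

The built-in fixtures reproduce the canonical worked examples: the
"first PDZ domain of PAR3alpha ... interact with PAR6" sentence, the
"domain of P1 interact with P2" training template with its "motif"
and "associates" probes, and a four-protein-mention sentence (PAHX,
FKBP52, FKBP12, FKBP52 + "interacts") that yields exactly five candidate
triplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .candidates import TripletCandidate
from .corpus import CorpusSentence
from .depgraph import SentenceGraph, Token, TypedDependency
from .lexicon import Lexicon, Mention, default_lexicon

__all__ = [
    "GeneratorConfig",
    "Template",
    "DEFAULT_TEMPLATES",
    "generate_corpus",
    "builtin_fixtures",
    "duplicate_corpus",
]


# ---------------------------------------------------------------------------
# Templates


@dataclass(frozen=True)
class Template:
    """A sentence shape with a precomputed dependency skeleton.

    ``tokens``: surface strings, or slot markers — ``{A}``..``{D}`` for
    protein slots, ``{I}`` / ``{I:ed}`` / ``{I:ion}`` for the interaction
    word (base, participle, nominalization).  ``deps``: (gov, dep, label),
    1-based.  ``gold``: per unordered protein-slot pair (earlier slot
    first), the gold label and direction expressed in sentence order.
    """

    name: str
    tokens: tuple[str, ...]
    deps: tuple[tuple[int, int, str], ...]
    gold: tuple[tuple[str, str, bool, str], ...]  # (slotE, slotL, label, dir)

    @property
    def protein_slots(self) -> list[str]:
        return [t[1] for t in self.tokens
                if t.startswith("{") and t[1] in "ABCD"]

    def slot_index(self, slot: str) -> int:
        for i, t in enumerate(self.tokens, start=1):
            if t.startswith("{") and t[1] == slot:
                return i
        raise KeyError(slot)

    @property
    def iword_index(self) -> int:
        for i, t in enumerate(self.tokens, start=1):
            if t.startswith("{I"):
                return i
        raise KeyError("template has no interaction slot")

    @property
    def iword_form(self) -> str:
        for t in self.tokens:
            if t.startswith("{I"):
                return t
        raise KeyError("template has no interaction slot")

    @property
    def n_true(self) -> int:
        return sum(1 for *_s, label, _d in self.gold if label)

    @property
    def n_candidates(self) -> int:
        return len(self.gold)


def _inflect(lemma: str, how: str) -> str:
    if how == "{I}":
        return lemma
    if how == "{I:ed}":
        return lemma + "d" if lemma.endswith("e") else lemma + "ed"
    if how == "{I:ion}":
        return lemma[:-1] + "ion" if lemma.endswith("e") else lemma + "ion"
    raise ValueError(f"unknown interaction slot {how!r}")


DEFAULT_TEMPLATES: tuple[Template, ...] = (
    Template(
        "simple_active",
        ("{A}", "{I}", "{B}", "."),
        ((2, 1, "nsubj"), (2, 3, "dobj"), (2, 4, "punct")),
        (("A", "B", True, "p1_to_p2"),)),
    Template(
        "active_with",
        ("{A}", "{I}", "with", "{B}", "."),
        ((2, 1, "nsubj"), (2, 4, "prep_with"), (3, 4, "pobj"),
         (2, 5, "punct")),
        (("A", "B", True, "p1_to_p2"),)),
    Template(
        "passive_by",
        ("{A}", "is", "{I:ed}", "by", "{B}", "."),
        ((3, 1, "nsubjpass"), (3, 2, "auxpass"), (3, 5, "agent"),
         (4, 5, "pobj"), (3, 6, "punct")),
        (("A", "B", True, "p2_to_p1"),)),
    Template(
        "domain_prep",
        ("The", "domain", "of", "{A}", "{I}", "with", "{B}", "."),
        ((2, 1, "det"), (2, 4, "prep_of"), (3, 4, "pobj"), (5, 2, "nsubj"),
         (5, 7, "prep_with"), (6, 7, "pobj"), (5, 8, "punct")),
        (("A", "B", True, "p1_to_p2"),)),
    Template(
        "nominalization",
        ("{I:ion}", "of", "{A}", "with", "{B}", "was", "observed", "."),
        ((1, 3, "prep_of"), (2, 3, "pobj"), (1, 5, "prep_with"),
         (4, 5, "pobj"), (7, 1, "nsubjpass"), (7, 6, "auxpass"),
         (7, 8, "punct")),
        (("A", "B", True, "undirected"),)),
    Template(
        "fails_to",
        ("{A}", "fails", "to", "{I}", "with", "{B}", "."),
        ((2, 1, "nsubj"), (2, 4, "xcomp"), (4, 3, "aux"),
         (4, 6, "prep_with"), (5, 6, "pobj"), (2, 7, "punct")),
        (("A", "B", False, "unknown"),)),
    Template(
        "no_between",
        ("There", "is", "no", "{I:ion}", "between", "{A}", "and", "{B}", "."),
        ((2, 1, "expl"), (2, 4, "nsubj"), (4, 3, "det"),
         (4, 6, "prep_between"), (5, 6, "pobj"), (6, 8, "conj_and"),
         (6, 7, "cc"), (2, 9, "punct")),
        (("A", "B", False, "unknown"),)),
    Template(
        "coordination_distractor",
        ("{A}", "{I}", "{B}", ",", "and", "{C}", "was", "purified", "."),
        ((2, 1, "nsubj"), (2, 3, "dobj"), (2, 4, "punct"), (2, 5, "cc"),
         (2, 8, "conj_and"), (8, 6, "nsubjpass"), (8, 7, "auxpass"),
         (8, 9, "punct")),
        (("A", "B", True, "p1_to_p2"),
         ("A", "C", False, "unknown"),
         ("B", "C", False, "unknown"))),
    Template(
        "relative_clause",
        ("{A}", ",", "which", "{I}", "{B}", ",", "was", "studied", "."),
        ((8, 1, "nsubjpass"), (1, 4, "rcmod"), (4, 3, "nsubj"),
         (4, 5, "dobj"), (1, 2, "punct"), (1, 6, "punct"),
         (8, 7, "auxpass"), (8, 9, "punct")),
        (("A", "B", True, "p1_to_p2"),)),
    Template(
        "complement_clause",
        ("{A}", "reported", "that", "{B}", "{I}", "with", "{C}", "."),
        ((2, 1, "nsubj"), (2, 5, "ccomp"), (5, 3, "complm"),
         (5, 4, "nsubj"), (5, 7, "prep_with"), (6, 7, "pobj"),
         (2, 8, "punct")),
        (("A", "B", False, "unknown"),
         ("A", "C", False, "unknown"),
         ("B", "C", True, "p1_to_p2"))),
    Template(
        "dobj_compound",
        ("{A}", "{I}", "the", "{B}", "protein", "."),
        ((2, 1, "nsubj"), (2, 5, "dobj"), (5, 3, "det"), (5, 4, "nn"),
         (2, 6, "punct")),
        (("A", "B", True, "p1_to_p2"),)),
)


# ---------------------------------------------------------------------------
# Generator


@dataclass
class GeneratorConfig:
    """Conditions for a synthetic corpus.

    ``true_fraction`` is the target fraction of gold-true triplets among
    all generated candidates (achieved by mixing true-bearing and
    negative templates; with this template set it is attainable up to
    ~0.69).  ``pattern_noise`` flips each gold label independently,
    emulating annotation inconsistency.
    """

    n_sentences: int = 200
    templates: tuple[Template, ...] = DEFAULT_TEMPLATES
    true_fraction: float = 0.25
    pattern_noise: float = 0.0
    protein_vocab_size: int = 50
    seed: int = 0
    interaction_lemmas: Optional[tuple[str, ...]] = None  # default: whole lexicon

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_fraction <= 1.0):
            raise ValueError("true_fraction must be in [0, 1]")
        if not (0.0 <= self.pattern_noise <= 1.0):
            raise ValueError("pattern_noise must be in [0, 1]")
        if not self.templates:
            raise ValueError("template list must be non-empty")
        if self.n_sentences < 0:
            raise ValueError("n_sentences must be non-negative")


def _positive_share(cfg: GeneratorConfig) -> float:
    """Probability of drawing a true-bearing template so that the expected
    gold-true triplet fraction matches cfg.true_fraction."""
    pos = [t for t in cfg.templates if t.n_true > 0]
    neg = [t for t in cfg.templates if t.n_true == 0]
    if not pos:
        return 0.0
    if not neg:
        return 1.0
    f = cfg.true_fraction
    tbar = sum(t.n_true for t in pos) / len(pos)
    cbar_p = sum(t.n_candidates for t in pos) / len(pos)
    cbar_n = sum(t.n_candidates for t in neg) / len(neg)
    denom = tbar - f * (cbar_p - cbar_n)
    if denom <= 0:
        return 1.0
    return min(1.0, max(0.0, f * cbar_n / denom))


def instantiate_template(tpl: Template, sentence_id: str,
                         protein_names: Sequence[str], iword_lemma: str,
                         label_flips: Optional[Sequence[bool]] = None
                         ) -> CorpusSentence:
    """Build one sentence by filling a template's slots.

    ``protein_names`` map onto the template's protein slots in slot-letter
    order and must be pairwise distinct.  ``label_flips`` (one per gold
    triplet) corrupt the template's labels; the uncorrupted label is kept
    in ``latent_labels``.
    """
    slots = tpl.protein_slots
    if len(protein_names) != len(slots):
        raise ValueError(f"template {tpl.name} needs {len(slots)} proteins")
    if len(set(protein_names)) != len(protein_names):
        raise ValueError("protein names must be distinct")
    name_of = dict(zip(slots, protein_names))
    forms: list[str] = []
    lemmas: list[str] = []
    for spec in tpl.tokens:
        if spec.startswith("{I"):
            forms.append(_inflect(iword_lemma, spec))
            lemmas.append(iword_lemma)
        elif spec.startswith("{"):
            forms.append(name_of[spec[1]])
            lemmas.append(name_of[spec[1]])
        else:
            forms.append(spec)
            lemmas.append(spec.lower())
    tokens = [Token(i, f, l) for i, (f, l) in
              enumerate(zip(forms, lemmas), start=1)]
    deps = [TypedDependency(g, d, lab) for g, d, lab in tpl.deps]
    graph = SentenceGraph(sentence_id, " ".join(forms), tokens, deps)
    mentions = []
    mention_of: dict[str, Mention] = {}
    for slot in slots:
        idx = tpl.slot_index(slot)
        m = Mention(sentence_id, idx, idx, "protein", name_of[slot])
        mention_of[slot] = m
        mentions.append(m)
    iw = Mention(sentence_id, tpl.iword_index, tpl.iword_index,
                 "interaction", iword_lemma)
    mentions.append(iw)
    mentions.sort(key=lambda m: m.token_start)
    cs = CorpusSentence(graph, mentions)
    flips = label_flips if label_flips is not None else [False] * len(tpl.gold)
    for i, (se, sl, label, direction) in enumerate(tpl.gold):
        me, ml = mention_of[se], mention_of[sl]
        if me.token_start > ml.token_start:
            me, ml = ml, me
        observed = bool(label) ^ bool(flips[i])
        cs.triplets.append(TripletCandidate(
            sentence_id, me, ml, iw, gold_label=observed,
            gold_direction=direction if observed else
            (direction if label == observed else "unknown")))
        cs.latent_labels[i] = bool(label)
    return cs


def generate_corpus(cfg: GeneratorConfig,
                    lex: Optional[Lexicon] = None) -> list[CorpusSentence]:
    """Generate a labeled synthetic corpus, fully reproducible from seed."""
    if lex is None:
        lex = default_lexicon()
    lemmas = (tuple(sorted(lex.interaction_words))
              if cfg.interaction_lemmas is None else cfg.interaction_lemmas)
    if not lemmas:
        raise ValueError("no interaction lemmas to sample from")
    vocab = [f"PROT{i:04d}" for i in range(1, cfg.protein_vocab_size + 1)]
    rng = np.random.default_rng(cfg.seed)
    pos = [t for t in cfg.templates if t.n_true > 0]
    neg = [t for t in cfg.templates if t.n_true == 0]
    q = _positive_share(cfg)
    out: list[CorpusSentence] = []
    for i in range(cfg.n_sentences):
        if neg and (not pos or rng.random() >= q):
            tpl = neg[rng.integers(len(neg))]
        else:
            tpl = pos[rng.integers(len(pos))]
        names = [vocab[j] for j in
                 rng.choice(len(vocab), size=len(tpl.protein_slots),
                            replace=False)]
        lemma = lemmas[rng.integers(len(lemmas))]
        flips = [bool(rng.random() < cfg.pattern_noise)
                 for _ in range(len(tpl.gold))]
        out.append(instantiate_template(tpl, f"syn-{i:05d}", names, lemma,
                                        flips))
    return out


def duplicate_corpus(corpus: Sequence[CorpusSentence],
                     suffix: str = "-dup") -> list[CorpusSentence]:
    """A copy of every sentence under a new id, appended to the corpus.

    Guarantees every pattern occurs at least twice with consistent labels
    (useful for studying the no-singleton regime of leave-one-out)."""
    import copy
    out = list(corpus)
    for cs in corpus:
        sid = cs.sentence_id + suffix
        g = SentenceGraph(sid, cs.graph.text, list(cs.graph.tokens),
                          list(cs.graph.dependencies))
        mentions = [Mention(sid, m.token_start, m.token_end, m.kind, m.norm)
                    for m in cs.mentions]
        by_span = {(m.token_start, m.token_end): m for m in mentions}
        dup = CorpusSentence(g, mentions,
                             latent_labels=dict(cs.latent_labels))
        for t in cs.triplets:
            dup.triplets.append(TripletCandidate(
                sid,
                by_span[(t.p1.token_start, t.p1.token_end)],
                by_span[(t.p2.token_start, t.p2.token_end)],
                by_span[(t.iword.token_start, t.iword.token_end)],
                t.gold_label, t.gold_direction))
        out.append(dup)
    return out


# ---------------------------------------------------------------------------
# Built-in fixtures


def _sentence(sid: str, rows: list[tuple[str, str]],
              deps: list[tuple[int, int, str]], text: str = ""
              ) -> SentenceGraph:
    tokens = [Token(i, form, lemma) for i, (form, lemma) in
              enumerate(rows, start=1)]
    return SentenceGraph(sid, text or " ".join(r[0] for r in rows), tokens,
                         [TypedDependency(*d) for d in deps])


def _fig2_sentence() -> CorpusSentence:
    """"The first PDZ domain of PAR3alpha is considered to interact with
    PAR6." — edge set consistent with the published dependency figure
    (nsubj(interact, domain); nn/amod/det on "domain"; collapsed
    prep_of / prep_with), completed with conventional Stanford-style
    edges for the copular/clausal tokens."""
    sid = "fig2"
    rows = [("The", "the"), ("first", "first"), ("PDZ", "pdz"),
            ("domain", "domain"), ("of", "of"), ("PAR3alpha", "PAR3alpha"),
            ("is", "be"), ("considered", "consider"), ("to", "to"),
            ("interact", "interact"), ("with", "with"), ("PAR6", "PAR6"),
            (".", ".")]
    deps = [(4, 1, "det"), (4, 2, "amod"), (4, 3, "nn"), (4, 6, "prep_of"),
            (5, 6, "pobj"), (10, 4, "nsubj"), (8, 4, "nsubjpass"),
            (8, 7, "auxpass"), (8, 10, "xcomp"), (10, 9, "aux"),
            (10, 12, "prep_with"), (11, 12, "pobj"), (8, 13, "punct")]
    g = _sentence(sid, rows, deps)
    mentions = [Mention(sid, 6, 6, "protein", "PAR3alpha"),
                Mention(sid, 10, 10, "interaction", "interact"),
                Mention(sid, 12, 12, "protein", "PAR6")]
    cs = CorpusSentence(g, mentions)
    cs.triplets.append(TripletCandidate(sid, mentions[0], mentions[2],
                                        mentions[1], gold_label=True,
                                        gold_direction="undirected"))
    return cs


def _worked_example(sid: str, first_word: str, iword_form: str,
                    iword_lemma: str, label: Optional[bool]
                    ) -> CorpusSentence:
    rows = [(first_word, first_word), ("of", "of"), ("P1", "P1"),
            (iword_form, iword_lemma), ("with", "with"), ("P2", "P2")]
    deps = [(1, 3, "prep_of"), (2, 3, "pobj"), (4, 1, "nsubj"),
            (4, 6, "prep_with"), (5, 6, "pobj")]
    g = _sentence(sid, rows, deps)
    mentions = [Mention(sid, 3, 3, "protein", "P1"),
                Mention(sid, 4, 4, "interaction", iword_lemma),
                Mention(sid, 6, 6, "protein", "P2")]
    cs = CorpusSentence(g, mentions)
    cs.triplets.append(TripletCandidate(sid, mentions[0], mentions[2],
                                        mentions[1], gold_label=label,
                                        gold_direction="p1_to_p2"
                                        if label else "unknown"))
    return cs


def _fig1_sentence() -> CorpusSentence:
    """Synthetic stand-in sentence carrying the documented mention list:
    protein mentions PAHX, FKBP52, FKBP12, FKBP52 (a "FKBP12-like" token
    is present but is not a protein mention) and the single interaction
    word "interacts" — so candidate enumeration yields exactly five
    triplets.  The sentence text itself is constructed, not quoted."""
    sid = "fig1"
    rows = [("PAHX", "PAHX"), ("interacts", "interact"), ("with", "with"),
            ("FKBP52", "FKBP52"), (",", ","), ("a", "a"),
            ("ligand", "ligand"), ("related", "relate"), ("to", "to"),
            ("FKBP12", "FKBP12"), (",", ","), ("but", "but"),
            ("not", "not"), ("with", "with"), ("the", "the"),
            ("FKBP12-like", "FKBP12-like"), ("protein", "protein"),
            ("FKBP52", "FKBP52"), (".", ".")]
    deps = [(2, 1, "nsubj"), (2, 4, "prep_with"), (3, 4, "pobj"),
            (4, 5, "punct"), (4, 7, "appos"), (7, 6, "det"),
            (7, 8, "partmod"), (8, 10, "prep_to"), (9, 10, "pobj"),
            (2, 11, "punct"), (2, 12, "cc"), (2, 13, "neg"),
            (2, 18, "prep_with"), (14, 18, "pobj"), (18, 15, "det"),
            (18, 16, "amod"), (18, 17, "nn"), (2, 19, "punct")]
    g = _sentence(sid, rows, deps)
    mentions = [Mention(sid, 1, 1, "protein", "PAHX"),
                Mention(sid, 2, 2, "interaction", "interact"),
                Mention(sid, 4, 4, "protein", "FKBP52"),
                Mention(sid, 10, 10, "protein", "FKBP12"),
                Mention(sid, 18, 18, "protein", "FKBP52")]
    return CorpusSentence(g, mentions)


def builtin_fixtures() -> list[CorpusSentence]:
    """The worked-example corpus shipped with the package.

    Contents: the PAR3alpha/PAR6 dependency-figure sentence; the
    "domain of P1 interact with P2" training sentence (gold true); probe
    sentences "motif of P1 interact with P2" and "motif of P1 associates
    with P2" with structurally identical skeletons (gold unknown); and
    the five-triplet mention-list sentence.
    """
    return [
        _fig2_sentence(),
        _worked_example("train-domain", "domain", "interact", "interact",
                        True),
        _worked_example("probe-motif-interact", "motif", "interact",
                        "interact", None),
        _worked_example("probe-motif-associate", "motif", "associates",
                        "associate", None),
        _fig1_sentence(),
    ]
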