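"""Pattern-probability model and the decision-tree cascade.

Training assigns every observed pattern key, at every generalization
level, the probability that a triplet carrying it is a true interaction:
the proportion of gold-true triplets among all training triplets with
that key.  Direction tallies (which protein acts on which) are kept from
the gold annotations of the true triplets.

Prediction walks the cascade: levels are tried in order and the FIRST
level whose key exists in the model supplies the probability (a match at
a specific level stops descent even when its probability is low; a
``fall_through`` switch relaxes this for experimentation).  A triplet
matching no level gets probability 0 and is classified false.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .candidates import TripletCandidate
from .core import PatternGraph, extract_grgt, pattern_keys
from .depgraph import LabelHierarchy, SentenceGraph
from .lexicon import Lexicon

__all__ = [
    "PatternEntry",
    "PatternModel",
    "Prediction",
    "train_model",
    "predict_triplet",
]

log = logging.getLogger(__name__)

DEFAULT_LEVELS: tuple[int, ...] = (1, 2, 3)
MODEL_FORMAT_VERSION = 1


@dataclass
class PatternEntry:
    """Counts and probability for one canonical pattern key."""

    key: str
    n_true: int = 0
    n_total: int = 0
    direction_tally: Counter = field(default_factory=Counter)

    @property
    def probability(self) -> float:
        if self.n_total == 0:
            raise ValueError(f"entry {self.key!r} has no observations")
        return self.n_true / self.n_total

    def majority_direction(self) -> str:
        """Most common gold direction among true triplets; ties or no
        annotated direction give ``unknown``."""
        tally = {d: c for d, c in self.direction_tally.items()
                 if d != "unknown" and c > 0}
        if not tally:
            return "unknown"
        best = max(tally.values())
        winners = [d for d, c in tally.items() if c == best]
        return winners[0] if len(winners) == 1 else "unknown"


@dataclass
class PatternModel:
    """Per-level mapping from canonical key to :class:`PatternEntry`."""

    levels: tuple[int, ...] = DEFAULT_LEVELS
    entries: dict[int, dict[str, PatternEntry]] = field(default_factory=dict)
    lexicon_fingerprint: str = ""
    n_trained: int = 0
    n_unextractable: int = 0
    reduce_steps: int = 1
    directed: bool = True

    def __post_init__(self) -> None:
        for lv in self.levels:
            self.entries.setdefault(lv, {})

    def entry(self, level: int, key: str) -> Optional[PatternEntry]:
        return self.entries.get(level, {}).get(key)

    def add_observation(self, keys: dict[int, str], gold_label: bool,
                        gold_direction: str = "unknown") -> None:
        for lv in self.levels:
            key = keys[lv]
            e = self.entries[lv].setdefault(key, PatternEntry(key))
            e.n_total += 1
            if gold_label:
                e.n_true += 1
                e.direction_tally[gold_direction] += 1
        self.n_trained += 1

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Versioned flat text format, bit-exact across runs/platforms."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"GRGT-MODEL\tv{MODEL_FORMAT_VERSION}\n")
            fh.write("levels\t" + ",".join(map(str, self.levels)) + "\n")
            fh.write(f"lexicon\t{self.lexicon_fingerprint}\n")
            fh.write(f"trained\t{self.n_trained}\t"
                     f"unextractable\t{self.n_unextractable}\n")
            fh.write(f"options\treduce_steps={self.reduce_steps}\t"
                     f"directed={int(self.directed)}\n")
            for lv in self.levels:
                for key in sorted(self.entries[lv]):
                    e = self.entries[lv][key]
                    dirs = ";".join(f"{d}={c}" for d, c in
                                    sorted(e.direction_tally.items()) if c)
                    fh.write(f"{lv}\t{e.n_true}\t{e.n_total}\t{dirs}\t{key}\n")

    @classmethod
    def load(cls, path: str | Path) -> "PatternModel":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "GRGT-MODEL":
                raise ValueError(f"{path}: not a GRGT model file")
            if header[1] != f"v{MODEL_FORMAT_VERSION}":
                raise ValueError(f"{path}: unsupported version {header[1]}")
            levels = tuple(int(x) for x in
                           fh.readline().rstrip("\n").split("\t")[1].split(","))
            fingerprint = fh.readline().rstrip("\n").split("\t")[1]
            counts = fh.readline().rstrip("\n").split("\t")
            opts = dict(kv.split("=") for kv in
                        fh.readline().rstrip("\n").split("\t")[1:])
            m = cls(levels=levels, lexicon_fingerprint=fingerprint,
                    n_trained=int(counts[1]), n_unextractable=int(counts[3]),
                    reduce_steps=int(opts["reduce_steps"]),
                    directed=bool(int(opts["directed"])))
            for line in fh:
                lv_s, n_true, n_total, dirs, key = \
                    line.rstrip("\n").split("\t", 4)
                tally = Counter()
                if dirs:
                    for kv in dirs.split(";"):
                        d, c = kv.split("=")
                        tally[d] = int(c)
                m.entries[int(lv_s)][key] = PatternEntry(
                    key, int(n_true), int(n_total), tally)
        return m


@dataclass
class Prediction:
    """Cascade outcome for one triplet."""

    triplet: TripletCandidate
    matched_level: Optional[int]
    probability: float
    predicted_label: bool
    predicted_direction: str = "unknown"

    def __post_init__(self) -> None:
        if self.matched_level is None:
            assert self.probability == 0.0 and not self.predicted_label


def train_model(corpus: Iterable[tuple[SentenceGraph, TripletCandidate]],
                levels: Sequence[int] = DEFAULT_LEVELS,
                lex: Optional[Lexicon] = None,
                hierarchy: Optional[LabelHierarchy] = None,
                reduce_steps: int = 1,
                directed: bool = True) -> PatternModel:
    """Train the pattern-probability model from labeled triplets.

    Every triplet must carry a gold label.  Triplets whose GRGT cannot be
    extracted (disconnected parse) are counted and logged but contribute
    no entries.  An empty corpus yields a valid empty model.
    """
    from .lexicon import default_lexicon
    if lex is None:
        lex = default_lexicon()
    m = PatternModel(levels=tuple(levels),
                     lexicon_fingerprint=lex.fingerprint(),
                     reduce_steps=reduce_steps, directed=directed)
    for g, t in corpus:
        if t.gold_label is None:
            raise ValueError(
                f"unlabeled triplet in training corpus: sentence "
                f"{t.sentence_id}, proteins {t.p1.norm}/{t.p2.norm}, "
                f"word {t.iword.norm}")
        p = extract_grgt(g, t)
        if p is None:
            m.n_unextractable += 1
            log.warning("unextractable GRGT for %s (%s, %s, %s); excluded",
                        t.sentence_id, t.p1.norm, t.iword.norm, t.p2.norm)
            continue
        keys = pattern_keys(p, m.levels, lex, hierarchy, reduce_steps,
                            directed)
        m.add_observation(keys, t.gold_label, t.gold_direction)
    return m


def predict_triplet(m: PatternModel, g: SentenceGraph, t: TripletCandidate,
                    lex: Lexicon,
                    threshold: float = 0.5,
                    hierarchy: Optional[LabelHierarchy] = None,
                    fall_through: bool = False,
                    check_lexicon: bool = True) -> Prediction:
    """Classify one triplet through the level cascade.

    The first level (in ``m.levels`` order) whose key exists in the model
    supplies the probability and stops the cascade; with ``fall_through``
    a match below ``threshold`` keeps descending and the first match is
    used only if nothing later clears the threshold.  No match at any
    level means probability 0 and a false label.
    """
    if check_lexicon and m.lexicon_fingerprint and \
            m.lexicon_fingerprint != lex.fingerprint():
        raise ValueError(
            "lexicon fingerprint mismatch: the model was trained with a "
            "different dictionary (pass check_lexicon=False to override)")
    p = extract_grgt(g, t)
    if p is None:
        warnings.warn(f"unextractable GRGT for triplet in {t.sentence_id}; "
                      "classified false", stacklevel=2)
        return Prediction(t, None, 0.0, False)
    first_match: Optional[tuple[int, PatternEntry]] = None
    for lv in m.levels:
        key = pattern_keys(p, [lv], lex, hierarchy, m.reduce_steps,
                           m.directed)[lv]
        e = m.entry(lv, key)
        if e is None:
            continue
        if first_match is None:
            first_match = (lv, e)
        if not fall_through or e.probability >= threshold:
            first_match = (lv, e)
            break
    if first_match is None:
        return Prediction(t, None, 0.0, False)
    lv, e = first_match
    prob = e.probability
    return Prediction(t, lv, prob, prob >= threshold,
                      e.majority_direction())
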