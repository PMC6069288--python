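"""Leave-one-out evaluation, precision/recall/F1, and pattern statistics.

Leave-one-out holds out one unit at a time — by default a whole sentence,
so that triplets sharing a parse can never vouch for each other — trains
the pattern model on the remainder, and predicts the held-out triplets.
Because training is pure counting over precomputed canonical keys, the
held-out model is obtained by subtracting the unit's own counts from the
global tallies rather than retraining from scratch.

Direction accuracy (agent protein identified correctly among true
positives with annotated gold direction) is reported separately and never
folded into precision/recall/F1.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .corpus import CorpusSentence
from .core import extract_grgt, pattern_keys
from .depgraph import LabelHierarchy
from .lexicon import Lexicon
from .model import DEFAULT_LEVELS, PatternEntry, PatternModel

__all__ = [
    "EvalReport",
    "PatternStats",
    "TripletRecord",
    "loo_evaluate",
    "pr_curve",
    "pattern_statistics",
]


@dataclass
class TripletRecord:
    """Per-triplet audit row from an evaluation run."""

    sentence_id: str
    p1: str
    p2: str
    iword: str
    matched_level: Optional[int]
    probability: float
    gold_label: bool
    predicted_label: bool
    predicted_direction: str = "unknown"
    gold_direction: str = "unknown"


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    pr_curve: list[tuple[float, float, float]]
    per_level_match_counts: dict[int, int]
    records: list[TripletRecord] = field(default_factory=list)
    direction_accuracy: Optional[float] = None

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def summary(self) -> str:
        lines = [
            f"evaluated triplets: {self.n_evaluated}",
            f"tp={self.tp} fp={self.fp} tn={self.tn} fn={self.fn}",
            f"precision={self.precision:.4f} recall={self.recall:.4f} "
            f"f1={self.f1:.4f}",
            "matches per level: " + ", ".join(
                f"L{lv}={c}" for lv, c in
                sorted(self.per_level_match_counts.items())),
        ]
        if self.direction_accuracy is not None:
            lines.append(f"direction accuracy (TP with gold direction): "
                         f"{self.direction_accuracy:.4f}")
        return "\n".join(lines)


@dataclass
class PatternStats:
    """Coverage statistics over level-1 patterns of a trained model."""

    n_patterns: int
    n_valid_patterns: int  # keys occurring at least twice
    triplets_per_valid_pattern: float


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


def pr_curve(predictions: Sequence[tuple[float, bool]]
             ) -> list[tuple[float, float, float]]:
    """Precision-recall points from (probability, gold_label) pairs.

    A triplet is predicted true at threshold t iff its probability is both
    >= t and > 0 (unmatched triplets, probability exactly 0, are
    predicted false at every threshold).  One point per distinct positive
    probability plus endpoints at thresholds 0 and 1; precision at an
    empty positive set is 1 by convention.  Recall is non-increasing in
    the threshold.
    """
    if not predictions:
        raise ValueError("no predictions")
    n_true = sum(1 for _, g in predictions if g)
    if n_true == 0:
        raise ValueError("pr_curve requires at least one gold-true item")
    thresholds = sorted({p for p, _ in predictions if p > 0})
    ts = [0.0] + thresholds
    if not thresholds or thresholds[-1] < 1.0:
        ts.append(1.0)
    points = []
    for t in ts:
        tp = sum(1 for p, g in predictions if g and p > 0 and p >= t)
        fp = sum(1 for p, g in predictions if not g and p > 0 and p >= t)
        precision = tp / (tp + fp) if tp + fp > 0 else 1.0
        recall = tp / n_true
        points.append((t, precision, recall))
    return points


def pattern_statistics(m: PatternModel, level: int = 1) -> PatternStats:
    """Distinct patterns, patterns occurring at least twice ("valid"),
    and mean occurrences among the valid ones."""
    entries = m.entries.get(level, {})
    totals = [e.n_total for e in entries.values()]
    valid = [c for c in totals if c >= 2]
    mean = sum(valid) / len(valid) if valid else 0.0
    return PatternStats(len(totals), len(valid), mean)


# ---------------------------------------------------------------------------
# Leave-one-out


def _index_corpus(corpus: Sequence[CorpusSentence],
                  levels: Sequence[int], lex: Lexicon,
                  hierarchy: Optional[LabelHierarchy],
                  reduce_steps: int, directed: bool):
    """Precompute canonical keys for every triplet once."""
    indexed = []  # (sent_pos, triplet, keys-or-None)
    for pos, cs in enumerate(corpus):
        for t in cs.triplets:
            if t.gold_label is None:
                raise ValueError(
                    f"unlabeled triplet in sentence {cs.sentence_id}")
            p = extract_grgt(cs.graph, t)
            keys = None if p is None else pattern_keys(
                p, levels, lex, hierarchy, reduce_steps, directed)
            indexed.append((pos, t, keys))
    return indexed


def loo_evaluate(corpus: Sequence[CorpusSentence],
                 levels: Sequence[int] = DEFAULT_LEVELS,
                 lex: Optional[Lexicon] = None,
                 threshold: float = 0.5,
                 unit: str = "sentence",
                 hierarchy: Optional[LabelHierarchy] = None,
                 reduce_steps: int = 1,
                 directed: bool = True) -> EvalReport:
    """Leave-one-out classification over a fully labeled corpus.

    ``unit`` is ``"sentence"`` (default: all triplets of the held-out
    sentence are predicted by a model trained on the other sentences) or
    ``"triplet"``.  The PR curve sweeps the threshold over all observed
    probabilities of the leave-one-out predictions.
    """
    if unit not in ("sentence", "triplet"):
        raise ValueError(f"unknown LOO unit {unit!r}")
    if lex is None:
        from .lexicon import default_lexicon
        lex = default_lexicon()
    levels = tuple(levels)
    indexed = _index_corpus(corpus, levels, lex, hierarchy, reduce_steps,
                            directed)
    n_units = len(corpus) if unit == "sentence" else len(indexed)
    if n_units < 2:
        raise ValueError(f"leave-one-out needs at least 2 units, "
                         f"got {n_units}")

    # global tallies: level -> key -> [n_true, n_total, Counter(directions)]
    tallies: dict[int, dict[str, list]] = {lv: {} for lv in levels}
    for _, t, keys in indexed:
        if keys is None:
            continue
        for lv in levels:
            rec = tallies[lv].setdefault(keys[lv], [0, 0, Counter()])
            rec[1] += 1
            if t.gold_label:
                rec[0] += 1
                rec[2][t.gold_direction] += 1

    def unit_id(item):
        pos, t, _ = item
        return pos if unit == "sentence" else id(t)

    groups: dict = defaultdict(list)
    for item in indexed:
        groups[unit_id(item)].append(item)

    tp = fp = tn = fn = 0
    per_level: Counter = Counter()
    curve_input: list[tuple[float, bool]] = []
    records: list[TripletRecord] = []
    dir_hits = dir_total = 0

    for held in groups.values():
        # subtract the held-out unit's contributions
        for _, t, keys in held:
            if keys is None:
                continue
            for lv in levels:
                rec = tallies[lv][keys[lv]]
                rec[1] -= 1
                if t.gold_label:
                    rec[0] -= 1
                    rec[2][t.gold_direction] -= 1
        for _, t, keys in held:
            matched_level = None
            prob = 0.0
            pred_dir = "unknown"
            if keys is not None:
                for lv in levels:
                    rec = tallies[lv].get(keys[lv])
                    if rec is not None and rec[1] > 0:
                        matched_level = lv
                        prob = rec[0] / rec[1]
                        entry = PatternEntry(keys[lv], rec[0], rec[1],
                                             Counter(rec[2]))
                        pred_dir = entry.majority_direction()
                        break
            predicted = prob >= threshold and matched_level is not None
            gold = bool(t.gold_label)
            if predicted and gold:
                tp += 1
                if t.gold_direction != "unknown" and pred_dir != "unknown":
                    dir_total += 1
                    dir_hits += int(pred_dir == t.gold_direction)
            elif predicted:
                fp += 1
            elif gold:
                fn += 1
            else:
                tn += 1
            if matched_level is not None:
                per_level[matched_level] += 1
            curve_input.append((prob, gold))
            records.append(TripletRecord(
                t.sentence_id, t.p1.norm, t.p2.norm, t.iword.norm,
                matched_level, prob, gold, predicted, pred_dir,
                t.gold_direction))
        # restore
        for _, t, keys in held:
            if keys is None:
                continue
            for lv in levels:
                rec = tallies[lv][keys[lv]]
                rec[1] += 1
                if t.gold_label:
                    rec[0] += 1
                    rec[2][t.gold_direction] += 1

    precision, recall, f1 = _prf(tp, fp, fn)
    curve = (pr_curve(curve_input)
             if any(g for _, g in curve_input) else [])
    return EvalReport(precision, recall, f1, tp, fp, tn, fn, curve,
                      dict(per_level), records,
                      dir_hits / dir_total if dir_total else None)
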