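"""Candidate PPI-triplet enumeration.

A candidate triplet is an unordered pair of protein mentions with
*distinct* normalized names plus one interaction-word mention from the
same sentence.  Pairing two mentions of the same protein name is never a
candidate (a protein interacting with itself via the same name string is
not an extractable assertion, and only this rule reproduces the standard
count: 4 mentions with one duplicated name and one interaction word give
C(4,2) - 1 = 5 triplets).  Directionality is a predicted attribute of a
triplet, not an enumeration axis: the earlier mention is always ``p1``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .lexicon import Mention

__all__ = ["TripletCandidate", "enumerate_triplets", "DIRECTIONS"]

DIRECTIONS = ("p1_to_p2", "p2_to_p1", "undirected", "unknown")


@dataclass(frozen=True)
class TripletCandidate:
    """Two protein mentions (sentence order) plus an interaction mention."""

    sentence_id: str
    p1: Mention
    p2: Mention
    iword: Mention
    gold_label: Optional[bool] = None  # None = unknown
    gold_direction: str = "unknown"

    def __post_init__(self) -> None:
        if not (self.p1.token_start < self.p2.token_start):
            raise ValueError("p1 must precede p2 in the sentence")
        if self.p1.norm == self.p2.norm:
            raise ValueError(
                f"identical protein names never pair: {self.p1.norm}")
        if not (self.p1.sentence_id == self.p2.sentence_id
                == self.iword.sentence_id == self.sentence_id):
            raise ValueError("triplet mentions must share one sentence")
        if self.gold_direction not in DIRECTIONS:
            raise ValueError(f"bad direction {self.gold_direction!r}")

    def with_label(self, label: Optional[bool],
                   direction: str = "unknown") -> "TripletCandidate":
        return replace(self, gold_label=label, gold_direction=direction)


def enumerate_triplets(mentions: Iterable[Mention]) -> list[TripletCandidate]:
    """All candidate triplets from one sentence's mentions.

    One candidate per (unordered protein-mention pair with distinct norms)
    x (interaction mention); deterministic order by (p1 position,
    p2 position, interaction-word position).  For n protein mentions and
    m interaction mentions the count is ``(C(n,2) - #same-norm pairs) * m``.
    """
    mentions = list(mentions)
    if not mentions:
        return []
    sids = {m.sentence_id for m in mentions}
    if len(sids) != 1:
        raise ValueError(f"mentions span multiple sentences: {sorted(sids)}")
    sid = sids.pop()
    proteins = sorted((m for m in mentions if m.kind == "protein"),
                      key=lambda m: m.token_start)
    iwords = sorted((m for m in mentions if m.kind == "interaction"),
                    key=lambda m: m.token_start)
    out: list[TripletCandidate] = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            if proteins[i].norm == proteins[j].norm:
                continue
            for w in iwords:
                out.append(TripletCandidate(sid, proteins[i], proteins[j], w))
    return out
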