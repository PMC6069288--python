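"""JSON-lines corpus: one sentence per line with parse, mentions, triplets.

Record schema::

    {"sentence_id": ..., "text": ...,
     "tokens": [{"index", "form", "lemma"}],
     "deps":   [{"gov", "dep", "label"}],
     "mentions": [{"start", "end", "kind", "norm"}],
     "triplets": [{"p1_span", "p2_span", "iword_span",
                   "label": true|false|null, "direction": ...,
                   "latent_label": true|false (optional; generator provenance)}]}

Round-trip guarantee: writing and re-reading reproduces the structure
token-by-token and edge-by-edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .candidates import TripletCandidate
from .depgraph import (CorpusLoadError, SentenceGraph, graph_from_json_obj,
                       graph_to_json_obj)
from .lexicon import Mention

__all__ = ["CorpusSentence", "read_corpus", "write_corpus"]


@dataclass
class CorpusSentence:
    """One sentence with its parse and (possibly empty) annotations."""

    graph: SentenceGraph
    mentions: list[Mention] = field(default_factory=list)
    triplets: list[TripletCandidate] = field(default_factory=list)
    latent_labels: dict[int, bool] = field(default_factory=dict)
    # latent_labels: triplet list position -> uncorrupted template label
    # (generator provenance; absent for real corpora)

    @property
    def sentence_id(self) -> str:
        return self.graph.sentence_id


def _mention_obj(m: Mention) -> dict:
    return {"start": m.token_start, "end": m.token_end,
            "kind": m.kind, "norm": m.norm}


def _mention_from(obj: dict, sid: str) -> Mention:
    return Mention(sid, obj["start"], obj["end"], obj["kind"], obj["norm"])


def _span_of(m: Mention) -> list[int]:
    return [m.token_start, m.token_end]


def sentence_to_obj(cs: CorpusSentence) -> dict:
    obj = graph_to_json_obj(cs.graph)
    obj["mentions"] = [_mention_obj(m) for m in cs.mentions]
    trips = []
    for i, t in enumerate(cs.triplets):
        rec = {"p1_span": _span_of(t.p1), "p2_span": _span_of(t.p2),
               "iword_span": _span_of(t.iword), "label": t.gold_label,
               "direction": t.gold_direction}
        if i in cs.latent_labels:
            rec["latent_label"] = cs.latent_labels[i]
        trips.append(rec)
    obj["triplets"] = trips
    return obj


def sentence_from_obj(obj: dict) -> CorpusSentence:
    g = graph_from_json_obj(obj)
    sid = g.sentence_id
    mentions = [_mention_from(m, sid) for m in obj.get("mentions", [])]
    by_span = {(m.token_start, m.token_end): m for m in mentions}

    def resolve(span: list[int], kind: str) -> Mention:
        m = by_span.get(tuple(span))
        if m is None or m.kind != kind:
            raise CorpusLoadError(
                f"sentence {sid}: triplet references span {span} with no "
                f"matching {kind} mention")
        return m

    cs = CorpusSentence(g, mentions)
    for i, rec in enumerate(obj.get("triplets", [])):
        t = TripletCandidate(
            sid,
            resolve(rec["p1_span"], "protein"),
            resolve(rec["p2_span"], "protein"),
            resolve(rec["iword_span"], "interaction"),
            gold_label=rec.get("label"),
            gold_direction=rec.get("direction", "unknown"))
        cs.triplets.append(t)
        if "latent_label" in rec:
            cs.latent_labels[i] = rec["latent_label"]
    return cs


def read_corpus(path: str | Path) -> list[CorpusSentence]:
    """Read a JSON-lines corpus; errors name the offending line."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusLoadError(
                    f"{path} line {line_no}: invalid JSON: {exc}") from exc
            try:
                out.append(sentence_from_obj(obj))
            except (CorpusLoadError, ValueError) as exc:
                raise CorpusLoadError(
                    f"{path} line {line_no}: {exc}") from exc
    return out


def write_corpus(sentences: Iterable[CorpusSentence],
                 path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for cs in sentences:
            fh.write(json.dumps(sentence_to_obj(cs), sort_keys=True) + "\n")
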