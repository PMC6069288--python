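"""Sentence dependency graphs and the typed-dependency label hierarchy.

A parsed sentence is represented as a :class:`SentenceGraph`: tokens plus
typed-dependency edges (Stanford-style labels such as ``nsubj``, ``nn``,
``prep_of``).  Edges are stored directed (governor -> dependent) but are
traversed as an undirected graph when paths are computed, because
grammatical paths between content words routinely cross edges against
their stored direction.

The module also exposes the hierarchy of dependency labels rooted at
``dep`` (dep -> arg -> subj -> nsubj, ...), which is used to coarsen edge
labels when patterns are generalized.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "Token",
    "TypedDependency",
    "SentenceGraph",
    "LabelHierarchy",
    "GraphDiagnostics",
    "CorpusLoadError",
    "read_parsed_corpus",
    "read_conllu",
    "reduce_label",
    "validate_graph",
    "map_ud_label",
    "DEFAULT_UD_LABEL_MAP",
]


class CorpusLoadError(ValueError):
    """Raised when a corpus file violates the sentence-graph invariants."""


@dataclass(frozen=True)
class Token:
    """One token of a sentence; ``index`` is 1-based sentence position."""

    index: int
    form: str
    lemma: str = ""

    def __post_init__(self) -> None:
        if not self.form:
            raise ValueError(f"token {self.index}: empty form")
        if not self.lemma:
            object.__setattr__(self, "lemma", self.form)


@dataclass(frozen=True)
class TypedDependency:
    """A typed grammatical relation: governor -> dependent with a label."""

    governor: int
    dependent: int
    label: str

    def __post_init__(self) -> None:
        if self.governor == self.dependent:
            raise ValueError(f"self-loop dependency on token {self.governor}")
        if not self.label:
            raise ValueError("empty dependency label")


@dataclass
class SentenceGraph:
    """Tokens plus typed-dependency edges of one sentence."""

    sentence_id: str
    text: str
    tokens: list[Token]
    dependencies: list[TypedDependency]

    def __post_init__(self) -> None:
        indices = [t.index for t in self.tokens]
        if indices != list(range(1, len(indices) + 1)):
            raise CorpusLoadError(
                f"sentence {self.sentence_id}: token indices must be 1..n contiguous"
            )
        seen_pairs: set[frozenset[int]] = set()
        n = len(self.tokens)
        for d in self.dependencies:
            if not (1 <= d.governor <= n and 1 <= d.dependent <= n):
                raise CorpusLoadError(
                    f"sentence {self.sentence_id}: dependency {d.label}"
                    f"({d.governor},{d.dependent}) references a missing token"
                )
            pair = frozenset((d.governor, d.dependent))
            if pair in seen_pairs:
                raise CorpusLoadError(
                    f"sentence {self.sentence_id}: duplicate parallel edge on "
                    f"token pair {sorted(pair)}"
                )
            seen_pairs.add(pair)

    def token(self, index: int) -> Token:
        return self.tokens[index - 1]

    def to_networkx(self) -> nx.Graph:
        """Undirected view used for path finding; edge attrs keep the stored
        direction (``gov``/``dep``) and the ``label``."""
        g = nx.Graph()
        g.add_nodes_from(t.index for t in self.tokens)
        for d in self.dependencies:
            g.add_edge(d.governor, d.dependent, label=d.label,
                       gov=d.governor, dep=d.dependent)
        return g


# ---------------------------------------------------------------------------
# Label hierarchy


#: Stanford typed-dependency hierarchy, child -> parent, rooted at ``dep``.
_DEFAULT_PARENTS: dict[str, str] = {
    # top level
    "aux": "dep", "arg": "dep", "cc": "dep", "conj": "dep", "expl": "dep",
    "mod": "dep", "parataxis": "dep", "punct": "dep", "ref": "dep",
    "sdep": "dep",
    # aux
    "auxpass": "aux", "cop": "aux",
    # arg
    "agent": "arg", "comp": "arg", "subj": "arg",
    # comp
    "acomp": "comp", "attr": "comp", "ccomp": "comp", "xcomp": "comp",
    "complm": "comp", "obj": "comp", "mark": "comp", "rel": "comp",
    # obj
    "dobj": "obj", "iobj": "obj", "pobj": "obj",
    # subj
    "nsubj": "subj", "csubj": "subj",
    "nsubjpass": "nsubj", "csubjpass": "csubj",
    # sdep
    "xsubj": "sdep",
    # mod
    "amod": "mod", "advmod": "mod", "advcl": "mod", "appos": "mod",
    "det": "mod", "predet": "mod", "preconj": "mod", "infmod": "mod",
    "partmod": "mod", "mwe": "mod", "neg": "mod", "nn": "mod",
    "npadvmod": "mod", "tmod": "mod", "num": "mod", "number": "mod",
    "prep": "mod", "poss": "mod", "possessive": "mod", "prt": "mod",
    "quantmod": "mod", "rcmod": "mod",
}


@dataclass
class LabelHierarchy:
    """Child -> parent map over dependency labels, rooted at ``dep``.

    Collapsed prepositional labels (``prep_of``, ``prepc_with``, ...) are
    resolved dynamically to ``prep`` (a child of ``mod``), and collapsed
    conjunctions (``conj_and``) to ``conj``, so they need no explicit rows.
    """

    parent_of: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_PARENTS))
    root: str = "dep"

    def parent(self, label: str) -> str | None:
        if label == self.root:
            return None
        if label in self.parent_of:
            return self.parent_of[label]
        if label.startswith("prep_") or label.startswith("prepc_"):
            return "prep"
        if label.startswith("conj_"):
            return "conj"
        return None

    def knows(self, label: str) -> bool:
        return label == self.root or self.parent(label) is not None


def reduce_label(label: str, hierarchy: LabelHierarchy, steps: int) -> str:
    """Coarsen ``label`` by walking up the hierarchy ``steps`` times.

    Walking stops at the root (``dep``); unknown labels are returned
    unchanged with a warning.  Total function:
    ``reduce_label(x, h, a + b) == reduce_label(reduce_label(x, h, a), h, b)``.
    """
    if steps < 0:
        raise ValueError("steps must be non-negative")
    if steps == 0:
        return label
    if not hierarchy.knows(label):
        warnings.warn(f"unknown dependency label {label!r}; kept verbatim",
                      stacklevel=2)
        return label
    current = label
    for _ in range(steps):
        parent = hierarchy.parent(current)
        if parent is None:
            break
        current = parent
    return current


# ---------------------------------------------------------------------------
# Validation


@dataclass
class GraphDiagnostics:
    """Structural findings for one sentence graph (never raises)."""

    sentence_id: str
    isolated_tokens: list[int] = field(default_factory=list)
    components: list[list[int]] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.isolated_tokens and len(self.components) <= 1


def validate_graph(g: SentenceGraph) -> GraphDiagnostics:
    """Report isolated tokens and connectivity of the dependency-bearing
    subgraph.  Diagnostics only; a graph with findings is still usable."""
    nxg = g.to_networkx()
    bearing = {n for n in nxg if nxg.degree(n) > 0}
    isolated = sorted(set(nxg) - bearing)
    comps = []
    if bearing:
        comps = [sorted(c) for c in
                 nx.connected_components(nxg.subgraph(bearing))]
        comps.sort(key=lambda c: c[0])
    return GraphDiagnostics(g.sentence_id, isolated_tokens=isolated,
                            components=comps)


# ---------------------------------------------------------------------------
# Readers


#: Common Universal Dependencies labels mapped onto the Stanford-style
#: labels used throughout this package.
DEFAULT_UD_LABEL_MAP: dict[str, str] = {
    "nsubj:pass": "nsubjpass",
    "csubj:pass": "csubjpass",
    "aux:pass": "auxpass",
    "compound": "nn",
    "obj": "dobj",
    "obl:agent": "agent",
    "acl:relcl": "rcmod",
    "nummod": "num",
    "case": "prep",
    "cc:preconj": "preconj",
    "det:predet": "predet",
    "nmod:poss": "poss",
    "compound:prt": "prt",
}


def map_ud_label(label: str, label_map: Mapping[str, str] | None = None) -> str:
    """Map one (possibly subtyped) UD label to a Stanford-style label.

    ``nmod:of`` / ``obl:with`` become collapsed ``prep_of`` / ``prep_with``;
    ``conj:and`` becomes ``conj_and``; everything else goes through the map
    (or is kept verbatim).
    """
    table = DEFAULT_UD_LABEL_MAP if label_map is None else label_map
    if label in table:
        return table[label]
    base, _, subtype = label.partition(":")
    if subtype:
        if base in ("nmod", "obl"):
            return f"prep_{subtype}"
        if base == "conj":
            return f"conj_{subtype}"
        mapped = table.get(base)
        if mapped is not None:
            return mapped
        return base
    return label


def read_conllu(path: str | Path,
                label_map: Mapping[str, str] | None = None,
                apply_ud_map: bool = True) -> list[SentenceGraph]:
    """Read a 10-column CoNLL-U file into sentence graphs.

    Columns ID, FORM, LEMMA, HEAD, DEPREL are used; multiword-token and
    empty-node lines (IDs containing ``-`` or ``.``) are skipped.  HEAD=0
    (root) contributes no edge.
    """
    path = Path(path)
    sentences: list[SentenceGraph] = []
    tokens: list[Token] = []
    deps: list[TypedDependency] = []
    sent_id = None
    text = ""
    n_sent = 0

    def flush(line_no: int) -> None:
        nonlocal tokens, deps, sent_id, text, n_sent
        if not tokens:
            return
        n_sent += 1
        sid = sent_id or f"{path.name}#{n_sent}"
        try:
            sentences.append(SentenceGraph(sid, text or " ".join(
                t.form for t in tokens), tokens, deps))
        except CorpusLoadError as exc:
            raise CorpusLoadError(f"{path} near line {line_no}: {exc}") from exc
        tokens, deps, sent_id, text = [], [], None, ""

    line_no = 0
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush(line_no)
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                key = key.strip()
                if key == "sent_id":
                    sent_id = value.strip()
                elif key == "text":
                    text = value.strip()
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise CorpusLoadError(
                    f"{path} line {line_no}: expected >= 8 tab-separated "
                    f"columns, got {len(cols)}")
            tok_id = cols[0]
            if "-" in tok_id or "." in tok_id:
                continue
            try:
                idx = int(tok_id)
                head = int(cols[6])
            except ValueError as exc:
                raise CorpusLoadError(
                    f"{path} line {line_no}: non-integer ID or HEAD") from exc
            lemma = cols[2] if cols[2] not in ("", "_") else cols[1]
            tokens.append(Token(idx, cols[1], lemma))
            if head != 0:
                label = cols[7]
                if apply_ud_map:
                    label = map_ud_label(label, label_map)
                elif label_map is not None:
                    label = label_map.get(label, label)
                deps.append(TypedDependency(head, idx, label))
    flush(line_no if tokens else 0)
    return sentences


def read_parsed_corpus(path: str | Path,
                       label_map: Mapping[str, str] | None = None
                       ) -> list[SentenceGraph]:
    """Read dependency parses from CoNLL-U or the JSON-lines corpus format.

    Returns sentence graphs only; mention and triplet annotations in a
    JSON-lines file are read by :func:`grgt.corpus.read_corpus`.
    """
    path = Path(path)
    if path.suffix in (".jsonl", ".json"):
        from . import corpus as _corpus
        return [cs.graph for cs in _corpus.read_corpus(path)]
    return read_conllu(path, label_map=label_map)


def graph_to_json_obj(g: SentenceGraph) -> dict:
    return {
        "sentence_id": g.sentence_id,
        "text": g.text,
        "tokens": [{"index": t.index, "form": t.form, "lemma": t.lemma}
                   for t in g.tokens],
        "deps": [{"gov": d.governor, "dep": d.dependent, "label": d.label}
                 for d in g.dependencies],
    }


def graph_from_json_obj(obj: dict) -> SentenceGraph:
    try:
        tokens = [Token(t["index"], t["form"], t.get("lemma", ""))
                  for t in obj["tokens"]]
        deps = [TypedDependency(d["gov"], d["dep"], d["label"])
                for d in obj.get("deps", [])]
        return SentenceGraph(obj["sentence_id"], obj.get("text", ""),
                             tokens, deps)
    except (KeyError, TypeError, ValueError) as exc:
        raise CorpusLoadError(
            f"malformed sentence record "
            f"{obj.get('sentence_id', '<missing id>')}: {exc}") from exc


def write_conllu(graphs: Iterable[SentenceGraph], path: str | Path) -> None:
    """Write sentence graphs as CoNLL-U (labels kept verbatim).

    A token with no incoming stored edge gets HEAD=0; if a token has more
    than one governor only the first is representable and the rest are
    dropped, so round-tripping is guaranteed only for single-head graphs.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for g in graphs:
            fh.write(f"# sent_id = {g.sentence_id}\n")
            fh.write(f"# text = {g.text}\n")
            head: dict[int, tuple[int, str]] = {}
            for d in g.dependencies:
                head.setdefault(d.dependent, (d.governor, d.label))
            for t in g.tokens:
                h, lab = head.get(t.index, (0, "root"))
                fh.write("\t".join([str(t.index), t.form, t.lemma, "_", "_",
                                    "_", str(h), lab, "_", "_"]) + "\n")
            fh.write("\n")
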