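"""Protein-name and interaction-word dictionaries, and mention tagging.

Interaction words are single words grouped into classes of verbs that can
substitute for one another without changing what the sentence asserts
(e.g. *interact* and *associate* share a group); the group identifier is
what the most general pattern level matches on.  Inflected forms are
reduced to dictionary lemmas by an auditable suffix-strip table rather
than a statistical stemmer.

Mention tagging is dictionary lookup: longest exact match over token
forms, left to right.  A token that merely contains a dictionary name as
a substring (``FKBP12-like``) is never a protein mention.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .depgraph import SentenceGraph

__all__ = [
    "Lexicon",
    "Mention",
    "LexiconError",
    "load_lexicon",
    "default_lexicon",
    "tag_sentence",
    "group_of",
]


class LexiconError(ValueError):
    """Raised for malformed dictionary files (e.g. a lemma in two groups)."""


#: fallback suffix-strip rules (suffix, replacement), applied in order,
#: used when a dictionary file has no [morphemes] section.
DEFAULT_MORPHEME_RULES: list[tuple[str, str]] = [
    ("ies", "y"),
    ("ation", "ate"),
    ("ion", ""),
    ("ing", ""),
    ("ing", "e"),
    ("ed", ""),
    ("ed", "e"),
    ("es", ""),
    ("s", ""),
]


@dataclass(frozen=True)
class Mention:
    """A tagged span: ``token_start``..``token_end`` inclusive, 1-based."""

    sentence_id: str
    token_start: int
    token_end: int
    kind: str  # "protein" | "interaction"
    norm: str  # normalized dictionary name, or interaction lemma

    def __post_init__(self) -> None:
        if self.token_start > self.token_end:
            raise ValueError("mention span reversed")
        if self.kind not in ("protein", "interaction"):
            raise ValueError(f"bad mention kind {self.kind!r}")


@dataclass
class Lexicon:
    """Protein names, interaction lemmas with groups, and morpheme rules."""

    protein_names: set[str] = field(default_factory=set)
    interaction_words: dict[str, str] = field(default_factory=dict)
    morpheme_rules: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_MORPHEME_RULES))

    @property
    def group_count(self) -> int:
        return len(set(self.interaction_words.values()))

    def lemma_of(self, word: str) -> str:
        """Reduce an inflected interaction word to its lemma.

        Dictionary membership decides: the surface form itself, then each
        suffix rule (with final-consonant de-doubling, ``blotted`` ->
        ``blot``).  A word no rule maps into the dictionary falls back to
        the first plausible generic strip so unknown words still get a
        stable lemma for singleton-group matching.
        """
        w = word.lower()
        if w in self.interaction_words:
            return w
        fallback: str | None = None
        for suffix, repl in self.morpheme_rules:
            if not w.endswith(suffix) or len(w) - len(suffix) < 3:
                continue
            stem = w[: len(w) - len(suffix)] + repl
            candidates = [stem]
            if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in "aeiouls":
                candidates.append(stem[:-1])  # de-double: blotted -> blot
            for cand in candidates:
                if cand in self.interaction_words:
                    return cand
            if fallback is None:
                fallback = stem
        return fallback if fallback is not None else w

    def fingerprint(self) -> str:
        """Stable hash of the dictionary content (order-independent)."""
        h = hashlib.sha256()
        for name in sorted(self.protein_names):
            h.update(b"P" + name.encode() + b"\n")
        for lemma in sorted(self.interaction_words):
            h.update(f"I{lemma}\t{self.interaction_words[lemma]}\n".encode())
        for suffix, repl in self.morpheme_rules:
            h.update(f"M{suffix}\t{repl}\n".encode())
        return h.hexdigest()[:16]


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a sectioned dictionary file.

    Format: ``[proteins]`` one name per line; ``[interactions]`` lines of
    ``lemma<TAB>group_id``; ``[morphemes]`` lines of ``suffix<TAB>replacement``
    (replacement may be empty).  ``#`` starts a comment.  A lemma assigned
    to two different groups is an error.
    """
    lex = Lexicon(morpheme_rules=[])
    section = None
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].rstrip()
            if not line.strip():
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1].strip().lower()
                if section not in ("proteins", "interactions", "morphemes"):
                    raise LexiconError(
                        f"{path} line {line_no}: unknown section {section!r}")
                continue
            if section == "proteins":
                lex.protein_names.add(line.strip())
            elif section == "interactions":
                parts = line.split("\t")
                if len(parts) != 2:
                    raise LexiconError(
                        f"{path} line {line_no}: expected lemma<TAB>group")
                lemma, group = parts[0].strip().lower(), parts[1].strip()
                if lemma in lex.interaction_words and \
                        lex.interaction_words[lemma] != group:
                    raise LexiconError(
                        f"{path} line {line_no}: lemma {lemma!r} assigned to "
                        f"groups {lex.interaction_words[lemma]!r} and {group!r}")
                lex.interaction_words[lemma] = group
            elif section == "morphemes":
                parts = line.split("\t")
                suffix = parts[0].strip()
                repl = parts[1].strip() if len(parts) > 1 else ""
                lex.morpheme_rules.append((suffix, repl))
            else:
                raise LexiconError(
                    f"{path} line {line_no}: content before any section")
    if not lex.morpheme_rules:
        lex.morpheme_rules = list(DEFAULT_MORPHEME_RULES)
    return lex


def default_lexicon() -> Lexicon:
    """The small dictionary shipped with the package (user-replaceable)."""
    ref = resources.files("grgt").joinpath("data/default_lexicon.txt")
    with resources.as_file(ref) as path:
        return load_lexicon(path)


def group_of(word: str, lex: Lexicon) -> str:
    """Interaction-word group of ``word`` after morpheme stripping.

    Words absent from the dictionary get a singleton group keyed by their
    own lemma (prefixed ``~``) so that group-level matching stays total.
    """
    lemma = lex.lemma_of(word)
    group = lex.interaction_words.get(lemma)
    return group if group is not None else f"~{lemma}"


def tag_sentence(g: SentenceGraph, lex: Lexicon) -> list[Mention]:
    """Tag protein and interaction mentions by dictionary lookup.

    Protein names: longest exact match over token-form sequences (joined
    by a space for multi-token names), left to right; matched spans never
    overlap.  Interaction words: single tokens, outside protein spans,
    whose form or lemma reduces to a dictionary lemma.
    """
    mentions: list[Mention] = []
    n = len(g.tokens)
    max_len = 1
    if lex.protein_names:
        max_len = max(name.count(" ") + 1 for name in lex.protein_names)
    covered: set[int] = set()
    i = 1
    while i <= n:
        hit = None
        for span in range(min(max_len, n - i + 1), 0, -1):
            candidate = " ".join(g.token(j).form for j in range(i, i + span))
            if candidate in lex.protein_names:
                hit = (span, candidate)
                break
        if hit is not None:
            span, name = hit
            mentions.append(Mention(g.sentence_id, i, i + span - 1,
                                    "protein", name))
            covered.update(range(i, i + span))
            i += span
        else:
            i += 1
    for t in g.tokens:
        if t.index in covered:
            continue
        for surface in (t.form, t.lemma):
            lemma = lex.lemma_of(surface)
            if lemma in lex.interaction_words:
                mentions.append(Mention(g.sentence_id, t.index, t.index,
                                        "interaction", lemma))
                break
    mentions.sort(key=lambda m: (m.token_start, m.kind))
    return mentions
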