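"""Dictionary tagging and candidate-triplet enumeration.

Tags the built-in four-protein-mention sentence with the default
dictionary, then enumerates every candidate (protein, interaction word,
protein) triplet.  Two mentions of the same protein name never pair, so
4 mentions with one duplicated name and 1 interaction word yield
C(4,2) - 1 = 5 candidates.  The "FKBP12-like" token is not a mention:
dictionary matching is exact, never substring.
"""

from grgt import builtin_fixtures, default_lexicon, enumerate_triplets, tag_sentence

lex = default_lexicon()
fig1 = next(cs for cs in builtin_fixtures() if cs.sentence_id == "fig1")
print("sentence:", fig1.graph.text, "\n")

mentions = tag_sentence(fig1.graph, lex)
for m in mentions:
    print(f"  token {m.token_start:2d}  {m.kind:11s}  {m.norm}")

cands = enumerate_triplets(mentions)
print(f"\n{len(cands)} candidate triplets:")
for c in cands:
    print(f"  ({c.p1.norm}, {c.iword.norm}, {c.p2.norm})")
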