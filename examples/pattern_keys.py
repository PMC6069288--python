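"""Canonical pattern keys at each generalization level.

Extracts the grammatical relationship graph of the triplet in
"domain of P1 interact with P2" — the union of the pairwise shortest
paths among the two protein heads and the interaction word in the
dependency graph — and prints its canonical key at levels 1-4.  Each
level forgets more: level 2 wildcards the intermediate word, level 3
replaces the interaction word by its group, level 4 coarsens the
dependency labels one step up the label hierarchy.
"""

from grgt import (LabelHierarchy, builtin_fixtures, canonical_key,
                  default_lexicon, extract_grgt)

lex = default_lexicon()
h = LabelHierarchy()
train = next(cs for cs in builtin_fixtures()
             if cs.sentence_id == "train-domain")
p = extract_grgt(train.graph, train.triplets[0])

print("GRGT nodes:", [(n.role, n.word) for n in p.nodes])
for level in (1, 2, 3, 4):
    k = canonical_key(p, level, lex, hierarchy=h, reduce_steps=1)
    print(f"level {level}: {k.key}")
print("\nEqual keys at a level mean two triplets are interchangeable")
print("evidence at that degree of abstraction.")
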