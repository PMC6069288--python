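# grgt — PPI triplet extraction from dependency parses

`grgt` extracts **protein–protein interaction triplets** — (protein 1,
interaction word, protein 2) — from dependency-parsed sentences and
classifies each candidate as a true or false statement of an interaction,
with a probability and an inferred direction (which protein acts on which).
It is aimed at biomedical text-mining pipelines that already run a
dependency parser and a protein-name tagger and need a transparent,
pattern-based relation classifier whose decisions can be audited pattern by
pattern — e.g. for high-precision extraction feeding interaction databases.

## The method

For a sentence with typed-dependency graph *G* (nodes = tokens, edges =
grammatical relations such as `nsubj`, `nn`, `prep_of`) and a candidate
triplet with protein head tokens *p₁*, *p₂* and interaction word *w*, the
feature is the **grammatical relationship graph of the triplet (GRGT)**:

> GRGT(p₁, p₂, w) = SP(p₁,p₂) ∪ SP(p₁,w) ∪ SP(p₂,w),

the union of the three pairwise shortest paths in the undirected view of
*G* (unit edge weights; `punct` edges carry no paths). Protein tokens are
abstracted to roles P1/P2, the interaction word to INT, every other path
token to LEX — so renaming the proteins leaves the pattern unchanged.

Each GRGT is canonicalized into a key at increasing **generalization
levels**:

| level | abstraction |
|---|---|
| 1 | exact: all LEX words and the interaction word kept |
| 2 | LEX words wildcarded (structure and labels kept) |
| 3 | interaction word replaced by its interaction-word *group* |
| 4 (optional, off by default) | edge labels coarsened through the dependency-label hierarchy (`nsubj` → `subj` → `arg` → `dep`) |

**Training** assigns every key the probability
`p(key) = n_true(key) / n_total(key)` — the proportion of gold-true
triplets among training triplets carrying that key — plus a direction
tally. **Prediction** is a decision-tree cascade: levels are tried in
order and the first level whose key is known supplies the probability;
a triplet matching no level gets probability 0 and is classified false.
This makes the classifier precision-oriented: its typical error is the
false negative (a true triplet whose pattern was never seen), not the
false positive.

## Worked example

`python examples/worked_example_cascade.py` trains on the single gold-true
sentence *“domain of P1 interact with P2”* and classifies three probes:

```
domain of CaM interact with RAF1 (renamed proteins)     -> level 1, P(true) = 1.00, direction = p1_to_p2
motif of P1 interact with P2                            -> level 2, P(true) = 1.00, direction = p1_to_p2
motif of P1 associates with P2                          -> level 3, P(true) = 1.00, direction = p1_to_p2
```

Renamed proteins still match exactly (level 1) because protein nodes carry
no words; changing *domain* → *motif* forces the wildcard level (2);
changing *interact* → *associates* additionally needs the group level (3),
which succeeds because `associate` and `interact` share an
interaction-word group in the dictionary. A probe with a different
grammatical structure, or an interaction word from a different group,
matches nothing and is classified false with probability 0.

`python examples/enumerate_candidates.py` shows candidate enumeration on a
sentence with protein mentions PAHX, FKBP52, FKBP12, FKBP52 and the word
*interacts*: mentions of the same name never pair, so it prints
`5 candidate triplets` (C(4,2) − 1). `python examples/simulate_and_evaluate.py`
generates a 500-sentence synthetic corpus and runs sentence-level
leave-one-out evaluation:

```
tp=131 fp=0 tn=424 fn=7
precision=1.0000 recall=0.9493 f1=0.9740
```

— perfect precision, with the 7 errors all false negatives from
singleton patterns, the signature behaviour of the method.

## Command line

A thin CLI wraps the library: `grgt import | tag | enumerate | train |
predict | evaluate | simulate | fixtures` (see `grgt --help`). Every
subcommand writes its resolved configuration next to its outputs, and
identical configuration + seed + inputs give identical outputs.

## Layout

- `src/grgt/` — library: `depgraph` (graphs, CoNLL-U, label hierarchy),
  `lexicon` (dictionaries, tagging), `candidates` (enumeration), `core`
  (GRGT extraction, canonical keys), `model` (training, cascade),
  `evaluate` (LOO, PR curves, pattern statistics), `synthdata`
  (templates, generator, fixtures), `corpus` (JSON-lines I/O), `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model assumptions, parameters, and limitations.
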