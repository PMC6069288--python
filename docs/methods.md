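# Methods

## Model

A candidate PPI triplet is two protein mentions with distinct normalized
names plus one single-token interaction word in the same sentence. The
classifier's only feature is the triplet's grammatical relationship graph
(GRGT): the union of the three pairwise minimum-hop paths, in the
undirected view of the sentence's typed-dependency graph, among the two
protein head tokens and the interaction word. The underlying assumption
is that the grammatical frame linking the three words — not the words
around it — determines whether the sentence asserts the interaction, and
that triplets whose frames are identical up to protein renaming are
exchangeable evidence.

Patterns are compared by canonical key at four generalization levels
(exact; intermediate words wildcarded; interaction word replaced by its
group; edge labels coarsened through the `dep`-rooted label hierarchy).
Training estimates, per key and level, the binomial proportion of
gold-true triplets; prediction is a first-match-wins cascade over levels.
There is deliberately no smoothing, no prior and no discriminative
re-scoring: the probability attached to a prediction is exactly a
training-set proportion, which keeps every decision auditable.

Direction (which protein acts on which) is predicted by majority vote
over the gold directions of the matched entry's true triplets; ties and
unannotated entries yield `unknown`. Direction accuracy is reported
separately from precision/recall and never folded into them.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `levels` | `(1, 2, 3)` | cascade order; level 4 is opt-in because label coarsening trades precision for recall and the three-level cascade is the reference configuration |
| `threshold` | 0.5 | classify true when the matched entry's probability is at least this; the PR curve sweeps it |
| `reduce_steps` | 1 | hierarchy steps applied at level 4 (`nsubj` → `subj`) |
| `directed` | on | stored governor→dependent direction is part of the key, distinguishing "A inhibits B" from "B inhibits A"; an undirected switch exists for sensitivity analysis |
| punct paths | excluded | `punct` edges stay in the graph but get no paths, avoiding degenerate shortcuts through commas; configurable via `exclude_labels` |
| `fall_through` | off | lets a low-probability match keep descending the cascade (experimental) |

Tie-breaks and numerical choices: shortest paths use unit weights
(minimum-hop, BFS-checkable) and, among equal-length paths, the
lexicographically smallest token-index sequence, so extraction is
deterministic. Canonical keys are the lexicographically smallest
serialization over breadth-first orders rooted at the INT node with
neighbors sorted by (edge label, direction, role, word); genuinely tied
neighbors are resolved by exhaustive permutation (path unions are tiny,
so the permutation cap is never approached in practice). Multi-token
mentions are represented by the span token governed from outside the
span. A triplet whose three head tokens are not distinct or not mutually
connected is "unextractable": excluded from training counts, classified
false at prediction with a warning. Probabilities are exact ratios of
integers; the model file stores the counts, not the ratios.

## Dictionaries

The shipped dictionary is a small, explicitly user-replaceable stand-in:
28 interaction lemmas in 7 groups (with `interact` and `associate`
sharing a group, which the level-3 worked example depends on), a handful
of protein names for the fixtures, and a suffix-strip morpheme table
(`-s`, `-es`, `-ed`, `-ing`, `-ion`, `-ation`, with e-restoration and
final-consonant de-doubling). A real deployment supplies its own
`[proteins]` / `[interactions]` / `[morphemes]` file; full curated
protein and interaction-word dictionaries are out of scope. Unknown
interaction words fall back to singleton groups so group-level matching
stays total. Models record a fingerprint of the dictionary they were
trained with and refuse, by default, to predict under a different one.

## Synthetic data: what it emulates and what it does not

Eleven sentence templates carry hand-authored Stanford-style dependency
skeletons spanning active, passive, prepositional-attachment,
nominalization, negation ("fails to", "no ... between"), coordination,
relative-clause and complement-clause shapes; multi-protein templates
contribute the false candidates that co-occurrence produces in real text.
Instantiation substitutes synthetic protein names (`PROT0001`…, avoiding
dictionary collisions) and sampled interaction lemmas into the slots, so
every generated parse is valid without running a parser, and two
instantiations of one template differ only in words that the level-1 key
ignores or records verbatim.

Generator defaults: 200 sentences, protein vocabulary 50, label noise 0,
gold-true triplet fraction 0.25. Benchmark PPI corpora show roughly
9–13 % gold-true candidates, but that rate is driven by dense
multi-entity sentences; forcing it with this template set would make
most sentences negation-type, so 0.25 is used as the default mix that
keeps all template families represented. The target fraction is achieved
by mixing true-bearing and negative templates and is attainable up to
about 0.69. `pattern_noise` flips each gold label independently, and the
pre-noise template label is kept in the corpus (`latent_label`) so
recovery experiments know each pattern's true rate.

What passing tests on this data do **not** show: robustness to parser
errors, to patterns whose decisive cue lies off the shortest paths
(classic negation "does not interact" has the same GRGT as its positive
counterpart — the template set deliberately uses structurally distinct
negations instead), to multi-word interaction phrases, or to the far
heavier pattern-sparsity of real corpora, where only ~10–20 % of
patterns recur and recall is correspondingly much lower. The
leave-one-out behaviour the tests do demonstrate — perfect precision
when every pattern recurs with consistent labels, and false negatives
exactly at singleton patterns — is the mechanism behind that trade-off,
at friendlier pattern coverage.

## Evaluation choices

Leave-one-out holds out whole sentences by default: triplets of one
sentence share a parse, and triplet-level holdout would let a sentence's
other annotations vouch for the held-out one. Because training is pure
counting, the held-out model is computed by subtracting the unit's
counts from global tallies (exactly equivalent to retraining, tested).
The PR curve emits one point per distinct positive probability plus
endpoints at thresholds 0 and 1, under the rule "predicted true iff
probability ≥ threshold and > 0", so unmatched triplets are
predicted-false at every threshold. F is F1. "Valid patterns" in the
coverage statistics are keys occurring at least twice.

Problem sizes used by the shipped test suite (chosen to make the checked
properties statistically meaningful): oracle equivalences on 1000 random
graphs/mention lists; structural properties on a 500-sentence corpus;
probability recovery on a 16 000-sentence corpus with label noise 0.1,
where ~400 level-1 patterns reach 10+ observations so the "99 % of
entries within 3-sigma" coverage claim is estimable rather than a
zero-failure demand.

## Known limitations

- Pattern matching is key equality, not subgraph isomorphism: a pattern
  never matches inside a larger context graph.
- The `punct`-exclusion and edge-direction policies follow drawn
  convention rather than a stated rule; both are configurable and
  flagged for sensitivity testing.
- CoNLL-U export is lossy for tokens with multiple stored governors
  (CoNLL-U allows one head per token); the JSON-lines format is the
  round-trip-safe representation.
- The Universal-Dependencies→Stanford label map covers the common
  relations; unmapped labels pass through verbatim with a warning at
  hierarchy reduction.
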