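# Methods

This note documents the model behind `dockboost`: what the campaign loop
assumes, what the synthetic benchmark does and does not emulate, and the
numerical and design choices a maintainer would want to know.

## Campaign model and assumptions

The campaign is greedy batched active learning for *retrieval*, not for
model quality: the goal is to have selected the library's true top-k
compounds (by brute-force docking score) after docking only a few percent
of it. Key assumptions:

- **One outcome per library id.** The score table maps each compound to a
  single score or an explicit failure; any upstream expansion (tautomers,
  stereoisomers) is assumed collapsed to one record before replay.
- **Lower is better, fixed.** The Glide sign convention is hard-coded; a
  configurable sign would make a silent ranking inversion possible.
- **Replay blindness.** The loop reads exactly the table rows it selected.
  `ScoreTable` logs row access, and the test suite asserts that the hash of
  accessed ids equals the hash of the cumulative docked set. Selection order
  therefore carries no information about unseen scores.
- **Fixed batch geometry.** Both the random initialization and every
  selection batch contain `⌊f·L⌋` compounds. Recall counts *selection*:
  a selected compound that fails to dock still consumed budget and is never
  re-selected.
- **From-scratch retraining.** Iteration i's model depends only on the
  cumulative docked data and derived seeds, never on the previous model
  state. This makes checkpoint resume bit-identical to an uninterrupted run
  (seeds are derived per-(context, iteration) from the base seed, not drawn
  from a shared stream). A resume may extend the iteration count; any other
  config change is rejected.
- **Split per iteration.** The 80/10/10 train/val/test split is redrawn each
  iteration over the full post-policy docked set (seeded by iteration), so
  per-iteration val/test RMSE can be reported. Whether the original
  procedure redraws or freezes assignments is ambiguous; a `frozen` mode
  (per-id hash assignment, stable as data grows) is config-selectable and
  `redraw` is the default. Val/test are diagnostics only — selection always
  operates on the whole library.
- **Tie-breaking by ascending id** everywhere a ranking is cut (selection
  and truth top-k), making results independent of input order.

## Failed-compound policies

When docking returns no score, the regression target is undefined. Two
treatments are implemented: `Substitute(v)` assigns an arbitrary unfavorable
score (+5.0 and 0.0 are the conventional choices, against scores that live
roughly in −12…0), and `Drop` excludes failed records from training.
Substitution teaches the model to *avoid* likely-failing compounds (their
selected count collapses after iteration 1) at the cost of injecting gross
target noise whenever failure is not predictable from structure; dropping
keeps the regression clean but leaves the model blind to the failure
mechanism. On benchmarks where ~45% of compounds fail, the trade favors
dropping; at a ~3% failure rate the choice barely matters. The package
treats the policy as a per-campaign configuration rather than fixing a
winner.

Featurization failures are distinct from docking failures: a SMILES the
fingerprinter cannot parse is skipped in training (hard error above 10%)
and assigned a worst-possible sentinel at prediction (never selected).

## Surrogate

Default: ridge regression on radius-2, 2048-bit Morgan **count**
fingerprints, `alpha = 30`. The heavy penalty reflects the geometry —
2048 correlated features against a few thousand training rows — and holds
the train/test RMSE gap under ~10% on a noise-free linear-oracle fixture
while costing essentially nothing in campaign recall. The solver
(`sparse_cg`, tol 1e-8) is deterministic, and predictions are exactly
chunk-invariant because the model is linear. A
`HistGradientBoostingRegressor` variant (`fingerprint_gbr`) is registered
for nonlinear fits; both hide behind the same `fit`/`predict` surface, which
is also the plugin point for an external message-passing model. Two
diagnostic doubles complete the registry: `oracle` (predict = truth;
deliberately outside the blindness contract) and `random` (per-SMILES
hash noise, order- and chunk-invariant), used for the
perfect-information and null controls.

No hyperparameter optimization is performed beyond the single alpha default
above; the protocol is meant to work with stock settings.

## Synthetic benchmark

`generate_library` enumerates a fragment grammar: 12 carbon-only scaffolds,
each with three chemically inequivalent attachment sites, crossed with 38
substituents (26 acceptor-free, 12 N/O-bearing), giving ~6.6e5 raw
combinations that are validated and deduplicated by canonical SMILES. A
seeded permutation of the combination space provides the shuffled order.
Scaffolds were chosen asymmetric so symmetric-duplicate collapse is rare
(<1%); the substituent set is deliberately skewed hydrophobic so that
(26/38)³ ≈ 32% of molecules carry no hydrogen-bond acceptor at all.

The oracle assigns
`score = offset + scale · (wᵀb + Σ u_m b_i(m) b_j(m)) + ε`,
with `b` the binary 2048-bit Morgan fingerprint, `w` a seeded standard
normal weight vector, and 64 seeded pairwise bit interactions. Interaction
pairs are drawn among bits with on-frequency 0.05–0.6 in a fixed probe
enumeration of the grammar, so they actually fire; with weight sd 2.0 the
correlation between the linear part and the full signal is ≈ 0.92 — a
fingerprint-linear surrogate is good but not perfect, mirroring the gap
between a surrogate and a docking engine. Defaults `offset = −6.0`,
`scale = 0.28`, `noise_sd = 0.3` place scores in a docking-like −12…0 range
with spread ≈ 1.6 (calibrated once on a 10⁴-molecule probe of the default
grammar).

Failure has two layers: a compound with no match to the constraint SMARTS
(`[#7,#8]`, a crude hydrogen-bond-acceptor mimic of a kinase hinge-bond
requirement) always fails; a constraint-satisfying compound fails with
probability `random_fail_prob`, emulating pose-level artifacts that are
invisible to the fingerprint. All per-compound randomness (failure draw,
score noise) comes from a hash of the canonical SMILES and the spec seed —
never a shared RNG stream — so outcomes are independent of enumeration and
query order, which the data-dependent selection loop requires.

Scenario presets:

| scenario    | constraint | random_fail_prob | realized failures |
|-------------|-----------|------------------|-------------------|
| `sura-like` | none      | 0.03             | ~3%, feature-independent |
| `gak-like`  | `[#7,#8]` | 0.19             | ~45%, ≈70% constraint-driven |

How feature-correlated real constraint failure is cannot be read off the
published data; ≈70% constraint-driven is this package's choice, recorded
in the spec YAML written next to every generated table.

**What the generator does not emulate:** 3D poses and pose-dependent score
multimodality, activity cliffs beyond the bit-interaction term, the heavy
left tail of real Glide HTVS score distributions, inter-target score-scale
differences, and any relationship between failure and molecular size or
charge. Passing tests therefore demonstrate that the *protocol logic* is
correct and that its qualitative failure-policy behavior reproduces under a
feature-correlated failure mechanism — not that any particular recall level
will transfer to a real target.

## Evaluation

- `true_top_k` excludes failed compounds (they have no score and cannot be
  virtual hits) and uses the same (score, id) sort key as selection.
- Recall is reported at full precision; rounding is a display concern.
- Replicate overlap partitions the true top-k by how many of exactly three
  replicates selected each compound; the partition sums to k by
  construction and `(by_3 + by_2 + by_1)/k` equals the recall of the
  replicate union.
- Similarity uses *binary* fingerprints (the 2048-bit convention), not
  counts, via RDKit's Tanimoto routines.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the protocol end-to-end at
the sizes a single CPU handles comfortably while keeping every rate
estimable: 50k-compound sura-like and 100k-compound gak-like benchmarks,
`f = 0.01`, 10 iterations (docking 10% total), five seeds for the policy
comparison, twenty replicates for the random null. The giga-scale numbers
(1.56e9 library, 0.1%/0.01% fractions) appear only as bookkeeping
arithmetic, which is exact at any scale. Fingerprints are featurized once
per library through a shared cache; a 100k-compound campaign takes seconds
per iteration after featurization.

Degenerate inputs are defined rather than accidental: `fraction = 1` docks
everything in one batch; a selection pool smaller than the batch returns
the whole pool; an empty prediction input returns an empty array; a
constant training target fits (approximately) a constant; zero `noise_sd`
with zero `score_scale` collapses the oracle to its offset.

## Known limitations

- The surrogate sees only 2D fingerprints; no uncertainty estimate, so the
  acquisition is purely greedy (no exploration term).
- `OracleSpec` grammars with highly symmetric scaffolds enumerate far fewer
  unique molecules than their raw capacity; the generator reports the
  achieved count when it runs out.
- The CSV/JSON artifact formats are meant for desk-scale runs (≤ a few
  million rows), not for giga-scale tables.
- No live docking adapter ships; the `ScoreTable` replay interface is the
  hook where one would attach an engine.
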