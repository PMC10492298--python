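# Methods

## Problem and pipeline

Public registries of randomized trials report, per intervention arm, the
number of participants affected by each adverse event. For any two
single-drug arms this yields a 2×2 table per adverse event, and hence an
experimentally grounded drug-vs-drug effect direction and magnitude — exactly
the ground truth needed to appraise non-experimental (observational)
causal-inference methods. The package runs in five stages:

1. **Ingest** (`trial_ingest`): parse normalized trial-record JSON, keep only
   randomized trials with participant blinding, drop arms with fewer than 100
   participants, map arm labels to single drug ingredients and adverse-event
   terms to ICD10.
2. **Tables** (`contingency`): pair arms within a trial, pool dosage arms and
   repeated trials, orient each comparison so its sample odds ratio is ≥ 1.
3. **Denoise** (`eb_core`): estimate a symmetric prior over log odds ratios
   across all comparisons and replace each raw estimate with its posterior
   mean.
4. **Subset** (`reference_set`): materialize nested reference sets
   S_t = {i : exp(ω̂_i) ≥ t}, plus a Fisher-exact-test ablation subset.
5. **Evaluate** (`evaluation`): score a method's (p-value, direction) outputs
   by concordant sign rate and recovery across the threshold sweep.

## Statistical model and assumptions

Conditioning each table on its margins removes the nuisance base rate and
leaves Fisher's noncentral hypergeometric likelihood L_i(ω), indexed only by
the log odds ratio. The hierarchical assumption is ω_i iid ~ G with G
symmetric about 0: symmetry is forced by the design (the two arms of a
head-to-head trial are exchangeable, and tables are re-oriented
mechanically), and exchangeability across comparisons is what lets thousands
of small tables share strength. G is estimated by the Kiefer–Wolfowitz NPMLE
restricted to a fixed symmetric grid; the posterior mean under Ĝ then shrinks
each comparison adaptively — heavily when the table carries little
information, hardly at all when events are plentiful. The same prior is
shared by all comparisons; effects from atypical drug classes (e.g.
cytotoxics) are therefore shrunk toward the global mixture, a known
limitation.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| quality filter | on | – | randomized + participant-blinded trials only; `apply_quality_filter=False` reproduces the ablated pipeline |
| min arm size | 100 | participants | small arms rarely carry statistical information and inflate mapping noise |
| token-overlap threshold | 0.5 (inclusive) | fraction of *label* tokens | conservative reading of "at least half the tokens match"; the label side is used as the denominator because registry labels, not lexicon names, carry the extra dosage/form tokens |
| continuity correction | 0.5 | pseudo-counts | used **only** for ordering/display of sample odds ratios (zero cells occur); likelihoods always use raw counts |
| grid step Δ | 0.05 | log-OR | fine enough that posterior means are insensitive to discretization |
| grid extent | ±log 1000 | log-OR | covers any plausible denoised OR with headroom |
| EM tolerance | 1e-9 relative | – | objective is flat near the optimum; posterior means stabilize well before this |
| EM max iterations | 10 000 | – | cap for pathological inputs; typical fits converge in ~2 000 |
| significance level α | 0.05 (inclusive ≤) | – | convention for both the method filter and the Fisher ablation subset |
| threshold sweep | 1.00–4.00 step 0.05 | odds ratio | covers the informative range; configurable |

## Numerical choices

* All likelihood work is in log space (log-binomials via `gammaln`,
  log-sum-exp denominators); each table's row is shifted by its value at
  ω = 0, a per-table constant that cancels in the NPMLE objective and in
  posterior means.
* Symmetry of Ĝ is imposed structurally, not by constrained optimization: the
  fit runs on symmetrized half-grid kernels K_i(j) = [L_i(+g_j) + L_i(−g_j)]/2
  and the half-grid solution is reflected. This makes the symmetric problem an
  ordinary NPMLE and guarantees weight symmetry to machine precision.
* Tables are canonicalized (lexicographically smaller column tuple first,
  evaluated at −ω when swapped) before likelihood evaluation. Mathematically
  L_swapped(ω) = L(−ω) exactly (because x_A + x_B equals the event margin);
  canonicalization makes it hold *bitwise*, so swapping drug columns negates a
  posterior mean exactly rather than to rounding.
* NPMLE mixing weights can be non-unique; weights below 1e-12 are truncated
  and renormalized, and correctness is asserted at the level of the objective
  and the posterior means, which are stable.
* Degenerate tables with zero events (m = 0) have a single-point support and
  a flat likelihood: log L ≡ 0 for every ω, posterior mean 0 by symmetry. A
  dataset consisting only of such tables leaves the EM at its uniform
  initialization (documented convention).
* Ties: orientation at an exact odds ratio of 1 puts the lexicographically
  smaller drug code in the A slot; effect ranking breaks ties by comparison
  id. Both make outputs order-independent.
* The two-sided Fisher exact p-value uses the point-probability convention
  (sum of central-hypergeometric outcomes no more probable than the observed
  one), the common software default; two-sided exact tests admit variants.

## The synthetic generator, and what passing tests show

`synthetic_data` draws tables from two binomial arms whose log odds ratio
comes from a known symmetric discrete prior. Under this design the
conditional law of a table given its margins is *exactly* the noncentral
hypergeometric likelihood the estimator assumes, so parameter recovery is a
faithful test of the estimation machinery. Defaults — 5 000 comparisons,
prior 0.8·δ₀ + 0.1·δ₊log4 + 0.1·δ₋log4, arm sizes 200–2 000, event base rates
0.01–0.3 — emulate registry-scale data where most drug pairs have no
differential adverse-event effect. Method outputs are simulated from an
independent observational 2×2 with configurable per-arm size (power) and a
log-odds bias term (systematic confounding); p-values come from the corrected
normal approximation to the log odds ratio.

What the generator does **not** emulate: real registry parsing quirks,
correlated adverse events within a trial, cross-trial heterogeneity in the
true effect for one drug pair (pooling is plain summation, as in the
pipeline), selection/publication bias, and claims-data phenomena (censoring,
exposure misclassification, confounding structure). Passing recovery tests
therefore demonstrates the statistical machinery is correct under its own
assumptions, not that real trial reports satisfy those assumptions.

Randomness: one root seed; substreams are derived as
`SeedSequence(root, spawn_key=(k,))` with a fixed index per operation
(0 prior draws, 1 tables, 2 method results) over the PCG64 generator, so all
outputs are bitwise reproducible.

## Problem sizes

The recovery analyses use 5 000 simulated tables on the 279-atom default grid
(a fit takes ~20 s on one CPU; EM typically converges in ~2 000 iterations)
and 2 000 tables for the evaluation-semantics checks. The EM-vs-exhaustive
comparison uses 5 tables on a 3-atom half-grid, where a zooming grid search
over the mixing simplex is exact to ~1e-10.

## Known limitations

* A single global prior across heterogeneous drug classes (no covariate
  modulation or stratification).
* No posterior uncertainty: point posterior means only, no intervals or local
  false-sign rates.
* Pooling across trials assumes a common effect per (drug pair, adverse
  event); conflicting trials are averaged, not modelled.
* Ingest consumes a normalized JSON schema; adapting a real registry export
  (arm-label conventions, serious vs. non-serious event tables, at-risk
  denominators) is left to a thin user-supplied adapter, and the merge of
  duplicate ICD10 terms within an arm (sum, then cap affected at at-risk) is
  a documented convention for inputs the schema cannot disambiguate.
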