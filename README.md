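# trialref

Build a denoised reference set of drug-vs-drug adverse-event effects from
public clinical-trial result records, and use it to benchmark non-experimental
(observational) causal-inference methods by the direction of their effects.

## Who this is for

Methodologists evaluating observational pipelines (Cox models on claims data,
propensity matching, inverse-propensity weighting, ...) need a ground truth to
compare against. Head-to-head ("active comparator") randomized trials provide
one: each trial arm reports adverse-event counts, so any pair of drug arms
yields a 2×2 contingency table per adverse event

|                         | drug A | drug B |
|-------------------------|--------|--------|
| patients with the event | x_A    | x_B    |
| patients without        | y_A    | y_B    |

The catch is that most per-comparison tables are small and noisy, so their raw
odds ratios overstate effect sizes. `trialref` addresses this with an
empirical-Bayes model.

## The model

For comparison *i* with table Z_i, condition on the table margins; the
observed x_A then follows Fisher's noncentral hypergeometric law indexed by
the log odds ratio ω_i:

    L_i(ω) = C(n_A, x_A) C(n_B, x_B) e^{ω x_A} / Σ_t C(n_A, t) C(n_B, m−t) e^{ω t}

The ω_i are modelled as i.i.d. draws from an unknown prior *G*, symmetric
about 0 (neither arm of an active-comparator trial is a natural baseline).
*G* is estimated by the Kiefer–Wolfowitz nonparametric maximum likelihood
estimator over a discrete log-OR grid,

    Ĝ = argmax_G Σ_i log ∫ L_i(ω) dG(ω),   G symmetric about 0,

fitted with EM, and each comparison is denoised by its posterior mean
ω̂_i = E_Ĝ[ω_i | Z_i]. Nested reference subsets S_t keep the comparisons with
exp(ω̂_i) ≥ t. A method under evaluation supplies a p-value and a predicted
direction per comparison; against each S_t the package reports the
**concordant sign rate** (among significant in-subset results, the fraction
agreeing with the trial direction) and the **recovery fraction** (the share of
S_t flagged significant with the concordant direction).

## Worked example

Simulate 5 000 comparisons whose log odds ratios come from a known
spike-and-slab prior (80% exact nulls, 10% each at odds ratio 4 and 1/4),
fit the prior, and denoise:

```python
import math, numpy as np
from trialref import (SimulationSpec, simulate_tables, EffectGrid,
                      fit_symmetric_npmle, denoise_all, sample_odds_ratio)

spec = SimulationSpec(seed=1)          # M=5000, arms 200-2000, rates 0.01-0.3
omegas, records = simulate_tables(spec)
grid = EffectGrid.symmetric()          # 279 atoms, step 0.05, out to log(1000)
prior = fit_symmetric_npmle([r.table for r in records], grid)

mass = prior.weights[np.abs(grid.atoms) >= math.log(2)].sum()
print(f"prior mass at |OR| >= 2: {mass:.3f}")

effects = denoise_all(prior, records)
eb = np.array([e.omega_eb for e in effects])
raw = np.array([math.log(sample_odds_ratio(r.table, 0.5)) for r in records])
print(f"MSE denoised: {np.mean((eb - omegas)**2):.4f}")
print(f"MSE raw:      {np.mean((raw - omegas)**2):.4f}")
```

prints

```
prior mass at |OR| >= 2: 0.191
MSE denoised: 0.0055
MSE raw:      0.0360
```

The fitted prior recovers the 20% slab mass placed outside odds ratio 2, and
posterior-mean denoising cuts the squared error of the raw (0.5-corrected)
sample log odds ratio by a factor of ~6.6: strong-looking noisy effects are
shrunk toward 1 while well-supported ones are kept.

The same flow is available from the shell:

```
trialref ingest --trials trials.json --lexicon lexicon.tsv --ae-map ae_map.tsv --out comparisons.tsv
trialref fit --comparisons comparisons.tsv --out-prior prior.tsv
trialref denoise --comparisons comparisons.tsv --prior prior.tsv --out denoised.tsv
trialref subset --denoised denoised.tsv --threshold 2.0 --out subset.tsv
trialref evaluate --denoised denoised.tsv --results method.tsv --out curves.tsv
```

`ingest` applies the trial-quality filters (randomized allocation +
participant blinding, ≥100-patient arms, single-ingredient name mapping),
pools dosage arms and repeated trials, and orients every comparison so the
corrected sample odds ratio is ≥ 1; `--no-quality-filter` runs the ablated
pipeline. See `docs/methods.md` for the full model and design notes.

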