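# likertfa

Ordinal (polychoric) exploratory factor analysis under floor-effect
censoring, with a repeated-sampling experiment contrasting skewed and
symmetrized sample selections.

## The problem

Disability questionnaires such as the 12-item WHODAS 2.0 (five response
categories per item, summary score 0–48) show strong *floor effects* in
general-population surveys: large fractions of respondents report no
difficulty on any item and score exactly zero. For those respondents every
item pair is perfectly concordant, which flattens the correlation structure
and can mask the instrument's latent dimensionality. Whether an exploratory
factor analysis recovers one, two or three factors then depends as much on
*who was sampled* as on the instrument itself.

`likertfa` packages the full analytic pipeline needed to study this:

* **Polychoric correlations** — two-step maximum likelihood: item
  thresholds `τ_c = Φ⁻¹(cumulative proportion)` from the margins, then the
  latent correlation ρ maximising `Σ n_ij log π_ij(ρ, τ)` with rectangle
  probabilities from the bivariate-normal CDF. Pairwise matrices are
  PSD-repaired by eigenvalue clipping when needed (always flagged).
* **Parallel analysis** — retained factors = leading PCA eigenvalues of
  the polychoric matrix exceeding the mean eigenvalues of column-permuted
  reference data (mean-eigenvalue criterion, contiguous stopping rule).
* **EFA** — minimum-residual (ULS) extraction, oblique Geomin rotation
  `min Σ_i (Π_j (λ_ij² + ε))^{1/k}` by gradient projection with random
  starts, Kaiser–Meyer–Olkin sampling adequacy, and a |λ| ≥ .40 salience
  mask.
* **Sampling schemes** — simple random sampling (preserving the skewed
  population distribution) versus stratified sampling whose per-stratum
  selection weights target an approximately symmetric summary-score
  distribution.
* **Repeated-sampling experiment** — counts of samples retaining 1, 2, 3…
  factors per scheme, representative-sample reports, and a floor-effect
  sweep.
* **Synthetic populations** — censored-Likert data with known loadings
  `y = Λf + e` discretised at thresholds shifted by a severity offset δ,
  calibrated by bisection to any target all-zero-row rate.

## Worked example

```python
import numpy as np
from dataclasses import replace
from likertfa import (SyntheticPopulationSpec, SamplingScheme,
                      calibrate_floor, generate_responses, simple_score,
                      describe_scores, stratified_sample, parallel_analysis,
                      polychoric_matrix, efa, EFAConfig, match_columns,
                      two_factor_pattern)

spec = SyntheticPopulationSpec(N=20_000, seed=11)       # 2 factors, λ=0.7
delta = calibrate_floor(spec, 0.32)                     # 32% zero rows
pop = generate_responses(replace(spec, severity_offset=delta))
scores = simple_score(pop.dataset)
print(round(describe_scores(scores).skewness, 2))       # 1.9

idx = stratified_sample(scores, SamplingScheme(
    kind="stratified_symmetric", n=750, seed=0))
sample = pop.dataset.subset(idx)
print(round(describe_scores(scores[idx]).skewness, 2))  # 0.0

pa = parallel_analysis(sample, n_replicates=100, seed=0)
print(pa.n_factors)                                     # 2
sol = efa(polychoric_matrix(sample), EFAConfig(k=pa.n_factors, seed=0))
matched, congruence = match_columns(sol.pattern, two_factor_pattern())
print(np.round(congruence, 2))                          # [0.99 0.99]
print(int((np.abs(matched) >= 0.40).sum()))             # 12
```

The population is heavily right-skewed (skewness 1.9); the symmetrized
stratified sample is balanced (skewness 0.0), parallel analysis retains
the two true factors, the Geomin-rotated pattern matches the generating
pattern with Tucker congruence 0.99 per factor, and all twelve items are
salient (|λ| ≥ .40) on their true factor. Note that the within-sample
*factor correlation* is attenuated relative to the generating 0.4:
selecting on the summary score conditions on a function of both factors
and distorts their correlation in the selected sample.

A command-line interface mirrors the library:

```bash
likertfa simulate --preset twofactor --zero-rate 0.32 --n 20000 --seed 7 --output pop.csv
likertfa describe --input pop.csv
likertfa pa --input pop.csv --replicates 100 --seed 7
likertfa experiment --population pop.csv --scheme srs --samples 1000 --output table.csv
```

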