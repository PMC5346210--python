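# Methods

## Scope and data model

The package analyses respondent-by-item matrices of ordinal codes
0..C−1 (default C = 5, twelve items — the 12-item WHODAS 2.0 layout with
six two-item domains: cognition, mobility, self-care, getting along,
life activities, participation). Summary scores are simple item sums.
Only complete cases are analysed; rows with any missing item are dropped
before scoring or correlation estimation.

Descriptives follow survey-reporting conventions: sample SD (ddof = 1),
adjusted Fisher–Pearson skewness `g1·√(n(n−1))/(n−2)` with the classical
standard error `√(6n(n−1)/((n−2)(n+1)(n+3)))` (≈ `√(6/n)` for large n),
and linearly interpolated percentiles. Neither the skewness estimator
nor the percentile rule is forced by the problem; both are documented
defaults chosen to match mainstream statistical software.

## Polychoric correlations

Each item is modelled as a discretised standard-normal latent variable.
Estimation is the standard two-step maximum likelihood: thresholds from
the marginal cumulative proportions (`τ_c = Φ⁻¹(p̂_≤c)`), then a bounded
one-dimensional search for the latent correlation maximising the
contingency-table likelihood with thresholds fixed. Rectangle
probabilities use the CDF identity
`π_ij = F(τ_i,υ_j) − F(τ_{i−1},υ_j) − F(τ_i,υ_{j−1}) + F(τ_{i−1},υ_{j−1})`.

Numerical choices:

* The bivariate-normal CDF is Genz's double-precision quadrature
  algorithm, compiled with numba; it was validated to ~3·10⁻¹⁶ against
  scipy's `multivariate_normal.cdf` across the full (h, k, ρ) range used,
  and the unit tests retain this cross-check. A numba kernel is used
  because the experiments require millions of pairwise fits.
* The optimiser is a port of the bounded Brent algorithm
  (golden-section + parabolic steps), tolerance 10⁻⁶ in ρ, bounds
  ±(1 − 10⁻⁴). The clamp keeps downstream eigendecompositions finite for
  degenerate (perfectly concordant) pairs.
* Empty categories are collapsed into the lower adjacent category — in
  the likelihood this is equivalent to a zero-width cell, since empty
  cells contribute nothing; collapses are recorded on the `ThresholdSet`.
* Cell probabilities are floored at 10⁻¹² inside the log and the floor is
  flagged on the estimate.
* An item whose observations fall in a single category has no finite
  thresholds; `polychoric_matrix` raises an error naming such items.

Pairwise assembly does not guarantee positive semidefiniteness. When the
minimum eigenvalue is negative, eigenvalues are clipped at 10⁻⁸, the
matrix reconstituted and rescaled to unit diagonal; the repair is always
flagged with before/after minimum eigenvalues. Eigenvalue clipping (not
nearest-correlation projection) is used for determinism and speed.

## Factor retention

Parallel analysis with principal-components extraction and the
mean-eigenvalue criterion. The reference distribution comes from
*column permutations* of the observed data: each replicate permutes
every item's column independently, destroying inter-item dependence
while preserving every marginal (and hence the thresholds); the
polychoric matrix is re-estimated per replicate and the per-position
mean spectrum is compared against the observed spectrum. A parametric
normal reference would not share the ordinal items' category structure.
The criterion counts leading observed eigenvalues exceeding their
reference means and stops at the first failure (non-contiguous
exceedances are ignored — a documented tie-break the retention rule
itself does not settle).

Default replicate count is 100 and configurable. Reference-mean noise is
tiny: each mean averages replicate eigenvalues whose SD is ~0.02, so even
20 replicates put the SE near 0.005, far below the observed-vs-reference
gaps (~0.3) that decide retention. The repeated-sampling experiments and
the acceptance script therefore run 20 replicates per parallel analysis;
a 750×12 parallel analysis costs ≈0.1 s (batched numba pair fits).

## Exploratory factor analysis

*Extraction* is minimum residuals (ULS): minimise
`Σ_{i<j}(r_ij − (ΛΛ')_ij)²` over the uniquenesses ψ, with Λ obtained
for each ψ from the truncated eigendecomposition of R with communalities
on the diagonal. Start values are squared multiple correlations;
optimisation is L-BFGS-B with ψ bounded to [0, 1]. Negative fitted
uniquenesses (Heywood cases) are clamped to 0 and flagged, matching
common software behaviour rather than aborting.

*Rotation* is oblique Geomin, ε = 0.01 with k-th-root normalisation (a
widespread software default, exposed in `EFAConfig`). The minimisation
uses the gradient-projection algorithm (statsmodels' GPA engine with a
custom Geomin objective/gradient). Geomin is multimodal, so the identity
start plus 10 random orthonormal starts are tried and the lowest
criterion kept; factors are ordered by explained pattern variance and
sign-aligned. Every solution satisfies the rotation-invariance contract
`ΛΦΛ' = Λ₀Λ₀'` to 10⁻⁸ (asserted throughout the test suite). With one
factor there is nothing to rotate and no factor-correlation block.

*Sampling adequacy* is Kaiser–Meyer–Olkin from anti-image partial
correlations (`q_ij = −R⁻¹_ij/√(R⁻¹_ii R⁻¹_jj)`), overall and per item,
with the conventional 0.60 suitability bar. Singular or diagonal
matrices yield an undefined-flag result, not an exception. Salient
loadings are |λ| ≥ 0.40 (absolute value — strong negative loadings are
salient).

## Sampling schemes

`srs` draws uniformly without replacement and reproduces the population's
(typically right-skewed) summary-score distribution. The
`stratified_symmetric` scheme targets an approximately symmetric score
distribution: strata are unit score bins (sparse bins merged toward the
median until each holds ≥10 respondents), the target is a symmetric
triangular mass over scores, and selection weights are target mass over
empirical mass, with expected draws capped at stratum counts, integerised
by largest-remainder rounding (infeasible remainders moved toward the
median stratum).

The triangle's centre and half-width are the genuinely open design
choice. Centring at the population median seems natural but fails its
purpose under heavy floors: with 32% zero scores the median sits at ~1,
and the symmetric triangle truncated to the support collapses onto
scores 0–2, producing samples with *less* disability variation than
simple random sampling. The package instead selects the **widest
feasible symmetric triangle** — maximising the half-width subject to
every stratum's expected draw count fitting its population count, ties
broken toward the median. For an already-symmetric population this
recovers the population's own centre and near-uniform weights; for a
floored population the centre moves above the median, so the sample
spans the available disability range, which is what the symmetrized
design exists to achieve. "Approximately symmetric" is operationalised
as |skewness| ≤ 0.3 in tests.

## Repeated-sampling experiment

For each scheme, `n_samples` samples (default 1000; tests and the
acceptance script use 100) of n = 750 are drawn; each sample is checked
for degenerate items (redrawn with a fresh derived seed if needed,
logged), parallel-analysed, and the retained counts tabulated.
Per-replicate seeds are derived from the master seed by counter-based
hashing (`SeedSequence(master, spawn_key=(replicate, attempt))`), so
results are independent of execution order. The representative sample
per scheme is the first replicate (in derived-seed order) whose retained
count equals the modal count; ties in the mode break toward fewer
factors (parsimony). Its full report re-uses the replicate's own
parallel-analysis result and adds KMO, the rotated solution and the
salience mask.

## Synthetic populations

Latent responses follow `y_ij = (Λ*f_i)_j + e_ij`, `f ~ N(0, Φ*)`,
`e_j ~ N(0, ψ*_j)` with `ψ*_j = 1 − λ_j'Φ*λ_j` so each `y_j` has unit
variance; codes are `searchsorted(τ_j + δ, y_ij)`. The severity offset δ
shifts all thresholds upward, pushing mass into the zero code: larger δ
means easier items, hence more all-zero respondents. `calibrate_floor`
resolves δ against a target all-zero-row rate by bisection on one fixed
calibration draw (≥20 000 respondents, seed derived from the spec's), so
the achieved rate is a deterministic, monotone function of δ; analytic
inversion is impractical because the all-zero probability couples items
through the factors.

Defaults: twelve items, five categories, symmetric per-item thresholds
(−1.5, −0.5, 0.5, 1.5), k = 2 with loadings 0.7 and inter-factor
correlation 0.4 — the two getting-along items plus one cognition item
against the remaining nine, mirroring the recurring two-factor structure
of the questionnaire; a three-factor preset separates getting-along and
self-care. Per-item thresholds can be set freely to emulate marginal
heterogeneity (e.g. walking-distance hardest, dressing easiest).

### What the generator does and does not emulate

The generator is exactly the censored latent-normal model that the
polychoric estimator assumes. This makes it ideal for validating the
pipeline (threshold recovery, ρ consistency, factor-number recovery,
rotation recovery) but it is *conservative* about the floor-effect
mechanism: because the model is correctly specified at any censoring
depth, polychoric correlations remain consistent, the observed second
eigenvalue barely moves, and censoring degrades retention only through
added sampling noise in the reference spectrum (measured reference λ₂ at
n = 750: ≈1.21 at 5% zeros, ≈1.31 at 30%, ≈1.68 at 60%). With loadings
0.7 and Φ₁₂ = 0.4 the observed λ₂ is ≈1.69, so the modal retained count
under simple random sampling drops below the true k = 2 only near ~60%
all-zero rows — far deeper than the 6–32% seen in real survey data. Real
zero-inflation is better described as a mixture (a "no-disability" class
atop the latent continuum), which violates bivariate normality and biases
polychoric matrices toward equicorrelation; emulating that mechanism is
outside the generator's deliberately simple scope. Consequently the
skewed-vs-symmetric *retention* contrast at a 32% floor does not
reproduce under this generator (both schemes retain two factors), and
passing pipeline tests here does not certify behaviour on real
zero-inflated data.

## Problem sizes

Tests and the acceptance script run at desk scale: populations of
20 000, samples of 750, 100 samples per experiment, 20 parallel-analysis
replicates inside experiments (50–100 elsewhere), 20 master seeds for
seed-majority properties. The experiment default of 1000 samples remains
available through the API and CLI.

## Known limitations

* Pairwise (not joint) polychoric ML; no standard errors on ρ.
* No survey weights, no missing-data models beyond complete-case
  filtering, no confirmatory models or fit indices.
* Geomin multimodality is handled by random restarts, not global
  optimisation; with ε → 0 and k > 2 distinct local optima can persist.
* The synthetic floor mechanism is threshold-shift censoring only (see
  above); degradation onsets deeper than in real zero-inflated data.
* Score-stratified selection conditions on a function of all factors, so
  within-sample factor correlations are attenuated (even sign-flipped)
  relative to the generating Φ*; the pattern structure and retained
  factor number are the quantities the symmetrized design preserves.
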