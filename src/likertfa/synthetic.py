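"""Censored-Likert population generator with known latent structure.

Responses follow a common-factor model on the latent scale:

    y_ij = (Lambda* f_i)_j + e_ij,   f ~ N(0, Phi*),  e_j ~ N(0, psi*_j),

with psi*_j chosen so every latent response has unit variance, then
discretised into codes 0..C-1 at per-item thresholds shifted by a global
severity offset delta.  Raising delta shifts all thresholds upward, which
pushes respondents toward the zero code and creates a floor effect
(all-zero rows); delta can be calibrated by bisection so that the
proportion of all-zero respondents matches a target rate.

The default truth mirrors a 12-item disability questionnaire organised in
six two-item domains: a two-factor pattern in which the two getting-along
items plus one cognition item load on one factor and the remaining nine
items on the other (loadings 0.7, factor correlation 0.4), and a
three-factor preset separating getting-along and self-care items.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import LikertDataset
from .experiment import run_retention_experiment
from .sampling import SamplingScheme

__all__ = [
    "SyntheticPopulationSpec",
    "SyntheticPopulation",
    "two_factor_pattern",
    "three_factor_pattern",
    "default_thresholds",
    "generate_responses",
    "calibrate_floor",
    "floor_sweep",
]

N_ITEMS = 12
N_CATEGORIES = 5

ITEM_LABELS = [
    "concentrating", "learning_new_task",
    "standing_long", "walking_km",
    "washing", "dressing",
    "maintaining_friendships", "dealing_with_strangers",
    "household_responsibilities", "day_to_day_work",
    "community_activities", "emotionally_affected",
]


def two_factor_pattern(loading: float = 0.7) -> np.ndarray:
    """Getting-along items plus one cognition item vs. the other nine."""
    L = np.zeros((N_ITEMS, 2))
    minority = [1, 6, 7]          # learning_new_task + both getting-along items
    for j in range(N_ITEMS):
        L[j, 1 if j in minority else 0] = loading
    return L


def three_factor_pattern(loading: float = 0.7) -> np.ndarray:
    """Getting-along and self-care items on their own factors."""
    L = np.zeros((N_ITEMS, 3))
    getting_along = [6, 7]
    self_care = [4, 5]
    for j in range(N_ITEMS):
        if j in getting_along:
            L[j, 1] = loading
        elif j in self_care:
            L[j, 2] = loading
        else:
            L[j, 0] = loading
    return L


def default_thresholds() -> np.ndarray:
    """Symmetric per-item thresholds (-1.5, -0.5, 0.5, 1.5)."""
    return np.tile(np.array([-1.5, -0.5, 0.5, 1.5]), (N_ITEMS, 1))


def _default_factor_corr(k: int) -> np.ndarray:
    Phi = np.full((k, k), 0.4)
    np.fill_diagonal(Phi, 1.0)
    return Phi


@dataclass
class SyntheticPopulationSpec:
    """Generating truth for a censored-Likert population.

    ``severity_offset`` (delta) shifts every threshold upward, producing
    the floor effect; ``target_zero_rate``, when set, is the all-zero-row
    proportion that ``calibrate_floor`` resolves delta against.
    """

    N: int = 20_000
    true_pattern: np.ndarray = field(default_factory=two_factor_pattern)
    true_factor_corr: np.ndarray | None = None
    thresholds: np.ndarray = field(default_factory=default_thresholds)
    severity_offset: float = 0.0
    target_zero_rate: float | None = None
    seed: int | None = None

    def __post_init__(self):
        self.true_pattern = np.asarray(self.true_pattern, dtype=float)
        if self.true_factor_corr is None:
            self.true_factor_corr = _default_factor_corr(self.k)
        self.true_factor_corr = np.asarray(self.true_factor_corr, dtype=float)
        if self.target_zero_rate is not None and not (
                0.0 <= self.target_zero_rate < 1.0):
            raise ValueError("target_zero_rate must be in [0, 1)")
        eig = np.linalg.eigvalsh(self.true_factor_corr)
        if eig[0] < -1e-10:
            raise ValueError("true_factor_corr must be PSD")
        communal = np.einsum(
            "jk,kl,jl->j", self.true_pattern, self.true_factor_corr,
            self.true_pattern)
        if (communal > 1.0 + 1e-10).any():
            raise ValueError("row communalities must not exceed 1")

    @property
    def k(self) -> int:
        return self.true_pattern.shape[1]

    @property
    def p(self) -> int:
        return self.true_pattern.shape[0]

    @property
    def uniquenesses(self) -> np.ndarray:
        communal = np.einsum(
            "jk,kl,jl->j", self.true_pattern, self.true_factor_corr,
            self.true_pattern)
        return 1.0 - communal


@dataclass
class SyntheticPopulation:
    dataset: LikertDataset
    latent_scores: np.ndarray
    spec: SyntheticPopulationSpec
    achieved_zero_rate: float


def _latent_responses(spec: SyntheticPopulationSpec,
                      rng: np.random.Generator, N: int) -> tuple:
    chol = np.linalg.cholesky(
        spec.true_factor_corr + 1e-12 * np.eye(spec.k))
    f = rng.standard_normal((N, spec.k)) @ chol.T
    e = rng.standard_normal((N, spec.p)) * np.sqrt(
        np.clip(spec.uniquenesses, 0.0, None))
    return f, f @ spec.true_pattern.T + e


def _discretize(y: np.ndarray, thresholds: np.ndarray,
                delta: float) -> np.ndarray:
    codes = np.empty(y.shape, dtype=np.int64)
    for j in range(y.shape[1]):
        codes[:, j] = np.searchsorted(thresholds[j] + delta, y[:, j])
    return codes


def generate_responses(spec: SyntheticPopulationSpec) -> SyntheticPopulation:
    """Draw a population of N respondents from the spec's latent truth."""
    rng = np.random.default_rng(spec.seed)
    f, y = _latent_responses(spec, rng, spec.N)
    codes = _discretize(y, spec.thresholds, spec.severity_offset)
    ds = LikertDataset(data=codes, n_categories=N_CATEGORIES,
                       item_labels=list(ITEM_LABELS[:spec.p])
                       if spec.p <= len(ITEM_LABELS) else [])
    zero_rate = float(np.mean((codes == 0).all(axis=1)))
    return SyntheticPopulation(
        dataset=ds, latent_scores=f, spec=spec,
        achieved_zero_rate=zero_rate)


def calibrate_floor(spec: SyntheticPopulationSpec, target_zero_rate: float,
                    tolerance: float = 0.02, n_calibration: int = 20_000,
                    delta_bounds: tuple = (-8.0, 8.0),
                    max_bisections: int = 60) -> float:
    """Severity offset delta whose all-zero-row rate matches the target.

    Bisection on delta over a single fixed calibration draw (the latent
    responses are generated once from a seed derived from the spec's, so
    the achieved rate is monotone and deterministic in delta).  Raises
    ``ValueError`` with the achievable range when the target cannot be
    bracketed.
    """
    if not 0.0 <= target_zero_rate < 1.0:
        raise ValueError("target_zero_rate must be in [0, 1)")
    ss = np.random.SeedSequence(entropy=spec.seed or 0,
                                spawn_key=(0xCA11B, ))
    rng = np.random.default_rng(ss)
    _, y = _latent_responses(spec, rng, max(n_calibration, 20_000))
    first_cut = spec.thresholds[:, 0]

    def rate(delta: float) -> float:
        return float(np.mean((y < (first_cut + delta)).all(axis=1)))

    lo, hi = delta_bounds
    r_lo, r_hi = rate(lo), rate(hi)
    if target_zero_rate < r_lo - tolerance or target_zero_rate > r_hi + tolerance:
        raise ValueError(
            f"target zero rate {target_zero_rate} outside achievable range "
            f"[{r_lo:.4f}, {r_hi:.4f}] for delta in {delta_bounds}")
    delta = 0.5 * (lo + hi)
    for _ in range(max_bisections):
        delta = 0.5 * (lo + hi)
        r = rate(delta)
        if abs(r - target_zero_rate) <= tolerance and hi - lo < 0.05:
            break
        if r < target_zero_rate:
            lo = delta
        else:
            hi = delta
    achieved = rate(delta)
    if abs(achieved - target_zero_rate) > tolerance:
        raise ValueError(
            f"bisection did not reach target {target_zero_rate} "
            f"(achieved {achieved:.4f})")
    return float(delta)


def floor_sweep(base_spec: SyntheticPopulationSpec, zero_rates,
                n_samples: int = 100, n: int = 750,
                pa_replicates: int = 20, seed: int | None = None):
    """Modal retained factor count under srs across floor-effect levels.

    For each target zero rate: calibrate delta, generate a population,
    run the repeated-sampling retention experiment under simple random
    sampling, and record the modal retained count.  Returns a pandas
    DataFrame with one row per rate.
    """
    import pandas as pd

    rows = []
    for i, rate in enumerate(zero_rates):
        delta = calibrate_floor(base_spec, rate)
        pop_seed = np.random.SeedSequence(
            entropy=seed or 0, spawn_key=(i, 1)).generate_state(1)[0] % (2**31)
        spec = replace(base_spec, severity_offset=delta, seed=int(pop_seed))
        pop = generate_responses(spec)
        exp_seed = np.random.SeedSequence(
            entropy=seed or 0, spawn_key=(i, 2)).generate_state(1)[0] % (2**31)
        scheme = SamplingScheme(kind="srs", n=n)
        table = run_retention_experiment(
            pop.dataset, scheme, n_samples=n_samples, seed=int(exp_seed),
            pa_replicates=pa_replicates)
        rows.append({
            "target_zero_rate": rate,
            "achieved_zero_rate": pop.achieved_zero_rate,
            "severity_offset": delta,
            "modal_n_factors": table.modal_count(),
            **{f"n_factors_{k}": v for k, v in sorted(table.counts.items())},
        })
    return pd.DataFrame(rows)
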