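"""Two-step maximum-likelihood polychoric correlations.

Each ordinal item is assumed to discretise a latent standard-normal
variable at unknown thresholds.  Step 1 estimates the thresholds from the
item's marginal category proportions (inverse-normal of cumulative
proportions); step 2 maximises the bivariate contingency-table likelihood
over the latent correlation rho with thresholds held fixed.  Rectangle
probabilities come from the bivariate-normal CDF identity

    pi_ij = F(t_i, u_j) - F(t_{i-1}, u_j) - F(t_i, u_{j-1}) + F(t_{i-1}, u_{j-1})

evaluated by a high-accuracy quadrature routine (see ``_bvn``).

The assembled item-by-item matrix need not be positive semidefinite
(pairs are estimated separately), so an eigenvalue-clipping repair is
applied when required and always flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from . import _bvn
from .datasets import LikertDataset

__all__ = [
    "ThresholdSet",
    "PolychoricEstimate",
    "CorrelationMatrix",
    "DegenerateItemError",
    "estimate_thresholds",
    "estimate_polychoric_pair",
    "polychoric_matrix",
    "smooth_to_psd",
]

RHO_BOUND = _bvn.RHO_BOUND


class DegenerateItemError(ValueError):
    """An item has all its mass in a single category."""


@dataclass
class ThresholdSet:
    """Strictly increasing normal-scale thresholds for one ordinal item.

    ``tau`` holds the finite interior thresholds (implicit -inf/+inf at the
    ends).  Categories with zero observed counts are collapsed into the
    lower adjacent category and recorded in ``collapsed_categories``.
    """

    tau: np.ndarray
    collapsed_categories: list[int] = field(default_factory=list)

    @property
    def n_thresholds(self) -> int:
        return len(self.tau)


@dataclass
class PolychoricEstimate:
    rho: float
    thresholds_pair: tuple[ThresholdSet, ThresholdSet]
    loglik: float
    converged: bool
    n_pairs: int
    prob_floored: bool = False


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation matrix, optionally PSD-smoothed."""

    values: np.ndarray
    item_labels: list[str] = field(default_factory=list)
    smoothed: bool = False
    min_eigenvalue_before: float | None = None
    min_eigenvalue_after: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("correlation matrix must be square")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("correlation matrix must be symmetric")
        if np.max(np.abs(np.diag(self.values) - 1.0)) != 0.0:
            raise ValueError("correlation matrix must have unit diagonal")
        if not self.item_labels:
            self.item_labels = [f"item_{j + 1:02d}" for j in range(p)]

    @property
    def p(self) -> int:
        return self.values.shape[0]


def _category_counts(codes: np.ndarray, n_categories: int) -> np.ndarray:
    return np.bincount(codes, minlength=n_categories).astype(float)


def estimate_thresholds(category_counts) -> ThresholdSet:
    """Thresholds from marginal counts: tau_c = Phi^-1(cumulative prop).

    Zero-count categories are collapsed into the lower adjacent category
    (their threshold is dropped) and recorded.  An item with all counts in
    one category has no finite threshold and raises
    ``DegenerateItemError``.
    """
    counts = np.asarray(category_counts, dtype=float)
    total = counts.sum()
    if total < 1:
        raise ValueError("at least one observation is required")
    if np.count_nonzero(counts) < 2:
        raise DegenerateItemError(
            "all observations fall in a single category; no finite thresholds")
    collapsed = [int(c) for c in np.flatnonzero(counts == 0)]
    nonzero = counts[counts > 0]
    cum = np.cumsum(nonzero) / total
    tau = norm.ppf(cum[:-1])
    return ThresholdSet(tau=tau, collapsed_categories=collapsed)


def _cut_vector(category_counts: np.ndarray) -> np.ndarray:
    """Full cut vector of length C+1 with -inf/+inf sentinels.

    Zero-count categories yield repeated cuts (zero-width cells); the
    likelihood kernel skips empty cells, so this is equivalent to
    collapsing them into the lower adjacent category.
    """
    counts = np.asarray(category_counts, dtype=float)
    cum = np.cumsum(counts) / counts.sum()
    interior = norm.ppf(np.clip(cum[:-1], 0.0, 1.0))
    return np.concatenate([[-np.inf], interior, [np.inf]])


def estimate_polychoric_pair(table, xatol: float = 1e-6,
                             maxiter: int = 200) -> PolychoricEstimate:
    """Two-step ML polychoric correlation from a C x C contingency table.

    Thresholds are fixed at the marginal estimates; rho then maximises
    ``sum_ij n_ij log pi_ij(rho, tau)`` by bounded one-dimensional search
    on ``[-RHO_BOUND, RHO_BOUND]``.  Cell probabilities are floored at
    1e-12 inside the log (flagged via ``prob_floored``).
    """
    table = np.asarray(table, dtype=float)
    row_margin = table.sum(axis=1)
    col_margin = table.sum(axis=0)
    if np.count_nonzero(row_margin) < 2:
        raise DegenerateItemError("row item is degenerate (single category)")
    if np.count_nonzero(col_margin) < 2:
        raise DegenerateItemError("column item is degenerate (single category)")
    cuts_a = _cut_vector(row_margin)
    cuts_b = _cut_vector(col_margin)
    rho, ll, converged, floored = _bvn.fit_pair(
        table, cuts_a, cuts_b, xatol, maxiter)
    return PolychoricEstimate(
        rho=float(rho),
        thresholds_pair=(estimate_thresholds(row_margin),
                         estimate_thresholds(col_margin)),
        loglik=float(ll),
        converged=bool(converged),
        n_pairs=int(table.sum()),
        prob_floored=bool(floored),
    )


def pair_tables(data: np.ndarray, n_categories: int) -> np.ndarray:
    """All p*(p-1)/2 pairwise contingency tables, vectorised.

    Returns an (m, C, C) array in the order of ``itertools.combinations``.
    """
    n, p = data.shape
    C = n_categories
    ii, jj = np.triu_indices(p, k=1)
    m = len(ii)
    combined = data[:, ii] * C + data[:, jj]          # (n, m)
    offsets = np.arange(m) * C * C
    flat = np.bincount((combined + offsets).ravel(), minlength=m * C * C)
    return flat.reshape(m, C, C).astype(float)


def fit_all_pairs(tables: np.ndarray, cuts: np.ndarray,
                  pair_a: np.ndarray, pair_b: np.ndarray,
                  xatol: float = 1e-6, maxiter: int = 200):
    """Batch two-step ML over many tables sharing an item cut bank."""
    return _bvn.fit_pairs_batch(
        np.ascontiguousarray(tables, dtype=np.float64),
        np.ascontiguousarray(cuts, dtype=np.float64),
        np.ascontiguousarray(pair_a, dtype=np.int64),
        np.ascontiguousarray(pair_b, dtype=np.int64),
        xatol, maxiter)


def item_cut_bank(data: np.ndarray, n_categories: int) -> np.ndarray:
    """Per-item cut vectors stacked as a (p, C+1) array."""
    p = data.shape[1]
    cuts = np.empty((p, n_categories + 1))
    for j in range(p):
        cuts[j] = _cut_vector(_category_counts(data[:, j], n_categories))
    return cuts


def check_degenerate_items(ds: LikertDataset) -> list[str]:
    """Labels of items whose observations fall in a single category."""
    bad = []
    for j in range(ds.p):
        counts = _category_counts(ds.data[:, j], ds.n_categories)
        if np.count_nonzero(counts) < 2:
            bad.append(ds.item_labels[j])
    return bad


def polychoric_matrix(ds: LikertDataset, smooth: bool = True,
                      xatol: float = 1e-6) -> CorrelationMatrix:
    """Pairwise polychoric correlation matrix of a complete dataset."""
    if not ds.is_complete:
        raise ValueError("polychoric_matrix requires complete data")
    bad = check_degenerate_items(ds)
    if bad:
        raise DegenerateItemError(
            f"degenerate items (single observed category): {bad}")
    p = ds.p
    tables = pair_tables(ds.data, ds.n_categories)
    cuts = item_cut_bank(ds.data, ds.n_categories)
    ii, jj = np.triu_indices(p, k=1)
    rho, _, _, _ = fit_all_pairs(tables, cuts, ii, jj, xatol=xatol)
    R = np.eye(p)
    R[ii, jj] = rho
    R[jj, ii] = rho
    out = CorrelationMatrix(values=R, item_labels=list(ds.item_labels))
    if smooth:
        out = smooth_to_psd(out)
    return out


def smooth_to_psd(R: CorrelationMatrix,
                  eig_floor: float = 1e-8) -> CorrelationMatrix:
    """Eigenvalue-clipping PSD repair, rescaled to unit diagonal.

    A no-op (``smoothed=False``) when the matrix is already PSD.
    """
    eigvals = np.linalg.eigvalsh(R.values)
    min_before = float(eigvals[0])
    if min_before >= 0.0:
        return CorrelationMatrix(
            values=R.values, item_labels=list(R.item_labels),
            smoothed=False, min_eigenvalue_before=min_before,
            min_eigenvalue_after=min_before)
    w, V = np.linalg.eigh(R.values)
    w = np.clip(w, eig_floor, None)
    M = (V * w) @ V.T
    d = np.sqrt(np.diag(M))
    M = M / np.outer(d, d)
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    min_after = float(np.linalg.eigvalsh(M)[0])
    return CorrelationMatrix(
        values=M, item_labels=list(R.item_labels), smoothed=True,
        min_eigenvalue_before=min_before, min_eigenvalue_after=min_after)
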