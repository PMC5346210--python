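"""Parallel-analysis factor retention on polychoric matrices.

The number of factors is decided by comparing the PCA eigenvalues of the
observed polychoric matrix with the mean eigenvalues of reference data in
which the dependence between items has been destroyed.  Reference data
are built by independently permuting each item's column (preserving every
marginal category distribution); each replicate's polychoric matrix is
re-estimated and its PCA spectrum recorded.  The mean-eigenvalue
criterion retains the leading factors whose observed eigenvalue exceeds
the reference mean, stopping at the first failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import LikertDataset
from .polychoric import (CorrelationMatrix, fit_all_pairs, item_cut_bank,
                         pair_tables, polychoric_matrix)

__all__ = [
    "RetentionResult",
    "pca_eigenvalues",
    "reference_eigenvalues",
    "retain_factors",
    "parallel_analysis",
]

REFERENCE_METHOD = "column-permutation"


@dataclass
class RetentionResult:
    observed_eigenvalues: np.ndarray
    reference_means: np.ndarray
    n_factors: int
    n_replicates: int
    method: str = REFERENCE_METHOD
    seed: int | None = None


def pca_eigenvalues(R: CorrelationMatrix | np.ndarray) -> np.ndarray:
    """Full PCA spectrum of a correlation matrix, descending.

    The spectrum sums to p (the trace of a unit-diagonal matrix).
    """
    values = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R)
    if np.max(np.abs(values - values.T)) > 1e-10:
        raise ValueError("matrix must be symmetric")
    return np.linalg.eigvalsh(values)[::-1]


def _replicate_spectra(ds: LikertDataset, n_replicates: int,
                       rng: np.random.Generator) -> np.ndarray:
    """PCA spectra of polychoric matrices of column-permuted replicates."""
    data = ds.data
    n, p = data.shape
    cuts = item_cut_bank(data, ds.n_categories)  # margins are permutation-invariant
    ii, jj = np.triu_indices(p, k=1)
    spectra = np.empty((n_replicates, p))
    perm = np.empty_like(data)
    for r in range(n_replicates):
        for j in range(p):
            perm[:, j] = data[rng.permutation(n), j]
        tables = pair_tables(perm, ds.n_categories)
        rho, _, _, _ = fit_all_pairs(tables, cuts, ii, jj)
        R = np.eye(p)
        R[ii, jj] = rho
        R[jj, ii] = rho
        spectra[r] = np.linalg.eigvalsh(R)[::-1]
    return spectra


def reference_eigenvalues(ds: LikertDataset, n_replicates: int = 100,
                          seed=None) -> np.ndarray:
    """Per-position mean of random-data eigenvalues across replicates."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    return _replicate_spectra(ds, n_replicates, rng).mean(axis=0)


def retain_factors(observed, reference_means) -> int:
    """Mean-eigenvalue criterion with a contiguous stopping rule.

    Counts leading positions where the observed eigenvalue exceeds the
    reference mean, stopping at the first failure (later exceedances are
    ignored).
    """
    observed = np.asarray(observed)
    reference_means = np.asarray(reference_means)
    if observed.shape != reference_means.shape:
        raise ValueError("observed and reference spectra must match in length")
    k = 0
    for obs, ref in zip(observed, reference_means):
        if obs > ref:
            k += 1
        else:
            break
    return k


def parallel_analysis(ds: LikertDataset, n_replicates: int = 100,
                      seed=None) -> RetentionResult:
    """Full parallel analysis of a complete ordinal dataset."""
    R = polychoric_matrix(ds)
    observed = pca_eigenvalues(R)
    reference = reference_eigenvalues(ds, n_replicates=n_replicates, seed=seed)
    return RetentionResult(
        observed_eigenvalues=observed,
        reference_means=reference,
        n_factors=retain_factors(observed, reference),
        n_replicates=n_replicates,
        seed=seed,
    )
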