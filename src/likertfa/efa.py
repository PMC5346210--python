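"""Exploratory factor analysis: minres extraction, Geomin rotation, KMO.

Extraction minimises the off-diagonal least-squares criterion

    f(psi) = sum_{i<j} (r_ij - (Lambda Lambda')_ij)^2

over the uniquenesses psi, with Lambda obtained for each psi from the
truncated eigendecomposition of R with communalities on the diagonal
(classical minres / ULS).  The unrotated solution is rotated obliquely by
minimising the Geomin criterion

    q(Lambda) = sum_i (prod_j (lambda_ij^2 + eps))^{1/k}

with the gradient-projection algorithm (multiple random orthonormal
starts; best criterion kept).  Sampling adequacy uses the
Kaiser-Meyer-Olkin index computed from anti-image partial correlations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from statsmodels.multivariate.factor_rotation._gpa_rotation import GPA

from .polychoric import CorrelationMatrix

__all__ = [
    "EFAConfig",
    "EFASolution",
    "KMOResult",
    "fit_minres",
    "rotate_geomin",
    "kmo",
    "salient_loadings",
    "tucker_congruence",
    "match_columns",
]


@dataclass
class EFAConfig:
    """Settings for extraction and rotation.

    geomin_epsilon is the small constant added to squared loadings inside
    the Geomin product (default 0.01, a widespread software default);
    random_starts counts random orthonormal starting rotations tried in
    addition to the identity start.
    """

    k: int = 2
    geomin_epsilon: float = 0.01
    max_iterations: int = 1000
    convergence_tol: float = 1e-6
    random_starts: int = 10
    seed: int | None = None

    def __post_init__(self):
        if self.geomin_epsilon <= 0:
            raise ValueError("geomin_epsilon must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class EFASolution:
    pattern: np.ndarray                 # p x k rotated loadings
    factor_correlations: np.ndarray     # k x k, unit diagonal
    uniquenesses: np.ndarray            # p, clamped to [0, 1]
    communalities: np.ndarray
    criterion_value: float
    residual_rms: float
    converged: bool
    heywood: np.ndarray = None          # per-item clamp flags
    unrotated: np.ndarray = None

    @property
    def k(self) -> int:
        return self.pattern.shape[1]

    def reproduced(self) -> np.ndarray:
        """Model-implied correlation matrix Lambda Phi Lambda' + diag(psi)."""
        L, P = self.pattern, self.factor_correlations
        return L @ P @ L.T + np.diag(self.uniquenesses)


@dataclass
class KMOResult:
    overall: float | None
    per_item: np.ndarray | None
    defined: bool = True


def _loadings_from_psi(R: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    Rstar = R.copy()
    np.fill_diagonal(Rstar, 1.0 - psi)
    w, V = np.linalg.eigh(Rstar)
    w = w[::-1][:k]
    V = V[:, ::-1][:, :k]
    return V * np.sqrt(np.clip(w, 0.0, None))


def _offdiag_objective(psi: np.ndarray, R: np.ndarray, k: int) -> float:
    L = _loadings_from_psi(R, psi, k)
    resid = R - L @ L.T
    iu = np.triu_indices_from(R, k=1)
    return float(np.sum(resid[iu] ** 2))


def smc_communalities(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations of each item on the remaining items."""
    Rinv = np.linalg.inv(R)
    return 1.0 - 1.0 / np.diag(Rinv)


def fit_minres(R: CorrelationMatrix | np.ndarray, k: int):
    """Minimum-residual (ULS) extraction of k factors.

    Returns ``(Lambda, psi, info)`` with unrotated columns ordered by
    decreasing sum of squared loadings.  Uniquenesses are clamped to
    [0, 1]; clamping marks a Heywood case in ``info['heywood']``.
    """
    values = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R)
    p = values.shape[0]
    if not 1 <= k < p:
        raise ValueError(f"k must satisfy 1 <= k < p={p}")
    min_eig = float(np.linalg.eigvalsh(values)[0])
    if min_eig < -1e-8:
        raise ValueError("matrix is not PSD; smooth it first")
    try:
        smc = smc_communalities(values)
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, 0.005, 1.0)
    start_objective = _offdiag_objective(psi0, values, k)
    res = minimize(
        _offdiag_objective, psi0, args=(values, k), method="L-BFGS-B",
        bounds=[(0.0, 1.0)] * p,
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-10})
    psi_opt = res.x
    L = _loadings_from_psi(values, psi_opt, k)
    # order columns by explained variance, fix sign so column sums >= 0
    ss = (L ** 2).sum(axis=0)
    order = np.argsort(-ss)
    L = L[:, order]
    signs = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    L = L * signs
    communal = (L ** 2).sum(axis=1)
    psi = 1.0 - communal
    heywood = psi < 0.0
    psi = np.clip(psi, 0.0, 1.0)
    resid = values - L @ L.T
    iu = np.triu_indices(p, k=1)
    info = {
        "converged": bool(res.success),
        "objective": float(res.fun),
        "start_objective": start_objective,
        "heywood": heywood,
        "residual_rms": float(np.sqrt(np.mean(resid[iu] ** 2))),
    }
    return L, psi, info


def geomin_objective(L: np.ndarray, epsilon: float):
    """Geomin criterion and its gradient with respect to the pattern."""
    k = L.shape[1]
    u = L ** 2 + epsilon
    log_rows = np.log(u).sum(axis=1) / k
    g = np.exp(log_rows)                      # row geometric means
    q = float(g.sum())
    grad = (2.0 / k) * L / u * g[:, None]
    return q, grad


def _gpa_geomin(A: np.ndarray, T0: np.ndarray, epsilon: float,
                max_tries: int, tol: float):
    def vgQ(L=None, A=None, T=None):
        return geomin_objective(L, epsilon)

    L, Phi, T, table = GPA(A, vgQ=vgQ, T=T0, max_tries=max_tries,
                           rotation_method="oblique", tol=tol)
    q = geomin_objective(L, epsilon)[0]
    return L, Phi, q, len(table) < max_tries


def rotate_geomin(L_unrotated: np.ndarray, config: EFAConfig,
                  psi: np.ndarray | None = None,
                  extraction_info: dict | None = None) -> EFASolution:
    """Oblique Geomin rotation by gradient projection with random starts.

    The identity start plus ``config.random_starts`` random orthonormal
    starts are tried; the solution with the smallest criterion is kept.
    The reproduced common part Lambda Phi Lambda' is invariant under
    rotation (equals the unrotated Lambda Lambda').
    """
    A = np.asarray(L_unrotated, dtype=float)
    p, k = A.shape
    if psi is None:
        psi = np.clip(1.0 - (A ** 2).sum(axis=1), 0.0, 1.0)
    communal = 1.0 - psi
    info = extraction_info or {}
    if k == 1:
        return EFASolution(
            pattern=A.copy(), factor_correlations=np.ones((1, 1)),
            uniquenesses=psi, communalities=communal,
            criterion_value=geomin_objective(A, config.geomin_epsilon)[0],
            residual_rms=info.get("residual_rms", np.nan),
            converged=info.get("converged", True),
            heywood=info.get("heywood", np.zeros(p, dtype=bool)),
            unrotated=A.copy())

    rng = np.random.default_rng(config.seed)
    starts = [np.eye(k)]
    for _ in range(config.random_starts):
        Q, _ = np.linalg.qr(rng.standard_normal((k, k)))
        starts.append(Q)
    best = None
    any_converged = False
    for T0 in starts:
        L, Phi, q, conv = _gpa_geomin(
            A, T0, config.geomin_epsilon, config.max_iterations,
            config.convergence_tol)
        any_converged = any_converged or conv
        if best is None or q < best[2]:
            best = (L, Phi, q)
    L, Phi, q = best
    # order factors by explained pattern variance, sign-align columns
    ss = (L ** 2).sum(axis=0)
    order = np.argsort(-ss)
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    signs = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    L = L * signs
    Phi = Phi * np.outer(signs, signs)
    Phi = (Phi + Phi.T) / 2.0
    np.fill_diagonal(Phi, 1.0)
    return EFASolution(
        pattern=L, factor_correlations=Phi, uniquenesses=psi,
        communalities=communal, criterion_value=float(q),
        residual_rms=info.get("residual_rms", np.nan),
        converged=bool(any_converged) and info.get("converged", True),
        heywood=info.get("heywood", np.zeros(p, dtype=bool)),
        unrotated=A.copy())


def efa(R: CorrelationMatrix | np.ndarray, config: EFAConfig) -> EFASolution:
    """Minres extraction followed by Geomin rotation."""
    L, psi, info = fit_minres(R, config.k)
    return rotate_geomin(L, config, psi=psi, extraction_info=info)


def kmo(R: CorrelationMatrix | np.ndarray) -> KMOResult:
    """Kaiser-Meyer-Olkin sampling adequacy, overall and per item.

    Uses anti-image partial correlations q_ij derived from the inverse of
    R.  A singular matrix, or zero numerator and denominator (e.g. the
    identity), yields an undefined-flag result rather than an exception.
    """
    values = R.values if isinstance(R, CorrelationMatrix) else np.asarray(R)
    p = values.shape[0]
    try:
        Rinv = np.linalg.inv(values)
    except np.linalg.LinAlgError:
        return KMOResult(overall=None, per_item=None, defined=False)
    d = np.sqrt(np.abs(np.diag(Rinv)))
    Q = -Rinv / np.outer(d, d)
    np.fill_diagonal(Q, 0.0)
    R2 = values ** 2
    np.fill_diagonal(R2, 0.0)
    Q2 = Q ** 2
    denom = R2.sum() + Q2.sum()
    if denom == 0.0:
        return KMOResult(overall=None, per_item=None, defined=False)
    overall = float(R2.sum() / denom)
    item_denom = R2.sum(axis=1) + Q2.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_item = np.where(item_denom > 0, R2.sum(axis=1) / item_denom, np.nan)
    return KMOResult(overall=overall, per_item=per_item, defined=True)


def salient_loadings(pattern: np.ndarray, threshold: float = 0.40) -> np.ndarray:
    """Boolean mask of loadings whose absolute value reaches the threshold."""
    return np.abs(np.asarray(pattern)) >= threshold


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's coefficient of congruence between two loading columns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def match_columns(estimated: np.ndarray, target: np.ndarray):
    """Match estimated factor columns to target columns.

    Maximises total |congruence| over column permutations (exhaustive)
    and aligns signs.  Returns ``(matched, congruences)`` where
    ``matched`` is the permuted, sign-aligned estimate and
    ``congruences`` the per-column congruence against the target.
    """
    k = target.shape[1]
    best_perm, best_total = None, -np.inf
    for perm in itertools.permutations(range(k)):
        total = sum(
            abs(tucker_congruence(estimated[:, perm[j]], target[:, j]))
            for j in range(k))
        if total > best_total:
            best_total, best_perm = total, perm
    matched = estimated[:, list(best_perm)].copy()
    congr = np.empty(k)
    for j in range(k):
        c = tucker_congruence(matched[:, j], target[:, j])
        if c < 0:
            matched[:, j] = -matched[:, j]
            c = -c
        congr[j] = c
    return matched, congr
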