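"""Sample-selection strategies over summary-score distributions.

Two schemes are implemented:

* ``srs`` — simple random sampling without replacement, which reproduces
  the population's (typically right-skewed) summary-score distribution;
* ``stratified_symmetric`` — stratified random sampling whose
  per-stratum selection weights are engineered so the sampled scores
  follow an approximately symmetric distribution around the population
  median.

Strata are unit score bins (sparse bins merged toward the median until
each holds a minimum count).  The symmetric target is a triangular mass
over scores, kept entirely inside the observed support so it is exactly
symmetric.  Its centre and half-width are chosen as the *widest* triangle
the population can actually supply at the requested sample size (every
stratum's expected draw count must not exceed its population count), with
ties broken toward the population median.  For an approximately symmetric
population this recovers the population's own centre and near-uniform
weights; for a heavily floored population it places the centre above the
median, so that respondents with varying degrees of disability are
represented instead of re-sampling the floor.  Stratum weights are
proportional to target mass over empirical mass, capped so that no
stratum is asked for more respondents than it contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingScheme",
    "InfeasibleTargetError",
    "srs_sample",
    "default_strata_edges",
    "derive_symmetric_weights",
    "stratified_sample",
    "draw_sample",
]


class InfeasibleTargetError(ValueError):
    """The symmetric target cannot be met from the available strata."""


@dataclass
class SamplingScheme:
    """Specification of a sample-selection strategy.

    ``strata_edges`` are half-open bin boundaries over summary scores
    (bin i is ``[edges[i], edges[i+1])``); ``selection_weights`` are the
    per-stratum inclusion weights (stratified scheme only).
    """

    kind: str = "srs"
    n: int = 750
    strata_edges: np.ndarray | None = None
    selection_weights: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("srs", "stratified_symmetric"):
            raise ValueError(f"unknown scheme kind: {self.kind}")
        if self.n < 1:
            raise ValueError("sample size must be >= 1")


def srs_sample(scores, n: int, seed=None) -> np.ndarray:
    """Uniform sample of n distinct row indices, sorted."""
    scores = np.asarray(scores)
    N = len(scores)
    if n > N:
        raise ValueError(f"sample size {n} exceeds population size {N}")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(N, size=n, replace=False))


def default_strata_edges(scores, min_count: int = 10) -> np.ndarray:
    """Unit score bins, merging sparse bins toward the median.

    Starts from one bin per integer score over the observed range and
    repeatedly merges any bin holding fewer than ``min_count``
    respondents into its neighbour toward the median bin.
    """
    scores = np.asarray(scores)
    lo, hi = int(scores.min()), int(scores.max())
    edges = list(range(lo, hi + 2))
    med = float(np.median(scores))
    while len(edges) > 2:
        counts = np.histogram(scores, bins=edges)[0]
        small = np.flatnonzero(counts < min_count)
        if small.size == 0:
            break
        mids = 0.5 * (np.asarray(edges[:-1]) + np.asarray(edges[1:]))
        s = int(small[np.argmax(np.abs(mids[small] - med))])
        if s == 0:
            del edges[1]              # merge into upper neighbour
        elif s == len(edges) - 2:
            del edges[s]              # merge into lower neighbour
        elif mids[s] >= med:
            del edges[s]              # merge toward the median (lower)
        else:
            del edges[s + 1]          # merge toward the median (upper)
    return np.asarray(edges, dtype=float)


def _stratum_index(scores: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, scores, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def _stratum_target(values: np.ndarray, tri: np.ndarray,
                    edges: np.ndarray) -> np.ndarray:
    strata = _stratum_index(values, edges)
    target = np.zeros(len(edges) - 1)
    np.add.at(target, strata, tri)
    return target / target.sum()


def _best_triangle(scores: np.ndarray, edges: np.ndarray,
                   counts: np.ndarray, n: int):
    """Widest feasible symmetric triangular target over summary scores.

    A candidate triangle with integer centre c and half-width w (support
    [c-w, c+w], fully inside the observed score range) is feasible when
    every stratum's expected draw count n * target_mass stays within the
    stratum's population count.  Among feasible triangles the widest wins;
    ties go to the centre closest to the population median.
    """
    lo, hi = int(scores.min()), int(scores.max())
    med = float(np.median(scores))
    values = np.arange(lo, hi + 1, dtype=float)
    best = None
    for c in range(lo + 1, hi):
        # endpoints carry zero mass, so the support may touch lo-1 / hi+1
        w_cap = min(c - (lo - 1), (hi + 1) - c)
        for w in range(w_cap, 1, -1):
            tri = np.clip(1.0 - np.abs(values - c) / w, 0.0, None)
            target = _stratum_target(values, tri, edges)
            if np.all(n * target <= counts + 1e-9):
                key = (w, -abs(c - med), -c)
                if best is None or key > best[0]:
                    best = (key, c, w, target)
                break
    if best is None:
        tri = np.clip(1.0 - np.abs(values - med)
                      / max(min(med - lo, hi - med), 1.0), 0.0, None)
        target = _stratum_target(values, tri, edges)
        binding = np.flatnonzero(n * target > counts).tolist()
        raise InfeasibleTargetError(
            "no symmetric triangular target is feasible at sample size "
            f"{n}; binding strata for the median-centred triangle: {binding}")
    _, c, w, target = best
    return c, w, target


def derive_symmetric_weights(scores, strata_edges, n: int = 750) -> np.ndarray:
    """Per-stratum selection weights yielding a symmetric score target.

    weight(stratum) is proportional to target mass / empirical mass;
    strata outside the target's support (and empty strata) get weight
    exactly 0.  Requires at least 3 non-empty strata and a feasible
    symmetric target at sample size ``n``.
    """
    scores = np.asarray(scores)
    edges = np.asarray(strata_edges, dtype=float)
    counts = np.histogram(scores, bins=edges)[0].astype(float)
    if np.count_nonzero(counts) < 3:
        raise InfeasibleTargetError("need at least 3 non-empty strata")
    _, _, target = _best_triangle(scores, edges, counts, n)
    emp = counts / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        weights = np.where(counts > 0, target / np.where(emp > 0, emp, 1.0), 0.0)
    if weights.sum() == 0:
        raise InfeasibleTargetError(
            "symmetric target assigns no mass to any non-empty stratum")
    return weights / weights.max()


def _allocate(counts: np.ndarray, weights: np.ndarray, n: int,
              median_stratum: int) -> np.ndarray:
    """Integer per-stratum allocations from weights.

    Expected allocations are proportional to weight * count, capped at
    the stratum counts (excess redistributed over uncapped strata);
    integerised by largest-remainder rounding with any infeasible
    remainder moved to the nearest feasible stratum toward the median.
    """
    expect = weights * counts
    if expect.sum() <= 0:
        raise InfeasibleTargetError("no selectable strata")
    expect = expect * (n / expect.sum())
    # water-filling cap: expected draws cannot exceed available counts
    for _ in range(len(counts)):
        over = expect > counts
        if not over.any():
            break
        excess = float((expect[over] - counts[over]).sum())
        expect[over] = counts[over]
        free = (~over) & (weights > 0) & (expect < counts)
        if not free.any():
            raise InfeasibleTargetError(
                "target infeasible at this sample size: binding strata "
                f"{np.flatnonzero(over).tolist()}")
        expect[free] += excess * expect[free] / expect[free].sum()
    alloc = np.floor(expect).astype(int)
    remainder = expect - alloc
    short = n - int(alloc.sum())
    order = np.argsort(-remainder)
    for s in order:
        if short == 0:
            break
        if alloc[s] < counts[s]:
            alloc[s] += 1
            short -= 1
    if short > 0:
        # push remaining draws to nearest feasible strata toward the median
        by_prox = np.argsort(np.abs(np.arange(len(counts)) - median_stratum))
        for s in by_prox:
            take = min(short, int(counts[s]) - alloc[s])
            alloc[s] += take
            short -= take
            if short == 0:
                break
    if short > 0:
        raise InfeasibleTargetError("population too small for requested n")
    return alloc


def stratified_sample(scores, scheme: SamplingScheme) -> np.ndarray:
    """Draw a stratified sample; returns sorted distinct row indices."""
    scores = np.asarray(scores)
    edges = scheme.strata_edges
    if edges is None:
        edges = default_strata_edges(scores)
    edges = np.asarray(edges, dtype=float)
    weights = scheme.selection_weights
    if weights is None:
        weights = derive_symmetric_weights(scores, edges, n=scheme.n)
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any() or not np.isfinite(weights).all():
        raise ValueError("selection weights must be non-negative and finite")
    counts = np.histogram(scores, bins=edges)[0].astype(float)
    m = float(np.median(scores))
    median_stratum = int(_stratum_index(np.array([m]), edges)[0])
    alloc = _allocate(counts, weights, scheme.n, median_stratum)
    strata = _stratum_index(scores, edges)
    rng = np.random.default_rng(scheme.seed)
    chosen = []
    for s in range(len(counts)):
        if alloc[s] == 0:
            continue
        members = np.flatnonzero(strata == s)
        chosen.append(rng.choice(members, size=alloc[s], replace=False))
    return np.sort(np.concatenate(chosen))


def draw_sample(scores, scheme: SamplingScheme, seed=None) -> np.ndarray:
    """Dispatch on scheme kind; ``seed`` overrides the scheme's seed."""
    if seed is not None:
        scheme = SamplingScheme(
            kind=scheme.kind, n=scheme.n, strata_edges=scheme.strata_edges,
            selection_weights=scheme.selection_weights, seed=seed)
    if scheme.kind == "srs":
        return srs_sample(scores, scheme.n, seed=scheme.seed)
    return stratified_sample(scores, scheme)
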