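"""Repeated-sampling retention experiment and full EFA reports.

For a given population and sampling scheme, many samples are drawn and
the number of factors retained by parallel analysis is recorded for each,
yielding a table of counts by retained-factor number.  One representative
sample — the first whose retained count equals the modal count — is then
factor-analysed in full (KMO adequacy, minres extraction, Geomin
rotation, salient-loading mask).

Per-replicate seeds are derived from the master seed by counter-based
hashing (``numpy.random.SeedSequence`` spawn keys), so results do not
depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import LikertDataset, describe_scores, simple_score
from .efa import EFAConfig, EFASolution, KMOResult, efa, kmo, salient_loadings
from .polychoric import check_degenerate_items, polychoric_matrix
from .retention import RetentionResult, parallel_analysis
from .sampling import SamplingScheme, draw_sample

__all__ = [
    "ExperimentTable",
    "EFAReport",
    "run_retention_experiment",
    "select_representative_sample",
    "full_efa_report",
]

MAX_REDRAWS = 20


@dataclass
class ExperimentTable:
    """Counts of replicate samples by retained-factor number."""

    counts: dict[int, int]
    n_samples: int
    n: int
    scheme_kind: str
    master_seed: int | None
    replicate_factors: list[int] = field(default_factory=list)
    replicate_seeds: list[int] = field(default_factory=list)
    n_redraws: int = 0

    def modal_count(self) -> int:
        """Most frequent retained-factor number (ties broken downward)."""
        best_k, best_n = None, -1
        for k in sorted(self.counts):
            if self.counts[k] > best_n:
                best_k, best_n = k, self.counts[k]
        return best_k

    def as_dict(self) -> dict:
        return {
            "scheme": self.scheme_kind,
            "n_samples": self.n_samples,
            "n": self.n,
            "seed": self.master_seed,
            "counts": {str(k): v for k, v in sorted(self.counts.items())},
            "modal_n_factors": self.modal_count(),
            "n_redraws": self.n_redraws,
        }


@dataclass
class EFAReport:
    kmo: KMOResult
    retention: RetentionResult
    solution: EFASolution | None
    salient: np.ndarray | None
    suitable: bool
    kmo_bar: float = 0.60


def _replicate_seed(master: int, index: int, attempt: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(index, attempt))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _draw_replicate(population: LikertDataset, scores, scheme: SamplingScheme,
                    master: int, index: int):
    """Draw one non-degenerate replicate sample (redrawing as needed)."""
    for attempt in range(MAX_REDRAWS):
        seed = _replicate_seed(master, index, attempt)
        idx = draw_sample(scores, scheme, seed=seed)
        sample = population.subset(idx)
        if not check_degenerate_items(sample):
            return sample, seed, attempt
    raise RuntimeError(
        f"replicate {index}: degenerate items persisted over "
        f"{MAX_REDRAWS} redraws")


def run_retention_experiment(population: LikertDataset,
                             scheme: SamplingScheme,
                             n_samples: int = 1000,
                             seed: int | None = None,
                             pa_replicates: int = 100) -> ExperimentTable:
    """Retained-factor counts over repeated samples from one population."""
    if not population.is_complete:
        raise ValueError("population must be complete-case filtered")
    if population.n < scheme.n:
        raise ValueError("population smaller than the sample size")
    master = 0 if seed is None else int(seed)
    scores = simple_score(population)
    counts: dict[int, int] = {}
    factors, seeds = [], []
    n_redraws = 0
    for i in range(n_samples):
        sample, rep_seed, attempt = _draw_replicate(
            population, scores, scheme, master, i)
        n_redraws += attempt
        pa = parallel_analysis(sample, n_replicates=pa_replicates,
                               seed=rep_seed)
        factors.append(pa.n_factors)
        seeds.append(rep_seed)
        counts[pa.n_factors] = counts.get(pa.n_factors, 0) + 1
    return ExperimentTable(
        counts=counts, n_samples=n_samples, n=scheme.n,
        scheme_kind=scheme.kind, master_seed=master,
        replicate_factors=factors, replicate_seeds=seeds,
        n_redraws=n_redraws)


def select_representative_sample(population: LikertDataset,
                                 scheme: SamplingScheme,
                                 experiment: ExperimentTable,
                                 seed: int | None = None) -> LikertDataset:
    """First replicate (in derived-seed order) with the modal factor count.

    The replicate's sample is reconstructed deterministically from its
    recorded seed.
    """
    modal = experiment.modal_count()
    scores = simple_score(population)
    for k, rep_seed in zip(experiment.replicate_factors,
                           experiment.replicate_seeds):
        if k == modal:
            idx = draw_sample(scores, scheme, seed=rep_seed)
            return population.subset(idx)
    raise RuntimeError("no replicate attained the modal count")  # unreachable


def full_efa_report(sample: LikertDataset,
                    config: EFAConfig | None = None,
                    pa_replicates: int = 100,
                    seed: int | None = None,
                    kmo_bar: float = 0.60) -> EFAReport:
    """KMO, parallel analysis and the rotated solution for one sample.

    The number of factors extracted equals the sample's parallel-analysis
    retention; with one factor the unrotated solution is reported and no
    factor-correlation block applies.
    """
    if not sample.is_complete:
        raise ValueError("sample must be complete")
    retention = parallel_analysis(sample, n_replicates=pa_replicates,
                                  seed=seed)
    R = polychoric_matrix(sample)
    adequacy = kmo(R)
    suitable = adequacy.defined and adequacy.overall is not None \
        and adequacy.overall > kmo_bar
    k = retention.n_factors
    if k < 1:
        return EFAReport(kmo=adequacy, retention=retention, solution=None,
                         salient=None, suitable=suitable, kmo_bar=kmo_bar)
    if config is None:
        config = EFAConfig(k=k, seed=seed)
    else:
        config = EFAConfig(
            k=k, geomin_epsilon=config.geomin_epsilon,
            max_iterations=config.max_iterations,
            convergence_tol=config.convergence_tol,
            random_starts=config.random_starts,
            seed=config.seed if config.seed is not None else seed)
    solution = efa(R, config)
    return EFAReport(
        kmo=adequacy, retention=retention, solution=solution,
        salient=salient_loadings(solution.pattern), suitable=suitable,
        kmo_bar=kmo_bar)
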