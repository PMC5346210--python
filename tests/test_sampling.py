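import numpy as np
import pytest

from likertfa import (SamplingScheme, default_strata_edges,
                      derive_symmetric_weights, describe_scores, simple_score,
                      srs_sample, stratified_sample)
from likertfa.sampling import InfeasibleTargetError, draw_sample


def triangular_population(rng, N=20_000, center=10, width=10):
    """Discrete symmetric triangular score distribution."""
    vals = np.arange(center - width, center + width + 1)
    mass = np.clip(1 - np.abs(vals - center) / width, 0, None)
    return rng.choice(vals, size=N, p=mass / mass.sum())


class TestSrsSample:
    def test_exhaustive_draw(self):
        idx = srs_sample(np.arange(10), 10, seed=0)
        np.testing.assert_array_equal(idx, np.arange(10))

    def test_reproducible_and_distinct(self):
        scores = np.arange(1000)
        a = srs_sample(scores, 100, seed=7)
        b = srs_sample(scores, 100, seed=7)
        np.testing.assert_array_equal(a, b)
        assert len(np.unique(a)) == 100

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError):
            srs_sample(np.arange(5), 6)

    def test_preserves_zero_proportion(self, censored_population):
        scores = simple_score(censored_population.dataset)
        pop_rate = np.mean(scores == 0)
        hits = 0
        for seed in range(20):
            idx = srs_sample(scores, 750, seed=seed)
            hits += abs(np.mean(scores[idx] == 0) - pop_rate) <= 0.05
        assert hits >= 19


class TestStrataAndWeights:
    def test_unit_bins_merged_to_min_count(self):
        rng = np.random.default_rng(0)
        scores = triangular_population(rng, N=2_000)
        edges = default_strata_edges(scores, min_count=10)
        counts = np.histogram(scores, bins=edges)[0]
        assert np.all(counts >= 10)
        assert edges[0] == scores.min() and edges[-1] == scores.max() + 1

    def test_symmetric_population_gets_near_uniform_weights(self):
        rng = np.random.default_rng(1)
        scores = triangular_population(rng)
        edges = default_strata_edges(scores)
        w = derive_symmetric_weights(scores, edges, n=750)
        active = w[w > 1e-6]
        assert active.max() / active.min() < 1.5

    def test_empty_stratum_weight_zero(self):
        rng = np.random.default_rng(2)
        scores = triangular_population(rng)
        scores = scores[scores != 12]        # hollow out one bin
        edges = np.arange(scores.min(), scores.max() + 2, dtype=float)
        w = derive_symmetric_weights(scores, edges, n=500)
        assert w[np.flatnonzero(edges[:-1] == 12)[0]] == 0.0

    def test_too_few_strata_rejected(self):
        scores = np.array([0] * 50 + [1] * 2)
        edges = np.array([0.0, 1.0, 2.0])
        with pytest.raises(InfeasibleTargetError):
            derive_symmetric_weights(scores, edges, n=10)

    def test_infeasible_target_names_binding_strata(self):
        scores = np.array([0] * 700 + [1] * 30 + [2] * 20)
        edges = default_strata_edges(scores)
        with pytest.raises(InfeasibleTargetError, match="binding"):
            derive_symmetric_weights(scores, edges, n=740)


class TestStratifiedSample:
    def test_equal_strata_equal_allocation(self):
        scores = np.array([0] * 50 + [1] * 50)
        scheme = SamplingScheme(
            kind="stratified_symmetric", n=10,
            strata_edges=np.array([0.0, 1.0, 2.0]),
            selection_weights=np.array([1.0, 1.0]), seed=0)
        idx = stratified_sample(scores, scheme)
        assert len(idx) == 10
        assert np.sum(scores[idx] == 0) == 5

    def test_reproducible_unique_and_exact_size(self, censored_population):
        scores = simple_score(censored_population.dataset)
        scheme = SamplingScheme(kind="stratified_symmetric", n=750, seed=3)
        a = stratified_sample(scores, scheme)
        b = stratified_sample(scores, scheme)
        np.testing.assert_array_equal(a, b)
        assert len(a) == 750
        assert len(np.unique(a)) == 750

    def test_symmetrizes_skewed_population(self, censored_population):
        scores = simple_score(censored_population.dataset)
        assert describe_scores(scores).skewness > 1.5
        hits = 0
        for seed in range(10):
            idx = stratified_sample(
                scores, SamplingScheme(kind="stratified_symmetric", n=750,
                                       seed=seed))
            hits += abs(describe_scores(scores[idx]).skewness) <= 0.3
        assert hits >= 9

    def test_median_mean_gap_smaller_than_srs(self, censored_population):
        scores = simple_score(censored_population.dataset)
        wins = 0
        for seed in range(20):
            srs = scores[srs_sample(scores, 750, seed=seed)]
            strat = scores[stratified_sample(
                scores, SamplingScheme(kind="stratified_symmetric", n=750,
                                       seed=seed))]
            gap_srs = abs(np.median(srs) - srs.mean())
            gap_strat = abs(np.median(strat) - strat.mean())
            wins += gap_strat < gap_srs
        assert wins > 10

    def test_draw_sample_dispatch(self):
        scores = np.arange(100)
        idx = draw_sample(scores, SamplingScheme(kind="srs", n=5), seed=1)
        assert len(idx) == 5
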