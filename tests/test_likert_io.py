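import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from likertfa import (LikertDataset, complete_cases, describe_scores,
                      read_likert_csv, simple_score)
from likertfa.datasets import ValidationError


def write_csv(tmp_path, text, name="data.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadLikertCsv:
    def test_all_zero_file(self, tmp_path):
        path = write_csv(tmp_path, "a,b,c\n" + "0,0,0\n" * 3)
        ds = read_likert_csv(path)
        assert ds.data.shape == (3, 3)
        assert not ds.missing_mask.any()
        assert (ds.data == 0).all()

    def test_out_of_range_code_names_location(self, tmp_path):
        path = write_csv(tmp_path, "a,b\n1,2\n5,0\n")
        with pytest.raises(ValidationError, match=r"row 1.*'a'"):
            read_likert_csv(path, n_categories=5)

    def test_blank_cell_becomes_missing(self, tmp_path):
        path = write_csv(tmp_path, "a,b\n1,\n2,3\n")
        ds = read_likert_csv(path)
        assert ds.missing_mask[0, 1]
        assert ds.missing_mask.sum() == 1

    def test_non_integer_cell_rejected(self, tmp_path):
        path = write_csv(tmp_path, "a,b\n1,x\n")
        with pytest.raises(ValidationError, match="non-integer"):
            read_likert_csv(path)


class TestCompleteCases:
    def test_drops_incomplete_rows_preserving_order(self):
        mask = np.zeros((5, 3), dtype=bool)
        mask[1, 2] = True
        mask[3, 0] = True
        data = np.arange(15).reshape(5, 3) % 5
        ds = LikertDataset(data=data, missing_mask=mask)
        out = complete_cases(ds)
        assert out.n == 3
        np.testing.assert_array_equal(out.data, data[[0, 2, 4]])

    def test_identity_when_no_missing(self):
        ds = LikertDataset(data=np.ones((4, 3), dtype=int))
        out = complete_cases(ds)
        np.testing.assert_array_equal(out.data, ds.data)

    def test_error_when_everything_missing(self):
        ds = LikertDataset(data=np.zeros((2, 2), dtype=int),
                           missing_mask=np.ones((2, 2), dtype=bool))
        with pytest.raises(ValidationError):
            complete_cases(ds)


class TestSimpleScore:
    @pytest.mark.parametrize("row,expected", [
        ([0] * 12, 0),
        ([4] * 12, 48),
        ([1, 0, 2, 0, 0, 0, 0, 0, 0, 0, 0, 0], 3),
    ])
    def test_known_sums(self, row, expected):
        ds = LikertDataset(data=np.array([row]).repeat(2, axis=0))
        assert simple_score(ds)[0] == expected

    def test_requires_complete_data(self):
        mask = np.zeros((3, 2), dtype=bool)
        mask[0, 0] = True
        ds = LikertDataset(data=np.zeros((3, 2), dtype=int),
                           missing_mask=mask)
        with pytest.raises(ValidationError):
            simple_score(ds)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 5, size=(8, 5))
        perm_items = rng.permutation(5)
        perm_rows = rng.permutation(8)
        s = simple_score(LikertDataset(data=data))
        s_items = simple_score(LikertDataset(data=data[:, perm_items]))
        np.testing.assert_array_equal(s, s_items)
        s_rows = simple_score(LikertDataset(data=data[perm_rows]))
        np.testing.assert_array_equal(s[perm_rows], s_rows)

    def test_zero_score_iff_all_zero_row(self):
        rng = np.random.default_rng(0)
        data = rng.integers(0, 5, size=(200, 12))
        data[rng.random(200) < 0.3] = 0
        s = simple_score(LikertDataset(data=data))
        np.testing.assert_array_equal(s == 0, (data == 0).all(axis=1))


class TestDescribeScores:
    def test_symmetric_scores_have_zero_skewness(self):
        scores = np.repeat([0, 1, 2, 3, 4], 10)
        d = describe_scores(scores)
        assert abs(d.skewness) < 1e-12
        assert d.skewness_defined

    @pytest.mark.parametrize("n,expected,atol", [
        (12_226, 0.02, 0.003),     # large-sample SE rounds to .02
        (750, 0.08926, 5e-4),      # direct evaluation of the SE formula
    ])
    def test_skewness_standard_error(self, n, expected, atol):
        rng = np.random.default_rng(1)
        d = describe_scores(rng.integers(0, 49, size=n))
        assert d.skewness_se == pytest.approx(expected, abs=atol)
        # SE depends on n only
        direct = math.sqrt(6 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
        assert d.skewness_se == pytest.approx(direct, rel=1e-12)

    def test_constant_scores_flagged_undefined(self):
        d = describe_scores(np.full(10, 7))
        assert not d.skewness_defined
        assert np.isfinite(d.skewness)

    def test_percentiles_monotone_and_zero_proportion(self):
        rng = np.random.default_rng(2)
        scores = rng.integers(0, 20, size=500)
        d = describe_scores(scores)
        p25, p50, p75 = d.percentiles
        assert p25 <= p50 <= p75
        assert d.zero_proportion == np.mean(scores == 0)

    def test_matches_adjusted_fisher_pearson(self):
        from scipy.stats import skew
        rng = np.random.default_rng(3)
        scores = rng.poisson(3, size=400)
        d = describe_scores(scores)
        assert d.skewness == pytest.approx(skew(scores, bias=False), rel=1e-10)
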