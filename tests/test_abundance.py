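"""Coverage normalization, contrast variables, SD bands, chi-square/OR."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magprofiler import abundance as ab
from magprofiler.core_io import ValidationError

coverage = st.floats(min_value=0.0, max_value=1e4, allow_nan=False)
positive_coverage = st.floats(min_value=1e-3, max_value=1e4, allow_nan=False)


def _matrix(values, totals):
    samples = [f"S{i+1}" for i in range(len(totals))]
    return ab.CoverageMatrix(
        values=pd.DataFrame(values, columns=samples),
        read_totals=pd.Series(totals, index=samples, dtype=float),
    )


class TestNormalize:
    def test_equal_totals_leave_values_unchanged(self):
        m = _matrix([[1.0, 2.0, 3.0, 4.0]], [1e6] * 4)
        out = ab.normalize_coverage(m)
        assert out.normalized
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_scale_factor_is_half_for_double_depth(self):
        m = _matrix([[7.0, 10.0]], [1e6, 2e6])
        out = ab.normalize_coverage(m)
        assert out.values.iloc[0, 1] == pytest.approx(5.0)
        # reference (shallowest) column unchanged
        assert out.values.iloc[0, 0] == pytest.approx(7.0)

    def test_rank_preservation_and_errors(self):
        vals = np.random.default_rng(0).uniform(0, 50, size=(20, 3))
        m = _matrix(vals, [2e6, 1e6, 3e6])
        out = ab.normalize_coverage(m)
        for j in range(3):
            assert (
                np.argsort(out.values.iloc[:, j]).tolist()
                == np.argsort(vals[:, j]).tolist()
            )
        with pytest.raises(ValidationError):
            ab.normalize_coverage(out)  # already normalized
        with pytest.raises(ValidationError):
            ab.normalize_coverage(_matrix([[1.0]], [0.0]))


class TestContrasts:
    def test_printed_contrast_for_25_fold_drop(self):
        # a PG at coverage 25 pre-H2 collapsing to 1 post-H2 in the
        # thermophilic reactor: log2(1/25) = -4.64
        cv = ab.compute_contrasts(4, 4, 25, 1, pseudocount=1e-6)
        assert cv.as_dict()["thermo_post_pre"] == pytest.approx(math.log2(1 / 25), abs=1e-4)

    @given(k=positive_coverage)
    @settings(max_examples=50, deadline=None)
    def test_equal_coverages_give_zero_everywhere(self, k):
        cv = ab.compute_contrasts(k, k, k, k)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in cv.v)

    @given(c=st.tuples(coverage, coverage, coverage, coverage))
    @settings(max_examples=100, deadline=None)
    def test_matches_direct_formula(self, c):
        pc = 0.01
        cv = ab.compute_contrasts(*c, pseudocount=pc)
        a = [x + pc for x in c]
        expected = [
            math.log2((a[2] + a[3]) / (a[0] + a[1])),
            math.log2((a[1] + a[3]) / (a[0] + a[2])),
            math.log2(a[1] / a[0]),
            math.log2(a[3] / a[2]),
            math.log2(a[2] / a[0]),
            math.log2(a[3] / a[1]),
        ]
        np.testing.assert_allclose(cv.v, expected, rtol=1e-12)

    @given(c=st.tuples(coverage, coverage, coverage, coverage))
    @settings(max_examples=100, deadline=None)
    def test_condition_swap_antisymmetry(self, c):
        """Swapping temperatures (C1<->C3, C2<->C4) negates (i),(v),(vi) and
        exchanges (iii)<->(iv)."""
        v = ab.compute_contrasts(*c).as_dict()
        w = ab.compute_contrasts(c[2], c[3], c[0], c[1]).as_dict()
        assert w["mean_thermo_meso"] == pytest.approx(-v["mean_thermo_meso"], abs=1e-9)
        assert w["pre_thermo_meso"] == pytest.approx(-v["pre_thermo_meso"], abs=1e-9)
        assert w["post_thermo_meso"] == pytest.approx(-v["post_thermo_meso"], abs=1e-9)
        assert w["meso_post_pre"] == pytest.approx(v["thermo_post_pre"], abs=1e-9)
        assert w["thermo_post_pre"] == pytest.approx(v["meso_post_pre"], abs=1e-9)

    @given(
        c=st.tuples(positive_coverage, positive_coverage, positive_coverage, positive_coverage),
        k=st.floats(min_value=0.1, max_value=100),
    )
    @settings(max_examples=50, deadline=None)
    def test_fold_change_scale_invariance(self, c, k):
        """With pseudocount scaled along, multiplying all coverages by k > 0
        changes no contrast, hence no fold change."""
        pc = 0.01
        v1 = ab.compute_contrasts(*c, pseudocount=pc).v
        v2 = ab.compute_contrasts(*(x * k for x in c), pseudocount=pc * k).v
        for a, b in zip(v1, v2):
            assert ab.fold_change(a)[1] == pytest.approx(ab.fold_change(b)[1], rel=1e-9)

    def test_negative_coverage_rejected(self):
        with pytest.raises(ValidationError):
            ab.compute_contrasts(-1, 1, 1, 1)

    def test_contrast_table_requires_full_design(self):
        m = _matrix([[1, 2, 3, 4]], [1e6] * 4)
        with pytest.raises(ValidationError):
            ab.contrast_table(m, {"S1": "C1", "S2": "C2", "S3": "C3"})


class TestFoldChange:
    @pytest.mark.parametrize(
        "v, direction, magnitude",
        [
            (-2.98, "decrease", 7.89),  # the ~8-fold SAOB collapse
            (-2.33, "decrease", 5.03),  # the ~5-fold one
            (-4.65, "decrease", 25.11),  # the most acute drop
            (0.0, "none", 1.0),
            (1.0, "increase", 2.0),
        ],
    )
    def test_log2_contrasts_match_printed_folds(self, v, direction, magnitude):
        d, m = ab.fold_change(v)
        assert d == direction
        assert m == pytest.approx(magnitude, abs=0.01)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            ab.fold_change(float("nan"))


class TestSDBands:
    def test_hand_computed_band(self):
        # mean 2, sample SD sqrt(20) ~ 4.472; deviation 8 -> band +1
        bands = ab.classify_sd_bands([0, 0, 0, 0, 10])
        assert list(bands) == [0, 0, 0, 0, 1]

    def test_value_at_mean_and_cap(self):
        vals = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        arr = np.append(vals, vals.mean())  # a value exactly at the combined mean
        bands = ab.classify_sd_bands(arr)
        assert bands[-1] == 0
        # one huge outlier among 100 zeros deviates by ~10 population SDs
        far = np.append(np.zeros(100), 1000.0)
        assert ab.classify_sd_bands(far)[-1] == 3  # capped at +/-3

    def test_zero_sd_warns(self):
        with pytest.warns(UserWarning):
            bands = ab.classify_sd_bands([1.0, 1.0, 1.0])
        assert list(bands) == [0, 0, 0]

    def test_band_zero_fraction_near_68_percent(self):
        """On a large normal sample ~68% of values sit within 1 SD."""
        x = np.random.default_rng(7).normal(size=20000)
        frac0 = (ab.classify_sd_bands(x) == 0).mean()
        assert frac0 == pytest.approx(0.6827, abs=0.015)


class TestAbundantAndPartition:
    @pytest.mark.parametrize(
        "cov, expected",
        [((5.1, 0, 0, 0), True), ((5, 5, 5, 5), False), ((0, 0, 0, 0), False)],
    )
    def test_abundance_threshold_strict(self, cov, expected):
        assert ab.flag_abundant(cov) is expected

    def test_temperature_partition_strict_2fold(self):
        labels = ab.temperature_partition([-1.5, -1.0, 0.0, 1.0, 1.01])
        assert list(labels) == ["meso", "neither", "neither", "neither", "thermo"]


class TestChiSquareOR:
    def test_derived_example(self):
        r = ab.chi_square_or(30, 10, 10, 30)
        assert r.chi2 == pytest.approx(20.0)
        assert r.odds_ratio == pytest.approx(9.0)
        assert r.ci_low == pytest.approx(3.271, abs=0.01)
        assert r.ci_high == pytest.approx(24.763, abs=0.01)
        assert not r.corrected

    def test_independence_table(self):
        r = ab.chi_square_or(10, 10, 10, 10)
        assert r.chi2 == pytest.approx(0.0)
        assert r.odds_ratio == pytest.approx(1.0)

    @given(
        a=st.integers(1, 60), b=st.integers(1, 60), c=st.integers(1, 60), d=st.integers(1, 60)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_textbook_formulas(self, a, b, c, d):
        """Closed-form Pearson chi2 n(ad-bc)^2/(row/col products) and Woolf CI."""
        r = ab.chi_square_or(a, b, c, d)
        n = a + b + c + d
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert r.chi2 == pytest.approx(chi2, rel=1e-9)
        odds = a * d / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert r.odds_ratio == pytest.approx(odds, rel=1e-9)
        assert r.ci_low == pytest.approx(odds * math.exp(-1.96 * se), rel=1e-9)
        assert r.ci_high == pytest.approx(odds * math.exp(1.96 * se), rel=1e-9)

    def test_zero_cell_haldane_correction(self):
        r = ab.chi_square_or(0, 10, 10, 10)
        assert r.corrected
        assert r.odds_ratio == pytest.approx((0.5 * 10.5) / (10.5 * 10.5), rel=1e-9)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValidationError):
            ab.chi_square_or(0, 0, 0, 0)
        with pytest.raises(ValidationError):
            ab.chi_square_or(0, 0, 5, 5)
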