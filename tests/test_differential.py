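import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from itertools import combinations
from scipy import stats

import ulmomics as u
from ulmomics.differential import DifferentialError, estimate_variance_prior, trigamma_inverse

from conftest import make_design, make_matrix


class TestLogTransformTpm:
    @pytest.mark.parametrize("tpm,expected", [(0.0, 0.0), (7.0, 3.0), (1023.0, 10.0)])
    def test_closed_form(self, tpm, expected):
        out = u.log_transform_tpm(pd.DataFrame([[tpm]], index=["G"], columns=["S"]))
        assert out.data.iloc[0, 0] == pytest.approx(expected, abs=1e-12)
        assert out.layer == "transcript"

    def test_negative_errors(self):
        with pytest.raises(DifferentialError):
            u.log_transform_tpm(pd.DataFrame([[-1.0]], index=["G"], columns=["S"]))


class TestFitTwoGroup:
    def test_exact_zero_variance(self):
        design = make_design(2, 2)
        m = make_matrix([[1, 1, 0, 0]], samples=design.sample_ids)
        fit = u.fit_two_group(m, design)
        assert fit.loc["F0", "log2FC"] == 1.0
        assert fit.loc["F0", "s2"] == 0.0
        assert fit.loc["F0", "df"] == 2.0

    def test_hand_pooled_variance(self):
        design = make_design(2, 2)
        m = make_matrix([[2, 4, 1, 1]], samples=design.sample_ids)
        fit = u.fit_two_group(m, design)
        assert fit.loc["F0", "log2FC"] == 2.0
        assert fit.loc["F0", "s2"] == 1.0  # ss_A = 2, ss_B = 0, df = 2
        assert fit.loc["F0", "df"] == 2.0

    def test_feature_missing_in_one_group_dropped(self):
        design = make_design(2, 2)
        m = make_matrix([[1, 2, np.nan, np.nan], [1, 2, 3, 4]], samples=design.sample_ids)
        fit = u.fit_two_group(m, design)
        assert list(fit.index) == ["F1"]

    def test_whole_group_missing_errors(self):
        design = make_design(2, 2)
        m = make_matrix([[1, 2, np.nan, np.nan]], samples=design.sample_ids)
        with pytest.raises(DifferentialError, match="entirely missing"):
            u.fit_two_group(m, design)


def _limma_fixture():
    """Regenerate the seeded 40 x (4+4) matrix the limma oracle values were
    computed from (Bioconductor limma 3.58.1, lmFit + eBayes)."""
    rng = np.random.default_rng(42)
    data = rng.normal(0, 1, (40, 8))
    scales = rng.uniform(0.3, 2.0, 40)
    data = data * scales[:, None]
    data[:5, :4] += 1.5
    design = make_design(4, 4)
    return make_matrix(data, features=[f"F{i:02d}" for i in range(40)], samples=design.sample_ids), design


#: frozen reference values from an independent moderated-t implementation
LIMMA_D0 = 3.7872098494
LIMMA_S0SQ = 0.7581205927
LIMMA_ROWS = {
    "F00": (3.70528907, 0.0042247971, 3.12829707),
    "F01": (1.68532775, 0.1234884224, 1.49376526),
    "F02": (3.36133163, 0.0074439522, 1.50474381),
    "F05": (-0.38562433, 0.7080236706, -0.22136847),
    "F19": (0.03347651, 0.9739674666, 0.01838349),
    "F39": (1.24682748, 0.2414737460, 0.67136905),
}


class TestEbayesModerate:
    def test_matches_independent_reference_implementation(self):
        matrix, design = _limma_fixture()
        mod = u.ebayes_moderate(u.fit_two_group(matrix, design))
        assert mod.attrs["d0"] == pytest.approx(LIMMA_D0, abs=1e-8)
        assert mod.attrs["s0_sq"] == pytest.approx(LIMMA_S0SQ, abs=1e-8)
        for feature, (t, p, logfc) in LIMMA_ROWS.items():
            assert mod.loc[feature, "t"] == pytest.approx(t, abs=1e-7)
            assert mod.loc[feature, "p"] == pytest.approx(p, abs=1e-8)
            assert mod.loc[feature, "log2FC"] == pytest.approx(logfc, abs=1e-7)

    def test_zero_spread_hits_infinite_prior_df(self):
        design = make_design(3, 3)
        rng = np.random.default_rng(1)
        data = rng.normal(size=(15, 6))
        # force identical pooled variance for every feature by scaling residuals
        m = make_matrix(data, samples=design.sample_ids)
        fits = u.fit_two_group(m, design)
        fits["s2"] = 0.7
        mod = u.ebayes_moderate(fits)
        assert np.isinf(mod.attrs["d0"])
        # every feature shares one posterior variance: an ordinary t with a
        # common variance (the bias-corrected ensemble estimate of log s2)
        assert np.allclose(mod["posterior_s2"], mod.attrs["s0_sq"])
        expected_t = fits["log2FC"] / (np.sqrt(mod.attrs["s0_sq"]) * fits["stdev_unscaled"])
        assert np.allclose(mod["t"], expected_t)
        assert np.allclose(mod["p"], 2 * stats.norm.sf(np.abs(mod["t"])))  # infinite df

    def test_closed_form_posterior_variance(self):
        design = make_design(3, 3)
        m = make_matrix(np.random.default_rng(2).normal(size=(12, 6)), samples=design.sample_ids)
        fits = u.fit_two_group(m, design)
        fits.loc["F0", "s2"] = 1.0
        mod = u.ebayes_moderate(fits, d0=4.0, s0_sq=1.0)
        assert mod.loc["F0", "posterior_s2"] == pytest.approx(1.0)  # (4*1 + 4*1) / 8

    def test_d0_zero_recovers_ordinary_t(self):
        matrix, design = _limma_fixture()
        fits = u.fit_two_group(matrix, design)
        mod = u.ebayes_moderate(fits, d0=0.0, s0_sq=1.0)
        a = matrix.data.iloc[:, :4].to_numpy()
        b = matrix.data.iloc[:, 4:].to_numpy()
        ref = stats.ttest_ind(a, b, axis=1)
        assert np.allclose(mod["t"], ref.statistic, atol=1e-10)
        assert np.allclose(mod["p"], ref.pvalue, atol=1e-12)

    def test_null_pvalues_uniform(self):
        """Moderated-t p-values on pure-noise ensembles pass a pooled
        Kolmogorov-Smirnov uniformity check."""
        design = make_design(4, 4)
        pooled = []
        rejections = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            m = make_matrix(rng.normal(size=(500, 8)), samples=design.sample_ids)
            mod = u.ebayes_moderate(u.fit_two_group(m, design))
            pooled.append(mod["p"].to_numpy())
            if stats.kstest(mod["p"], "uniform").pvalue < 0.01:
                rejections += 1
        assert stats.kstest(np.concatenate(pooled), "uniform").pvalue > 0.01
        assert rejections <= 2

    def test_degenerate_variance_ensemble_errors(self):
        design = make_design(2, 2)
        m = make_matrix(np.tile([1.0, 1.0, 0.0, 0.0], (12, 1)), samples=design.sample_ids)
        with pytest.raises(DifferentialError, match="degenerate"):
            u.ebayes_moderate(u.fit_two_group(m, design))

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for y in (0.1, 1.0, 5.0, 40.0):
            assert trigamma_inverse(float(polygamma(1, y))) == pytest.approx(y, rel=1e-6)


def bh_brute_force(p):
    """Literal step-up definition: q_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranks = np.empty(m, int)
    ranks[order] = np.arange(1, m + 1)
    return np.array([
        min(1.0, min(m * pj / rj for pj, rj in zip(p, ranks) if pj >= pi))
        for pi in p
    ])


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
            ([0.05, 1.0], [0.10, 1.0]),
        ],
    )
    def test_hand_examples(self, p, expected):
        assert np.allclose(u.bh_adjust(p), expected)

    def test_out_of_range_errors(self):
        with pytest.raises(DifferentialError):
            u.bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, p):
        assert np.allclose(u.bh_adjust(p), bh_brute_force(p), atol=1e-12)

    def test_order_preserving(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        q = u.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p - 1e-15).all()


def mwu_enumeration_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of rank splits."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for idx in combinations(range(n), nx):
        r = ranks[list(idx)].sum() - nx * (nx + 1) / 2
        us.append(r)
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestMwuTest:
    def test_extreme_separation_exact(self):
        un, p = u.mwu_test([1, 2, 3], [4, 5, 6])
        assert un == 0
        assert p == pytest.approx(0.1)

    def test_complete_tie(self):
        _, p = u.mwu_test([1.0], [1.0])
        assert p == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(DifferentialError):
            u.mwu_test([], [1.0])

    @settings(derandomize=True, max_examples=150)
    @given(
        st.lists(st.integers(min_value=0, max_value=10 ** 6), min_size=1, max_size=6),
        st.lists(st.integers(min_value=0, max_value=10 ** 6), min_size=1, max_size=6),
    )
    def test_exact_branch_matches_enumeration(self, x, y):
        pooled = x + y
        if len(set(pooled)) < len(pooled) or len(pooled) > 10:
            return  # exact branch applies only to small untied samples
        _, p = u.mwu_test(x, y)
        assert p == pytest.approx(mwu_enumeration_p(np.array(x, float), np.array(y, float)), abs=1e-12)

    def test_asymptotic_calibration(self):
        """Null rejection rate at alpha = 0.05 for n = 16 vs 12 stays in [0.03, 0.07]."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = rng.normal(size=16)
            y = rng.normal(size=12)
            _, p = u.mwu_test(x, y)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestGroupMedianDifference:
    def test_hand_median(self):
        design = make_design(2, 1)
        m = make_matrix([[1, 3, 0]], samples=design.sample_ids)
        assert u.group_median_difference(m, design).iloc[0] == 2.0

    def test_all_equal_is_zero(self, design_4_4):
        m = make_matrix(np.full((2, 8), 3.14), samples=design_4_4.sample_ids)
        assert (u.group_median_difference(m, design_4_4) == 0).all()

    def test_empty_group_feature_dropped(self):
        design = make_design(2, 2)
        m = make_matrix([[1, 2, np.nan, np.nan], [0, 0, 1, 1]], samples=design.sample_ids)
        diffs = u.group_median_difference(m, design)
        assert list(diffs.index) == ["F1"]

    def test_planted_shift_recovery(self, design_16_12):
        """A single planted -1.39 protein shift is recovered within +-0.15."""
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            is_a = np.array([c == "HLRCC" for c in design_16_12.table["cohort"]])
            vals = -1.39 * is_a + rng.normal(0, 0.3, len(is_a))
            m = make_matrix([vals], features=["FH"], samples=design_16_12.sample_ids)
            diffs.append(u.group_median_difference(m, design_16_12).iloc[0])
        assert np.mean(diffs) == pytest.approx(-1.39, abs=0.15)


def test_statistics_invariant_to_sample_permutation(design_4_4):
    rng = np.random.default_rng(5)
    m = make_matrix(rng.normal(size=(30, 8)), samples=design_4_4.sample_ids)
    res = u.differential_analysis(m, design_4_4)
    perm = rng.permutation(m.sample_ids).tolist()
    m_perm = u.ExpressionMatrix(m.data[perm], "protein")
    res_perm = u.differential_analysis(m_perm, design_4_4)
    pd.testing.assert_frame_equal(res.table, res_perm.table)


def test_result_invariants(design_4_4):
    rng = np.random.default_rng(6)
    m = make_matrix(rng.normal(size=(50, 8)), samples=design_4_4.sample_ids)
    res = u.differential_analysis(m, design_4_4).table
    assert (res["q"] >= res["p"] - 1e-15).all()
    assert np.all(np.sign(res["log2FC"]) == np.sign(res["t"]))
    ordered = res.sort_values("p")
    assert (np.diff(ordered["q"]) >= -1e-15).all()
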