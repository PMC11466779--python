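"""Normalization and moderated-statistics engine."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import special, stats as sps

from chromalink.stats import (
    DIAGNOSIS,
    RELAPSE,
    CountMatrix,
    bh_adjust,
    ebayes,
    fit_f_dist,
    fit_two_group,
    log_norm,
    moderated_test,
    read_count_matrix,
    tmm_factors,
    top_variable,
    trigamma_inverse,
    write_count_matrix,
)

GROUPS22 = [DIAGNOSIS, DIAGNOSIS, RELAPSE, RELAPSE]


def make_cm(values):
    values = np.asarray(values, dtype=float)
    return CountMatrix(
        [f"f{i}" for i in range(values.shape[0])],
        ["D1", "D2", "R1", "R2"],
        values,
        GROUPS22,
    )


def reference_tmm_factor(y_sample, y_ref, lib_sample, lib_ref):
    """Straight-line recomputation of one sample's TMM factor.

    Deliberately scalar and loop-based, mirroring a by-hand spreadsheet
    walk through the published formula.
    """
    rows = [
        (ys, yr)
        for ys, yr in zip(y_sample, y_ref)
        if ys > 0 and yr > 0
    ]
    M = [math.log2((ys / lib_sample) / (yr / lib_ref)) for ys, yr in rows]
    A = [
        0.5 * math.log2((ys / lib_sample) * (yr / lib_ref))
        for ys, yr in rows
    ]
    v = [
        (lib_sample - ys) / (lib_sample * ys) + (lib_ref - yr) / (lib_ref * yr)
        for ys, yr in rows
    ]
    n = len(M)
    lo_m, lo_a = math.floor(n * 0.3) + 1, math.floor(n * 0.05) + 1
    hi_m, hi_a = n + 1 - lo_m, n + 1 - lo_a
    rank_m = sps.rankdata(M)
    rank_a = sps.rankdata(A)
    num = den = 0.0
    for i in range(n):
        if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
            num += M[i] / v[i]
            den += 1.0 / v[i]
    return 2.0 ** (num / den)


class TestTMM:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.lognormal(2, 1, size=200)
        cm = make_cm(np.column_stack([col] * 4))
        np.testing.assert_allclose(tmm_factors(cm).tmm_factor, 1.0, atol=1e-12)

    def test_pure_depth_differences_absorbed_by_lib_size(self, rng):
        col = rng.lognormal(2, 1, size=200)
        cm = make_cm(np.column_stack([col, 2 * col, 5 * col, 0.5 * col]))
        np.testing.assert_allclose(tmm_factors(cm).tmm_factor, 1.0, atol=1e-12)

    def test_scaling_one_sample_leaves_factors_stable(self, rng):
        # depth rescaling cancels in the M-values; only the precision
        # weights shift, so factors move very little
        y = rng.lognormal(2, 1, size=(500, 4))
        f1 = tmm_factors(make_cm(y)).tmm_factor
        y2 = y.copy()
        y2[:, 2] *= 7.3
        f2 = tmm_factors(make_cm(y2)).tmm_factor
        np.testing.assert_allclose(f1, f2, rtol=0.1)

    def test_matches_stepwise_recomputation(self, rng):
        # 10% of features inflated 8-fold in one sample (composition bias)
        y = rng.lognormal(2, 1, size=(5000, 4))
        y[:500, 1] *= 8
        cm = make_cm(y)
        nf = tmm_factors(cm)
        lib = y.sum(axis=0)
        f75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(4)])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        raw = np.ones(4)
        for j in range(4):
            if j != ref:
                raw[j] = reference_tmm_factor(y[:, j], y[:, ref], lib[j], lib[ref])
        expected = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(nf.tmm_factor, expected, atol=1e-10)

    def test_all_zero_sample_rejected(self):
        y = np.ones((50, 4))
        y[:, 1] = 0
        with pytest.raises(ValueError, match="zero library size"):
            tmm_factors(make_cm(y))

    def test_geometric_mean_is_one(self, rng):
        y = rng.lognormal(2, 1, size=(400, 4))
        y[:80, 3] *= 5
        f = tmm_factors(make_cm(y)).tmm_factor
        assert abs(float(np.mean(np.log(f)))) < 1e-12


class TestLogNorm:
    def test_cpm_identity_at_unit_factor(self):
        col = np.array([1e5, 2e5, 3e5, 4e5])
        cm = make_cm(np.column_stack([col] * 4))  # lib size 1e6 per sample
        f = tmm_factors(cm)
        out = log_norm(cm, f, prior=0.0)
        np.testing.assert_allclose(out[:, 0], np.log2(col), rtol=1e-12)

    def test_prior_keeps_zeros_finite(self):
        y = np.zeros((5, 4))
        y[0] = 100.0
        cm = make_cm(y)
        out = log_norm(cm, tmm_factors(cm), prior=0.5)
        assert np.all(np.isfinite(out))

    def test_monotone_in_counts(self, rng):
        y = rng.lognormal(2, 1, size=(50, 4))
        cm = make_cm(y)
        f = tmm_factors(cm)
        base = log_norm(cm, f)[10, 2]
        y2 = y.copy()
        y2[10, 2] += 1.0
        bumped = log_norm(make_cm(y2), f)[10, 2]
        assert bumped > base


class TestTopVariable:
    def test_picks_largest_sd_rows(self):
        logm = np.array([[0, 6.0, 0, 6.0], [0, 4.0, 0, 4.0], [0, 2.0, 0, 2.0]])
        np.testing.assert_array_equal(top_variable(logm, 2), [0, 1])

    def test_matches_full_sort_oracle(self, rng):
        logm = rng.normal(size=(500, 4))
        sd = logm.std(axis=1, ddof=1)
        expected = set(np.argsort(-sd, kind="stable")[:100])
        assert set(top_variable(logm, 100)) == expected

    def test_n_larger_than_rows_is_noop(self, rng):
        logm = rng.normal(size=(20, 4))
        np.testing.assert_array_equal(top_variable(logm, 10_000), np.arange(20))

    def test_ties_broken_by_input_order(self):
        logm = np.tile([0.0, 1.0, 0.0, 1.0], (5, 1))
        np.testing.assert_array_equal(top_variable(logm, 2), [0, 1])


class TestTwoGroupFit:
    def test_constant_groups(self):
        logm = np.array([[1.0, 1.0, 3.0, 3.0]])
        lfc, s2, df = fit_two_group(logm, GROUPS22)
        assert lfc[0] == 2.0 and s2[0] == 0.0 and df == 2

    def test_equal_means_zero_lfc(self):
        logm = np.array([[1.0, 3.0, 3.0, 1.0]])
        lfc, _, _ = fit_two_group(logm, GROUPS22)
        assert lfc[0] == 0.0

    def test_matches_ols_oracle(self, rng):
        logm = rng.normal(size=(200, 4))
        lfc, s2, df = fit_two_group(logm, GROUPS22)
        X = np.column_stack([np.ones(4), [0, 0, 1, 1.0]])
        for i in range(200):
            beta, res, *_ = np.linalg.lstsq(X, logm[i], rcond=None)
            assert lfc[i] == pytest.approx(beta[1], rel=1e-10)
            assert s2[i] == pytest.approx(float(res[0]) / df, rel=1e-10)

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError, match=">=2 samples"):
            fit_two_group(np.ones((3, 3)), [DIAGNOSIS, RELAPSE, RELAPSE])


class TestTrigammaInverse:
    @pytest.mark.parametrize("x", [1e-5, 0.01, 0.5, 2.0, 50.0, 1e8])
    def test_inverts_trigamma(self, x):
        y = trigamma_inverse(x)
        assert float(special.polygamma(1, y)) == pytest.approx(x, rel=1e-6)


class TestEbayes:
    def test_equal_variances_give_infinite_prior_df(self):
        from chromalink.stats import squeeze_var

        s2 = np.full(100, 0.7)
        d0, s0_sq, s2_post = squeeze_var(s2, 2)
        assert math.isinf(d0)
        assert s0_sq == pytest.approx(0.7, rel=1e-9)
        np.testing.assert_allclose(s2_post, 0.7, rtol=1e-9)

    def test_posterior_between_s2_and_prior(self, rng):
        from chromalink.stats import squeeze_var

        s2 = 0.25 * rng.f(2, 4, size=500)
        d0, s0_sq, s2_post = squeeze_var(s2, 2)
        lo = np.minimum(s2, s0_sq)
        hi = np.maximum(s2, s0_sq)
        inner = np.abs(s2 - s0_sq) > 1e-12
        assert np.all(s2_post[inner] > lo[inner])
        assert np.all(s2_post[inner] < hi[inner])

    def test_forcing_zero_prior_df_recovers_ordinary_t(self, rng):
        logm = rng.normal(size=(200, 4))
        lfc, s2, df = fit_two_group(logm, GROUPS22)
        out = ebayes(lfc, s2, df, 1.0, d0=0)
        t_ref, p_ref = sps.ttest_ind(logm[:, 2:], logm[:, :2], axis=1)
        np.testing.assert_allclose(out["t_mod"], t_ref, rtol=1e-9)
        np.testing.assert_allclose(out["p"], p_ref, rtol=1e-9)

    def test_all_zero_variances_instruct_floor(self):
        from chromalink.stats import squeeze_var

        with pytest.raises(ValueError, match="variance floor"):
            squeeze_var(np.zeros(100), 2)

    def test_few_features_fall_back_to_mean(self):
        from chromalink.stats import squeeze_var

        s2 = np.array([0.1, 0.2, 0.3])
        d0, s0_sq, s2_post = squeeze_var(s2, 2)
        assert math.isinf(d0)
        np.testing.assert_allclose(s2_post, s2.mean())

    def test_prior_recovery_from_scaled_f(self, rng):
        s2 = 0.25 * rng.f(2, 4, size=20_000)
        d0, s0_sq = fit_f_dist(s2, 2)
        assert d0 == pytest.approx(4.0, rel=0.2)
        assert s0_sq == pytest.approx(0.25, rel=0.1)


def brute_force_bh(p):
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank_pos, i in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        out[i] = min(1.0, min(candidates))
    return out


class TestBHAdjust:
    def test_linear_pattern_collapses(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), 0.04
        )

    def test_direct_formula(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.005, 0.1, 0.9])), [0.015, 0.15, 0.9]
        )

    def test_matches_textbook_definition(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=500)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_never_decreases_and_preserves_ranking(self, p):
        p = np.asarray(p)
        adj = bh_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestModeratedTest:
    def test_null_matrix_yields_no_small_padj(self, rng):
        logm = rng.normal(size=(500, 4))
        res = moderated_test(logm, [f"f{i}" for i in range(500)], GROUPS22)
        assert (res.table["p_adj"] < 0.1).sum() == 0

    def test_group_swap_negates_logfc(self, rng):
        logm = rng.normal(size=(100, 4))
        feats = [f"f{i}" for i in range(100)]
        a = moderated_test(logm, feats, GROUPS22)
        b = moderated_test(
            logm, feats, [RELAPSE, RELAPSE, DIAGNOSIS, DIAGNOSIS]
        )
        np.testing.assert_allclose(
            a.table["log_fc"], -b.table["log_fc"], rtol=1e-12
        )
        np.testing.assert_allclose(a.table["p"], b.table["p"], rtol=1e-12)


def test_count_matrix_round_trip(tmp_path, rng):
    cm = make_cm(rng.lognormal(2, 1, size=(30, 4)))
    write_count_matrix(cm, tmp_path / "m.tsv")
    back = read_count_matrix(tmp_path / "m.tsv")
    np.testing.assert_array_equal(back.values, cm.values)
    assert back.group == cm.group


def test_count_matrix_validation():
    with pytest.raises(ValueError, match="negative"):
        make_cm(np.full((2, 4), -1.0))
    with pytest.raises(ValueError, match="unique"):
        CountMatrix(["a", "a"], ["D1", "D2", "R1", "R2"], np.ones((2, 4)), GROUPS22)
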