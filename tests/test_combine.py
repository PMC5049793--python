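import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cpmeta.combine import (
    HetNull,
    SingularCorrelationError,
    WeightSpec,
    build_shet_null,
    p_het,
    p_het_batch,
    panel_weights,
    s_het,
    s_het_batch,
    s_hom,
    s_hom_batch,
    s_tau,
)
from cpmeta.scan import weighted_z_meta

from .conftest import oracle_s_het, oracle_s_hom, oracle_s_tau, random_corr

R2_BMI = np.array([[1.0, 0.096], [0.096, 1.0]])
N_SEX = np.array([60586.0, 73137.0])


@pytest.fixture(scope="module")
def null_2panel():
    return build_shet_null(R2_BMI, N_SEX, B=50_000, seed=11)


class TestSHom:
    def test_null_vector_zero_statistic(self):
        stat, p, k = s_hom([0.0, 0.0], [100, 100], np.eye(2))
        assert stat == 0.0 and p == 1.0 and k == 2

    def test_single_panel_chi2_tail(self):
        stat, p, _ = s_hom([2.0], [1.0], np.eye(1), scheme="unit")
        assert stat == pytest.approx(4.0)
        assert p == pytest.approx(0.0455, abs=1e-4)

    def test_table2_height_snp_reaches_genome_wide(self):
        # PAPER inputs: per-sex P 3.88E-05 / 2.11E-05 (both beta < 0),
        # n 60,586 / 73,137, male-female height correlation 0.0126
        z_m = -stats.norm.isf(3.88e-5 / 2)
        z_f = -stats.norm.isf(2.11e-5 / 2)
        r = np.array([[1.0, 0.0126], [0.0126, 1.0]])
        _, p, _ = s_hom([z_m, z_f], N_SEX, r, scheme="sqrt_n")
        assert p < 5e-8

    def test_agrees_with_dense_formula_oracle(self, rng):
        for _ in range(50):
            p = rng.integers(2, 5)
            R = random_corr(p, rng)
            T = rng.standard_normal(p) * 2
            n = rng.uniform(500, 5000, p)
            for scheme in ("sqrt_n", "n", "unit"):
                stat, _, _ = s_hom(T, n, R, scheme)
                assert stat == pytest.approx(oracle_s_hom(T, n, R, scheme), rel=1e-10)

    def test_missing_entries_subset(self, rng):
        R = random_corr(3, rng)
        T = np.array([1.0, np.nan, -2.0])
        n = np.array([100.0, 200.0, 300.0])
        stat, _, k = s_hom(T, n, R)
        sub = np.ix_([0, 2], [0, 2])
        expect = oracle_s_hom(T[[0, 2]], n[[0, 2]], R[sub])
        assert k == 2
        assert stat == pytest.approx(expect, rel=1e-12)

    def test_all_missing_flagged(self):
        stat, p, k = s_hom([np.nan, np.nan], [1, 1], np.eye(2))
        assert np.isnan(stat) and np.isnan(p) and k == 0

    def test_singular_r_raises(self):
        r = np.ones((2, 2))
        with pytest.raises(SingularCorrelationError):
            s_hom([1.0, 2.0], [100, 100], r)

    def test_weight_scale_invariance(self, rng):
        R = random_corr(3, rng)
        T = rng.standard_normal(3)
        n = np.array([100.0, 900.0, 2500.0])
        a, _, _ = s_hom(T, n, R, "sqrt_n")
        b, _, _ = s_hom(T, 16.0 * n, R, "sqrt_n")  # weights x4
        assert a == pytest.approx(b, rel=1e-12)

    def test_reduction_to_weighted_z_with_equal_n(self, rng):
        T = rng.standard_normal(4)
        n = np.full(4, 1234.0)
        stat, _, _ = s_hom(T, n, np.eye(4), "sqrt_n")
        z, _ = weighted_z_meta(T, n)
        assert stat == pytest.approx(z * z, rel=1e-10)

    def test_unequal_n_matches_dense_oracle_not_weighted_z(self, rng):
        # with unequal n the implemented form is the printed one, which
        # differs from the baseline z^2; pin both facts
        T = np.array([1.0, 2.0])
        n = np.array([100.0, 10000.0])
        stat, _, _ = s_hom(T, n, np.eye(2), "sqrt_n")
        assert stat == pytest.approx(oracle_s_hom(T, n, np.eye(2)), rel=1e-12)
        z, _ = weighted_z_meta(T, n)
        assert stat != pytest.approx(z * z, rel=1e-6)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 10_000))
    def test_sign_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(1, 6))
        R = random_corr(p, rng)
        T = rng.standard_normal(p) * 3
        n = rng.uniform(100, 1000, p)
        assert s_hom(T, n, R)[0] == pytest.approx(s_hom(-T, n, R)[0], rel=1e-12)
        assert s_het(T, n, R)[0] == pytest.approx(s_het(-T, n, R)[0], rel=1e-12)


class TestSTau:
    def test_single_component_signed_weight_cancels(self):
        assert s_tau([3.0], [100.0], np.eye(1), tau=1.0) == pytest.approx(9.0)

    def test_opposite_signs_hand_algebra(self):
        # a = (1/w, -1/w); a'T = 5/w; a'a = 2/w^2 -> 12.5
        val = s_tau([2.5, -2.5], [400.0, 400.0], np.eye(2), tau=2.0)
        assert val == pytest.approx(12.5, rel=1e-10)
        assert val == pytest.approx(
            oracle_s_tau([2.5, -2.5], [400.0, 400.0], np.eye(2), 2.0), rel=1e-10
        )

    def test_empty_active_set_undefined(self):
        assert np.isnan(s_tau([2.5, -2.5], [400.0, 400.0], np.eye(2), tau=3.0))

    def test_matches_oracle_random(self, rng):
        for _ in range(30):
            p = int(rng.integers(2, 6))
            R = random_corr(p, rng)
            T = rng.standard_normal(p) * 2
            n = rng.uniform(100, 1000, p)
            tau = float(rng.uniform(0, 2))
            got = s_tau(T, n, R, tau=tau)
            want = oracle_s_tau(T, n, R, tau)
            if want is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-10)


class TestSHet:
    def test_single_panel_square(self):
        stat, tau, act, k = s_het([-3.2], [100.0], np.eye(1))
        assert stat == pytest.approx(10.24)
        assert act == (0,)

    def test_drops_weak_component(self):
        # keeping only the strong component beats combining: 25.0 > 13.005
        stat, tau, act, _ = s_het([5.0, 0.1], [400.0, 400.0], np.eye(2))
        assert stat == pytest.approx(25.0, rel=1e-9)
        assert act == (0,)
        assert tau == pytest.approx(5.0, abs=1e-6)

    def test_all_zero_vector(self):
        stat, _, act, _ = s_het([0.0, 0.0], [1.0, 1.0], np.eye(2))
        assert stat == 0.0 and act == ()

    def test_exhaustive_subset_oracle_100_random_cases(self, rng):
        for _ in range(100):
            p = int(rng.integers(2, 7))
            R = random_corr(p, rng)
            T = rng.standard_normal(p) * 2.5
            n = rng.uniform(100, 5000, p)
            stat, _, _, _ = s_het(T, n, R)
            assert stat == pytest.approx(oracle_s_het(T, n, R), rel=1e-10)

    def test_dominates_every_s_tau(self, rng):
        p = 5
        R = random_corr(p, rng)
        T = rng.standard_normal(p) * 2
        n = rng.uniform(100, 1000, p)
        stat, _, _, _ = s_het(T, n, R)
        for tau in np.linspace(0.01, np.abs(T).max() - 1e-6, 17):
            val = s_tau(T, n, R, tau=tau)
            if np.isfinite(val):
                assert stat >= val - 1e-10

    def test_batch_matches_scalar(self, rng):
        p = 4
        R = random_corr(p, rng)
        Z = rng.standard_normal((40, p)) * 2
        Z[3, 1] = np.nan
        n = rng.uniform(100, 1000, p)
        batch_s, batch_tau, batch_k = s_het_batch(Z, n, R)
        for i in range(40):
            stat, tau, _, k = s_het(Z[i], n, R)
            assert batch_s[i] == pytest.approx(stat, rel=1e-12)
            assert batch_k[i] == k

    def test_hom_batch_matches_scalar(self, rng):
        p = 4
        R = random_corr(p, rng)
        Z = rng.standard_normal((40, p)) * 2
        Z[5, 2] = np.nan
        n = rng.uniform(100, 1000, p)
        batch_s, batch_p, batch_k = s_hom_batch(Z, n, R)
        for i in range(40):
            stat, pv, k = s_hom(Z[i], n, R)
            assert batch_s[i] == pytest.approx(stat, rel=1e-12)
            assert batch_p[i] == pytest.approx(pv, rel=1e-12)


class TestHetNull:
    def test_determinism(self):
        a = build_shet_null(np.eye(2), [100.0, 100.0], B=1_000, seed=3)
        b = build_shet_null(np.eye(2), [100.0, 100.0], B=1_000, seed=3)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_draws_nonnegative_sorted(self, null_2panel):
        assert (null_2panel.draws >= 0).all()
        assert (np.diff(null_2panel.draws) >= 0).all()

    def test_identity_null_tail_against_integration_oracle(self):
        # DERIVED: for two independent equal-weight panels
        # S_het = max(T1^2, T2^2, (|T1|+|T2|)^2/2), so P(S_het > q) follows
        # from a 2-D normal integral (= 0.13247 at the chi2(1) 0.95 quantile;
        # note S_het >= max T^2 forces P >= 1 - 0.95^2 = 0.0975)
        from scipy import integrate

        q95 = stats.chi2.isf(0.05, df=1)
        a, b = np.sqrt(q95), np.sqrt(2 * q95)
        inside, _ = integrate.dblquad(
            lambda y, x: 4 * stats.norm.pdf(x) * stats.norm.pdf(y),
            0, a, lambda x: 0, lambda x: min(a, b - x),
        )
        expect = 1 - inside
        assert expect == pytest.approx(0.13247, abs=1e-4)
        null = build_shet_null(np.eye(2), [100.0, 100.0], B=100_000, seed=5)
        frac = float((null.draws > q95).mean())
        assert frac == pytest.approx(expect, abs=4 * np.sqrt(expect * (1 - expect) / null.n_draws))

    def test_median_stability_across_b(self):
        small = build_shet_null(R2_BMI, N_SEX, B=1_000, seed=20)
        big = build_shet_null(R2_BMI, N_SEX, B=100_000, seed=22)
        m_small = float(np.median(small.draws))
        m_big = float(np.median(big.draws))
        assert abs(m_small - m_big) / m_big < 0.05

    def test_tail_fit_diagnostic_recorded(self, null_2panel):
        assert null_2panel.diagnostics["q99_rel_err"] < 0.10

    def test_b_minimum_enforced(self):
        with pytest.raises(ValueError):
            build_shet_null(np.eye(2), [1.0, 1.0], B=10, seed=0)

    def test_save_load_round_trip(self, tmp_path, null_2panel):
        null_2panel.save(tmp_path / "null")
        back = HetNull.load(tmp_path / "null")
        np.testing.assert_array_equal(back.draws, null_2panel.draws)
        assert back.seed == null_2panel.seed
        assert back.tail_alpha == pytest.approx(null_2panel.tail_alpha)

    def test_p_het_zero_statistic(self, null_2panel):
        assert p_het(0.0, null_2panel) == pytest.approx(1.0, abs=2 / null_2panel.n_draws)

    def test_p_het_median(self, null_2panel):
        med = float(np.median(null_2panel.draws))
        assert p_het(med, null_2panel) == pytest.approx(0.5, abs=0.01)

    def test_p_het_monotone_into_fitted_tail(self, null_2panel):
        top = float(null_2panel.draws[-1])
        grid = np.linspace(0.5 * top, 2.0 * top, 25)
        ps = [p_het(s, null_2panel) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert ps[-1] > 0

    def test_p_het_negative_raises(self, null_2panel):
        with pytest.raises(ValueError):
            p_het(-1.0, null_2panel)


class TestCalibrationAndPower:
    def test_p_hom_type_i_error(self):
        # type-I error within 3 MC standard errors at alpha 0.05 and 0.001
        rng = np.random.default_rng(99)
        B = 200_000
        chol = np.linalg.cholesky(R2_BMI)
        Z = rng.standard_normal((B, 2)) @ chol.T
        _, pvals, _ = s_hom_batch(Z, N_SEX, R2_BMI)
        for alpha in (0.05, 0.001):
            rate = float((pvals < alpha).mean())
            se = np.sqrt(alpha * (1 - alpha) / B)
            assert abs(rate - alpha) < 3 * se

    def test_p_het_uniform_under_null(self):
        null = build_shet_null(R2_BMI, N_SEX, B=100_000, seed=101)
        rng = np.random.default_rng(202)  # independent of the null's seed
        chol = np.linalg.cholesky(R2_BMI)
        Z = rng.standard_normal((2_000, 2)) @ chol.T
        s, _, _ = s_het_batch(Z, N_SEX, R2_BMI)
        ps = p_het_batch(s, null)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_power_ordering_heterogeneous_vs_homogeneous(self):
        # opposite-direction effects: s_het wins; same-direction: s_hom wins
        rng = np.random.default_rng(77)
        alpha = 5e-4
        reps = 500
        chol = np.linalg.cholesky(R2_BMI)
        null = build_shet_null(R2_BMI, N_SEX, B=20_000, seed=303)
        thr_het = float(np.quantile(null.draws, 1 - alpha))
        thr_hom = float(stats.chi2.isf(alpha, df=1))
        delta = 3.2
        for pattern, expect_het_wins in (((+1, -1), True), ((+1, +1), False)):
            mean = delta * np.asarray(pattern)
            Z = rng.standard_normal((reps, 2)) @ chol.T + mean
            s_hom_v, _, _ = s_hom_batch(Z, N_SEX, R2_BMI)
            s_het_v, _, _ = s_het_batch(Z, N_SEX, R2_BMI)
            power_hom = float((s_hom_v > thr_hom).mean())
            power_het = float((s_het_v > thr_het).mean())
            if expect_het_wins:
                assert power_het > power_hom
            else:
                assert power_hom >= power_het


class TestWeightSpec:
    def test_schemes(self):
        n = np.array([4.0, 9.0])
        np.testing.assert_allclose(panel_weights(n, "sqrt_n"), [2.0, 3.0])
        np.testing.assert_allclose(panel_weights(n, "n"), n)
        np.testing.assert_allclose(panel_weights(n, "unit"), [1.0, 1.0])
        with pytest.raises(ValueError):
            panel_weights(n, "bogus")
        with pytest.raises(ValueError):
            WeightSpec(scheme="bogus")
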