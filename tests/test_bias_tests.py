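import itertools
import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from metabias import (
    METHOD_ORDER,
    MetaAnalysis,
    arcsine_difference,
    as_thompson_test,
    begg_test,
    egger_test,
    harbord_test,
    log_odds_ratio,
    mantel_haenszel_or,
    moments_tau2,
    nchg_moments,
    peters_test,
    rank_correlation_test,
    run_all_tests,
    schwarzer_test,
    smoothed_variance,
    sve_test,
    svt_test,
    wls_fit,
)
from metabias.exceptions import (
    CollinearDesignError,
    TooFewStudiesError,
    ValidationError,
)
from metabias.simulator import Scenario, calibrate_scenario, generate_meta


def closed_form_wls(y, x, w):
    """Independent weighted normal-equations solution (scalar arithmetic)."""
    y, x, w = (np.asarray(v, dtype=float) for v in (y, x, w))
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx**2
    beta = (sw * swxy - swx * swy) / det
    alpha = (swy - beta * swx) / sw
    return alpha, beta


class TestWlsFit:
    def test_exact_line_is_interpolated(self):
        x = np.array([0.1, 0.4, 0.9, 1.3])
        y = 2.0 - 3.0 * x
        fit = wls_fit(y, x, [1.0, 2.0, 0.5, 4.0])
        assert fit.alpha == pytest.approx(2.0, rel=1e-12)
        assert fit.beta == pytest.approx(-3.0, rel=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)

    def test_three_point_closed_form(self):
        y, x, w = [0.1, 0.5, 0.9], [0.2, 0.4, 0.8], [1.0, 1.0, 1.0]
        fit = wls_fit(y, x, w)
        alpha, beta = closed_form_wls(y, x, w)
        assert fit.alpha == pytest.approx(alpha, rel=1e-12)
        assert fit.beta == pytest.approx(beta, rel=1e-12)

    def test_matches_statsmodels_on_random_instances(self, rng):
        for _ in range(50):
            k = int(rng.integers(3, 40))
            x = rng.uniform(0.1, 2.0, size=k)
            y = rng.normal(size=k)
            w = rng.uniform(0.2, 5.0, size=k)
            fit = wls_fit(y, x, w, dispersion="multiplicative")
            ref = sm.WLS(y, sm.add_constant(x), weights=w).fit()
            assert fit.alpha == pytest.approx(ref.params[0], rel=1e-9)
            assert fit.beta == pytest.approx(ref.params[1], rel=1e-9)
            assert fit.se_beta == pytest.approx(ref.bse[1], rel=1e-8)
            assert fit.p_beta == pytest.approx(ref.pvalues[1], rel=1e-8)

    def test_constant_covariate_raises(self):
        with pytest.raises(CollinearDesignError):
            wls_fit([0.1, 0.2, 0.3], [0.3, 0.3, 0.3], [1, 1, 1])

    def test_too_few_studies(self):
        with pytest.raises(TooFewStudiesError):
            wls_fit([0.1, 0.2], [0.1, 0.2], [1, 1])

    def test_floor_dispersion_never_shrinks_standard_errors(self, rng):
        k = 10
        x = rng.uniform(0.1, 1.0, size=k)
        y = 0.2 * x + rng.normal(scale=0.01, size=k)  # under-dispersed
        w = 1.0 / rng.uniform(0.5, 1.5, size=k)
        multiplicative = wls_fit(y, x, w, dispersion="multiplicative")
        floored = wls_fit(y, x, w, dispersion="floor")
        assert floored.se_beta >= multiplicative.se_beta
        assert floored.beta == multiplicative.beta


class TestMomentsTau2:
    def test_zero_when_no_excess_dispersion(self):
        x = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        y = 0.1 + 0.5 * x  # zero scatter: Q = 0 <= k - 2
        assert moments_tau2(y, x, np.full(5, 0.04)) == 0.0

    def test_matches_independent_matrix_evaluation(self):
        y = np.array([0.12, 0.47, 0.31, 0.88, 0.50])
        x = np.array([0.30, 0.55, 0.42, 0.90, 0.61])
        v = np.array([0.05, 0.08, 0.03, 0.10, 0.06])
        # independent route: explicit hat-matrix algebra
        design = np.column_stack([np.ones(5), x])
        w_mat = np.diag(1.0 / v)
        bread = np.linalg.inv(design.T @ w_mat @ design)
        coef = bread @ design.T @ w_mat @ y
        resid = y - design @ coef
        q = float(resid @ w_mat @ resid)
        denom = float(
            np.trace(w_mat) - np.trace(w_mat @ design @ bread @ design.T @ w_mat)
        )
        expected = max(0.0, (q - 3.0) / denom)
        assert moments_tau2(y, x, v) == pytest.approx(expected, rel=1e-10)

    def test_recovers_true_between_study_variance(self, rng):
        # meta-regression with tau2 = 0.25: the moments estimator is
        # approximately unbiased, so its mean over replicates is close
        k, tau2_true, n_reps = 200, 0.25, 500
        estimates = []
        for _ in range(n_reps):
            x = rng.uniform(0.1, 1.0, size=k)
            v = rng.uniform(0.02, 0.2, size=k)
            y = 0.3 + 0.8 * x + rng.normal(scale=np.sqrt(v + tau2_true))
            estimates.append(moments_tau2(y, x, v))
        assert np.mean(estimates) == pytest.approx(tau2_true, rel=0.10)


class TestRankCorrelation:
    def test_perfect_concordance_counts_all_pairs(self):
        t = np.arange(10.0)
        s = t**2
        res = rank_correlation_test(t, s)
        # S = C(10, 2) = 45; continuity-corrected z = 44 / sqrt(125)
        var = 10 * 9 * 25 / 18.0
        assert res.statistic == pytest.approx(44.0 / math.sqrt(var), rel=1e-12)

    def test_antisymmetry(self):
        t = np.array([0.3, 1.2, 0.7, 2.5, 1.9])
        s = np.array([1.0, 4.0, 2.0, 9.0, 5.0])
        res_up = rank_correlation_test(t, s)
        res_down = rank_correlation_test(-t, s)
        assert res_down.statistic == pytest.approx(-res_up.statistic, rel=1e-12)
        assert res_down.p_value == pytest.approx(res_up.p_value, rel=1e-12)

    def test_degenerate_constant_vector(self):
        res = rank_correlation_test([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert res.degenerate and res.p_value == 1.0

    def test_statistic_matches_brute_force_with_ties(self, rng):
        for _ in range(20):
            k = int(rng.integers(4, 15))
            t = rng.integers(0, 5, size=k).astype(float)  # many ties
            s = rng.integers(0, 5, size=k).astype(float)
            if np.ptp(t) == 0 or np.ptp(s) == 0:
                continue
            s_stat = sum(
                np.sign(t[j] - t[i]) * np.sign(s[j] - s[i])
                for i, j in itertools.combinations(range(k), 2)
            )
            res = rank_correlation_test(t, s, continuity=False)
            if res.degenerate:
                assert s_stat == 0 or res.p_value == 1.0
                continue
            # reconstruct S from the reported z and the tie-adjusted variance
            tau_ref, _ = stats.kendalltau(t, s)
            assert np.sign(res.statistic) == np.sign(s_stat)
            # z must be proportional to S with a positive scale
            if s_stat != 0:
                scale = s_stat / res.statistic
                assert scale > 0


class TestBegg:
    def test_identical_studies_degenerate(self):
        meta = MetaAnalysis.from_counts([(10, 10, 10, 10)] * 5)
        res = begg_test(meta)
        assert res.p_value == 1.0 and res.degenerate

    def test_matches_brute_force_oracle(self, six_study_meta):
        ests = [log_odds_ratio(t) for t in six_study_meta]
        theta = np.array([e.theta for e in ests])
        v = np.array([e.var_asym for e in ests])
        theta_bar = np.sum(theta / v) / np.sum(1 / v)
        v_star = v - 1 / np.sum(1 / v)
        t_std = (theta - theta_bar) / np.sqrt(v_star)
        s_stat = sum(
            np.sign(t_std[j] - t_std[i]) * np.sign(v[j] - v[i])
            for i, j in itertools.combinations(range(6), 2)
        )
        var = 6 * 5 * 17 / 18.0  # no ties
        z = (abs(s_stat) - 1) / math.sqrt(var) * np.sign(s_stat)
        p = 2 * stats.norm.sf(abs(z))
        res = begg_test(six_study_meta)
        assert res.statistic == pytest.approx(z, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_exposure_flip_invariance(self, six_study_meta):
        res = begg_test(six_study_meta)
        flipped = begg_test(six_study_meta.flipped_exposure())
        assert flipped.p_value == pytest.approx(res.p_value, rel=1e-12)


class TestEgger:
    def test_flat_funnel_gives_p_one(self):
        # identical effect (theta = 0) at three precisions
        meta = MetaAnalysis.from_counts(
            [(10, 10, 10, 10), (20, 20, 20, 20), (40, 40, 40, 40)]
        )
        res = egger_test(meta)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_statsmodels(self, five_study_meta):
        ests = [log_odds_ratio(t) for t in five_study_meta]
        theta = np.array([e.theta for e in ests])
        v = np.array([e.var_asym for e in ests])
        ref = sm.WLS(theta, sm.add_constant(np.sqrt(v)), weights=1 / v).fit()
        res = egger_test(five_study_meta)
        assert res.statistic == pytest.approx(ref.tvalues[1], rel=1e-9)
        assert res.p_value == pytest.approx(ref.pvalues[1], rel=1e-9)
        assert res.df == 3

    def test_sign_symmetry_under_exposure_flip(self, five_study_meta):
        res = egger_test(five_study_meta)
        flipped = egger_test(five_study_meta.flipped_exposure())
        assert flipped.statistic == pytest.approx(-res.statistic, rel=1e-9)
        assert flipped.p_value == pytest.approx(res.p_value, rel=1e-9)


class TestSmoothedVarianceTests:
    def test_sve_matches_hand_computed_oracle(self, size_ladder_meta):
        tables = size_ladder_meta.studies
        p1 = sum(t.a for t in tables) / sum(t.n1 for t in tables)
        p2 = sum(t.b for t in tables) / sum(t.n2 for t in tables)
        sv = np.array(
            [
                1 / (t.n1 * p1 * (1 - p1)) + 1 / (t.n2 * p2 * (1 - p2))
                for t in tables
            ]
        )
        theta = np.array([log_odds_ratio(t).theta for t in tables])
        ref = sm.WLS(theta, sm.add_constant(np.sqrt(sv)), weights=1 / sv).fit()
        scale = max(1.0, float(ref.ssr / 3.0))  # weighted RSS / (k - 2)
        se_beta = ref.bse[1] / math.sqrt(ref.mse_resid) * math.sqrt(scale)
        t_ref = ref.params[1] / se_beta
        res = sve_test(size_ladder_meta)
        assert res.statistic == pytest.approx(t_ref, rel=1e-9)
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(abs(t_ref), 3), rel=1e-9
        )

    def test_sve_equal_sizes_not_identifiable(self, equal_size_meta):
        with pytest.raises(CollinearDesignError):
            sve_test(equal_size_meta)

    def test_svt_reduces_to_sve_without_heterogeneity(self):
        # exactly proportional tables: all theta-hat equal, so Q = 0
        meta = MetaAnalysis.from_counts(
            [
                (40, 40, 60, 60),
                (80, 80, 120, 120),
                (120, 120, 180, 180),
                (200, 200, 300, 300),
            ]
        )
        theta = [log_odds_ratio(t).theta for t in meta]
        sv = np.array([p.sv for p in smoothed_variance(meta)])
        assert moments_tau2(theta, np.sqrt(sv), sv) == 0.0
        sve = sve_test(meta)
        svt = svt_test(meta)
        assert svt.statistic == sve.statistic
        assert svt.p_value == sve.p_value

    def test_svt_matches_two_stage_oracle(self):
        # six studies with strongly conflicting odds ratios: tau2 > 0
        meta = MetaAnalysis.from_counts(
            [
                (30, 10, 10, 30),
                (10, 28, 30, 12),
                (50, 20, 40, 60),
                (5, 15, 20, 10),
                (150, 100, 120, 160),
                (20, 20, 60, 60),
            ]
        )
        theta = np.array([log_odds_ratio(t).theta for t in meta])
        sv = np.array([p.sv for p in smoothed_variance(meta)])
        se = np.sqrt(sv)
        tau2 = moments_tau2(theta, se, sv)
        assert tau2 > 0  # heterogeneous fixture
        w = 1 / (sv + tau2)
        alpha_ref, beta_ref = closed_form_wls(theta, se, w)
        res = svt_test(meta)
        design = np.column_stack([np.ones(6), se])
        resid = theta - design @ np.array([alpha_ref, beta_ref])
        rss_w = float(w @ resid**2)
        cov = max(1.0, rss_w / 4.0) * np.linalg.inv(design.T @ (w[:, None] * design))
        t_ref = beta_ref / math.sqrt(cov[1, 1])
        assert res.statistic == pytest.approx(t_ref, rel=1e-9)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t_ref), 4), rel=1e-9)

    def test_svt_empirical_size_near_nominal(self):
        # simulated null metas: no selection, OR = 1.4, I2 = 50 %, k = 30
        scenario = Scenario(
            k=30, or_true=1.4, event_regime="common", i2_target=0.50, ratio=1,
            bias="none", seed=777,
        )
        rng = np.random.default_rng(777)
        calibration = calibrate_scenario(scenario, rng)
        n_reps = 500
        rejections = 0
        for _ in range(n_reps):
            meta = generate_meta(scenario, rng, calibration)
            if svt_test(meta).p_value <= 0.10:
                rejections += 1
        rate = rejections / n_reps
        mc = math.sqrt(0.10 * 0.90 / n_reps)
        assert abs(rate - 0.10) <= 3 * mc


class TestArcsineThompson:
    def test_equal_rate_studies_flat(self):
        meta = MetaAnalysis.from_counts(
            [(8, 8, 12, 12), (16, 16, 24, 24), (40, 40, 60, 60)]
        )
        res = as_thompson_test(meta)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_two_stage_oracle(self, six_study_meta):
        ests = [arcsine_difference(t) for t in six_study_meta]
        theta = np.array([e.theta for e in ests])
        v = np.array([e.var_asym for e in ests])
        tau2 = moments_tau2(theta, np.sqrt(v), v)
        w = 1 / (v + tau2)
        _, beta_ref = closed_form_wls(theta, np.sqrt(v), w)
        res = as_thompson_test(six_study_meta)
        design = np.column_stack([np.ones(6), np.sqrt(v)])
        coef = np.array(closed_form_wls(theta, np.sqrt(v), w))
        resid = theta - design @ coef
        rss_w = float(w @ resid**2)
        cov = max(1.0, rss_w / 4.0) * np.linalg.inv(design.T @ (w[:, None] * design))
        assert res.statistic == pytest.approx(
            beta_ref / math.sqrt(cov[1, 1]), rel=1e-9
        )

    def test_reduces_to_additive_as_egger_when_tau2_zero(self):
        # equal exposure rates scale-free: arcsine effects identical, Q = 0
        meta = MetaAnalysis.from_counts(
            [(10, 5, 15, 20), (20, 10, 30, 40), (40, 20, 60, 80)]
        )
        ests = [arcsine_difference(t) for t in meta]
        theta = np.array([e.theta for e in ests])
        v = np.array([e.var_asym for e in ests])
        assert moments_tau2(theta, np.sqrt(v), v) == 0.0
        res = as_thompson_test(meta)
        fit = wls_fit(theta, np.sqrt(v), 1 / v, dispersion="floor")
        assert res.statistic == pytest.approx(fit.t_beta, rel=1e-12)


class TestHarbord:
    def test_score_and_information_of_balanced_table(self):
        # (10,10,10,10): Z = 0, V = 20^4 / (1600 * 39)
        meta = MetaAnalysis.from_counts(
            [(10, 10, 10, 10), (12, 9, 8, 11), (30, 25, 20, 26)]
        )
        t = meta.studies[0]
        v0 = (t.a + t.b) * (t.c + t.d) * t.n1 * t.n2 / (t.n**2 * (t.n - 1))
        assert v0 == pytest.approx(20**4 / (1600 * 39), rel=1e-12)
        z0 = t.a - (t.a + t.b) * t.n1 / t.n
        assert z0 == 0.0

    def test_all_balanced_null_tables_flat(self):
        meta = MetaAnalysis.from_counts(
            [(10, 10, 10, 10), (20, 20, 20, 20), (35, 35, 35, 35)]
        )
        res = harbord_test(meta)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_independent_implementation(self, five_study_meta):
        z, v = [], []
        for t in five_study_meta:
            z.append(t.a - (t.a + t.b) * (t.a + t.c) / t.n)
            v.append(
                (t.a + t.b)
                * (t.c + t.d)
                * (t.a + t.c)
                * (t.b + t.d)
                / (t.n**2 * (t.n - 1))
            )
        z, v = np.array(z), np.array(v)
        ref = sm.WLS(z / v, sm.add_constant(1 / np.sqrt(v)), weights=v).fit()
        res = harbord_test(five_study_meta)
        assert res.statistic == pytest.approx(ref.tvalues[1], rel=1e-9)
        assert res.p_value == pytest.approx(ref.pvalues[1], rel=1e-9)


class TestPeters:
    def test_weight_is_margin_product_over_n(self):
        t = MetaAnalysis.from_counts([(20, 10, 10, 20)]).studies[0]
        assert (t.a + t.b) * (t.c + t.d) / t.n == pytest.approx(15.0)

    def test_constant_effect_flat(self):
        meta = MetaAnalysis.from_counts(
            [(10, 10, 10, 10), (20, 20, 20, 20), (45, 45, 45, 45)]
        )
        res = peters_test(meta)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_statsmodels(self, five_study_meta):
        theta = np.array([log_odds_ratio(t).theta for t in five_study_meta])
        n = np.array([t.n for t in five_study_meta], dtype=float)
        w = np.array([(t.a + t.b) * (t.c + t.d) / t.n for t in five_study_meta])
        ref = sm.WLS(theta, sm.add_constant(1 / n), weights=w).fit()
        res = peters_test(five_study_meta)
        assert res.statistic == pytest.approx(ref.tvalues[1], rel=1e-9)
        assert res.p_value == pytest.approx(ref.pvalues[1], rel=1e-9)

    def test_equal_total_sizes_not_identifiable(self, equal_size_meta):
        with pytest.raises(CollinearDesignError):
            peters_test(equal_size_meta)


class TestMantelHaenszel:
    def test_single_table(self):
        assert mantel_haenszel_or(
            MetaAnalysis.from_counts([(20, 10, 10, 20)])
        ) == pytest.approx(4.0)

    def test_null_tables_give_one(self):
        meta = MetaAnalysis.from_counts([(10, 10, 10, 10), (25, 25, 25, 25)])
        assert mantel_haenszel_or(meta) == pytest.approx(1.0)

    def test_two_table_hand_summation(self):
        meta = MetaAnalysis.from_counts([(12, 18, 8, 22), (30, 28, 45, 40)])
        num = 12 * 22 / 60 + 30 * 40 / 143
        den = 18 * 8 / 60 + 28 * 45 / 143
        assert mantel_haenszel_or(meta) == pytest.approx(num / den, rel=1e-12)

    def test_zero_numerator_corrected(self):
        meta = MetaAnalysis.from_counts([(0, 10, 10, 0), (0, 8, 12, 0)])
        psi = mantel_haenszel_or(meta)
        assert 0 < psi < math.inf


class TestNoncentralHypergeometric:
    def test_central_case_mean(self):
        for n1, n2, m1 in [(5, 5, 5), (10, 20, 8), (7, 3, 6)]:
            mean, var = nchg_moments(n1, n2, m1, 1.0)
            assert mean == pytest.approx(n1 * m1 / (n1 + n2), rel=1e-12)
            assert var >= 0

    def test_against_brute_force_enumeration(self):
        n1, n2, m1, psi = 5, 5, 5, 2.0
        support = range(max(0, m1 - n2), min(m1, n1) + 1)
        weights = np.array(
            [math.comb(n1, a) * math.comb(n2, m1 - a) * psi**a for a in support]
        )
        probs = weights / weights.sum()
        mean_ref = sum(p * a for p, a in zip(probs, support))
        var_ref = sum(p * (a - mean_ref) ** 2 for p, a in zip(probs, support))
        mean, var = nchg_moments(n1, n2, m1, psi)
        assert mean == pytest.approx(mean_ref, rel=1e-12)
        assert var == pytest.approx(var_ref, rel=1e-12)

    def test_against_scipy(self, rng):
        for _ in range(25):
            n1 = int(rng.integers(1, 30))
            n2 = int(rng.integers(1, 30))
            m1 = int(rng.integers(0, n1 + n2 + 1))
            psi = float(rng.uniform(0.2, 5.0))
            dist = stats.nchypergeom_fisher(n1 + n2, n1, m1, psi)
            mean, var = nchg_moments(n1, n2, m1, psi)
            assert mean == pytest.approx(float(dist.mean()), rel=1e-8, abs=1e-10)
            assert var == pytest.approx(float(dist.var()), rel=1e-7, abs=1e-9)

    def test_single_point_support_has_zero_variance(self):
        mean, var = nchg_moments(5, 5, 10, 3.0)
        assert (mean, var) == (5.0, 0.0)

    def test_infeasible_margins_raise(self):
        with pytest.raises(ValidationError):
            nchg_moments(5, 5, 11, 1.0)


class TestSchwarzer:
    def test_identical_studies_degenerate(self):
        meta = MetaAnalysis.from_counts([(12, 9, 8, 11)] * 5)
        res = schwarzer_test(meta)
        assert res.degenerate and res.p_value == 1.0

    def test_matches_brute_force_oracle(self, six_study_meta):
        psi = mantel_haenszel_or(six_study_meta)
        z, v = [], []
        for t in six_study_meta:
            dist = stats.nchypergeom_fisher(t.n, t.n1, t.a + t.b, psi)
            e, var = float(dist.mean()), float(dist.var())
            z.append((t.a - e) / math.sqrt(var))
            v.append(var)
        z, v = np.array(z), np.array(v)
        s_stat = sum(
            np.sign(z[j] - z[i]) * np.sign(v[j] - v[i])
            for i, j in itertools.combinations(range(6), 2)
        )
        var_s = 6 * 5 * 17 / 18.0
        z_ref = np.sign(s_stat) * (abs(s_stat) - 1) / math.sqrt(var_s)
        res = schwarzer_test(six_study_meta)
        assert res.statistic == pytest.approx(z_ref, rel=1e-6)
        assert res.p_value == pytest.approx(
            2 * stats.norm.sf(abs(z_ref)), rel=1e-6
        )

    def test_exposure_flip_invariance(self, six_study_meta):
        res = schwarzer_test(six_study_meta)
        flipped = schwarzer_test(six_study_meta.flipped_exposure())
        assert flipped.p_value == pytest.approx(res.p_value, rel=1e-9)
        assert flipped.statistic == pytest.approx(-res.statistic, rel=1e-9)


class TestRunAllTests:
    def test_default_batch_in_fixed_order(self, five_study_meta):
        results = run_all_tests(five_study_meta)
        assert [r.method for r in results] == list(METHOD_ORDER)
        assert all(0 <= r.p_value <= 1 for r in results if r.applicable)

    def test_unknown_method_rejected(self, five_study_meta):
        with pytest.raises(ValidationError):
            run_all_tests(five_study_meta, methods=["Egger", "nonsense"])

    def test_subset_keeps_order(self, five_study_meta):
        results = run_all_tests(five_study_meta, methods=["SVT", "Begg"])
        assert [r.method for r in results] == ["Begg", "SVT"]

    def test_degenerate_designs_reported_not_raised(self, equal_size_meta):
        results = run_all_tests(equal_size_meta)
        by_name = {r.method: r for r in results}
        assert not by_name["SVE"].applicable
        assert not by_name["SVT"].applicable
        assert not by_name["Peters"].applicable
        assert by_name["Begg"].applicable
        assert math.isnan(by_name["SVE"].p_value)

    def test_all_p_values_invariant_under_global_exposure_flip(
        self, six_study_meta
    ):
        direct = run_all_tests(six_study_meta)
        flipped = run_all_tests(six_study_meta.flipped_exposure())
        for r_direct, r_flip in zip(direct, flipped):
            assert r_flip.p_value == pytest.approx(r_direct.p_value, rel=1e-8)
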