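"""Factor models, jackknife variance, Barnard's test and risk thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sonarcee import risk_stats as rs


def toy_records(values, sessions, groups, response="SPL_max_dB"):
    n = len(values)
    return pd.DataFrame(
        {
            "whale_id": [f"w{i}" for i in range(n)],
            "group_id": groups,
            "session_type": sessions,
            "avoided": [False] * n,
            "feeding": [False] * n,
            response: values,
        }
    )


class TestFitFactorModel:
    def test_saturated_gaussian_predictions_are_cell_means(self):
        df = toy_records(
            [170.0, 172.0, 168.0, 175.0, 174.0, 171.0],
            ["FullPower", "FullPower", "RampUp1", "RampUp1", "RampUp2", "RampUp2"],
            ["g1", "g2", "g1", "g2", "g3", "g3"],
        )
        fit = rs.fit_factor_model(df, "SPL_max_dB", ["session_type"])
        assert fit.predict_cell(("FullPower",)) == pytest.approx(171.0)
        assert fit.predict_cell(("RampUp1",)) == pytest.approx(171.5)
        assert fit.predict_cell(("RampUp2",)) == pytest.approx(172.5)

    def test_gaussian_equals_ols_to_machine_precision(self):
        rng = np.random.default_rng(0)
        sessions = ["FullPower", "RampUp1", "RampUp2"] * 5
        vals = rng.normal(172, 3, 15)
        df = toy_records(vals, sessions, [f"g{i % 5}" for i in range(15)])
        fit = rs.fit_factor_model(df, "SPL_max_dB", ["session_type"])
        # OLS on the saturated cell-means design
        X = pd.get_dummies(df["session_type"]).to_numpy(dtype=float)
        beta = np.linalg.lstsq(X, vals, rcond=None)[0]
        order = sorted(df["session_type"].unique())
        for lv, b in zip(order, beta):
            assert fit.predict_cell((lv,)) == pytest.approx(b, abs=1e-12)

    def test_gamma_saturated_predictions_equal_means(self):
        df = toy_records(
            [100.0, 300.0, 220.0, 180.0],
            ["RampUp1", "RampUp1", "FullPower", "FullPower"],
            ["g1", "g2", "g1", "g2"],
            response="R_min_m",
        )
        fit = rs.fit_factor_model(df, "R_min_m", ["session_type"], family="gamma")
        assert fit.predict_cell(("RampUp1",)) == pytest.approx(200.0)
        assert fit.predict_cell(("FullPower",)) == pytest.approx(200.0)
        assert fit.coef_[fit.cell_index(("RampUp1",))] == pytest.approx(np.log(200.0))

    def test_jackknife_matches_explicit_loo_formula(self):
        # 3 clusters; the delete-one-cluster covariance recomputed by hand
        df = toy_records(
            [170.0, 171.0, 174.0, 169.0, 175.0, 172.0],
            ["RampUp1"] * 6,
            ["g1", "g1", "g2", "g2", "g3", "g3"],
        )
        fit = rs.fit_factor_model(df, "SPL_max_dB", ["session_type"])
        loo = []
        for g in ("g1", "g2", "g3"):
            loo.append(df[df["group_id"] != g]["SPL_max_dB"].mean())
        loo = np.array(loo)
        expected = (3 - 1) / 3 * np.sum((loo - loo.mean()) ** 2)
        assert fit.cov_[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_singleton_clusters_reduce_to_loo_observations(self):
        vals = [170.0, 173.0, 176.0, 168.0]
        df = toy_records(vals, ["RampUp1"] * 4, [f"g{i}" for i in range(4)])
        fit = rs.fit_factor_model(df, "SPL_max_dB", ["session_type"])
        loo = np.array([np.mean(np.delete(vals, i)) for i in range(4)])
        expected = (4 - 1) / 4 * np.sum((loo - loo.mean()) ** 2)
        assert fit.cov_[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_interaction_model_cells(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(16):
            rows.append(
                {
                    "whale_id": f"w{i}",
                    "group_id": f"g{i % 8}",
                    "session_type": ["RampUp1", "RampUp2"][i % 2],
                    "avoided": bool((i // 2) % 2),
                    "feeding": False,
                    "SEL_cum_dB": float(rng.normal(176, 3)),
                }
            )
        df = pd.DataFrame(rows)
        fit = rs.fit_factor_model(df, "SEL_cum_dB", ["session_type", "avoided"])
        assert len(fit.levels) == 4
        for combo in fit.levels:
            sub = df[(df["session_type"] == combo[0]) & (df["avoided"] == combo[1])]
            assert fit.predict_cell(combo) == pytest.approx(sub["SEL_cum_dB"].mean())

    def test_single_cluster_rejected(self):
        df = toy_records([1.0, 2.0], ["RampUp1"] * 2, ["g1", "g1"])
        with pytest.raises(ValueError):
            rs.fit_factor_model(df, "SPL_max_dB", ["session_type"])


class TestBootstrapContrast:
    def fit_with_cov(self, cov):
        return rs.FactorModelFit(
            family="gaussian",
            response="SPL_max_dB",
            factors=["session_type"],
            levels=[("A",), ("B",)],
            coef_=np.array([170.0, 173.0]),
            cov_=np.asarray(cov, dtype=float),
            n_clusters=5,
            n_obs=10,
        )

    def test_self_contrast_centred_on_zero(self):
        fit = self.fit_with_cov(np.eye(2))
        res = rs.bootstrap_contrast(fit, ("A",), ("A",), n_boot=500, seed=0)
        assert res.difference == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high
        assert not res.significant

    def test_zero_covariance_degenerate_interval(self):
        fit = self.fit_with_cov(np.zeros((2, 2)))
        res = rs.bootstrap_contrast(fit, ("A",), ("B",), n_boot=500, seed=0)
        assert res.ci_low == res.ci_high == pytest.approx(-3.0)
        assert res.significant

    def test_interval_matches_normal_quantiles(self):
        # independent cells, var 0.5 each: difference ~ N(-3, 1)
        fit = self.fit_with_cov(0.5 * np.eye(2))
        res = rs.bootstrap_contrast(fit, ("A",), ("B",), n_boot=40_000, seed=1)
        assert res.difference == pytest.approx(-3.0)
        assert res.ci_low == pytest.approx(-3.0 - 1.96, abs=0.05)
        assert res.ci_high == pytest.approx(-3.0 + 1.96, abs=0.05)

    def test_significance_follows_ci_sign_rule(self):
        tight = self.fit_with_cov(0.01 * np.eye(2))
        assert rs.bootstrap_contrast(tight, ("A",), ("B",), n_boot=2000, seed=2).significant
        wide = self.fit_with_cov(25.0 * np.eye(2))
        assert not rs.bootstrap_contrast(wide, ("A",), ("B",), n_boot=2000, seed=2).significant


class TestWald:
    def test_zero_estimate(self):
        z, p = rs.wald_test(0.0, 1.0)
        assert z == 0.0 and p == 1.0

    def test_quantile_anchor(self):
        z, p = rs.wald_test(1.96, 1.0)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_signed_statistic(self):
        z, p = rs.wald_test(-3.0, 1.0)
        assert z == -3.0
        assert p == pytest.approx(0.0027, abs=1e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rs.wald_test(1.0, 0.0)


def barnard_oracle(table, grid_size=1001):
    """Independent enumeration of the unconditional p-value."""
    (a, b), (c, d) = table
    n1, n2 = a + b, c + d
    p1, p2 = a / n1, c / n2
    pool = (a + c) / (n1 + n2)
    var = pool * (1 - pool) * (1 / n1 + 1 / n2)
    z_obs = 0.0 if var == 0 else (p1 - p2) / np.sqrt(var)
    best = 0.0
    for pi in np.linspace(0.0, 1.0, grid_size):
        total = 0.0
        for x1 in range(n1 + 1):
            for x2 in range(n2 + 1):
                q1, q2 = x1 / n1, x2 / n2
                pl = (x1 + x2) / (n1 + n2)
                v = pl * (1 - pl) * (1 / n1 + 1 / n2)
                z = 0.0 if v == 0 else (q1 - q2) / np.sqrt(v)
                if abs(z) >= abs(z_obs) - 1e-12:
                    total += stats.binom.pmf(x1, n1, pi) * stats.binom.pmf(x2, n2, pi)
        best = max(best, total)
    return z_obs, best


class TestBarnard:
    def test_equal_proportions_p_one(self):
        z, p = rs.barnard_test([[2, 2], [2, 2]])
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_perfect_separation_matches_enumeration(self):
        z, p = rs.barnard_test([[3, 0], [0, 3]])
        z_o, p_o = barnard_oracle([[3, 0], [0, 3]], grid_size=201)
        assert z == pytest.approx(z_o)
        assert p == pytest.approx(p_o, abs=1e-3)

    @pytest.mark.parametrize(
        "table", [[[3, 1], [1, 3]], [[5, 0], [2, 3]], [[4, 2], [0, 6]], [[2, 5], [5, 0]]]
    )
    def test_matches_scipy_unconditional(self, table):
        z, p = rs.barnard_test(table)
        ref = stats.barnard_exact(table, alternative="two-sided", pooled=True)
        assert p == pytest.approx(ref.pvalue, abs=5e-3)

    def test_analytically_tied_outcomes_included(self):
        # for [[1,5],[4,2]] the outcome (2,5) shares the observed |Z|
        # exactly in algebra but differs in float rounding; our region keeps
        # such ties, so p is at least scipy's float-strict value
        z, p = rs.barnard_test([[1, 5], [4, 2]])
        ref = stats.barnard_exact([[1, 5], [4, 2]], alternative="two-sided", pooled=True)
        assert p >= ref.pvalue - 1e-12
        z_tied = rs._score_statistic(2, 6, 5, 6)
        assert abs(z_tied) == pytest.approx(abs(z), abs=1e-9)

    def test_session_level_field_table_consistency(self):
        # 8 avoidance responses in 18 sonar sessions vs 0 in 11 controls:
        # clearly significant, with a score statistic near the reported one
        z, p = rs.barnard_test([[8, 10], [0, 11]])
        assert p < 0.02
        assert 2.0 < z < 3.5

    def test_degenerate_arm_rejected(self):
        with pytest.raises(ValueError):
            rs.barnard_test([[0, 0], [1, 2]])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert rs.pearson_r(x, x)[0] == pytest.approx(1.0)
        assert rs.pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_four_point_hand_computation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 2.0, 5.0]
        r, p = rs.pearson_r(x, y)
        assert r == pytest.approx(5.5 / np.sqrt(5.0 * 8.75), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rs.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestHearingRisk:
    def test_tts_range_with_margin(self):
        hr = rs.hearing_risk(183.0)
        assert hr.category == "TTS_range"
        assert hr.margin_to_PTS_dB == pytest.approx(16.0)

    def test_below_tts(self):
        assert rs.hearing_risk(178.9).category == "below_TTS"

    def test_pts_boundary_inclusive(self):
        assert rs.hearing_risk(199.0).category == "above_PTS"
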