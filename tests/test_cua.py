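"""Cost-utility engine: QALYs, SUR vs GLS oracle, BCa, ICER, CEAC."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from eq5dsim import (
    CostUtilityModel,
    bca_interval,
    builtin_tariff,
    ceac,
    compute_icer,
    compute_qalys,
    decide,
    score_dataset,
    sur_fit,
)
from eq5dsim.cua import EstimationError, bca_bootstrap, quadrant_proportions


class TestQalys:
    @pytest.mark.parametrize(
        "u0,u1,horizon,expected",
        [(1.0, 1.0, 1.0, 1.0), (0.4, 0.6, 1.0, 0.5), (0.8, 0.8, 0.5, 0.4)],
    )
    def test_trapezoid(self, u0, u1, horizon, expected):
        assert compute_qalys(u0, u1, horizon) == pytest.approx(expected)

    def test_score_dataset_columns(self, small_trial):
        scored = score_dataset(small_trial, builtin_tariff("NL", "3L"))
        assert {"baseline_utility", "followup_utility", "qaly", "cost", "arm"} <= set(
            scored.columns
        )
        assert (scored["qaly"] <= 1.0 + 1e-12).all()


def stacked_gls_oracle(y_cost, y_qaly, X_c, X_q):
    """Independent brute-force FGLS: dense block design, dense Omega^{-1}."""
    n = len(y_cost)
    bc = np.linalg.lstsq(X_c, y_cost, rcond=None)[0]
    bq = np.linalg.lstsq(X_q, y_qaly, rcond=None)[0]
    E = np.stack([y_cost - X_c @ bc, y_qaly - X_q @ bq])
    S = E @ E.T / n
    X = np.zeros((2 * n, X_c.shape[1] + X_q.shape[1]))
    X[:n, : X_c.shape[1]] = X_c
    X[n:, X_c.shape[1] :] = X_q
    y = np.concatenate([y_cost, y_qaly])
    Oinv = np.kron(np.linalg.inv(S), np.eye(n))
    beta = np.linalg.solve(X.T @ Oinv @ X, X.T @ Oinv @ y)
    cov = np.linalg.inv(X.T @ Oinv @ X)
    return beta, cov


class TestSur:
    def eight_row_system(self):
        rng = np.random.default_rng(42)
        arm = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        base_u = rng.uniform(0.3, 0.9, 8)
        X_c = np.column_stack([np.ones(8), arm])
        X_q = np.column_stack([np.ones(8), arm, base_u])
        y_cost = 2000 + 250 * arm + rng.normal(0, 300, 8)
        y_qaly = 0.5 + 0.05 * arm + 0.3 * base_u + rng.normal(0, 0.05, 8)
        return y_cost, y_qaly, X_c, X_q

    def test_matches_stacked_gls_oracle_to_1e8(self):
        y_cost, y_qaly, X_c, X_q = self.eight_row_system()
        fit = sur_fit(y_cost, y_qaly, X_c, X_q)
        beta, cov = stacked_gls_oracle(y_cost, y_qaly, X_c, X_q)
        assert np.allclose(fit.params, beta, atol=1e-8)
        assert np.allclose(fit.cov, cov, atol=1e-8)

    def test_identical_regressors_collapse_to_ols(self):
        """With the same design in both equations SUR equals per-equation
        OLS exactly (statsmodels as the independent route)."""
        import statsmodels.api as sm

        y_cost, y_qaly, X_c, _ = self.eight_row_system()
        fit = sur_fit(y_cost, y_qaly, X_c, X_c)
        ols_c = sm.OLS(y_cost, X_c).fit().params
        ols_q = sm.OLS(y_qaly, X_c).fit().params
        assert np.allclose(fit.params[:2], ols_c, atol=1e-10)
        assert np.allclose(fit.params[2:], ols_q, atol=1e-10)

    def test_treatment_only_equals_difference_in_means(self, small_trial):
        scored = score_dataset(small_trial, builtin_tariff("NL", "3L"))
        model = CostUtilityModel(scored, qaly_covariates=())
        res = model.fit(n_boot=0)
        g = scored.groupby("arm")
        assert res.delta_cost == pytest.approx(
            g["cost"].mean()[1] - g["cost"].mean()[0], abs=1e-10
        )
        assert res.delta_qaly == pytest.approx(
            g["qaly"].mean()[1] - g["qaly"].mean()[0], abs=1e-10
        )

    def test_rank_deficiency_raises(self):
        y = np.arange(8.0)
        X = np.column_stack([np.ones(8), np.ones(8)])
        with pytest.raises(EstimationError):
            sur_fit(y, y, X, X)


class TestBca:
    def test_constant_statistic_degenerates_to_point(self):
        with pytest.warns(UserWarning, match="degenerate"):
            ci = bca_interval(np.full(500, 3.2), 3.2, np.full(10, 3.2))
        assert (ci.lower, ci.upper) == (3.2, 3.2)
        assert ci.degenerate

    def test_hand_executed_textbook_formula(self):
        """Fixed 10-point sample, statistic = mean: endpoints recomputed
        from scratch with the textbook BCa formulas must match."""
        sample = np.array([2.1, 3.4, 1.9, 5.6, 4.4, 2.8, 3.9, 6.1, 2.2, 4.8])
        rng = np.random.default_rng(7)
        B = 2000
        idx = rng.integers(0, 10, size=(B, 10))
        reps = sample[idx].mean(axis=1)
        point = sample.mean()
        jack = np.array([np.delete(sample, i).mean() for i in range(10)])

        ci = bca_interval(reps, point, jack, level=0.95)

        # independent hand computation
        z0 = special.ndtri((reps < point).mean())
        jbar = jack.mean()
        a = ((jbar - jack) ** 3).sum() / (6 * (((jbar - jack) ** 2).sum()) ** 1.5)
        zlo, zhi = special.ndtri(0.025), special.ndtri(0.975)
        a1 = special.ndtr(z0 + (z0 + zlo) / (1 - a * (z0 + zlo)))
        a2 = special.ndtr(z0 + (z0 + zhi) / (1 - a * (z0 + zhi)))
        lo, hi = np.quantile(reps, [a1, a2])
        assert ci.lower == pytest.approx(lo, abs=1e-12)
        assert ci.upper == pytest.approx(hi, abs=1e-12)
        assert ci.z0 == pytest.approx(z0, abs=1e-12)
        assert ci.acceleration == pytest.approx(a, abs=1e-12)

    def test_symmetric_statistic_close_to_percentile(self):
        """Symmetric sampling, statistic = mean: z0 ~ 0 and the BCa interval
        sits within half a percentile unit of the plain percentile interval
        on average over 50 seeds."""
        shifts = []
        z0s = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            sample = rng.normal(0, 1, 40)
            idx = rng.integers(0, 40, size=(2000, 40))
            reps = sample[idx].mean(axis=1)
            jack = (sample.sum() - sample) / 39
            ci = bca_interval(reps, sample.mean(), jack)
            for endpoint, alpha in ((ci.lower, 2.5), (ci.upper, 97.5)):
                rank = stats.percentileofscore(reps, endpoint, kind="mean")
                shifts.append(abs(rank - alpha))
            z0s.append(ci.z0)
        assert np.mean(np.abs(z0s)) < 0.05
        assert np.mean(shifts) < 0.5

    def test_against_scipy_bootstrap(self):
        """Cross-check on a simple mean: scipy's BCa interval and ours agree
        to bootstrap noise."""
        rng = np.random.default_rng(3)
        sample = rng.gamma(2, 1.5, 60)
        idx = rng.integers(0, 60, size=(4000, 60))
        reps = sample[idx].mean(axis=1)
        jack = (sample.sum() - sample) / 59
        ours = bca_interval(reps, sample.mean(), jack)
        ref = stats.bootstrap(
            (sample,),
            np.mean,
            method="BCa",
            n_resamples=4000,
            confidence_level=0.95,
            random_state=np.random.default_rng(9),
        ).confidence_interval
        se = reps.std()
        assert ours.lower == pytest.approx(ref.low, abs=0.15 * se)
        assert ours.upper == pytest.approx(ref.high, abs=0.15 * se)

    def test_bootstrap_wrapper_stratified_and_seeded(self, small_trial):
        df = small_trial.data[["arm", "cost"]].copy()

        def stat(d):
            g = d.groupby("arm")["cost"].mean()
            return g[1] - g[0]

        rng1 = np.random.default_rng(12)
        rng2 = np.random.default_rng(12)
        reps1, point1, cis1 = bca_bootstrap(df, stat, n_boot=150, rng=rng1)
        reps2, _, _ = bca_bootstrap(df, stat, n_boot=150, rng=rng2)
        assert np.array_equal(reps1, reps2)
        assert cis1[0].lower < point1[0] < cis1[0].upper


class TestDecisionOutputs:
    @pytest.mark.parametrize(
        "dc,dq,value,defined,quadrant",
        [
            (250.0, 0.05, 5000.0, True, "NE"),
            (250.0, 0.0, None, False, "NE"),
            (-100.0, 0.1, -1000.0, True, "SE"),
            (100.0, -0.1, -1000.0, True, "NW"),
        ],
    )
    def test_icer(self, dc, dq, value, defined, quadrant):
        icer = compute_icer(dc, dq)
        assert icer.defined is defined
        assert icer.quadrant == quadrant
        if defined:
            assert icer.value == pytest.approx(value)

    def test_ceac_brute_force_five_replicates(self):
        cloud = np.array([(100, 0.01), (-50, 0.02), (200, -0.01), (10, 0.005), (-5, 0.0)])
        # brute force INB = 20000*dE - dC > 0: 100, 450, -400, 90, 5 -> 4 of 5
        assert ceac(cloud, [20000.0])[20000.0] == pytest.approx(0.8)
        # pCE(0) = fraction with dC < 0
        assert ceac(cloud, [0.0])[0.0] == pytest.approx(np.mean(cloud[:, 0] < 0))

    def test_ceac_matches_brute_force_random_clouds(self, rng):
        for _ in range(5):
            cloud = rng.normal(0, 1, size=(400, 2)) * [300, 0.05] + [100, 0.02]
            for lam in (0.0, 20000.0, 30000.0, 50000.0):
                brute = sum(lam * de - dc > 0 for dc, de in cloud) / len(cloud)
                assert ceac(cloud, [lam])[lam] == brute

    def test_dominant_cloud_pce_one(self):
        cloud = np.column_stack([-np.abs(np.random.rand(50)) - 1, np.abs(np.random.rand(50)) + 0.1])
        pce = ceac(cloud)
        assert all(v == 1.0 for v in pce.values())

    @pytest.mark.parametrize("p,expected", [(0.80, True), (0.79, False), (1.0, True)])
    def test_decision_threshold_inclusive(self, p, expected):
        assert decide({20000.0: p})[20000.0] is expected

    def test_quadrant_proportions_sum_to_one(self, rng):
        cloud = rng.normal(size=(1000, 2))
        assert sum(quadrant_proportions(cloud).values()) == pytest.approx(1.0)


class TestModelResults:
    def test_fit_deterministic_under_seed(self, small_trial):
        m = CostUtilityModel.from_dataset(small_trial, builtin_tariff("NL", "3L"))
        r1 = m.fit(n_boot=300, seed=5)
        r2 = m.fit(n_boot=300, seed=5)
        assert np.array_equal(r1.cloud, r2.cloud)
        assert r1.pce == r2.pce
        assert r1.conf_int("qaly") == r2.conf_int("qaly")

    def test_parameter_recovery_cost_difference(self):
        """Mean SUR cost effect over 200 simulated trials is within 2 Monte
        Carlo standard errors of the true 250."""
        from eq5dsim import ScenarioConfig, simulate_trial

        tariff = builtin_tariff("NL", "3L")
        estimates = []
        for i in range(200):
            config = ScenarioConfig("depression", "moderate", "medium", seed=3000 + i)
            ds = simulate_trial(config, "3L")
            res = CostUtilityModel(score_dataset(ds, tariff)).fit(n_boot=0)
            estimates.append(res.delta_cost)
        estimates = np.array(estimates)
        mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - 250) < 2 * mc_se + 1e-9

    def test_summary_renders(self, small_trial):
        res = CostUtilityModel.from_dataset(small_trial, builtin_tariff("NL", "3L")).fit(
            n_boot=200, seed=0
        )
        text = res.summary()
        assert "Delta QALY" in text and "WTP" in text
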