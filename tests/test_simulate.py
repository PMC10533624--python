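"""Synthetic trial generator: sampling laws, calibration, costs, seeding."""

import numpy as np
import pytest
from scipy import stats

from eq5dsim import (
    BaselineProbabilityTable,
    CalibrationError,
    CostConfig,
    ScenarioConfig,
    Tariff,
    TariffTerm,
    TransitionModel,
    baseline_populations,
    baseline_table,
    calibrate_effect_size,
    factorial,
    generate_baseline,
    generate_costs,
    generate_covariates,
    generate_followup,
    population_cohens_d,
    simulate_trial,
    tilt_matrix,
    transition_model,
)
from eq5dsim.simulate import EFFECT_BANDS, SimulationError
from eq5dsim.states import strings_to_levels


def table_point_mass(version="3L", level=1):
    nlev = {"3L": 3, "5L": 5}[version]
    p = np.zeros((5, nlev))
    p[:, level - 1] = 1.0
    return BaselineProbabilityTable(version, {"control": p, "intervention": p.copy()})


class TestBaseline:
    def test_point_mass_gives_constant_profiles(self, rng):
        out = generate_baseline(table_point_mass(), 20, rng)
        assert (out["control"] == 1).all() and (out["intervention"] == 1).all()

    def test_default_design_is_150_per_arm(self):
        assert ScenarioConfig("depression", "mild", "small").n_per_arm == 150

    def test_large_sample_frequencies_match_probabilities(self, rng):
        table = baseline_table("low_back_pain", "severe", "3L")
        out = generate_baseline(table, 100_000, rng)
        for d in range(5):
            observed = np.bincount(out["control"][:, d] - 1, minlength=3)
            expected = table.probs["control"][d] * 100_000
            keep = expected > 5
            chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
            p = stats.chi2.sf(chi2, keep.sum() - 1)
            assert p > 0.001

    def test_non_stochastic_table_rejected(self):
        p = np.full((5, 3), 0.3)
        with pytest.raises(SimulationError):
            BaselineProbabilityTable("3L", {"control": p, "intervention": p})


class TestFollowup:
    def test_identity_matrices_keep_baseline(self, rng):
        base = strings_to_levels(["21232", "33333", "11111"], "3L")
        eye = np.broadcast_to(np.eye(3), (5, 3, 3)).copy()
        out = generate_followup(base, eye, "3L", rng)
        assert np.array_equal(out, base)

    def test_point_mass_improvement_to_full_health(self, rng):
        base = strings_to_levels(["33333", "21232"], "3L")
        m = np.zeros((5, 3, 3))
        m[:, :, 0] = 1.0
        out = generate_followup(base, m, "3L", rng)
        assert (out == 1).all()

    def test_transition_frequencies_match_matrix_row(self, rng):
        base = np.full((100_000, 5), 2)
        mats = transition_model("3L").matrices["control"]
        out = generate_followup(base, mats, "3L", rng)
        observed = np.bincount(out[:, 3] - 1, minlength=3) / 100_000
        assert np.abs(observed - mats[3, 1]).max() < 0.01


class TestEffectSizeCalibration:
    def test_zero_shift_means_zero_d(self):
        table = baseline_table("cancer", "moderate", "3L")
        model = transition_model("3L")
        from eq5dsim.scenarios import calibration_tariff

        assert population_cohens_d(table, model, calibration_tariff("3L")) == 0.0

    def test_tilt_identity_at_zero(self):
        m = transition_model("5L").matrices["control"]
        assert np.allclose(tilt_matrix(m, 0.0), m)

    def test_d_monotone_in_shift(self):
        table = baseline_table("depression", "moderate", "3L")
        model = transition_model("3L")
        from eq5dsim.scenarios import calibration_tariff

        tariff = calibration_tariff("3L")
        base = model.matrices["intervention"]
        ds = []
        for shift in np.linspace(0, 6, 13):
            m = TransitionModel(
                "3L",
                {"control": model.matrices["control"], "intervention": tilt_matrix(base, shift)},
            )
            ds.append(population_cohens_d(table, m, tariff))
        assert (np.diff(ds) >= -1e-12).all()

    def test_two_level_analytic_oracle(self):
        """Single informative dimension with two effective levels: the
        closed-form d as a function of the tilted transition probability
        matches the calibrated result."""
        # 3L table with MO on levels {1,2} only, all other dims fixed at 1
        p = np.zeros((5, 3))
        p[:, 0] = 1.0
        p[0] = [0.5, 0.5, 0.0]
        table = BaselineProbabilityTable("3L", {"control": p, "intervention": p.copy()})
        mats = np.zeros((5, 3, 3))
        mats[:, :, 0] = 1.0  # all dims jump to 1...
        mats[0] = [[0.8, 0.2, 0.0], [0.4, 0.6, 0.0], [0.0, 0.0, 1.0]]
        model = TransitionModel("3L", {"control": mats, "intervention": mats.copy()})
        tariff = Tariff(
            country="T",
            version="3L",
            terms=[TariffTerm("level_dummy", 0.3, dimension="MO", level=2)],
        )

        def analytic_d(shift):
            # follow-up P(MO=2) per arm; utility = 1 - 0.3*[MO=2]
            rows = tilt_matrix(mats[0], shift)
            q_i = 0.5 * rows[0, 1] + 0.5 * rows[1, 1]
            q_c = 0.5 * mats[0][0][1] + 0.5 * mats[0][1][1]
            mean_c, var_c = 1 - 0.3 * q_c, 0.09 * q_c * (1 - q_c)
            mean_i, var_i = 1 - 0.3 * q_i, 0.09 * q_i * (1 - q_i)
            return (mean_i - mean_c) / np.sqrt((var_c + var_i) / 2)

        calibrated = calibrate_effect_size(table, model, "small", tariff)
        d_pkg = population_cohens_d(table, calibrated, tariff)
        assert d_pkg == pytest.approx(analytic_d(calibrated.shift), abs=1e-10)
        assert 0.15 <= d_pkg <= 0.25

    def test_medium_band_reached(self):
        from eq5dsim.scenarios import calibrated_transitions, calibration_tariff

        m = calibrated_transitions("osteoarthritis", "mild", "medium", "5L")
        d = population_cohens_d(
            baseline_table("osteoarthritis", "mild", "5L"), m, calibration_tariff("5L")
        )
        lo, hi = EFFECT_BANDS["medium"]
        assert lo <= d <= hi

    def test_unreachable_band_reports_maximum(self):
        # a tariff that ignores every dimension: utility constant, d = 0
        table = baseline_table("cancer", "mild", "3L")
        flat = Tariff(country="FLAT", version="3L", terms=[])
        with pytest.raises(CalibrationError, match="unreachable"):
            calibrate_effect_size(table, transition_model("3L"), "large", flat)


class TestCovariatesAndCosts:
    def test_age_bounds_and_determinism(self):
        rng1 = np.random.default_rng(4)
        rng2 = np.random.default_rng(4)
        ages, male = generate_covariates(10_000, rng1)
        ages2, male2 = generate_covariates(10_000, rng2)
        assert ages.min() >= 25 and ages.max() <= 75
        assert np.array_equal(ages, ages2) and np.array_equal(male, male2)

    def test_male_proportion_large_sample(self, rng):
        _, male = generate_covariates(100_000, rng)
        assert abs(male.mean() - 0.19) < 0.01

    def test_zero_target_correlation_independent(self, rng):
        qalys = rng.normal(0.6, 0.2, 100_000)
        arm = np.zeros(100_000, int)
        costs = generate_costs(qalys, arm, CostConfig(target_correlation=0.0), rng)
        assert abs(np.corrcoef(costs, qalys)[0, 1]) < 0.02

    def test_pearson_correlation_hits_target(self, rng):
        qalys = rng.beta(4, 2, 100_000)
        arm = (np.arange(100_000) % 2).astype(int)
        costs = generate_costs(qalys, arm, CostConfig(), rng)
        assert np.corrcoef(costs, qalys)[0, 1] == pytest.approx(-0.10, abs=0.02)

    def test_marginal_gamma_preserved_by_coupling(self, rng):
        """Copula coupling leaves the gamma marginal untouched (KS against
        the analytic CDF and against an uncoupled sample)."""
        qalys = rng.normal(0.6, 0.2, 100_000)
        arm = np.zeros(100_000, int)
        coupled = generate_costs(qalys, arm, CostConfig(), rng)
        uncoupled = generate_costs(qalys, arm, CostConfig(target_correlation=0.0), rng)
        assert stats.kstest(coupled, stats.gamma(a=1, scale=2000).cdf).pvalue > 0.001
        assert stats.ks_2samp(coupled, uncoupled).pvalue > 0.001
        assert coupled.mean() == pytest.approx(2000, rel=0.02)

    def test_invalid_configs_rejected(self):
        with pytest.raises(SimulationError):
            CostConfig(mean=-5)
        with pytest.raises(SimulationError):
            CostConfig(dispersion=0)


class TestTrialAssembly:
    def test_bit_identical_reproducibility(self):
        config = ScenarioConfig("depression", "severe", "large", seed=99)
        a = simulate_trial(config, "5L")
        b = simulate_trial(config, "5L")
        assert a.data.equals(b.data)

    def test_baseline_shared_across_effect_bands(self):
        """Substream keying: the three bands of a population see identical
        baseline profiles and covariates (no treatment effect at baseline)."""
        small = simulate_trial(ScenarioConfig("cancer", "mild", "small", seed=5), "3L")
        large = simulate_trial(ScenarioConfig("cancer", "mild", "large", seed=5), "3L")
        assert small.data["baseline_state"].equals(large.data["baseline_state"])
        assert small.data["age"].equals(large.data["age"])
        assert not small.data["followup_state"].equals(large.data["followup_state"])

    def test_factorial_enumerates_36_scenarios(self):
        scenarios = factorial()
        assert len(scenarios) == 36
        assert sorted(s.scenario_id for s in scenarios) == list(range(1, 37))
        assert len(baseline_populations()) == 12

    def test_csv_round_trip(self, small_trial, tmp_path):
        path = tmp_path / "trial.csv"
        small_trial.to_csv(path)
        from eq5dsim import TrialDataset

        back = TrialDataset.from_csv(path, "3L")
        assert back.data["baseline_state"].equals(small_trial.data["baseline_state"])
        assert np.allclose(back.data["cost"], small_trial.data["cost"])

    def test_cost_difference_ci_covers_truth(self):
        """Over repeated trials the 95% CI for the arm cost difference
        covers the true 250 about 95% of the time (spot check, 150 trials)."""
        from eq5dsim import CostUtilityModel, builtin_tariff, score_dataset

        tariff = builtin_tariff("NL", "3L")
        cover = 0
        n_rep = 150
        for i in range(n_rep):
            config = ScenarioConfig("osteoarthritis", "moderate", "small", seed=7000 + i)
            ds = simulate_trial(config, "3L")
            res = CostUtilityModel(score_dataset(ds, tariff)).fit(n_boot=0)
            lo, hi = res.conf_int("cost", kind="model")
            cover += lo <= 250 <= hi
        assert cover / n_rep == pytest.approx(0.95, abs=0.05)
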