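"""Scenario factorial and builtin data-generating recipes.

The study design crosses four chronic health conditions (depression, low
back pain, osteoarthritis, cancer) with three severity levels (mild,
moderate, severe) and three treatment effect-size bands (small, medium,
large Cohen's d) — 36 scenarios, each simulated at n = 150 per arm for both
EQ-5D versions and valued for NL, US and JP.

The baseline response-level probabilities and control-arm transition
kernels here are deterministic *synthetic* recipes, not the empirical
probabilities the original eight trial datasets would give: each condition
loads specific dimensions (e.g. low back pain concentrates mass on high
pain/discomfort levels), severity moves the overall location, and
probabilities are binomial discretisations over the response levels.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import simulate as sim
from ._seeding import substream
from .simulate import (
    ARMS,
    BaselineProbabilityTable,
    CostConfig,
    SimulationError,
    TransitionModel,
    TrialDataset,
)
from .states import DIMENSIONS, LEVELS, check_version, levels_to_strings
from .tariffs import Tariff, builtin_tariff

CONDITIONS = ("depression", "low_back_pain", "osteoarthritis", "cancer")
SEVERITIES = ("mild", "moderate", "severe")
EFFECT_SIZES = ("small", "medium", "large")

#: Relative salience of each dimension (MO, SC, UA, PD, AD) per condition.
CONDITION_WEIGHTS = {
    "depression": (0.10, 0.20, 0.50, 0.30, 1.00),
    "low_back_pain": (0.60, 0.30, 0.50, 1.00, 0.20),
    "osteoarthritis": (0.90, 0.40, 0.50, 0.80, 0.15),
    "cancer": (0.40, 0.35, 0.70, 0.60, 0.50),
}

#: Overall dysfunction location per severity level (0 = full health).
SEVERITY_LOCATION = {"mild": 0.22, "moderate": 0.45, "severe": 0.70}


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the factorial plus the generator's global parameters."""

    condition: str
    severity: str
    effect_size: str
    n_per_arm: int = 150
    cost_mean: float = 2000.0
    cost_true_difference: float = 250.0
    cost_dispersion: float = 1.0
    target_correlation: float = -0.10
    horizon: float = 1.0
    seed: int = 0
    scenario_id: int = field(default=None)

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise SimulationError(f"unknown condition {self.condition!r}")
        if self.severity not in SEVERITIES:
            raise SimulationError(f"unknown severity {self.severity!r}")
        if self.effect_size not in EFFECT_SIZES:
            raise SimulationError(f"unknown effect size {self.effect_size!r}")
        if self.n_per_arm < 1:
            raise SimulationError("n_per_arm must be >= 1")
        if self.scenario_id is None:
            object.__setattr__(self, "scenario_id", default_scenario_id(self))

    @property
    def population(self) -> str:
        return f"{self.severity} {self.condition.replace('_', ' ')}"

    def cost_config(self) -> CostConfig:
        return CostConfig(
            mean=self.cost_mean,
            difference=self.cost_true_difference,
            dispersion=self.cost_dispersion,
            target_correlation=self.target_correlation,
        )


def default_scenario_id(config: ScenarioConfig) -> int:
    """1..36 numbering: condition-major, then severity, then effect size."""
    return (
        CONDITIONS.index(config.condition) * 9
        + SEVERITIES.index(config.severity) * 3
        + EFFECT_SIZES.index(config.effect_size)
        + 1
    )


def factorial(seed: int = 0, **overrides) -> list:
    """All 36 scenarios (4 conditions x 3 severities x 3 effect sizes)."""
    return [
        ScenarioConfig(condition=c, severity=s, effect_size=e, seed=seed, **overrides)
        for c, s, e in itertools.product(CONDITIONS, SEVERITIES, EFFECT_SIZES)
    ]


def baseline_populations() -> list:
    """The 12 condition x severity populations (baseline has no treatment
    effect, so effect size does not enter)."""
    return list(itertools.product(CONDITIONS, SEVERITIES))


# -- builtin probability recipes ------------------------------------------


def _binomial_levels(p: float, n_levels: int) -> np.ndarray:
    k = np.arange(n_levels)
    return stats.binom.pmf(k, n_levels - 1, p)


def baseline_table(condition: str, severity: str, version: str) -> BaselineProbabilityTable:
    """Synthetic baseline response probabilities; identical in both arms
    (no treatment effect at baseline)."""
    check_version(version)
    weights = CONDITION_WEIGHTS[condition]
    mu = SEVERITY_LOCATION[severity]
    nlev = LEVELS[version]
    rows = []
    for w in weights:
        p = float(np.clip(mu * (0.35 + 0.65 * w), 0.02, 0.95))
        rows.append(_binomial_levels(p, nlev))
    probs = np.stack(rows)
    return BaselineProbabilityTable(version=version, probs={a: probs.copy() for a in ARMS})


def control_transitions(version: str) -> np.ndarray:
    """Stay-biased control transition kernel, identical across dimensions:
    weight exp(-2 |t - s|), i.e. mostly stable health with symmetric
    adjacent-level movement."""
    nlev = LEVELS[check_version(version)]
    s = np.arange(nlev)[:, None]
    t = np.arange(nlev)[None, :]
    w = np.exp(-2.0 * np.abs(t - s))
    m = w / w.sum(axis=1, keepdims=True)
    return np.broadcast_to(m, (5, nlev, nlev)).copy()


def transition_model(version: str) -> TransitionModel:
    base = control_transitions(version)
    return TransitionModel(
        version=version, matrices={"control": base.copy(), "intervention": base.copy()}
    )


_calibration_cache = {}


def calibrated_transitions(
    condition: str, severity: str, effect_size: str, version: str
) -> TransitionModel:
    """Transition model with the intervention arm tilted into the requested
    Cohen's d band, scored under the NL calibration tariff (cached)."""
    key = (condition, severity, effect_size, version)
    if key not in _calibration_cache:
        table = baseline_table(condition, severity, version)
        _calibration_cache[key] = sim.calibrate_effect_size(
            table,
            transition_model(version),
            effect_size,
            calibration_tariff(version),
        )
    return _calibration_cache[key]


def calibration_tariff(version: str) -> Tariff:
    """The single tariff the effect-size tweak is anchored to (NL)."""
    return builtin_tariff("NL", version)


# -- trial assembly --------------------------------------------------------


def simulate_trial(
    config: ScenarioConfig, version: str, master_seed: int = None
) -> TrialDataset:
    """Generate one complete TrialDataset for a scenario and EQ-5D version.

    Substreams are keyed so that baseline profiles and covariates depend
    only on (condition, severity, version) — the three effect-size bands of
    a population share identical baselines — while follow-up and costs also
    key on the band.
    """
    check_version(version)
    seed = config.seed if master_seed is None else master_seed
    cond, sev, band = config.condition, config.severity, config.effect_size

    table = baseline_table(cond, sev, version)
    model = calibrated_transitions(cond, sev, band, version)

    rng_base = substream(seed, "baseline", cond, sev, version)
    baseline = sim.generate_baseline(table, config.n_per_arm, rng_base)

    rng_fu = substream(seed, "followup", cond, sev, band, version)
    followup = {
        arm: sim.generate_followup(baseline[arm], model.matrices[arm], version, rng_fu)
        for arm in ARMS
    }

    rng_cov = substream(seed, "covariates", cond, sev, version)
    n_total = 2 * config.n_per_arm
    ages, male = sim.generate_covariates(n_total, rng_cov)

    arm = np.repeat([0, 1], config.n_per_arm)
    base_levels = np.vstack([baseline["control"], baseline["intervention"]])
    fu_levels = np.vstack([followup["control"], followup["intervention"]])

    tariff = calibration_tariff(version)
    u0 = tariff.utilities(base_levels)
    u1 = tariff.utilities(fu_levels)
    qalys = config.horizon * (u0 + u1) / 2.0

    rng_cost = substream(seed, "costs", cond, sev, band, version)
    costs = sim.generate_costs(qalys, arm, config.cost_config(), rng_cost)

    df = pd.DataFrame(
        {
            "subject": np.arange(n_total),
            "arm": arm,
            "age": ages,
            "male": male,
            "baseline_state": levels_to_strings(base_levels),
            "followup_state": levels_to_strings(fu_levels),
            "cost": costs,
        }
    )
    return TrialDataset(
        version=version,
        data=df,
        scenario=config,
        shift=model.shift,
        meta={"calibration_tariff": f"{tariff.country}-{version}"},
    )


# -- table I/O (spec CSV schema) ------------------------------------------


def write_probability_table(table: BaselineProbabilityTable, path) -> None:
    """``arm,dimension,level,probability`` CSV for baseline tables."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["arm", "dimension", "level", "probability"])
        for arm in ARMS:
            for d, dim in enumerate(DIMENSIONS):
                for lev in range(LEVELS[table.version]):
                    w.writerow([arm, dim, lev + 1, repr(float(table.probs[arm][d, lev]))])


def load_probability_table(path, version: str) -> BaselineProbabilityTable:
    df = pd.read_csv(path)
    nlev = LEVELS[check_version(version)]
    probs = {arm: np.zeros((5, nlev)) for arm in ARMS}
    for _, row in df.iterrows():
        probs[row["arm"]][DIMENSIONS.index(row["dimension"]), int(row["level"]) - 1] = (
            float(row["probability"])
        )
    return BaselineProbabilityTable(version=version, probs=probs)


def write_transition_model(model: TransitionModel, path) -> None:
    """``arm,dimension,from_level,to_level,probability`` CSV."""
    nlev = LEVELS[model.version]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["arm", "dimension", "from_level", "to_level", "probability"])
        for arm in ARMS:
            for d, dim in enumerate(DIMENSIONS):
                for s in range(nlev):
                    for t in range(nlev):
                        w.writerow(
                            [arm, dim, s + 1, t + 1, repr(float(model.matrices[arm][d, s, t]))]
                        )


def load_transition_model(path, version: str) -> TransitionModel:
    df = pd.read_csv(path)
    nlev = LEVELS[check_version(version)]
    mats = {arm: np.zeros((5, nlev, nlev)) for arm in ARMS}
    for _, row in df.iterrows():
        mats[row["arm"]][
            DIMENSIONS.index(row["dimension"]),
            int(row["from_level"]) - 1,
            int(row["to_level"]) - 1,
        ] = float(row["probability"])
    return TransitionModel(version=version, matrices=mats)
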