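"""Comparison of EQ-5D scoring methods across the scenario factorial.

For each country two pairings are compared: the 3L value set
against the 3L-to-5L crosswalk, and the 5L value set against the 5L-to-3L
crosswalk. Utilities and QALYs are compared subject-by-subject with paired
t tests and a minimally clinically important difference (MCID) of 0.074
utility points; full cost-utility analyses are compared on incremental
QALYs, ICERs, probabilities of cost-effectiveness at each willingness-to-
pay threshold, and the resulting reimbursement decisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seeding import seed_sequence
from .crosswalks import CrosswalkModel, builtin_crosswalk
from .cua import DEFAULT_THRESHOLD, DEFAULT_WTP, CostUtilityModel, score_dataset
from .scenarios import (
    EFFECT_SIZES,
    ScenarioConfig,
    baseline_populations,
    factorial,
    simulate_trial,
)
from .tariffs import Tariff, builtin_tariff

MCID = 0.074

PAIRINGS = ("3L", "5L")  # source version of each value-set/crosswalk pairing
_PAIR_DIRECTION = {"3L": "3L_to_5L", "5L": "5L_to_3L"}


class ComparisonError(ValueError):
    """Invalid comparison specification."""


# -- elementary statistics -------------------------------------------------


@dataclass(frozen=True)
class PairedT:
    """Paired t test of a - b: mean difference, CI, p; degenerate when the
    differences have zero variance (mean reported, no test)."""

    mean_difference: float
    ci: tuple
    p_value: float
    n: int
    degenerate: bool = False


def paired_t(values_a, values_b, level: float = 0.95) -> PairedT:
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ComparisonError("paired_t needs two equal-length 1d samples, n >= 2")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return PairedT(mean, (mean, mean), float("nan"), len(d), degenerate=True)
    se = sd / np.sqrt(len(d))
    tcrit = stats.t.ppf(0.5 + level / 2, df=len(d) - 1)
    tstat = mean / se
    p = 2 * stats.t.sf(abs(tstat), df=len(d) - 1)
    return PairedT(mean, (mean - tcrit * se, mean + tcrit * se), float(p), len(d))


def mcid_flag(mean_difference: float, threshold: float = MCID) -> bool:
    """Clinically relevant when |difference| >= threshold (inclusive)."""
    if not np.isfinite(mean_difference):
        raise ComparisonError("mean difference must be finite")
    return bool(abs(mean_difference) >= threshold)


def density_summary(utilities, grid_size: int = 512, n_bins: int = 24) -> dict:
    """Deterministic description of a utility distribution.

    Histogram over ``n_bins`` equal bins spanning the data, plus a Gaussian
    KDE (normal-reference/Silverman bandwidth) evaluated on a fixed
    ``grid_size``-point grid. Zero-variance input yields a single occupied
    bin and no KDE.
    """
    u = np.asarray(utilities, float)
    if len(u) == 0:
        raise ComparisonError("empty utility sample")
    out = {
        "n": int(len(u)),
        "mean": float(u.mean()),
        "sd": float(u.std(ddof=1)) if len(u) > 1 else 0.0,
        "min": float(u.min()),
        "max": float(u.max()),
    }
    if out["max"] == out["min"]:
        out["sd"] = 0.0
        out["hist_edges"] = [out["min"] - 0.5, out["min"] + 0.5]
        out["hist_counts"] = [out["n"]]
        out["kde_grid"] = None
        out["kde_density"] = None
        return out
    counts, edges = np.histogram(u, bins=n_bins)
    kde = stats.gaussian_kde(u, bw_method="silverman")
    pad = 3.0 * kde.factor * out["sd"]
    grid = np.linspace(out["min"] - pad, out["max"] + pad, grid_size)
    out["hist_edges"] = edges.tolist()
    out["hist_counts"] = counts.tolist()
    out["kde_grid"] = grid
    out["kde_density"] = kde(grid)
    return out


def identity_lookup_crosswalk(country_tariffs: dict, direction: str = "3L_to_5L") -> CrosswalkModel:
    """A crosswalk rigged to return each source state's own value-set
    utility (lookup built from the given {country: source-version tariff}).

    Useful as a null method: comparing a value set against this crosswalk
    must yield exactly zero differences everywhere, verifying that the
    pipeline introduces no spurious method effects.
    """
    from .states import enumerate_levels, levels_to_strings

    source = _PAIR_DIRECTION_SOURCE[direction]
    strings = levels_to_strings(enumerate_levels(source))
    lookup = {}
    for country, tariff in country_tariffs.items():
        if tariff.version != source:
            raise ComparisonError(
                f"identity crosswalk for {direction} needs {source} tariffs"
            )
        lookup[country] = dict(zip(strings, (float(v) for v in tariff.utility_table())))
    return CrosswalkModel(direction=direction, lookup=lookup)


_PAIR_DIRECTION_SOURCE = {"3L_to_5L": "3L", "5L_to_3L": "5L"}


# -- method pairs ----------------------------------------------------------


@dataclass(frozen=True)
class MethodPair:
    """A value set and the crosswalk it is compared against.

    ``pairing`` names the source EQ-5D version: "3L" compares the 3L value
    set with the 3L-to-5L crosswalk, "5L" the 5L value set with the
    5L-to-3L crosswalk. Both methods score the same source-version states.
    """

    country: str
    pairing: str
    base_tariff: Tariff
    crosswalk: CrosswalkModel
    crosswalk_tariff: Tariff

    @classmethod
    def builtin(cls, country: str, pairing: str, crosswalks: dict = None) -> "MethodPair":
        if pairing not in PAIRINGS:
            raise ComparisonError(f"pairing must be one of {PAIRINGS}, got {pairing!r}")
        direction = _PAIR_DIRECTION[pairing]
        model = (crosswalks or {}).get(direction) or builtin_crosswalk(direction)
        target_version = "5L" if pairing == "3L" else "3L"
        return cls(
            country=country,
            pairing=pairing,
            base_tariff=builtin_tariff(country, pairing),
            crosswalk=model,
            crosswalk_tariff=builtin_tariff(country, target_version),
        )

    @property
    def source_version(self) -> str:
        return self.pairing

    @property
    def base_name(self) -> str:
        return f"{self.pairing} value set"

    @property
    def mapped_name(self) -> str:
        return f"{_PAIR_DIRECTION[self.pairing].replace('_', ' ')} crosswalk"

    def mapped_method(self):
        return (self.crosswalk, self.crosswalk_tariff)


# -- the factorial run -----------------------------------------------------


@dataclass
class FactorialResult:
    """Tables and summary of a full scoring-method comparison run."""

    utilities_table: pd.DataFrame
    qalys_table: pd.DataFrame
    cua_table: pd.DataFrame
    summary: dict
    failures: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def _utility_row(pair: MethodPair, dataset, condition, severity) -> dict:
    """Pooled-arm baseline utility comparison for one population."""
    levels = dataset.levels("baseline_state")
    u_base = pair.base_tariff.utilities(levels)
    u_mapped = pair.crosswalk.utilities(levels, pair.crosswalk_tariff)
    test = paired_t(u_base, u_mapped)
    return {
        "condition": condition,
        "severity": severity,
        "country": pair.country,
        "pairing": pair.pairing,
        "mean_base": float(u_base.mean()),
        "sd_base": float(u_base.std(ddof=1)),
        "min_base": float(u_base.min()),
        "max_base": float(u_base.max()),
        "mean_mapped": float(u_mapped.mean()),
        "sd_mapped": float(u_mapped.std(ddof=1)),
        "min_mapped": float(u_mapped.min()),
        "max_mapped": float(u_mapped.max()),
        "diff": test.mean_difference,
        "diff_lo": test.ci[0],
        "diff_hi": test.ci[1],
        "p_value": test.p_value,
        "mcid": mcid_flag(test.mean_difference),
    }


def run_factorial(
    scenarios=None,
    countries=("NL", "US", "JP"),
    pairings=PAIRINGS,
    seed: int = 0,
    n_boot: int = 2000,
    wtp=DEFAULT_WTP,
    threshold: float = DEFAULT_THRESHOLD,
    crosswalks: dict = None,
    mcid: float = MCID,
) -> FactorialResult:
    """Analyse every scenario x country x pairing cell.

    Produces the three report tables: baseline utility comparisons (12
    populations per country per pairing), QALY comparisons (one row per
    scenario), and cost-utility comparisons (incremental estimates, ICERs,
    pCE and decisions per method with their differences). Scenario failures
    are recorded and the run continues.
    """
    if scenarios is None:
        scenarios = factorial(seed=seed)
    pairs = [
        MethodPair.builtin(country, pairing, crosswalks)
        for country in countries
        for pairing in pairings
    ]
    datasets = {}

    def dataset_for(config: ScenarioConfig, version: str):
        key = (config.scenario_id, version)
        if key not in datasets:
            datasets[key] = simulate_trial(config, version, master_seed=seed)
        return datasets[key]

    util_rows, qaly_rows, cua_rows, failures = [], [], [], []

    # Baseline utilities: one row per (population, country, pairing); the
    # baseline profiles are band-independent, so use each population's
    # first-band scenario.
    first_band = {}
    for config in scenarios:
        first_band.setdefault((config.condition, config.severity), config)
    for (condition, severity), config in first_band.items():
        for pair in pairs:
            try:
                ds = dataset_for(config, pair.source_version)
                util_rows.append(_utility_row(pair, ds, condition, severity))
            except Exception as exc:  # noqa: BLE001 - isolate per population
                failures.append(
                    {"stage": "utilities", "population": f"{severity} {condition}",
                     "country": pair.country, "pairing": pair.pairing, "error": str(exc)}
                )

    for config in scenarios:
        for pair in pairs:
            try:
                ds = dataset_for(config, pair.source_version)
                scored_base = score_dataset(ds, pair.base_tariff)
                scored_mapped = score_dataset(ds, pair.mapped_method())
                test = paired_t(scored_base["qaly"], scored_mapped["qaly"])
                qaly_rows.append(
                    {
                        "scenario_id": config.scenario_id,
                        "condition": config.condition,
                        "severity": config.severity,
                        "effect_size": config.effect_size,
                        "country": pair.country,
                        "pairing": pair.pairing,
                        "qaly_base": float(scored_base["qaly"].mean()),
                        "qaly_base_sd": float(scored_base["qaly"].std(ddof=1)),
                        "qaly_mapped": float(scored_mapped["qaly"].mean()),
                        "qaly_mapped_sd": float(scored_mapped["qaly"].std(ddof=1)),
                        "diff": test.mean_difference,
                        "diff_lo": test.ci[0],
                        "diff_hi": test.ci[1],
                        "p_value": test.p_value,
                        "mcid": mcid_flag(test.mean_difference, mcid),
                    }
                )

                row = {
                    "scenario_id": config.scenario_id,
                    "condition": config.condition,
                    "severity": config.severity,
                    "effect_size": config.effect_size,
                    "country": pair.country,
                    "pairing": pair.pairing,
                }
                results = {}
                for label, scored in (("base", scored_base), ("mapped", scored_mapped)):
                    # identical resampling for the two methods of a pair
                    rng = np.random.default_rng(
                        seed_sequence(
                            seed, "bootstrap", config.scenario_id, pair.country, pair.pairing
                        )
                    )
                    res = CostUtilityModel(scored).fit(
                        n_boot=n_boot, seed=rng, wtp=wtp, threshold=threshold
                    )
                    results[label] = res
                    for k, v in res.row().items():
                        row[f"{label}_{k}"] = v
                base_res, mapped_res = results["base"], results["mapped"]
                row["delta_incr_qaly"] = base_res.delta_qaly - mapped_res.delta_qaly
                both_defined = base_res.icer.defined and mapped_res.icer.defined
                row["delta_icer"] = (
                    base_res.icer.value - mapped_res.icer.value if both_defined else np.nan
                )
                if n_boot:
                    for lam in wtp:
                        row[f"delta_pce_{int(lam)}"] = (
                            base_res.pce[float(lam)] - mapped_res.pce[float(lam)]
                        )
                        row[f"decision_changed_{int(lam)}"] = (
                            base_res.decisions[float(lam)] != mapped_res.decisions[float(lam)]
                        )
                cua_rows.append(row)
            except Exception as exc:  # noqa: BLE001 - isolate per scenario
                failures.append(
                    {"stage": "cua", "scenario_id": config.scenario_id,
                     "country": pair.country, "pairing": pair.pairing, "error": str(exc)}
                )

    utilities_table = pd.DataFrame(util_rows)
    qalys_table = pd.DataFrame(qaly_rows)
    cua_table = pd.DataFrame(cua_rows)
    summary = summarise(utilities_table, qalys_table, cua_table, wtp if n_boot else ())
    return FactorialResult(utilities_table, qalys_table, cua_table, summary, failures)


def summarise(utilities_table, qalys_table, cua_table, wtp=DEFAULT_WTP) -> dict:
    """Min/max differences and MCID fractions per (country, pairing)."""
    out = {"n_populations": 0, "n_scenarios": 0, "mcid_fraction": {}}
    if len(utilities_table):
        out["n_populations"] = int(
            utilities_table.groupby(["condition", "severity"]).ngroups
        )
        out["utility_diff_range"] = [
            float(utilities_table["diff"].min()),
            float(utilities_table["diff"].max()),
        ]
        for (country, pairing), grp in utilities_table.groupby(["country", "pairing"]):
            out["mcid_fraction"][f"{country}/{pairing}"] = float(grp["mcid"].mean())
    if len(qalys_table):
        out["n_scenarios"] = int(qalys_table["scenario_id"].nunique())
        out["qaly_diff_range"] = [
            float(qalys_table["diff"].min()),
            float(qalys_table["diff"].max()),
        ]
    if len(cua_table):
        out["incr_qaly_diff_range"] = [
            float(cua_table["delta_incr_qaly"].min()),
            float(cua_table["delta_incr_qaly"].max()),
        ]
        for lam in wtp:
            col = f"delta_pce_{int(lam)}"
            if col in cua_table:
                out[f"pce_diff_range_{int(lam)}"] = [
                    float(cua_table[col].min()),
                    float(cua_table[col].max()),
                ]
        changed = [c for c in cua_table.columns if c.startswith("decision_changed_")]
        if changed:
            out["any_decision_changed"] = bool(cua_table[changed].any().any())
    return out
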