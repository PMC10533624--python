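"""Run orchestration: config loading, manifests, fixtures, output trees.

A run is fully determined by its YAML config (which embeds the master
seed): the manifest records the config hash, per-stage substream seeds and
data-file digests, and two runs with equal manifests produce byte-identical
CSV outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from ._seeding import derived_seed
from .compare import run_factorial
from .crosswalks import builtin_crosswalk, load_crosswalk, write_crosswalk, write_lookup
from .cua import DEFAULT_THRESHOLD, DEFAULT_WTP
from .scenarios import (
    CONDITIONS,
    EFFECT_SIZES,
    SEVERITIES,
    ScenarioConfig,
    baseline_table,
    calibrated_transitions,
    simulate_trial,
    transition_model,
    write_probability_table,
    write_transition_model,
)
from .tariffs import TariffTerm, Tariff, builtin_tariff, load_tariff, write_tariff

log = logging.getLogger("eq5dsim")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    substream_seeds: dict
    data_digests: dict
    artifact_version: str
    created: str = ""
    extra: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


_DEFAULT_CONFIG = {
    "seed": 0,
    "countries": ["NL", "US", "JP"],
    "pairings": ["3L", "5L"],
    "scenarios": "all",
    "n_per_arm": 150,
    "bootstrap": 2000,
    "wtp": list(DEFAULT_WTP),
    "threshold": DEFAULT_THRESHOLD,
    "cost": {"mean": 2000.0, "difference": 250.0, "dispersion": 1.0, "correlation": -0.10},
    "horizon": 1.0,
    "crosswalk_files": {},
    "tariff_files": {},
    "currency": "EUR",
}


def load_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(doc) - set(_DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    config = {**_DEFAULT_CONFIG, **doc}
    config["cost"] = {**_DEFAULT_CONFIG["cost"], **(doc.get("cost") or {})}
    for country in config["countries"]:
        if country not in ("NL", "US", "JP") and country not in config["tariff_files"]:
            raise ConfigError(
                f"country {country!r} has no embedded tariff and no entry under "
                "tariff_files"
            )
    for key, fp in {**config["crosswalk_files"], **config["tariff_files"]}.items():
        if not Path(fp).exists():
            raise ConfigError(f"referenced data file missing for {key!r}: {fp}")
    if config["bootstrap"] < 0 or config["n_per_arm"] < 1:
        raise ConfigError("bootstrap must be >= 0 and n_per_arm >= 1")
    return config


def _scenario_list(config) -> list:
    spec = config["scenarios"]
    common = dict(
        n_per_arm=int(config["n_per_arm"]),
        cost_mean=float(config["cost"]["mean"]),
        cost_true_difference=float(config["cost"]["difference"]),
        cost_dispersion=float(config["cost"]["dispersion"]),
        target_correlation=float(config["cost"]["correlation"]),
        horizon=float(config["horizon"]),
        seed=int(config["seed"]),
    )
    if spec == "all":
        cells = [
            {"condition": c, "severity": s, "effect_size": e}
            for c in CONDITIONS
            for s in SEVERITIES
            for e in EFFECT_SIZES
        ]
    elif isinstance(spec, list):
        cells = spec
    else:
        raise ConfigError("scenarios must be 'all' or a list of cells")
    return [ScenarioConfig(**cell, **common) for cell in cells]


def run_pipeline(config_path, out_dir) -> RunManifest:
    """Simulate, score, analyse and compare; write the full output tree."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = load_config(config_path)
    seed = int(config["seed"])
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()

    crosswalks = {
        direction: load_crosswalk(fp)
        for direction, fp in config["crosswalk_files"].items()
    }
    digests = {str(k): _sha256(v) for k, v in
               {**config["crosswalk_files"], **config["tariff_files"]}.items()}

    manifest = RunManifest(
        config_hash=config_hash,
        master_seed=seed,
        substream_seeds={
            stage: derived_seed(seed, stage)
            for stage in ("baseline", "followup", "covariates", "costs", "bootstrap")
        },
        data_digests=digests,
        artifact_version=__version__,
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        extra={"currency": config["currency"]},
    )
    manifest.write(out / "manifest.json")
    log.info("manifest written; %d scenarios", len(_scenario_list(config)))

    result = run_factorial(
        scenarios=_scenario_list(config),
        countries=tuple(config["countries"]),
        pairings=tuple(config["pairings"]),
        seed=seed,
        n_boot=int(config["bootstrap"]),
        wtp=tuple(float(w) for w in config["wtp"]),
        threshold=float(config["threshold"]),
        crosswalks=crosswalks or None,
    )
    result.utilities_table.to_csv(out / "table_utilities.csv", index=False)
    result.qalys_table.to_csv(out / "table_qalys.csv", index=False)
    result.cua_table.to_csv(out / "table_cua.csv", index=False)
    summary = dict(result.summary)
    summary["failures"] = result.failures
    summary["currency"] = config["currency"]
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    if result.failures:
        log.error("%d scenario cells failed", len(result.failures))
    return manifest


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Write a self-consistent fixture set: a small synthetic tariff, a
    crosswalk whose lookup is generated from its own matrices (so the
    consistency check is exactly zero), probability tables, and a toy
    simulated trial CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    fixture_tariff = Tariff(
        country="FX",
        version="3L",
        terms=[
            TariffTerm("any_level_ge", 0.07, level=2),
            TariffTerm("level_dummy", 0.05, dimension="MO", level=2),
            TariffTerm("level_dummy", 0.12, dimension="MO", level=3),
            TariffTerm("level_dummy", 0.04, dimension="SC", level=2),
            TariffTerm("level_dummy", 0.09, dimension="SC", level=3),
            TariffTerm("level_dummy", 0.03, dimension="UA", level=2),
            TariffTerm("level_dummy", 0.08, dimension="UA", level=3),
            TariffTerm("level_dummy", 0.06, dimension="PD", level=2),
            TariffTerm("level_dummy", 0.20, dimension="PD", level=3),
            TariffTerm("level_dummy", 0.06, dimension="AD", level=2),
            TariffTerm("level_dummy", 0.15, dimension="AD", level=3),
            TariffTerm("any_level_ge", 0.10, level=3),
        ],
        notes="Synthetic fixture tariff for tests and demos.",
    )
    paths["tariff"] = out / "fixture_tariff_3l.yaml"
    write_tariff(fixture_tariff, paths["tariff"])

    model = builtin_crosswalk("5L_to_3L")
    paths["crosswalk"] = out / "fixture_crosswalk_5l_to_3l.csv"
    write_crosswalk(model, paths["crosswalk"])
    paths["lookup"] = out / "fixture_lookup_5l_to_3l.csv"
    write_lookup(model, [fixture_tariff], paths["lookup"])

    table = baseline_table("low_back_pain", "moderate", "3L")
    paths["baseline_table"] = out / "fixture_baseline_probs.csv"
    write_probability_table(table, paths["baseline_table"])
    paths["transitions"] = out / "fixture_transitions.csv"
    write_transition_model(
        calibrated_transitions("low_back_pain", "moderate", "medium", "3L"),
        paths["transitions"],
    )

    config = ScenarioConfig(
        condition="low_back_pain", severity="moderate", effect_size="medium",
        n_per_arm=25, seed=seed,
    )
    paths["trial"] = out / "fixture_trial_3l.csv"
    simulate_trial(config, "3L").to_csv(paths["trial"])
    return {k: str(v) for k, v in paths.items()}
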