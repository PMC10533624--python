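"""Synthetic two-arm trial generation.

The generator mirrors a trial-based economic evaluation with two
measurement points: per-arm baseline EQ-5D profiles drawn dimension-wise
from response-level probability vectors, follow-up profiles drawn from
per-dimension transition matrices, an intervention-arm effect calibrated to
a Cohen's d band by exponential tilting toward improvement, uniform ages,
a fixed male proportion, and gamma follow-up costs coupled to QALYs through
a Gaussian copula with a negative correlation target.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .states import DIMENSIONS, LEVELS, check_version, validate_levels
from .tariffs import Tariff

ARMS = ("control", "intervention")
PROB_TOL = 1e-9

#: Cohen's d bands and the midpoint each band is calibrated to.
EFFECT_BANDS = {
    "small": (0.1, 0.3),
    "medium": (0.5, 0.7),
    "large": (0.8, np.inf),
}
EFFECT_TARGETS = {"small": 0.2, "medium": 0.6, "large": 0.9}
CALIBRATION_TOL = 0.05

AGE_RANGE = (25, 75)
MALE_PROPORTION = 0.19


class SimulationError(ValueError):
    """Invalid generator specification."""


class CalibrationError(RuntimeError):
    """The requested effect-size band is unreachable by tilting."""


def _check_stochastic(vectors: np.ndarray, what: str):
    if (vectors < -PROB_TOL).any():
        raise SimulationError(f"{what}: negative probability")
    sums = vectors.sum(axis=-1)
    if np.abs(sums - 1.0).max() > PROB_TOL:
        raise SimulationError(f"{what}: probabilities sum to {sums.ravel()} != 1")


@dataclass
class BaselineProbabilityTable:
    """Per-arm, per-dimension response-level probabilities at baseline."""

    version: str
    probs: dict  # {arm: (5, n_levels) array}

    def __post_init__(self):
        check_version(self.version)
        nlev = LEVELS[self.version]
        out = {}
        for arm in ARMS:
            if arm not in self.probs:
                raise SimulationError(f"baseline table missing arm {arm!r}")
            p = np.asarray(self.probs[arm], dtype=float)
            if p.shape != (5, nlev):
                raise SimulationError(
                    f"baseline probabilities for {arm} have shape {p.shape}, "
                    f"expected (5, {nlev})"
                )
            _check_stochastic(p, f"baseline {arm}")
            out[arm] = p
        self.probs = out


@dataclass
class TransitionModel:
    """Per-arm, per-dimension transition matrices (baseline -> follow-up)."""

    version: str
    matrices: dict  # {arm: (5, n_levels, n_levels) array}
    shift: float = 0.0  # tilting already applied to the intervention arm

    def __post_init__(self):
        check_version(self.version)
        nlev = LEVELS[self.version]
        if self.shift < 0:
            raise SimulationError("shift parameter must be >= 0")
        out = {}
        for arm in ARMS:
            if arm not in self.matrices:
                raise SimulationError(f"transition model missing arm {arm!r}")
            m = np.asarray(self.matrices[arm], dtype=float)
            if m.shape != (5, nlev, nlev):
                raise SimulationError(
                    f"transition matrices for {arm} have shape {m.shape}, "
                    f"expected (5, {nlev}, {nlev})"
                )
            _check_stochastic(m, f"transitions {arm}")
            out[arm] = m
        self.matrices = out


# -- state sampling --------------------------------------------------------


def _sample_categorical(pvals: np.ndarray, n: int, rng: np.random.Generator):
    """n draws from one probability vector, returned as levels 1..L."""
    cum = np.cumsum(pvals)
    cum[-1] = 1.0
    return 1 + np.searchsorted(cum, rng.random(n), side="right").clip(0, len(pvals) - 1)


def generate_baseline(
    table: BaselineProbabilityTable, n_per_arm: int, rng: np.random.Generator
) -> dict:
    """Baseline level arrays {arm: (n_per_arm, 5)}; dimensions independent."""
    if n_per_arm < 1:
        raise SimulationError("n_per_arm must be >= 1")
    out = {}
    for arm in ARMS:
        cols = [
            _sample_categorical(table.probs[arm][d], n_per_arm, rng) for d in range(5)
        ]
        out[arm] = np.stack(cols, axis=1)
    return out


def generate_followup(
    baseline: np.ndarray, matrices: np.ndarray, version: str, rng: np.random.Generator
) -> np.ndarray:
    """Follow-up levels for one arm: each dimension drawn from the transition
    row of its baseline level."""
    baseline = validate_levels(baseline, version)
    matrices = np.asarray(matrices, dtype=float)
    _check_stochastic(matrices, "transitions")
    n = len(baseline)
    out = np.empty_like(baseline)
    for d in range(5):
        u = rng.random(n)
        for s in range(matrices.shape[1]):
            mask = baseline[:, d] == s + 1
            if not mask.any():
                continue
            cum = np.cumsum(matrices[d, s])
            cum[-1] = 1.0
            out[mask, d] = 1 + np.searchsorted(cum, u[mask], side="right").clip(
                0, matrices.shape[2] - 1
            )
    return out


# -- effect-size calibration ----------------------------------------------


def tilt_matrix(matrix: np.ndarray, shift: float) -> np.ndarray:
    """Exponentially tilt transition rows toward improvement.

    The probability of moving from level s to level t is reweighted by
    exp(shift * steps_improved) with steps_improved = max(0, s - t) (lower
    level = better health), then rows are renormalised. shift = 0 is the
    identity.
    """
    matrix = np.asarray(matrix, dtype=float)
    nlev = matrix.shape[-1]
    s_idx = np.arange(1, nlev + 1)[:, None]
    t_idx = np.arange(1, nlev + 1)[None, :]
    weight = np.exp(shift * np.maximum(0, s_idx - t_idx))
    tilted = matrix * weight
    return tilted / tilted.sum(axis=-1, keepdims=True)


def followup_state_distribution(
    baseline_probs: np.ndarray, matrices: np.ndarray
) -> np.ndarray:
    """Joint follow-up state distribution (product of per-dimension
    marginals), canonical state order."""
    joint = np.ones(1)
    for d in range(5):
        joint = np.kron(joint, baseline_probs[d] @ matrices[d])
    return joint


def population_cohens_d(
    table: BaselineProbabilityTable, model: TransitionModel, tariff: Tariff
) -> float:
    """Exact Cohen's d of follow-up utilities between arms (pooled SD)."""
    u = tariff.utility_table()
    stats_by_arm = {}
    for arm in ARMS:
        p = followup_state_distribution(table.probs[arm], model.matrices[arm])
        mean = p @ u
        var = p @ (u**2) - mean**2
        stats_by_arm[arm] = (mean, max(var, 0.0))
    (mc, vc), (mi, vi) = stats_by_arm["control"], stats_by_arm["intervention"]
    pooled = np.sqrt((vc + vi) / 2)
    if pooled == 0:
        return 0.0
    return float((mi - mc) / pooled)


def calibrate_effect_size(
    table: BaselineProbabilityTable,
    model: TransitionModel,
    band: str,
    calibration_tariff: Tariff,
    tol: float = CALIBRATION_TOL,
) -> TransitionModel:
    """Tilt the intervention-arm transitions until Cohen's d of follow-up
    utilities hits the band midpoint (0.2 / 0.6 / 0.9) within ``tol``.

    The control arm is left untouched. Cohen's d is computed exactly from
    the enumerated follow-up state distribution, so the bisection is
    deterministic; d is non-decreasing in the shift parameter.
    """
    if band not in EFFECT_TARGETS:
        raise SimulationError(f"unknown effect-size band {band!r}")
    target = EFFECT_TARGETS[band]
    base = model.matrices["intervention"]

    def d_at(shift):
        tilted = replace(
            model,
            matrices={"control": model.matrices["control"], "intervention": tilt_matrix(base, shift)},
            shift=shift,
        )
        return population_cohens_d(table, tilted, calibration_tariff)

    lo, hi = 0.0, 1.0
    d_hi = d_at(hi)
    while d_hi < target and hi < 64:
        hi *= 2.0
        d_hi = d_at(hi)
    if d_hi < target - tol:
        raise CalibrationError(
            f"band {band!r} unreachable: maximum achievable Cohen's d is "
            f"about {d_hi:.3f} (target {target})"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        d_mid = d_at(mid)
        if abs(d_mid - target) <= tol * 0.5:
            lo = hi = mid
            break
        if d_mid < target:
            lo = mid
        else:
            hi = mid
    shift = 0.5 * (lo + hi)
    calibrated = replace(
        model,
        matrices={
            "control": model.matrices["control"],
            "intervention": tilt_matrix(base, shift),
        },
        shift=shift,
    )
    d_final = population_cohens_d(table, calibrated, calibration_tariff)
    if abs(d_final - target) > tol:
        raise CalibrationError(
            f"bisection did not converge for band {band!r}: d = {d_final:.3f}"
        )
    return calibrated


# -- covariates and costs --------------------------------------------------


def generate_covariates(n: int, rng: np.random.Generator):
    """Ages uniform on 25..75 inclusive; male ~ Bernoulli(0.19)."""
    if n < 1:
        raise SimulationError("n must be >= 1")
    ages = rng.integers(AGE_RANGE[0], AGE_RANGE[1] + 1, size=n)
    male = (rng.random(n) < MALE_PROPORTION).astype(int)
    return ages, male


@dataclass(frozen=True)
class CostConfig:
    """Gamma cost marginal and its coupling to QALYs.

    ``dispersion`` is nu with Var = nu * mean^2 (shape = 1/nu,
    scale = mean * nu); the default nu = 1 makes the SD equal the mean.
    """

    mean: float = 2000.0
    difference: float = 250.0
    dispersion: float = 1.0
    target_correlation: float = -0.10

    def __post_init__(self):
        if self.mean <= 0 or self.mean + self.difference <= 0:
            raise SimulationError("arm cost means must be positive")
        if self.dispersion <= 0:
            raise SimulationError("dispersion must be positive")
        if not -1 < self.target_correlation < 1:
            raise SimulationError("target correlation must be in (-1, 1)")


def _gamma_normal_loading(shape: float) -> float:
    """Corr(F_gamma^{-1}(Phi(Z)), Z) for a standard-normal Z, via
    Gauss-Hermite quadrature (scale-invariant)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(96)
    w = weights / weights.sum()
    u = special.ndtr(nodes).clip(1e-15, 1 - 1e-15)
    g = stats.gamma.ppf(u, a=shape)
    mean = w @ g
    var = w @ (g - mean) ** 2
    cov = w @ (g * nodes)
    return float(cov / np.sqrt(var))


def generate_costs(
    qalys: np.ndarray,
    arm: np.ndarray,
    config: CostConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gamma follow-up costs coupled to QALYs via a Gaussian copula.

    Marginals: control mean ``config.mean``, intervention mean
    ``mean + difference``, both gamma with dispersion nu. The latent normal
    correlation is solved so the implied *Pearson* correlation between costs
    and QALYs matches ``target_correlation`` (the gamma loading comes from
    quadrature, the QALY loading from its empirical normal scores), so the
    realised pooled correlation lands on the target without disturbing the
    gamma marginals.
    """
    qalys = np.asarray(qalys, dtype=float)
    arm = np.asarray(arm, dtype=int)
    if qalys.shape != arm.shape:
        raise SimulationError("qalys and arm indicators must align")
    n = len(qalys)
    shape = 1.0 / config.dispersion
    eps = rng.standard_normal(n)

    # Normal scores of the QALYs are taken *within arm* so the coupling
    # transfers no part of the treatment effect into the cost margin: the
    # arm cost means stay unbiased while the within-arm (and hence pooled)
    # cost-QALY correlation hits the target.
    target = config.target_correlation
    if target == 0.0 or np.std(qalys) == 0:
        z_cost = eps
    else:
        z_q = np.empty(n)
        loads, weights = [], []
        for a in np.unique(arm):
            idx = np.nonzero(arm == a)[0]
            ranks = stats.rankdata(qalys[idx], method="average")
            z = special.ndtri((ranks - 0.5) / len(idx))
            sd = np.std(z)
            z_q[idx] = z / sd if sd > 0 else 0.0
            if np.std(qalys[idx]) > 0 and sd > 0:
                loads.append(float(np.corrcoef(qalys[idx], z)[0, 1]))
                weights.append(len(idx))
        load_q = float(np.average(loads, weights=weights)) if loads else 0.0
        if load_q == 0.0:
            z_cost = eps
        else:
            load_c = _gamma_normal_loading(shape)
            rho = np.clip(target / (load_c * load_q), -0.99, 0.99)
            z_cost = rho * z_q + np.sqrt(1.0 - rho**2) * eps

    u = special.ndtr(z_cost).clip(1e-12, 1 - 1e-12)
    means = np.where(arm == 1, config.mean + config.difference, config.mean)
    scale = means * config.dispersion
    return stats.gamma.ppf(u, a=shape, scale=scale)


# -- the assembled dataset -------------------------------------------------

_STATE_COLS = ("baseline_state", "followup_state")


@dataclass
class TrialDataset:
    """Per-subject simulated trial data for one EQ-5D version.

    ``data`` columns: subject, arm (0 control / 1 intervention), age, male,
    baseline_state, followup_state (5-digit strings), cost. Scoring methods
    append utility/QALY columns downstream.
    """

    version: str
    data: pd.DataFrame
    scenario: object = None
    shift: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        check_version(self.version)
        needed = {"subject", "arm", "age", "male", "cost", *_STATE_COLS}
        missing = needed - set(self.data.columns)
        if missing:
            raise SimulationError(f"dataset missing columns {sorted(missing)}")
        if (self.data["cost"] < 0).any():
            raise SimulationError("negative costs")
        for col in _STATE_COLS:
            validate_levels(self.levels(col), self.version)

    def levels(self, col: str) -> np.ndarray:
        from .states import strings_to_levels

        return strings_to_levels(self.data[col].tolist(), self.version)

    @property
    def n_per_arm(self) -> dict:
        counts = self.data["arm"].value_counts()
        return {"control": int(counts.get(0, 0)), "intervention": int(counts.get(1, 0))}

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, version: str, **kwargs) -> "TrialDataset":
        df = pd.read_csv(
            path, dtype={"baseline_state": str, "followup_state": str}
        )
        return cls(version=version, data=df, **kwargs)

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.data.to_csv(buf, index=False)
        return buf.getvalue()
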