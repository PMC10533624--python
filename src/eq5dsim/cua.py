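"""Trial-based cost-utility analysis.

The estimation core is a two-equation seemingly-unrelated-regression (SUR)
system — a cost equation and a QALY equation sharing a treatment indicator —
fitted by feasible GLS so that the residual correlation between costs and
effects enters the joint covariance of the incremental estimates. Sampling
uncertainty is quantified by a nonparametric bootstrap stratified by arm
(subjects resampled with replacement within arm, the SUR refitted per
replicate) with bias-corrected and accelerated (BCa) intervals. Decision
outputs are the ICER with its cost-effectiveness-plane quadrant, the CEAC
(probability that the incremental net benefit lambda*dE - dC is positive at
each willingness-to-pay lambda) and a reimbursement decision at a
probability threshold.

Exposed in the modelling style of statsmodels: build a
:class:`CostUtilityModel` from a per-subject DataFrame, call ``fit()``, and
read estimates, intervals and the CEAC off the returned
:class:`CostUtilityResults` (``summary()`` prints the full table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

DEFAULT_WTP = (0.0, 20000.0, 30000.0, 50000.0)
DEFAULT_THRESHOLD = 0.80
ICER_EPSILON = 1e-6


class EstimationError(RuntimeError):
    """Rank-deficient design or degenerate residuals."""


# -- QALYs -----------------------------------------------------------------


def compute_qalys(u_baseline, u_followup, horizon: float = 1.0) -> np.ndarray:
    """Area-under-the-curve QALYs from two measurement points.

    Linear interpolation between baseline and follow-up utility over a
    ``horizon`` of years gives the trapezoid
    ``horizon * (u_baseline + u_followup) / 2``.
    """
    u0 = np.asarray(u_baseline, dtype=float)
    u1 = np.asarray(u_followup, dtype=float)
    return horizon * (u0 + u1) / 2.0


def score_dataset(dataset, method, horizon: float = None, prefix: str = "") -> pd.DataFrame:
    """Utility and QALY columns for a TrialDataset under a scoring method.

    ``method`` is anything with a ``utilities((n, 5) levels) -> (n,)``
    surface: a Tariff, or a (CrosswalkModel, target Tariff) pair.
    """
    if horizon is None:
        horizon = getattr(dataset.scenario, "horizon", 1.0) if dataset.scenario else 1.0
    if isinstance(method, tuple):
        model, tariff = method
        u0 = model.utilities(dataset.levels("baseline_state"), tariff)
        u1 = model.utilities(dataset.levels("followup_state"), tariff)
    else:
        u0 = method.utilities(dataset.levels("baseline_state"))
        u1 = method.utilities(dataset.levels("followup_state"))
    out = dataset.data[["subject", "arm", "cost"]].copy()
    out[f"{prefix}baseline_utility"] = u0
    out[f"{prefix}followup_utility"] = u1
    out[f"{prefix}qaly"] = compute_qalys(u0, u1, horizon)
    return out


# -- SUR -------------------------------------------------------------------


@dataclass
class SurFit:
    """Feasible-GLS estimates for the (cost, qaly) system."""

    params: np.ndarray  # stacked (cost equation first)
    cov: np.ndarray
    names: list
    delta_cost: float
    delta_qaly: float
    delta_cov: np.ndarray  # 2x2 joint covariance of the treatment effects
    resid_cov: np.ndarray

    def ci(self, which: str, level: float = 0.95):
        i = {"cost": 0, "qaly": 1}[which]
        est = (self.delta_cost, self.delta_qaly)[i]
        se = float(np.sqrt(self.delta_cov[i, i]))
        z = special.ndtri(0.5 + level / 2)
        return (est - z * se, est + z * se)


def _ols(X, y):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise EstimationError("rank-deficient design matrix")
    return beta


def sur_fit(y_cost, y_qaly, X_cost, X_qaly) -> SurFit:
    """Two-equation SUR by one-step feasible GLS.

    Residual covariance comes from equation-wise OLS (divisor n); with
    identical regressor matrices the FGLS estimator reduces algebraically
    to OLS. The treatment indicator must be the second column of each
    design matrix.
    """
    y_cost = np.asarray(y_cost, float)
    y_qaly = np.asarray(y_qaly, float)
    X_c = np.asarray(X_cost, float)
    X_q = np.asarray(X_qaly, float)
    n = len(y_cost)
    if not (len(y_qaly) == len(X_c) == len(X_q) == n):
        raise EstimationError("system rows misaligned")

    b_c = _ols(X_c, y_cost)
    b_q = _ols(X_q, y_qaly)
    e = np.stack([y_cost - X_c @ b_c, y_qaly - X_q @ b_q])
    S = (e @ e.T) / n
    if S[0, 0] <= 0 or S[1, 1] <= 0:
        raise EstimationError("zero residual variance in one equation")
    Sinv = np.linalg.inv(S)

    kc, kq = X_c.shape[1], X_q.shape[1]
    XtX = np.empty((kc + kq, kc + kq))
    XtX[:kc, :kc] = Sinv[0, 0] * (X_c.T @ X_c)
    XtX[:kc, kc:] = Sinv[0, 1] * (X_c.T @ X_q)
    XtX[kc:, :kc] = Sinv[1, 0] * (X_q.T @ X_c)
    XtX[kc:, kc:] = Sinv[1, 1] * (X_q.T @ X_q)
    Xty = np.concatenate(
        [
            Sinv[0, 0] * (X_c.T @ y_cost) + Sinv[0, 1] * (X_c.T @ y_qaly),
            Sinv[1, 0] * (X_q.T @ y_cost) + Sinv[1, 1] * (X_q.T @ y_qaly),
        ]
    )
    try:
        cov = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular stacked system") from exc
    params = cov @ Xty

    i_cost, i_qaly = 1, kc + 1  # treatment is column 1 of each equation
    delta_cov = cov[np.ix_([i_cost, i_qaly], [i_cost, i_qaly])]
    names = [f"cost_b{j}" for j in range(kc)] + [f"qaly_b{j}" for j in range(kq)]
    return SurFit(
        params=params,
        cov=cov,
        names=names,
        delta_cost=float(params[i_cost]),
        delta_qaly=float(params[i_qaly]),
        delta_cov=delta_cov,
        resid_cov=S,
    )


def _design(df, response_covariates, arm_col="arm"):
    cols = [np.ones(len(df)), df[arm_col].to_numpy(float)]
    cols += [df[c].to_numpy(float) for c in response_covariates]
    return np.column_stack(cols)


# -- BCa bootstrap ---------------------------------------------------------


@dataclass
class BcaInterval:
    lower: float
    upper: float
    z0: float
    acceleration: float
    degenerate: bool = False


def bca_interval(
    replicates: np.ndarray,
    point: float,
    jackknife: np.ndarray,
    level: float = 0.95,
) -> BcaInterval:
    """Bias-corrected and accelerated percentile interval.

    z0 = Phi^-1(fraction of replicates below the point estimate);
    acceleration a from the jackknife skewness; the returned endpoints are
    the adjusted percentiles of the replicate distribution.
    """
    reps = np.asarray(replicates, float)
    reps = reps[np.isfinite(reps)]
    if len(reps) == 0:
        raise EstimationError("no finite bootstrap replicates")
    if len(reps) < 100:
        warnings.warn("fewer than 100 bootstrap replicates; BCa unstable", stacklevel=2)
    if np.ptp(reps) == 0:
        warnings.warn("degenerate bootstrap distribution; point interval", stacklevel=2)
        return BcaInterval(float(reps[0]), float(reps[0]), 0.0, 0.0, degenerate=True)

    prop = np.mean(reps < point)
    prop = min(max(prop, 1.0 / (len(reps) + 1)), len(reps) / (len(reps) + 1.0))
    z0 = float(special.ndtri(prop))

    jk = np.asarray(jackknife, float)
    jbar = jk.mean()
    num = np.sum((jbar - jk) ** 3)
    den = 6.0 * np.sum((jbar - jk) ** 2) ** 1.5
    a = float(num / den) if den > 0 else 0.0

    alpha = (1.0 - level) / 2.0
    z_lo, z_hi = special.ndtri(alpha), special.ndtri(1.0 - alpha)
    lo_p = special.ndtr(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo)))
    hi_p = special.ndtr(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi)))
    lower, upper = np.quantile(reps, [lo_p, hi_p])
    return BcaInterval(float(lower), float(upper), z0, a)


def stratified_indices(arm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One bootstrap resample of subject indices, stratified by arm."""
    idx = []
    for a in (0, 1):
        pool = np.nonzero(arm == a)[0]
        idx.append(rng.choice(pool, size=len(pool), replace=True))
    return np.concatenate(idx)


def bca_bootstrap(
    data: pd.DataFrame,
    statistic,
    n_boot: int = 2000,
    level: float = 0.95,
    rng: np.random.Generator = None,
    arm_col: str = "arm",
):
    """Stratified-by-arm BCa bootstrap of an arbitrary statistic.

    ``statistic(df) -> float or 1d array``. Returns (replicates, point,
    [BcaInterval per output]).
    """
    if rng is None:
        rng = np.random.default_rng()
    arm = data[arm_col].to_numpy()
    point = np.atleast_1d(np.asarray(statistic(data), float))
    reps = np.empty((n_boot, len(point)))
    for b in range(n_boot):
        take = stratified_indices(arm, rng)
        reps[b] = np.atleast_1d(statistic(data.iloc[take]))
    jack = np.empty((len(data), len(point)))
    for i in range(len(data)):
        jack[i] = np.atleast_1d(statistic(data.drop(data.index[i])))
    cis = [
        bca_interval(reps[:, j], float(point[j]), jack[:, j], level)
        for j in range(len(point))
    ]
    return reps, point, cis


# -- ICER / CEAC / decisions ----------------------------------------------


@dataclass(frozen=True)
class Icer:
    """ICER value with CE-plane quadrant; undefined when |dQALY| < epsilon."""

    value: float
    defined: bool
    quadrant: str

    def __float__(self):
        return self.value if self.defined else float("nan")


def compute_icer(delta_cost: float, delta_qaly: float, epsilon: float = ICER_EPSILON) -> Icer:
    # ties on the axes fall on the positive (N / E) side
    quadrant = ("N" if delta_cost >= 0 else "S") + ("E" if delta_qaly >= 0 else "W")
    if abs(delta_qaly) < epsilon:
        return Icer(float("nan"), False, quadrant)
    return Icer(float(delta_cost / delta_qaly), True, quadrant)


def ceac(cloud: np.ndarray, wtp_grid=DEFAULT_WTP) -> dict:
    """pCE(lambda) = fraction of bootstrap replicates with INB > 0, where
    INB = lambda * dQALY - dCost and the cloud columns are (dCost, dQALY)."""
    cloud = np.asarray(cloud, float)
    if cloud.ndim != 2 or cloud.shape[1] != 2 or len(cloud) == 0:
        raise EstimationError("bootstrap cloud must be a non-empty (B, 2) array")
    return {
        float(lam): float(np.mean(lam * cloud[:, 1] - cloud[:, 0] > 0))
        for lam in wtp_grid
    }


def decide(pce: dict, threshold: float = DEFAULT_THRESHOLD) -> dict:
    """Cost-effective at lambda when pCE(lambda) >= threshold (inclusive)."""
    return {lam: bool(p >= threshold) for lam, p in pce.items()}


def quadrant_proportions(cloud: np.ndarray) -> dict:
    cloud = np.asarray(cloud, float)
    dc, de = cloud[:, 0], cloud[:, 1]
    return {
        "NE": float(np.mean((dc >= 0) & (de >= 0))),
        "SE": float(np.mean((dc < 0) & (de >= 0))),
        "NW": float(np.mean((dc >= 0) & (de < 0))),
        "SW": float(np.mean((dc < 0) & (de < 0))),
    }


# -- the model / results pair ---------------------------------------------


class CostUtilityModel:
    """Cost-utility analysis of a two-arm trial, one scoring method.

    Parameters
    ----------
    data : DataFrame
        Per-subject rows with at least the cost, QALY and arm columns.
    cost, qaly, arm : str
        Column names. ``arm`` is 0 (control) / 1 (intervention).
    cost_covariates, qaly_covariates : sequence of str
        Extra regressors per equation. By default the QALY equation adjusts
        for baseline utility (when the column is present) and the cost
        equation is treatment-only.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        cost: str = "cost",
        qaly: str = "qaly",
        arm: str = "arm",
        cost_covariates=(),
        qaly_covariates=None,
    ):
        self.data = data.reset_index(drop=True)
        self.cost_col, self.qaly_col, self.arm_col = cost, qaly, arm
        for col in (cost, qaly, arm):
            if col not in self.data.columns:
                raise EstimationError(f"column {col!r} not in data")
        if qaly_covariates is None:
            qaly_covariates = (
                ("baseline_utility",) if "baseline_utility" in self.data.columns else ()
            )
        self.cost_covariates = tuple(cost_covariates)
        self.qaly_covariates = tuple(qaly_covariates)
        counts = self.data[arm].value_counts()
        if counts.get(0, 0) < 2 or counts.get(1, 0) < 2:
            raise EstimationError("need at least 2 subjects per arm")

    @classmethod
    def from_dataset(cls, dataset, method, horizon: float = None, **kwargs):
        """Build directly from a TrialDataset plus a scoring method."""
        scored = score_dataset(dataset, method, horizon=horizon)
        return cls(scored, **kwargs)

    def _fit_once(self, df) -> SurFit:
        return sur_fit(
            df[self.cost_col],
            df[self.qaly_col],
            _design(df, self.cost_covariates, self.arm_col),
            _design(df, self.qaly_covariates, self.arm_col),
        )

    def fit(
        self,
        n_boot: int = 2000,
        seed=None,
        wtp=DEFAULT_WTP,
        level: float = 0.95,
        threshold: float = DEFAULT_THRESHOLD,
    ) -> "CostUtilityResults":
        """Point SUR fit plus stratified BCa bootstrap, CEAC and decisions.

        ``seed`` may be an int or a numpy Generator; ``n_boot=0`` skips the
        bootstrap (model-based intervals only).
        """
        point = self._fit_once(self.data)
        cloud = reps_icer = cis = None
        pce = decisions = quads = None
        if n_boot:
            rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
            arm = self.data[self.arm_col].to_numpy()
            yc = self.data[self.cost_col].to_numpy(float)
            yq = self.data[self.qaly_col].to_numpy(float)
            Xc = _design(self.data, self.cost_covariates, self.arm_col)
            Xq = _design(self.data, self.qaly_covariates, self.arm_col)

            def refit(idx):
                f = sur_fit(yc[idx], yq[idx], Xc[idx], Xq[idx])
                return f.delta_cost, f.delta_qaly

            cloud = np.empty((n_boot, 2))
            for b in range(n_boot):
                cloud[b] = refit(stratified_indices(arm, rng))
            n = len(self.data)
            jack = np.empty((n, 2))
            keep = np.arange(n)
            for i in range(n):
                jack[i] = refit(np.delete(keep, i))
            point_vec = np.array([point.delta_cost, point.delta_qaly])
            cis = [
                bca_interval(cloud[:, j], point_vec[j], jack[:, j], level)
                for j in range(2)
            ]
            icer_point = compute_icer(point.delta_cost, point.delta_qaly)
            with np.errstate(divide="ignore", invalid="ignore"):
                rep_ratio = np.where(
                    np.abs(cloud[:, 1]) < ICER_EPSILON, np.nan, cloud[:, 0] / cloud[:, 1]
                )
            jack_ratio = np.where(
                np.abs(jack[:, 1]) < ICER_EPSILON, np.nan, jack[:, 0] / jack[:, 1]
            )
            reps_icer = rep_ratio
            pce = ceac(cloud, wtp)
            decisions = decide(pce, threshold)
            quads = quadrant_proportions(cloud)
            icer_ci = (
                bca_interval(
                    rep_ratio[np.isfinite(rep_ratio)],
                    icer_point.value,
                    jack_ratio[np.isfinite(jack_ratio)],
                    level,
                )
                if icer_point.defined and np.isfinite(rep_ratio).sum() >= 100
                else None
            )
        else:
            icer_ci = None
        return CostUtilityResults(
            model=self,
            sur=point,
            level=level,
            threshold=threshold,
            cloud=cloud,
            bca_cis=cis,
            icer_replicates=reps_icer,
            icer_ci=icer_ci,
            pce=pce,
            decisions=decisions,
            quadrants=quads,
            n_boot=n_boot,
        )


@dataclass
class CostUtilityResults:
    """Fitted cost-utility analysis: estimates, uncertainty and decisions."""

    model: CostUtilityModel
    sur: SurFit
    level: float
    threshold: float
    cloud: np.ndarray = None
    bca_cis: list = None
    icer_replicates: np.ndarray = None
    icer_ci: BcaInterval = None
    pce: dict = None
    decisions: dict = None
    quadrants: dict = None
    n_boot: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def delta_cost(self) -> float:
        return self.sur.delta_cost

    @property
    def delta_qaly(self) -> float:
        return self.sur.delta_qaly

    @property
    def icer(self) -> Icer:
        return compute_icer(self.delta_cost, self.delta_qaly)

    def conf_int(self, which: str, kind: str = "bca"):
        """CI for 'cost' or 'qaly': BCa from the bootstrap, or model-based."""
        if kind == "model" or self.bca_cis is None:
            return self.sur.ci(which, self.level)
        ci = self.bca_cis[{"cost": 0, "qaly": 1}[which]]
        return (ci.lower, ci.upper)

    def row(self) -> dict:
        """Flat record for report tables."""
        out = {
            "delta_cost": self.delta_cost,
            "delta_cost_lo": self.conf_int("cost")[0],
            "delta_cost_hi": self.conf_int("cost")[1],
            "delta_qaly": self.delta_qaly,
            "delta_qaly_lo": self.conf_int("qaly")[0],
            "delta_qaly_hi": self.conf_int("qaly")[1],
            "icer": self.icer.value if self.icer.defined else np.nan,
            "icer_defined": self.icer.defined,
            "quadrant": self.icer.quadrant,
        }
        if self.pce:
            for lam, p in self.pce.items():
                out[f"pce_{int(lam)}"] = p
            for lam, dec in self.decisions.items():
                out[f"decision_{int(lam)}"] = dec
        if self.quadrants:
            for q, p in self.quadrants.items():
                out[f"plane_{q}"] = p
        return out

    def summary(self) -> str:
        lines = []
        add = lines.append
        add("Cost-utility analysis (SUR + stratified BCa bootstrap)")
        add("=" * 58)
        n = self.model.data[self.model.arm_col].value_counts()
        add(f"n control = {int(n.get(0, 0))}, n intervention = {int(n.get(1, 0))}, "
            f"bootstrap B = {self.n_boot}")
        ci_c = self.conf_int("cost")
        ci_q = self.conf_int("qaly")
        pct = f"{self.level * 100:.0f}%"
        add(f"Delta cost : {self.delta_cost:12.2f}  {pct} CI ({ci_c[0]:.2f}, {ci_c[1]:.2f})")
        add(f"Delta QALY : {self.delta_qaly:12.4f}  {pct} CI ({ci_q[0]:.4f}, {ci_q[1]:.4f})")
        icer = self.icer
        if icer.defined:
            txt = f"{icer.value:.0f} per QALY"
            if self.icer_ci is not None:
                txt += f"  BCa CI ({self.icer_ci.lower:.0f}, {self.icer_ci.upper:.0f})"
            add(f"ICER       : {txt}  [{icer.quadrant}]")
        else:
            add(f"ICER       : undefined (|Delta QALY| < {ICER_EPSILON})  [{icer.quadrant}]")
        if self.pce:
            add("-" * 58)
            add("WTP (per QALY)   pCE     cost-effective (pCE >= "
                f"{self.threshold:.2f})")
            for lam in sorted(self.pce):
                add(f"{lam:14.0f}  {self.pce[lam]:.3f}   {self.decisions[lam]}")
        return "\n".join(lines)

    def plot_ce_plane(self, ax=None):
        """Scatter of the bootstrap cloud on the cost-effectiveness plane."""
        import matplotlib.pyplot as plt

        if self.cloud is None:
            raise EstimationError("no bootstrap cloud; fit with n_boot > 0")
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.cloud[:, 1], self.cloud[:, 0], s=4, alpha=0.4)
        ax.axhline(0, color="k", lw=0.8)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("incremental QALYs")
        ax.set_ylabel("incremental costs")
        return ax

    def plot_ceac(self, ax=None, grid=None):
        """CEAC over a fine WTP grid evaluated on the stored cloud."""
        import matplotlib.pyplot as plt

        if self.cloud is None:
            raise EstimationError("no bootstrap cloud; fit with n_boot > 0")
        if grid is None:
            grid = np.linspace(0, 100000, 201)
        vals = [ceac(self.cloud, [lam])[float(lam)] for lam in grid]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(grid, vals)
        ax.axhline(self.threshold, color="r", ls="--", lw=0.8)
        ax.set_ylim(0, 1)
        ax.set_xlabel("willingness to pay (per QALY)")
        ax.set_ylabel("probability cost-effective")
        return ax
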