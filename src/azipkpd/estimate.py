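"""Naive-pooled maximum-likelihood estimation with bootstrap uncertainty.

Fitting proceeds in stages: the two PK submodels are fitted first from the
closed-form solution and frozen; the cascade parameters are then estimated
from the fully coupled ODE model.  Every observation is treated as an
independent Gaussian draw around the typical-trajectory prediction (naive
pooling over animals), with a per-analyte proportional error model by
default — the error variance scales with the prediction, which is how a
sum-of-likelihood objective puts more weight on small values.  Parameters
are optimized in log10 space (they are positive and span orders of
magnitude) by bounded quasi-Newton search with multi-start.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

from . import nca as _nca
from .config import ParamSet
from .model_core import (
    CascadeParams,
    OneCompartmentPK,
    pk_concentration,
    with_updates,
)
from .simulate import SimulationError, simulate_study_arm

__all__ = [
    "BootstrapResult",
    "FitResult",
    "FitSpec",
    "FreeParam",
    "NaivePooledProblem",
    "aic",
    "bootstrap_cv",
    "cascade_fit_spec",
    "fit_stage",
    "neg_log_likelihood",
    "pk_fit_spec",
]

PENALTY = 1e12
#: Residual-SD floor: proportional errors below 0.1% (or additive errors
#: below 1e-3 analyte units) are treated as numerically perfect, which keeps
#: the profiled likelihood smooth on noise-free data.
SIGMA_FLOOR = 1e-3
#: Prediction magnitude floor for the proportional error model.
PRED_FLOOR = 1e-8
#: Rows where both observation and prediction sit at zero carry no
#: information and are dropped.
ZERO_TOL = 1e-12

#: arm -> (compound measured for PK fitting, PK condition label)
_PK_STAGE_ARMS = {
    "pk_azi": {"azi_only": "normal", "lps_azi": "lps_challenged"},
    "pk_lps": {"lps": "normal", "lps_azi": "azi_treated"},
}


@dataclass(frozen=True)
class FreeParam:
    name: str
    init: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.init <= self.upper):
            raise ValueError(
                f"{self.name}: bounds must bracket the initial value "
                f"({self.lower}, {self.init}, {self.upper})"
            )


@dataclass(frozen=True)
class FitSpec:
    """What to fit: stage, free parameters, data subset, error model."""

    stage: Literal["pk_azi", "pk_lps", "pd_cascade"]
    free: tuple[FreeParam, ...]
    arms: tuple[str, ...]
    analytes: tuple[str, ...]
    error_model: str = "proportional"      # or "additive"

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.free)


@dataclass(frozen=True)
class FitResult:
    estimates: dict[str, float]
    objective: float               # -2 log-likelihood at the optimum
    aic: float
    sigmas: dict[str, float]       # profiled residual SD per analyte
    residuals: pd.DataFrame        # arm, analyte, time_h, observed, predicted
    n_obs: int
    spec: FitSpec
    starts: pd.DataFrame           # per-start objective and convergence flag
    success: bool


@dataclass(frozen=True)
class BootstrapResult:
    cv_percent: dict[str, float]
    replicates: pd.DataFrame
    n_requested: int
    n_dropped: int


def aic(objective: float, n_free_params: int) -> float:
    """Akaike information criterion: (-2 log L) + 2 k."""
    if n_free_params < 0:
        raise ValueError("n_free_params must be >= 0")
    return objective + 2.0 * n_free_params


class NaivePooledProblem:
    """Binds a parameter set and study design to the pooled likelihood.

    ``paramset`` provides the frozen context: for PK stages the dosing and
    conversion, for the cascade stage also the previously fitted (frozen)
    PK parameters.
    """

    def __init__(self, paramset: ParamSet, ode_rtol: float = 1e-6,
                 ode_atol: float = 1e-9):
        self.paramset = paramset
        self.ode_rtol = ode_rtol
        self.ode_atol = ode_atol

    # -- predictions --------------------------------------------------------

    def compile(self, spec: FitSpec, obs: pd.DataFrame) -> "_CompiledData":
        """Precompute the data layout so repeated evaluations stay cheap."""
        return _CompiledData(self, spec, obs)

    def _pk_predict(self, spec: FitSpec, values: Mapping[str, float],
                    obs: pd.DataFrame) -> np.ndarray:
        compound = "AZI" if spec.stage == "pk_azi" else "LPS"
        conversion = self.paramset.conversion if compound == "LPS" else None
        pred = np.empty(len(obs))
        for arm_label, sub in obs.groupby("arm", sort=True):
            arm = self.paramset.arm(arm_label)
            dose = next(d for d in arm.doses if d.compound_label == compound)
            base = arm.azi_pk if compound == "AZI" else arm.lps_pk
            pk = OneCompartmentPK(
                ka=values.get("ka", base.ka),
                ke=values.get("ke", base.ke),
                v_over_f=values.get("v_over_f", base.v_over_f),
                compound_label=compound,
                condition_label=base.condition_label,
            )
            t = sub["time_h"].to_numpy() - dose.time
            pred[sub.index.to_numpy()] = pk_concentration(
                pk, dose.amount_per_kg, t, conversion=conversion
            )
        return pred

    def _cascade_predict(self, values: Mapping[str, float],
                         obs: pd.DataFrame) -> np.ndarray:
        cascade = with_updates(self.paramset.cascade, **values)
        pred = np.empty(len(obs))
        for arm_label, sub in obs.groupby("arm", sort=True):
            arm = self.paramset.arm(arm_label)
            times = np.unique(sub["time_h"].to_numpy())
            grid = times if len(times) > 1 else np.append(times, times[-1] + 1.0)
            result = simulate_study_arm(
                arm, cascade, grid=grid,
                conversion=self.paramset.conversion,
                rtol=self.ode_rtol, atol=self.ode_atol,
            )
            lookup = {
                analyte: dict(zip(result.time_h, traj))
                for analyte, traj in result.trajectories.items()
            }
            pred[sub.index.to_numpy()] = [
                lookup[a][t] for a, t in zip(sub["analyte"], sub["time_h"])
            ]
        return pred

    def predictions(self, spec: FitSpec, values: Mapping[str, float],
                    obs: pd.DataFrame) -> np.ndarray:
        if spec.stage in ("pk_azi", "pk_lps"):
            return self._pk_predict(spec, values, obs)
        return self._cascade_predict(values, obs)

    def subset(self, spec: FitSpec, observations: pd.DataFrame) -> pd.DataFrame:
        sub = observations[
            observations["arm"].isin(spec.arms)
            & observations["analyte"].isin(spec.analytes)
        ].reset_index(drop=True)
        if sub.empty:
            raise ValueError(
                f"no observations match stage {spec.stage!r} "
                f"(arms={spec.arms}, analytes={spec.analytes})"
            )
        return sub


class _CompiledData:
    """Precomputed observation layout for one (spec, observations) pair.

    Avoids per-evaluation pandas traversals: rows are grouped by arm with
    integer time/analyte indices, so each objective evaluation is one
    closed-form call or one ODE solve per arm plus array indexing.
    """

    def __init__(self, problem: NaivePooledProblem, spec: FitSpec,
                 observations: pd.DataFrame):
        self.problem = problem
        self.spec = spec
        obs = problem.subset(spec, observations)
        self.obs = obs
        self.y = obs["value"].to_numpy(dtype=float)
        self.analyte_rows = {
            analyte: sub.index.to_numpy()
            for analyte, sub in obs.groupby("analyte", sort=True)
        }
        ps = problem.paramset
        self.arm_plans = []
        for arm_label, sub in obs.groupby("arm", sort=True):
            arm = ps.arm(arm_label)
            rows = sub.index.to_numpy()
            if spec.stage in ("pk_azi", "pk_lps"):
                compound = "AZI" if spec.stage == "pk_azi" else "LPS"
                dose = next(d for d in arm.doses
                            if d.compound_label == compound)
                base = arm.azi_pk if compound == "AZI" else arm.lps_pk
                self.arm_plans.append({
                    "rows": rows,
                    "t": sub["time_h"].to_numpy(dtype=float) - dose.time,
                    "dose": dose.amount_per_kg,
                    "base": base,
                    "compound": compound,
                })
            else:
                times = np.unique(sub["time_h"].to_numpy(dtype=float))
                grid = (times if len(times) > 1
                        else np.append(times, times[-1] + 1.0))
                t_idx = np.searchsorted(times, sub["time_h"].to_numpy())
                self.arm_plans.append({
                    "rows": rows,
                    "arm": arm,
                    "grid": grid,
                    "t_idx": t_idx,
                    "analytes": sub["analyte"].to_numpy(),
                })

    def predict(self, values: Mapping[str, float]) -> np.ndarray:
        pred = np.empty(len(self.y))
        problem, spec = self.problem, self.spec
        if spec.stage in ("pk_azi", "pk_lps"):
            conversion = (problem.paramset.conversion
                          if spec.stage == "pk_lps" else None)
            for plan in self.arm_plans:
                base = plan["base"]
                pk = OneCompartmentPK(
                    ka=values.get("ka", base.ka),
                    ke=values.get("ke", base.ke),
                    v_over_f=values.get("v_over_f", base.v_over_f),
                    compound_label=plan["compound"],
                    condition_label=base.condition_label,
                )
                pred[plan["rows"]] = pk_concentration(
                    pk, plan["dose"], plan["t"], conversion=conversion
                )
            return pred
        cascade = with_updates(problem.paramset.cascade, **values)
        for plan in self.arm_plans:
            result = simulate_study_arm(
                plan["arm"], cascade, grid=plan["grid"],
                conversion=problem.paramset.conversion,
                rtol=problem.ode_rtol, atol=problem.ode_atol,
            )
            for analyte in np.unique(plan["analytes"]):
                sel = plan["analytes"] == analyte
                pred[plan["rows"][sel]] = (
                    result.trajectories[analyte][plan["t_idx"][sel]]
                )
        return pred

    def nll(self, values: Mapping[str, float],
            sigmas: Mapping[str, float] | None = None) -> float:
        try:
            pred = self.predict(values)
        except (SimulationError, ValueError, OverflowError):
            return PENALTY
        if not np.all(np.isfinite(pred)):
            return PENALTY
        total = 0.0
        for analyte, rows in self.analyte_rows.items():
            y, f = self.y[rows], pred[rows]
            keep = ~((np.abs(y) <= ZERO_TOL) & (np.abs(f) <= ZERO_TOL))
            if not keep.any():
                continue
            sigma = None if sigmas is None else sigmas.get(analyte)
            part, _ = _analyte_nll(y[keep], f[keep],
                                   self.spec.error_model, sigma)
            total += part
        return total


def _analyte_nll(y: np.ndarray, f: np.ndarray, model: str,
                 sigma: float | None) -> tuple[float, float]:
    """Gaussian NLL of one analyte; returns (nll, sigma_used).

    With ``sigma=None`` the ML (profiled) sigma is used.  Proportional:
    sd = sigma * |prediction| (floored); additive: sd = sigma.
    """
    n = len(y)
    if model == "proportional":
        scale = np.maximum(np.abs(f), PRED_FLOOR)
        z = (y - f) / scale
        if sigma is None:
            s2 = max(float(np.mean(z**2)), SIGMA_FLOOR**2)
        else:
            s2 = sigma**2
        nll = (
            0.5 * n * math.log(2.0 * math.pi * s2)
            + float(np.sum(np.log(scale)))
            + float(np.sum(z**2)) / (2.0 * s2)
        )
    elif model == "additive":
        r = y - f
        if sigma is None:
            s2 = max(float(np.mean(r**2)), SIGMA_FLOOR**2)
        else:
            s2 = sigma**2
        nll = 0.5 * n * math.log(2.0 * math.pi * s2) + float(np.sum(r**2)) / (2.0 * s2)
    else:
        raise ValueError(f"unknown error model {model!r}")
    return nll, math.sqrt(s2)


def neg_log_likelihood(
    problem: NaivePooledProblem,
    spec: FitSpec,
    values: Mapping[str, float],
    observations: pd.DataFrame,
    sigmas: Mapping[str, float] | None = None,
) -> float:
    """Pooled Gaussian negative log-likelihood over all animals and times.

    ``sigmas`` fixes the per-analyte residual SD; when omitted the ML
    (profiled) value is used.  A failed simulation returns a large penalty
    so the optimizer can continue.
    """
    return problem.compile(spec, observations).nll(values, sigmas)


def fit_stage(
    problem: NaivePooledProblem,
    spec: FitSpec,
    observations: pd.DataFrame,
    n_starts: int = 8,
    seed: int | None = 0,
    maxiter: int = 200,
) -> FitResult:
    """Bounded multi-start ML fit of one stage.

    Start 1 uses the spec's initial values; the remaining starts are drawn
    log-uniformly within the bounds.  The best-objective solution is
    returned.  An empty free-parameter list evaluates the objective at the
    fixed parameters (zero-parameter AIC).
    """
    compiled = problem.compile(spec, observations)
    obs = compiled.obs

    if not spec.free:
        obj = 2.0 * compiled.nll({})
        pred = compiled.predict({})
        sigmas = _profiled_sigmas(spec, obs, pred)
        return FitResult(
            estimates={}, objective=obj, aic=aic(obj, 0), sigmas=sigmas,
            residuals=_residual_frame(obs, pred), n_obs=len(obs), spec=spec,
            starts=pd.DataFrame({"objective": [obj], "success": [True]}),
            success=True,
        )

    lo = np.log10([p.lower for p in spec.free])
    hi = np.log10([p.upper for p in spec.free])
    x_init = np.log10([p.init for p in spec.free])

    def objective(x: np.ndarray) -> float:
        return compiled.nll(dict(zip(spec.names, 10.0**x)))

    rng = np.random.default_rng(seed)
    starts = [x_init]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(lo, hi))

    rows, best = [], None
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            # eps well above the ODE integration noise so finite-difference
            # gradients stay meaningful; ftol/gtol tight enough for ~0.1%
            # parameter resolution in log10 space.
            options={"maxiter": maxiter, "maxfun": 8 * maxiter,
                     "ftol": 1e-10, "gtol": 1e-8, "eps": 1e-5},
        )
        rows.append({"objective": 2.0 * res.fun, "success": bool(res.success),
                     "nit": res.nit})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= PENALTY:
        raise RuntimeError(
            f"all {len(starts)} starts failed for stage {spec.stage}: "
            f"{pd.DataFrame(rows).to_string()}"
        )

    estimates = dict(zip(spec.names, 10.0**best.x))
    pred = compiled.predict(estimates)
    sigmas = _profiled_sigmas(spec, obs, pred)
    obj = 2.0 * best.fun
    return FitResult(
        estimates=estimates,
        objective=obj,
        aic=aic(obj, len(spec.free)),
        sigmas=sigmas,
        residuals=_residual_frame(obs, pred),
        n_obs=len(obs),
        spec=spec,
        starts=pd.DataFrame(rows),
        success=any(r["success"] for r in rows),
    )


def _profiled_sigmas(spec: FitSpec, obs: pd.DataFrame,
                     pred: np.ndarray) -> dict[str, float]:
    sigmas = {}
    for analyte, sub in obs.groupby("analyte", sort=True):
        idx = sub.index.to_numpy()
        y, f = sub["value"].to_numpy(dtype=float), pred[idx]
        keep = ~((np.abs(y) <= ZERO_TOL) & (np.abs(f) <= ZERO_TOL))
        if keep.any():
            _, s = _analyte_nll(y[keep], f[keep], spec.error_model, None)
            sigmas[analyte] = s
    return sigmas


def _residual_frame(obs: pd.DataFrame, pred: np.ndarray) -> pd.DataFrame:
    out = obs[["arm", "analyte", "time_h", "subject", "value"]].copy()
    out = out.rename(columns={"value": "observed"})
    out["predicted"] = pred
    out["residual"] = out["observed"] - out["predicted"]
    return out


def bootstrap_cv(
    problem: NaivePooledProblem,
    spec: FitSpec,
    observations: pd.DataFrame,
    n_boot: int = 200,
    seed: int | None = 0,
    estimates: Mapping[str, float] | None = None,
    maxiter: int = 60,
) -> BootstrapResult:
    """Case-resampling bootstrap CV% of the stage's parameter estimates.

    Animals are resampled with replacement within each (arm, analyte, time)
    cell — the destructive-sampling analogue of resampling subjects — and the
    stage is refitted per replicate, warm-started from the point estimates.
    CV% = 100 * sd / mean over converged replicates; non-finite replicates
    are dropped and counted.
    """
    if n_boot < 2:
        raise ValueError("bootstrap needs n_boot >= 2")
    if n_boot < 50:
        warnings.warn(
            f"n_boot={n_boot} is below the reporting minimum of 50",
            UserWarning, stacklevel=2,
        )
    obs = problem.subset(spec, observations)
    cell_sizes = obs.groupby(["arm", "analyte", "time_h"])["subject"].nunique()
    if (cell_sizes < 2).any():
        raise ValueError("every (arm, analyte, time) cell needs >= 2 subjects")

    if estimates is None:
        estimates = fit_stage(problem, spec, obs, n_starts=1, seed=seed).estimates
    warm = tuple(
        FreeParam(p.name,
                  float(np.clip(estimates[p.name], p.lower, p.upper)),
                  p.lower, p.upper)
        for p in spec.free
    )
    warm_spec = FitSpec(spec.stage, warm, spec.arms, spec.analytes,
                        spec.error_model)

    rng = np.random.default_rng(seed)
    groups = [sub for _, sub in obs.groupby(["arm", "analyte", "time_h"],
                                            sort=True)]
    rows, dropped = [], 0
    for b in range(n_boot):
        resampled = [
            sub.iloc[rng.integers(0, len(sub), size=len(sub))]
            for sub in groups
        ]
        boot = pd.concat(resampled, ignore_index=True)
        try:
            fit = fit_stage(problem, warm_spec, boot, n_starts=1, seed=None,
                            maxiter=maxiter)
        except RuntimeError:
            dropped += 1
            continue
        if not all(np.isfinite(v) for v in fit.estimates.values()):
            dropped += 1
            continue
        rows.append({"replicate": b, **fit.estimates})
    if dropped > 0.2 * n_boot:
        warnings.warn(
            f"{dropped}/{n_boot} bootstrap replicates dropped",
            UserWarning, stacklevel=2,
        )
    reps = pd.DataFrame(rows)
    cv = {}
    for name in spec.names:
        vals = reps[name].to_numpy() if name in reps else np.array([])
        if len(vals) >= 2 and np.mean(vals) != 0:
            cv[name] = float(100.0 * np.std(vals, ddof=1) / abs(np.mean(vals)))
        else:
            cv[name] = float("nan")
    return BootstrapResult(
        cv_percent=cv, replicates=reps, n_requested=n_boot, n_dropped=dropped
    )


# ---------------------------------------------------------------------------
# Spec builders
# ---------------------------------------------------------------------------

def _ka_from_tmax(tmax: float, ke: float) -> float:
    """Invert tmax = ln(ka/ke)/(ka - ke) for ka > ke."""
    def f(ka):
        return math.log(ka / ke) / (ka - ke) - tmax
    lo, hi = ke * 1.001, 1e3
    try:
        return brentq(f, lo, hi)
    except ValueError:
        return 10.0 * ke      # fall back to a fast-absorption guess


def pk_fit_spec(
    stage: Literal["pk_azi", "pk_lps"],
    arm_label: str,
    paramset: ParamSet,
    observations: pd.DataFrame | None = None,
    bound_factor: float = 10.0,
) -> FitSpec:
    """Build a PK-stage spec with NCA-derived initial values.

    When observations are supplied, the mean concentration profile of the
    arm is summarized by NCA: the terminal slope seeds ke, the AUC seeds
    V/F, and Tmax seeds ka.  Without observations the paramset's values
    seed the fit.  Bounds span ``bound_factor`` either side of the inits.
    """
    compound = "AZI" if stage == "pk_azi" else "LPS"
    if arm_label not in _PK_STAGE_ARMS[stage]:
        raise ValueError(
            f"stage {stage} cannot be fitted from arm {arm_label!r}; "
            f"choose one of {tuple(_PK_STAGE_ARMS[stage])}"
        )
    arm = paramset.arm(arm_label)
    base = arm.azi_pk if compound == "AZI" else arm.lps_pk
    inits = {"ka": base.ka, "ke": base.ke, "v_over_f": base.v_over_f}

    if observations is not None:
        sub = observations[
            (observations["arm"] == arm_label)
            & (observations["analyte"] == compound)
        ]
        if len(sub):
            dose = next(d for d in arm.doses if d.compound_label == compound)
            prof = (
                sub.groupby("time_h")["value"].mean().reset_index()
            )
            prof = prof[prof["value"] > 0]
            if len(prof) >= 5:
                try:
                    res = _nca.run_nca(
                        prof["time_h"].to_numpy() - dose.time,
                        prof["value"].to_numpy(),
                    )
                    ke0 = res.lambda_z
                    ka0 = _ka_from_tmax(max(res.tmax, 1e-3), ke0)
                    # For LPS the AUC is in Eu h/ml; fold the conversion back.
                    dose_units = dose.amount_per_kg
                    if compound == "LPS":
                        dose_units = float(
                            paramset.conversion.eu_per_ml_from_mg_per_l(
                                dose.amount_per_kg
                            )
                        )
                    v0 = dose_units / (res.auc_0_inf * ke0)
                    if ka0 > ke0 > 0 and v0 > 0:
                        inits = {"ka": ka0, "ke": ke0, "v_over_f": v0}
                except ValueError:
                    pass
    free = tuple(
        FreeParam(name, init, init / bound_factor, init * bound_factor)
        for name, init in inits.items()
    )
    return FitSpec(stage=stage, free=free, arms=(arm_label,),
                   analytes=(compound,))


def cascade_fit_spec(
    names: Sequence[str],
    start: CascadeParams,
    arms: Sequence[str] = ("lps", "lps_azi"),
    analytes: Sequence[str] = ("PCs", "KYN"),
    bound_factor: float = 10.0,
) -> FitSpec:
    """Build a cascade-stage spec from starting values in ``start``.

    The inhibition capacity Imax is capped at 1 by construction.
    """
    from .model_core import flat_value

    free = []
    for name in names:
        init = flat_value(start, name)
        if init <= 0:
            raise ValueError(f"cannot free {name!r}: starting value {init} <= 0")
        upper = init * bound_factor
        if name == "imax":
            upper = min(upper, 1.0)
        free.append(FreeParam(name, init, init / bound_factor, upper))
    return FitSpec(stage="pd_cascade", free=tuple(free), arms=tuple(arms),
                   analytes=tuple(analytes))
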