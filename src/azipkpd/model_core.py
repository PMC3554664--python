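"""Core types and equations of the endotoxin–cytokine–kynurenine–behavior cascade.

The model couples two one-compartment, first-order-absorption pharmacokinetic
(PK) submodels — azithromycin (AZI, intragastric) and lipopolysaccharide
(LPS, intraperitoneal) — to a chain of indirect-response (turnover) models
with one transit compartment per transduction step:

    LPS plasma concentration --(sigmoid stimulation, Smax/SC50)--> PCs
    AZI plasma concentration --(sigmoid inhibition,  Imax/IC50)--> PCs
    PCs deviation from baseline --(linear slope)--> KYN
    KYN deviation from baseline --(linear slope)--> FST and TST immobility

Each turnover variable R obeys zero-order production kin = kout * R0 modified
by its driver, routed through a single transit compartment T:

    dT/dt = kin * driver(t) - ktr * T
    dR/dt = ktr * T - kout * R

so the unperturbed system sits exactly at its baseline.  Analyte units are
fixed: AZI ug/ml, LPS Eu/ml, total proinflammatory cytokines (PCs) pg/ml,
kynurenine (KYN) ng/ml, forced-swimming and tail-suspension immobility
(FST, TST) seconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np

__all__ = [
    "ANALYTES",
    "STATE_NAMES",
    "AZI_DOSE_MG_PER_KG",
    "AZI_PREDOSE_TIME_H",
    "LPS_DOSE_MG_PER_KG",
    "CascadeParams",
    "DegenerateKineticsError",
    "DoseEvent",
    "FlipFlopWarning",
    "LPSUnitConversion",
    "LinearDriver",
    "OneCompartmentPK",
    "SigmoidDriver",
    "StudyArm",
    "TurnoverState",
    "baseline_state",
    "cascade_rhs",
    "inhibition_factor",
    "linear_factor",
    "pk_concentration",
    "pk_tmax_thalf",
    "production_modifier",
    "stimulation_factor",
]

ANALYTES = ("AZI", "LPS", "PCs", "KYN", "FST", "TST")

#: Ordered state vector of the coupled ODE system.  Amount states are mg/kg;
#: turnover states carry their analyte's concentration/score units.
STATE_NAMES = (
    "azi_absorption",
    "azi_central",
    "lps_absorption",
    "lps_central",
    "pc_transit",
    "pc",
    "kyn_transit",
    "kyn",
    "fst_transit",
    "fst",
    "tst_transit",
    "tst",
)

IDX = {name: i for i, name in enumerate(STATE_NAMES)}

# Study dosing conventions: LPS 0.8 mg/kg i.p. at t = 0; AZI 100 mg/kg i.g.
# 20 min before the LPS challenge.
LPS_DOSE_MG_PER_KG = 0.8
AZI_DOSE_MG_PER_KG = 100.0
AZI_PREDOSE_TIME_H = -1.0 / 3.0


class DegenerateKineticsError(ValueError):
    """Absorption and elimination rate constants coincide (ka == ke)."""


class FlipFlopWarning(UserWarning):
    """ka <= ke: the terminal phase reflects absorption, not elimination."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0 and math.isfinite(value)):
            raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class OneCompartmentPK:
    """First-order absorption / first-order elimination PK parameter triple.

    Parameters
    ----------
    ka : float
        Absorption rate constant (1/h).
    ke : float
        Elimination rate constant (1/h).
    v_over_f : float
        Apparent distribution volume per kg body weight (L/kg).
    compound_label, condition_label : str
        Identifiers, e.g. ``("AZI", "normal")`` or ``("LPS", "azi_treated")``.
    """

    ka: float
    ke: float
    v_over_f: float
    compound_label: str = ""
    condition_label: str = ""

    def __post_init__(self) -> None:
        _require_positive(ka=self.ka, ke=self.ke, v_over_f=self.v_over_f)
        if math.isclose(self.ka, self.ke, rel_tol=1e-9):
            raise DegenerateKineticsError(
                f"ka == ke == {self.ka}: the biexponential closed form is "
                "degenerate; keep the rate constants apart"
            )


@dataclass(frozen=True)
class LPSUnitConversion:
    """Endotoxin mass-to-activity conversion: 1 ng LPS ~ 3.4 endotoxin units."""

    eu_per_ng: float = 3.4

    def __post_init__(self) -> None:
        _require_positive(eu_per_ng=self.eu_per_ng)

    def eu_per_ml_from_mg_per_l(self, c_mg_per_l):
        """Convert a concentration in mg/L (== ug/ml == 1000 ng/ml) to Eu/ml."""
        return np.asarray(c_mg_per_l) * 1000.0 * self.eu_per_ng


@dataclass(frozen=True)
class TurnoverState:
    """Baseline/turnover description of one indirect-response variable.

    ``kin = kout * baseline`` (zero-order production) is implied so that the
    unperturbed variable is stationary; ``ktr`` is the transit rate of the
    single production-side transfer compartment.
    """

    baseline: float
    kout: float
    ktr: float
    analyte_label: str = ""

    def __post_init__(self) -> None:
        _require_positive(baseline=self.baseline, kout=self.kout, ktr=self.ktr)

    @property
    def kin(self) -> float:
        """Zero-order production rate balancing the baseline (units/h)."""
        return self.kout * self.baseline


@dataclass(frozen=True)
class SigmoidDriver:
    """Hill-1 capacity model: stimulation Smax/SC50 or inhibition Imax/IC50."""

    emax_like: float
    c50: float
    direction: Literal["stimulation", "inhibition"] = "stimulation"

    def __post_init__(self) -> None:
        _require_positive(emax_like=self.emax_like, c50=self.c50)
        if self.direction not in ("stimulation", "inhibition"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "inhibition" and self.emax_like > 1.0:
            raise ValueError(
                f"inhibition capacity Imax must be <= 1, got {self.emax_like}"
            )


@dataclass(frozen=True)
class LinearDriver:
    """Linear transduction: factor 1 + slope * (upstream - upstream baseline)."""

    slope: float

    def __post_init__(self) -> None:
        if not (self.slope >= 0 and math.isfinite(self.slope)):
            raise ValueError(f"slope must be finite and >= 0, got {self.slope!r}")


@dataclass(frozen=True)
class CascadeParams:
    """Complete pharmacodynamic parameter set of the four-variable cascade."""

    pc: TurnoverState
    kyn: TurnoverState
    fst: TurnoverState
    tst: TurnoverState
    lps_stim: SigmoidDriver
    azi_inhib: SigmoidDriver
    pc_to_kyn: LinearDriver
    kyn_to_fst: LinearDriver
    kyn_to_tst: LinearDriver
    #: "stimulated_only": AZI scales only the LPS-stimulated production
    #: increment, so an AZI-only arm stays at baseline (matches the observed
    #: indistinguishability of the AZI-only and control groups).
    #: "classical": AZI multiplies total production (kin * S * I).
    inhibition_scope: Literal["stimulated_only", "classical"] = "stimulated_only"

    def __post_init__(self) -> None:
        if self.lps_stim.direction != "stimulation":
            raise ValueError("lps_stim must be a stimulation driver")
        if self.azi_inhib.direction != "inhibition":
            raise ValueError("azi_inhib must be an inhibition driver")
        if self.inhibition_scope not in ("stimulated_only", "classical"):
            raise ValueError(f"unknown inhibition_scope {self.inhibition_scope!r}")


@dataclass(frozen=True)
class DoseEvent:
    """A bolus dose: time (h, relative to the LPS challenge), compound, route."""

    time: float
    compound_label: Literal["AZI", "LPS"]
    amount_per_kg: float
    route: Literal["intraperitoneal", "intragastric"] = "intraperitoneal"

    def __post_init__(self) -> None:
        if self.amount_per_kg < 0:
            raise ValueError("amount_per_kg must be >= 0")
        if self.compound_label not in ("AZI", "LPS"):
            raise ValueError(f"unknown compound {self.compound_label!r}")


@dataclass(frozen=True)
class StudyArm:
    """A treatment arm: its label, bolus doses, and condition-matched PK."""

    label: str
    doses: tuple[DoseEvent, ...]
    azi_pk: OneCompartmentPK | None = None
    lps_pk: OneCompartmentPK | None = None


# ---------------------------------------------------------------------------
# Closed-form pharmacokinetics
# ---------------------------------------------------------------------------

def pk_concentration(
    pk: OneCompartmentPK,
    dose_per_kg: float,
    t,
    bioavail_fraction: float = 1.0,
    conversion: LPSUnitConversion | None = None,
):
    """Closed-form plasma concentration after a single extravascular bolus.

    C(t) = (F * dose / (V/F)) * ka/(ka - ke) * (exp(-ke t) - exp(-ka t)),
    with ``dose_per_kg`` in mg/kg and ``v_over_f`` in L/kg, giving mg/L
    (== ug/ml).  If ``conversion`` is given the result is translated to
    endotoxin units (Eu/ml).  ``t`` is hours since this compound's dose and
    may be an array.

    Raises
    ------
    ValueError
        If any ``t < 0`` or ``dose_per_kg < 0``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 relative to the dose time")
    if dose_per_kg < 0:
        raise ValueError("dose_per_kg must be >= 0")
    scale = bioavail_fraction * dose_per_kg / pk.v_over_f
    c = scale * pk.ka / (pk.ka - pk.ke) * (np.exp(-pk.ke * t) - np.exp(-pk.ka * t))
    if conversion is not None:
        c = conversion.eu_per_ml_from_mg_per_l(c)
    return c if c.ndim else float(c)


def pk_tmax_thalf(pk: OneCompartmentPK) -> tuple[float, float]:
    """Peak time and terminal half-life of the closed-form profile.

    tmax = ln(ka/ke) / (ka - ke); terminal half-life = ln 2 / ke.  If
    ka <= ke the terminal phase is absorption-limited (flip-flop kinetics)
    and a :class:`FlipFlopWarning` is emitted.
    """
    if pk.ka <= pk.ke:
        warnings.warn(
            f"ka={pk.ka} <= ke={pk.ke}: flip-flop kinetics, the terminal "
            "slope reflects absorption",
            FlipFlopWarning,
            stacklevel=2,
        )
    tmax = math.log(pk.ka / pk.ke) / (pk.ka - pk.ke)
    return tmax, math.log(2.0) / pk.ke


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def stimulation_factor(driver: SigmoidDriver, c):
    """Production multiplier 1 + Smax * c / (SC50 + c), in [1, 1 + Smax)."""
    if driver.direction != "stimulation":
        raise ValueError("driver is not a stimulation driver")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("driver concentration must be >= 0")
    out = 1.0 + driver.emax_like * c / (driver.c50 + c)
    return out if out.ndim else float(out)


def inhibition_factor(driver: SigmoidDriver, c):
    """Production multiplier 1 - Imax * c / (IC50 + c), in (1 - Imax, 1]."""
    if driver.direction != "inhibition":
        raise ValueError("driver is not an inhibition driver")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("driver concentration must be >= 0")
    out = 1.0 - driver.emax_like * c / (driver.c50 + c)
    return out if out.ndim else float(out)


def linear_factor(driver: LinearDriver, upstream: float, upstream_baseline: float) -> float:
    """Linear transduction factor 1 + slope * (upstream - baseline), floored at 0.

    Anchored at the upstream baseline so the factor is exactly 1 in the
    unperturbed system; the floor keeps production non-negative for deep
    (unphysiological) undershoots.
    """
    return max(0.0, 1.0 + driver.slope * (upstream - upstream_baseline))


def production_modifier(
    params: CascadeParams, c_lps: float, c_azi: float
) -> float:
    """Combined LPS-stimulation / AZI-inhibition multiplier on PCs production.

    stimulated_only (default):  1 + (S(C_LPS) - 1) * I(C_AZI)
    classical:                  S(C_LPS) * I(C_AZI)

    The default leaves production untouched when no LPS is present, whatever
    the AZI concentration.
    """
    s = stimulation_factor(params.lps_stim, c_lps)
    i = inhibition_factor(params.azi_inhib, c_azi)
    if params.inhibition_scope == "stimulated_only":
        return 1.0 + (s - 1.0) * i
    return s * i


# ---------------------------------------------------------------------------
# Coupled system
# ---------------------------------------------------------------------------

def baseline_state(params: CascadeParams) -> np.ndarray:
    """Steady-state vector with no drug on board.

    Transit compartments sit at kin/ktr, responses at their baselines, PK
    amounts at zero.
    """
    y = np.zeros(len(STATE_NAMES))
    for name, tv in (("pc", params.pc), ("kyn", params.kyn),
                     ("fst", params.fst), ("tst", params.tst)):
        y[IDX[f"{name}_transit"]] = tv.kin / tv.ktr
        y[IDX[name]] = tv.baseline
    return y


def cascade_rhs(
    t: float,
    y: np.ndarray,
    params: CascadeParams,
    pks: Mapping[str, OneCompartmentPK | None],
    conversion: LPSUnitConversion = LPSUnitConversion(),
) -> np.ndarray:
    """Right-hand side of the 12-state coupled PK-PD ODE system.

    ``pks`` maps compound labels ("AZI", "LPS") to their condition-matched PK
    parameter sets; a missing/None entry means that compound is absent from
    the arm and its concentration is held at zero.  Dose boluses are applied
    by the integrator (state re-initialization), not here.

    States are clipped at zero only when evaluating drivers; the state vector
    itself is never altered.
    """
    azi_pk = pks.get("AZI")
    lps_pk = pks.get("LPS")
    dy = np.empty_like(y)

    # PK subsystem: amounts (mg/kg) in absorption and central compartments.
    if azi_pk is not None:
        dy[0] = -azi_pk.ka * y[0]
        dy[1] = azi_pk.ka * y[0] - azi_pk.ke * y[1]
        c_azi = max(y[1], 0.0) / azi_pk.v_over_f
    else:
        dy[0] = dy[1] = 0.0
        c_azi = 0.0
    if lps_pk is not None:
        dy[2] = -lps_pk.ka * y[2]
        dy[3] = lps_pk.ka * y[2] - lps_pk.ke * y[3]
        c_lps = float(
            conversion.eu_per_ml_from_mg_per_l(max(y[3], 0.0) / lps_pk.v_over_f)
        )
    else:
        dy[2] = dy[3] = 0.0
        c_lps = 0.0

    # PCs: sigmoid stimulation by LPS, sigmoid inhibition by AZI.
    m_pc = production_modifier(params, c_lps, c_azi)
    dy[4] = params.pc.kin * m_pc - params.pc.ktr * y[4]
    dy[5] = params.pc.ktr * y[4] - params.pc.kout * y[5]

    # KYN: linear stimulation by the PCs excursion above baseline.
    f_kyn = linear_factor(params.pc_to_kyn, max(y[5], 0.0), params.pc.baseline)
    dy[6] = params.kyn.kin * f_kyn - params.kyn.ktr * y[6]
    dy[7] = params.kyn.ktr * y[6] - params.kyn.kout * y[7]

    # Behavioral endpoints: linear stimulation by the KYN excursion.
    kyn_level = max(y[7], 0.0)
    f_fst = linear_factor(params.kyn_to_fst, kyn_level, params.kyn.baseline)
    dy[8] = params.fst.kin * f_fst - params.fst.ktr * y[8]
    dy[9] = params.fst.ktr * y[8] - params.fst.kout * y[9]
    f_tst = linear_factor(params.kyn_to_tst, kyn_level, params.kyn.baseline)
    dy[10] = params.tst.kin * f_tst - params.tst.ktr * y[10]
    dy[11] = params.tst.ktr * y[10] - params.tst.kout * y[11]
    return dy


def with_updates(params: CascadeParams, **flat: float) -> CascadeParams:
    """Return a copy of ``params`` with flat-named fields replaced.

    Recognized names: smax, sc50, imax, ic50; {baseline,kout,ktr}_{pc,kyn,
    fst,tst}; slope_pc_kyn, slope_kyn_fst, slope_kyn_tst.
    """
    p = params
    turnover = {"pc": p.pc, "kyn": p.kyn, "fst": p.fst, "tst": p.tst}
    stim, inhib = p.lps_stim, p.azi_inhib
    slopes = {
        "slope_pc_kyn": p.pc_to_kyn,
        "slope_kyn_fst": p.kyn_to_fst,
        "slope_kyn_tst": p.kyn_to_tst,
    }
    for name, value in flat.items():
        if name == "smax":
            stim = replace(stim, emax_like=value)
        elif name == "sc50":
            stim = replace(stim, c50=value)
        elif name == "imax":
            inhib = replace(inhib, emax_like=value)
        elif name == "ic50":
            inhib = replace(inhib, c50=value)
        elif name in slopes:
            slopes[name] = LinearDriver(slope=value)
        else:
            try:
                attr, key = name.split("_", 1)
                turnover[key] = replace(turnover[key], **{attr: value})
            except (ValueError, KeyError, TypeError):
                raise KeyError(f"unknown cascade parameter name {name!r}") from None
    return replace(
        p,
        pc=turnover["pc"],
        kyn=turnover["kyn"],
        fst=turnover["fst"],
        tst=turnover["tst"],
        lps_stim=stim,
        azi_inhib=inhib,
        pc_to_kyn=slopes["slope_pc_kyn"],
        kyn_to_fst=slopes["slope_kyn_fst"],
        kyn_to_tst=slopes["slope_kyn_tst"],
    )


def flat_value(params: CascadeParams, name: str) -> float:
    """Read a flat-named cascade parameter (inverse of :func:`with_updates`)."""
    p = params
    simple = {
        "smax": p.lps_stim.emax_like,
        "sc50": p.lps_stim.c50,
        "imax": p.azi_inhib.emax_like,
        "ic50": p.azi_inhib.c50,
        "slope_pc_kyn": p.pc_to_kyn.slope,
        "slope_kyn_fst": p.kyn_to_fst.slope,
        "slope_kyn_tst": p.kyn_to_tst.slope,
    }
    if name in simple:
        return simple[name]
    attr, _, key = name.partition("_")
    turnover = {"pc": p.pc, "kyn": p.kyn, "fst": p.fst, "tst": p.tst}
    if key in turnover and attr in ("baseline", "kout", "ktr"):
        return getattr(turnover[key], attr)
    raise KeyError(f"unknown cascade parameter name {name!r}")
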