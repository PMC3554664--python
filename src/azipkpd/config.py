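"""Parameter-file loading and study-arm construction.

Parameter files are nested YAML mirroring the published tables: PK triples
per compound and condition, the endotoxin unit conversion, and the cascade
turnover/driver parameters.  :func:`default_params` loads the packaged
fixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .model_core import (
    AZI_DOSE_MG_PER_KG,
    AZI_PREDOSE_TIME_H,
    LPS_DOSE_MG_PER_KG,
    CascadeParams,
    DoseEvent,
    LPSUnitConversion,
    LinearDriver,
    OneCompartmentPK,
    SigmoidDriver,
    StudyArm,
    TurnoverState,
)

ARM_LABELS = ("control", "lps", "lps_azi", "azi_only")


@dataclass(frozen=True)
class ParamSet:
    """Everything needed to simulate any study arm."""

    azi_pk: Mapping[str, OneCompartmentPK]   # conditions: normal, lps_challenged
    lps_pk: Mapping[str, OneCompartmentPK]   # conditions: normal, azi_treated
    conversion: LPSUnitConversion
    cascade: CascadeParams

    def arm(self, label: str) -> StudyArm:
        """Build a standard arm with condition-matched PK and default doses.

        The AZI pre-dose (100 mg/kg i.g.) precedes the LPS challenge
        (0.8 mg/kg i.p. at t = 0) by 20 minutes.  The combination arm uses
        the LPS-challenged AZI kinetics and the AZI-treated LPS kinetics.
        """
        lps_dose = DoseEvent(0.0, "LPS", LPS_DOSE_MG_PER_KG, "intraperitoneal")
        azi_dose = DoseEvent(
            AZI_PREDOSE_TIME_H, "AZI", AZI_DOSE_MG_PER_KG, "intragastric"
        )
        if label == "control":
            return StudyArm(label, ())
        if label == "lps":
            return StudyArm(label, (lps_dose,), lps_pk=self.lps_pk["normal"])
        if label == "lps_azi":
            return StudyArm(
                label,
                (azi_dose, lps_dose),
                azi_pk=self.azi_pk["lps_challenged"],
                lps_pk=self.lps_pk["azi_treated"],
            )
        if label == "azi_only":
            return StudyArm(label, (azi_dose,), azi_pk=self.azi_pk["normal"])
        raise ValueError(f"unknown arm label {label!r}; expected one of {ARM_LABELS}")


def _pk_block(block: Mapping, compound: str) -> dict[str, OneCompartmentPK]:
    return {
        condition: OneCompartmentPK(
            ka=float(v["ka"]),
            ke=float(v["ke"]),
            v_over_f=float(v["v_over_f"]),
            compound_label=compound,
            condition_label=condition,
        )
        for condition, v in block.items()
    }


def _turnover(block: Mapping, label: str) -> TurnoverState:
    return TurnoverState(
        baseline=float(block["baseline"]),
        kout=float(block["kout"]),
        ktr=float(block.get("ktr", block["kout"])),
        analyte_label=label,
    )


def params_from_dict(raw: Mapping) -> ParamSet:
    """Build a :class:`ParamSet` from the nested-mapping file layout."""
    c = raw["cascade"]
    cascade = CascadeParams(
        pc=_turnover(c["pc"], "PCs"),
        kyn=_turnover(c["kyn"], "KYN"),
        fst=_turnover(c["fst"], "FST"),
        tst=_turnover(c["tst"], "TST"),
        lps_stim=SigmoidDriver(
            float(c["lps_stim"]["emax_like"]),
            float(c["lps_stim"]["c50"]),
            "stimulation",
        ),
        azi_inhib=SigmoidDriver(
            float(c["azi_inhib"]["emax_like"]),
            float(c["azi_inhib"]["c50"]),
            "inhibition",
        ),
        pc_to_kyn=LinearDriver(float(c["pc_to_kyn"]["slope"])),
        kyn_to_fst=LinearDriver(float(c["kyn_to_fst"]["slope"])),
        kyn_to_tst=LinearDriver(float(c["kyn_to_tst"]["slope"])),
        inhibition_scope=c.get("inhibition_scope", "stimulated_only"),
    )
    return ParamSet(
        azi_pk=_pk_block(raw["azi_pk"], "AZI"),
        lps_pk=_pk_block(raw["lps_pk"], "LPS"),
        conversion=LPSUnitConversion(float(raw["lps_unit"]["eu_per_ng"])),
        cascade=cascade,
    )


def params_to_dict(ps: ParamSet) -> dict:
    """Inverse of :func:`params_from_dict` (for saving calibrated sets)."""
    def pk_map(block):
        return {
            cond: {"ka": pk.ka, "ke": pk.ke, "v_over_f": pk.v_over_f}
            for cond, pk in block.items()
        }

    def tv(t: TurnoverState):
        return {"baseline": t.baseline, "kout": t.kout, "ktr": t.ktr}

    c = ps.cascade
    return {
        "azi_pk": pk_map(ps.azi_pk),
        "lps_pk": pk_map(ps.lps_pk),
        "lps_unit": {"eu_per_ng": ps.conversion.eu_per_ng},
        "cascade": {
            "pc": tv(c.pc),
            "kyn": tv(c.kyn),
            "fst": tv(c.fst),
            "tst": tv(c.tst),
            "lps_stim": {"emax_like": c.lps_stim.emax_like, "c50": c.lps_stim.c50},
            "azi_inhib": {"emax_like": c.azi_inhib.emax_like, "c50": c.azi_inhib.c50},
            "pc_to_kyn": {"slope": c.pc_to_kyn.slope},
            "kyn_to_fst": {"slope": c.kyn_to_fst.slope},
            "kyn_to_tst": {"slope": c.kyn_to_tst.slope},
            "inhibition_scope": c.inhibition_scope,
        },
    }


def load_params(path: str | Path) -> ParamSet:
    """Load a parameter file (YAML) from disk."""
    with open(path, "r", encoding="utf-8") as fh:
        return params_from_dict(yaml.safe_load(fh))


def save_params(ps: ParamSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params_to_dict(ps), fh, sort_keys=False)


def default_params() -> ParamSet:
    """The packaged published parameter tables (slopes uncalibrated)."""
    text = resources.files("azipkpd.data").joinpath("tables.yaml").read_text()
    return params_from_dict(yaml.safe_load(text))
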