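"""Body-composition estimating equations and derived muscle indices.

Implements the published prediction equations that turn raw CT, BIA, US and
anthropometric measurements into whole-body muscle mass (MM), fat-free mass
(FFM), skeletal-muscle indices and an estimated L3 skeletal muscle area:

* CT: Shen MM and Mourtzakis FFM (linear in L3-SMA), SMI-CT, SMG.
* BIA: Janssen MM (height²/resistance), Kanellakis FFM, Kotler FFM.
* US: Fischer (USVALID) L3-SMA and a refitted variant of the same model.

Unit conventions: records store height in metres and muscle thicknesses in
millimetres.  Each equation adapter performs its own declared conversion
(Janssen, Kotler, Fischer and the refit model take height in cm; Fischer-type
models take quadriceps thickness in cm), so conversions are testable in
isolation.  Sex is coded female = 0, male = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DomainError, SingularFitError
from .records import DerivedBiomarkers, SubjectRecord

__all__ = [
    "bmi",
    "smi",
    "smg",
    "shen_mm",
    "mourtzakis_ffm",
    "janssen_mm",
    "kanellakis_ffm",
    "kotler_ffm",
    "fischer_sma",
    "newmodel_sma",
    "fit_sma_regression",
    "derive_all",
    "RegressionFit",
    "equation_registry",
]

#: Coefficients of the refitted US→L3-SMA model (predictors: quadriceps
#: thickness in cm, weight kg, height cm, sex code).
NEWMODEL_COEF = {
    "intercept": -74.04,
    "quad_mt_cm": 12.03,
    "weight": 0.56,
    "height_cm": 0.70,
    "sex": 18.86,
}

#: Coefficients of the original USVALID (Fischer) equation, same predictors.
FISCHER_COEF = {
    "intercept": -54.0,
    "quad_mt_cm": 15.0,
    "weight": 0.4,
    "height_cm": 0.6,
    "sex": 21.0,
}


def bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m² (weight kg, height m)."""
    if weight <= 0 or height <= 0:
        raise DomainError("bmi requires weight > 0 and height > 0")
    return weight / height**2


def smi(area_or_mass: float, height: float) -> float:
    """Height-squared index: value / height² (height in m).

    Produces SMI-CT (cm²/m²) from L3-SMA, or mass indices (kg/m²) from
    whole-body MM estimates.
    """
    if height <= 0:
        raise DomainError("smi requires height > 0")
    return area_or_mass / height**2


def smg(smi_ct: float, smd: float) -> float:
    """Skeletal muscle gauge (AU): SMI-CT × SMD, a quantity-quality product."""
    if not (math.isfinite(smi_ct) and math.isfinite(smd)):
        raise DomainError("smg requires finite inputs")
    return smi_ct * smd


def shen_mm(l3_sma: float) -> float:
    """Shen whole-body muscle mass (kg) from L3-SMA (cm²)."""
    if l3_sma < 0:
        raise DomainError("shen_mm requires l3_sma >= 0")
    return (0.166 * l3_sma + 2.142) * 1.06


def mourtzakis_ffm(l3_sma: float) -> float:
    """Mourtzakis fat-free mass (kg) from L3-SMA (cm²)."""
    if l3_sma < 0:
        raise DomainError("mourtzakis_ffm requires l3_sma >= 0")
    return 0.30 * l3_sma + 6.06


def janssen_mm(height_cm: float, resistance: float, sex: int, age: float) -> float:
    """Janssen BIA muscle mass (kg).

    height in cm, resistance R_z in Ω at 50 kHz.  Increasing in height and the
    male sex code, decreasing in resistance and age.
    """
    if resistance <= 0:
        raise DomainError("janssen_mm requires resistance > 0")
    if height_cm <= 0:
        raise DomainError("janssen_mm requires height > 0")
    return 5.102 + 0.401 * (height_cm**2 / resistance) + 3.825 * sex - 0.071 * age


def kanellakis_ffm(
    weight: float, sex: int, rz: float, xc: float, height_m: float
) -> float:
    """Kanellakis BIA fat-free mass (kg); height in **metres** throughout."""
    if height_m <= 0 or rz <= 0:
        raise DomainError("kanellakis_ffm requires height > 0 and rz > 0")
    if xc < 0:
        raise DomainError("kanellakis_ffm requires xc >= 0")
    return (
        12.299
        + 0.164 * weight
        + 7.287 * sex
        - 0.116 * (rz / height_m)
        + 0.365 * (xc / height_m**2)
        + 21.570 * height_m
    )


def kotler_ffm(height_cm: float, impedance: float, weight: float) -> float:
    """Kotler BIA fat-free mass (kg); height in **centimetres**."""
    if impedance <= 0 or height_cm <= 0:
        raise DomainError("kotler_ffm requires impedance > 0 and height > 0")
    return 0.88 * (height_cm**2.24 / impedance**0.63) * (1.0 / 37.63) + 0.16 * weight - 3.96


def _fischer_family(coef: dict, sex: int, weight: float, height_cm: float, quad_mt_cm: float) -> float:
    return (
        coef["intercept"]
        + coef["sex"] * sex
        + coef["weight"] * weight
        + coef["height_cm"] * height_cm
        + coef["quad_mt_cm"] * quad_mt_cm
    )


def fischer_sma(sex: int, weight: float, height_cm: float, quad_mt_cm: float) -> float:
    """USVALID (Fischer) estimated L3-SMA (cm²); height and Quad-MT in cm."""
    return _fischer_family(FISCHER_COEF, sex, weight, height_cm, quad_mt_cm)


def newmodel_sma(sex: int, weight: float, height_cm: float, quad_mt_cm: float) -> float:
    """Refitted US→L3-SMA model (cm²), same predictors as the Fischer equation."""
    return _fischer_family(NEWMODEL_COEF, sex, weight, height_cm, quad_mt_cm)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of L3-SMA on (Quad-MT cm, weight kg, height cm, sex code)."""

    intercept: float
    coef_quad_mt: float
    coef_weight: float
    coef_height: float
    coef_sex: float
    adjusted_r2: float
    n: int

    def predict(self, sex: int, weight: float, height_cm: float, quad_mt_cm: float) -> float:
        return (
            self.intercept
            + self.coef_quad_mt * quad_mt_cm
            + self.coef_weight * weight
            + self.coef_height * height_cm
            + self.coef_sex * sex
        )


def fit_sma_regression(records: Sequence[SubjectRecord]) -> RegressionFit:
    """Refit the US→L3-SMA regression on a cohort by ordinary least squares.

    Uses complete records only (l3_sma, quad_mt, weight, height, sex all
    present).  Requires at least 6 complete records and a full-rank design.
    """
    rows = [
        (r.l3_sma, r.quad_mt / 10.0, r.weight, r.height * 100.0, float(r.sex))
        for r in records
        if r.l3_sma is not None and r.quad_mt is not None
    ]
    if len(rows) < 6:
        raise SingularFitError(
            f"fit_sma_regression needs >= 6 complete records, got {len(rows)}"
        )
    arr = np.asarray(rows, dtype=float)
    y = arr[:, 0]
    X = sm.add_constant(arr[:, 1:], has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError("design matrix is rank deficient (collinear predictors)")
    res = sm.OLS(y, X).fit()
    b = res.params
    return RegressionFit(
        intercept=float(b[0]),
        coef_quad_mt=float(b[1]),
        coef_weight=float(b[2]),
        coef_height=float(b[3]),
        coef_sex=float(b[4]),
        adjusted_r2=float(res.rsquared_adj),
        n=int(res.nobs),
    )


def derive_all(record: SubjectRecord) -> DerivedBiomarkers:
    """Evaluate every derivable equation for one subject.

    A derived field is present exactly when all of its inputs are; nothing is
    zero-filled.  SMI-Shen is the Shen whole-body MM indexed by height².
    """
    r = record
    height_cm = r.height * 100.0
    out: dict[str, Optional[float]] = {"bmi": bmi(r.weight, r.height)}

    if r.l3_sma is not None:
        out["smi_ct"] = smi(r.l3_sma, r.height)
        out["shen_mm"] = shen_mm(r.l3_sma)
        out["smi_shen"] = smi(out["shen_mm"], r.height)
        out["mourtzakis_ffm"] = mourtzakis_ffm(r.l3_sma)
        if r.l3_smd is not None:
            out["smg"] = smg(out["smi_ct"], r.l3_smd)
    if r.rz is not None:
        out["janssen_mm"] = janssen_mm(height_cm, r.rz, r.sex, r.age)
        out["smi_janssen"] = smi(out["janssen_mm"], r.height)
        if r.xc is not None:
            out["kanellakis_ffm"] = kanellakis_ffm(r.weight, r.sex, r.rz, r.xc, r.height)
    if r.z is not None:
        out["kotler_ffm"] = kotler_ffm(height_cm, r.z, r.weight)
    if r.quad_mt is not None:
        quad_cm = r.quad_mt / 10.0
        out["fischer_sma"] = fischer_sma(r.sex, r.weight, height_cm, quad_cm)
        out["newmodel_sma"] = newmodel_sma(r.sex, r.weight, height_cm, quad_cm)
    return DerivedBiomarkers(**out)


def equation_registry() -> dict:
    """Machine-readable description of every shipped equation.

    Lists coefficients and unit conventions so new equations can be reviewed or
    added without reading code.  Serialisable to YAML/JSON as-is.
    """
    return {
        "sex_coding": {"female": 0, "male": 1},
        "canonical_units": {
            "height": "m",
            "weight": "kg",
            "thickness": "mm",
            "area": "cm^2",
            "resistance": "ohm",
        },
        "equations": {
            "shen_mm": {
                "output": "kg",
                "inputs": {"l3_sma": "cm^2"},
                "form": "(0.166*l3_sma + 2.142) * 1.06",
            },
            "mourtzakis_ffm": {
                "output": "kg",
                "inputs": {"l3_sma": "cm^2"},
                "form": "0.30*l3_sma + 6.06",
            },
            "janssen_mm": {
                "output": "kg",
                "inputs": {"height": "cm", "rz": "ohm", "sex": "code", "age": "years"},
                "form": "5.102 + 0.401*(height^2/rz) + 3.825*sex - 0.071*age",
            },
            "kanellakis_ffm": {
                "output": "kg",
                "inputs": {"weight": "kg", "sex": "code", "rz": "ohm", "xc": "ohm", "height": "m"},
                "form": "12.299 + 0.164*weight + 7.287*sex - 0.116*(rz/height) + 0.365*(xc/height^2) + 21.570*height",
            },
            "kotler_ffm": {
                "output": "kg",
                "inputs": {"height": "cm", "z": "ohm", "weight": "kg"},
                "form": "0.88*(height^2.24/z^0.63)/37.63 + 0.16*weight - 3.96",
            },
            "fischer_sma": {
                "output": "cm^2",
                "inputs": {"sex": "code", "weight": "kg", "height": "cm", "quad_mt": "cm"},
                "coefficients": dict(FISCHER_COEF),
            },
            "newmodel_sma": {
                "output": "cm^2",
                "inputs": {"sex": "code", "weight": "kg", "height": "cm", "quad_mt": "cm"},
                "coefficients": dict(NEWMODEL_COEF),
            },
        },
    }


def derived_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Raw + derived biomarkers for a cohort as one DataFrame (row per subject)."""
    raw = pd.DataFrame([r.model_dump() for r in records])
    derived = pd.DataFrame([derive_all(r).model_dump() for r in records])
    return pd.concat([raw, derived], axis=1)
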