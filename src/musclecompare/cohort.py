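"""Synthetic cohort generation.

Generates cohorts with the statistical structure the analysis assumes for an
older colorectal-cancer outpatient population: roughly balanced sexes, ages
50–90 (median ≈ 65), median BMI ≈ 27 with ≈ 26% obesity, and one latent
*muscularity* factor M shared across measurement channels so that CT area,
ultrasound thicknesses and handgrip rise with M while whole-body resistance
falls with it — reproducing the sign pattern of the observed inter-technique
correlation matrices (e.g. corr(R_z, L3-SMA) ≈ −0.65, corr(θ, HGS) ≈ +0.5).

Each measurement channel is a linear model over (sex, M, age − 65,
BMI − 27.3) plus Gaussian noise, clipped to its physiological range.
Reactance is derived from resistance and phase angle via X_c = R_z·tan(θ) and
Z = sqrt(R_z² + X_c²), keeping the raw bioimpedance parameters internally
consistent.  Generation is a deterministic function of (spec, seed).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import DomainError
from .records import SubjectRecord

__all__ = ["ChannelModel", "CohortSpec", "generate_cohort", "make_paired_channel",
           "cohort_frame"]

_AGE_REF = 65.0
_BMI_REF = 27.3


class ChannelModel(BaseModel):
    """Linear generative model for one measurement channel."""

    model_config = ConfigDict(extra="forbid")

    intercept: float           # value for a female at age 65, BMI 27.3, M = 0
    sex_effect: float = 0.0    # added for males
    latent: float = 0.0        # loading on the muscularity factor M
    age_slope: float = 0.0     # per year from age 65
    bmi_slope: float = 0.0     # per kg/m² from BMI 27.3
    noise_sd: float = Field(0.0, ge=0.0)
    lower: Optional[float] = None
    upper: Optional[float] = None

    def draw(self, rng, sex, m, age, bmi_vals):
        v = (
            self.intercept
            + self.sex_effect * sex
            + self.latent * m
            + self.age_slope * (age - _AGE_REF)
            + self.bmi_slope * (bmi_vals - _BMI_REF)
            + rng.normal(0.0, self.noise_sd, size=sex.shape)
        )
        return np.clip(v, self.lower, self.upper)


def _default_channels() -> dict[str, ChannelModel]:
    return {
        # CT muscle area (cm²): strong sexual dimorphism, rises with M and BMI.
        "l3_sma": ChannelModel(intercept=103.4, sex_effect=41.8, latent=16.0,
                               bmi_slope=1.5, noise_sd=8.0, lower=35.0),
        # CT radiodensity (HU): falls with age and adiposity.
        "l3_smd": ChannelModel(intercept=41.0, age_slope=-0.43, bmi_slope=-0.5,
                               noise_sd=6.5, lower=-29.0, upper=150.0),
        # Whole-body resistance (Ω): falls with muscularity and adiposity.
        "rz": ChannelModel(intercept=560.0, sex_effect=-40.0, latent=-35.0,
                           bmi_slope=-3.0, noise_sd=40.0, lower=250.0),
        # Phase angle (°): cell-mass marker, falls with age.
        "theta": ChannelModel(intercept=4.85, sex_effect=0.4, latent=0.30,
                              age_slope=-0.045, noise_sd=0.35, lower=2.0, upper=9.0),
        # Ultrasound thicknesses (mm) and area (cm²).
        "rf_mt": ChannelModel(intercept=12.7, sex_effect=2.9, latent=1.3,
                              bmi_slope=0.15, noise_sd=1.8, lower=3.0),
        "quad_mt": ChannelModel(intercept=23.5, sex_effect=6.1, latent=2.8,
                                bmi_slope=0.4, noise_sd=3.5, lower=6.0),
        "rf_csa": ChannelModel(intercept=3.6, sex_effect=1.0, latent=0.45,
                               bmi_slope=0.05, noise_sd=0.6, lower=0.8),
        # Handgrip strength (kg): rises with M, falls with age.
        "hgs": ChannelModel(intercept=29.0, sex_effect=11.0, latent=4.5,
                            age_slope=-0.25, noise_sd=4.0, lower=5.0),
    }


class CohortSpec(BaseModel):
    """Generative parameters for a synthetic cohort."""

    model_config = ConfigDict(extra="forbid")

    n: int = Field(156, ge=0)
    female_fraction: float = Field(0.481, ge=0.0, le=1.0)
    # age: shifted gamma on [age_min, age_max]
    age_shape: float = Field(3.0, gt=0)
    age_scale: float = Field(5.5, gt=0)
    age_min: float = 50.0
    age_max: float = 90.0
    # height (m) by sex: (mean, sd)
    height_female: tuple[float, float] = (1.58, 0.06)
    height_male: tuple[float, float] = (1.705, 0.06)
    # BMI (kg/m²) normal, clipped
    bmi_mean: float = 27.3
    bmi_sd: float = Field(4.3, ge=0)
    bmi_range: tuple[float, float] = (16.0, 48.0)
    latent_mean: float = 0.0
    latent_sd: float = Field(1.0, ge=0)
    channels: dict[str, ChannelModel] = Field(default_factory=_default_channels)
    # optional fraction of records with each optional channel blanked at random
    missing_rate: float = Field(0.0, ge=0.0, le=1.0)
    seed: int = 0


_OPTIONAL_CHANNELS = ("l3_sma", "l3_smd", "rz", "xc", "z", "theta",
                      "rf_mt", "quad_mt", "rf_csa", "hgs")


def generate_cohort(spec: CohortSpec, seed: Optional[int] = None) -> list[SubjectRecord]:
    """Draw a cohort of validated :class:`SubjectRecord`; deterministic in (spec, seed)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n
    if n == 0:
        return []

    sex = (rng.random(n) >= spec.female_fraction).astype(int)  # 1 = male
    age = np.clip(spec.age_min + rng.gamma(spec.age_shape, spec.age_scale, n),
                  spec.age_min, spec.age_max)
    h_mean = np.where(sex == 1, spec.height_male[0], spec.height_female[0])
    h_sd = np.where(sex == 1, spec.height_male[1], spec.height_female[1])
    height = np.clip(rng.normal(h_mean, h_sd), 1.35, 2.10)
    bmi_vals = np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd, n), *spec.bmi_range)
    weight = bmi_vals * height**2
    m = rng.normal(spec.latent_mean, spec.latent_sd, n)

    cols = {
        name: model.draw(rng, sex, m, age, bmi_vals)
        for name, model in spec.channels.items()
    }
    # Derived raw BIA parameters consistent with resistance and phase angle.
    if "rz" in cols and "theta" in cols:
        cols["xc"] = cols["rz"] * np.tan(np.deg2rad(cols["theta"]))
        cols["z"] = np.hypot(cols["rz"], cols["xc"])

    missing = None
    if spec.missing_rate > 0:
        missing = {ch: rng.random(n) < spec.missing_rate for ch in cols}

    records = []
    for i in range(n):
        fields = dict(
            id=f"S{i:04d}", sex=int(sex[i]), age=float(age[i]),
            height=float(height[i]), weight=float(weight[i]),
        )
        for ch, values in cols.items():
            if missing is not None and missing[ch][i]:
                continue
            fields[ch] = float(values[i])
        records.append(SubjectRecord(**fields))
    return records


def cohort_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame, one row per subject (missing → NaN)."""
    return pd.DataFrame([r.model_dump() for r in records])


def make_paired_channel(
    frame: pd.DataFrame, source_field: str, bias: float, noise_sd: float,
    seed: int, name: Optional[str] = None,
) -> pd.DataFrame:
    """Add a paired re-measurement column: source + bias + Normal(0, noise_sd).

    Treating the new column as the reference and the source as the index
    method, a Bland–Altman analysis recovers ``bias`` and ``noise_sd``; used
    for parameter-recovery checks of the agreement battery.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    if source_field not in frame.columns:
        raise DomainError(f"unknown source column {source_field!r}")
    source = frame[source_field]
    if source.isna().any():
        raise DomainError(f"source column {source_field!r} has missing values")
    rng = np.random.default_rng(seed)
    out = frame.copy()
    new_name = name or f"{source_field}_paired"
    out[new_name] = source + bias + rng.normal(0.0, noise_sd, size=len(frame))
    return out
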