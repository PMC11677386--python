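"""Subject-level data containers.

A :class:`SubjectRecord` holds one participant's raw multi-technique
measurements in the package's canonical units: height in metres, weight in kg,
muscle thicknesses in millimetres, areas in cm², radiodensity in Hounsfield
units (HU), bioimpedance quantities in ohms, phase angle in degrees, and
handgrip strength in kg.  Sex is coded female = 0, male = 1 throughout the
package; the code is stored once here and every equation reads it unchanged.

:class:`DerivedBiomarkers` holds the outputs of all estimating equations for a
single subject.  A derived field is ``None`` exactly when one of its required
inputs is missing — missing inputs are never zero-filled.
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

# CT segmentation window for skeletal muscle (HU); mean radiodensity of the
# segmented region cannot fall outside it.
SMD_WINDOW = (-29.0, 150.0)


class SubjectRecord(BaseModel):
    """One participant's raw measurements and weight-history fields."""

    model_config = ConfigDict(extra="forbid")

    id: str
    sex: int
    age: float
    height: float  # m
    weight: float  # kg
    l3_sma: Optional[float] = None  # cm²
    l3_smd: Optional[float] = None  # HU
    rz: Optional[float] = None      # Ω, resistance at 50 kHz
    xc: Optional[float] = None      # Ω, capacitive reactance
    z: Optional[float] = None       # Ω, impedance modulus
    theta: Optional[float] = None   # °, phase angle
    rf_mt: Optional[float] = None   # mm, rectus femoris thickness
    quad_mt: Optional[float] = None  # mm, rectus femoris + vastus intermedius
    rf_csa: Optional[float] = None  # cm², rectus femoris cross-section
    hgs: Optional[float] = None     # kg, best handgrip strength
    talluri_mm: Optional[float] = None   # kg, device-proprietary estimate
    talluri_ffm: Optional[float] = None  # kg, device-proprietary estimate
    weight_loss_pct: Optional[float] = None       # % of usual body weight
    weight_loss_window: Optional[float] = None    # months over which lost
    weight_loss_voluntary: Optional[bool] = None

    @field_validator("sex")
    @classmethod
    def _sex_binary(cls, v: int) -> int:
        if v not in (0, 1):
            raise ValueError("sex must be coded female=0 or male=1")
        return v

    @field_validator("age")
    @classmethod
    def _age_nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("age must be >= 0")
        return v

    @field_validator("height", "weight")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    @field_validator(
        "l3_sma", "rz", "xc", "z", "theta", "rf_mt", "quad_mt", "rf_csa", "hgs"
    )
    @classmethod
    def _positive_when_present(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError("must be > 0 when present")
        return v

    @field_validator("l3_smd")
    @classmethod
    def _smd_in_window(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not (SMD_WINDOW[0] <= v <= SMD_WINDOW[1]):
            raise ValueError(
                f"l3_smd must lie in the segmentation window {SMD_WINDOW} HU"
            )
        return v

    @field_validator("weight_loss_pct")
    @classmethod
    def _loss_nonnegative(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v < 0:
            raise ValueError("weight_loss_pct must be >= 0")
        return v

    @model_validator(mode="after")
    def _height_unit_guard(self) -> "SubjectRecord":
        # A height of e.g. 164 is almost certainly centimetres.
        if self.height > 3.0:
            raise ValueError(
                f"height={self.height} is implausible in metres; "
                "the schema expects metres (did you supply centimetres?)"
            )
        return self


class DerivedBiomarkers(BaseModel):
    """Equation outputs for one subject; ``None`` marks an underivable field."""

    model_config = ConfigDict(extra="forbid")

    bmi: float                              # kg/m²
    smi_ct: Optional[float] = None          # cm²/m²
    smg: Optional[float] = None             # AU
    shen_mm: Optional[float] = None         # kg
    mourtzakis_ffm: Optional[float] = None  # kg
    janssen_mm: Optional[float] = None      # kg
    smi_janssen: Optional[float] = None     # kg/m²
    smi_shen: Optional[float] = None        # kg/m²
    kanellakis_ffm: Optional[float] = None  # kg
    kotler_ffm: Optional[float] = None      # kg
    fischer_sma: Optional[float] = None     # cm²
    newmodel_sma: Optional[float] = None    # cm²

    def present_fields(self) -> list[str]:
        return [k for k, v in self.model_dump().items() if v is not None]


DERIVED_FIELDS = list(DerivedBiomarkers.model_fields)
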