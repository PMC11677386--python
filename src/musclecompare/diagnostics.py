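"""Covariate-conditional diagnostic rules.

Operationalised definitions used in morphofunctional assessment:

* **Muscle atrophy** — a biomarker strictly below a threshold that may depend
  on sex, BMI stratum and age (Dolan SMI-CT cut-offs, Masanés and EWGSOP2
  SMI-Janssen cut-offs, DRECO ultrasound cut-offs).
* **Myosteatosis** — L3 muscle radiodensity strictly below a BMI-dependent
  threshold (Dolan).
* **Dynapenia** — handgrip strength strictly below an age/sex normative 10th
  percentile (replaceable table).
* **Sarcopenia** — atrophy AND dynapenia (EWGSOP2 conjunction).
* **GLIM malnutrition** — worst severity across involuntary-weight-loss and
  age-conditional low-BMI phenotypic criteria, with the etiologic criterion
  assumed met for the study population.
* **BMI categories** — WHO bands; obesity = BMI ≥ 30 kg/m².

Every threshold comparison is *strictly below = abnormal*; boundary values are
normal.  Covariates outside all declared strata raise
:class:`~musclecompare.errors.UnclassifiableError` — never a silent default.
"""

from __future__ import annotations

import enum
import importlib.resources as resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .errors import DomainError, UnclassifiableError
from .records import SubjectRecord

__all__ = [
    "CutoffRule",
    "CutoffSet",
    "GripNormativeTable",
    "GlimSeverity",
    "classify_atrophy",
    "classify_myosteatosis",
    "dynapenia",
    "sarcopenia",
    "glim",
    "bmi_category",
    "prevalence",
    "load_cutoff_set",
    "load_grip_table",
    "shipped_cutoff_sets",
]

_INF = float("inf")


@dataclass(frozen=True)
class CutoffRule:
    """One stratum: covariate constraints plus a strictly-below threshold.

    Range constraints are half-open ``[min, max)`` so adjacent strata tile
    without overlap; ``sex=None`` matches both sexes.
    """

    threshold: float
    sex: Optional[int] = None
    bmi_min: float = -_INF
    bmi_max: float = _INF
    age_min: float = -_INF
    age_max: float = _INF

    def matches(self, sex: int, bmi: Optional[float], age: Optional[float]) -> bool:
        if self.sex is not None and sex != self.sex:
            return False
        if (self.bmi_min, self.bmi_max) != (-_INF, _INF):
            if bmi is None or not (self.bmi_min <= bmi < self.bmi_max):
                return False
        if (self.age_min, self.age_max) != (-_INF, _INF):
            if age is None or not (self.age_min <= age < self.age_max):
                return False
        return True


@dataclass(frozen=True)
class CutoffSet:
    """A named cut-off table driving one diagnosis on one biomarker."""

    name: str
    biomarker: str
    rules: tuple[CutoffRule, ...]
    citation: str = ""

    def threshold_for(
        self, sex: int, bmi: Optional[float] = None, age: Optional[float] = None
    ) -> float:
        for rule in self.rules:
            if rule.matches(sex, bmi, age):
                return rule.threshold
        raise UnclassifiableError(
            f"cut-off set {self.name!r}: no stratum covers "
            f"sex={sex}, bmi={bmi}, age={age}"
        )

    def classify(
        self, value: float, sex: int, bmi: Optional[float] = None,
        age: Optional[float] = None,
    ) -> bool:
        """True iff the biomarker value is strictly below the stratum threshold."""
        return value < self.threshold_for(sex, bmi=bmi, age=age)


def classify_atrophy(
    value: float, cutoffs: CutoffSet, *, sex: int,
    bmi: Optional[float] = None, age: Optional[float] = None,
) -> bool:
    """Muscle atrophy flag for one subject under one cut-off set."""
    return cutoffs.classify(value, sex, bmi=bmi, age=age)


def classify_myosteatosis(
    smd: float, cutoffs: CutoffSet, *, bmi: float, sex: int = 0,
) -> bool:
    """Myosteatosis flag: radiodensity below a (typically BMI-keyed) threshold."""
    return cutoffs.classify(smd, sex, bmi=bmi)


@dataclass(frozen=True)
class GripNormativeTable:
    """Age/sex 10th-percentile handgrip table (kg), half-open age bands."""

    name: str
    # per sex code: tuple of (age_min, age_max, p10_kg)
    bands: Mapping[int, tuple[tuple[float, float, float], ...]] = field(
        default_factory=dict
    )

    def p10(self, sex: int, age: float) -> float:
        for age_min, age_max, value in self.bands.get(sex, ()):
            if age_min <= age < age_max:
                return value
        raise UnclassifiableError(
            f"grip table {self.name!r}: no band for sex={sex}, age={age}"
        )


def dynapenia(hgs: float, age: float, sex: int, normative: GripNormativeTable) -> bool:
    """True iff handgrip strength is strictly below the normative 10th percentile."""
    return hgs < normative.p10(sex, age)


def sarcopenia(atrophy: bool, dynapenia_flag: bool) -> bool:
    """EWGSOP2 conjunction: sarcopenia = muscle atrophy AND dynapenia."""
    return bool(atrophy and dynapenia_flag)


class GlimSeverity(enum.IntEnum):
    NONE = 0
    MODERATE = 1
    SEVERE = 2


def _glim_weight_loss(record: SubjectRecord) -> GlimSeverity:
    # Only involuntary loss counts; absent history means no qualifying loss.
    pct = record.weight_loss_pct
    window = record.weight_loss_window
    if pct is None or window is None or record.weight_loss_voluntary:
        return GlimSeverity.NONE
    recent = window <= 6.0
    if (recent and pct > 10.0) or (not recent and pct > 20.0):
        return GlimSeverity.SEVERE
    if (recent and pct > 5.0) or (not recent and pct > 10.0):
        return GlimSeverity.MODERATE
    return GlimSeverity.NONE


def _glim_low_bmi(bmi: float, age: float) -> GlimSeverity:
    # Age >= 70 uses the older thresholds (the exactly-70 case is assigned to
    # the older band, consistent with "70 years or older" reporting).
    older = age >= 70.0
    severe_cut = 20.0 if older else 18.5
    moderate_cut = 22.0 if older else 20.0
    if bmi < severe_cut:
        return GlimSeverity.SEVERE
    if bmi < moderate_cut:
        return GlimSeverity.MODERATE
    return GlimSeverity.NONE


def glim(record: SubjectRecord, bmi: float) -> GlimSeverity:
    """GLIM severity: worst of the weight-loss and low-BMI phenotypic criteria.

    The etiologic (inflammation) criterion is assumed satisfied for every
    subject, as appropriate for an active-disease oncology population.
    """
    return max(_glim_weight_loss(record), _glim_low_bmi(bmi, record.age))


BMI_CATEGORIES = (
    (18.5, "underweight"),
    (25.0, "normal weight"),
    (30.0, "overweight"),
    (35.0, "grade 1 obesity"),
    (40.0, "grade 2 obesity"),
    (_INF, "grade 3 obesity"),
)


def bmi_category(bmi: float) -> tuple[str, bool]:
    """WHO BMI band and an obesity flag (BMI ≥ 30 kg/m²)."""
    if bmi <= 0:
        raise DomainError("bmi_category requires bmi > 0")
    for upper, label in BMI_CATEGORIES:
        if bmi < upper:
            return label, bmi >= 30.0
    raise AssertionError("unreachable")


def prevalence(flags: Sequence[bool]) -> tuple[int, int, float]:
    """(positives, N, percent) for a vector of diagnosis flags."""
    flags = list(flags)
    if not flags:
        raise DomainError("prevalence of an empty cohort is undefined")
    n_pos = sum(bool(f) for f in flags)
    return n_pos, len(flags), 100.0 * n_pos / len(flags)


# ---------------------------------------------------------------------------
# Config loading

def _data_path(*parts: str) -> Path:
    return Path(resources.files("musclecompare").joinpath("data", *parts))


def load_cutoff_set(path_or_name: str | Path) -> CutoffSet:
    """Load a cut-off set from YAML (a shipped name or a file path)."""
    path = Path(path_or_name)
    if not path.exists():
        path = _data_path("cutoffs", f"{path_or_name}.yaml")
    doc = yaml.safe_load(path.read_text())
    rules = tuple(
        CutoffRule(
            threshold=float(r["threshold"]),
            sex=r.get("sex"),
            bmi_min=float(r.get("bmi_min", -_INF)),
            bmi_max=float(r.get("bmi_max", _INF)),
            age_min=float(r.get("age_min", -_INF)),
            age_max=float(r.get("age_max", _INF)),
        )
        for r in doc.get("rules") or ()
    )
    return CutoffSet(
        name=doc["name"], biomarker=doc["biomarker"], rules=rules,
        citation=doc.get("citation", ""),
    )


def load_grip_table(path_or_name: str | Path) -> GripNormativeTable:
    path = Path(path_or_name)
    if not path.exists():
        path = _data_path(f"{path_or_name}.yaml")
    doc = yaml.safe_load(path.read_text())
    bands = {
        int(sex): tuple(
            (float(b["age_min"]), float(b["age_max"]), float(b["p10"]))
            for b in entries
        )
        for sex, entries in doc["bands"].items()
    }
    return GripNormativeTable(name=doc["name"], bands=bands)


#: Cut-off sets shipped with populated thresholds (the Van Vugt template is
#: intentionally empty and excluded until the user fills it in).
SHIPPED_CUTOFF_NAMES = (
    "dolan_smi_ct",
    "dolan_smd",
    "masanes_smi_janssen",
    "ewgsop2_smi_janssen",
    "dreco_rf_mt",
    "dreco_rf_csa",
)


def shipped_cutoff_sets() -> dict[str, CutoffSet]:
    return {name: load_cutoff_set(name) for name in SHIPPED_CUTOFF_NAMES}
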