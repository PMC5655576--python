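"""Severity grading of the five acromegaly health-status parameters.

Each parameter is graded on a 3-level ordinal scale: level 1, adequately
controlled; level 2, mild activity warranting further evaluation; level 3,
significant activity requiring clinical action.

Grading rules:

* **IGF-I** — relative to the assay's age-adjusted normal range.  Level 1:
  within [LLN, ULN].  Level 2: above ULN but not more than 1.2x ULN, or
  below LLN.  Level 3: above 1.2x ULN.  Both boundaries follow the printed
  inequalities: a value exactly at ULN is normal; exactly 1.2x ULN is
  level 2 ("not > 1.2x ULN").
* **Tumor status** — from the most recent MRI versus the prior one.
  Level 3: size increase > 20%, or increased invasiveness, or worsening
  vision.  Level 2: a slight size increase (0 < change <= 20%).  Level 1:
  tumor not visible, unchanged, or reduced.
* **Comorbidities** — diabetes, sleep apnea, cardiac disease.  Level 3 if
  any of: uncontrolled diabetes, moderate/severe sleep apnea, uncontrolled
  cardiac disease.  Level 1 requires no diabetes, no sleep apnea, and
  cardiac disease absent or well controlled.  Everything else is level 2.
* **Symptoms (SSS)** — 5 items (headache, perspiration, joint pain,
  fatigue, soft-tissue swelling), each 0-8, total 0-40.  Level 3: mean
  item score > 4 or any single item > 6.  Level 1: all items <= 2.
  Otherwise level 2.  The level-3 test takes precedence.
* **Quality of life (AcroQoL)** — 22 items each 1-5, raw total 22-110,
  standardized to 0-100% where 100 is best possible QoL.  Level 1:
  score >= 60.  Level 2: 40 <= score < 60.  Level 3: score < 40.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import (
    IncompleteRecordError,
    InvalidMeasurementError,
    InvalidResponseError,
    ValidationError,
)
from .scenario import LevelVector

__all__ = [
    "IGFMeasurement",
    "TumorAssessment",
    "ComorbidityProfile",
    "SSSResponse",
    "AcroQoLResponse",
    "PatientRecord",
    "DiabetesStatus",
    "SleepApneaStatus",
    "CardiacStatus",
    "classify_igf",
    "classify_tumor",
    "classify_comorbidity",
    "sss_total",
    "classify_sss",
    "acroqol_standardize",
    "classify_qol",
    "assess_patient",
    "SeverityAssessor",
]


@dataclass(frozen=True)
class IGFMeasurement:
    """Serum IGF-I with the assay's age-adjusted normal range (same units)."""

    value: float
    lln: float
    uln: float

    def __post_init__(self):
        if not (self.value > 0):
            raise InvalidMeasurementError(f"IGF-I value must be positive; got {self.value!r}")
        if not (0 < self.lln < self.uln):
            raise InvalidMeasurementError(
                f"normal range requires 0 < LLN < ULN; got LLN={self.lln!r}, ULN={self.uln!r}"
            )

    @property
    def uln_ratio(self) -> float:
        return self.value / self.uln


@dataclass(frozen=True)
class TumorAssessment:
    """Pituitary tumor status from the most recent MRI versus the prior one.

    ``size_change_pct`` is the signed percent change in tumor size; it must
    be ``None`` when the tumor is not visible, and may be ``None`` when no
    prior MRI exists (treated as no documented change).
    """

    visible: bool
    size_change_pct: Optional[float] = None
    invasiveness_increased: bool = False
    vision_worsened: bool = False

    def __post_init__(self):
        if not self.visible and self.size_change_pct is not None:
            raise InvalidMeasurementError(
                "size_change_pct must be absent when the tumor is not visible"
            )


class DiabetesStatus(str, enum.Enum):
    NONE = "none"
    CONTROLLED = "controlled"
    UNCONTROLLED = "uncontrolled"


class SleepApneaStatus(str, enum.Enum):
    ABSENT = "absent"
    MILD = "mild"
    MODERATE_SEVERE = "moderate_severe"


class CardiacStatus(str, enum.Enum):
    ABSENT = "absent"
    CONTROLLED = "controlled"
    UNCONTROLLED = "uncontrolled"


@dataclass(frozen=True)
class ComorbidityProfile:
    """Status of the three key acromegaly comorbidities."""

    diabetes: DiabetesStatus
    sleep_apnea: SleepApneaStatus
    cardiac: CardiacStatus

    def __post_init__(self):
        object.__setattr__(self, "diabetes", DiabetesStatus(self.diabetes))
        object.__setattr__(self, "sleep_apnea", SleepApneaStatus(self.sleep_apnea))
        object.__setattr__(self, "cardiac", CardiacStatus(self.cardiac))


_SSS_ITEMS = ("headache", "perspiration", "joint_pain", "fatigue", "soft_tissue_swelling")


@dataclass(frozen=True)
class SSSResponse:
    """Signs and Symptoms Score: 5 items, each 0-8."""

    items: tuple[int, ...]

    def __post_init__(self):
        items = tuple(self.items)
        if len(items) != 5:
            raise InvalidResponseError(f"SSS requires exactly 5 items; got {len(items)}")
        for name, score in zip(_SSS_ITEMS, items):
            if not (isinstance(score, (int, np.integer)) and 0 <= score <= 8):
                raise InvalidResponseError(f"SSS item {name} must be an integer in [0, 8]; got {score!r}")
        object.__setattr__(self, "items", tuple(int(s) for s in items))


@dataclass(frozen=True)
class AcroQoLResponse:
    """Acromegaly Quality of Life questionnaire: 22 items, each 1-5."""

    items: tuple[int, ...]

    def __post_init__(self):
        items = tuple(self.items)
        if len(items) != 22:
            raise InvalidResponseError(f"AcroQoL requires exactly 22 items; got {len(items)}")
        for i, score in enumerate(items, start=1):
            if not (isinstance(score, (int, np.integer)) and 1 <= score <= 5):
                raise InvalidResponseError(f"AcroQoL item {i} must be an integer in [1, 5]; got {score!r}")
        object.__setattr__(self, "items", tuple(int(s) for s in items))


@dataclass(frozen=True)
class PatientRecord:
    """All five parameter measurements for one patient at one visit."""

    igf: IGFMeasurement
    tumor: TumorAssessment
    comorbidity: ComorbidityProfile
    sss: SSSResponse
    acroqol: AcroQoLResponse

    def __post_init__(self):
        for name in ("igf", "tumor", "comorbidity", "sss", "acroqol"):
            if getattr(self, name) is None:
                raise IncompleteRecordError(f"patient record is missing the {name} component")


# ---------------------------------------------------------------------------
# classifiers

def classify_igf(m: IGFMeasurement) -> int:
    if m.value > 1.2 * m.uln:
        return 3
    if m.value > m.uln or m.value < m.lln:
        return 2
    return 1


def classify_tumor(t: TumorAssessment) -> int:
    pct = t.size_change_pct
    if (pct is not None and pct > 20) or t.invasiveness_increased or t.vision_worsened:
        return 3
    if pct is not None and 0 < pct <= 20:
        return 2
    return 1


def classify_comorbidity(c: ComorbidityProfile) -> int:
    if (
        c.diabetes is DiabetesStatus.UNCONTROLLED
        or c.sleep_apnea is SleepApneaStatus.MODERATE_SEVERE
        or c.cardiac is CardiacStatus.UNCONTROLLED
    ):
        return 3
    if (
        c.diabetes is DiabetesStatus.NONE
        and c.sleep_apnea is SleepApneaStatus.ABSENT
        and c.cardiac in (CardiacStatus.ABSENT, CardiacStatus.CONTROLLED)
    ):
        return 1
    return 2


def sss_total(s: SSSResponse) -> int:
    return sum(s.items)


def classify_sss(s: SSSResponse) -> int:
    mean = sss_total(s) / 5.0
    if mean > 4 or max(s.items) > 6:
        return 3
    if max(s.items) <= 2:
        return 1
    return 2


def acroqol_standardize(a: AcroQoLResponse) -> float:
    """Standardized AcroQoL score in [0, 100]; 100 is best possible QoL."""
    return 100.0 * (sum(a.items) - 22) / 88.0


def classify_qol(pct: float) -> int:
    if not 0 <= pct <= 100:
        raise ValidationError(f"standardized QoL score must be in [0, 100]; got {pct!r}")
    if pct >= 60:
        return 1
    if pct >= 40:
        return 2
    return 3


def assess_patient(p: PatientRecord) -> LevelVector:
    """Grade all five parameters of a complete record, in fixed order."""
    if not isinstance(p, PatientRecord):
        raise IncompleteRecordError("assess_patient requires a complete PatientRecord")
    return LevelVector(
        igf=classify_igf(p.igf),
        tumor=classify_tumor(p.tumor),
        comorbidity=classify_comorbidity(p.comorbidity),
        symptoms=classify_sss(p.sss),
        qol=classify_qol(acroqol_standardize(p.acroqol)),
    )


# ---------------------------------------------------------------------------
# sklearn-style transformer

class SeverityAssessor:
    """Stateless transformer: patient records -> (n, 5) severity level array.

    Accepts a sequence of :class:`PatientRecord` or a DataFrame in the flat
    patients-file schema (see :func:`acrodat.io.patients_from_frame`), and
    produces the integer level matrix consumed by the activity classifiers,
    so that record grading and activity scoring compose as an sklearn
    pipeline.  ``fit`` is a no-op (the grading rules are fixed by the
    instrument definitions).
    """

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        records = self._as_records(X)
        return np.array([tuple(assess_patient(r)) for r in records], dtype=int)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params):
        if params:
            raise ValueError(f"SeverityAssessor takes no parameters; got {params}")
        return self

    @staticmethod
    def _as_records(X) -> list[PatientRecord]:
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            from .io import patients_from_frame

            return patients_from_frame(X)
        records = list(X)
        for r in records:
            if not isinstance(r, PatientRecord):
                raise IncompleteRecordError(
                    "expected PatientRecord instances or a patients DataFrame"
                )
        return records
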