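"""Patient records, pain-score outcome rules, and cohort exclusions.

The unit of analysis is one surgical case. Pain is recorded on the 0-10
Numeric Rating Scale (NRS); some observations arrive as one of six text
categories that map onto the even NRS values. The outcome of interest is the
daily *maximum* pain on postoperative days 0-4 (day 0 = day of surgery).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

N_DAYS = 5

#: Six-category text vocabulary for pain, mapped onto even NRS values.
PAIN_STRING_MAP: dict[str, int] = {
    "no pain": 0,
    "mild pain": 2,
    "moderate pain": 4,
    "severe pain": 6,
    "very severe pain": 8,
    "worst possible pain": 10,
}

#: Inverse map, used by the simulator to render latent pain as text.
PAIN_VALUE_TO_STRING: dict[int, str] = {v: k for k, v in PAIN_STRING_MAP.items()}


class PainStringError(ValueError):
    """Raised for pain text outside the six-category vocabulary."""


@dataclass
class PatientRecord:
    """One surgical patient: demographics, preoperative variables, code set,
    and timestamped pain observations.

    ``codes`` maps each CPT/ICD-10 code string to its kind (``"CPT"`` or
    ``"ICD10"``); within a record a code appears at most once. ``pain_obs``
    is a list of ``(day_offset, value)`` pairs where ``value`` is numeric NRS
    or one of the six pain strings.
    """

    patient_id: str
    age: float
    weight: float
    height: float
    sex: str
    race: str
    preop_pain: float | None
    service: str
    urgency: str
    inpatient: bool
    codes: dict[str, str] = field(default_factory=dict)
    pain_obs: list[tuple[int, Any]] = field(default_factory=list)
    died_intraop: bool = False
    icu_admit: bool = False

    def cpt_codes(self) -> list[str]:
        return sorted(c for c, k in self.codes.items() if k == "CPT")

    def icd_codes(self) -> list[str]:
        return sorted(c for c, k in self.codes.items() if k == "ICD10")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pain_obs"] = [[int(day), v] for day, v in self.pain_obs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PatientRecord":
        d = dict(d)
        d["pain_obs"] = [(int(day), v) for day, v in d.get("pain_obs", [])]
        return cls(**d)


@dataclass
class OutcomeVector:
    """Per-day maximum pain with an availability mask.

    ``max_pain[d]`` is meaningful only where ``available[d]`` is True; days
    with no recorded score are unavailable (the patient was typically no
    longer in hospital).
    """

    max_pain: np.ndarray  # shape (5,), float
    available: np.ndarray  # shape (5,), bool

    def __post_init__(self) -> None:
        self.max_pain = np.asarray(self.max_pain, dtype=float)
        self.available = np.asarray(self.available, dtype=bool)
        if self.max_pain.shape != (N_DAYS,) or self.available.shape != (N_DAYS,):
            raise ValueError("OutcomeVector requires 5-day vectors")


def convert_pain_string(value: str) -> int:
    """Map one of the six pain strings to its NRS value.

    Matching is case-insensitive and ignores surrounding whitespace. Numeric
    text (e.g. ``"7"``) is parsed as a number first, since EHR exports mix
    types. Anything else raises :class:`PainStringError` — unknown strings
    are never silently dropped.
    """
    key = str(value).strip().lower()
    try:
        return int(float(key))  # numeric given as text
    except ValueError:
        pass
    if key in PAIN_STRING_MAP:
        return PAIN_STRING_MAP[key]
    raise PainStringError(f"unrecognized pain string: {value!r}")


def _obs_value(value: Any) -> float:
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        v = float(value)
        if not np.isfinite(v) or not 0 <= v <= 10:
            raise ValueError(f"numeric pain value out of range: {value!r}")
        return v
    return float(convert_pain_string(value))


def build_outcomes(record: PatientRecord) -> OutcomeVector:
    """Daily maximum pain over postoperative days 0-4.

    Strings are converted through the six-category map before taking the
    maximum; observations outside the 5-day window are ignored; days with no
    observation are marked unavailable.
    """
    max_pain = np.zeros(N_DAYS)
    available = np.zeros(N_DAYS, dtype=bool)
    for day, value in record.pain_obs:
        if not 0 <= day < N_DAYS:
            continue
        v = _obs_value(value)
        if not available[day] or v > max_pain[day]:
            max_pain[day] = v
        available[day] = True
    max_pain[~available] = np.nan
    return OutcomeVector(max_pain=max_pain, available=available)


def binarize_outcome(v: float, threshold: int) -> bool:
    """Moderate/severe pain indicator: NRS strictly above the threshold.

    ``threshold`` is 4 (moderate) or 6 (severe); boundary values are negative.
    """
    if threshold not in (4, 6):
        raise ValueError("threshold must be 4 or 6")
    if not 0 <= v <= 10:
        raise ValueError(f"pain value out of range: {v}")
    return v > threshold


def apply_exclusions(
    records: list[PatientRecord],
) -> tuple[list[PatientRecord], list[tuple[str, str]]]:
    """Cohort exclusion rules: intraoperative death, immediate ICU
    admission, and absence of any in-window pain observation.

    Returns the kept records and ``(patient_id, reason)`` pairs for every
    exclusion (a patient may contribute several reasons).
    """
    kept: list[PatientRecord] = []
    excluded: list[tuple[str, str]] = []
    for rec in records:
        reasons = []
        if rec.died_intraop:
            reasons.append("died_intraop")
        if rec.icu_admit:
            reasons.append("icu_admit")
        if not any(0 <= day < N_DAYS for day, _ in rec.pain_obs):
            reasons.append("no_pain_observations")
        if reasons:
            excluded.extend((rec.patient_id, r) for r in reasons)
        else:
            kept.append(rec)
    return kept, excluded
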