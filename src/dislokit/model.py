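"""Domain types and code handling for registry-based THA dislocation detection.

The unit of analysis is a primary total hip arthroplasty (THA). Hospital
contacts are coded with ICD-10 diagnoses (Danish dialect: a leading ``D``,
subcodes appended as letters, e.g. ``DT840A``) and NCSP/NOMESCO procedure
codes (``K``-prefixed). Diagnosis codes are matched by prefix, so ``DT840A``
qualifies wherever ``DT840`` does; procedure codes are fixed-length and
matched exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Optional, Sequence

import json

import yaml

#: Length of the follow-up window after the index operation, in days.
#: "Two years" operationalised as a closed-open 730-day window
#: [index_date, index_date + 730 days), further truncated by censoring
#: (the censoring day itself remains inside the window).
FOLLOW_UP_DAYS = 730

SIDES = ("left", "right")
CONTACT_SIDES = ("left", "right", "unknown")
ADMISSION_TYPES = ("acute", "elective")
SETTINGS = ("inpatient", "outpatient_er", "outpatient_clinic")
SPECIALTIES = ("orthopedic", "other")
INDICATIONS = ("primary_OA", "other")
CENSOR_REASONS = ("revision", "death", "emigration", "none")


class DislokitError(Exception):
    """Base class for package errors."""


class ValidationError(DislokitError, ValueError):
    """Raised when an input violates a documented invariant."""


def normalize_code(raw: str) -> str:
    """Normalise a diagnosis or procedure code string.

    Uppercases and strips dots and all whitespace, e.g. ``"dt84.0a"`` →
    ``"DT840A"``. Idempotent.

    Raises
    ------
    ValidationError
        If ``raw`` is empty or whitespace-only.
    """
    if raw is None or not str(raw).strip():
        raise ValidationError("empty code string")
    return "".join(str(raw).split()).replace(".", "").upper()


def code_matches(code: str, prefix: str) -> bool:
    """True iff ``code`` equals ``prefix`` or extends it by a suffix.

    Both arguments must already be normalised. Used for diagnosis codes,
    where subcode variants (``DT840A``) must match the parent (``DT840``).
    """
    return code.startswith(prefix)


@dataclass(frozen=True)
class CodeSet:
    """The code groups driving the stepwise algorithm.

    ``correct_dx`` is the dislocation-of-prosthesis diagnosis (mechanical
    complication, ``DT840`` and subcodes); ``correct_proc`` the closed
    reduction of a prosthetic hip (``KNFH20``); ``alt_dx``/``alt_proc`` are
    the alternative, frequently mis-applied codes for native-hip dislocation
    and open/other reductions. Diagnoses match by prefix, procedures exactly.
    """

    correct_dx: frozenset = frozenset({"DT840"})
    correct_proc: frozenset = frozenset({"KNFH20"})
    alt_dx: frozenset = frozenset({"DS730"})
    alt_proc: frozenset = frozenset({"KNFH00", "KNFH02", "KNFH21", "KNFH22"})

    def __post_init__(self):
        sets = {
            "correct_dx": frozenset(normalize_code(c) for c in self.correct_dx),
            "correct_proc": frozenset(normalize_code(c) for c in self.correct_proc),
            "alt_dx": frozenset(normalize_code(c) for c in self.alt_dx),
            "alt_proc": frozenset(normalize_code(c) for c in self.alt_proc),
        }
        for name, value in sets.items():
            object.__setattr__(self, name, value)
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if sets[a] & sets[b]:
                    raise ValidationError(
                        f"code sets must be pairwise disjoint: {a} ∩ {b} = {sets[a] & sets[b]}"
                    )

    # -- membership helpers used by the classifier ------------------------

    def is_correct_dx(self, code: str) -> bool:
        return any(code_matches(code, p) for p in self.correct_dx)

    def is_alt_dx(self, code: str) -> bool:
        return any(code_matches(code, p) for p in self.alt_dx)

    def is_correct_proc(self, code: str) -> bool:
        return code in self.correct_proc

    def is_alt_proc(self, code: str) -> bool:
        return code in self.alt_proc

    def all_codes(self) -> frozenset:
        return self.correct_dx | self.correct_proc | self.alt_dx | self.alt_proc

    @classmethod
    def from_file(cls, path) -> "CodeSet":
        """Load a code configuration from YAML or JSON (keys: correct_dx,
        correct_proc, alt_dx, alt_proc)."""
        text = open(path).read()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(
            correct_dx=frozenset(data["correct_dx"]),
            correct_proc=frozenset(data["correct_proc"]),
            alt_dx=frozenset(data["alt_dx"]),
            alt_proc=frozenset(data["alt_proc"]),
        )

    def to_dict(self) -> dict:
        return {
            "correct_dx": sorted(self.correct_dx),
            "correct_proc": sorted(self.correct_proc),
            "alt_dx": sorted(self.alt_dx),
            "alt_proc": sorted(self.alt_proc),
        }


@dataclass
class THARecord:
    """One primary THA: the unit of analysis.

    ``censor_date`` marks end of follow-up before two years (revision,
    death or emigration); ``follow_up_last_day`` is the last calendar day
    whose hospital contacts still belong to this THA's observation window.
    """

    patient_id: str
    index_date: date
    side: str
    age_at_surgery: int
    indication: str = "primary_OA"
    censor_date: Optional[date] = None
    censor_reason: str = "none"

    def __post_init__(self):
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}: {self.side!r}")
        if self.indication not in INDICATIONS:
            raise ValidationError(f"unknown indication {self.indication!r}")
        if self.censor_reason not in CENSOR_REASONS:
            raise ValidationError(f"unknown censor reason {self.censor_reason!r}")
        if self.censor_date is not None and self.censor_date < self.index_date:
            raise ValidationError(
                f"censor_date {self.censor_date} before index_date {self.index_date}"
            )
        if (self.censor_date is None) != (self.censor_reason == "none"):
            raise ValidationError("censor_date and censor_reason must be given together")

    @property
    def follow_up_last_day(self) -> date:
        """Last day inside the follow-up window (always defined)."""
        last = self.index_date + timedelta(days=FOLLOW_UP_DAYS - 1)
        if self.censor_date is not None and self.censor_date < last:
            return self.censor_date
        return last

    def in_window(self, d: date) -> bool:
        return self.index_date <= d <= self.follow_up_last_day


@dataclass
class HospitalContact:
    """One national-patient-register style hospital contact.

    ``diagnoses`` is an ordered list of (code, position) with position in
    {"primary", "secondary"}; both positions qualify for group assignment.
    ``procedures`` is a list of (code, date). All codes are normalised on
    construction.
    """

    patient_id: str
    contact_id: str
    admit_date: date
    discharge_date: date
    specialty: str = "orthopedic"
    admission_type: str = "acute"
    setting: str = "inpatient"
    side: str = "unknown"
    diagnoses: list = field(default_factory=list)
    procedures: list = field(default_factory=list)

    def __post_init__(self):
        if self.discharge_date < self.admit_date:
            raise ValidationError(
                f"discharge {self.discharge_date} before admission {self.admit_date} "
                f"(contact {self.contact_id})"
            )
        if self.specialty not in SPECIALTIES:
            raise ValidationError(f"unknown specialty {self.specialty!r}")
        if self.admission_type not in ADMISSION_TYPES:
            raise ValidationError(f"unknown admission_type {self.admission_type!r}")
        if self.setting not in SETTINGS:
            raise ValidationError(f"unknown setting {self.setting!r}")
        if self.side not in CONTACT_SIDES:
            raise ValidationError(f"contact side must be one of {CONTACT_SIDES}")
        self.diagnoses = [
            (normalize_code(code), pos) for code, pos in self.diagnoses
        ]
        for _, pos in self.diagnoses:
            if pos not in ("primary", "secondary"):
                raise ValidationError(f"diagnosis position must be primary/secondary: {pos!r}")
        self.procedures = [(normalize_code(code), d) for code, d in self.procedures]

    @property
    def dx_codes(self) -> list:
        return [c for c, _ in self.diagnoses]

    @property
    def proc_codes(self) -> list:
        return [c for c, _ in self.procedures]

    @property
    def is_acute_or_er(self) -> bool:
        """Acute readmission or emergency-room contact (the access route
        required for detection on the dislocation diagnosis alone)."""
        return self.admission_type == "acute" or self.setting == "outpatient_er"


@dataclass(frozen=True)
class DislocationEvent:
    """A chart-review-verified dislocation episode (gold standard)."""

    patient_id: str
    event_id: str
    event_date: date
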