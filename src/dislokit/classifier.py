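"""Code-group assignment and cumulative step classification.

The algorithm sorts each hospital contact into one of five code groups:

1. correct dislocation diagnosis (DT840*) AND closed-reduction procedure
   (KNFH20), laterality matching the index hip;
2. closed-reduction procedure alone (any diagnosis), laterality matching;
3. alternative dislocation/reduction codes (DS730*, KNFH00/02/21/22),
   laterality matching;
4. any group 1-3 code combination but contact laterality unknown;
5. correct diagnosis alone (no closed-reduction code), laterality matching,
   restricted to acute admissions or emergency-room contacts.

A contact gets exactly one group (lowest number wins); contacts coded for
the opposite hip never qualify. Detection step k flags a patient whose best
contact has group <= k, so steps are cumulative: step 1 = group 1 alone,
step 2 = groups 1-2, and so on. Steps 4A and 5A model a manual chart review
of the group-4 (and group-5) contacts in which false positives are
discarded; true positives are never removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from typing import Dict, Iterable, List, Optional, Sequence

from .cohort import Cohort
from .model import (
    CodeSet,
    DislocationEvent,
    DislokitError,
    HospitalContact,
    THARecord,
)

STEPS = (1, 2, 3, 4, 5)
REVIEW_STEPS = ("4A", "5A")
ALL_STEPS = (1, 2, 3, 4, 5, "4A", "5A")

#: Maximum |contact admission - event date| for event-level matching, days.
EVENT_MATCH_DAYS = 1


def assign_group(
    contact: HospitalContact, tha: THARecord, codes: Optional[CodeSet] = None
) -> Optional[int]:
    """Assign a contact to a code group (1-5) or ``None``.

    Laterality gates everything: a contact coded for the opposite hip never
    qualifies, a contact with unknown laterality can only reach group 4 (and
    only on group 1-3 code criteria; the correct diagnosis alone with
    unknown side does not qualify).
    """
    codes = codes or CodeSet()
    has_cdx = any(codes.is_correct_dx(c) for c in contact.dx_codes)
    has_adx = any(codes.is_alt_dx(c) for c in contact.dx_codes)
    has_cproc = any(codes.is_correct_proc(c) for c in contact.proc_codes)
    has_aproc = any(codes.is_alt_proc(c) for c in contact.proc_codes)

    if contact.side == tha.side:
        if has_cdx and has_cproc:
            return 1
        if has_cproc:
            return 2
        if has_adx or has_aproc:
            return 3
        if has_cdx and contact.is_acute_or_er:
            return 5
        return None
    if contact.side == "unknown":
        # group 1-3 code criteria, laterality uncertain
        if has_cproc or has_adx or has_aproc:
            return 4
        return None
    return None  # opposite side


@dataclass
class StepClassification:
    """Per-patient detection status for steps 1-5 and review steps 4A/5A."""

    patient_id: str
    detected_at_step: Dict = field(default_factory=dict)
    qualifying_contacts: Dict = field(default_factory=dict)
    contact_groups: Dict[str, int] = field(default_factory=dict)
    reviewed: set = field(default_factory=set)

    @property
    def min_group(self) -> Optional[int]:
        return min(self.contact_groups.values(), default=None)


def classify_patients(
    cohort: Cohort,
    windowed_contacts: Dict[str, List[HospitalContact]],
    codes: Optional[CodeSet] = None,
) -> List[StepClassification]:
    """Classify every cohort patient at each cumulative step.

    ``detected_at_step[k]`` is true iff some windowed contact has group <= k
    (group 4 counting from step 4, group 5 from step 5). Steps "4A"/"5A"
    start as copies of 4/5; :func:`review_adjust` applies the chart-review
    correction.
    """
    codes = codes or CodeSet()
    out: List[StepClassification] = []
    for tha in cohort.records:
        groups: Dict[str, int] = {}
        for c in windowed_contacts.get(tha.patient_id, ()):
            g = assign_group(c, tha, codes)
            if g is not None:
                groups[c.contact_id] = g
        detected = {k: any(g <= k for g in groups.values()) for k in STEPS}
        detected["4A"] = detected[4]
        detected["5A"] = detected[5]
        qualifying = {
            k: sorted(cid for cid, g in groups.items() if g <= k) for k in STEPS
        }
        qualifying["4A"] = qualifying[4]
        qualifying["5A"] = qualifying[5]
        out.append(
            StepClassification(
                patient_id=tha.patient_id,
                detected_at_step=detected,
                qualifying_contacts=qualifying,
                contact_groups=groups,
            )
        )
    return out


def review_adjust(
    classifications: Sequence[StepClassification],
    truth: Iterable[DislocationEvent],
    scope: str,
) -> List[StepClassification]:
    """Apply the chart-review correction for step 4A or 5A in place.

    4A: a patient who is positive at step 4 solely through group-4 contacts
    and has no verified dislocation is reset to negative at 4A. 5A repeats
    this for patients positive solely through group-4/5 contacts (and
    requires the 4A review to have been applied first). Review never touches
    true positives, so sensitivity is unchanged and only false positives are
    discarded.
    """
    if scope not in REVIEW_STEPS:
        raise DislokitError(f"review scope must be one of {REVIEW_STEPS}: {scope!r}")
    positives = {e.patient_id for e in truth}
    if scope == "5A":
        missing_4a = [c for c in classifications if "4A" not in c.reviewed]
        if missing_4a:
            raise DislokitError("5A review assumes the 4A review was applied first")
    for c in classifications:
        if scope == "4A":
            c.detected_at_step["4A"] = c.detected_at_step[4]
            if (
                c.detected_at_step[4]
                and c.min_group == 4
                and c.patient_id not in positives
            ):
                c.detected_at_step["4A"] = False
        else:
            c.detected_at_step["5A"] = c.detected_at_step[5]
            if (
                c.detected_at_step[5]
                and c.min_group in (4, 5)
                and c.patient_id not in positives
            ):
                c.detected_at_step["5A"] = False
        c.reviewed.add(scope)
    return list(classifications)


@dataclass
class EventDetection:
    """Detection status of one verified dislocation episode per step."""

    event_id: str
    patient_id: str
    event_date: object
    detected_at_step: Dict[int, bool] = field(default_factory=dict)


def match_contacts_to_events(
    truth: Iterable[DislocationEvent],
    classifications: Sequence[StepClassification],
    windowed_contacts: Dict[str, List[HospitalContact]],
) -> Dict[str, Optional[str]]:
    """Match each qualifying contact to at most one verified episode.

    A contact matches an episode of the same patient whose date lies within
    +/- 1 day of the admission; the nearest date wins and, on a tie, the
    earlier episode. Returns contact_id -> event_id (or ``None`` for
    qualifying contacts matching no episode).
    """
    events_by_patient: Dict[str, List[DislocationEvent]] = {}
    for e in truth:
        events_by_patient.setdefault(e.patient_id, []).append(e)
    out: Dict[str, Optional[str]] = {}
    for c in classifications:
        events = sorted(
            events_by_patient.get(c.patient_id, ()),
            key=lambda e: (e.event_date, e.event_id),
        )
        for contact in windowed_contacts.get(c.patient_id, ()):
            if contact.contact_id not in c.contact_groups:
                continue
            best = None
            for i, e in enumerate(events):
                delta = abs((contact.admit_date - e.event_date).days)
                if delta <= EVENT_MATCH_DAYS and (best is None or (delta, i) < best):
                    best = (delta, i)
            out[contact.contact_id] = events[best[1]].event_id if best else None
    return out


def classify_events(
    truth: Iterable[DislocationEvent],
    classifications: Sequence[StepClassification],
    windowed_contacts: Dict[str, List[HospitalContact]],
) -> List[EventDetection]:
    """Event-level detection: which verified episodes does each step find?

    An episode is detected at step k if one of its matched contacts (see
    :func:`match_contacts_to_events`) has group <= k. Unmatched episodes are
    undetected at every step.
    """
    truth = list(truth)
    matching = match_contacts_to_events(truth, classifications, windowed_contacts)
    groups_by_contact: Dict[str, int] = {}
    for c in classifications:
        groups_by_contact.update(c.contact_groups)
    matched_groups: Dict[str, List[int]] = {}
    for cid, eid in matching.items():
        if eid is not None:
            matched_groups.setdefault(eid, []).append(groups_by_contact[cid])
    return [
        EventDetection(
            event_id=e.event_id,
            patient_id=e.patient_id,
            event_date=e.event_date,
            detected_at_step={
                k: any(g <= k for g in matched_groups.get(e.event_id, ()))
                for k in STEPS
            },
        )
        for e in sorted(truth, key=lambda e: (e.patient_id, e.event_date, e.event_id))
    ]
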