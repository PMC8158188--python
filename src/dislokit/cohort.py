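"""Cohort construction: inclusion/exclusion rules and follow-up windowing.

Inclusion mirrors the validation study: primary-osteoarthritis THAs in
patients aged 40 or older; when a patient has more than one THA in the
inclusion period only the first (earliest index date) is kept, the
contralateral procedure is excluded to avoid dependent observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

from .model import HospitalContact, THARecord, ValidationError

MIN_AGE = 40


@dataclass
class Cohort:
    records: List[THARecord]
    exclusion_log: List[Tuple[str, str]] = field(default_factory=list)

    def __len__(self):
        return len(self.records)

    @property
    def patient_ids(self):
        return {r.patient_id for r in self.records}

    def by_patient(self) -> Dict[str, THARecord]:
        return {r.patient_id: r for r in self.records}


def build_cohort(raw_records: Iterable[THARecord]) -> Cohort:
    """Apply inclusion/exclusion rules to a raw arthroplasty-register extract.

    Exclusion reasons (one per excluded record, logged in order of
    application): ``"indication"`` (not primary OA), ``"age<40"``,
    ``"contralateral"`` (a later THA of a patient already contributing one).

    Raises
    ------
    ValidationError
        On duplicate (patient_id, index_date, side) rows.
    """
    raw = list(raw_records)
    seen = set()
    for r in raw:
        key = (r.patient_id, r.index_date, r.side)
        if key in seen:
            raise ValidationError(f"duplicate THA row {key}")
        seen.add(key)

    kept: List[THARecord] = []
    log: List[Tuple[str, str]] = []
    eligible: List[THARecord] = []
    for r in raw:
        if r.indication != "primary_OA":
            log.append((r.patient_id, "indication"))
        elif r.age_at_surgery < MIN_AGE:
            log.append((r.patient_id, "age<40"))
        else:
            eligible.append(r)

    # one THA per patient: earliest index date wins, stable on input order
    first_for: Dict[str, THARecord] = {}
    for r in eligible:
        cur = first_for.get(r.patient_id)
        if cur is None or r.index_date < cur.index_date:
            first_for[r.patient_id] = r
    for r in eligible:
        if first_for[r.patient_id] is r:
            kept.append(r)
        else:
            log.append((r.patient_id, "contralateral"))

    return Cohort(records=kept, exclusion_log=log)


def window_contacts(
    cohort: Cohort, contacts: Iterable[HospitalContact]
) -> Dict[str, List[HospitalContact]]:
    """Restrict contacts to each cohort patient's follow-up window.

    A contact is kept iff its admission date falls on or after the index
    date and on or before the patient's last follow-up day (two years, or
    earlier censoring by revision/death/emigration; the censoring day itself
    counts). Contacts of non-cohort patients are dropped. Output lists are
    sorted by (admit_date, contact_id) so the result does not depend on
    input order.
    """
    by_patient = cohort.by_patient()
    out: Dict[str, List[HospitalContact]] = {r.patient_id: [] for r in cohort.records}
    for c in contacts:
        tha = by_patient.get(c.patient_id)
        if tha is None:
            continue
        if tha.in_window(c.admit_date):
            out[c.patient_id].append(c)
    for lst in out.values():
        lst.sort(key=lambda c: (c.admit_date, c.contact_id))
    return out
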