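"""Factories for compact construction of registry objects in tests."""

from datetime import date, timedelta

from dislokit import DislocationEvent, HospitalContact, THARecord

INDEX = date(2012, 3, 1)


def tha(pid="P1", index=INDEX, side="left", age=70, indication="primary_OA",
        censor_day=None, reason="none"):
    return THARecord(
        patient_id=pid,
        index_date=index,
        side=side,
        age_at_surgery=age,
        indication=indication,
        censor_date=index + timedelta(days=censor_day) if censor_day is not None else None,
        censor_reason=reason if censor_day is not None else "none",
    )


def contact(pid="P1", cid="C1", day=10, index=INDEX, dx=(), procs=(), side="left",
            admission_type="acute", setting="inpatient", specialty="orthopedic",
            stay=1):
    admit = index + timedelta(days=day)
    return HospitalContact(
        patient_id=pid,
        contact_id=cid,
        admit_date=admit,
        discharge_date=admit + timedelta(days=stay),
        specialty=specialty,
        admission_type=admission_type,
        setting=setting,
        side=side,
        diagnoses=[(c, "primary") for c in dx],
        procedures=[(c, admit) for c in procs],
    )


def event(pid="P1", eid="E1", day=10, index=INDEX):
    return DislocationEvent(
        patient_id=pid, event_id=eid, event_date=index + timedelta(days=day)
    )
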