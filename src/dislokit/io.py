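"""CSV schemas and conversions between DataFrames and domain objects.

Schemas (comma-separated, header row, ISO-8601 dates; multi-valued fields
semicolon-delimited and positionally aligned):

- cohort.csv:  patient_id,index_date,side,age_at_surgery,indication,
               censor_date,censor_reason
- contacts.csv: patient_id,contact_id,admit_date,discharge_date,specialty,
                admission_type,setting,side,dx_codes,dx_positions,
                proc_codes,proc_dates
- truth.csv:   patient_id,event_id,event_date
"""

from __future__ import annotations

from datetime import date
from typing import List, Optional

import pandas as pd

from .model import DislocationEvent, HospitalContact, THARecord

COHORT_COLUMNS = [
    "patient_id", "index_date", "side", "age_at_surgery",
    "indication", "censor_date", "censor_reason",
]
CONTACT_COLUMNS = [
    "patient_id", "contact_id", "admit_date", "discharge_date", "specialty",
    "admission_type", "setting", "side", "dx_codes", "dx_positions",
    "proc_codes", "proc_dates",
]
TRUTH_COLUMNS = ["patient_id", "event_id", "event_date"]


def _parse_date(s) -> Optional[date]:
    if s is None or (isinstance(s, float) and pd.isna(s)) or s == "":
        return None
    return date.fromisoformat(str(s))


def _split(s) -> List[str]:
    if s is None or (isinstance(s, float) and pd.isna(s)) or str(s) == "":
        return []
    return str(s).split(";")


def cohort_from_df(df: pd.DataFrame) -> List[THARecord]:
    records = []
    for row in df.itertuples(index=False):
        censor = _parse_date(row.censor_date)
        records.append(
            THARecord(
                patient_id=str(row.patient_id),
                index_date=_parse_date(row.index_date),
                side=row.side,
                age_at_surgery=int(row.age_at_surgery),
                indication=row.indication,
                censor_date=censor,
                censor_reason=row.censor_reason if censor is not None else "none",
            )
        )
    return records


def contacts_from_df(df: pd.DataFrame) -> List[HospitalContact]:
    contacts = []
    for row in df.itertuples(index=False):
        dx = _split(row.dx_codes)
        pos = _split(row.dx_positions)
        procs = _split(row.proc_codes)
        pdates = _split(row.proc_dates)
        contacts.append(
            HospitalContact(
                patient_id=str(row.patient_id),
                contact_id=str(row.contact_id),
                admit_date=_parse_date(row.admit_date),
                discharge_date=_parse_date(row.discharge_date),
                specialty=row.specialty,
                admission_type=row.admission_type,
                setting=row.setting,
                side=row.side,
                diagnoses=list(zip(dx, pos)),
                procedures=[(c, _parse_date(d)) for c, d in zip(procs, pdates)],
            )
        )
    return contacts


def truth_from_df(df: pd.DataFrame) -> List[DislocationEvent]:
    return [
        DislocationEvent(
            patient_id=str(r.patient_id),
            event_id=str(r.event_id),
            event_date=_parse_date(r.event_date),
        )
        for r in df.itertuples(index=False)
    ]


def _read(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_cohort(path) -> List[THARecord]:
    return cohort_from_df(_read(path, COHORT_COLUMNS))


def read_contacts(path) -> List[HospitalContact]:
    return contacts_from_df(_read(path, CONTACT_COLUMNS))


def read_truth(path) -> List[DislocationEvent]:
    return truth_from_df(_read(path, TRUTH_COLUMNS))


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def cohort_to_df(records: List[THARecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "index_date": r.index_date.isoformat(),
                "side": r.side,
                "age_at_surgery": r.age_at_surgery,
                "indication": r.indication,
                "censor_date": r.censor_date.isoformat() if r.censor_date else "",
                "censor_reason": r.censor_reason,
            }
            for r in records
        ],
        columns=COHORT_COLUMNS,
    )


def contacts_to_df(contacts: List[HospitalContact]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "contact_id": c.contact_id,
                "admit_date": c.admit_date.isoformat(),
                "discharge_date": c.discharge_date.isoformat(),
                "specialty": c.specialty,
                "admission_type": c.admission_type,
                "setting": c.setting,
                "side": c.side,
                "dx_codes": ";".join(code for code, _ in c.diagnoses),
                "dx_positions": ";".join(pos for _, pos in c.diagnoses),
                "proc_codes": ";".join(code for code, _ in c.procedures),
                "proc_dates": ";".join(d.isoformat() for _, d in c.procedures),
            }
            for c in contacts
        ],
        columns=CONTACT_COLUMNS,
    )


def truth_to_df(events: List[DislocationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "event_id": e.event_id,
                "event_date": e.event_date.isoformat(),
            }
            for e in events
        ],
        columns=TRUTH_COLUMNS,
    )
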