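"""Uniform longitudinal "standard data" record stream.

Every domain event collapses to one 9-field record

    patient_id, time, code, name, value, unit, datatype, encounter_id, status

and the stream is sorted by patient id then time, which presents each
patient's journey chronologically.  Non-observation domains (conditions,
procedures, medications, immunizations, allergies) have no measured
value, so they carry the categorical value ``"present"``; observations
keep their value, unit and datatype.  Codes are opaque strings — no
terminology mapping happens here.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic_ehr import EVENT_TABLES, DomainBundle

STANDARD_COLUMNS = [
    "patient_id",
    "time",
    "code",
    "name",
    "value",
    "unit",
    "datatype",
    "encounter_id",
    "status",
]


def to_standard_records(bundle: DomainBundle) -> pd.DataFrame:
    """Flatten all event tables into one sorted standard-record frame.

    Conservation: the output has exactly one record per source event
    (``len(out) == sum of event-table lengths``).  Same-timestamp ties
    keep the canonical domain order (conditions before observations
    before procedures, ...) via the stable sort.
    """
    parts = []
    for name in EVENT_TABLES:
        tab = bundle.table(name)
        if len(tab) == 0:
            continue
        rec = pd.DataFrame(
            {
                "patient_id": tab["patient_id"].astype(str),
                "time": pd.to_datetime(tab["time"] if "time" in tab.columns else tab["start"]),
                "code": tab["code"].astype(str),
                "name": tab["description"].astype(str),
                "value": tab["value"].astype(str) if "value" in tab.columns else "present",
                "unit": tab["unit"].astype(str) if "unit" in tab.columns else "",
                "datatype": tab["datatype"].astype(str) if "datatype" in tab.columns else "categorical",
                "encounter_id": tab["encounter_id"].astype(str),
                "status": tab["status"].astype(str) if "status" in tab.columns else "final",
            }
        )
        if rec["time"].isna().any():
            raise ValueError(f"{name}: unparseable timestamp")
        parts.append(rec)
    if not parts:
        return pd.DataFrame({c: pd.Series(dtype="datetime64[ns]" if c == "time" else object) for c in STANDARD_COLUMNS})
    records = pd.concat(parts, ignore_index=True)
    return sort_records(records)


def sort_records(records: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by (patient_id, time); equal keys keep input order."""
    return records.sort_values(["patient_id", "time"], kind="stable", ignore_index=True)


def write_standard_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.loc[:, STANDARD_COLUMNS].to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_standard_csv(path: str | Path) -> pd.DataFrame:
    records = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(STANDARD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"standard-data file missing columns {sorted(missing)}")
    records["time"] = pd.to_datetime(records["time"], format="ISO8601")
    return records[STANDARD_COLUMNS]
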