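"""Per-patient compressed data profiles.

Two profile kinds, mirroring the case/control asymmetry of the
screening design:

* **Target (case) profiles** — the patient-diagnosis-journey: every
  record *strictly before* the first target-disease diagnosis, compressed
  to the latest value per code.  Records at or after diagnosis, and the
  target-disease codes themselves, never enter the feature space (they
  would leak the label).
* **Background (control) profiles** — records inside an age window
  (default 30-70 years), compressed per code to the modal value for
  categorical data and the arithmetic mean for numeric data.  The
  patient's age is taken from the last record in the window.

Both profile kinds gain a pseudo-code ``"age"`` (numeric, years) so age
can act as a model variable after categorical conversion.

Profiles are handled in two forms: a :class:`PatientProfile` dataclass
for single patients, and a long-format frame (patient_id, label, code,
value, unit, datatype, age_years) for whole populations — the latter is
what the ML-table stage consumes and what the profile CSV files store.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_ehr import DAYS_PER_YEAR, AGE_FEATURE, DiseaseSpec

PROFILE_COLUMNS = ["patient_id", "label", "code", "value", "unit", "datatype", "age_years"]


class EmptyProfileError(ValueError):
    """A patient has no usable records for the requested profile."""


@dataclass(frozen=True)
class WindowSpec:
    """Age window applied to background patients only."""

    start_age: float = 30.0
    end_age: float = 70.0

    def __post_init__(self):
        if not self.start_age < self.end_age:
            raise ValueError("start_age must be < end_age")


@dataclass
class PatientProfile:
    patient_id: str
    label: int
    code_values: dict[str, tuple[object, str, str]]  # code -> (value, datatype, unit)
    age_years: float
    reference_time: pd.Timestamp


@dataclass
class ProfileReport:
    """Accounting of the target/background/dropped partition."""

    n_targets: int
    n_backgrounds: int
    n_dropped_targets: int
    n_dropped_backgrounds: int

    @property
    def total(self) -> int:
        return self.n_targets + self.n_backgrounds + self.n_dropped_targets + self.n_dropped_backgrounds


def find_target_patients(records: pd.DataFrame, disease: DiseaseSpec) -> dict[str, pd.Timestamp]:
    """Map each patient carrying a disease code to the FIRST occurrence time."""
    hits = records[records["code"].isin(disease.snomed_codes)]
    if len(hits) == 0:
        return {}
    return hits.groupby("patient_id")["time"].min().to_dict()


def _age_at(time, birthdate) -> float:
    return (time - birthdate) / pd.Timedelta(days=DAYS_PER_YEAR)


def build_target_profile(
    records: pd.DataFrame,
    diagnosis_time: pd.Timestamp,
    disease: DiseaseSpec,
    birthdate: pd.Timestamp | None = None,
) -> PatientProfile:
    """Compress one target patient's pre-diagnosis journey (latest value per code)."""
    pre = records[(records["time"] < diagnosis_time) & ~records["code"].isin(disease.snomed_codes)]
    if len(pre) == 0:
        raise EmptyProfileError("no records strictly before diagnosis")
    pre = pre.sort_values(["time"], kind="stable")
    code_values: dict[str, tuple[object, str, str]] = {}
    for _, row in pre.iterrows():
        val = float(row["value"]) if row["datatype"] == "numeric" else row["value"]
        code_values[row["code"]] = (val, row["datatype"], row["unit"])
    age = _age_at(diagnosis_time, birthdate) if birthdate is not None else float("nan")
    pid = str(records["patient_id"].iloc[0])
    return PatientProfile(pid, 1, code_values, age, diagnosis_time)


def build_background_profile(
    records: pd.DataFrame,
    window: WindowSpec,
    birthdate: pd.Timestamp,
) -> PatientProfile:
    """Compress one background patient inside the age window (mode/mean per code)."""
    age = _age_at(records["time"], birthdate)
    inw = records[(age >= window.start_age) & (age <= window.end_age)]
    if len(inw) == 0:
        raise EmptyProfileError("no records inside the age window")
    code_values: dict[str, tuple[object, str, str]] = {}
    for code, grp in inw.groupby("code", sort=True):
        dtype = grp["datatype"].iloc[-1]
        unit = grp["unit"].iloc[-1]
        if dtype == "numeric":
            val = float(np.mean([float(v) for v in grp["value"]]))
        else:
            counts = Counter(grp["value"])
            top = max(counts.values())
            val = min(v for v, c in counts.items() if c == top)  # lexicographic tie-break
        code_values[code] = (val, dtype, unit)
    ref = inw["time"].max()
    pid = str(records["patient_id"].iloc[0])
    return PatientProfile(pid, 0, code_values, _age_at(ref, birthdate), ref)


# ---------------------------------------------------------------------
# Vectorized population-scale builder
# ---------------------------------------------------------------------


def build_profiles(
    records: pd.DataFrame,
    patients: pd.DataFrame,
    disease: DiseaseSpec,
    window: WindowSpec = WindowSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame, ProfileReport]:
    """Build all target and background profiles as long-format frames.

    ``records`` must be sorted standard data; ``patients`` supplies
    birthdates.  Returns (targets_long, backgrounds_long, report); the
    report accounts for every patient in ``patients`` (target,
    background, or dropped with reason).
    """
    birth = patients.set_index("id")["birthdate"]
    diag = pd.Series(find_target_patients(records, disease), dtype="datetime64[ns]")
    diag.index.name = "patient_id"

    # ---- targets -----------------------------------------------------
    tmask = records["patient_id"].isin(diag.index)
    tr = records[tmask].merge(diag.rename("diag_time"), left_on="patient_id", right_index=True, sort=False)
    tr = tr[(tr["time"] < tr["diag_time"]) & ~tr["code"].isin(disease.snomed_codes)]
    # stable groupby keeps time order within (patient, code): 'last' = latest value
    tprof = (
        tr.groupby(["patient_id", "code"], sort=True)
        .agg(value=("value", "last"), unit=("unit", "last"), datatype=("datatype", "last"))
        .reset_index()
    )
    kept_targets = pd.Index(tprof["patient_id"].unique())
    t_age = _age_at(diag.loc[kept_targets], birth.loc[kept_targets].to_numpy())
    tprof["label"] = 1
    tprof["age_years"] = t_age.reindex(tprof["patient_id"]).to_numpy()
    t_rows = [tprof] if len(tprof) else []
    if len(kept_targets):
        t_rows.append(_age_rows(kept_targets, t_age, label=1))
    targets_long = _finish_long(t_rows)
    n_dropped_targets = len(diag) - len(kept_targets)

    # ---- backgrounds -------------------------------------------------
    bg = records[~records["patient_id"].isin(diag.index)].copy()
    bg_age = _age_at(bg["time"], birth.reindex(bg["patient_id"]).to_numpy())
    bg = bg[(bg_age >= window.start_age) & (bg_age <= window.end_age)]

    num = bg[bg["datatype"] == "numeric"].copy()
    num["fval"] = pd.to_numeric(num["value"])
    nprof = (
        num.groupby(["patient_id", "code"], sort=True)
        .agg(value=("fval", "mean"), unit=("unit", "last"), datatype=("datatype", "last"))
        .reset_index()
    )

    cat = bg[bg["datatype"] != "numeric"]
    counts = cat.groupby(["patient_id", "code", "value"], sort=True).agg(n=("value", "size"), unit=("unit", "last"), datatype=("datatype", "last")).reset_index()
    counts = counts.sort_values(["patient_id", "code", "n", "value"], ascending=[True, True, False, True], kind="stable")
    cprof = counts.drop_duplicates(["patient_id", "code"], keep="first")[["patient_id", "code", "value", "unit", "datatype"]]

    last_time = bg.groupby("patient_id")["time"].max()
    b_age = _age_at(last_time, birth.reindex(last_time.index).to_numpy())
    bprof = pd.concat([nprof, cprof], ignore_index=True)
    bprof["label"] = 0
    bprof["age_years"] = b_age.reindex(bprof["patient_id"]).to_numpy()
    b_rows = [bprof] if len(bprof) else []
    kept_backgrounds = last_time.index
    if len(kept_backgrounds):
        b_rows.append(_age_rows(kept_backgrounds, b_age, label=0))
    backgrounds_long = _finish_long(b_rows)

    n_background_total = len(patients) - len(diag)
    report = ProfileReport(
        n_targets=len(kept_targets),
        n_backgrounds=len(kept_backgrounds),
        n_dropped_targets=n_dropped_targets,
        n_dropped_backgrounds=n_background_total - len(kept_backgrounds),
    )
    return targets_long, backgrounds_long, report


def _age_rows(pids: pd.Index, ages: pd.Series, label: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pids,
            "code": AGE_FEATURE,
            "value": ages.loc[pids].to_numpy(),
            "unit": "years",
            "datatype": "numeric",
            "label": label,
            "age_years": ages.loc[pids].to_numpy(),
        }
    )


def _finish_long(parts: list[pd.DataFrame]) -> pd.DataFrame:
    if not parts:
        return pd.DataFrame(columns=PROFILE_COLUMNS)
    out = pd.concat(parts, ignore_index=True)
    # parse numeric target values (backgrounds already numeric via mean)
    nmask = (out["datatype"] == "numeric") & out["value"].map(lambda v: isinstance(v, str))
    if nmask.any():
        out.loc[nmask, "value"] = pd.to_numeric(out.loc[nmask, "value"])
    out = out.sort_values(["patient_id", "code"], kind="stable", ignore_index=True)
    return out[PROFILE_COLUMNS]


def write_profiles_csv(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.loc[:, PROFILE_COLUMNS].to_csv(path, index=False)


def read_profiles_csv(path: str | Path) -> pd.DataFrame:
    out = pd.read_csv(path, dtype={"patient_id": str, "code": str, "value": object, "unit": str, "datatype": str})
    nmask = out["datatype"] == "numeric"
    out.loc[nmask, "value"] = pd.to_numeric(out.loc[nmask, "value"])
    return out[PROFILE_COLUMNS]
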