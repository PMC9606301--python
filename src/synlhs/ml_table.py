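"""ML-ready table assembly: shared codes, balancing, conversion, selection.

The feature space is the set of codes shared by at least one target and
one background profile.  The table stays sparse (missing cells are NaN,
never imputed here); balancing works by keeping only code-rich
background patients; continuous values are binned into named categories;
variables are finally ranked and selected by patient-occurrence count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vocab import CHOLESTEROL_CODE

LABEL_COLUMN = "label"


@dataclass
class MLTable:
    """Patients x shared-code matrix plus the binary label column.

    ``frame`` is indexed by patient_id with one column per code and a
    ``label`` column; ``datatypes`` is the current per-code datatype,
    ``origin_datatypes`` the pre-conversion one (needed to subset
    "categorical only" vs "categorical + converted numeric" variables).
    """

    frame: pd.DataFrame
    datatypes: dict[str, str]
    units: dict[str, str] = field(default_factory=dict)
    origin_datatypes: dict[str, str] | None = None

    def __post_init__(self):
        if self.origin_datatypes is None:
            self.origin_datatypes = dict(self.datatypes)

    @property
    def codes(self) -> list[str]:
        return [c for c in self.frame.columns if c != LABEL_COLUMN]

    @property
    def n_targets(self) -> int:
        return int((self.frame[LABEL_COLUMN] == 1).sum())

    @property
    def n_backgrounds(self) -> int:
        return int((self.frame[LABEL_COLUMN] == 0).sum())


@dataclass(frozen=True)
class ConversionMap:
    """Per-code binning rules: strictly increasing breakpoints, one more
    category than breakpoints; a value equal to a breakpoint falls into
    the upper bin (>= semantics, as in the age < 50 / >= 50 rule)."""

    rules: dict[str, tuple[tuple[float, ...], tuple[str, ...]]]

    def __post_init__(self):
        for code, (bps, cats) in self.rules.items():
            if list(bps) != sorted(set(bps)):
                raise ValueError(f"{code}: breakpoints must be strictly increasing")
            if len(cats) != len(bps) + 1:
                raise ValueError(f"{code}: need len(breakpoints)+1 category names")

    def apply(self, code: str, values: pd.Series) -> pd.Series:
        bps, cats = self.rules[code]
        idx = np.searchsorted(np.asarray(bps, dtype=float), values.to_numpy(dtype=float), side="right")
        out = pd.Series(np.asarray(cats, dtype=object)[idx], index=values.index)
        out[values.isna()] = np.nan
        return out


def default_conversion_map() -> ConversionMap:
    """Clinically anchored defaults: total cholesterol (<200 mg/dL normal),
    age (<50 / >=50), and the common screening measurements the generator
    plants (systolic BP 140 mmHg, fasting glucose 126 mg/dL, FEV1/FVC 0.7)."""
    return ConversionMap(
        {
            CHOLESTEROL_CODE: ((200.0,), ("normal", "high")),
            "age": ((50.0,), ("under50", "over50")),
            "8480-6": ((140.0,), ("normal", "high")),
            "2339-0": ((126.0,), ("normal", "high")),
            "19926-5": ((0.7,), ("low", "normal")),
            "39156-5": ((30.0,), ("normal", "obese")),
        }
    )


@dataclass(frozen=True)
class BalanceConfig:
    """Keep background patients with at least this many distinct
    non-missing shared-code variables; targets are never dropped."""

    min_shared_codes: int = 100

    def __post_init__(self):
        if self.min_shared_codes < 1:
            raise ValueError("min_shared_codes must be >= 1")


@dataclass(frozen=True)
class VariableSelection:
    """Occurrence-based variable selection.

    ``patient_count_cutoff``: minimum number of patients a variable must
    occur in (full-scale defaults: 500 for lung cancer at 30k-patient
    batches, 1000 for stroke).  ``kind`` restricts to originally
    categorical variables or allows converted numeric ones too.
    """

    patient_count_cutoff: int = 500
    n_top: int | None = None
    kind: str = "all"  # "all" | "categorical"

    def __post_init__(self):
        if self.patient_count_cutoff < 1:
            raise ValueError("patient_count_cutoff must be >= 1")
        if self.kind not in ("all", "categorical"):
            raise ValueError("kind must be 'all' or 'categorical'")


# ---------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------


def shared_codes(targets_long: pd.DataFrame, backgrounds_long: pd.DataFrame) -> list[str]:
    """Codes present in >=1 target and >=1 background profile, ordered by
    descending patient count (ties lexicographic)."""
    if len(targets_long) == 0 or len(backgrounds_long) == 0:
        raise ValueError("both profile sets must be non-empty")
    tcodes = set(targets_long["code"])
    bcodes = set(backgrounds_long["code"])
    common = tcodes & bcodes
    if not common:
        raise ValueError("target and background vocabularies are disjoint")
    both = pd.concat([targets_long[["patient_id", "code"]], backgrounds_long[["patient_id", "code"]]])
    counts = both[both["code"].isin(common)].groupby("code")["patient_id"].nunique()
    return sorted(common, key=lambda c: (-counts[c], c))


def build_table(targets_long: pd.DataFrame, backgrounds_long: pd.DataFrame, codes: list[str]) -> MLTable:
    """Pivot profiles into one row per patient over the shared codes."""
    long = pd.concat([targets_long, backgrounds_long], ignore_index=True)
    labels = long.drop_duplicates("patient_id").set_index("patient_id")[LABEL_COLUMN]
    tdup = targets_long["patient_id"].unique()
    bdup = backgrounds_long["patient_id"].unique()
    if len(set(tdup) & set(bdup)):
        raise ValueError("duplicate patient_id across target and background profiles")
    sub = long[long["code"].isin(codes)]
    if sub.duplicated(["patient_id", "code"]).any():
        raise ValueError("profiles are not compressed: duplicate (patient, code)")
    wide = sub.pivot(index="patient_id", columns="code", values="value")
    wide = wide.reindex(index=labels.index, columns=codes)
    wide[LABEL_COLUMN] = labels.astype(int)
    meta = long[long["code"].isin(codes)].drop_duplicates("code").set_index("code")
    datatypes = meta["datatype"].to_dict()
    units = meta["unit"].to_dict()
    return MLTable(frame=wide, datatypes=datatypes, units=units)


def positive_rate(table: MLTable) -> float:
    """Fraction of rows labelled positive: targets / total."""
    if len(table.frame) == 0:
        raise ValueError("empty table")
    return float((table.frame[LABEL_COLUMN] == 1).mean())


def target_background_ratio(table: MLTable) -> float:
    """targets / backgrounds — the alternative 'positive sample rate'
    convention (1158/4221 = 27.4%)."""
    nb = table.n_backgrounds
    if nb == 0:
        raise ValueError("no background rows")
    return table.n_targets / nb


def balance(table: MLTable, config: BalanceConfig = BalanceConfig()) -> MLTable:
    """Drop code-poor background rows; keep every target row.

    A background row survives when its count of non-missing shared-code
    cells is >= ``min_shared_codes`` (inclusive threshold)."""
    f = table.frame
    nonmissing = f[table.codes].notna().sum(axis=1)
    keep = (f[LABEL_COLUMN] == 1) | (nonmissing >= config.min_shared_codes)
    out = f[keep]
    if (out[LABEL_COLUMN] == 0).sum() == 0:
        raise ValueError("no background row survives balancing")
    return MLTable(out, dict(table.datatypes), dict(table.units), dict(table.origin_datatypes))


def convert_values(table: MLTable, cmap: ConversionMap | None = None) -> MLTable:
    """Bin every numeric column into named categories.

    Numeric columns without a rule get a median-split two-bin fallback
    ("low"/"high") with a warning.  Already-categorical tables pass
    through unchanged (idempotence)."""
    if cmap is None:
        cmap = default_conversion_map()
    f = table.frame.copy()
    datatypes = dict(table.datatypes)
    for code in table.codes:
        if datatypes.get(code) != "numeric":
            continue
        col = pd.to_numeric(f[code], errors="coerce")
        bad = col.isna() & f[code].notna()
        if bad.any():
            raise ValueError(f"non-numeric cell in numeric column {code!r}")
        if code in cmap.rules:
            rule = cmap
        else:
            med = float(col.median())
            warnings.warn(f"no conversion rule for numeric code {code!r}; using median split at {med:.3g}")
            rule = ConversionMap({code: ((med,), ("low", "high"))})
        f[code] = rule.apply(code, col)
        datatypes[code] = "categorical"
    return MLTable(f, datatypes, dict(table.units), dict(table.origin_datatypes))


def select_variables(table: MLTable, sel: VariableSelection) -> list[str]:
    """Variables occurring in >= cutoff patients, sorted by occurrence
    descending (ties lexicographic), optionally truncated to n_top."""
    codes = table.codes
    if sel.kind == "categorical":
        codes = [c for c in codes if table.origin_datatypes.get(c) == "categorical"]
    occ = table.frame[codes].notna().sum()
    passing = occ[occ >= sel.patient_count_cutoff]
    if len(passing) == 0:
        raise ValueError("no variable passes the patient-count cutoff")
    ordered = sorted(passing.index, key=lambda c: (-passing[c], c))
    return ordered[: sel.n_top] if sel.n_top is not None else ordered


def variable_report(table: MLTable, sel: VariableSelection) -> pd.DataFrame:
    """Selection file: code, occurrence count, selected flag."""
    occ = table.frame[table.codes].notna().sum()
    try:
        selected = set(select_variables(table, sel))
    except ValueError:
        selected = set()
    rep = pd.DataFrame(
        {
            "code": occ.index,
            "patient_count": occ.to_numpy(),
            "datatype": [table.origin_datatypes.get(c, "") for c in occ.index],
            "selected": [c in selected for c in occ.index],
        }
    )
    return rep.sort_values(["patient_count", "code"], ascending=[False, True], ignore_index=True)


def write_table_csv(table: MLTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=True, na_rep="")


def read_table_csv(path: str | Path, datatypes: dict[str, str] | None = None) -> MLTable:
    f = pd.read_csv(path, index_col=0, dtype=object)
    f[LABEL_COLUMN] = f[LABEL_COLUMN].astype(int)
    dts = datatypes or {c: "categorical" for c in f.columns if c != LABEL_COLUMN}
    return MLTable(f, dts)
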