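"""Shared fixtures: small generated populations and toy record builders."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from synlhs import (
    LUNG_CANCER,
    PopulationConfig,
    build_profiles,
    generate_population,
    to_standard_records,
)

warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")


@pytest.fixture(scope="session")
def small_config():
    return PopulationConfig(n_patients=1200, seed=90210)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """~1200-patient lung-cancer population used across module tests."""
    return generate_population(small_config)


@pytest.fixture(scope="session")
def small_records(small_bundle):
    return to_standard_records(small_bundle)


@pytest.fixture(scope="session")
def small_profiles(small_bundle, small_records):
    return build_profiles(small_records, small_bundle.patients, LUNG_CANCER)


def make_records(rows: list[tuple]) -> pd.DataFrame:
    """Toy standard-record frame from (patient_id, time, code, value[, datatype, unit]) tuples."""
    out = []
    for row in rows:
        pid, time, code, value = row[:4]
        datatype = row[4] if len(row) > 4 else "categorical"
        unit = row[5] if len(row) > 5 else ""
        out.append(
            {
                "patient_id": pid,
                "time": pd.Timestamp(time),
                "code": str(code),
                "name": f"name-{code}",
                "value": value,
                "unit": unit,
                "datatype": datatype,
                "encounter_id": "e0",
                "status": "final",
            }
        )
    return pd.DataFrame(out)


def random_toy_records(rng: np.random.Generator, n_records: int = 50, n_codes: int = 8) -> pd.DataFrame:
    """Random single-patient record stream for oracle comparisons."""
    codes = [f"c{i}" for i in range(n_codes)]
    numeric = {c: i % 2 == 0 for i, c in enumerate(codes)}
    rows = []
    base = pd.Timestamp("1990-01-01")
    for _ in range(n_records):
        code = codes[rng.integers(n_codes)]
        t = base + pd.Timedelta(days=int(rng.integers(0, 15000)))
        if numeric[code]:
            rows.append(("px", t, code, f"{rng.uniform(1, 200):.1f}", "numeric", "u"))
        else:
            rows.append(("px", t, code, rng.choice(["A", "B", "C"]), "categorical", ""))
    rec = make_records(rows)
    return rec.sort_values(["patient_id", "time"], kind="stable", ignore_index=True)
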