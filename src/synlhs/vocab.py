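"""Synthetic medical-code vocabulary.

The nuisance (non-risk, non-target) event vocabulary emulates the coded
content of a Synthea export: SNOMED-CT-style condition / procedure /
medication / immunization / allergy codes and LOINC-style observation
codes, the latter split into numeric labs (value + unit) and categorical
assessments.  Per-code popularity follows a Zipf-like law so that
patient-occurrence counts span a wide range, which is what makes an
occurrence-based variable-selection cutoff meaningful downstream.

The vocabulary is a deterministic function of its size: every call with
the same ``n_codes`` returns the identical table, independently of any
population seed.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd

# fraction of the vocabulary allotted to each domain
_DOMAIN_SHARES = {
    "conditions": 0.28,
    "observations_numeric": 0.30,
    "observations_categorical": 0.08,
    "procedures": 0.15,
    "medications": 0.12,
    "immunizations": 0.03,
    "allergies": 0.04,
}

_UNITS = ["mg/dL", "mmol/L", "g/dL", "%", "mmHg", "kg/m2", "U/L", "10*3/uL"]

_CATEGORY_POOLS = [
    ("low", "normal", "high"),
    ("negative", "positive"),
    ("absent", "present"),
    ("never", "former", "current"),
    ("mild", "moderate", "severe"),
]

#: LOINC code and default conversion anchor for serum total cholesterol;
#: guaranteed to be present in every vocabulary so the documented
#: <200 mg/dL -> "normal" rule always has a column to act on.
CHOLESTEROL_CODE = "2093-3"

_VOCAB_SEED = 20221026  # fixed: the vocabulary is part of the schema, not of a draw


@lru_cache(maxsize=8)
def build_vocabulary(n_codes: int = 760) -> pd.DataFrame:
    """Return the nuisance-code table.

    Columns: code, name, domain, datatype, unit, mu, sigma, categories,
    weight.  ``weight`` sums to 1 and drives event sampling.
    """
    if n_codes < 50:
        raise ValueError("vocabulary needs at least 50 codes")
    rng = np.random.default_rng(_VOCAB_SEED)

    counts = {d: max(1, int(round(s * n_codes))) for d, s in _DOMAIN_SHARES.items()}
    # absorb rounding drift into the condition block
    counts["conditions"] += n_codes - sum(counts.values())

    rows = []
    serial = 0
    for domain, k in counts.items():
        for _ in range(k):
            serial += 1
            if domain.startswith("observations"):
                code = f"{10000 + serial}-{serial % 10}"
            else:
                code = str(100000000 + 7919 * serial)
            if domain == "observations_numeric":
                mu = float(np.round(rng.lognormal(mean=3.5, sigma=1.0), 1))
                rows.append(
                    dict(
                        code=code,
                        name=f"Lab result {code}",
                        domain="observations",
                        datatype="numeric",
                        unit=_UNITS[serial % len(_UNITS)],
                        mu=mu,
                        sigma=max(0.1, round(0.15 * mu, 2)),
                        categories=(),
                    )
                )
            elif domain == "observations_categorical":
                pool = _CATEGORY_POOLS[serial % len(_CATEGORY_POOLS)]
                rows.append(
                    dict(
                        code=code,
                        name=f"Assessment {code}",
                        domain="observations",
                        datatype="categorical",
                        unit="",
                        mu=np.nan,
                        sigma=np.nan,
                        categories=pool,
                    )
                )
            else:
                rows.append(
                    dict(
                        code=code,
                        name=f"{domain[:-1].capitalize()} {code}",
                        domain=domain,
                        datatype="categorical",
                        unit="",
                        mu=np.nan,
                        sigma=np.nan,
                        categories=("present",),
                    )
                )

    vocab = pd.DataFrame(rows)

    # pin total cholesterol onto the first numeric-observation slot
    i = vocab.index[(vocab.domain == "observations") & (vocab.datatype == "numeric")][0]
    vocab.loc[i, ["code", "name", "unit", "mu", "sigma"]] = [
        CHOLESTEROL_CODE,
        "Total cholesterol",
        "mg/dL",
        195.0,
        35.0,
    ]

    # Zipf-like popularity, rank order shuffled across domains
    ranks = rng.permutation(len(vocab))
    w = 1.0 / np.power(ranks + 3.0, 0.85)
    vocab["weight"] = w / w.sum()
    return vocab
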