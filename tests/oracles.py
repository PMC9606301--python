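"""Independent brute-force reference implementations.

Deliberately naive (per-row loops, no pandas groupby tricks) so they can
serve as oracles for the vectorized pipeline operations.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd


def latest_value_profile(records: pd.DataFrame, cutoff, disease_codes) -> dict:
    """Last value per code among records strictly before the cutoff time."""
    out = {}
    for _, row in records.iterrows():
        if row["time"] < cutoff and row["code"] not in disease_codes:
            out[row["code"]] = row["value"]
    return out


def mode_mean_profile(records: pd.DataFrame, birthdate, start_age, end_age) -> dict:
    """Per-code mode (lexicographic ties) / mean inside the age window."""
    per_code: dict[str, list] = {}
    dtypes: dict[str, str] = {}
    for _, row in records.iterrows():
        age = (row["time"] - birthdate) / pd.Timedelta(days=365.25)
        if start_age <= age <= end_age:
            per_code.setdefault(row["code"], []).append(row["value"])
            dtypes[row["code"]] = row["datatype"]
    out = {}
    for code, vals in per_code.items():
        if dtypes[code] == "numeric":
            out[code] = float(np.mean([float(v) for v in vals]))
        else:
            counts = Counter(vals)
            top = max(counts.values())
            out[code] = min(v for v, k in counts.items() if k == top)
    return out


def balance_filter(frame: pd.DataFrame, code_columns, min_codes: int) -> list:
    """Row labels surviving the background code-count filter."""
    keep = []
    for idx, row in frame.iterrows():
        if row["label"] == 1:
            keep.append(idx)
        else:
            n = sum(pd.notna(row[c]) for c in code_columns)
            if n >= min_codes:
                keep.append(idx)
    return keep


def select_by_occurrence(frame: pd.DataFrame, code_columns, cutoff: int, n_top=None) -> list:
    occ = {}
    for c in code_columns:
        occ[c] = int(frame[c].notna().sum())
    passing = [c for c in code_columns if occ[c] >= cutoff]
    passing.sort(key=lambda c: (-occ[c], c))
    return passing[:n_top] if n_top is not None else passing


def confusion_metrics(y_true, y_prob, threshold=0.5) -> dict:
    tp = fp = tn = fn = 0
    for yt, yp in zip(y_true, y_prob):
        pred = 1 if yp >= threshold else 0
        if pred == 1 and yt == 1:
            tp += 1
        elif pred == 1 and yt == 0:
            fp += 1
        elif pred == 0 and yt == 0:
            tn += 1
        else:
            fn += 1
    # AUC as the rank statistic: P(score_pos > score_neg) + 0.5 P(tie)
    pos = [p for yt, p in zip(y_true, y_prob) if yt == 1]
    neg = [p for yt, p in zip(y_true, y_prob) if yt == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    auc = (wins + 0.5 * ties) / (len(pos) * len(neg))
    return {
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "accuracy": (tp + tn) / len(list(y_true)),
        "auc": auc,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
    }


def grid_search_auc(make_estimator, param_grid: dict, X, y, cv) -> tuple[dict, dict]:
    """Exhaustive loop over grid combinations with explicit CV folds."""
    from itertools import product

    from sklearn.metrics import roc_auc_score

    keys = list(param_grid)
    results = {}
    for combo in product(*(param_grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        scores = []
        for tr, te in cv.split(X, y):
            est = make_estimator(params)
            est.fit(X[tr], y[tr])
            scores.append(roc_auc_score(y[te], est.predict_proba(X[te])[:, 1]))
        results[tuple(sorted(params.items()))] = float(np.mean(scores))
    best = max(results, key=lambda k: results[k])
    return dict(best), results
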