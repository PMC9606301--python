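"""ROC and reliability-curve output (CSV point lists + PNG figures)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .modeling import ReliabilityCurve


def save_roc(points: pd.DataFrame, stem: str | Path, title: str = "ROC curve") -> None:
    """Write <stem>.csv and <stem>.png for a roc_points() frame."""
    stem = Path(stem)
    points.to_csv(stem.with_suffix(".csv"), index=False)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(points["fpr"], points["tpr"], lw=1.5)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(stem.with_suffix(".png"), dpi=120)
    plt.close(fig)


def save_reliability(curve: ReliabilityCurve, stem: str | Path, title: str = "Reliability curve") -> None:
    """Write <stem>.csv and <stem>.png for a reliability curve."""
    stem = Path(stem)
    pd.DataFrame(
        {
            "bin_lower": curve.bin_edges[:-1],
            "bin_upper": curve.bin_edges[1:],
            "mean_predicted": curve.mean_predicted,
            "observed_fraction": curve.observed_fraction,
            "count": curve.counts,
        }
    ).to_csv(stem.with_suffix(".csv"), index=False)
    filled = curve.counts > 0
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8, label="perfect")
    ax.plot(
        np.asarray(curve.mean_predicted)[filled],
        np.asarray(curve.observed_fraction)[filled],
        marker="o",
        lw=1.2,
        label=f"model (max dev {curve.max_deviation:.3f})",
    )
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed positive fraction")
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(stem.with_suffix(".png"), dpi=120)
    plt.close(fig)
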