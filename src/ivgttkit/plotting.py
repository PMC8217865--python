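"""Mean ± SEM time-course figures per experimental group."""

from __future__ import annotations

from typing import Iterable, List

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import curves_to_frame
from .types import IVGTTCurve


def group_timecourse_stats(curves: Iterable[IVGTTCurve]) -> pd.DataFrame:
    """Per-(group, time) mean and SEM of glucose and insulin."""
    df = curves_to_frame(curves)
    df["group"] = df["genotype"] + "/" + df["treatment"] + df["arm"].map(
        lambda a: "" if a is None or (isinstance(a, float) and np.isnan(a)) else f"/{a}"
    )

    def sem(x):
        x = x.dropna()
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) >= 2 else np.nan

    out = (
        df.groupby(["group", "time_min"])
        .agg(
            glucose_mean=("glucose_mmol_l", "mean"),
            glucose_sem=("glucose_mmol_l", sem),
            insulin_mean=("insulin_pmol_l", "mean"),
            insulin_sem=("insulin_pmol_l", sem),
            n=("animal_id", "count"),
        )
        .reset_index()
    )
    return out


def plot_cohort_timecourses(curves: Iterable[IVGTTCurve], path) -> pd.DataFrame:
    """Two-panel figure (glucose above, insulin below), one line per group.

    SEM error bars are drawn where a group has at least two animals.
    Returns the plotted per-group statistics.
    """
    stats = group_timecourse_stats(curves)
    fig, axes = plt.subplots(2, 1, figsize=(7, 8), sharex=True)
    for group, sub in stats.groupby("group"):
        sub = sub.sort_values("time_min")
        axes[0].errorbar(
            sub["time_min"], sub["glucose_mean"], yerr=sub["glucose_sem"],
            marker="o", capsize=3, label=group,
        )
        axes[1].errorbar(
            sub["time_min"], sub["insulin_mean"], yerr=sub["insulin_sem"],
            marker="o", capsize=3, label=group,
        )
    axes[0].set_ylabel("Glucose (mmol/l)")
    axes[1].set_ylabel("Insulin (pmol/l)")
    axes[1].set_xlabel("Time (min)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return stats
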