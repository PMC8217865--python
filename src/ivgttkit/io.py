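"""Readers and writers for the tidy IVGTT interchange CSV and results tables.

The interchange format is long ("tidy"): one row per (animal, time) with
columns ``animal_id, genotype, treatment, time_min, glucose_mmol_l,
insulin_pmol_l`` and an optional ``arm`` column carrying the experimental-arm
label.  Values round-trip through ``read`` / ``write`` exactly for times and
to at least 6 significant digits for concentrations.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import Genotype, IVGTTCurve, SchemaError, Treatment, ValidationError

REQUIRED_COLUMNS = [
    "animal_id",
    "genotype",
    "treatment",
    "time_min",
    "glucose_mmol_l",
    "insulin_pmol_l",
]
OPTIONAL_COLUMNS = ["arm"]


def read_ivgtt_csv(path) -> List[IVGTTCurve]:
    """Read a tidy IVGTT CSV into one validated curve per animal.

    Rows are grouped by ``animal_id`` and sorted by time.  Curve invariants
    (strictly increasing times starting at 0, positive glucose, baseline
    insulin present) are enforced; a violation raises
    :class:`~ivgttkit.types.ValidationError` naming the animal.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If an animal has duplicated times, no t=0 sample, inconsistent
        metadata, or otherwise invalid values.
    """
    df = pd.read_csv(path, dtype={"animal_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    has_arm = "arm" in df.columns

    curves: List[IVGTTCurve] = []
    for animal_id, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("time_min")
        times = sub["time_min"].to_numpy(dtype=float)
        if len(np.unique(times)) != len(times):
            raise ValidationError(f"animal {animal_id!r}: duplicated (animal, time) row")
        for col in ("genotype", "treatment"):
            if sub[col].nunique() != 1:
                raise ValidationError(f"animal {animal_id!r}: inconsistent {col} across rows")
        try:
            genotype = Genotype(sub["genotype"].iloc[0])
            treatment = Treatment(sub["treatment"].iloc[0])
        except ValueError as exc:
            raise ValidationError(f"animal {animal_id!r}: {exc}") from exc
        arm = None
        if has_arm:
            raw = sub["arm"].iloc[0]
            arm = None if (isinstance(raw, float) and math.isnan(raw)) else str(raw)
        curves.append(
            IVGTTCurve(
                animal_id=str(animal_id),
                genotype=genotype,
                treatment=treatment,
                times=times,
                glucose=sub["glucose_mmol_l"].to_numpy(dtype=float),
                insulin=sub["insulin_pmol_l"].to_numpy(dtype=float),
                arm=arm,
            )
        )
    return curves


def curves_to_frame(curves: Iterable[IVGTTCurve]) -> pd.DataFrame:
    """Flatten curves into the tidy long-format DataFrame."""
    rows = []
    for c in curves:
        for t, g, i in zip(c.times, c.glucose, c.insulin):
            rows.append(
                {
                    "animal_id": c.animal_id,
                    "genotype": c.genotype.value,
                    "treatment": c.treatment.value,
                    "time_min": t,
                    "glucose_mmol_l": g,
                    "insulin_pmol_l": i,
                    "arm": c.arm,
                }
            )
    return pd.DataFrame(rows, columns=REQUIRED_COLUMNS[:3] + REQUIRED_COLUMNS[3:] + OPTIONAL_COLUMNS)


def write_ivgtt_csv(curves: Iterable[IVGTTCurve], path) -> None:
    """Write curves as tidy long-format CSV, one row per sample.

    An empty collection yields a header-only file.  Concentrations are
    written with 10 significant digits so that read-back agrees to well
    beyond assay precision.
    """
    df = curves_to_frame(curves)
    if df.empty:
        df = pd.DataFrame(columns=REQUIRED_COLUMNS + OPTIONAL_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


def format_mean_sem(mean: float, sem: Optional[float], decimals: int) -> str:
    """Render a ``mean ± SEM`` cell at a fixed number of decimals."""
    if sem is None or not np.isfinite(sem):
        return f"{mean:.{decimals}f}"
    return f"{mean:.{decimals}f} ± {sem:.{decimals}f}"


def format_p(p: Optional[float]) -> str:
    if p is None or not np.isfinite(p):
        return ""
    if p < 0.001:
        return "<0.001"
    return f"{p:.3f}"


def write_results_table(table, path, fmt: str = "csv") -> None:
    """Write a group-comparison results table as CSV or aligned text.

    Each row is one metric: ``label, <group A> mean ± SEM, P, <group B>
    mean ± SEM``, at the per-metric decimal precision carried by the table
    rows.

    Parameters
    ----------
    table : ResultsTable
    fmt : {"csv", "text"}
    """
    df = table.to_frame()
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "text":
        widths = {c: max(len(str(c)), df[c].astype(str).str.len().max() if len(df) else 0) for c in df.columns}
        lines = ["  ".join(str(c).ljust(widths[c]) for c in df.columns)]
        for _, row in df.iterrows():
            lines.append("  ".join(str(row[c]).ljust(widths[c]) for c in df.columns))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'text'")
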