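"""Group summaries and pairwise comparisons for IVGTT cohorts.

Groups are summarised as mean ± SEM (sample SD with n-1 denominator over
sqrt(n)) and compared with the classical equal-variance unpaired Student's
t-test.  Insulin concentrations in mice are right-skewed, so insulin-level
metrics are compared on the natural-log scale when every value is positive;
when a group contains non-positive values (suprabasal insulin AUCs after
diazoxide are negative) the untransformed test is used and flagged.  A Welch
switch exists but is off by default.  No multiple-testing correction is
applied; each metric row carries its own P value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import format_mean_sem, format_p
from .types import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "ResultsTable",
    "TableRow",
    "MetricSpec",
    "TABLE1_METRICS",
    "summarize_group",
    "compare_groups",
    "build_results_table",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SEM of one metric in one group; SEM is None for n < 2."""

    label: str
    metric: str
    n: int
    mean: float
    sem: Optional[float]


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sided unpaired t-test between two groups on one metric."""

    metric: str
    label_a: str
    label_b: str
    t: float
    df: float
    p: float
    log_transformed: bool
    note: str = ""


def summarize_group(values: Sequence[float], label: str, metric: str) -> GroupSummary:
    """Mean and SEM of the finite values of one metric in one group."""
    v = np.asarray([x for x in values if x is not None], dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValidationError(f"group {label!r}, metric {metric!r}: no finite values")
    sem = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) >= 2 else None
    return GroupSummary(label=label, metric=metric, n=int(len(v)), mean=float(np.mean(v)), sem=sem)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    metric: str,
    log_transform: Union[bool, str] = False,
    label_a: str = "A",
    label_b: str = "B",
    welch: bool = False,
) -> ComparisonResult:
    """Two-sided unpaired t-test (equal-variance by default).

    ``log_transform`` may be ``True`` (require positive values, error
    otherwise), ``False``, or ``"auto"`` (transform only when every value in
    both groups is positive; otherwise fall back to the untransformed test
    with a note).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(f"metric {metric!r}: each group needs >= 2 finite values")

    note = ""
    all_positive = bool(np.all(a > 0) and np.all(b > 0))
    if log_transform is True:
        if not all_positive:
            raise ValidationError(f"metric {metric!r}: non-positive value under log transform")
        used_log = True
    elif log_transform == "auto":
        used_log = all_positive
        if not used_log:
            note = "log transform skipped: non-positive values present"
            logger.warning("%s: %s", metric, note)
    elif log_transform is False:
        used_log = False
    else:
        raise ValueError(f"log_transform must be True, False or 'auto', got {log_transform!r}")

    xa, xb = (np.log(a), np.log(b)) if used_log else (a, b)
    res = sps.ttest_ind(xa, xb, equal_var=not welch)
    return ComparisonResult(
        metric=metric,
        label_a=label_a,
        label_b=label_b,
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        log_transformed=used_log,
        note=note,
    )


@dataclass(frozen=True)
class MetricSpec:
    """Display rule for one table row: label, decimals, transform policy."""

    key: str
    label: str
    decimals: int
    log_transform: Union[bool, str] = False
    scale: float = 1.0


# Row order and formatting of the vehicle/diazoxide results tables.  S_I is
# displayed scaled by 1e4; insulin-derived metrics use the auto log policy.
TABLE1_METRICS: List[MetricSpec] = [
    MetricSpec("baseline_glucose", "Baseline glucose (mmol/l)", 1),
    MetricSpec("baseline_insulin", "Baseline insulin (pmol/l)", 0, log_transform="auto"),
    MetricSpec("auc_glucose_suprabasal", "Suprabasal AUC glucose (mmol/l min)", 0),
    MetricSpec("auc_insulin_suprabasal", "Suprabasal AUC insulin (nmol/l min)", 2, log_transform="auto"),
    MetricSpec("kg", "K_G (%/min)", 2),
    MetricSpec("s_g", "S_G (1/min)", 3),
    MetricSpec("s_i", "S_I (1e-4/min per pmol/l)", 2, log_transform="auto", scale=1e4),
    MetricSpec("beta_cell_sensitivity", "Beta-cell sensitivity (nmol/mmol)", 3),
]


@dataclass(frozen=True)
class TableRow:
    spec: MetricSpec
    summary_a: GroupSummary
    comparison: ComparisonResult
    summary_b: GroupSummary


@dataclass
class ResultsTable:
    """Ordered metric rows for one two-group contrast."""

    label_a: str
    label_b: str
    rows: List[TableRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            d = row.spec.decimals
            s = row.spec.scale
            records.append(
                {
                    "metric": row.spec.label,
                    self.label_a: format_mean_sem(
                        row.summary_a.mean * s,
                        None if row.summary_a.sem is None else row.summary_a.sem * s,
                        d,
                    ),
                    "P": format_p(row.comparison.p),
                    self.label_b: format_mean_sem(
                        row.summary_b.mean * s,
                        None if row.summary_b.sem is None else row.summary_b.sem * s,
                        d,
                    ),
                }
            )
        return pd.DataFrame(records, columns=["metric", self.label_a, "P", self.label_b])


def build_results_table(
    values_a: Dict[str, Sequence[float]],
    values_b: Dict[str, Sequence[float]],
    label_a: str,
    label_b: str,
    metrics: Optional[List[MetricSpec]] = None,
) -> ResultsTable:
    """Assemble a two-group results table in fixed row order.

    ``values_a`` / ``values_b`` map metric key to the per-animal values of
    each group.  A metric absent (or without enough finite values) in either
    group is dropped with a logged warning rather than aborting the table.
    """
    metrics = metrics if metrics is not None else TABLE1_METRICS
    table = ResultsTable(label_a=label_a, label_b=label_b)
    for spec in metrics:
        if spec.key not in values_a or spec.key not in values_b:
            logger.warning("metric %r missing in one group; row dropped", spec.key)
            continue
        try:
            sa = summarize_group(values_a[spec.key], label_a, spec.key)
            sb = summarize_group(values_b[spec.key], label_b, spec.key)
            cmp_ = compare_groups(
                np.asarray([x for x in values_a[spec.key] if x is not None], dtype=float),
                np.asarray([x for x in values_b[spec.key] if x is not None], dtype=float),
                spec.key,
                log_transform=spec.log_transform,
                label_a=label_a,
                label_b=label_b,
            )
        except ValidationError as exc:
            logger.warning("metric %r dropped: %s", spec.key, exc)
            continue
        table.rows.append(TableRow(spec=spec, summary_a=sa, comparison=cmp_, summary_b=sb))
    return table
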