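"""End-to-end cohort analysis: curves -> per-animal summaries -> results tables.

Each knockout group is compared only with the wildtype control group from
the same experimental arm and treatment (concurrent controls), mirroring the
study design; pooled cross-arm comparisons are never formed.
Per-animal failures (unfittable curves, missing windows) are quarantined and
counted rather than aborting the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .metrics import summarize_animal
from .minimal_model import FitConfig, FitError, fit_minimal_model
from .stats import TABLE1_METRICS, ResultsTable, build_results_table
from .types import Genotype, IVGTTCurve, Treatment, ValidationError

logger = logging.getLogger(__name__)

METRIC_KEYS = [
    "baseline_glucose",
    "baseline_insulin",
    "auc_glucose_suprabasal",
    "auc_insulin_suprabasal",
    "kg",
    "s_g",
    "s_i",
    "beta_cell_sensitivity",
]


@dataclass
class AnalysisResult:
    summaries: pd.DataFrame
    tables: List[Tuple[str, ResultsTable]]
    n_failed_fits: int


def summarize_cohort(
    curves: Iterable[IVGTTCurve],
    fit_config: Optional[FitConfig] = None,
    kg_window: Tuple[float, float] = (5.0, 20.0),
    t_end: float = 50.0,
) -> Tuple[pd.DataFrame, int]:
    """Fit and summarise every animal; returns (summary frame, fit-failure count)."""
    rows = []
    n_failed = 0
    for curve in curves:
        fit = None
        try:
            fit = fit_minimal_model(curve, fit_config)
        except (FitError, ValidationError) as exc:
            n_failed += 1
            logger.warning("fit failed for animal %s: %s", curve.animal_id, exc)
        s = summarize_animal(curve, fit, kg_window=kg_window, t_end=t_end)
        rows.append(
            {
                "animal_id": s.animal_id,
                "arm": curve.arm,
                "genotype": curve.genotype.value,
                "treatment": curve.treatment.value,
                "baseline_glucose": s.baselines.G_b,
                "baseline_insulin": s.baselines.I_b,
                "auc_glucose_suprabasal": s.auc_glucose_suprabasal,
                "auc_insulin_suprabasal": s.auc_insulin_suprabasal,
                "kg": s.kg,
                "s_g": s.s_g,
                "s_i": s.s_i,
                "beta_cell_sensitivity": s.beta_cell_sensitivity,
                "fit_ok": s.fit_ok,
                "notes": "; ".join(f"{k}: {v}" for k, v in s.missing.items()),
            }
        )
    return pd.DataFrame(rows), n_failed


def _metric_values(sub: pd.DataFrame) -> Dict[str, np.ndarray]:
    return {k: sub[k].to_numpy(dtype=float) for k in METRIC_KEYS}


def contrast_tables(summaries: pd.DataFrame) -> List[Tuple[str, ResultsTable]]:
    """Build one wildtype-vs-knockout table per (arm, treatment) contrast."""
    tables: List[Tuple[str, ResultsTable]] = []
    for (arm, treatment), sub in summaries.groupby(["arm", "treatment"], dropna=False):
        wt = sub[sub["genotype"] == Genotype.WT.value]
        for ko_genotype in (Genotype.GIPR_KO, Genotype.GLP1R_KO):
            ko = sub[sub["genotype"] == ko_genotype.value]
            if len(wt) == 0 or len(ko) == 0:
                continue
            label_a = f"WT ({treatment})"
            label_b = f"{ko_genotype.value} ({treatment})"
            table = build_results_table(
                _metric_values(wt), _metric_values(ko), label_a, label_b, TABLE1_METRICS
            )
            name = f"{ko_genotype.value.lower()}_vs_wt_{treatment}"
            if arm is not None and not (isinstance(arm, float) and np.isnan(arm)):
                name = f"{name}_{arm}"
            tables.append((name, table))
    return tables


def analyze_cohort(
    curves: Iterable[IVGTTCurve],
    fit_config: Optional[FitConfig] = None,
    kg_window: Tuple[float, float] = (5.0, 20.0),
    t_end: float = 50.0,
) -> AnalysisResult:
    """Run the full pipeline on a collection of curves."""
    curves = list(curves)
    if not curves:
        raise ValidationError("empty cohort: no curves to analyze")
    summaries, n_failed = summarize_cohort(curves, fit_config, kg_window, t_end)
    tables = contrast_tables(summaries)
    return AnalysisResult(summaries=summaries, tables=tables, n_failed_fits=n_failed)
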