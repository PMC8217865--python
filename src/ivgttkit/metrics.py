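"""Model-free per-animal IVGTT metrics.

Covers the glucose tolerance index K_G (log-linear elimination slope over
minutes 5–20), suprabasal trapezoid AUCs over the 50-min test, and beta-cell
glucose sensitivity (insulin AUC over glucose AUC), plus assembly of all
metrics into one :class:`~ivgttkit.types.AnimalSummary` per animal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .types import AnimalSummary, IVGTTCurve, ValidationError
from .minimal_model import MinimalModelFit

__all__ = [
    "KGResult",
    "compute_kg",
    "suprabasal_auc",
    "beta_cell_sensitivity",
    "summarize_animal",
]


@dataclass(frozen=True)
class KGResult:
    """Glucose elimination rate from the log-linear slope.

    ``kg`` is in %/min; positive when glucose falls over the window.
    ``r_squared`` is the coefficient of determination of the ln(G)-vs-t
    ordinary least-squares regression.
    """

    kg: float
    window: Tuple[float, float]
    n_points: int
    r_squared: float


def compute_kg(curve: IVGTTCurve, window: Tuple[float, float] = (5.0, 20.0)) -> KGResult:
    """Net glucose elimination rate K_G over the closed window (default [5, 20] min).

    K_G = -100 * b where b is the OLS slope of ln(glucose) against time over
    the samples inside the window.  The 1-min peak sample lies outside the
    default window and does not enter the regression.

    Raises
    ------
    ValidationError
        If fewer than 2 samples fall inside the window.
    """
    lo, hi = window
    mask = (curve.times >= lo) & (curve.times <= hi)
    t = curve.times[mask]
    g = curve.glucose[mask]
    if len(t) < 2:
        raise ValidationError(
            f"animal {curve.animal_id!r}: need >= 2 samples in [{lo}, {hi}] min for K_G, got {len(t)}"
        )
    res = sps.linregress(t, np.log(g))
    return KGResult(
        kg=float(-100.0 * res.slope),
        window=(float(lo), float(hi)),
        n_points=int(len(t)),
        r_squared=float(res.rvalue**2),
    )


def suprabasal_auc(times: Sequence[float], values: Sequence[float], t_end: float = 50.0) -> float:
    """Trapezoid integral of (value - baseline) from 0 to the last sample <= t_end.

    The baseline is the single t = 0 value.  The result may be negative when
    the series falls below baseline (as insulin does after diazoxide).
    Missing (NaN) values are dropped before integration; the baseline must
    be present.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t[0] != 0.0:
        raise ValidationError("suprabasal AUC needs the t=0 baseline sample first")
    keep = np.isfinite(v) & (t <= t_end)
    t, v = t[keep], v[keep]
    if len(t) < 2 or t[0] != 0.0:
        raise ValidationError("suprabasal AUC needs a finite baseline and >= 1 later sample")
    return float(np.trapezoid(v - v[0], t))


def beta_cell_sensitivity(curve: IVGTTCurve, t_end: float = 50.0) -> Optional[float]:
    """Suprabasal insulin AUC (nmol/l·min) over suprabasal glucose AUC (mmol/l·min).

    Returns ``None`` when the glucose AUC is zero (ratio undefined).
    """
    auc_g = suprabasal_auc(curve.times, curve.glucose, t_end)
    auc_i_nmol = suprabasal_auc(curve.times, curve.insulin, t_end) / 1000.0
    if auc_g == 0.0:
        return None
    return auc_i_nmol / auc_g


def summarize_animal(
    curve: IVGTTCurve,
    fit: Optional[MinimalModelFit] = None,
    kg_window: Tuple[float, float] = (5.0, 20.0),
    t_end: float = 50.0,
) -> AnimalSummary:
    """Assemble all per-animal metrics; components that fail are recorded as
    missing with a reason, never silently zeroed."""
    summary = AnimalSummary(animal_id=curve.animal_id, baselines=curve.baselines)

    try:
        summary.kg = compute_kg(curve, kg_window).kg
    except ValidationError as exc:
        summary.missing["kg"] = str(exc)

    try:
        summary.auc_glucose_suprabasal = suprabasal_auc(curve.times, curve.glucose, t_end)
    except ValidationError as exc:
        summary.missing["auc_glucose_suprabasal"] = str(exc)
    try:
        summary.auc_insulin_suprabasal = suprabasal_auc(curve.times, curve.insulin, t_end) / 1000.0
    except ValidationError as exc:
        summary.missing["auc_insulin_suprabasal"] = str(exc)

    if summary.auc_glucose_suprabasal is not None and summary.auc_insulin_suprabasal is not None:
        if summary.auc_glucose_suprabasal != 0.0:
            summary.beta_cell_sensitivity = summary.auc_insulin_suprabasal / summary.auc_glucose_suprabasal
        else:
            summary.missing["beta_cell_sensitivity"] = "suprabasal glucose AUC is zero"
    else:
        summary.missing["beta_cell_sensitivity"] = "component AUC missing"

    if fit is not None and fit.converged:
        # a fit pinned at a kinetic bound is reported but never accepted as
        # an estimate: p1 at either bound, or p3 at its upper bound, marks a
        # degenerate solution where insulin action absorbs the whole decay
        pinned = "p1" in fit.at_bound or ("p3" in fit.at_bound and fit.params.p3 > 5e-4)
        if pinned:
            reason = f"parameter(s) pinned at optimizer bound: {', '.join(fit.at_bound)}"
            summary.missing["s_g"] = reason
            summary.missing["s_i"] = reason
        else:
            summary.s_g = fit.s_g
            summary.s_i = fit.s_i
            summary.fit_ok = True
            if not fit.si_identifiable:
                summary.missing["s_i_identifiability"] = fit.message
    else:
        summary.missing["s_g"] = "no converged minimal-model fit"
        summary.missing["s_i"] = "no converged minimal-model fit"

    return summary
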