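"""Domain types for intravenous glucose tolerance test (IVGTT) experiments.

The central object is :class:`IVGTTCurve`: one animal's sampled blood-glucose
and plasma-insulin time course after an intravenous glucose bolus, together
with its genotype and pretreatment.  Units are fixed throughout the package:
time in minutes, glucose in mmol/l, insulin in pmol/l.  There is no unit
auto-detection.

A missing insulin value at a post-injection time point is allowed (stored as
NaN); glucose must be present at every sample because both the elimination
slope and the kinetic fit require it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np


class Genotype(str, Enum):
    """Mouse genotype: wildtype or incretin-receptor knockout."""

    WT = "WT"
    GIPR_KO = "GIPR_KO"
    GLP1R_KO = "GLP1R_KO"


class Treatment(str, Enum):
    """Pretreatment before the glucose bolus."""

    VEHICLE = "vehicle"
    DIAZOXIDE = "diazoxide"


class ValidationError(ValueError):
    """A curve or table violates a structural invariant."""


class SchemaError(ValueError):
    """An input file does not match the expected column schema."""


@dataclass(frozen=True)
class Baselines:
    """Pre-injection (t = 0) glucose and insulin levels.

    Attributes
    ----------
    G_b : float
        Baseline blood glucose, mmol/l.  Must be positive.
    I_b : float
        Baseline plasma insulin, pmol/l.  Must be non-negative.
    """

    G_b: float
    I_b: float

    def __post_init__(self) -> None:
        if not (self.G_b > 0):
            raise ValidationError(f"baseline glucose must be > 0, got {self.G_b}")
        if not (self.I_b >= 0):
            raise ValidationError(f"baseline insulin must be >= 0, got {self.I_b}")


@dataclass(frozen=True)
class IVGTTCurve:
    """One animal's IVGTT time series.

    Parameters
    ----------
    animal_id : str
        Unique animal identifier.
    genotype : Genotype
    treatment : Treatment
    times : array of float
        Sampling times in minutes, strictly increasing, first element 0
        (the pre-injection sample).
    glucose : array of float
        Blood glucose in mmol/l, one value per time, all positive.
    insulin : array of float
        Plasma insulin in pmol/l; NaN marks a missing sample.  The t = 0
        value must be present (it defines the insulin baseline).
    arm : str, optional
        Experimental-arm label used to pair each knockout group with its
        concurrent wildtype control group.  Purely metadata.
    """

    animal_id: str
    genotype: Genotype
    treatment: Treatment
    times: np.ndarray
    glucose: np.ndarray
    insulin: np.ndarray
    arm: Optional[str] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        g = np.asarray(self.glucose, dtype=float)
        i = np.asarray(self.insulin, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "glucose", g)
        object.__setattr__(self, "insulin", i)
        who = f"animal {self.animal_id!r}"
        if not (len(t) == len(g) == len(i)):
            raise ValidationError(f"{who}: times/glucose/insulin lengths differ")
        if len(t) < 2:
            raise ValidationError(f"{who}: need at least 2 samples, got {len(t)}")
        if not np.all(np.isfinite(t)):
            raise ValidationError(f"{who}: non-finite time value")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"{who}: times not strictly increasing")
        if t[0] != 0.0:
            raise ValidationError(f"{who}: missing t=0 pre-injection sample")
        if not np.all(np.isfinite(g)) or np.any(g <= 0):
            raise ValidationError(f"{who}: glucose must be finite and > 0 at every sample")
        if np.any(i[np.isfinite(i)] < 0):
            raise ValidationError(f"{who}: negative insulin value")
        if not np.isfinite(i[0]):
            raise ValidationError(f"{who}: missing insulin at t=0 (baseline)")

    @property
    def baselines(self) -> Baselines:
        return Baselines(G_b=float(self.glucose[0]), I_b=float(self.insulin[0]))

    @property
    def n_samples(self) -> int:
        return len(self.times)


@dataclass
class AnimalSummary:
    """Per-animal derived metrics.

    A metric that could not be computed is ``None`` with the reason recorded
    in :attr:`missing`; values are never silently zeroed.

    Units: ``kg`` %/min; AUC glucose mmol/l·min; AUC insulin nmol/l·min;
    beta-cell sensitivity (nmol/l·min)/(mmol/l·min); ``s_g`` 1/min;
    ``s_i`` 1/min per pmol/l (tables report it scaled by 1e4).
    """

    animal_id: str
    baselines: Baselines
    kg: Optional[float] = None
    auc_glucose_suprabasal: Optional[float] = None
    auc_insulin_suprabasal: Optional[float] = None
    beta_cell_sensitivity: Optional[float] = None
    s_g: Optional[float] = None
    s_i: Optional[float] = None
    fit_ok: bool = False
    missing: dict = field(default_factory=dict)
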