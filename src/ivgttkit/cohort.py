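"""Synthetic IVGTT cohort generator.

No raw per-animal data accompany the study this package re-implements, so
every pipeline stage is exercised against synthetic cohorts that emulate the
study design: 5-h-fasted mice receive 0.35 g/kg intravenous glucose (after
vehicle or 25 mg/kg diazoxide) and are sampled at 0, 1, 5, 10, 20 and 50
min.  Each simulated animal draws its kinetic parameters log-normally around
published group means, secretes insulin along a first-phase pulse (vehicle)
or a suppressed decline (diazoxide), has its glucose trajectory generated by
the minimal model, and is observed with multiplicative assay noise.

Built-in design profiles:

* ``"table1"`` — the four vehicle groups (two wildtype control groups, GIP
  receptor KO, GLP-1 receptor KO; n = 11, 12, 10, 17).
* ``"table2"`` — the four diazoxide groups (n = 11, 11, 6, 7), with raised
  glucose baselines and near-abolished dynamic insulin.
* ``"toy"`` — a 2-group, 3-animal miniature for fast tests.

Between-animal coefficients of variation are back-solved from the published
SEMs at the published group sizes (CV = SEM·sqrt(n)/mean), so cohorts have
dispersion of roughly the reported magnitude; exact SEM reproduction is not
attempted because the biological/assay variance split is unknowable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .minimal_model import MinimalModelParams, PiecewiseLinearForcing, simulate_minimal_model
from .types import Genotype, IVGTTCurve, Treatment, ValidationError

__all__ = [
    "GroupGeneratorParams",
    "NoiseModel",
    "CohortDesign",
    "Cohort",
    "insulin_curve",
    "generate_animal",
    "generate_cohort",
    "default_design",
    "load_design",
    "save_design",
    "PUBLISHED_SG_VEHICLE_SERIES",
    "PUBLISHED_KG_VEHICLE_SERIES",
]

# Published vehicle-series group means (full series, pooled over experiments):
# glucose effectiveness S_G (1/min) and elimination rate K_G (%/min) with n.
PUBLISHED_SG_VEHICLE_SERIES = {
    "WT": (0.0646, 28),
    "GIPR_KO": (0.0521, 17),
    "GLP1R_KO": (0.037, 12),
}
PUBLISHED_KG_VEHICLE_SERIES = {
    "WT": (1.78, 28),
    "GIPR_KO": (1.43, 17),
    "GLP1R_KO": (0.96, 12),
}


def _cv(mean: float, sem: float, n: int) -> float:
    """Between-animal CV implied by a published mean ± SEM at group size n."""
    return sem * math.sqrt(n) / abs(mean)


@dataclass
class NoiseModel:
    """Multiplicative measurement noise and insulin assay floor.

    Defaults follow the assay characteristics: insulin ELISA intra-assay CV
    4% with a lower limit of quantification of 6 pmol/l; glucometer CV 2%
    (typical strip-based glucose oxidase precision).
    """

    glucose_cv: float = 0.02
    insulin_cv: float = 0.04
    insulin_lloq: float = 6.0
    censor_at_lloq: bool = True

    def __post_init__(self) -> None:
        if self.glucose_cv < 0 or self.insulin_cv < 0 or self.insulin_lloq < 0:
            raise ValidationError("noise CVs and LLOQ must be >= 0")


@dataclass
class GroupGeneratorParams:
    """Generating distribution of one experimental group.

    Means are the group-level targets; ``*_cv`` are between-animal
    log-normal coefficients of variation (0 means every animal is at the
    mean).  Insulin secretion: under vehicle a first-phase pulse
    I_b + A·(t/t_p)·exp(1 - t/t_p) peaking at I_b + A at t_p (default 1
    min); under diazoxide a monotone decline I_b·[1 - d·(1 - exp(-t/tau))]
    toward I_b·(1 - d), giving the negative suprabasal insulin AUCs seen
    after insulin-secretion blockade.
    """

    label: str
    genotype: Genotype
    treatment: Treatment
    arm: str
    n_animals: int
    G_b_mean: float
    G_b_cv: float
    I_b_mean: float
    I_b_cv: float
    S_G_mean: float
    S_G_cv: float
    S_I_mean: float
    S_I_cv: float
    dG0_mean: float = 12.0
    dG0_cv: float = 0.15
    pulse_A_mean: float = 0.0
    pulse_A_cv: float = 0.0
    pulse_tp: float = 1.0
    diazoxide_d_mean: float = 0.0
    diazoxide_d_cv: float = 0.0
    diazoxide_tau: float = 10.0
    p2_mean: float = 0.05
    p2_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.n_animals < 0:
            raise ValidationError("n_animals must be >= 0")
        for name in ("G_b_mean", "I_b_mean", "S_G_mean", "S_I_mean", "dG0_mean",
                     "pulse_A_mean", "diazoxide_d_mean", "p2_mean"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("G_b_cv", "I_b_cv", "S_G_cv", "S_I_cv", "dG0_cv",
                     "pulse_A_cv", "diazoxide_d_cv"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class CohortDesign:
    """Full generator configuration: groups, noise, schedule, seed."""

    groups: List[GroupGeneratorParams]
    noise: NoiseModel = field(default_factory=NoiseModel)
    times: Tuple[float, ...] = (0.0, 1.0, 5.0, 10.0, 20.0, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 not in self.times:
            raise ValidationError("sampling times must include 0")


class Cohort:
    """Generated curves plus the true per-animal generating parameters."""

    def __init__(self, curves: List[IVGTTCurve], truth: pd.DataFrame, design: CohortDesign):
        self.curves = curves
        self.truth = truth
        self.design = design

    def __iter__(self) -> Iterator[IVGTTCurve]:
        return iter(self.curves)

    def __len__(self) -> int:
        return len(self.curves)


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Mean-preserving log-normal draw; degenerate at the mean for cv = 0."""
    if mean == 0.0 or cv == 0.0:
        return mean
    sigma2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)))


def insulin_curve(
    I_b: float,
    treatment: Treatment,
    pulse_A: float = 0.0,
    pulse_tp: float = 1.0,
    diazoxide_d: float = 0.0,
    diazoxide_tau: float = 10.0,
) -> Callable[[float], float]:
    """Noise-free insulin time course for one animal."""
    if treatment is Treatment.VEHICLE:

        def curve(t):
            t = np.asarray(t, dtype=float)
            return I_b + pulse_A * (t / pulse_tp) * np.exp(1.0 - t / pulse_tp)

    else:

        def curve(t):
            t = np.asarray(t, dtype=float)
            return I_b * (1.0 - diazoxide_d * (1.0 - np.exp(-t / diazoxide_tau)))

    return curve


def pulse_suprabasal_auc(pulse_A: float, pulse_tp: float, t_end: float = 50.0) -> float:
    """Exact suprabasal AUC of the first-phase pulse over [0, t_end], pmol/l·min."""
    u = t_end / pulse_tp
    return pulse_A * math.e * pulse_tp * (1.0 - (1.0 + u) * math.exp(-u))


def decline_suprabasal_auc(I_b: float, d: float, tau: float, t_end: float = 50.0) -> float:
    """Exact suprabasal AUC of the diazoxide decline over [0, t_end], pmol/l·min."""
    return -I_b * d * (t_end - tau * (1.0 - math.exp(-t_end / tau)))


def generate_animal(
    group: GroupGeneratorParams,
    noise: NoiseModel,
    times: Sequence[float],
    rng: np.random.Generator,
    animal_id: Optional[str] = None,
) -> Tuple[IVGTTCurve, Dict[str, float]]:
    """Draw one animal, simulate its IVGTT, and observe it with assay noise.

    Returns the observed curve and a record of the true drawn parameters.
    The t = 0 samples report baseline glucose and insulin with measurement
    noise only; post-injection glucose comes from the minimal model driven
    by the animal's noise-free insulin curve, with G0 = G_b + ΔG0.
    """
    times = np.asarray(sorted(times), dtype=float)
    G_b = _lognormal(rng, group.G_b_mean, group.G_b_cv)
    I_b = _lognormal(rng, group.I_b_mean, group.I_b_cv)
    S_G = _lognormal(rng, group.S_G_mean, group.S_G_cv)
    S_I = _lognormal(rng, group.S_I_mean, group.S_I_cv)
    dG0 = _lognormal(rng, group.dG0_mean, group.dG0_cv)
    p2 = _lognormal(rng, group.p2_mean, group.p2_cv)
    pulse_A = _lognormal(rng, group.pulse_A_mean, group.pulse_A_cv)
    d = min(_lognormal(rng, group.diazoxide_d_mean, group.diazoxide_d_cv), 1.0)

    forcing = insulin_curve(
        I_b,
        group.treatment,
        pulse_A=pulse_A,
        pulse_tp=group.pulse_tp,
        diazoxide_d=d,
        diazoxide_tau=group.diazoxide_tau,
    )
    params = MinimalModelParams(
        p1=S_G, p2=p2, p3=S_I * p2, G0=G_b + dG0, G_b=G_b, I_b=I_b
    )
    insulin_true = np.asarray(forcing(times), dtype=float)
    insulin_true[times == 0.0] = I_b
    # Glucose is driven by the piecewise-linear interpolant of the *sampled*
    # insulin values — the same forcing representation the fitting stage
    # reconstructs — so that noise-free cohorts are exactly fittable and
    # parameter recovery is testable without interpolation bias.
    sampled_forcing = PiecewiseLinearForcing(times, insulin_true)
    glucose_true = simulate_minimal_model(params, sampled_forcing, times)
    glucose_true[times == 0.0] = G_b  # observed t=0 sample is pre-injection

    glucose_obs = glucose_true.copy()
    insulin_obs = insulin_true.copy()
    if noise.glucose_cv > 0:
        sg = math.sqrt(math.log(1.0 + noise.glucose_cv**2))
        glucose_obs *= rng.lognormal(-sg * sg / 2.0, sg, size=len(times))
    if noise.insulin_cv > 0:
        si = math.sqrt(math.log(1.0 + noise.insulin_cv**2))
        insulin_obs *= rng.lognormal(-si * si / 2.0, si, size=len(times))
    if noise.censor_at_lloq:
        insulin_obs = np.maximum(insulin_obs, noise.insulin_lloq)

    aid = animal_id if animal_id is not None else f"{group.label}-000"
    curve = IVGTTCurve(
        animal_id=aid,
        genotype=group.genotype,
        treatment=group.treatment,
        times=times,
        glucose=glucose_obs,
        insulin=insulin_obs,
        arm=group.arm,
    )
    truth = {
        "animal_id": aid,
        "group": group.label,
        "G_b": G_b,
        "I_b": I_b,
        "S_G": S_G,
        "S_I": S_I,
        "p2": p2,
        "G0": G_b + dG0,
        "pulse_A": pulse_A,
        "diazoxide_d": d,
    }
    return curve, truth


def generate_cohort(design: CohortDesign) -> Cohort:
    """Generate the full cohort; one top-level seed fixes every draw."""
    rng = np.random.default_rng(design.seed)
    curves: List[IVGTTCurve] = []
    truths: List[Dict[str, float]] = []
    for group in design.groups:
        for k in range(group.n_animals):
            aid = f"{group.label}-{k + 1:03d}"
            curve, truth = generate_animal(group, design.noise, design.times, rng, animal_id=aid)
            curves.append(curve)
            truths.append(truth)
    truth_df = pd.DataFrame(truths) if truths else pd.DataFrame(
        columns=["animal_id", "group", "G_b", "I_b", "S_G", "S_I", "p2", "G0", "pulse_A", "diazoxide_d"]
    )
    return Cohort(curves, truth_df, design)


# ---------------------------------------------------------------------------
# Design profiles calibrated to the published group means.
# Each entry: (mean, sem) at the published group size n; CVs are back-solved.
# ---------------------------------------------------------------------------

_E = math.e
_TAU = 10.0
_AUC_FACTOR = 50.0 - _TAU * (1.0 - math.exp(-50.0 / _TAU))  # decline AUC / (I_b * d)


def _vehicle_group(label, genotype, arm, n, gb, ib, auc_i_nmol, sg, si4):
    """One vehicle group; the pulse amplitude is calibrated so the noise-free
    suprabasal insulin AUC over 0-50 min hits the published group mean."""
    auc_pmol = auc_i_nmol[0] * 1000.0
    A = auc_pmol / (_E * 1.0)  # pulse AUC ≈ A·e·t_p over 0-50 min (t_p = 1)
    return GroupGeneratorParams(
        label=label,
        genotype=genotype,
        treatment=Treatment.VEHICLE,
        arm=arm,
        n_animals=n,
        G_b_mean=gb[0], G_b_cv=_cv(gb[0], gb[1], n),
        I_b_mean=ib[0], I_b_cv=_cv(ib[0], ib[1], n),
        S_G_mean=sg[0], S_G_cv=_cv(sg[0], sg[1], n),
        S_I_mean=si4[0] * 1e-4, S_I_cv=_cv(si4[0], si4[1], n),
        pulse_A_mean=A, pulse_A_cv=_cv(auc_i_nmol[0], auc_i_nmol[1], n),
    )


def _diazoxide_group(label, genotype, arm, n, gb, ib, auc_i_nmol, sg, si4):
    """One diazoxide group; the suppression depth d is calibrated so the
    noise-free suprabasal insulin AUC matches the published (negative) mean."""
    d = min(abs(auc_i_nmol[0]) * 1000.0 / (ib[0] * _AUC_FACTOR), 1.0)
    return GroupGeneratorParams(
        label=label,
        genotype=genotype,
        treatment=Treatment.DIAZOXIDE,
        arm=arm,
        n_animals=n,
        G_b_mean=gb[0], G_b_cv=_cv(gb[0], gb[1], n),
        I_b_mean=ib[0], I_b_cv=_cv(ib[0], ib[1], n),
        S_G_mean=sg[0], S_G_cv=_cv(sg[0], sg[1], n),
        S_I_mean=si4[0] * 1e-4, S_I_cv=_cv(si4[0], si4[1], n),
        diazoxide_d_mean=d, diazoxide_d_cv=_cv(auc_i_nmol[0], auc_i_nmol[1], n),
    )


def default_design(profile: str, seed: int = 0) -> CohortDesign:
    """A fully populated cohort design for a named profile.

    ``"table1"``: four vehicle groups whose generating means match the
    published baseline glucose/insulin, S_G and S_I columns (the GIP-KO
    suprabasal insulin AUC, whose published cell is a typesetting artifact,
    is set to 1.0 nmol/l·min, between the two wildtype groups).
    ``"table2"``: the four diazoxide groups (the wildtype S_G SEM printed as
    0.026, larger than its mean 0.011, is replaced by a plausible 0.003).
    ``"toy"``: a fast 2-group miniature.
    """
    if profile == "table1":
        groups = [
            _vehicle_group("WT-gip", Genotype.WT, "gip", 11,
                           (7.9, 0.3), (183, 10), (1.12, 0.22), (0.060, 0.010), (1.45, 0.11)),
            _vehicle_group("GIPRKO", Genotype.GIPR_KO, "gip", 12,
                           (8.2, 0.4), (246, 36), (1.00, 0.20), (0.052, 0.005), (1.11, 0.10)),
            _vehicle_group("WT-glp1", Genotype.WT, "glp1", 10,
                           (7.5, 0.4), (178, 14), (1.85, 0.43), (0.060, 0.007), (1.23, 0.14)),
            _vehicle_group("GLP1RKO", Genotype.GLP1R_KO, "glp1", 17,
                           (9.1, 0.3), (262, 21), (0.30, 0.05), (0.037, 0.006), (0.94, 0.12)),
        ]
    elif profile == "table2":
        groups = [
            _diazoxide_group("WT-gip-dz", Genotype.WT, "gip", 11,
                             (9.5, 0.5), (302, 33), (-3.43, 0.75), (0.012, 0.003), (0.26, 0.04)),
            _diazoxide_group("GIPRKO-dz", Genotype.GIPR_KO, "gip", 11,
                             (9.0, 0.4), (295, 20), (-1.56, 0.95), (0.016, 0.003), (0.48, 0.13)),
            _diazoxide_group("WT-glp1-dz", Genotype.WT, "glp1", 6,
                             (8.2, 0.4), (306, 57), (-3.93, 1.68), (0.011, 0.003), (0.19, 0.03)),
            _diazoxide_group("GLP1RKO-dz", Genotype.GLP1R_KO, "glp1", 7,
                             (13.0, 0.5), (168, 54), (-2.03, 1.68), (0.003, 0.001), (0.44, 0.14)),
        ]
    elif profile == "toy":
        groups = [
            _vehicle_group("WT-toy", Genotype.WT, "toy", 3,
                           (7.9, 0.3), (183, 10), (1.12, 0.22), (0.060, 0.010), (1.45, 0.11)),
            _vehicle_group("GLP1RKO-toy", Genotype.GLP1R_KO, "toy", 3,
                           (9.1, 0.3), (262, 21), (0.30, 0.05), (0.037, 0.006), (0.94, 0.12)),
        ]
    else:
        raise ValueError(f"unknown profile {profile!r}; expected 'table1', 'table2' or 'toy'")
    return CohortDesign(groups=groups, seed=seed)


# ---------------------------------------------------------------------------
# Design (de)serialisation
# ---------------------------------------------------------------------------

def design_to_dict(design: CohortDesign) -> dict:
    d = {
        "seed": design.seed,
        "times": list(design.times),
        "noise": asdict(design.noise),
        "groups": [],
    }
    for g in design.groups:
        gd = asdict(g)
        gd["genotype"] = g.genotype.value
        gd["treatment"] = g.treatment.value
        d["groups"].append(gd)
    return d


def design_from_dict(d: dict) -> CohortDesign:
    groups = []
    for gd in d["groups"]:
        gd = dict(gd)
        gd["genotype"] = Genotype(gd["genotype"])
        gd["treatment"] = Treatment(gd["treatment"])
        groups.append(GroupGeneratorParams(**gd))
    return CohortDesign(
        groups=groups,
        noise=NoiseModel(**d.get("noise", {})),
        times=tuple(d.get("times", (0.0, 1.0, 5.0, 10.0, 20.0, 50.0))),
        seed=int(d.get("seed", 0)),
    )


def save_design(design: CohortDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)


def load_design(path) -> CohortDesign:
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))
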