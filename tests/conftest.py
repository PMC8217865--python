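import numpy as np
import pytest

from ivgttkit.cohort import insulin_curve
from ivgttkit.minimal_model import (
    MinimalModelParams,
    PiecewiseLinearForcing,
    simulate_piecewise_linear,
)
from ivgttkit.types import Genotype, IVGTTCurve, Treatment

SCHEDULE = np.array([0.0, 1.0, 5.0, 10.0, 20.0, 50.0])


@pytest.fixture
def schedule():
    return SCHEDULE.copy()


def make_synthetic_curve(
    s_g=0.060,
    s_i=1.45e-4,
    p2=0.05,
    g_b=7.9,
    g0=19.9,
    i_b=183.0,
    pulse_a=412.0,
    times=SCHEDULE,
    animal_id="wt-001",
    genotype=Genotype.WT,
):
    """Noise-free curve generated by the minimal model itself.

    Insulin follows a first-phase pulse sampled at the schedule; glucose is
    driven by the piecewise-linear interpolant of those samples, so the fit
    model can reproduce the data exactly.
    """
    pulse = insulin_curve(i_b, Treatment.VEHICLE, pulse_A=pulse_a, pulse_tp=1.0)
    insulin = np.asarray(pulse(times), dtype=float)
    insulin[0] = i_b
    forcing = PiecewiseLinearForcing(times, insulin)
    params = MinimalModelParams(p1=s_g, p2=p2, p3=s_i * p2, G0=g0, G_b=g_b, I_b=i_b)
    glucose = simulate_piecewise_linear(params, forcing, times)
    glucose = np.asarray(glucose, dtype=float)
    glucose[times == 0.0] = g_b
    return IVGTTCurve(
        animal_id=animal_id,
        genotype=genotype,
        treatment=Treatment.VEHICLE,
        times=times,
        glucose=glucose,
        insulin=insulin,
    )


@pytest.fixture
def wildtype_curve():
    return make_synthetic_curve()
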