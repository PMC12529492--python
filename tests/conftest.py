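import numpy as np
import pytest

from metaclamp.cohort import FENG_SHAPE, feng_shape
from metaclamp.records import SubjectProfile, TimeActivityCurve

#: all stochastic channels silenced
NOISELESS = {"tac": 0.0, "gir": 0.0, "glucose": 0.0, "insulin": 0.0,
             "assay": 0.0, "dose": 0.0}


@pytest.fixture
def noiseless():
    return dict(NOISELESS)


@pytest.fixture
def profile():
    """A hand-built LL subject with round-number physiology."""
    return SubjectProfile(
        subject_id="S0001",
        group="LL",
        sex="F",
        age=48.0,
        bmi=25.0,
        weight=68.0,
        body_surface_area=1.75,
        htg_percent=0.9,
        vat_mass=2.0,
        basal_egp=11.0,
        egp_suppression=0.95,
        insulin_disposal=38.0,
        kinetic_params={
            "muscle": (0.08, 0.22, 0.045),
            "liver": (0.85, 0.98, 0.0037),
            "asat": (0.025, 0.12, 0.009),
        },
        fasting_insulin=35.0,
        fasting_glucose=5.6,
        fasting_ffa=0.5,
        fasting_glycerol=0.06,
        ogtt_sensitivity=1.0,
    )


def make_feng_plasma(scale: float = 30.0, t_max: float = 90.0,
                     dt: float = 0.05) -> TimeActivityCurve:
    """Fine-grid plasma curve from the parametric bolus + washout shape."""
    times = np.arange(dt, t_max + dt / 2, dt)
    return TimeActivityCurve(times, scale * feng_shape(times), label="plasma")


@pytest.fixture
def feng_plasma():
    return make_feng_plasma()
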