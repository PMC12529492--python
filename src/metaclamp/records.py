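"""Core record types shared across the simulation and quantification stages.

Units are fixed throughout the package and embedded in field names where
ambiguity is possible: time in minutes, tracer activity in kBq/mL, glucose
in mmol/L, insulin in pmol/L, free fatty acids and glycerol in mmol/L,
glucose fluxes (GIR, Rd, EGP, M value) in umol/kg/min. Conversions are
always explicit operations, never implicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DataError

OGTT_TIMES = (0, 30, 60, 120)

#: Tissue regions quantified from the dynamic FDG scans.
REGIONS = ("muscle", "liver", "asat")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class TimeActivityCurve:
    """Tracer activity sampled over time in plasma or a tissue region.

    Parameters
    ----------
    times
        Sampling mid-times in minutes, strictly increasing, all >= 0.
    activities
        Decay-corrected activity concentration in kBq/mL.
    label
        ``"plasma"`` or a tissue-region name.
    """

    times: np.ndarray
    activities: np.ndarray
    label: str = "plasma"

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        activities = _as_float_array(self.activities, "activities")
        if times.size != activities.size:
            raise DataError("times and activities must have equal length")
        if times.size < 3:
            raise DataError("a time-activity curve needs at least 3 samples")
        if np.any(np.diff(times) <= 0):
            raise DataError("times must be strictly increasing")
        if times[0] < 0:
            raise DataError("times must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "activities", activities)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ClampRecord:
    """Hyperinsulinaemic-euglycaemic clamp trace for one subject.

    The glucose infusion rate (GIR) trace is recorded on the controller
    grid (piecewise-constant between updates); plasma glucose and insulin
    are sampled every 30 min as in standard clamp protocols.
    """

    subject_id: str
    gir_times: np.ndarray          # min
    gir_values: np.ndarray         # umol/kg/min
    glucose_times: np.ndarray      # min
    glucose_values: np.ndarray     # mmol/L
    insulin_times: np.ndarray      # min
    insulin_values: np.ndarray     # pmol/L
    weight: float                  # kg
    insulin_infusion_rate: float = 40.0  # mU/m^2/min

    def __post_init__(self):
        for name in ("gir_times", "gir_values", "glucose_times",
                     "glucose_values", "insulin_times", "insulin_values"):
            object.__setattr__(self, name, _as_float_array(getattr(self, name), name))
        if self.gir_times.size != self.gir_values.size:
            raise DataError("GIR trace times/values length mismatch")
        if np.any(self.gir_values < 0):
            raise DataError("GIR must be non-negative")
        if self.weight <= 0:
            raise DataError("weight must be positive")


@dataclass(frozen=True)
class OGTTRecord:
    """Glucose (mmol/L) and insulin (pmol/L) at the 0/30/60/120-min OGTT points."""

    glucose: Mapping[int, float]
    insulin: Mapping[int, float]

    def __post_init__(self):
        for name, series in (("glucose", self.glucose), ("insulin", self.insulin)):
            if set(series) != set(OGTT_TIMES):
                raise DataError(
                    f"OGTT {name} must be sampled exactly at {OGTT_TIMES} min"
                )
            if any(v <= 0 or not np.isfinite(v) for v in series.values()):
                raise DataError(f"OGTT {name} values must be positive and finite")
        object.__setattr__(self, "glucose", dict(self.glucose))
        object.__setattr__(self, "insulin", dict(self.insulin))


@dataclass(frozen=True)
class FastingSample:
    """Fasting plasma sample used by the insulin-resistance indices."""

    glucose: float               # mmol/L
    insulin: float               # pmol/L
    ffa: float = 0.0             # mmol/L
    glycerol: float | None = None  # mmol/L

    def __post_init__(self):
        if not (self.glucose > 0 and np.isfinite(self.glucose)):
            raise DataError("fasting glucose must be positive")
        if not (self.insulin > 0 and np.isfinite(self.insulin)):
            raise DataError("fasting insulin must be positive")
        if self.ffa < 0:
            raise DataError("fasting FFA must be non-negative")


@dataclass
class SubjectProfile:
    """Ground-truth physiological parameters driving every simulator.

    ``group`` is assigned from the liver-triglyceride fraction measured by
    MRS: ``LL`` for <= 1.85 % and ``MEL`` for > 1.85 % and <= 5.56 %.
    ``kinetic_params`` maps each PET region to the irreversible
    two-tissue-compartment rate constants (K1 mL/min/mL, k2 1/min, k3 1/min).
    ``insulin_disposal`` is the programmed whole-body insulin-stimulated
    glucose disposal at euglycaemia; together with ``basal_egp`` and
    ``egp_suppression`` it fixes the steady-state glucose infusion rate
    through the clamp mass balance GIR = disposal - EGP.
    """

    subject_id: str
    group: str                      # "LL" | "MEL"
    sex: str                        # "F" | "M"
    age: float                      # years
    bmi: float                      # kg/m^2
    weight: float                   # kg
    body_surface_area: float        # m^2
    htg_percent: float              # % liver triglyceride
    vat_mass: float                 # kg
    basal_egp: float                # umol/kg/min
    egp_suppression: float          # fraction in [0, 1]
    insulin_disposal: float         # umol/kg/min
    kinetic_params: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    fasting_insulin: float = 35.0   # pmol/L
    fasting_glucose: float = 5.3    # mmol/L
    fasting_ffa: float = 0.5        # mmol/L
    fasting_glycerol: float = 0.06  # mmol/L
    ogtt_sensitivity: float = 1.0   # dimensionless, LL median 1
    scan_timing_min: float = 60.0   # PET scan start relative to clamp start

    def validate(self) -> None:
        if self.group not in ("LL", "MEL"):
            raise DataError(f"unknown group {self.group!r}")
        if self.group == "LL" and not (0 < self.htg_percent <= 1.85):
            raise DataError("LL subjects must have htg_percent in (0, 1.85]")
        if self.group == "MEL" and not (1.85 < self.htg_percent <= 5.56):
            raise DataError("MEL subjects must have htg_percent in (1.85, 5.56]")
        if not 0.0 <= self.egp_suppression <= 1.0:
            raise DataError("egp_suppression must lie in [0, 1]")
        for region, (k1, k2, k3) in self.kinetic_params.items():
            if min(k1, k2, k3) <= 0:
                raise DataError(f"kinetic constants for {region} must be positive")
        for name in ("age", "bmi", "weight", "body_surface_area", "basal_egp",
                     "fasting_insulin", "fasting_glucose", "fasting_ffa"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if self.insulin_disposal < 0:
            raise DataError("insulin_disposal must be non-negative")

    @property
    def residual_egp(self) -> float:
        """EGP remaining under hyperinsulinaemia, basal_egp * (1 - suppression)."""
        return self.basal_egp * (1.0 - self.egp_suppression)


@dataclass(frozen=True)
class MetabolitePanel:
    """Quantified serum metabolite measures for one subject.

    All concentrations are strictly positive; the panel is simulated and
    analysed on the log scale.
    """

    subject_id: str
    measures: Mapping[str, float]

    def __post_init__(self):
        for name, value in self.measures.items():
            if not (value > 0 and np.isfinite(value)):
                raise DataError(f"measure {name} must be positive, got {value}")
        object.__setattr__(self, "measures", dict(self.measures))
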