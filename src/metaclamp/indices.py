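"""Fasting and OGTT-derived insulin sensitivity and secretion indices.

All indices follow their standard published formulas:

* HOMA-IR = glucose [mmol/L] x insulin [uU/mL] / 22.5
* simplified Matsuda ISI = 10,000 / sqrt(G0 x I0 x G120 x I120)
* first-phase secretion = AUC(insulin) / AUC(glucose) over 0-30 min
  (trapezoid on the 0 and 30 min points only)
* total-phase secretion = AUC(insulin) / AUC(glucose) over 0-120 min
  (trapezoid on the 0, 60 and 120 min points only)
* Adipo-IR = fasting insulin [pmol/L] x fasting FFA [mmol/L]
  (glycerol variant substitutes glycerol for FFA)

Insulin is carried in pmol/L throughout the package; conversion to the
uU/mL convention used by HOMA-IR (and the classic Matsuda convention) uses
an explicit, configurable factor of 6.00 pmol/L per uU/mL.
"""

from __future__ import annotations

import math

from .errors import ConfigurationError, DataError
from .records import FastingSample, OGTTRecord

#: pmol/L per uU/mL; configurable in every function that converts.
INSULIN_PMOL_PER_UU = 6.00

#: mg/dL per mmol/L of glucose.
GLUCOSE_MG_PER_MMOL = 18.016


def insulin_pmol_to_uu(insulin_pmol_l: float,
                       factor: float = INSULIN_PMOL_PER_UU) -> float:
    """Convert insulin from pmol/L to uU/mL."""
    if factor <= 0:
        raise ConfigurationError("insulin conversion factor must be positive")
    return insulin_pmol_l / factor


def insulin_uu_to_pmol(insulin_uu_ml: float,
                       factor: float = INSULIN_PMOL_PER_UU) -> float:
    """Convert insulin from uU/mL to pmol/L (exact inverse of the above)."""
    if factor <= 0:
        raise ConfigurationError("insulin conversion factor must be positive")
    return insulin_uu_ml * factor


def homa_ir(sample: FastingSample,
            insulin_factor: float = INSULIN_PMOL_PER_UU) -> float:
    """Homeostatic model assessment of insulin resistance (dimensionless)."""
    return sample.glucose * insulin_pmol_to_uu(sample.insulin, insulin_factor) / 22.5


def matsuda_isi(ogtt: OGTTRecord, units_mode: str = "si",
                insulin_factor: float = INSULIN_PMOL_PER_UU) -> float:
    """Simplified (two-point) Matsuda insulin sensitivity index.

    ``units_mode="si"`` evaluates the formula directly on mmol/L glucose
    and pmol/L insulin; ``"mgdl"`` first converts to the classic mg/dL and
    uU/mL convention. The index is homogeneous of degree -1/2 in each of
    its four inputs, so the two modes differ only by a constant factor.
    """
    g0, i0 = ogtt.glucose[0], ogtt.insulin[0]
    g120, i120 = ogtt.glucose[120], ogtt.insulin[120]
    if units_mode == "si":
        pass
    elif units_mode == "mgdl":
        g0, g120 = g0 * GLUCOSE_MG_PER_MMOL, g120 * GLUCOSE_MG_PER_MMOL
        i0 = insulin_pmol_to_uu(i0, insulin_factor)
        i120 = insulin_pmol_to_uu(i120, insulin_factor)
    else:
        raise ConfigurationError(f"units_mode must be 'si' or 'mgdl', got {units_mode!r}")
    return 10_000.0 / math.sqrt(g0 * i0 * g120 * i120)


def _trapezoid_auc(points: list[tuple[float, float]]) -> float:
    auc = 0.0
    for (t0, v0), (t1, v1) in zip(points, points[1:]):
        auc += 0.5 * (v0 + v1) * (t1 - t0)
    return auc


def secretion_first_phase(ogtt: OGTTRecord) -> float:
    """Insulin AUC / glucose AUC over 0-30 min (pmol/mmol).

    Uses exactly the 0 and 30 min points; a compensatory rise marks early
    beta-cell response to the oral load.
    """
    ins = _trapezoid_auc([(0, ogtt.insulin[0]), (30, ogtt.insulin[30])])
    glc = _trapezoid_auc([(0, ogtt.glucose[0]), (30, ogtt.glucose[30])])
    if glc <= 0:
        raise DataError("glucose AUC over 0-30 min must be positive")
    return ins / glc


def secretion_total_phase(ogtt: OGTTRecord) -> float:
    """Insulin AUC / glucose AUC over 0-120 min (pmol/mmol).

    Uses exactly the 0, 60 and 120 min points (the 30-min sample is not
    interpolated into this AUC).
    """
    ins = _trapezoid_auc([(0, ogtt.insulin[0]), (60, ogtt.insulin[60]),
                          (120, ogtt.insulin[120])])
    glc = _trapezoid_auc([(0, ogtt.glucose[0]), (60, ogtt.glucose[60]),
                          (120, ogtt.glucose[120])])
    if glc <= 0:
        raise DataError("glucose AUC over 0-120 min must be positive")
    return ins / glc


def adipo_ir(sample: FastingSample) -> float:
    """Adipose tissue insulin resistance: insulin [pmol/L] x FFA [mmol/L].

    The same product applies to clamp-state samples when the inputs are the
    clamp insulin and FFA levels.
    """
    return sample.insulin * sample.ffa


def adipo_ir_glycerol(sample: FastingSample) -> float:
    """Glycerol-based adipose insulin resistance: insulin x glycerol."""
    if sample.glycerol is None:
        raise DataError("glycerol measurement missing")
    if sample.glycerol < 0:
        raise DataError("glycerol must be non-negative")
    return sample.insulin * sample.glycerol
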