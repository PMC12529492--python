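"""Synthetic two-group metabolic cohort generator.

Emulates the data structure of a cross-sectional clamp + FDG-PET study of
people with low (LL, liver triglyceride <= 1.85 %) versus mildly elevated
(MEL, > 1.85 % and <= 5.56 %) liver lipid content: per-subject ground-truth
physiology, hyperinsulinaemic-euglycaemic clamp traces, dynamic FDG plasma
and tissue time-activity curves, OGTT excursions, and an NMR-style serum
metabolite panel with programmable group effects.

Every simulator is a pure function of its inputs and a seed, so the
downstream quantification and statistics stages are testable end-to-end
without any external data. Default parameters are calibrated so that
cohort summaries (group medians of liver fat, adipose insulin resistance,
clamp fluxes) fall in the range typical of non-diabetic European adults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .kinetics import solve_irreversible_2tc
from .records import (
    REGIONS,
    ClampRecord,
    MetabolitePanel,
    OGTTRecord,
    SubjectProfile,
    TimeActivityCurve,
)

# ---------------------------------------------------------------------------
# Outcome parameter tables
# ---------------------------------------------------------------------------
# Outcomes load on population-standardized log-BMI and on sex, so part of
# any raw group contrast is attributable to the covariate imbalance between
# groups (heavier, more often male MEL subjects) and is removed again by
# covariate adjustment downstream. The configured effect scales are
# therefore *residual* (covariate-independent) group effects. Base levels
# are chosen so that the LL-group medians land on values typical of
# non-diabetic European adults once the loadings are applied.
_BMI_REF_LOG = math.log(27.2)   # population log-BMI center
_BMI_REF_SCALE = 0.20           # population log-BMI SD
_MALE_FRACTION_REF = 0.30       # population male fraction

# Log-normal outcomes: name -> (base median, log-scale SD, BMI loading per
# population SD of log-BMI, additive male effect on the log scale).
_LOGNORMAL_OUTCOMES: dict[str, tuple[float, float, float, float]] = {
    "fasting_insulin": (37.8, 0.55, 0.30, 0.10),     # pmol/L
    "fasting_ffa": (0.547, 0.45, 0.10, -0.10),       # mmol/L
    "fasting_glycerol": (0.0607, 0.40, 0.10, -0.15), # mmol/L
    "insulin_disposal": (35.2, 0.30, -0.20, 0.00),   # umol/kg/min
    "egp_residual_fraction": (0.0954, 0.70, 0.15, 0.00),
    "ogtt_sensitivity": (0.908, 0.45, -0.25, 0.00),
    "vat_mass": (2.56, 0.55, 0.45, 0.35),            # kg
}

# Normal (additive) outcomes: name -> (LL mean, SD, BMI loading, male effect).
_NORMAL_OUTCOMES: dict[str, tuple[float, float, float, float]] = {
    "fasting_glucose": (5.60, 0.30, 0.08, 0.05),     # mmol/L
    "basal_egp": (11.0, 1.3, -0.30, 0.20),           # umol/kg/min
}

# Fasting glucose is kept above the clamp steady-state band (target + 0.3
# mmol/L) so that "reaching 5 mmol/L" is always a downward crossing, as in
# the clamp protocol the generator emulates.
_FASTING_GLUCOSE_RANGE = (5.45, 7.5)

#: Default standardized (per-SD) residual shifts applied to the MEL group,
#: i.e. the part of the group contrast that survives sex/age/BMI
#: adjustment. Signs follow the directional pattern expected with early
#: hepatic steatosis: poorer EGP suppression and lipolysis suppression
#: (insulin x FFA/glycerol products up), lower whole-body disposal and
#: OGTT sensitivity, and only small residual deficits in regional FDG
#: trapping or fasting glycaemia.
DEFAULT_EFFECT_SCALES: dict[str, float] = {
    "fasting_insulin": 0.10,
    "fasting_glucose": 0.10,
    "fasting_ffa": 0.32,
    "fasting_glycerol": 0.79,
    "insulin_disposal": -0.35,
    "egp_residual_fraction": 1.38,
    "ogtt_sensitivity": -0.52,
    "vat_mass": 0.10,
    "basal_egp": 0.0,
    "ki_muscle": -0.10,
    "ki_liver": -0.10,
    "ki_asat": -0.10,
}

#: Irreversible 2TC rate constants (K1 mL/min/mL, k2 1/min, k3 1/min) at the
#: LL median, per region, under hyperinsulinaemic euglycaemia.
KINETIC_DEFAULTS: dict[str, tuple[float, float, float]] = {
    "muscle": (0.080, 0.22, 0.045),
    "liver": (0.850, 0.98, 0.0037),
    "asat": (0.025, 0.12, 0.009),
}
_KINETIC_SIGMA = (0.15, 0.12, 0.12)  # log-scale SD of (K1, k2, k3)
# BMI loading of K1 (log units per population SD of log-BMI) per region:
# insulin-stimulated tracer delivery/uptake falls with adiposity.
_KINETIC_BMI_LOADING = {"muscle": -0.20, "liver": -0.05, "asat": -0.10}

# Liver-fat distributions per group: (median %, log-scale SD, low, high].
_HTG_PARAMS = {"LL": (0.9, 0.45, 0.0, 1.85), "MEL": (3.2, 0.37, 1.85, 5.56)}

DEFAULT_NOISE_LEVELS: dict[str, float] = {
    "tac": 0.05,      # multiplicative CV on tissue/plasma activities
    "gir": 0.03,      # CV on the recorded GIR trace
    "glucose": 0.015, # CV on clamp glucose samples
    "insulin": 0.06,  # CV on insulin samples
    "assay": 0.04,    # CV on OGTT glucose/insulin points
    "dose": 0.10,     # CV of the recorded dose/urine calibration, i.e. the
                      # per-subject systematic error of the clearance route
}

#: Default dynamic-scan sampling schedule (min): dense over the bolus peak,
#: sparser through the Patlak window out to 90 min.
DEFAULT_SAMPLING_TIMES: tuple[float, ...] = tuple(
    np.concatenate([
        np.arange(0.25, 3.01, 0.25),
        [4.0, 5.0, 6.0, 8.0, 10.0, 12.5, 15.0, 20.0, 25.0, 30.0,
         40.0, 50.0, 60.0, 75.0, 90.0],
    ])
)

DEFAULT_DOSE_MBQ = 155.0
DEFAULT_URINE_FRACTION = 0.10


# ---------------------------------------------------------------------------
# Metabolite panel definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasureDef:
    """One serum metabolite measure: LL median, log2-scale SD, default
    standardized MEL shift (log2-SD units) and its correlation block."""

    name: str
    ll_median: float
    sigma_log2: float
    effect_sd: float
    block: str


PANEL_DEFINITIONS: tuple[MeasureDef, ...] = (
    # triglycerides / VLDL axis
    MeasureDef("Serum_TG", 1.00, 0.55, 0.55, "vldl"),       # mmol/L
    MeasureDef("VLDL_TG", 0.55, 0.65, 0.55, "vldl"),        # mmol/L
    MeasureDef("VLDL_C", 0.70, 0.50, 0.45, "vldl"),         # mmol/L
    MeasureDef("VLDL_P", 55.0, 0.55, 0.45, "vldl"),         # nmol/L
    MeasureDef("Total_FA", 10.5, 0.25, 0.35, "vldl"),       # mmol/L
    # apoB axis
    MeasureDef("IDL_C", 0.75, 0.30, 0.35, "apob"),          # mmol/L
    MeasureDef("LDL_C", 1.60, 0.35, 0.35, "apob"),          # mmol/L
    MeasureDef("LDL_P", 1100.0, 0.32, 0.35, "apob"),        # nmol/L
    MeasureDef("ApoB", 0.90, 0.28, 0.40, "apob"),           # g/L
    # HDL axis (size decreases with MEL; cholesterol/ApoA1 null)
    MeasureDef("HDL_C", 1.50, 0.28, 0.00, "hdl"),           # mmol/L
    MeasureDef("ApoA1", 1.55, 0.18, 0.00, "hdl"),           # g/L
    MeasureDef("HDL_size", 9.80, 0.05, -0.45, "hdl"),       # nm
    # branched-chain amino acids
    MeasureDef("Ile", 55.0, 0.30, 0.55, "bcaa"),            # umol/L
    MeasureDef("Leu", 75.0, 0.25, 0.50, "bcaa"),            # umol/L
    MeasureDef("Val", 180.0, 0.25, 0.50, "bcaa"),           # umol/L
    # glycolysis-related / gluconeogenic substrates
    MeasureDef("Lactate", 0.95, 0.40, 0.40, "glyco"),       # mmol/L
    MeasureDef("Pyruvate", 0.070, 0.40, 0.40, "glyco"),     # mmol/L
    MeasureDef("Glycerol_NMR", 0.060, 0.45, 0.30, "glyco"), # mmol/L
    MeasureDef("Ala", 350.0, 0.22, 0.00, "glyco"),          # umol/L
    # fatty-acid composition (ratios to total fatty acids)
    MeasureDef("PUFA_pct", 38.0, 0.10, -0.45, "fa"),        # %
    MeasureDef("Omega6_pct", 32.0, 0.11, -0.40, "fa"),      # %
    MeasureDef("Omega3_pct", 4.5, 0.25, 0.00, "fa"),        # %
    # inflammation
    MeasureDef("GlycA", 1.25, 0.18, 0.45, "infl"),          # mmol/L
    # designated null measures
    MeasureDef("Gln", 550.0, 0.18, 0.00, "aa"),             # umol/L
    MeasureDef("His", 75.0, 0.15, 0.00, "aa"),              # umol/L
    MeasureDef("Phe", 80.0, 0.15, 0.00, "aa"),              # umol/L
    MeasureDef("Tyr", 65.0, 0.20, 0.00, "aa"),              # umol/L
    MeasureDef("Citrate", 0.11, 0.18, 0.00, "misc"),        # mmol/L
    MeasureDef("Acetate", 0.045, 0.30, 0.00, "misc"),       # mmol/L
    MeasureDef("Albumin", 45.0, 0.08, 0.00, "misc"),        # g/L
    MeasureDef("Creatinine", 70.0, 0.18, 0.00, "misc"),     # umol/L
)

PANEL_MEASURES: tuple[str, ...] = tuple(d.name for d in PANEL_DEFINITIONS)

DEFAULT_METABOLITE_EFFECTS: dict[str, float] = {
    d.name: d.effect_sd for d in PANEL_DEFINITIONS
}

# BMI loading (log2 units per SD of within-group log-BMI) per block.
_BLOCK_BMI_LOADING = {
    "vldl": 0.20, "apob": 0.15, "bcaa": 0.20, "glyco": 0.15,
    "hdl": -0.10, "fa": -0.05, "infl": 0.15, "aa": 0.0, "misc": 0.0,
}
_BLOCK_RHO = 0.6  # within-block correlation of the latent log2 scores


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the two-group cohort generator.

    ``effect_scales`` gives the standardized (per log-scale SD) shift each
    physiological outcome receives in the MEL group; ``metabolite_effects``
    does the same for the serum panel on the log2 scale. Setting every
    entry to zero (see :meth:`null`) makes the two groups statistically
    indistinguishable.
    """

    n_per_group: int = 101
    seed: int = 0
    effect_scales: Mapping[str, float] | None = None
    noise_levels: Mapping[str, float] | None = None
    sex_fraction_per_group: Mapping[str, float] | None = None  # fraction female
    bmi_params_per_group: Mapping[str, tuple[float, float]] | None = None
    metabolite_effects: Mapping[str, float] | None = None

    def resolved_effects(self) -> dict[str, float]:
        effects = dict(DEFAULT_EFFECT_SCALES)
        if self.effect_scales is not None:
            for key, value in self.effect_scales.items():
                if key not in DEFAULT_EFFECT_SCALES:
                    raise ConfigurationError(
                        f"effect_scales: unknown outcome {key!r}"
                    )
                effects[key] = float(value)
        return effects

    def resolved_noise(self) -> dict[str, float]:
        noise = dict(DEFAULT_NOISE_LEVELS)
        if self.noise_levels is not None:
            for key, value in self.noise_levels.items():
                if key not in DEFAULT_NOISE_LEVELS:
                    raise ConfigurationError(f"noise_levels: unknown channel {key!r}")
                noise[key] = float(value)
        return noise

    def resolved_sex_fractions(self) -> dict[str, float]:
        fractions = {"LL": 0.77, "MEL": 0.62}
        if self.sex_fraction_per_group is not None:
            fractions.update({k: float(v) for k, v in self.sex_fraction_per_group.items()})
        return fractions

    def resolved_bmi_params(self) -> dict[str, tuple[float, float]]:
        params = {"LL": (25.2, 0.19), "MEL": (29.4, 0.21)}
        if self.bmi_params_per_group is not None:
            params.update({k: (float(v[0]), float(v[1]))
                           for k, v in self.bmi_params_per_group.items()})
        return params

    def resolved_metabolite_effects(self) -> dict[str, float]:
        effects = dict(DEFAULT_METABOLITE_EFFECTS)
        if self.metabolite_effects is not None:
            for key, value in self.metabolite_effects.items():
                if key not in DEFAULT_METABOLITE_EFFECTS:
                    raise ConfigurationError(
                        f"metabolite_effects: unknown measure {key!r}"
                    )
                effects[key] = float(value)
        return effects

    def validate(self) -> None:
        if not isinstance(self.n_per_group, (int, np.integer)) or self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be an integer >= 2")
        for key, value in self.resolved_noise().items():
            if value < 0:
                raise ConfigurationError(f"noise_levels[{key!r}] must be >= 0")
        for group, frac in self.resolved_sex_fractions().items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(
                    f"sex_fraction_per_group[{group!r}] must lie in [0, 1]"
                )
        for group, (median, sigma) in self.resolved_bmi_params().items():
            if median <= 0 or sigma <= 0:
                raise ConfigurationError(
                    f"bmi_params_per_group[{group!r}] must have positive "
                    "location and scale"
                )
        self.resolved_effects()
        self.resolved_metabolite_effects()

    @classmethod
    def null(cls, n_per_group: int = 101, seed: int = 0, **kwargs) -> "CohortConfig":
        """A no-effect configuration: all group shifts zero and identical
        covariate (sex, BMI) distributions, so LL and MEL outcome
        distributions coincide exactly."""
        return cls(
            n_per_group=n_per_group,
            seed=seed,
            effect_scales={k: 0.0 for k in DEFAULT_EFFECT_SCALES},
            metabolite_effects={k: 0.0 for k in DEFAULT_METABOLITE_EFFECTS},
            sex_fraction_per_group={"LL": 0.70, "MEL": 0.70},
            bmi_params_per_group={"LL": (26.5, 0.20), "MEL": (26.5, 0.20)},
            **kwargs,
        )


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def _mult_noise(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    """Mean-preserving multiplicative log-normal noise at the given CV."""
    if cv <= 0:
        return values
    sigma = math.sqrt(math.log1p(cv * cv))
    return values * np.exp(rng.normal(0.0, sigma, size=np.shape(values))
                           - 0.5 * sigma * sigma)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _truncated_lognormal(rng, median: float, sigma: float,
                         low: float, high: float) -> float:
    for _ in range(1000):
        value = float(np.exp(np.log(median) + sigma * rng.standard_normal()))
        if low < value <= high:
            return value
    # pathological parameters: fall back to the interval midpoint
    return 0.5 * (low + high) if low > 0 else min(median, high)


def generate_cohort(config: CohortConfig) -> list[SubjectProfile]:
    """Generate ``2 * n_per_group`` subject profiles (LL first, then MEL).

    Identical config and seed give an identical cohort. Group membership is
    defined by the liver-triglyceride interval; the MEL group additionally
    receives the configured standardized shifts on each outcome's log (or
    natural) scale. BMI and sex loadings act on within-group standardized
    covariates, so the configured group medians are preserved while
    covariate adjustment downstream remains non-trivial.
    """
    config.validate()
    effects = config.resolved_effects()
    sex_fractions = config.resolved_sex_fractions()
    bmi_params = config.resolved_bmi_params()

    profiles: list[SubjectProfile] = []
    idx = 0
    for group in ("LL", "MEL"):
        is_mel = 1.0 if group == "MEL" else 0.0
        bmi_median, bmi_sigma = bmi_params[group]
        frac_female = sex_fractions[group]
        for _ in range(config.n_per_group):
            idx += 1
            rng = _rng(config.seed, idx)
            sex = "F" if rng.random() < frac_female else "M"
            is_male = 1.0 if sex == "M" else 0.0
            male_c = is_male - _MALE_FRACTION_REF  # population-centered

            age = float(np.clip(rng.normal(49.0, 11.0), 25.0, 75.0))
            bmi = float(np.exp(np.log(bmi_median) + bmi_sigma * rng.standard_normal()))
            z_bmi = (math.log(bmi) - _BMI_REF_LOG) / _BMI_REF_SCALE
            height_m = rng.normal(1.78, 0.07) if sex == "M" else rng.normal(1.66, 0.06)
            height_m = float(np.clip(height_m, 1.45, 2.05))
            weight = bmi * height_m**2
            bsa = 0.007184 * weight**0.425 * (height_m * 100.0) ** 0.725

            med, sigma, low, high = _HTG_PARAMS[group]
            htg = _truncated_lognormal(rng, med, sigma, low, high)

            values: dict[str, float] = {}
            for name, (ll_median, s, bmi_load, male_eff) in _LOGNORMAL_OUTCOMES.items():
                shift = effects.get(name, 0.0) * s * is_mel
                log_value = (math.log(ll_median) + shift
                             + bmi_load * z_bmi + male_eff * male_c
                             + s * rng.standard_normal())
                values[name] = float(np.exp(log_value))
            for name, (ll_mean, s, bmi_load, male_eff) in _NORMAL_OUTCOMES.items():
                shift = effects.get(name, 0.0) * s * is_mel
                values[name] = float(max(
                    0.1,
                    ll_mean + shift + bmi_load * z_bmi + male_eff * male_c
                    + s * rng.standard_normal(),
                ))
            values["fasting_glucose"] = float(
                np.clip(values["fasting_glucose"], *_FASTING_GLUCOSE_RANGE)
            )

            residual_fraction = min(1.0, values["egp_residual_fraction"])
            kinetic_params: dict[str, tuple[float, float, float]] = {}
            for region in REGIONS:
                k1_0, k2_0, k3_0 = KINETIC_DEFAULTS[region]
                s1, s2, s3 = _KINETIC_SIGMA
                k1_shift = (effects.get(f"ki_{region}", 0.0) * s1 * is_mel
                            + _KINETIC_BMI_LOADING[region] * z_bmi)
                k1 = k1_0 * math.exp(k1_shift + s1 * rng.standard_normal())
                k2 = k2_0 * math.exp(s2 * rng.standard_normal())
                k3 = k3_0 * math.exp(s3 * rng.standard_normal())
                kinetic_params[region] = (k1, k2, k3)

            profile = SubjectProfile(
                subject_id=f"S{idx:04d}",
                group=group,
                sex=sex,
                age=age,
                bmi=bmi,
                weight=float(weight),
                body_surface_area=float(bsa),
                htg_percent=htg,
                vat_mass=values["vat_mass"],
                basal_egp=values["basal_egp"],
                egp_suppression=1.0 - residual_fraction,
                insulin_disposal=values["insulin_disposal"],
                kinetic_params=kinetic_params,
                fasting_insulin=values["fasting_insulin"],
                fasting_glucose=values["fasting_glucose"],
                fasting_ffa=values["fasting_ffa"],
                fasting_glycerol=values["fasting_glycerol"],
                ogtt_sensitivity=values["ogtt_sensitivity"],
                scan_timing_min=float(rng.uniform(0.0, 120.0)),
            )
            profile.validate()
            profiles.append(profile)
    return profiles


# ---------------------------------------------------------------------------
# Clamp simulation
# ---------------------------------------------------------------------------

# Controller and plant constants. The glucose pool is 0.19 L/kg, i.e. 190
# umol/kg per mmol/L; insulin action ramps with an 8-min time constant. The
# controller mimics bedside clamp practice: every 5 min it estimates the
# net endogenous flux from the observed glucose drift and the infusion it
# applied (a disturbance observer, which supplies the integral action) and
# sets the next rate to cancel it plus a proportional correction toward the
# 5.0 mmol/L target.
_GLUCOSE_POOL = 190.0     # umol/kg per mmol/L
_TAU_EFFECT = 8.0         # min
_CTRL_KP = 20.0           # umol/kg/min per mmol/L
_CLAMP_INSULIN_SS = 420.0 # pmol/L rise at 40 mU/m^2/min


def simulate_clamp(
    profile: SubjectProfile,
    duration: float = 180.0,
    seed: int = 0,
    noise_levels: Mapping[str, float] | None = None,
    target: float = 5.0,
    insulin_infusion_rate: float = 40.0,
    dt_control: float = 5.0,
    dt_sim: float = 0.5,
) -> ClampRecord:
    """Simulate a hyperinsulinaemic-euglycaemic clamp for one subject.

    A discrete feedback controller servos plasma glucose to ``target`` by
    adjusting the glucose infusion rate every ``dt_control`` minutes,
    against a one-pool glucose plant in which insulin action (both
    stimulation of disposal and suppression of EGP) rises with an 8-min
    time constant. At steady state GIR equals
    ``insulin_disposal - basal_egp * (1 - egp_suppression)`` exactly (mass
    balance). Glucose and insulin samples are emitted every 30 min; the GIR
    trace is recorded on the controller grid.
    """
    profile.validate()
    if duration < 120.0:
        raise ConfigurationError(
            f"clamp duration {duration:g} min too short: steady state plus a "
            "60-min averaging window is unreachable in < 120 min"
        )
    noise = dict(DEFAULT_NOISE_LEVELS)
    if noise_levels is not None:
        noise.update(noise_levels)

    disposal = profile.insulin_disposal
    basal = profile.basal_egp
    suppression = profile.egp_suppression
    g_fast = profile.fasting_glucose

    n_steps = int(round(duration / dt_sim))
    times = np.arange(n_steps + 1) * dt_sim
    glucose = np.empty(n_steps + 1)
    glucose[0] = g_fast
    gir_times: list[float] = []
    gir_values: list[float] = []
    gir = 0.0
    flux_estimate = 0.0  # estimated EGP - Rd, umol/kg/min
    glucose_prev_ctrl = g_fast
    steps_per_ctrl = int(round(dt_control / dt_sim))
    for i in range(n_steps):
        t = times[i]
        if i % steps_per_ctrl == 0:
            if i > 0:
                flux_estimate = (_GLUCOSE_POOL * (glucose[i] - glucose_prev_ctrl)
                                 / dt_control - gir)
            glucose_prev_ctrl = glucose[i]
            gir = max(0.0, -flux_estimate - _CTRL_KP * (glucose[i] - target))
            gir_times.append(float(t))
            gir_values.append(gir)
        effect = 1.0 - math.exp(-t / _TAU_EFFECT)
        egp = basal * (1.0 - suppression * effect)
        rd = (basal * (1.0 - effect) * glucose[i] / g_fast
              + disposal * effect * glucose[i] / target)
        glucose[i + 1] = glucose[i] + dt_sim * (gir + egp - rd) / _GLUCOSE_POOL

    rng = _rng(int(profile.subject_id[1:]) if profile.subject_id[1:].isdigit() else 0,
               seed, 11)
    sample_times = np.arange(0.0, duration + 1e-9, 30.0)
    glucose_samples = np.interp(sample_times, times, glucose)
    glucose_samples = _mult_noise(rng, glucose_samples, noise["glucose"])
    insulin_rise = _CLAMP_INSULIN_SS * insulin_infusion_rate / 40.0
    insulin_samples = profile.fasting_insulin + insulin_rise * (
        1.0 - np.exp(-sample_times / 15.0)
    )
    insulin_samples = _mult_noise(rng, insulin_samples, noise["insulin"])
    gir_arr = _mult_noise(rng, np.asarray(gir_values), noise["gir"])

    return ClampRecord(
        subject_id=profile.subject_id,
        gir_times=np.asarray(gir_times),
        gir_values=gir_arr,
        glucose_times=sample_times,
        glucose_values=glucose_samples,
        insulin_times=sample_times,
        insulin_values=insulin_samples,
        weight=profile.weight,
        insulin_infusion_rate=insulin_infusion_rate,
    )


# ---------------------------------------------------------------------------
# Dynamic FDG study simulation
# ---------------------------------------------------------------------------

# Bolus + washout plasma input shape (Feng-type tri-exponential): zero at
# injection, sharp peak near 0.5 min, then bi-exponential washout.
FENG_SHAPE = {"a1": 800.0, "a2": 30.0, "a3": 12.0,
              "l1": 2.0, "l2": 0.25, "l3": 0.018}


def feng_shape(t: np.ndarray, p: Mapping[str, float] = FENG_SHAPE) -> np.ndarray:
    """Unit-scale tri-exponential bolus + washout input shape."""
    t = np.asarray(t, dtype=float)
    return ((p["a1"] * t - p["a2"] - p["a3"]) * np.exp(-p["l1"] * t)
            + p["a2"] * np.exp(-p["l2"] * t)
            + p["a3"] * np.exp(-p["l3"] * t))


def feng_shape_auc_inf(p: Mapping[str, float] = FENG_SHAPE) -> float:
    """Closed-form integral of :func:`feng_shape` over [0, inf)."""
    return (p["a1"] / p["l1"] ** 2 - (p["a2"] + p["a3"]) / p["l1"]
            + p["a2"] / p["l2"] + p["a3"] / p["l3"])


def simulate_fdg_study(
    profile: SubjectProfile,
    clamp: ClampRecord | None = None,
    sampling_times: Sequence[float] = DEFAULT_SAMPLING_TIMES,
    seed: int = 0,
    noise_levels: Mapping[str, float] | None = None,
    dose_mbq: float = DEFAULT_DOSE_MBQ,
    urine_fraction: float = DEFAULT_URINE_FRACTION,
    target_glucose: float = 5.0,
) -> tuple[TimeActivityCurve, dict[str, TimeActivityCurve], float, float]:
    """Simulate a dynamic FDG study during the clamp steady state.

    Returns ``(plasma_tac, {region: tissue_tac}, injected_dose_mbq,
    urine_activity_mbq)``. The plasma input is the parametric
    bolus + washout form scaled so that the urinary-loss-corrected plasma
    clearance equals the subject's programmed whole-body glucose disposal
    divided by the steady-state glucose level — i.e. the FDG-clearance
    route recovers the programmed disposal by construction. Tissue curves
    are the exact irreversible-2TC response to that input plus
    multiplicative noise at the configured CV.
    """
    profile.validate()
    sampling_times = np.asarray(sampling_times, dtype=float)
    if sampling_times.size < 3 or np.any(np.diff(sampling_times) <= 0):
        raise ConfigurationError("sampling_times must be >= 3 strictly increasing values")
    if sampling_times[0] < 0:
        raise ConfigurationError("sampling_times must start at or after injection")
    noise = dict(DEFAULT_NOISE_LEVELS)
    if noise_levels is not None:
        noise.update(noise_levels)
    if noise["tac"] < 0:
        raise ConfigurationError("noise_levels['tac'] must be >= 0")
    if not 0.0 <= urine_fraction < 1.0:
        raise ConfigurationError("urine_fraction must lie in [0, 1)")

    urine_mbq = urine_fraction * dose_mbq
    # programmed whole-body clearance (mL/min); glucose in mmol/L = umol/mL
    clearance = profile.insulin_disposal * profile.weight / target_glucose
    scale = (dose_mbq - urine_mbq) * 1000.0 / (clearance * feng_shape_auc_inf())

    rng = _rng(int(profile.subject_id[1:]) if profile.subject_id[1:].isdigit() else 0,
               seed, 23)
    # recorded dose/urine carry a shared calibration error (channel "dose"):
    # the quantified clearance — hence Rd — scales with this factor
    calib = float(_mult_noise(rng, np.asarray([1.0]), noise["dose"])[0])
    recorded_dose = dose_mbq * calib
    recorded_urine = urine_fraction * recorded_dose

    t_max = float(sampling_times[-1])
    fine = np.arange(0.0, t_max + 0.05, 0.05)
    cp_fine = scale * feng_shape(fine)
    plasma_fine = TimeActivityCurve(times=fine[1:], activities=cp_fine[1:],
                                    label="plasma")

    plasma_sampled = np.interp(sampling_times, fine, cp_fine)
    plasma_sampled = _mult_noise(rng, plasma_sampled, noise["tac"])
    plasma = TimeActivityCurve(times=sampling_times, activities=plasma_sampled,
                               label="plasma")

    tissues: dict[str, TimeActivityCurve] = {}
    for region in REGIONS:
        params = profile.kinetic_params.get(region)
        if params is None:
            continue
        clean = solve_irreversible_2tc(params, plasma_fine, sampling_times)
        noisy = _mult_noise(rng, clean.activities, noise["tac"])
        tissues[region] = TimeActivityCurve(times=sampling_times,
                                            activities=noisy, label=region)
    return plasma, tissues, recorded_dose, recorded_urine


# ---------------------------------------------------------------------------
# OGTT simulation
# ---------------------------------------------------------------------------

_OGTT_GLUCOSE_AMPLITUDE = 1.8   # mmol/L at ogtt_sensitivity = 1
_OGTT_INSULIN_AMPLITUDE = 130.0 # pmol/L at ogtt_sensitivity = 1


def simulate_ogtt(
    profile: SubjectProfile,
    seed: int = 0,
    noise_cv: float | None = None,
    glucose_amplitude: float | None = None,
    insulin_amplitude: float | None = None,
) -> OGTTRecord:
    """Simulate 75-g OGTT glucose/insulin at 0, 30, 60 and 120 min.

    Excursions above fasting follow gamma-like response curves peaking at
    45 min (glucose) and 60 min (insulin) whose amplitudes scale inversely
    with the subject's OGTT sensitivity scalar; passing an explicit zero
    amplitude gives the degenerate flat response.
    """
    profile.validate()
    s = profile.ogtt_sensitivity
    a_glc = _OGTT_GLUCOSE_AMPLITUDE / math.sqrt(s) if glucose_amplitude is None \
        else glucose_amplitude
    a_ins = _OGTT_INSULIN_AMPLITUDE / s if insulin_amplitude is None \
        else insulin_amplitude
    cv = DEFAULT_NOISE_LEVELS["assay"] if noise_cv is None else float(noise_cv)
    if cv < 0:
        raise ConfigurationError("noise_cv must be >= 0")

    rng = _rng(int(profile.subject_id[1:]) if profile.subject_id[1:].isdigit() else 0,
               seed, 37)
    times = np.array([0.0, 30.0, 60.0, 120.0])
    g_resp = (times / 45.0) * np.exp(1.0 - times / 45.0)
    i_resp = (times / 60.0) * np.exp(1.0 - times / 60.0)
    glucose = profile.fasting_glucose + a_glc * g_resp
    insulin = profile.fasting_insulin + a_ins * i_resp
    glucose = np.maximum(_mult_noise(rng, glucose, cv), 0.1)
    insulin = np.maximum(_mult_noise(rng, insulin, cv), 0.1)
    return OGTTRecord(
        glucose={int(t): float(g) for t, g in zip(times, glucose)},
        insulin={int(t): float(v) for t, v in zip(times, insulin)},
    )


# ---------------------------------------------------------------------------
# Metabolite panel simulation
# ---------------------------------------------------------------------------

def simulate_metabolome(
    profile: SubjectProfile,
    seed: int = 0,
    effects: Mapping[str, float] | None = None,
    noise_extra_cv: float = 0.0,
    rho: float = _BLOCK_RHO,
) -> MetabolitePanel:
    """Simulate the serum metabolite panel for one subject.

    Each measure is log-normal on the log2 scale with a block-equicorrelated
    latent structure (blocks follow lipoprotein class / metabolic pathway);
    the MEL group mean is shifted by ``effects[name]`` log2-SD units
    (defaults in :data:`DEFAULT_METABOLITE_EFFECTS`).
    """
    profile.validate()
    resolved = dict(DEFAULT_METABOLITE_EFFECTS)
    if effects is not None:
        for key, value in effects.items():
            if key not in resolved:
                raise ConfigurationError(f"unknown measure {key!r} in effect map")
            resolved[key] = float(value)
    if not 0.0 <= rho < 1.0:
        raise ConfigurationError("rho must lie in [0, 1)")

    rng = _rng(int(profile.subject_id[1:]) if profile.subject_id[1:].isdigit() else 0,
               seed, 41)
    is_mel = 1.0 if profile.group == "MEL" else 0.0
    z_bmi = (math.log(profile.bmi) - _BMI_REF_LOG) / _BMI_REF_SCALE

    block_factor = {block: rng.standard_normal()
                    for block in sorted({d.block for d in PANEL_DEFINITIONS})}
    measures: dict[str, float] = {}
    for d in PANEL_DEFINITIONS:
        z = (math.sqrt(rho) * block_factor[d.block]
             + math.sqrt(1.0 - rho) * rng.standard_normal())
        x = (math.log2(d.ll_median)
             + resolved[d.name] * d.sigma_log2 * is_mel
             + _BLOCK_BMI_LOADING[d.block] * z_bmi * d.sigma_log2
             + d.sigma_log2 * z)
        value = 2.0 ** x
        if noise_extra_cv > 0:
            value = float(_mult_noise(rng, np.asarray([value]), noise_extra_cv)[0])
        measures[d.name] = value
    return MetabolitePanel(subject_id=profile.subject_id, measures=measures)
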