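"""End-to-end pipeline: simulate -> quantify -> indices -> compare.

File dialects (all UTF-8, comma/tab separated, "." decimal, mandatory
header; "#"-prefixed metadata lines precede the header and are skipped on
read):

* ``cohort.csv``   wide, one row per subject; numeric columns embed units.
* ``clamp.csv``    long: subject_id, time_min, gir_umol_kg_min,
                   glucose_mmol_l, insulin_pmol_l (blank where unsampled).
* ``tac.csv``      long: subject_id, region ("plasma" or tissue),
                   time_min, activity_kbq_per_ml.
* ``doses.csv``    subject_id, dose_mbq, urine_mbq, weight_kg.
* ``ogtt.csv``     long: subject_id, time_min, glucose_mmol_l,
                   insulin_pmol_l.
* ``metabolome.csv`` wide: subject_id + one column per measure.
* ``kinetics.json``  per-subject Ki/GU per region, M value, Rd, EGP.
* ``indices.csv``    per-subject insulin sensitivity/secretion indices.
* ``comparisons.tsv`` adjusted group comparisons, one row per outcome.
* ``scan_forest.tsv`` metabolite scan (forest-plot table).
* ``manifest.json``  artifact hashes + config snapshot (determinism
                     contract: identical config+seed => identical hashes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import indices as idx
from .cohort import (
    DEFAULT_DOSE_MBQ,
    DEFAULT_SAMPLING_TIMES,
    DEFAULT_URINE_FRACTION,
    CohortConfig,
    generate_cohort,
    simulate_clamp,
    simulate_fdg_study,
    simulate_metabolome,
    simulate_ogtt,
)
from .errors import ConfigurationError, DataError, MetaclampError
from .groupstats import adjusted_group_comparison, metabolite_scan
from .kinetics import (
    DEFAULT_T_STAR,
    LUMPED_CONSTANTS,
    TISSUE_DENSITIES,
    endogenous_glucose_production,
    m_value,
    patlak_ki,
    rate_of_disappearance,
    tissue_glucose_uptake,
)
from .records import REGIONS, ClampRecord, FastingSample, OGTTRecord, TimeActivityCurve

__version_tag__ = "metaclamp-pipeline-1"


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration; every sub-config has study defaults."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    output_dir: str = "out"
    t_star: float = DEFAULT_T_STAR
    densities: Mapping[str, float] = field(default_factory=lambda: dict(TISSUE_DENSITIES))
    steady_tolerance: float = 0.3
    units_mode: str = "si"
    insulin_factor: float = idx.INSULIN_PMOL_PER_UU
    covariates: tuple[str, ...] = ("sex", "age", "bmi")
    scan_timing_covariate: bool = True
    transforms: Mapping[str, str] = field(default_factory=dict)
    clamp_duration: float = 180.0
    dose_mbq: float = DEFAULT_DOSE_MBQ
    urine_fraction: float = DEFAULT_URINE_FRACTION

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        cohort_raw = dict(raw.pop("cohort", {}))
        seed = int(raw.pop("seed", cohort_raw.get("seed", 0)))
        cohort_raw.setdefault("seed", seed)
        cohort = CohortConfig(**cohort_raw)
        kin = raw.pop("kinetics", {})
        ind = raw.pop("indices", {})
        stats_cfg = raw.pop("stats", {})
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(extra)}")
        return cls(
            cohort=cohort,
            seed=seed,
            output_dir=str(raw.get("output_dir", "out")),
            t_star=float(kin.get("t_star", DEFAULT_T_STAR)),
            densities={**TISSUE_DENSITIES, **kin.get("densities", {})},
            steady_tolerance=float(kin.get("steady_tolerance", 0.3)),
            units_mode=str(ind.get("units_mode", "si")),
            insulin_factor=float(ind.get("insulin_factor", idx.INSULIN_PMOL_PER_UU)),
            covariates=tuple(stats_cfg.get("covariates", ("sex", "age", "bmi"))),
            scan_timing_covariate=bool(stats_cfg.get("scan_timing_covariate", True)),
            transforms=dict(stats_cfg.get("transforms", {})),
            clamp_duration=float(raw.get("clamp_duration", 180.0)),
            dose_mbq=float(raw.get("dose_mbq", DEFAULT_DOSE_MBQ)),
            urine_fraction=float(raw.get("urine_fraction", DEFAULT_URINE_FRACTION)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = {k: v for k, v in dataclasses.asdict(self.cohort).items()}
        return d


# ---------------------------------------------------------------------------
# CSV dialect helpers
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: Path, seed: int, sep: str = ",") -> None:
    """Write a table with '#' metadata header lines (seed, generator tag)."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# generator: {__version_tag__}\n")
        fh.write(f"# seed: {seed}\n")
        frame.to_csv(fh, index=False, sep=sep, lineterminator="\n")


def read_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


# ---------------------------------------------------------------------------
# Stage 1: simulate
# ---------------------------------------------------------------------------

_COHORT_TRUTH_COLUMNS = {
    "basal_egp_umol_kg_min", "egp_suppression_frac",
    "insulin_disposal_umol_kg_min", "ogtt_sensitivity",
}


def cohort_to_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "subject_id": p.subject_id,
            "group": p.group,
            "sex": p.sex,
            "age_yr": p.age,
            "bmi_kg_m2": p.bmi,
            "weight_kg": p.weight,
            "bsa_m2": p.body_surface_area,
            "htg_percent": p.htg_percent,
            "vat_mass_kg": p.vat_mass,
            "fasting_glucose_mmol_l": p.fasting_glucose,
            "fasting_insulin_pmol_l": p.fasting_insulin,
            "fasting_ffa_mmol_l": p.fasting_ffa,
            "fasting_glycerol_mmol_l": p.fasting_glycerol,
            "scan_timing_min": p.scan_timing_min,
            # ground-truth simulator parameters (not used by quantification)
            "basal_egp_umol_kg_min": p.basal_egp,
            "egp_suppression_frac": p.egp_suppression,
            "insulin_disposal_umol_kg_min": p.insulin_disposal,
            "ogtt_sensitivity": p.ogtt_sensitivity,
        }
        for region, (k1, k2, k3) in p.kinetic_params.items():
            row[f"true_k1_{region}_ml_min_ml"] = k1
            row[f"true_k2_{region}_per_min"] = k2
            row[f"true_k3_{region}_per_min"] = k3
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_cohort_tables(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every simulator and return the pipeline's input tables."""
    profiles = generate_cohort(config.cohort)
    clamp_rows, tac_rows, dose_rows, ogtt_rows, panel_rows = [], [], [], [], []
    for p in profiles:
        clamp = simulate_clamp(p, duration=config.clamp_duration, seed=config.seed)
        frame = pd.DataFrame({"time_min": clamp.gir_times,
                              "gir_umol_kg_min": clamp.gir_values})
        samples = pd.DataFrame({"time_min": clamp.glucose_times,
                                "glucose_mmol_l": clamp.glucose_values,
                                "insulin_pmol_l": clamp.insulin_values})
        merged = frame.merge(samples, on="time_min", how="outer").sort_values("time_min")
        merged.insert(0, "subject_id", p.subject_id)
        clamp_rows.append(merged)

        plasma, tissues, dose, urine = simulate_fdg_study(
            p, clamp, sampling_times=DEFAULT_SAMPLING_TIMES, seed=config.seed,
            dose_mbq=config.dose_mbq, urine_fraction=config.urine_fraction,
        )
        for label, tac in [("plasma", plasma)] + list(tissues.items()):
            tac_rows.append(pd.DataFrame({
                "subject_id": p.subject_id, "region": label,
                "time_min": tac.times, "activity_kbq_per_ml": tac.activities,
            }))
        dose_rows.append({"subject_id": p.subject_id, "dose_mbq": dose,
                          "urine_mbq": urine, "weight_kg": p.weight})

        ogtt = simulate_ogtt(p, seed=config.seed)
        ogtt_rows.append(pd.DataFrame({
            "subject_id": p.subject_id,
            "time_min": list(ogtt.glucose),
            "glucose_mmol_l": list(ogtt.glucose.values()),
            "insulin_pmol_l": list(ogtt.insulin.values()),
        }))

        panel = simulate_metabolome(p, seed=config.seed)
        panel_rows.append({"subject_id": p.subject_id, **panel.measures})

    return {
        "cohort": cohort_to_frame(profiles),
        "clamp": pd.concat(clamp_rows, ignore_index=True),
        "tac": pd.concat(tac_rows, ignore_index=True),
        "doses": pd.DataFrame(dose_rows),
        "ogtt": pd.concat(ogtt_rows, ignore_index=True),
        "metabolome": pd.DataFrame(panel_rows),
    }


# ---------------------------------------------------------------------------
# Stage 2: quantify
# ---------------------------------------------------------------------------

def _clamp_from_long(sub: pd.DataFrame, subject_id: str, weight: float) -> ClampRecord:
    gir = sub.dropna(subset=["gir_umol_kg_min"])
    glc = sub.dropna(subset=["glucose_mmol_l"])
    ins = sub.dropna(subset=["insulin_pmol_l"])
    return ClampRecord(
        subject_id=subject_id,
        gir_times=gir["time_min"].to_numpy(),
        gir_values=gir["gir_umol_kg_min"].to_numpy(),
        glucose_times=glc["time_min"].to_numpy(),
        glucose_values=glc["glucose_mmol_l"].to_numpy(),
        insulin_times=ins["time_min"].to_numpy(),
        insulin_values=ins["insulin_pmol_l"].to_numpy(),
        weight=weight,
    )


def quantify_subject(
    subject_id: str,
    tacs: Mapping[str, TimeActivityCurve],
    clamp: ClampRecord,
    dose_mbq: float,
    urine_mbq: float,
    t_star: float = DEFAULT_T_STAR,
    densities: Mapping[str, float] | None = None,
    steady_tolerance: float = 0.3,
) -> dict:
    """Quantify one subject: regional Ki and GU, M value, Rd and EGP."""
    plasma = tacs["plasma"]
    mv = m_value(clamp, tolerance=steady_tolerance)
    # average plasma glucose over the steady-state window (Rd formula input)
    steady = clamp.glucose_times >= mv.steady_state_time
    avg_glucose = float(clamp.glucose_values[steady].mean())

    out: dict = {
        "m_value_umol_kg_min": mv.m_value,
        "steady_state_min": mv.steady_state_time,
        "avg_glucose_mmol_l": avg_glucose,
        "ki_ml_min_ml": {},
        "ki_r_squared": {},
        "gu_umol_kg_min": {},
    }
    for region, tac in tacs.items():
        if region == "plasma":
            continue
        fit = patlak_ki(tac, plasma, t_star=t_star)
        out["ki_ml_min_ml"][region] = fit.ki
        out["ki_r_squared"][region] = fit.r_squared
        out["gu_umol_kg_min"][region] = tissue_glucose_uptake(
            fit, avg_glucose, region, densities=densities)
    rd = rate_of_disappearance(dose_mbq, urine_mbq, plasma, avg_glucose, clamp.weight)
    egp = endogenous_glucose_production(rd, mv.m_value)
    out["rd_umol_kg_min"] = egp.rd
    out["gir_steady_umol_kg_min"] = egp.gir_steady
    out["egp_umol_kg_min"] = egp.egp
    return out


def quantify_tables(
    tac: pd.DataFrame,
    clamp: pd.DataFrame,
    doses: pd.DataFrame,
    t_star: float = DEFAULT_T_STAR,
    densities: Mapping[str, float] | None = None,
    steady_tolerance: float = 0.3,
) -> dict[str, dict]:
    """Quantify every subject found in the dose table."""
    results: dict[str, dict] = {}
    doses = doses.set_index("subject_id")
    for subject_id, dose_row in doses.iterrows():
        try:
            sub_tac = tac[tac["subject_id"] == subject_id]
            tacs = {
                region: TimeActivityCurve(
                    grp["time_min"].to_numpy(),
                    grp["activity_kbq_per_ml"].to_numpy(),
                    label=region,
                )
                for region, grp in sub_tac.groupby("region")
            }
            if "plasma" not in tacs:
                raise DataError("no plasma curve")
            record = _clamp_from_long(clamp[clamp["subject_id"] == subject_id],
                                      subject_id, float(dose_row["weight_kg"]))
            results[subject_id] = quantify_subject(
                subject_id, tacs, record,
                float(dose_row["dose_mbq"]), float(dose_row["urine_mbq"]),
                t_star=t_star, densities=densities,
                steady_tolerance=steady_tolerance,
            )
        except MetaclampError as exc:
            raise MetaclampError(
                f"quantify stage failed for subject {subject_id}: {exc}"
            ) from exc
    return results


# ---------------------------------------------------------------------------
# Stage 3: indices
# ---------------------------------------------------------------------------

def indices_table(cohort: pd.DataFrame, ogtt: pd.DataFrame,
                  units_mode: str = "si",
                  insulin_factor: float = idx.INSULIN_PMOL_PER_UU) -> pd.DataFrame:
    """Per-subject fasting and OGTT indices from the cohort/ogtt tables."""
    rows = []
    ogtt_by_subject = dict(tuple(ogtt.groupby("subject_id")))
    for _, subj in cohort.iterrows():
        sample = FastingSample(
            glucose=float(subj["fasting_glucose_mmol_l"]),
            insulin=float(subj["fasting_insulin_pmol_l"]),
            ffa=float(subj["fasting_ffa_mmol_l"]),
            glycerol=float(subj["fasting_glycerol_mmol_l"]),
        )
        row = {
            "subject_id": subj["subject_id"],
            "homa_ir": idx.homa_ir(sample, insulin_factor),
            "adipo_ir_pmol_mmol": idx.adipo_ir(sample),
            "adipo_ir_glycerol_pmol_mmol": idx.adipo_ir_glycerol(sample),
        }
        sub_ogtt = ogtt_by_subject.get(subj["subject_id"])
        if sub_ogtt is not None:
            record = OGTTRecord(
                glucose=dict(zip(sub_ogtt["time_min"].astype(int),
                                 sub_ogtt["glucose_mmol_l"])),
                insulin=dict(zip(sub_ogtt["time_min"].astype(int),
                                 sub_ogtt["insulin_pmol_l"])),
            )
            row["matsuda_isi"] = idx.matsuda_isi(record, units_mode, insulin_factor)
            row["secretion_first_pmol_mmol"] = idx.secretion_first_phase(record)
            row["secretion_total_pmol_mmol"] = idx.secretion_total_phase(record)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage 4: compare
# ---------------------------------------------------------------------------

#: outcome -> (source, default transform, needs scan-timing covariate)
_COMPARE_OUTCOMES: dict[str, tuple[str, str, bool]] = {
    "m_value_umol_kg_min": ("kinetics", "log", False),
    "rd_umol_kg_min": ("kinetics", "log", False),
    "egp_umol_kg_min": ("kinetics", "identity", False),
    "gu_muscle_umol_kg_min": ("kinetics", "log", True),
    "gu_liver_umol_kg_min": ("kinetics", "log", True),
    "gu_asat_umol_kg_min": ("kinetics", "log", True),
    "homa_ir": ("indices", "log", False),
    "adipo_ir_pmol_mmol": ("indices", "log", False),
    "adipo_ir_glycerol_pmol_mmol": ("indices", "log", False),
    "matsuda_isi": ("indices", "log", False),
    "secretion_first_pmol_mmol": ("indices", "log", False),
    "secretion_total_pmol_mmol": ("indices", "log", False),
}


def _covariate_frame(cohort: pd.DataFrame, covariates: Sequence[str],
                     with_timing: bool) -> pd.DataFrame:
    frame = pd.DataFrame(index=cohort.index)
    mapping = {"sex": (cohort["sex"] == "M").astype(float) if "sex" in cohort else None,
               "age": cohort.get("age_yr"),
               "bmi": cohort.get("bmi_kg_m2")}
    for name in covariates:
        if name not in mapping or mapping[name] is None:
            raise ConfigurationError(f"unknown covariate {name!r}")
        frame[name] = np.asarray(mapping[name], dtype=float)
    if with_timing:
        frame["scan_timing"] = cohort["scan_timing_min"].to_numpy(dtype=float)
    return frame


def compare_tables(
    cohort: pd.DataFrame,
    kinetics: Mapping[str, dict],
    indices_frame: pd.DataFrame,
    metabolome: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "age", "bmi"),
    scan_timing_covariate: bool = True,
    transforms: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjusted comparisons for every outcome plus the metabolite scan.

    Returns ``(comparisons, scan_forest)`` frames mirroring the TSV
    outputs.
    """
    transforms = transforms or {}
    cohort = cohort.reset_index(drop=True)

    kin_frame = pd.DataFrame.from_dict(kinetics, orient="index")
    flat = pd.DataFrame(index=kin_frame.index)
    for col in ("m_value_umol_kg_min", "rd_umol_kg_min", "egp_umol_kg_min"):
        flat[col] = kin_frame[col]
    for region in REGIONS:
        flat[f"gu_{region}_umol_kg_min"] = [
            row.get(region, np.nan) for row in kin_frame["gu_umol_kg_min"]
        ]
    flat.index.name = "subject_id"
    merged = cohort.merge(flat.reset_index(), on="subject_id", how="left") \
                   .merge(indices_frame, on="subject_id", how="left")

    rows = []
    for outcome, (_, default_transform, needs_timing) in _COMPARE_OUTCOMES.items():
        if outcome not in merged:
            continue
        values = merged[outcome].to_numpy(dtype=float)
        keep = np.isfinite(values)
        if keep.sum() < 4 or len(pd.unique(merged.loc[keep, "group"])) < 2:
            continue
        sub = merged.loc[keep]
        transform = transforms.get(outcome, default_transform)
        if transform == "log" and np.any(values[keep] <= 0):
            transform = "rank_normal"  # EGP-like sign-crossing fallback
        cov = _covariate_frame(sub, covariates,
                               needs_timing and scan_timing_covariate)
        result = adjusted_group_comparison(
            values[keep], sub["group"].to_numpy(), cov,
            transform=transform, outcome_name=outcome,
        )
        rows.append({
            "outcome": outcome, "estimate": result.estimate,
            "ci_low": result.ci_low, "ci_high": result.ci_high,
            "p": result.p, "evidence": result.evidence,
            "transform": result.transform,
            "covariates": "+".join(result.covariates),
            "n": result.nobs,
        })
    comparisons = pd.DataFrame(rows)

    panel = metabolome.set_index("subject_id")
    cohort_idx = cohort.set_index("subject_id").loc[panel.index]
    scan = metabolite_scan(
        panel, cohort_idx["group"].to_numpy(),
        _covariate_frame(cohort_idx.reset_index(), covariates, False),
    )
    forest = scan.table.reset_index(drop=True)[
        ["measure", "or_per_sd", "ci_low", "ci_high", "p", "q", "flagged"]
    ]
    return comparisons, forest


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> quantify -> indices -> compare and write all
    artifacts plus a manifest with content hashes."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    tables = simulate_cohort_tables(config)
    for name in ("cohort", "clamp", "tac", "doses", "ogtt", "metabolome"):
        write_table(tables[name], out / f"{name}.csv", seed)

    kinetics = quantify_tables(
        tables["tac"], tables["clamp"], tables["doses"],
        t_star=config.t_star, densities=config.densities,
        steady_tolerance=config.steady_tolerance,
    )
    kin_payload = {
        "_meta": {
            "seed": seed, "t_star_min": config.t_star,
            "densities_kg_per_l": dict(config.densities),
            "lumped_constants": dict(LUMPED_CONSTANTS),
            "steady_tolerance_mmol_l": config.steady_tolerance,
        },
        "subjects": kinetics,
    }
    (out / "kinetics.json").write_text(json.dumps(kin_payload, indent=1, sort_keys=True))

    ind = indices_table(tables["cohort"], tables["ogtt"],
                        units_mode=config.units_mode,
                        insulin_factor=config.insulin_factor)
    write_table(ind, out / "indices.csv", seed)

    comparisons, forest = compare_tables(
        tables["cohort"], kinetics, ind, tables["metabolome"],
        covariates=config.covariates,
        scan_timing_covariate=config.scan_timing_covariate,
        transforms=config.transforms,
    )
    write_table(comparisons, out / "comparisons.tsv", seed, sep="\t")
    write_table(forest, out / "scan_forest.tsv", seed, sep="\t")

    manifest = {
        "seed": seed,
        "config": config.snapshot(),
        "artifacts": {
            p.name: {"path": str(p), "sha256": _sha256(p)}
            for p in sorted(out.iterdir())
            if p.name != "manifest.json" and p.is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    file: str
    row: int | None
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, file: str, row: int | None, message: str) -> None:
        self.violations.append(Violation(file, row, message))

    def summary(self) -> str:
        if self.ok:
            return "all inputs valid"
        return "\n".join(f"{v.file}:{'' if v.row is None else v.row}: {v.message}"
                         for v in self.violations)


_UNIT_SUFFIXES = ("_percent", "_kg", "_m2", "_yr", "_mmol_l", "_pmol_l",
                  "_umol_kg_min", "_frac", "_min", "_kbq_per_ml", "_mbq",
                  "_ml_min_ml", "_per_min", "_pmol_mmol")
_UNITLESS_OK = {"subject_id", "group", "sex", "region", "time_min",
                "ogtt_sensitivity", "homa_ir", "matsuda_isi", "flagged",
                "or_per_sd", "ci_low", "ci_high", "p", "q", "n", "estimate"}


def validate_inputs(paths: Mapping[str, str | Path]) -> ValidationReport:
    """Schema-check the pipeline CSV dialects without mutating them.

    ``paths`` maps dialect name ("cohort", "tac", "clamp", "ogtt",
    "metabolome", "doses") to a file path; unknown names are rejected.
    Row numbers refer to data rows (0-based, header excluded).
    """
    report = ValidationReport()
    handlers = {"cohort": _validate_cohort, "tac": _validate_tac,
                "clamp": _validate_clamp, "ogtt": _validate_ogtt,
                "metabolome": _validate_metabolome, "doses": _validate_doses}
    for name, path in paths.items():
        if name not in handlers:
            raise ConfigurationError(f"unknown input dialect {name!r}")
        path = Path(path)
        try:
            frame = read_table(path)
        except OSError as exc:
            raise DataError(f"cannot read {path}: {exc}") from exc
        handlers[name](frame, path.name, report)
    return report


def _check_units(frame: pd.DataFrame, fname: str, report: ValidationReport) -> None:
    for col in frame.columns:
        if col in _UNITLESS_OK or not pd.api.types.is_numeric_dtype(frame[col]):
            continue
        if not any(col.endswith(suf) or suf in col for suf in _UNIT_SUFFIXES):
            report.add(fname, None, f"numeric column {col!r} lacks a unit suffix")


def _validate_cohort(frame, fname, report):
    required = {"subject_id", "group", "sex", "age_yr", "bmi_kg_m2",
                "weight_kg", "htg_percent"}
    missing = required - set(frame.columns)
    if missing:
        report.add(fname, None, f"missing columns: {sorted(missing)}")
        return
    _check_units(frame, fname, report)
    for i, row in frame.iterrows():
        if row["group"] not in ("LL", "MEL"):
            report.add(fname, int(i), f"group {row['group']!r} not in LL/MEL")
            continue
        htg = row["htg_percent"]
        if not 0 < htg <= 5.56:
            report.add(fname, int(i),
                       f"htg_percent {htg} outside the <= 5.56 % inclusion rule")
        elif row["group"] == "LL" and htg > 1.85:
            report.add(fname, int(i), f"LL subject with htg_percent {htg} > 1.85")
        elif row["group"] == "MEL" and htg <= 1.85:
            report.add(fname, int(i), f"MEL subject with htg_percent {htg} <= 1.85")


def _validate_tac(frame, fname, report):
    required = {"subject_id", "region", "time_min", "activity_kbq_per_ml"}
    missing = required - set(frame.columns)
    if missing:
        report.add(fname, None, f"missing columns: {sorted(missing)}")
        return
    if (frame["activity_kbq_per_ml"] < 0).any():
        for i in frame.index[frame["activity_kbq_per_ml"] < 0]:
            report.add(fname, int(i), "negative activity")
    for (subject, region), grp in frame.groupby(["subject_id", "region"]):
        times = grp["time_min"].to_numpy()
        bad = np.where(np.diff(times) <= 0)[0]
        for j in bad:
            report.add(fname, int(grp.index[j + 1]),
                       f"non-monotone time for {subject}/{region}")


def _validate_clamp(frame, fname, report):
    required = {"subject_id", "time_min", "gir_umol_kg_min"}
    missing = required - set(frame.columns)
    if missing:
        report.add(fname, None, f"missing columns: {sorted(missing)}")
        return
    gir = frame["gir_umol_kg_min"]
    for i in frame.index[gir.notna() & (gir < 0)]:
        report.add(fname, int(i), "negative GIR")


def _validate_ogtt(frame, fname, report):
    required = {"subject_id", "time_min", "glucose_mmol_l", "insulin_pmol_l"}
    missing = required - set(frame.columns)
    if missing:
        report.add(fname, None, f"missing columns: {sorted(missing)}")
        return
    bad_times = ~frame["time_min"].isin([0, 30, 60, 120])
    for i in frame.index[bad_times]:
        report.add(fname, int(i), f"OGTT time {frame.loc[i, 'time_min']} not in 0/30/60/120")


def _validate_metabolome(frame, fname, report):
    if "subject_id" not in frame.columns:
        report.add(fname, None, "missing subject_id column")
        return
    values = frame.drop(columns="subject_id")
    for col in values.columns:
        nonpos = values[col] <= 0
        for i in frame.index[nonpos]:
            report.add(fname, int(i), f"non-positive concentration in {col}")


def _validate_doses(frame, fname, report):
    required = {"subject_id", "dose_mbq", "urine_mbq", "weight_kg"}
    missing = required - set(frame.columns)
    if missing:
        report.add(fname, None, f"missing columns: {sorted(missing)}")
        return
    bad = frame["urine_mbq"] >= frame["dose_mbq"]
    for i in frame.index[bad]:
        report.add(fname, int(i), "urine activity >= injected dose")
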