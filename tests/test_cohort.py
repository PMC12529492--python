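"""Synthetic cohort generator: determinism, group structure, physics."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from metaclamp.cohort import (
    DEFAULT_SAMPLING_TIMES,
    CohortConfig,
    generate_cohort,
    simulate_clamp,
    simulate_fdg_study,
    simulate_metabolome,
    simulate_ogtt,
)
from metaclamp.errors import ConfigurationError
from metaclamp.kinetics import m_value, patlak_ki
from metaclamp.pipeline import cohort_to_frame

from conftest import NOISELESS


class TestGenerateCohort:
    def test_identical_seed_gives_byte_identical_cohort(self):
        cfg = CohortConfig(n_per_group=20, seed=42)
        a = cohort_to_frame(generate_cohort(cfg)).to_csv(index=False)
        b = cohort_to_frame(generate_cohort(cfg)).to_csv(index=False)
        assert a == b
        c = cohort_to_frame(
            generate_cohort(CohortConfig(n_per_group=20, seed=43))
        ).to_csv(index=False)
        assert a != c

    def test_liver_fat_intervals_partition_groups(self):
        profiles = generate_cohort(CohortConfig(n_per_group=150, seed=1))
        assert len(profiles) == 300
        ll = [p.htg_percent for p in profiles if p.group == "LL"]
        mel = [p.htg_percent for p in profiles if p.group == "MEL"]
        assert len(ll) == len(mel) == 150
        assert all(0 < h <= 1.85 for h in ll)
        assert all(1.85 < h <= 5.56 for h in mel)

    @pytest.mark.parametrize("kwargs,field", [
        ({"n_per_group": 1}, "n_per_group"),
        ({"noise_levels": {"tac": -0.1}}, "noise_levels"),
        ({"noise_levels": {"beeps": 0.1}}, "noise_levels"),
        ({"sex_fraction_per_group": {"LL": 1.5}}, "sex_fraction"),
        ({"effect_scales": {"nonexistent": 1.0}}, "effect_scales"),
        ({"bmi_params_per_group": {"MEL": (-5.0, 0.2)}}, "bmi_params"),
    ])
    def test_invalid_config_names_offending_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            generate_cohort(CohortConfig(**kwargs))

    def test_default_medians_near_study_scale(self):
        """Group medians of liver fat and adipose-IR land near the values
        typical of a low/mildly-elevated liver-lipid contrast."""
        profiles = generate_cohort(CohortConfig(n_per_group=101, seed=0))
        ll = [p for p in profiles if p.group == "LL"]
        mel = [p for p in profiles if p.group == "MEL"]
        htg_ll = np.median([p.htg_percent for p in ll])
        htg_mel = np.median([p.htg_percent for p in mel])
        assert 0.7 < htg_ll < 1.1      # ~0.9 %
        assert 2.7 < htg_mel < 3.7     # ~3.2 %
        adipo_ll = np.median([p.fasting_insulin * p.fasting_ffa for p in ll])
        adipo_mel = np.median([p.fasting_insulin * p.fasting_ffa for p in mel])
        assert 13.0 < adipo_ll < 23.0   # ~17.6 pmol/L x mmol/L
        assert 22.0 < adipo_mel < 36.0  # ~28.4
        assert adipo_mel > adipo_ll
        glyc_ll = np.median([p.fasting_insulin * p.fasting_glycerol for p in ll])
        glyc_mel = np.median([p.fasting_insulin * p.fasting_glycerol for p in mel])
        assert glyc_mel > glyc_ll       # 3.75 vs 1.97 direction

    def test_null_config_groups_indistinguishable(self):
        """All effects zero and equal covariates: the two groups' outcome
        distributions coincide (two-sample KS not rejected)."""
        profiles = generate_cohort(CohortConfig.null(n_per_group=400, seed=9))
        for attr in ("fasting_insulin", "insulin_disposal", "vat_mass"):
            ll = [getattr(p, attr) for p in profiles if p.group == "LL"]
            mel = [getattr(p, attr) for p in profiles if p.group == "MEL"]
            assert stats.ks_2samp(ll, mel).pvalue > 0.01


class TestSimulateClamp:
    def test_zero_disposal_zero_egp_gives_zero_gir(self, profile):
        quiet = dataclasses.replace(profile, insulin_disposal=0.0,
                                    basal_egp=0.1, egp_suppression=1.0)
        clamp = simulate_clamp(quiet, seed=1, noise_levels=NOISELESS)
        assert clamp.gir_values[-6:] == pytest.approx(0.0, abs=0.15)

    def test_steady_state_mass_balance(self, profile):
        """GIR converges to disposal - suppressed EGP (30 - 2 -> 28)."""
        p = dataclasses.replace(profile, insulin_disposal=30.0,
                                basal_egp=10.0, egp_suppression=0.8)
        clamp = simulate_clamp(p, seed=1, noise_levels=NOISELESS)
        assert clamp.gir_values[-3:] == pytest.approx(28.0, rel=2e-3)

    def test_noiseless_glucose_clamped_at_target(self, profile):
        clamp = simulate_clamp(profile, seed=1, noise_levels=NOISELESS)
        late = clamp.glucose_times >= 60.0
        assert np.all(np.abs(clamp.glucose_values[late] - 5.0) <= 0.1)
        # steady-state GIR equals disposal - residual EGP
        expected = profile.insulin_disposal - profile.residual_egp
        assert m_value(clamp).m_value == pytest.approx(expected, rel=0.03)

    def test_too_short_duration_rejected(self, profile):
        with pytest.raises(ConfigurationError, match="steady state"):
            simulate_clamp(profile, duration=90.0)

    def test_determinism(self, profile):
        a = simulate_clamp(profile, seed=5)
        b = simulate_clamp(profile, seed=5)
        assert np.array_equal(a.gir_values, b.gir_values)
        assert np.array_equal(a.glucose_values, b.glucose_values)


class TestSimulateFdgStudy:
    def test_linearity_in_dose(self, profile):
        """Doubling the dose doubles every activity exactly (same seed)."""
        a_plasma, a_tissues, a_dose, _ = simulate_fdg_study(profile, seed=3)
        b_plasma, b_tissues, b_dose, _ = simulate_fdg_study(profile, seed=3,
                                                            dose_mbq=310.0)
        ratio = b_dose / a_dose
        assert ratio == pytest.approx(2.0)
        assert b_plasma.activities == pytest.approx(2.0 * a_plasma.activities)
        for region in a_tissues:
            assert b_tissues[region].activities == pytest.approx(
                2.0 * a_tissues[region].activities)

    def test_no_trapping_region_has_vanishing_patlak_slope(self, profile):
        p = dataclasses.replace(
            profile,
            kinetic_params={"muscle": (0.08, 0.22, 1e-9)},
        )
        plasma, tissues, _, _ = simulate_fdg_study(p, seed=1,
                                                   noise_levels=NOISELESS)
        early = patlak_ki(tissues["muscle"], plasma, t_star=20.0)
        late = patlak_ki(tissues["muscle"], plasma, t_star=40.0)
        # residual equilibration leaves a slope ~50x below a trapping
        # region's Ki, and it keeps shrinking as the window moves out
        assert abs(early.ki) < 5e-4
        assert abs(late.ki) <= abs(early.ki)

    def test_urine_is_configured_fraction_of_dose(self, profile):
        _, _, dose, urine = simulate_fdg_study(profile, seed=1,
                                               noise_levels=NOISELESS,
                                               urine_fraction=0.17)
        assert urine == pytest.approx(0.17 * dose)

    def test_invalid_sampling_and_noise_rejected(self, profile):
        with pytest.raises(ConfigurationError, match="sampling"):
            simulate_fdg_study(profile, sampling_times=[5.0, 4.0, 6.0])
        with pytest.raises(ConfigurationError, match="tac"):
            simulate_fdg_study(profile, noise_levels={"tac": -0.5})


class TestSimulateOgtt:
    def test_flat_response_degenerates_to_fasting(self, profile):
        rec = simulate_ogtt(profile, seed=1, noise_cv=0.0,
                            glucose_amplitude=0.0, insulin_amplitude=0.0)
        assert list(rec.glucose.values()) == pytest.approx(
            [profile.fasting_glucose] * 4)
        assert list(rec.insulin.values()) == pytest.approx(
            [profile.fasting_insulin] * 4)

    def test_determinism_and_positivity(self, profile):
        a = simulate_ogtt(profile, seed=2)
        b = simulate_ogtt(profile, seed=2)
        assert a.glucose == b.glucose and a.insulin == b.insulin
        assert all(v > 0 for v in list(a.glucose.values()) + list(a.insulin.values()))

    def test_lower_sensitivity_raises_total_phase_secretion(self, profile):
        from metaclamp.indices import secretion_total_phase
        resistant = dataclasses.replace(profile, ogtt_sensitivity=0.5)
        sens = secretion_total_phase(simulate_ogtt(profile, seed=3, noise_cv=0.0))
        res = secretion_total_phase(simulate_ogtt(resistant, seed=3, noise_cv=0.0))
        assert res > sens


class TestSimulateMetabolome:
    def test_determinism_and_shared_measure_set(self, profile):
        a = simulate_metabolome(profile, seed=4)
        b = simulate_metabolome(profile, seed=4)
        assert a.measures == b.measures
        other = dataclasses.replace(profile, subject_id="S0002")
        c = simulate_metabolome(other, seed=4)
        assert set(c.measures) == set(a.measures)
        assert all(v > 0 for v in a.measures.values())

    def test_unknown_measure_in_effect_map_rejected(self, profile):
        with pytest.raises(ConfigurationError, match="unknown measure"):
            simulate_metabolome(profile, seed=1, effects={"Unobtainium": 1.0})

    def test_programmed_shift_moves_group_mean(self, profile):
        """A 1-SD log2 shift on one measure separates the group means."""
        mel = dataclasses.replace(profile, group="MEL", htg_percent=3.0)
        effects = {name: 0.0 for name in simulate_metabolome(profile).measures}
        effects["Ile"] = 1.0
        ll_vals, mel_vals = [], []
        for i in range(120):
            pl = dataclasses.replace(profile, subject_id=f"S{i:04d}")
            pm = dataclasses.replace(mel, subject_id=f"S{i + 500:04d}")
            ll_vals.append(np.log2(simulate_metabolome(pl, seed=6,
                                                       effects=effects).measures["Ile"]))
            mel_vals.append(np.log2(simulate_metabolome(pm, seed=6,
                                                        effects=effects).measures["Ile"]))
        diff = np.mean(mel_vals) - np.mean(ll_vals)
        assert diff == pytest.approx(0.30, abs=0.12)  # 1 SD x sigma_log2(Ile)
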