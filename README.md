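# metaclamp

Quantitative analysis of tissue-specific insulin sensitivity from
hyperinsulinaemic–euglycaemic clamp studies combined with dynamic
[¹⁸F]FDG-PET, for metabolic-research groups comparing cohorts stratified
by liver lipid content (low, ≤ 1.85 % liver triglyceride by ¹H-MRS,
vs. mildly elevated, > 1.85 % and ≤ 5.56 %).

The package implements the full chain from raw records to group-level
inference:

* **Tracer kinetics** — the Gjedde–Patlak graphical estimate of the FDG
  fractional phosphorylation rate `Ki` (the late-time slope of
  `Ct/Cp` vs `∫Cp/Cp`), tissue glucose uptake
  `GU = Ki · [glucose] / (density · LC)` with lumped constants 1.2
  (skeletal muscle), 1.0 (liver) and 1.14 (adipose tissue), the clamp
  M value (mean glucose infusion rate over three 20-min steady-state
  intervals after plasma glucose reaches 5 mmol/L), the glucose rate of
  disappearance from urinary-loss-corrected FDG plasma clearance
  `Rd = (dose − urine) / AUC(Cp) · [glucose] / weight`, and endogenous
  glucose production `EGP = Rd − GIR`.
* **Insulin indices** — HOMA-IR, the simplified two-point Matsuda ISI
  `10,000 / √(G₀·I₀·G₁₂₀·I₁₂₀)`, first-phase (0–30 min) and total-phase
  (0–120 min) OGTT secretion ratios, and the adipose-tissue insulin
  resistance products insulin × FFA and insulin × glycerol.
* **Group statistics** — multiple linear regression of each outcome on
  group + sex + age + BMI (+ PET scan timing where relevant) with an
  explicit transform registry; a per-metabolite logistic scan (odds
  ratio per 1 SD of the log₂ measure, Wald CIs, Firth fallback under
  separation); Storey q-values with a smoother π₀ estimate; the graded
  evidence scale (p < 0.01 strong, < 0.05 moderate, < 0.1 weak); a
  median-split helper; and exact noncentral-t power / sample-size
  calculations.
* **Synthetic cohort generator** — a fully seeded simulator of the same
  data structure (clamp traces under a feedback glucose controller,
  two-tissue-compartment FDG time–activity curves, OGTT excursions, an
  NMR-style metabolite panel with block correlation and programmable
  group effects), so the entire pipeline is testable end to end without
  any external data.

## Worked example

Sample size for a two-sample comparison at Cohen's d = 0.62, 80 % power,
two-sided α = 0.05:

```
$ metaclamp power --d 0.62
total N = 84 (42 per group), achieved power 0.802
```

Full synthetic study at the default conditions (101 subjects per group):

```
$ metaclamp run --seed 1 --out out
pipeline complete; 10 artifacts in out
```

`out/comparisons.tsv` then holds the covariate-adjusted group contrasts
(MEL vs LL, log scale unless noted):

```
outcome                      estimate  ci_low  ci_high      p  evidence
m_value_umol_kg_min           -0.1740 -0.2887  -0.0593 0.0031  strong
egp_umol_kg_min                2.4979  1.1259   3.8700 0.0004  strong
gu_muscle_umol_kg_min         -0.0441 -0.1084   0.0203 0.1784  little
homa_ir                        0.0226 -0.1449   0.1901 0.7907  little
adipo_ir_glycerol_pmol_mmol    0.3330  0.1125   0.5535 0.0033  strong
matsuda_isi                   -0.1029 -0.2168   0.0111 0.0767  weak
```

Read: at these simulated conditions the mildly-elevated-liver-lipid group
produces ~2.5 µmol/kg/min more glucose endogenously during the clamp and
has an ~16 % lower M value (e⁻⁰·¹⁷⁴), while regional glucose uptake shows
little adjusted difference — the whole-body deficit is carried by
unsuppressed hepatic glucose output. `out/scan_forest.tsv` is the
forest-plot table of the metabolite scan; the top of the q < 0.05 block:

```
measure    or_per_sd  ci_low  ci_high  q
VLDL_TG        3.746   2.330    6.023  0.0
Serum_TG       3.071   2.028    4.648  0.0
GlycA          2.334   1.610    3.385  0.0
Leu            2.109   1.452    3.064  0.0
```

Library use mirrors the CLI: `generate_cohort`, `simulate_clamp`,
`simulate_fdg_study`, `PatlakModel(...).fit()`, `m_value`,
`rate_of_disappearance`, `endogenous_glucose_production`,
`adjusted_group_comparison`, `metabolite_scan`, `storey_qvalues`,
`sample_size_two_sample_t`; see the module docstrings.

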