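# Methods

This note documents the models behind each stage, the defaults that
matter, and what the synthetic-data tests do and do not demonstrate.

## Tracer kinetics

**Forward model.** Tissue FDG kinetics follow the irreversible
two-tissue compartment model: free tracer `C1' = K1·Cp − (k2+k3)·C1`,
trapped tracer `C2' = k3·C1`, measured activity `Ct = C1 + C2`. The
solver (`solve_irreversible_2tc`) evaluates the convolution on a 0.05-min
grid with an exponentially exact linear recursion (implemented as an IIR
filter), so it is accurate enough to serve as the oracle for the Patlak
estimator rather than sharing its discretisation.

**Patlak estimate.** `x(t) = ∫₀ᵗCp dτ / Cp(t)`, `y(t) = Ct(t)/Cp(t)`;
unweighted OLS of `y` on `x` for `t ≥ t*` gives `Ki` (slope) and the
apparent distribution volume (intercept). The true slope is
`K1·k3/(k2+k3)`; the residual equilibration transient decays like
`e^-(k2+k3)t`, so the default `t* = 20 min` keeps the bias below 2 % for
rate constants in the simulated range and the bias shrinks monotonically
as `t*` grows. The regression is unweighted because late-time Patlak
points have comparable variance under multiplicative noise; no weighting
scheme is imposed.

**Glucose uptake.** `GU = Ki · [glucose]·1000 / (density · LC)` in
µmol/(kg tissue)/min, with lumped constants muscle 1.2, liver 1.0,
adipose 1.14 and default densities 1.04 / 1.05 / 0.92 kg/L (configurable;
recorded in the kinetics output metadata).

**M value.** Mean of three consecutive 20-min interval means of the
glucose infusion rate, starting at the first glucose sample within
0.3 mmol/L above the 5.0 mmol/L target (both configurable). The
qualifying time is reported with the result.

**Rd and EGP.** Plasma clearance is `(dose − urine)/AUC(Cp)` with the
AUC taken as trapezoid over the samples plus a mono-exponential tail
fitted to the last three points (the late plasma curve is effectively
single-exponential, so the tail term is near exact; the combined AUC
agrees with the closed-form integral of the parametric input to < 1 %).
`Rd = clearance · ḡ / weight` with ḡ the mean plasma glucose over the
clamp steady-state window — the formula's "average plasma glucose" is not
otherwise pinned down, so the steady-state mean is the default and the
window is configurable. `EGP = Rd − GIR` exactly; negative values are
legal outputs (measurement error around a near-zero hepatic output) and
are preserved.

## Insulin indices

HOMA-IR uses glucose [mmol/L] × insulin [µU/mL] / 22.5; insulin is
carried in pmol/L package-wide and converted with an explicit factor of
6.00 pmol/L per µU/mL (configurable — assay conventions vary between 6.0
and 6.945 and no single value is canonical). The simplified Matsuda ISI
is evaluated directly on SI units by default because its typical
magnitude (~20–30) in such cohorts matches that convention; a `mgdl`
mode applies the classic mg/dL + µU/mL units first (the two differ by a
constant factor). OGTT secretion AUCs use exactly the named time points
(0/30 for first phase; 0/60/120 for total phase) with no interpolation
of unused samples.

## Group statistics

**Adjusted comparisons.** OLS of the (optionally transformed) outcome on
group + covariates; sex is a single 0/1 indicator, scan timing a
continuous covariate in minutes. The transform registry holds identity,
log and rank-based inverse-normal (Blom) scores; right-skewed positive
outcomes default to log, and a sign-crossing outcome (EGP) falls back to
identity/rank-normal. The applied transform is always recorded — which
outcome received which transform is a package choice, not something the
estimators infer.

**Metabolite scan.** Each measure is log₂-transformed and standardized
to unit SD, then logistic regression of group on measure + sex + age +
BMI gives an odds ratio per 1 SD with Wald 95 % CIs (Wald rather than
profile intervals: deterministic and standard in forest-plot outputs).
Fits with (quasi-)separation are refit with Firth's bias-reduced
penalized likelihood, which keeps estimates and intervals finite, and
are flagged in the output.

**Storey q-values.** `q(p₍ᵢ₎) = min_{j≥i} π₀·m·p₍ⱼ₎/j` with π₀ from the
smoother method: `π₀(λ) = #(p>λ)/(m(1−λ))` on λ = 0.05…0.95, cubic
smoothing spline evaluated at λ = 0.95. The λ→1 extrapolation is
unstable for small or signal-heavy panels and its failure mode (π₀ → 0)
would make every q-value vacuously small, so the estimate is floored at
the fixed-λ = 0.5 estimator — the more conservative of the two is always
used — with the Pounds–Cheng bound 2·mean(p) as a final fallback. With
π₀ forced to 1 the q-values reduce to Benjamini–Hochberg adjusted
p-values bit-for-bit. The bootstrap π₀ variant is not implemented.

**Evidence scale.** p < 0.01 strong; 0.01 ≤ p < 0.05 moderate;
0.05 ≤ p < 0.1 weak; p ≥ 0.1 little — half-open boundaries exactly as
stated, also applied to FDR values in scan output.

**Power.** Two-sided two-sample t-test power from the noncentral t
distribution with noncentrality `d·√(n/2)`; the minimal per-group n is
found by integer search upward from the normal-approximation bound, so
the returned total 2n is exactly minimal.

## Synthetic cohort generator

The generator emulates a two-group cross-sectional study (default
101 + 101 subjects) whose records have the structure the analysis
expects. Everything is a pure function of (inputs, seed) via
`numpy.random.SeedSequence`, which the pipeline turns into a determinism
contract (identical manifest hashes).

**Covariate structure.** Liver-fat intervals define the groups
(truncated log-normals with medians ~0.9 % and ~3.2 %). Sex fractions
(77 %/62 % female) and BMI distributions (log-normal medians 25.2 and
29.4 kg/m²) differ between groups by default. Outcomes load on
*population*-standardized log-BMI and on sex; the configured
`effect_scales` are therefore residual (covariate-independent) group
shifts: the raw group contrast a user sees is the sum of the
covariate-carried part and the programmed residual part, and covariate
adjustment removes the former. This reproduces the qualitative pattern
typical of such cohorts — raw fasting-insulin/HOMA differences that
largely dissolve under BMI adjustment, while EGP suppression, disposal
and the lipolysis products retain adjusted effects. `CohortConfig.null()`
zeroes every effect *and* equalizes the covariate distributions, giving
two statistically identical groups for calibration tests.

**Clamp.** One-pool glucose plant (0.19 L/kg distribution volume);
insulin action on both disposal and EGP suppression rises with an 8-min
time constant; insulin infusion fixed at 40 mU/m²/min. The controller
mimics bedside practice: every 5 min it estimates the net endogenous
flux from the observed glucose drift plus the infusion it applied (a
disturbance observer, which provides integral action) and cancels it
with a proportional correction toward 5.0 mmol/L. Steady-state GIR
equals `disposal − basal_EGP·(1 − suppression)` by mass balance; in
noiseless mode the M-value estimator recovers it to ≲ 2 %. Fasting
glucose is kept above the steady-state band (floor 5.45 mmol/L) so that
"reaching 5 mmol/L" is always a downward crossing, as in the protocol
being emulated.

**FDG study.** The plasma input is a parametric bolus + washout form
(Feng-type: `(A₁t − A₂ − A₃)e^{−λ₁t} + A₂e^{−λ₂t} + A₃e^{−λ₃t}`), chosen
because its AUC has a closed form that serves as an exact oracle. The
curve is scaled so that the urinary-loss-corrected plasma clearance
equals `disposal · weight / 5.0` — i.e. the FDG-clearance route recovers
the programmed whole-body disposal by construction, closing the
mass-balance loop Rd ≈ disposal, EGP ≈ residual hepatic output. Tissue
curves are exact 2TC responses per region (muscle/liver/adipose rate
constants at physiologic FDG values). Urinary loss is a fixed 10 % of
dose by default. Noise channels (all multiplicative log-normal,
mean-preserving): 5 % on activities, 3 % on GIR, 1.5 % on clamp glucose,
6 % on insulin, 4 % on OGTT points, and a 10 % dose/urine calibration
error that propagates into Rd — this last channel is what gives the
simulated EGP its realistic measurement spread (without it EGP estimates
would be implausibly precise).

**OGTT.** Gamma-shaped excursions over fasting (glucose peaking at
45 min, insulin at 60 min) with amplitudes scaling inversely with the
subject's sensitivity scalar; zero amplitude degenerates to a flat
response for oracle tests.

**Metabolite panel.** 31 measures (triglyceride/VLDL axis, apoB axis,
HDL, branched-chain amino acids, gluconeogenic substrates, fatty-acid
composition, GlycA, plus designated null measures) simulated log-normally
on the log₂ scale with block-equicorrelated latent structure (ρ = 0.6
within lipoprotein-class/pathway blocks). Default shifts are positive
for the triglyceride/apoB/BCAA/GlycA/lactate-pyruvate measures, negative
for HDL size and PUFA/omega-6 ratios, zero for the nulls.

**What the simulations do not emulate.** PET image formation and ROI
placement, MRS spectral fitting, insulin-assay family differences,
inter-scanner bias, within-subject visit-to-visit drift, and any
non-log-normal tail behaviour of the metabolome. Passing tests therefore
demonstrate correctness of the estimators and calibration of the
statistics under the stated generative assumptions — not robustness to
these real-data complications.

## Problem sizes and numerical choices

Test and acceptance runs use: 200 replicates for noisy-Patlak and
scan-recovery Monte Carlo (100 in the acceptance script's scan block),
1,000 simulated outcomes for null calibration, 50 subjects for the
noiseless mass-balance check, and 101/group for cohort summaries —
sizes chosen so the full suite runs in tens of seconds while Monte-Carlo
standard errors stay well inside the asserted tolerances. Degenerate
inputs are rejected with typed errors (configuration vs data vs
estimation) naming the offending field; ties in the median split go to
the lower group; the Patlak fit requires ≥ 2 points past `t*` and
positive plasma activity in the window.

## Known limitations

* Only Patlak estimation is provided; full nonlinear compartment fitting
  (and hence k4/dephosphorylation effects, relevant for liver at late
  times) is out of scope.
* The Matsuda ISI is the simplified two-point form, not the full
  multi-point index; HOMA2 is not implemented.
* Wald intervals for logistic ORs can be poor at tiny n even with the
  Firth fallback; flagged rows should be treated with caution.
* The π₀ smoother floor trades a little power for stability on small
  panels; with hundreds of measures the floor rarely binds.
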