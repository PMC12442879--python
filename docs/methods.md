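# Methods

## Scope and model

`carbscape` implements a complete analysis chain for mapping phytoplankton
(specifically coastal diatom) growth across seawater carbonate-chemistry
space:

1. **Speciation.** The seawater carbonate system is solved on the total
   hydrogen-ion scale from any of the pairs (TA, pH_t), (TA, DIC),
   (TA, pCO2), plus closed-form paths from (DIC, pH), (DIC, CO2),
   (DIC, pCO2) and (pH, pCO2) used for literature ingestion.
2. **Growth kinetics.** Growth rate V (d⁻¹) as a function of dissolved CO2
   (c, μmol kg⁻¹) follows a Michaelis–Menten form with a linear inhibition
   term,

       V(c) = X·c/(Y + c) − S·c,

   whose S = 0 limit is the standard saturating hyperbola. The inhibition
   term stands in for proton stress: CO2 and H⁺ are so tightly correlated
   across TA×DIC space (R² of ln CO2 vs ln H⁺ > 0.95 over the design grid)
   that a single abscissa carries both effects — CO2 limitation on the
   ascending limb, H⁺ inhibition on the descending limb.
3. **Derived quantities.** With S > 0 the curve has a single interior
   maximum at C_opt = √(X·Y/S) − Y (requires X > S·Y; violations raise a
   "monotone curve" error). Vmax = V(C_opt). The half-saturation constant
   K½ is defined as the ascending-limb concentration where V = Vmax/2,
   obtained by bracketed root-finding on (0, C_opt); this definition
   reduces exactly to K½ = Y in the S = 0 limit, preserving the standard
   Michaelis–Menten meaning in the nested model. The inversion
   (Vmax, K½, S) → (X, Y, S), used to build species profiles from reported
   kinetic summaries, is solved numerically by Powell's hybrid method.
4. **Uncertainty.** Percentile bootstrap (2.5/97.5) on X, Y, S, Vmax, K½
   and C_opt. Nonparametric resampling of (c, V) points is the default;
   parametric residual resampling is available. 1000 replicates by
   default; replicates are refit from the point estimate (warm start) and
   failures are dropped and counted, with > 50% failure an error.
5. **Landscapes and scenarios.** A fitted curve is projected over a TA×DIC
   lattice by speciating every cell; the species' "optimum" is the region
   with V ≥ f·Vmax (f = 0.90 by default). Ocean-alkalinity-enhancement
   (OAE) scenarios add ΔTA at constant DIC and then re-equilibrate with
   the atmosphere along a linear bridge in pCO2 between the unequilibrated
   and atmospheric endpoints. Threshold utilities report the smallest ΔTA
   (bisection on [0, 2000] μmol kg⁻¹) that pushes growth below f·Vmax, and
   the upper pCO2/H⁺ edge of the optimum under acidification.

## Carbonate-system solver

Constant formulations (all evaluated at surface pressure, returned on the
total scale): Weiss (1974) K0; Lueker et al. (2000) K1/K2; Dickson (1990b)
boric acid; Millero (1995) water and silicic acid and Yao & Millero (1995)
phosphoric acid, converted from the seawater scale; Dickson (1990a)
bisulfate (free scale, defining the scale conversions); Perez & Fraga
(1987) HF; Mucci (1983) aragonite solubility; Uppström (1974) total
borate. These match the default configuration of the widely used
CO2-system calculators, and the implementation reproduces published check
values at S = 35, 25 °C (pK1 = 5.8472, pK2 = 8.9660, ln K0 = −3.5617,
pKB = 8.5975, Ksp_arag = 6.48·10⁻⁷) to the printed precision.

The alkalinity balance includes carbonate, borate, water, silicate,
phosphate, free-H⁺, bisulfate and fluoride terms. Nutrient terms are on by
default — the cultures the package targets measured dissolved silicate and
assume 3 μmol kg⁻¹ phosphate — and can be zeroed for literature data.
pH root-finding uses Brent's method on pH ∈ [2, 12] with xtol 10⁻¹²
(the TA residual is strictly monotone in pH, so the root is unique).
Concentrations are μmol kg⁻¹ at the interface and mol kg⁻¹ internally,
converted exactly once at the boundary.

pCO2 is reported as a plain partial pressure through Henry's law,
CO2 = K0·pCO2, with no fugacity correction (`APPLY_FUGACITY` documents the
switch point). Published scenario endpoints computed with related tools
differ from this package by up to ~2–3% in pCO2 (e.g. the +300 μmol kg⁻¹
TA endpoint computes to 139.3 μatm here against a published ~136); probing
fugacity, water-vapour, borate and salinity variants did not close that
gap, so the package reports its own faithfully computed value rather than
adopting the printed one.

## Synthetic experiment generator

The generator emulates the study design it is meant to stand in for: 11 TA
levels spanning 2000–3350 μmol kg⁻¹ crossed with 8 DIC levels spanning
1800–3666.67 μmol kg⁻¹ (88 nominal treatments, all feasible at the default
conditions; a warning fires below 67), at 15 °C, salinity 33.06, media
nitrate 48 μmol kg⁻¹ and silicate/phosphate 3 μmol kg⁻¹ each.

Per culture: a target DIC drawdown fraction is drawn uniformly from
5–10% (harvest rule); the end state has DIC reduced by that fraction and
TA increased by 1 μmol kg⁻¹ per μmol kg⁻¹ nitrate consumed (Redfield
16:106 N:C coupling, capped at the 48 μmol kg⁻¹ in the medium); the end pH
is recomputed so start and end measurements are exactly
carbonate-consistent. The realized growth rate is the optimum curve
evaluated at the *mean* of start and end CO2 — matching how the analysis
attributes conditions to cultures — plus additive Gaussian noise
(σ = 0.05 d⁻¹ default). Non-positive draws become zero-growth/mortality
records with no drawdown, which downstream exclusion flags must catch.
Fluorescence is exponential with multiplicative lognormal noise (5%
default), sampled daily from day 0 until the biomass implied by the
drawdown target is reached (3–30 days; the inoculum is 2 μmol C kg⁻¹ of
drawdown equivalent, the carbon quota 10 pmol C cell⁻¹, BSi:C 0.13).
Fv/Fm is an affine function of the deterministic relative rate
(0.25 + 0.45·V/Vmax) with Gaussian coupling noise σ = 0.04, clipped to
[0, 1] — enough structure to reproduce the strong growth–Fv/Fm
correlation (R² ≥ 0.75) without modelling photophysiology mechanistically.

Five canonical species profiles anchor the generator to reported kinetic
summaries: K½ = 1.22 (T. nitzschioides), 1.21 (C. affinis), 0.90
(P. cuspidata), 5.55 (T. rotula) and 0.44 μmol kg⁻¹ (Melosira sp.), with
sensitivity S from 0.0005 (Melosira sp.) to 0.0065 (P. cuspidata).
Maximum rates are not all reported, so plausible coastal-diatom values
(0.8–1.38 d⁻¹) were chosen once such that the optima C_opt fall inside the
observed 13.8–58.5 μmol kg⁻¹ window; they are package choices, not
measurements.

What the generator does *not* emulate: within-day DIC/pH trajectories
(drawdown is imposed at the harvest target, not integrated), lag phases,
replicate vessels per treatment, instrument noise on TA/pH measurements,
temperature or light effects, and any BSi debris artefacts. Tests passing
on synthetic data therefore demonstrate the statistical machinery
(estimator accuracy, CI calibration, exclusion logic, threshold
computation) under the design's geometry and noise level — not the
biology of any particular culture collection.

## Numerical choices

- Least squares: Levenberg–Marquardt with analytic Jacobians; multi-start
  (5 starts) with heuristic initials — X from the maximum observed rate,
  Y from the concentration nearest half the maximum, S from the terminal
  slope if negative — plus deterministic seed-jittered restarts; best SSE
  wins. A fitted S < 0 triggers a clamped S = 0 refit and sets the
  boundary flag (saturating data).
- Model choice ("is a decline evident?"): fit both forms; use the
  inhibited form only when the bootstrap CI of S excludes zero.
- R² is the plain 1 − SSres/SStot against the mean-only model, no
  degrees-of-freedom adjustment.
- Exclusion: growth ≤ 0 (configurable threshold) flags a culture as zero
  net growth/mortality; flagged cultures are retained in outputs but
  barred from fitting and from setting the normalization maximum.
- Growth-rate estimation uses the OLS slope of ln F over the full
  monitored span (minimum 3 days); no lag trimming.
- Optimum intervals: bracketed root-finding on V(c) = f·Vmax on each side
  of C_opt; for S = 0 the lower edge is the closed form f·Y/(1−f) and the
  upper edge is +∞ (no decline → no upper threshold, reported as a
  sentinel).
- The H⁺ coordinate of an interval endpoint is obtained by speciating at
  a stated reference DIC (2030 μmol kg⁻¹ surface-ocean default) via the
  closed-form quadratic for [H⁺] at fixed (DIC, CO2).
- Infeasible TA/DIC grid cells (no pH root in [2, 12]) are masked at grid
  level but raise errors in scalar speciation calls.

## Known limitations

- The bootstrap treats each culture as one independent point (no replicate
  weighting), matching the analysis it reproduces.
- The OAE equilibration fan interpolates linearly in pCO2 between the
  unequilibrated and atmospheric endpoints; real air–sea exchange follows
  gas-exchange kinetics that this package deliberately does not model.
- The alkalinity-threshold convention (constant experimental DIC during
  addition) is one of several possible; thresholds under partially
  equilibrated DIC can be built by composing `oae_scenario` with the
  fitted curve.
- pH-scale conversion for literature records supports total, free and
  seawater scales; NBS-scale records are not supported and are skipped
  with a logged reason.

## Problem sizes used in the shipped studies

The recovery and calibration studies run at the design's own size:
67-treatment experiments, 1000 bootstrap replicates, 100 seeds for
end-to-end CI recovery and 200 simulations for coverage. These sizes are
the study conditions themselves, and the test suite and acceptance script
run them in full (a few minutes on one CPU).
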