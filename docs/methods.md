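# Methods

This note documents the models, constants, numerical conventions and design
choices behind `fenflux`, and what the synthetic-data benchmarks do and do
not demonstrate.

## Vessel model and gas partitioning

A sealed incubation tube is described by `VesselSpec`: total volume
(default 27 ml), initial liquid volume (10 ml: 1 g fresh material + 9 ml
mineral solution), post-sampling liquid volume (9.5 ml), fresh mass, dry
weight fraction, temperature (default 288.15 K) and headspace pressure.
Headspace pressure is fixed at 1 atm at every sampling; overpressure from
gas addition is ignored — a documented simplification, adequate for the
small headspace withdrawals of routine sampling.

The total amount of a gas is the ideal-gas headspace amount plus the
Henry's-law dissolved amount. Henry solubilities are pinned in
`src/fenflux/data/constants.yaml`:

| gas | K_H at 298.15 K (mol l⁻¹ atm⁻¹) | van't Hoff B (K) |
|-----|------|------|
| H₂  | 7.8×10⁻⁴ | 500 |
| CO₂ | 3.4×10⁻² | 2400 |
| CH₄ | 1.4×10⁻³ | 1700 |

with K_H(T) = K_H(298.15)·exp(B·(1/T − 1/298.15)); these are standard
compilation values, shipped explicitly so every conversion is bit-stable
and auditable. For CO₂ the dissolved pool additionally includes bicarbonate
from the first carbonic-acid dissociation, with pK₁(T) from the
Harned–Davis fit (6.352 at 25 °C, 6.42 at 15 °C); carbonate is neglected
because all relevant pH are below 6, and no ionic-strength activity
corrections are applied (dilute mineral medium). Molar concentrations are
total amounts divided by the post-sampling liquid volume (µmol / 9.5 ml =
mM); dry-weight normalisation multiplies by V_liq/(fresh mass × dw
fraction), which reproduces the four integer factors used in the field for
the printed dry-weight fractions (11 % → 86, 13 % → 73, 16 % → 59,
36 % → 26).

Observations below the detection limit (default 10 ppmV H₂) are
left-censored: records carry the limit itself plus a flag, are excluded
from rate fits, and propagate as "undefined" through every downstream
computation that needs the value. Linear rates are OLS on per-day replicate
means; replicates are never averaged silently elsewhere. Degenerate
conventions: a zero-variance response fits slope 0 with R² defined as 0;
duplicate days within one stream are rejected.

## Reductant recovery

Recoveries follow the electron bookkeeping described in the README: 2
reducing equivalents per H₂, 8 per acetate or CH₄, control-corrected
concentration differences, sign arranged so that net H₂ consumption with
product excess gives a positive percentage. Choices:

* Recoveries are computed from replicate-*mean* concentrations, not
  per-replicate and then averaged.
* The recovery is undefined (flagged, no number) when |2·ΔΔH₂| < 0.05 mM —
  a contrast that small carries no meaningful exogenous-H₂ signal.
* The unknown fraction is a pure residual, never clipped to [0, 100]:
  a negative product recovery (less product with H₂ than without) is a real
  observation and pushes the residual above 100 %.
* Report tables round half-up to one decimal; raw full-precision companions
  are always written.
* Full-period rows equal the consumption-weighted mean of their sub-period
  rows; this is an algebraic identity of the R definition and is tested as
  such.

`estimate_two_stage_partition` fits the generator's two-stage model (below)
to a whole time series: the H₂ consumption line is fitted in log space
(multiplicative noise), optionally anchored at the known dose — in a
supplementation experiment the dose is part of the design and known more
precisely than any single measurement, and anchoring it removes the dominant
uncertainty in the consumed-H₂ scale. Product curves of both treatments are
then fitted jointly as f_P·max(C(t) − pool, 0)/4 + baseline_P·t, with the
pool profiled on a grid (the fractions and baselines are linear given the
pool and solved in closed form), using inverse-squared-magnitude weights
consistent with multiplicative noise. A CO₂-coupled variant was evaluated
and rejected: the large CO₂ background contributes more noise than
constraint.

## Thermodynamics

Standard free energies and enthalpies of formation follow the classic
anaerobe-energetics compilations, in the aqueous-species convention for all
solutes including dissolved gases (H₂(aq) ΔGf = +17.57 kJ mol⁻¹, etc.);
the constants file is versioned and test-pinned, and element/charge balance
of every shipped reaction is machine-verified at load. Temperature
correction uses the Gibbs–Helmholtz/van't Hoff form with
temperature-independent ΔH°, adequate over the ±25 K window of interest; a
warning fires outside (250, 350) K. The reaction quotient uses dissolved
molar concentrations (not partial pressures), proton activity 10^(−pH),
water activity 1; CO₂ enters as CO₂(aq) only (bicarbonate is tracked for
mass balance but is not a reactant in the written equations). Because the
three shipped reactions are built from one formation table, the Hess
coupling ΔG(acetogenesis) + ΔG(aceticlastic) = ΔG(hydrogenotrophic
methanogenesis) holds to rounding error at any conditions — this is both a
consistency test and a guard against constant-table typos.

The feasibility classifier compares ΔG against 0 and against an
organism-scale limit (default −5 kJ mol⁻¹, the lowest energy yield at which
cultured acetogens have been shown to operate); both bounds are
configurable. The standard-state convention (aqueous vs gaseous) is a
config choice via the constants file; figure-level ΔG values from field
studies are not reproducible without the underlying concentrations and are
deliberately not test targets.

## The stimulation screen

The screen is the published LEfSe recipe with pinned internals, plus a
manual ratio criterion:

* per-sample total-sum scaling to 10⁶;
* Kruskal–Wallis per feature with the chi-square p (k−1 df). With n = 3 vs
  3 the exact two-sided permutation floor is p = 0.1, so criterion (a)
  would be unattainable under an exact test; the chi-square approximation
  (p ≈ 0.0495 at full separation) is what the published implementation
  uses and is the default here. An exact-permutation mode exists behind a
  flag for two groups.
* 30 bootstrap rounds, each subsampling ⌈2/3⌉ of every class (min 2);
  per round, the effect of a feature is the mean of its raw class-mean
  difference and its |loading| on the Fisher discriminant axis times the
  projected class gap; the score is sign·log₁₀(1 + |mean effect|).
* The within-class scatter is singular by construction at these sample
  sizes; a small deterministic diagonal ridge (10⁻⁶·mean diagonal + 10⁻⁶)
  replaces the random jitter of the original implementation so results are
  exactly reproducible for a given seed. The subclass (one-against-all)
  stage of the original is a no-op with two plain classes and is omitted.
* A random seed is a required input of every bootstrap operation.
* The abundance-ratio criterion (c) divides replicate-mean relative
  abundances (H₂ / unsupplemented). A zero denominator with a positive
  numerator is +∞ and passes (a maximal response); zero over zero is
  undefined and cannot pass. Criteria must align within a marker type: a
  gene-level ratio cannot rescue an rRNA-level discriminant hit.
* All thresholds (p ≤ 0.05, score ≥ 3, ratio ≥ 2) are inclusive and
  configurable.

The one-sided Wilcoxon rank-sum test ("amounts formed" = final-day minus
day-0 concentration per replicate) uses exact enumeration of rank-sum
assignments with midranks up to a combined n of 12, and the tie-corrected
normal approximation above; fully tied data return p = 1. Bray–Curtis
distances come from the standard pdist routine; pairs involving an all-zero
sample are set undefined and warned about. Cross-experiment phylotype
matching demands exact, case-insensitive sequence identity over the full
common primer region — no alignment, by design.

## Synthetic data: what it emulates, what it does not

The chemistry generator is a phenomenological, rate-ruled electron ledger,
not a mechanistic growth model. Defaults are the study conditions: 10 mM
dosed H₂ consumed linearly at 0.45 mM d⁻¹ over a 17-day, 8-point schedule
at 15 °C in the 27/10/9.5 ml vessel with 3 replicates. Consumed H₂ first
reduces an unknown-sink pool (default 4 mM H₂-equivalents — the surrogate
for ferric iron/sulfate/humics), then splits between acetogenesis
(f_acetate = 0.7) and methanogenesis (f_ch4 = 0.2), consuming CO₂
stoichiometrically; small baseline production rates stand in for
peat-carbon turnover in both treatments. Electron balance of the ledger is
exact by construction. Observation noise is multiplicative log-normal
(default σ = 0.05, about the scatter implied by the R² ≈ 0.98 consumption
fits in comparable incubations) applied after mass balance, so
mass-balance tests run on the noiseless ledger. Unsupplemented treatments
keep H₂ at zero, which the emitter censors at the detection limit —
matching the observation that control H₂ sits below ~10 ppmV.

The community generator draws a log-normal baseline composition
(σ = 2 across features, a typical rank-abundance spread), multiplies
planted responders by their fold change in H₂-treatment samples of the
chosen marker types, applies per-sample log-normal dispersion (σ = 0.5, a
moderate replicate-to-replicate wiggle), and draws multinomial counts at
depth 50,000. Spike-in responders pin their baseline at the composition
median (`base_abundance=1.0`) in the benchmarks: the discriminant effect
size is absolute-abundance-dependent, so an uncontrolled spike abundance
would measure the rarity lottery rather than the procedure. The benchmarks
therefore show that the screen recovers clearly separated, fold-8,
median-abundance responders with ≥90 % sensitivity at ≤5 % average null
false-positive rate — they do not show sensitivity for rare taxa (a known
limitation of score-thresholded discriminant screens), nor do they model
PCR/primer bias, compositional coupling beyond the multinomial, or
read-level error.

## Pipeline and reporting

`run_pipeline` routes tables between the modules and writes
recovery/ΔG/stimulation/distance reports plus a JSON manifest (inputs,
seed, thresholds, version, row counts, aggregated warnings); every number
in a report is produced by a library function, and outputs are written
atomically so an interrupted run cannot leave a truncated table behind a
complete-looking name. Reports round per-table (one decimal for
recoveries); full-precision companions are always emitted. Identical
config + seed reruns are byte-identical.

## Known limitations

* No fugacity or ionic-strength corrections; 1 atm headspace assumed.
* Organic acids are treated as liquid-only analytes (no volatilisation).
* ΔG uses a single pH per treatment/day and assumes equilibrium gas
  partitioning when back-calculating dissolved concentrations from totals.
* The two-stage partition estimator assumes the generator's model family
  (linear consumption, sharp pool transition); real transitions are
  smoother, which would bias the pool estimate low by a few percent.
* The stimulation screen inherits LEfSe's insensitivity to rare taxa and
  the anticonservative nature of the chi-square Kruskal–Wallis p at n = 3.
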