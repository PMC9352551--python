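# Methods

## The assay and its estimator

A supernatant-depletion assay equilibrates a soluble receptor R (total
concentration [R]ₜ, typically 10⁻⁷ M here) against a resin-immobilized
ligand L presented as a two-fold serial dilution of labeled resin. The
readout is the receptor band intensity in the supernatant. The estimator
assumes:

* binding has reached equilibrium at the sampling time;
* a single-site mass-action law R + L ⇌ RL describes the chosen dilution
  (for multivalent constructs the resulting energy is a composite,
  flagged `apparent`);
* the band intensity is proportional to supernatant receptor concentration,
  and the no-ligand control lane measures the same proportionality constant;
* the stated total concentrations [L]ₜ and [R]ₜ are accurate (their
  experimental determination is outside this package's scope).

Unlike trace-receptor treatments, no species is assumed in excess: the
closed form `K_d = ([L]ₜ − F_b[R]ₜ)([R]ₜ − F_b[R]ₜ)/(F_b[R]ₜ)` corrects for
depletion of both partners. The `equilibrium` solvers are the exact inverse
of this estimator; the test suite verifies the round trip to a relative
1 × 10⁻⁹ over a 10×10×10 logarithmic grid of (K_d, [L]ₜ, [R]ₜ).

Energies are positive magnitudes −RT ln K_d against the 1 M standard
state. The incubation temperature, 20 °C (293.15 K), fixes RT =
0.5825 kcal/mol; conditions are an explicit parameter everywhere, since
using 25 °C instead would shift every energy by ~1.7%.

## Titration-point selection and aggregation

The dilution with mean fraction bound in [0.30, 0.60] closest to 0.45 is
selected once per experiment (ties toward the larger F_b, i.e. the stronger
signal); if no dilution is in band, the nearest point is used and flagged.
The band keeps the signal well above densitometry noise while avoiding the
saturating regime where F_b barely constrains K_d. Replicates are converted
to energies individually and then averaged — matching how replicate points
are plotted and summarized in estimation graphics — rather than averaging
F_b first (the two differ because the F_b → ΔG° map is nonlinear). Sample
SD uses the n−1 denominator. Replicates with F_b ≤ 0 are reported as
below-detection and excluded, never imputed; an experiment with zero valid
replicates raises an explicit all-below-detection signal.

## Bootstrap confidence intervals

Three methods are implemented over the same resampling core
(`numpy.random.default_rng(seed)`, resamples drawn with replacement within
each group, fully seed-deterministic):

* **studentized** (bootstrap-t) — the default for reported CIs. At the
  assay's n = 6, the plain percentile and BCa intervals of a mean are
  substantially anticonservative (measured empirical coverage of nominal
  95% intervals on normal replicate sets: ≈86% and ≈88%); the studentized
  interval measures ≈94–95% and is the defensible default at this sample
  size. Degenerate resamples (zero resample SD) contribute a pivot of 0.
* **percentile** — plain quantiles of the resampled statistic; used as the
  enumeration oracle in tests (for n = 3 the full 27-outcome resample
  distribution is enumerable) and in the power analysis.
* **bca** — bias-corrected and accelerated, the convention of the DABEST
  estimation-statistics software commonly used for Cumming plots. When the
  bias or acceleration correction is undefined (all values equal, zero
  jackknife variance, or a degenerate bias count) it falls back to
  percentile with an explicit flag. Cross-checked against
  `scipy.stats.bootstrap(method="BCa")` in the tests.

Group comparisons resample each group independently (experiments are
independent; nothing is paired), report mean(b) − mean(a), and export the
quantiles of the resampled difference distribution for Cumming-style
plotting without any plotting dependency. The studentized comparison uses
the unequal-variance (Welch) pivot.

Default 5000 resamples; CIs are 95% two-sided throughout.

## Detectability and limit of detection

`min_detectable_difference` defines "reliably detects" as: the two-sided
bootstrap 95% CI of the mean difference excludes zero in ≥80% of simulated
two-group experiments (normal replicate noise, common SD). The 80%-power /
5% two-sided criterion is a package choice, echoed in the output metadata.
True differences are scanned on a 0.02 kcal/mol grid; detection power is
monotone in the true difference, so the scan stops at the first grid point
meeting the power target. The simulation uses the percentile CI — the
detection rule as practiced with estimation-statistics software — and at
n = 6, SD = 0.1 kcal/mol yields 0.16 kcal/mol, consistent with the
normal-theory value (z₀.₉₇₅ + z₀.₈)·σ·√(2/n) = 0.162.

`limit_of_detection` converts the weakest quantifiable signal — the minimum
usable depletion `f_b_min` at the highest usable solid-phase concentration
`l_max` — through the same closed form. The defaults (l_max = 5×10⁻⁵ M,
[R]ₜ = 10⁻⁷ M, f_b_min = 0.1) are package parameters describing a typical
implementation of the assay, not measured facts; they give ≈4.5 kcal/mol.

## Synthetic data generator

`simulate_assay` emulates: a two-fold serial dilution of the solid phase
(10 dilutions from 10⁻⁴ M ligand molecules), exact multi-site equilibrium
occupancy at each dilution (receptor 10⁻⁷ M), one control lane per
replicate gel, and multiplicative log-normal densitometry noise — band
intensities are positive and staining/quantification error scales with
signal — with σ = ln(1 + cv) and cv defaulting to 0.05, chosen to
reproduce replicate-set SDs of ≈0.03–0.15 kcal/mol as observed on real
gels. Each replicate's control draw is shared across that replicate's
fraction-bound computations, as one control lane serves a gel, which
correlates the lanes of a replicate exactly as in practice. Optional
leaching adds supernatant contamination proportional to the control
intensity (the MBP-tag problem with amylose resin); it biases recovered
energies downward monotonically and defaults to 0. One seed governs a
scenario; replicate k draws from `default_rng([seed, k])`.

What the generator does **not** emulate: gel-to-gel calibration drift,
saturation/nonlinearity of Coomassie staining, pipetting error in the
dilution series, non-equilibrium sampling, and nonspecific background
beyond the control lane. Passing recovery tests therefore demonstrate the
estimator's correctness and its behavior under realistic multiplicative
noise, not robustness to every gel artifact.

Presets encode the measured scenarios (true energies 5.5–9.3 kcal/mol,
sextuplicate, with `apparent` flags matching the measured constructs' text
labels — including the PDZ2/PBM pair, whose reported energy is labeled
apparent despite both constructs carrying a single documented element),
plus a two-site avidity scenario and a solid-vs-soluble competition
scenario. Preset concentrations guarantee an in-band dilution for every
true energy in that range.

## Avidity and competition models

The multisite solver assumes independent site classes — receptor
conservation `r = f + Σᵢ Lᵢ f/(K_dᵢ + f)` solved for free receptor f by
bracketed root-finding (`scipy.optimize.brentq` on [0, r], machine-precision
relative tolerance; the conservation function is strictly monotone so the
root is unique and bracketing is guaranteed). No cooperativity parameter is
fitted: the model's role is the *independent-site null*. In the dilute-
receptor limit the apparent dissociation constant against ligand-molecule
concentration is (Σᵢ nᵢ/K_dᵢ)⁻¹, so two identical independent sites gain
exactly RT ln 2 ≈ 0.40 kcal/mol — the ceiling for statistical avidity, and
the yardstick separating it from genuine cooperativity or linked binding.
The competition solver is the same machinery with the competitor class
marked soluble, so only the solid class counts toward the depletion readout.

## Numerical choices

* Single-site occupancy uses the cancellation-free quadratic root
  `2lr/((l+r+K_d) + √disc)`, accurate at small fractional occupancy.
* F_b values produced by noise below 0 are clipped to 0 and flagged
  below-detection; F_b = 1 (empty receptor band) raises a saturation error
  rather than returning an infinite energy.
* A measurement whose implied complex exceeds total ligand raises a
  depletion-inconsistency error: the stated concentrations cannot produce it.
* Intensity tables are written with `%.17g` and read with round-trip float
  parsing, so write→read is bit-exact.

## Known limitations

* The estimator is a one-point method: it uses the chosen dilution only,
  not a fit across the whole isotherm, so a systematic error in [L]ₜ or
  [R]ₜ propagates directly into K_d.
* Apparent energies for multivalent constructs are composites; the package
  quantifies the independent-site bound but cannot decompose a measured
  composite into site contributions.
* The intramolecular (single-complex bivalent) avidity regime with
  effective local concentration is out of scope; only intermolecular,
  independent-site multivalency is modeled.
* Bootstrap CIs at n = 6 are approximate even when studentized; coverage
  was verified on normal replicate noise, and heavier-tailed densitometry
  error would degrade it.
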