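# Methods

## Models and procedure

The analysis chain reduces titration fluorescence spectra to binding
parameters in four stages.

**Quench ratios.** F₀ is read from the unquenched spectrum and F from
each quenched spectrum, after centered moving-average smoothing
(default window 5 grid points — wide enough to suppress single-point
noise spikes, narrow against a ~20 nm emission band) and parabolic
refinement of the discrete maximum. Two evaluation conventions are
provided because the literature rarely states which was used:
`reference_peak` (default) reads every F at the unquenched λmax — the
standard Stern–Volmer convention — while `per_spectrum_peak` reads each
spectrum's own peak height. When binding blue-shifts the band, the
fixed-wavelength convention mixes quenching with band displacement;
per-spectrum evaluation separates them (see *Limitations*). Rows with
F > F₀ are flagged as enhancement and excluded from fits, never
silently clamped.

**Stern–Volmer fit.** Ordinary least squares of F₀/F on [Q] with a free
intercept; the model forces intercept 1, so a fitted intercept outside
1 ± 0.1 raises a curvature warning. A through-(0, 1) constrained mode
is available. k_q = K_SV/τ₀ with τ₀ = 10⁻⁸ s (overridable).

**Mechanism call.** Static evidence: every k_q above the diffusion
collision limit 2×10¹⁰ L·mol⁻¹·s⁻¹ *and* K_SV non-increasing with
temperature (ties tolerated within one pooled standard error of the
per-temperature slopes). Dynamic evidence: k_q at or below the limit
and K_SV increasing. The reported trend is the sign of the OLS slope of
K_SV against T (sign of the difference for two temperatures), read as
flat when the predicted change over the temperature span is within the
pooled standard error. Any disagreement between the two criteria yields
"ambiguous" rather than a forced call.

**Double-log binding fit.** OLS of log₁₀((F₀−F)/F) on log₁₀[Q]
(base-10 throughout); slope = n, intercept = log₁₀ K_a. Rows with
non-positive (F₀−F)/F are dropped with a warning.

**Thermodynamics.** OLS of ln K_a on 1/T; ΔH⁰ = −slope·R,
ΔS⁰ = intercept·R with R = 8.314 J·mol⁻¹·K⁻¹; linear van't Hoff (ΔH
temperature-independent, no ΔCp term). ΔG⁰(T) = ΔH⁰ − T·ΔS⁰ is reported
from the fitted decomposition; −RT·ln K_a is carried as a separate
diagnostic column because the two routes disagree whenever the K_a set
is not exactly van't Hoff-consistent. All energies are joules
throughout; the classifier applies the Ross–Subramanian sign rules with
zeros mapped to "indeterminate".

## Synthetic generator

The generator is the exact conjugate of the fitting equations: bound
fraction b = K_a·Qⁿ/(1 + K_a·Qⁿ), peak intensity F = F₀/(1 + K_a·Qⁿ)
(so (F₀−F)/F = K_a·Qⁿ identically), a single Gaussian emission band
whose center moves from 338 nm by −blueshift_max·b, and multiplicative
Gaussian noise (1 + ε), ε ~ N(0, noise_rel), from a seeded generator.
Free-ligand depletion is neglected (ligand in excess), matching the
fitting equations' own assumption.

Defaults emulate the four-temperature soy-protein/β-carotene design:
T ∈ {273, 298, 318, 338} K, five ligand levels 2–10 µM plus the zero
reference, wavelength grid 300–500 nm at 1 nm, F₀ = 1000 a.u., band
σ = 10 nm, saturation blue shift 3 nm, noise_rel = 0.01. The
thermodynamic defaults are ΔH = 4003 J/mol (endothermic, so K_a rises
with temperature as observed in such systems) with ΔS = 108.2
J·mol⁻¹·K⁻¹ chosen so K_a(298 K) ≈ 0.9×10⁵ L/mol, the magnitude
reported for these complexes. Published (ΔH, ΔS) pairs for this system
are not van't Hoff-consistent with the published K_a magnitudes (they
imply K_a ≈ 10 L/mol); the generator is self-consistent by
construction, and `ka_override` lets callers pin K_a(T) to any external
table instead.

What the generator does *not* emulate: asymmetric real emission bands
(band shape cancels from intensity ratios, so fitted constants are
unaffected), scattering backgrounds, inner-filter effects, baseline
drift, or FTIR/CD spectra. Passing tests therefore demonstrate the
correctness of the estimators under the stated noise model, not
robustness to instrument artifacts.

The assay generator draws DPPH, foam, and emulsion records from linear
trends in the ligand/protein ratio index (scavenging 20→70%, foaming
capacity 30→55%, foam loss 45→10%, emulsion A₀ 0.8→0.5, ESI 60→90%)
with the same multiplicative noise, so computed indices are monotone in
expectation in the directions such studies report.

## Numerical choices

- Regressions use `scipy.stats.linregress`; tests verify agreement with
  an independent closed-form Σ-formula implementation to 10⁻¹⁰ relative.
- Peak refinement fits a parabola through the three points around the
  smoothed argmax (exact for an on-grid symmetric band; sub-0.05-step
  bias for off-grid Gaussian centers on a 1 nm grid). Edge maxima are
  returned unrefined with a boundary flag; flat spectra are an error.
- Smoothing requires a uniform axis grid; non-uniform grids are
  accepted with window 1.
- Two-temperature van't Hoff systems are solved exactly with r² = 1.
- CD signal is accepted in degrees; `CDRecord.from_millidegrees`
  divides by 1000 for instruments reporting mdeg. The mean residue
  weight is carried as metadata only — the molar-ellipticity formula
  uses residue count, molar concentration, and path length.
- The emulsifying-activity index defaults to the standard turbidimetric
  (Pearce–Kinsella) form 2×2.303×A₀×DF/(C·(1−φ)·10⁴); the reduced
  absorbance-free variant sometimes printed in methods sections is kept
  as an explicit `as_printed` mode. Foaming capacity divides by the
  whipped volume as printed (the unwhipped-volume convention is a flag),
  and "foaming stability" is the printed foam-*loss* percentage, with a
  `foam_retention` convenience for the complementary convention.

## Problem sizes

Test and acceptance runs use desk-scale problems: 20 random ground
truths for noiseless closure, 30 seeds × 4 noise levels for stochastic
recovery, 100 random datasets for the OLS-oracle comparison, 201-point
spectra. The full suite runs in a few seconds.

## Limitations

- The double-log intercept is an extrapolation of roughly five decades
  from the measured concentration window (log₁₀[Q] ≈ −5.1) to
  log₁₀[Q] = 0, so small slope noise is amplified ~5× in log₁₀ K_a:
  at 1% spectral noise the intercept-route K_a has ~18% median error
  while the Stern–Volmer slope — which equals K_a for the 1:1 static
  model — recovers it to under 1%. Parameter-recovery checks therefore
  score K_a through the Stern–Volmer slope and n through the double-log
  slope; both fits are always reported side by side. This conditioning
  gap is also a plausible source of the K_a/ΔG inconsistencies seen in
  published tables of this kind.
- With a nonzero blue shift, fixed-wavelength ratios fold band
  displacement into the quenching signal (a ~2% K_SV bias at the
  default 3 nm shift); per-spectrum-peak evaluation avoids this and is
  the better choice when a shift is evident.
- No Lehrer (modified Stern–Volmer), sphere-of-action, or global
  multi-temperature fitting; no error propagation from K_a uncertainty
  into (ΔH, ΔS) beyond the OLS standard errors.
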