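# quenchbind

Analysis toolkit for ligand–protein binding studied by intrinsic
fluorescence quenching, with the surrounding spectroscopy and
functional-property calculations used in food-protein work (e.g. a soy
protein isolate titrated with β-carotene).

When a hydrophobic ligand binds a protein, the tryptophan emission band
(λmax ≈ 338 nm) is quenched and blue-shifts. Titrating ligand
concentration [Q] at several temperatures and reading intensities F
(quenched) and F₀ (unquenched) gives access to the binding constants
and thermodynamics through four classical linear models:

- **Stern–Volmer**: F₀/F = 1 + K_SV·[Q]; the bimolecular quenching rate
  constant is k_q = K_SV/τ₀ with τ₀ = 10⁻⁸ s the unquenched lifetime.
  k_q above the diffusion-controlled limit (2×10¹⁰ L·mol⁻¹·s⁻¹) and
  K_SV falling with temperature both indicate *static* quenching
  (ground-state complex formation).
- **Double-logarithmic plot**: log₁₀((F₀−F)/F) = log₁₀(K_a) + n·log₁₀[Q]
  yields the apparent binding constant K_a and the binding-site number n.
- **Van't Hoff**: ln K_a = −ΔH⁰/(RT) + ΔS⁰/R decomposes the temperature
  dependence into enthalpy and entropy; ΔG⁰ = ΔH⁰ − T·ΔS⁰. Sign rules
  (Ross–Subramanian): ΔH⁰ > 0 and ΔS⁰ > 0 → hydrophobic driving force;
  both negative → van der Waals + hydrogen bonding; ΔG⁰ < 0 →
  spontaneous association.
- **Molar ellipticity** for CD traces: [θ] = θ/(R·C·l·10), and peak-shift
  classification for fluorescence and FTIR band positions.

Functional-property indices (DPPH radical scavenging, foaming capacity
and stability, emulsifying activity and stability) are included as
validated scalar formulas over CSV tables.

A seeded synthetic-titration generator produces spectra from known
ground truth (ΔH, ΔS, n, Gaussian band with saturation blue shift,
multiplicative noise), so the entire chain is verifiable end-to-end:
noiseless simulations are fitted back to machine precision.

## Worked example

Simulate a four-temperature titration bundle (1% multiplicative noise)
and analyze it:

```sh
quenchbind simulate --config sim.yaml --out-dir bundle --seed 1
quenchbind analyze --spectra-csv bundle/spectra.csv --out-dir out
```

prints (abridged):

```
Stern-Volmer fits:
  T=273 K  K_SV=7.773e+04 L/mol  kq=7.773e+12 L/mol/s  r2=0.9990
  T=298 K  K_SV=8.951e+04 L/mol  kq=8.951e+12 L/mol/s  r2=0.9999
  ...
Double-log binding fits:
  T=273 K  Ka=9.024e+04 L/mol  n=1.014  r2=0.9994
  ...
Quenching mechanism: ambiguous (K_SV trend increasing, diffusion limit 2e+10)
Driving force: hydrophobic
  dG(273 K) = -25738.6 J/mol  [spontaneous]
Peak shift at 273 K: blue shift of 0.835041 nm (337.7 -> 336.8)
```

The default ground truth is an endothermic binder (ΔH > 0), so K_a
rises with temperature and the fitted k_q ≈ 9×10¹² L·mol⁻¹·s⁻¹ is far
above the diffusion limit — one static criterion holds while the K_SV
trend points the other way, hence the honest "ambiguous" call. The
~1 nm blue shift reflects the bound fraction reached at 10 µM ligand.
The same chain is available in Python via `quenchbind.run_simulate` /
`run_analyze` or the individual functions (`quench_ratios`,
`stern_volmer_fit`, `double_log_fit`, `analyze_thermodynamics`, ...).

Analysis of measured data takes the same long-format spectra CSV
(`sample_id, temperature_K, quencher_conc_M, axis_kind, axis_value,
signal`), or — in skip-spectra mode — a direct map of temperature to
K_a in the config.

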