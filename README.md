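# ladkit

Phase-field modeling and super-resolution quantification of nuclear
heterochromatin domains and lamina-associated domains (LADs).

Chromatin in the nucleus segregates into dense, transcriptionally silent
heterochromatin (HC) and open euchromatin (EC). HC appears both as
interior domains with a characteristic radius and as LADs — HC tethered to
the nuclear lamina, quantified by a thickness profile along the nuclear
boundary. `ladkit` is for researchers who want to connect these two
observables to the biophysical parameters that control them: the effective
histone methylation rate Γ_me and the chromatin–lamina affinity V_LAD.

The package couples three layers:

* **Forward model** — a mesoscale reaction–diffusion (phase-field)
  simulator. The nuclear composition (φ_h, φ_e, φ_n, summing to 1) evolves
  by conserved Cahn–Hilliard-type fluxes of the chemical potentials of the
  free energy

      f = (c/2)[φ_e² + φ_h²(φ_h0−φ_h)²]
          + (κ/2)(|∇φ_n|² + |∇φ_d|²) − (V(φ_h)/d0)·e^(−d/d0),

  plus epigenetic interconversion 2(Γ_me φ_e − Γ_ac φ_h) acting on the
  order parameter φ_d = φ_h − φ_e. Spatially heterogeneous Γ_me(x) and
  V_LAD(s) fields are sampled as truncated Gaussian random fields.
* **Quantification** — a localization-microscopy (STORM) pipeline:
  Voronoi densities, pooled percentile density classes, DBSCAN domain
  calling (≥3 localizations), alpha-shape boundary estimation, LAD
  classification (2.5%-of-radius rule) and 50-segment thickness profiles.
  Simulated fields and localization tables land in one DomainTable schema.
* **Inverse extraction** — interior radii invert the kinetic-balance
  relation R_d = sqrt(3 D_h φ̄_h*/Γ_ac) in closed form; LAD thicknesses
  invert a simulation-built monotone response surface T_LAD(Γ_me, V_LAD),
  with plateau thicknesses assigned to the zero/saturated affinity bins —
  the mechanism behind bimodal extracted affinity distributions.

A synthetic-data generator (`ladkit.synthetic`) produces localization
clouds with known ground truth, so the whole pipeline is testable without
any imaging data. See `docs/methods.md` for model details, numerical
choices and known limitations.

## Worked example

```bash
python examples/02_quantify_localizations.py
```

generates a synthetic nucleus (radius 2.5 µm, 30 HC clusters of 50 nm,
200 nm LAD band, ~28k localizations) and quantifies it:

```
localizations               : 28033
estimated nuclear radius    : 2498 nm (true 2500)
interior domains called     : 30 (true 30)
mean interior radius R_d    : 51.8 nm (true 51.3)
mean LAD thickness T_LAD    : 193 nm (true 200)
```

All 30 generated clusters are recovered, the area-equivalent radius
matches the generated mean within the localization-noise floor, and the
LAD band reads back through the segment method within ~4%.

The other examples simulate a nucleus to quasi-steady state and quantify
it (`01_simulate_nucleus.py`) and run the inverse extraction on measured
sizes, including the bimodality readout (`03_extract_parameters.py`).
A thin CLI wraps the same stages:

```bash
ladkit synth --seed 1 --out out/synth
ladkit quantify-storm --input out/synth/localizations.csv --out out/quant
ladkit simulate --seed 1 --out out/sim
ladkit report --seed 1 --out out/panel     # perturbation panel
```

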