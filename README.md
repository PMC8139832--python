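# morphodyn

Quantitative machinery for studying how secreted signalling proteins (Wnt
ligands and their inhibitors, and secreted proteins generally) spread through
the intercellular space of an embryo while binding to discrete cell-surface
scaffolds such as heparan-sulfate clusters. The package bundles three things a
lab doing this kind of work needs:

1. **A two-state reaction-diffusion simulator.** Free ligand `u(x,t)` diffuses
   with coefficient `D`; bound ligand `v(x,t)` sits immobilised on docking
   sites. On a 1-D domain `0 ≤ x ≤ L`:

   ```
   ∂u/∂t = D ∂²u/∂x² − a(x)·u + b·v + g(x)
   dv/dt =             a(x)·u − b·v − c·v
   ```

   with binding rate `a(x)` nonzero only on a lattice of docking sites
   (interval `p1`, width `p2`), release rate `b`, internalization rate `c` and
   production `g(x)` confined to a small source region. Bound-peak values at
   steady state follow `c(x) = c0·exp(−x/λ)`; the decay length λ is the
   headline readout, with the homogenized closed form
   `λ_hom = √(D(b+c)/(ā·c))`, `ā = a_max·p2/p1`, as an analytic cross-check.

2. **Trace fitters for the two live-imaging modalities** used to measure the
   kinetic rates: FDAP (fluorescence decay after photoconversion) with the
   reaction-dominant model `I(t) = C + (1−C)·e^(−k_off·t)` and a
   strip-diffusion alternative parameterised by an apparent `D_a`, including
   per-scan photobleaching correction (`÷ q^n`, default q = 0.9991); and FCS
   (fluorescence correlation spectroscopy) with one- and two-component
   triplet + 3-D diffusion models, AIC model selection, quality filters and a
   multi-tau correlator for raw photon traces.

3. **Seeded synthetic-data generators** standing in for the microscope:
   photoconversion decays with bleaching and noise, immobilized bleaching
   controls, and Brownian-dynamics photon traces from emitters crossing a 3-D
   Gaussian detection volume (one or two species, optional triplet blinking).

Fitters follow the statsmodels convention: a model object built from data
whose `fit()` returns a results object with estimates, standard errors,
diagnostics and `summary()`.

## Worked example

Simulate the three canonical docking-site scenarios and fit their decay
lengths (half-resolution smoke mode; ~10 s):

```bash
$ morphodyn scenarios --fast
scenario                   b      c  lambda (um)  homogenized  rel diff      R^2
--------------------------------------------------------------------------------
baseline                0.10  0.100       6.3501       6.3246    0.40%  1.00000
slow_internalization    0.10  0.010      10.7873      14.8324   27.27%  0.99934
no_dissociation         0.00  0.100       4.5089       4.4721    0.82%  1.00000
```

Reading the table: slowing internalization tenfold (`c` 0.1 → 0.01) widens
the gradient from λ ≈ 6.35 µm to ≈ 10.8 µm, and removing release (`b = 0`)
narrows it to ≈ 4.5 µm — dissociation from scaffolds lengthens the range. The
`homogenized` column is the analytic steady-state prediction; the
slow-internalization row deviates from it because that scenario has not yet
reached steady state when the simulation stops at t = 100 s (deliberately —
that is the measured protocol).

Fitting a synthetic photoconversion decay:

```python
import morphodyn as md

trace = md.gen_fdap_trace(k_off=0.19, C=0.78, q=0.9991, noise_sd=0.02, rng=7)
fit = md.fit_dissociation(md.bleach_correct(trace, 0.9991))
print(fit.summary())
```

```
Dissociation model fit: I(t) = C + (1 - C) exp(-k_off t)
  k_off (1/s)      : 0.183889 +/- 0.0088
  C (immobile)     : 0.780928 +/- 0.0041
  SSE              : 0.235441
  R^2              : 0.842841
  max |residual|   : 0.0990
  within 0.05/0.10 : 96.2% / 100.0%
```

The fitted off-rate and immobile fraction recover the generating values
(0.19 s⁻¹, 0.78) within their standard errors; the residual-band lines are
the usual FDAP quality check (here: 96% of residuals within 0.05, all within
0.10).

CLI verbs: `simulate`, `fit-decay`, `fdap-fit`, `fcs-fit`, `generate`,
`scenarios`; run `morphodyn --help` for options.

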