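# imctissue

Inverse Monte Carlo recovery of tissue optical properties from
integrating-sphere spectra, with a synthetic-data pipeline that emulates
heated-skin spectroscopy.

## The problem

Dosimetry of photothermal treatments needs the absorption coefficient
(μa), scattering coefficient (μs) and scattering anisotropy (g) of skin —
and how they change when tissue is heated.  The canonical in-vivo
measurement sandwiches a thin sample (e.g. a mouse ear) between sapphire
windows on the port of a single integrating sphere and records, per
wavelength over 400–1650 nm, the diffuse reflectance R_d, total
transmittance T_t and diffuse transmittance T_d, with collimated
transmittance T_c = T_t − T_d.  Recovering (μa, μs, g) from
(R_d, T_t, T_c) requires a radiative-transfer model of the exact layered
geometry; this package implements the full chain:

* **Forward model** — weighted-photon Monte Carlo transport through the
  sapphire/tissue/sapphire stack with a finite beam, finite collection
  ports, Henyey–Greenstein scattering, Fresnel/Snell interfaces, Russian
  roulette and lateral edge losses, scoring all channels with exact weight
  bookkeeping (they sum to 1 to ~1e−15) and Monte Carlo standard errors.
* **Inverse solver** — per-wavelength quasi-Newton fit of
  x = (log μa, log μs, logit g) driving the relative residual on
  (R_d, T_t, T_c) to zero, with a finite-difference-initialized Jacobian
  maintained by rank-1 Broyden updates inside a dogleg trust region, and
  common random numbers so the stochastic forward map behaves
  deterministically within an inversion.
* **Synthetic spectra** — parametric ground truth (Gaussian chromophore
  bands + power-law scattering) with presets for 25 °C, 36 °C and 60 °C:
  heating deoxygenates hemoglobin (Soret band 417 → 426 nm, the 545/575 nm
  oxyhemoglobin double band collapsing to a single 557 nm band), blue-shifts
  the water bands (1192 → 1184 nm, 1454 → 1449 → 1441 nm), raises
  chromophore concentration and steepens the scattering slope.
* **Spectral analysis** — band-maximum localization (discrete argmax with
  parabolic refinement, plus a band-top quadratic fit for noisy spectra),
  OLS gradients of μs and μs′ = μs(1−g) versus wavelength, and two-stage
  (replicate summary + Welch / permutation) comparisons between
  temperature groups.

## Worked example

```python
from imctissue import (OpticalProperties, sandwich, SphereGeometry,
                       SimulationConfig, simulate_measurements,
                       InversionConfig, invert_optical_properties)

truth = OpticalProperties(mu_a=0.5, mu_s=8.0, g=0.90, n=1.4)  # mm^-1
stack = sandwich(truth)                  # sapphire / 0.3 mm tissue / sapphire
geom = SphereGeometry()                  # 1.9 mm beam, 5 mm port, 2.5 deg cone

meas = simulate_measurements(stack, geom, SimulationConfig(n_photons=20_000, seed=5))
print(f"Rd={meas.Rd:.4f}  Tt={meas.Tt:.4f}  Tc={meas.Tc:.4f}")

res = invert_optical_properties(meas, stack, geom,
                                InversionConfig(seed=5, residual_tolerance=1e-4,
                                                max_iterations=200))
r = res.recovered
print(f"mu_a={r.mu_a:.4f}  mu_s={r.mu_s:.3f}  g={r.g:.4f}  "
      f"residual={res.residual_norm:.2e}  calls={res.forward_calls}")
```

Output:

```
Rd=0.0527  Tt=0.5649  Tc=0.0753
mu_a=0.5020  mu_s=7.989  g=0.9001  residual=7.70e-04  calls=33
```

The simulated sphere observables (5.3% diffuse reflectance, 56% total and
7.5% collimated transmittance) are inverted back to the generating optical
properties within a fraction of a percent in 33 forward-model calls.  At
much weaker absorption (μa·d below ~0.01) μa becomes the
weakest-constrained parameter and is recovered only to within tens of
percent; see docs/methods.md.

The same flow runs from the shell:

```sh
imctissue synth 60C --seed 1 --out run/ --grid 1350:1550:2
imctissue invert run/measurements.csv --seed 1 --out run/
imctissue analyze --group 60C=run/results.csv --out run/report/
```

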