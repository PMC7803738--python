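# Temperature preset: 60 C (coagulated tissue).
# Fully deoxygenated blood: Soret band red-shifted to 426 nm, single deoxyhemoglobin
# band near 557 nm, deoxy NIR band near 905 nm.  Water bands blue-shifted to 1184 and
# 1441 nm.  Chromophore concentration raised by shrinkage (amplitude scales > 1),
# steeper scattering power law and slightly lower anisotropy after coagulation.
label: 60C
oxygen_saturation: 0.0
blood_amplitude_scale: 1.4
water_amplitude_scale: 1.25
baseline_mu_a: 0.13
scatter_a: 18.0
scatter_b: 1.50
g0: 0.89
g_slope: 0.0
n: 1.4
hemoglobin_bands_oxy:
  - {center: 417.0, width: 15.0, amplitude: 2.50}
  - {center: 545.0, width: 10.0, amplitude: 0.45}
  - {center: 575.0, width: 10.0, amplitude: 0.50}
hemoglobin_bands_deoxy:
  - {center: 426.0, width: 15.0, amplitude: 2.80}
  - {center: 557.0, width: 12.0, amplitude: 0.55}
  - {center: 905.0, width: 40.0, amplitude: 0.035}
water_bands:
  - {center: 1184.0, width: 35.0, amplitude: 0.10}
  - {center: 1441.0, width: 45.0, amplitude: 1.10}
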