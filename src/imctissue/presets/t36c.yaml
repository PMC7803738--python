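# Temperature preset: 36 C (body temperature).
# Identical chromophore state to 25 C except the 1454 nm water band sits at 1449 nm
# and the scattering slope is marginally steeper.
label: 36C
oxygen_saturation: 0.95
blood_amplitude_scale: 1.0
water_amplitude_scale: 1.0
baseline_mu_a: 0.10
scatter_a: 15.0
scatter_b: 1.15
g0: 0.92
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
  - {center: 1192.0, width: 35.0, amplitude: 0.08}
  - {center: 1449.0, width: 45.0, amplitude: 1.10}
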