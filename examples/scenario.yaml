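# Example scenario configuration for `cardiogrowth run`.
#
# Any subset of the default tree may be overridden; unknown keys are
# rejected.  Run with:
#   cardiogrowth run --config examples/scenario.yaml --out out_run

duration_days: 180.0
update_days: 90.0
equal_rates: false

geometry:
  preset: biventricle
  options: {}          # passed to the preset, e.g. {resolution: 5.0}

filling:
  lv_mmhg: 8.0
  rv_mmhg: 4.0

pacing:
  normal_azimuth_deg: 135.0   # septal initiation (normal conduction)
  paced_azimuth_deg: 315.0    # LV free-wall pacing site

growth:
  f: {tau_g: 3.8, tau_rg: 9.6}
  s: {tau_g: 9.6, tau_rg: 3.8}
  n: {tau_g: 9.6, tau_rg: 3.8}

output:
  write_vtk: false
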