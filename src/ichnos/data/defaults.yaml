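# Default estimator configuration.
#
# Ratio intervals are the published foot(print)-length ratios used for the
# Laetoli track-makers; the walk-only regression coefficients are not set
# here because their defaults are recovered at run time from the packaged
# printed-table fixtures (see ichnos.calibration.recover_paper_specs).
# Any regression block given below overrides the recovered default.
ratios:
  hs_foot_stature: [0.14, 0.16]        # dimensionless, H. sapiens foot/stature
  aa_foot_stature: [0.155, 0.162]      # dimensionless, Au. afarensis
  aa_footlength_mass: [0.543, 0.632]   # cm per kg, Au. afarensis
see:
  stature_by_length: 5.4   # cm
  mass_by_area: 3.7        # kg
  mass_by_length: 3.8      # kg
s2_exception:
  - S2          # individuals whose max width is unreliable: mass via length
gravity_m_s2: 9.81
walk_run_transition_m_s: 2.2
regressions: {}  # optional overrides: {name: {slope: .., intercept: .., see: ..}}
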