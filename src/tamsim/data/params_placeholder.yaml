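# PLACEHOLDER parameter set for the joint tamoxifen-endoxifen model.
# These are NOT published estimates: magnitudes are plausible for
# tamoxifen clinical pharmacology, but attainment percentages computed
# from them are illustrative only.  Transcribe the published estimates
# into a copy of this file (same keys) to reproduce reported results.
#
# Units: ka 1/h; tlag h; volumes L; clearances L/h; ref_age years;
# ref_wt kg; theta_* dimensionless power exponents; frac_change
# dimensionless fractional change of CL_23/F vs activity-score class 2;
# omega2_* variances of log-scale random effects; sigma_resid optional
# log-scale residual SD (null = simulate residual-free concentrations).
cl20_f_typ: 5.5
cl23_f_typ: 0.25
cl30_f: 5.0
frac_change:
  '0': -0.85
  '0.5': -0.65
  '1': -0.45
  '1.5': -0.1
  '2': 0.0
  '>2': 0.2
is_placeholder: true
ka: 0.4
omega2_cl20: 0.09
omega2_cl23: 0.16
ref_age: 55.0
ref_wt: 67.0
sigma_resid: null
theta_age: -0.25
theta_wt: 0.75
tlag: 0.5
v_endx_f: 400.0
v_tam_f: 1000.0
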