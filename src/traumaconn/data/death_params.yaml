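# Versioned registry of cell-death tolerance surfaces.
#
# Each region kind maps (t, eps, epsdot) -> D, the percent area of cell
# death, where t is time from insult in days, eps the local axonal strain
# (dimensionless) and epsdot the local effective strain rate (1/s).
# All surfaces are multiplicative power laws
#
#     D = amplitude * t^time_exponent * eps^strain_exponent
#                   * epsdot^rate_exponent        (rate-dependent regions)
#
# chosen because culture-derived tolerance criteria decompose the effects
# of strain, strain rate and time into separate multiplicative terms and
# are monotone non-decreasing in time over the validated 0-4 day window.
# Cortical cell death depends on the applied strain rate; hippocampal cell
# death does not. The default amplitudes are calibrated so that a 3% death
# threshold evaluated at 4 days predicts damage comparable to the classic
# 18% axonal-strain electrophysiological criterion (cortex: D(4 d, 0.18,
# 30/s) ~= 3%). The registry exists precisely so these coefficients can be
# replaced as region-specific (e.g. white-matter) criteria become
# available, without touching code.
version: 1
regions:
  cortex:
    form: power_law
    rate_dependent: true
    amplitude: 16.5
    time_exponent: 1.0
    strain_exponent: 2.0
    rate_exponent: 0.1
  hippocampus_ca1:
    form: power_law
    rate_dependent: false
    amplitude: 30.0
    time_exponent: 0.5
    strain_exponent: 1.8
  hippocampus_ca3_dg:
    form: power_law
    rate_dependent: false
    amplitude: 18.0
    time_exponent: 0.5
    strain_exponent: 2.0
aliases:
  # the more conservative (higher-death) hippocampal form is applied to the
  # entire hippocampus, which imaging cannot subdivide into CA1/CA3/DG
  hippocampus: hippocampus_ca1
  # white matter voxels default to the rate-dependent cortical surface
  white_matter: cortex
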