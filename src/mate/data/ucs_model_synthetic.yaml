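# SYNTHETIC default coefficients for the vertebral ultimate-compressive-
# strength (UCS) regression:
#   UCS [kN] = (c0 + c_sex*[male] - c_age*age/10) * clip(b0 + b1*BMI, 0.5, 1.5)
#
# Representative stand-in values, not a transcribed published regression:
# they place UCS in the 2-12 kN range reported for lumbar vertebrae in
# cadaver compression tests, declining with age and higher in males, with
# BMI as a linear endplate-area proxy normalised to 1.0 at BMI 20.
# Substitute study-specific coefficients for real assessments.
c0_kn: 9.0               # female strength extrapolated to age 0
c_age_kn_per_decade: 0.65
c_sex_kn: 1.5            # additive male offset
area_b0: 0.76
area_b1: 0.012           # per kg/m^2; BMI 20 -> factor 1.0
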