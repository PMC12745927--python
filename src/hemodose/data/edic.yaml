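# Effective dose to immune cells (EDIC): weighted combination of mean organ
# doses.  EDIC = lung*MLD + heart*MHD + liver*MLivD + body(n)*MBD with
# body(n) = body_base + body_slope * (n_fractions / 45).
#
# Coefficient values transcribed from the published immune-cell dose model
# for fractionated photon therapy (lung 0.12, heart 0.08, liver 0.15, body
# term 0.45 + 0.35*0.85*(n/45)); override this file to use a different
# parameterisation.  EDIC is reported as not-applicable (never zero) when
# any of lungs/heart/liver is outside the imaged field of view.
coefficients:
  lung: 0.12
  heart: 0.08
  liver: 0.15
  body_base: 0.45
  body_slope: 0.2975
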