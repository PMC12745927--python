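# Per-compartment blood physiology for the flat flow-weighted mixing topology.
#
# f_volume: fraction of the total blood volume residing in the compartment
#           (ICRP Report 89 reference distribution of blood volume, adult).
# f_flow:   fraction of the total transit flux (cardiac output) assigned to
#           the compartment in the parallel mixing topology.  In real
#           circulation the lungs and heart chambers carry the full cardiac
#           output in series; the flat topology redistributes flux so that
#           mean residence times t = f_volume*V/(f_flow*CO) stay on the
#           physiological order of seconds to minutes.  See docs/methods.md.
#
# Fractions not claimed by compartments present in a given patient fall to
# the automatically added rest_of_body remainder.
compartments:
  brain:            {f_volume: 0.012,  f_flow: 0.10}
  heart:            {f_volume: 0.090,  f_flow: 0.15}
  lungs:            {f_volume: 0.105,  f_flow: 0.15}
  liver:            {f_volume: 0.100,  f_flow: 0.14}
  kidneys:          {f_volume: 0.020,  f_flow: 0.08}
  spleen:           {f_volume: 0.014,  f_flow: 0.02}
  thyroid:          {f_volume: 0.0006, f_flow: 0.008}
  large_arteries:   {f_volume: 0.060,  f_flow: 0.06}
  large_veins:      {f_volume: 0.180,  f_flow: 0.06}
  skeletal_muscle:  {f_volume: 0.140,  f_flow: 0.09}
  fat:              {f_volume: 0.050,  f_flow: 0.04}
  skin:             {f_volume: 0.030,  f_flow: 0.03}
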