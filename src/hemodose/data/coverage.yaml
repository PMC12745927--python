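# Field-of-view coverage fractions: portion of a compartment's reference
# volume contained in the treatment-planning CT.  Compartments absent from
# this table default to 1.0 (fully imaged).  The out-of-view remainder is
# assumed to be far from the irradiated target and therefore unirradiated.
#
# Distributed tissues (skeletal muscle, fat, skin) extend over the whole
# body and are only partially captured by a site-limited scan; the defaults
# below are representative of a head-and-neck/thorax field of view and are
# meant to be overridden per site via --coverage-table.
coverage:
  skeletal_muscle: 0.30
  fat: 0.30
  skin: 0.30
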