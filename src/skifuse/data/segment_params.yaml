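# Reduced body-segment parameter table for the marker-based centre of mass:
# mass fraction of total body mass and CoM position fraction along the
# proximal->distal marker pair.  A deliberately coarse 3-segment model (the
# full anthropometric tables resolve ~16 segments); fractions sum to 1.
segments:
  - name: trunk
    mass_fraction: 0.50
    com_fraction: 0.50
    proximal: trunk_prox
    distal: trunk_dist
  - name: legs
    mass_fraction: 0.35
    com_fraction: 0.45
    proximal: legs_prox
    distal: legs_dist
  - name: arms
    mass_fraction: 0.15
    com_fraction: 0.45
    proximal: arms_prox
    distal: arms_dist
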