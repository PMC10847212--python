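# Structural / compositional classes per FBP fuel type (collapsed vocabulary).
# A synthetic rubric derived from the FBP System's descriptive fuel-type names;
# overridable by user config.  Used only to type mismatches, never to assign.
C-1: {structural_class: woodland, compositional_class: spruce}
C-2: {structural_class: closed-mature, compositional_class: spruce}
C-3: {structural_class: closed-mature, compositional_class: pine}
C-4: {structural_class: closed-immature, compositional_class: pine}
C-5: {structural_class: closed-mature, compositional_class: red-white-pine}
C-6: {structural_class: plantation, compositional_class: pine}
C-7: {structural_class: open-forest, compositional_class: fir-pine-dry-mix}
D-1: {structural_class: closed-mature, compositional_class: deciduous}
D-2: {structural_class: closed-mature, compositional_class: deciduous}
M-1: {structural_class: closed-mature, compositional_class: mixedwood}
M-2: {structural_class: closed-mature, compositional_class: mixedwood}
M-3: {structural_class: closed-mature, compositional_class: dead-fir-mixedwood}
M-4: {structural_class: closed-mature, compositional_class: dead-fir-mixedwood}
S-1: {structural_class: slash, compositional_class: pine}
S-2: {structural_class: slash, compositional_class: spruce-fir}
S-3: {structural_class: slash, compositional_class: cedar-hemlock-fir}
O-1: {structural_class: grass, compositional_class: grass}
NF: {structural_class: non-fuel, compositional_class: non-fuel}
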