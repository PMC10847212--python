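# Provincial inventory species letter codes used in plot records.
# habit: conifer | broadleaf | deciduous_conifer.  Western larch (LW) is the
# deciduous conifer whose grouping with broadleaf species is controlled by the
# rule-set flag larch_as_deciduous.
FD: {name: interior Douglas-fir, habit: conifer}
PY: {name: ponderosa pine, habit: conifer}
PL: {name: lodgepole pine, habit: conifer}
SE: {name: Engelmann spruce, habit: conifer}
SX: {name: hybrid spruce, habit: conifer}
BL: {name: subalpine fir, habit: conifer}
CW: {name: western redcedar, habit: conifer}
HW: {name: western hemlock, habit: conifer}
LW: {name: western larch, habit: deciduous_conifer}
AT: {name: trembling aspen, habit: broadleaf}
ACT: {name: black cottonwood, habit: broadleaf}
EP: {name: paper birch, habit: broadleaf}
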