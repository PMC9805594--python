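# JAK-STAT signalling: cytoplasmic STAT x1 (in its own measurement units; p2
# converts to the units of the phosphorylated pools), phosphorylated STAT x2,
# cytoplasmic dimer x3, nuclear dimer x4.  u(t) is the measured receptor
# activity (EpoR); activation, dimerization, nuclear import and recycling form
# the cycle.  Outputs are total phosphorylated STAT (absolute units) and total
# STAT with the unphosphorylated pool entering through the scale p6.
name: jakstat
states: [x1, x2, x3, x4]
parameters: [p1, p2, p3, p4, p5, p6]
known_inputs: [u]
unknown_inputs: []
rhs:
  x1: "-p1*u*x1 + 2*p5*x4"
  x2: "p1*p2*u*x1 - 2*p3*x2**2"
  x3: "p3*x2**2 - p4*x3"
  x4: "p4*x3 - p2*p5*x4"
outputs: ["x2 + 2*x3", "p6*x1 + x2 + 2*x3"]
x0: {x1: 1.0, x2: 0.0, x3: 0.0, x4: 0.0}
nominal: {p1: 0.05, p2: 2.0, p3: 0.2, p4: 0.1, p5: 0.05, p6: 0.5}
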