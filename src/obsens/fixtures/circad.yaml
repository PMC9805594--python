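# Circadian oscillator (activator-repressor gene circuit).  States follow the
# conventional ordering: x1/x2 free and activator-bound activator gene, x3/x4
# free and activator-bound repressor gene, x5 activator mRNA (MA), x6 activator
# protein (A), x7 repressor mRNA (MR), x8 repressor protein (R), x9 the A-R
# complex (C).  The three proteins A, R and C are measured; the two mRNAs are
# not.
name: circad
states: [x1, x2, x3, x4, x5, x6, x7, x8, x9]
parameters: [aA, aAp, aR, aRp, bA, bR, dMA, dMR, dA, dR, gA, gR, gC, thA, thR]
known_inputs: []
unknown_inputs: []
rhs:
  x1: "thA*x2 - gA*x1*x6"
  x2: "gA*x1*x6 - thA*x2"
  x3: "thR*x4 - gR*x3*x6"
  x4: "gR*x3*x6 - thR*x4"
  x5: "aAp*x2 + aA*x1 - dMA*x5"
  x6: "bA*x5 + thA*x2 + thR*x4 - x6*(gA*x1 + gR*x3 + gC*x8) - dA*x6"
  x7: "aRp*x4 + aR*x3 - dMR*x7"
  x8: "bR*x7 - gC*x6*x8 + dA*x9 - dR*x8"
  x9: "gC*x6*x8 - dA*x9"
outputs: ["x6", "x8", "x9"]
x0: {x1: 1.0, x2: 0.0, x3: 1.0, x4: 0.0, x5: 0.0, x6: 0.0, x7: 0.0, x8: 0.0, x9: 0.0}
nominal:
  aA: 50.0
  aAp: 500.0
  aR: 0.01
  aRp: 50.0
  bA: 50.0
  bR: 5.0
  dMA: 10.0
  dMR: 0.5
  dA: 1.0
  dR: 0.2
  gA: 1.0
  gR: 1.0
  gC: 2.0
  thA: 50.0
  thR: 100.0
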