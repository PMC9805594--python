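# Cell-division cycle oscillator (cdc2-cyclin interactions).  States: free
# cdc2 x1, phosphorylated cdc2 x2, inactive complex (preMPF) x3, active MPF x4,
# free cyclin x5, degraded cyclin-phosphate x6.  Concentrations are normalized
# to total cdc2, which is conserved (x1+x2+x3+x4 = const).  MPF activation is
# autocatalytic through the quadratic feedback in x4.  Measured: MPF activity
# and the undegraded cyclin pool.
name: celldiv
states: [x1, x2, x3, x4, x5, x6]
parameters: [k1, k3, k4, k4p, k6, k7, k8, k9]
known_inputs: []
unknown_inputs: []
rhs:
  x1: "k6*x4 - k8*x1 + k9*x2"
  x2: "-k3*x2*x5 + k8*x1 - k9*x2"
  x3: "k3*x2*x5 - x3*(k4p + k4*x4**2/(x1 + x2 + x3 + x4)**2)"
  x4: "x3*(k4p + k4*x4**2/(x1 + x2 + x3 + x4)**2) - k6*x4"
  x5: "k1 - k3*x2*x5"
  x6: "k6*x4 - k7*x6"
outputs: ["x4", "x3 + x4 + x5"]
x0: {x1: 0.0, x2: 1.0, x3: 0.0, x4: 0.0, x5: 0.0, x6: 0.0}
nominal: {k1: 0.015, k3: 200.0, k4: 180.0, k4p: 0.018, k6: 1.0, k7: 0.6, k8: 100.0, k9: 100.0}
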