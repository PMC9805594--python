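# Glucose regulation circuit (betaIG): glucose x1 (mM), insulin x2 (in units
# of its glycemic action, so si is of order one), beta-cell mass x3
# (normalized).  Glucose is produced at a basal rate u0 = 0.2 mM/min and
# cleared at the physiological fractional turnover (c + si*x2 ~ 0.04/min);
# insulin is secreted with a sigmoidal glucose response (half-max alpha) and
# degraded with a ~7 min half-life; beta-cell mass adapts very slowly around
# the 5 mM glucose set point.  The meal glucose appearance w(t) is an unknown
# (unmeasured) input.  Only glucose is measured.
name: big
states: [x1, x2, x3]
parameters: [c, si, gamma, p, alpha]
known_inputs: []
unknown_inputs: [w]
rhs:
  x1: "w + 1/5 - (c + si*x2)*x1"
  x2: "p*x3*x1**2/(alpha**2 + x1**2) - gamma*x2"
  x3: "x3*(2*x1**2/(25 + x1**2) - 1)/10000"
outputs: ["x1"]
x0: {x1: 5.0, x2: 0.04, x3: 1.0}
nominal: {c: 0.01, si: 0.75, gamma: 0.1, p: 0.008, alpha: 5.0}
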