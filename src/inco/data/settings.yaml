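# Simulation settings: log-odds effect sizes of the disease model.
# Part A: one causal region (beta1 SNV, beta2 CNV, beta3 their product).
# Part B: two causal regions; gamma terms mirror the betas for region 2.
# The intercept is the baseline disease prevalence (0.01) on the
# probability scale.  Settings marked verified: false are placeholders for
# parameter combinations published only in supplementary material.
prevalence: 0.01
part_a:
  A1: {beta: [0.0, 0.0, 0.0]}
  A2: {beta: [0.01, 0.01, 0.01]}
  A3: {beta: [0.01, 0.01, 1.0]}
  A4: {beta: [0.01, 0.01, 2.0]}
  A5: {beta: [0.5, 0.5, 1.0]}
  A6: {beta: [0.1, 0.1, 0.0]}
  A7: {beta: [0.5, 0.5, 0.0]}
  A8: {beta: [1.0, 1.0, 0.0]}
  A9: {beta: [2.0, 2.0, 0.0]}
part_b:
  B1: {beta: [0.01, 0.01, 0.01], gamma: [0.01, 0.01, 0.01]}
  B2: {beta: [0.01, 0.01, 0.5], gamma: [0.01, 0.01, 0.5]}
  B3: {beta: [0.01, 0.01, 1.0], gamma: [0.01, 0.01, 1.0]}
  B4: {beta: null, gamma: null, verified: false}
  B5: {beta: [0.5, 0.5, 0.01], gamma: [0.5, 0.5, 0.01]}
  B6: {beta: [1.0, 1.0, 0.01], gamma: [1.0, 1.0, 0.01]}
  B7: {beta: null, gamma: null, verified: false}
  B8: {beta: [1.0, 1.0, 1.0], gamma: [1.0, 1.0, 1.0]}
  B9: {beta: [0.01, 0.01, 0.5], gamma: [-0.01, -0.01, -0.5]}
  B10: {beta: [0.01, 0.01, 1.0], gamma: [-0.01, -0.01, -1.0]}
  B11: {beta: null, gamma: null, verified: false}
  B12: {beta: [0.5, 0.0, 0.01], gamma: [0.0, 0.5, 0.01]}
  B13: {beta: [1.0, 0.0, 0.01], gamma: [0.0, 1.0, 0.01]}
  B14: {beta: null, gamma: null, verified: false}
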