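{
  "name": "table2_printed",
  "description": "Reference parameter set as printed, with the transmission rates at their threshold-analysis values (beta1=0.003, beta2=0.007) and neutral co-infection modification factors.",
  "params": {
    "Lambda": 50.0,
    "mu": 0.01,
    "beta1": 0.003,
    "beta2": 0.007,
    "beta_mod": 1.2,
    "kappa": 1.3,
    "delta": 0.40,
    "epsilon": 0.60,
    "alpha": 0.51,
    "sigma": 0.50,
    "rho": 0.61,
    "omega": 0.60,
    "phi": 0.50,
    "theta": 0.72,
    "theta1": 1.0,
    "theta2": 1.0
  }
}
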