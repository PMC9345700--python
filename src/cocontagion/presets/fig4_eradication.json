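{
  "name": "fig4_eradication",
  "description": "Sub-threshold scenario (beta1=0.0001, beta2=0.0002 on the reconciled preset, R0 < 1 for both behaviours): both contagions and their coexistence die out.",
  "params": {
    "Lambda": 5.0,
    "mu": 0.01,
    "beta1": 0.0001,
    "beta2": 0.0002,
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
  },
  "scenario": {
    "t_end": 200.0
  }
}
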