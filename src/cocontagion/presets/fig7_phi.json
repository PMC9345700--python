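{
  "name": "fig7_phi",
  "description": "Control experiment on the persistence scenario: sweep the co-infection recuperation rate phi over 0.6, 0.7, 0.8 and compare the co-infected trajectories.",
  "params": {
    "Lambda": 5.0,
    "mu": 0.01,
    "beta1": 0.001,
    "beta2": 0.004,
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
    "t_end": 10.0,
    "control": {"name": "phi", "values": [0.6, 0.7, 0.8]}
  }
}
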