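{
  "description": "General differential pathlength factor model DPF(lambda, age) = alpha + beta*age^gamma + delta*lambda^3 + epsilon*lambda^2 + zeta*lambda, lambda in nm, age in years (Scholkmann & Wolf general DPF equation).",
  "version": 1,
  "alpha": 223.3,
  "beta": 0.05624,
  "gamma": 0.8493,
  "delta": -5.723e-7,
  "epsilon": 0.001245,
  "zeta": -0.9025,
  "wavelength_range_nm": [650, 900],
  "age_range_years": [18, 100]
}
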