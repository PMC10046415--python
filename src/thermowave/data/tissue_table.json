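{
  "_comment": "Synthetic, representative two-pole Cole-Cole parameters for neck tissues at 37 degC. Values are fixture data chosen to give realistic permittivity/conductivity in the 0.5-2.5 GHz band; they are not a transcription of any published database. Temperature coefficients are linear relative rates per degC, applied only to heat-sensitive structures (tumor, spinal cord). The tumor is modelled as an elevated-permittivity nodular thyroid lesion.",
  "version": 1,
  "tissues": {
    "skin": {
      "cole_cole": {"eps_inf": 4.0, "delta_eps1": 34.0, "delta_eps2": 110.0, "tau1": 7.23e-12, "tau2": 3.25e-8, "alpha1": 0.0, "alpha2": 0.2, "sigma": 0.0002}
    },
    "fat": {
      "cole_cole": {"eps_inf": 2.5, "delta_eps1": 9.0, "delta_eps2": 35.0, "tau1": 7.96e-12, "tau2": 1.59e-8, "alpha1": 0.2, "alpha2": 0.1, "sigma": 0.035}
    },
    "muscle": {
      "cole_cole": {"eps_inf": 4.0, "delta_eps1": 50.0, "delta_eps2": 7000.0, "tau1": 7.23e-12, "tau2": 3.54e-7, "alpha1": 0.1, "alpha2": 0.1, "sigma": 0.2}
    },
    "bone": {
      "cole_cole": {"eps_inf": 2.5, "delta_eps1": 10.0, "delta_eps2": 180.0, "tau1": 1.33e-11, "tau2": 7.96e-8, "alpha1": 0.2, "alpha2": 0.2, "sigma": 0.02}
    },
    "spinal_cord": {
      "cole_cole": {"eps_inf": 4.0, "delta_eps1": 28.0, "delta_eps2": 500.0, "tau1": 7.96e-12, "tau2": 1.59e-8, "alpha1": 0.1, "alpha2": 0.15, "sigma": 0.006},
      "temperature_coefficients": {"sigma": 0.02, "delta_eps1": -0.005}
    },
    "thyroid": {
      "cole_cole": {"eps_inf": 4.0, "delta_eps1": 55.0, "delta_eps2": 100.0, "tau1": 7.23e-12, "tau2": 1.59e-7, "alpha1": 0.1, "alpha2": 0.1, "sigma": 0.5}
    },
    "tumor": {
      "cole_cole": {"eps_inf": 4.0, "delta_eps1": 62.0, "delta_eps2": 120.0, "tau1": 7.23e-12, "tau2": 1.59e-7, "alpha1": 0.1, "alpha2": 0.1, "sigma": 0.7},
      "temperature_coefficients": {"sigma": 0.02, "delta_eps1": -0.005}
    }
  }
}
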