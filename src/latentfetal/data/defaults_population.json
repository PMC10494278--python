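{
 "n": 1253,
 "seed": 20150701,
 "variant": "population",
 "continuous": {
  "age": {
   "dist": "normal",
   "mu": 25.0,
   "sigma": 6.9,
   "clip": [
    13.0,
    49.0
   ]
  },
  "height_m": {
   "dist": "normal",
   "mu": 1.57,
   "sigma": 0.0593,
   "clip": [
    1.3,
    1.95
   ]
  },
  "prepreg_weight_kg": {
   "dist": "lognormal",
   "mu": 4.0483,
   "sigma": 0.18,
   "clip": [
    35.0,
    150.0
   ]
  }
 },
 "binary_prev": {
  "primiparity": 0.397,
  "smoking": 0.052,
  "malaria_pregnancy": 0.075
 },
 "latent_names": [
  "age",
  "height_m",
  "prepreg_weight_kg",
  "primiparity",
  "smoking",
  "malaria_pregnancy"
 ],
 "latent_corr": [
  [
   1.0,
   0.05,
   0.2,
   -0.6,
   0.1,
   0.0
  ],
  [
   0.05,
   1.0,
   0.4,
   0.0,
   0.0,
   0.0
  ],
  [
   0.2,
   0.4,
   1.0,
   -0.15,
   0.0,
   0.0
  ],
  [
   -0.6,
   0.0,
   -0.15,
   1.0,
   0.05,
   0.05
  ],
  [
   0.1,
   0.0,
   0.0,
   0.05,
   1.0,
   0.05
  ],
  [
   0.0,
   0.0,
   0.0,
   0.05,
   0.05,
   1.0
  ]
 ],
 "endo_paths": {
  "elevated_bp": {
   "prepreg_weight_kg": 0.004,
   "age": 0.003,
   "primiparity": -0.02,
   "const": -0.17466,
   "omega_gaussian": 0.110124
  },
  "insufficient_gwg": {
   "prepreg_weight_kg": 0.002,
   "primiparity": 0.06,
   "smoking": 0.08,
   "malaria_pregnancy": 0.06,
   "const": 0.18572,
   "omega_gaussian": 0.222775
  }
 },
 "gamma": {
  "age": 0.0,
  "height_cm": 0.01,
  "prepreg_weight_kg": 0.02,
  "elevated_bp": -0.22,
  "primiparity": -0.29,
  "smoking": -0.55,
  "malaria_pregnancy": -0.17,
  "insufficient_gwg": -0.36
 },
 "lam": 0.82,
 "nu": {
  "bwz": -2.350686,
  "blz": -1.943163
 },
 "psi": 0.53209,
 "theta": {
  "bwz": 0.086507,
  "blz": 0.378496
 },
 "outcome_params": {
  "preterm": {
   "a": -2.709648,
   "b": -0.693147
  },
  "reanimation": {
   "a": -3.102603,
   "b": 0.0
  },
  "formula_rx": {
   "a": -1.918759,
   "b": 0.0
  },
  "stay_gt3d": {
   "a": -2.868911,
   "b": -0.693147
  }
 },
 "missingness": {},
 "skewed_residuals": false,
 "gaussian_covariates": false,
 "direct_effects": null
}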