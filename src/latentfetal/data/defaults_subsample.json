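{
 "n": 499,
 "seed": 20150701,
 "variant": "subsample",
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
  },
  "hc_z": {
   "dist": "normal",
   "mu": -0.25,
   "sigma": 0.956,
   "clip": [
    -5.0,
    5.0
   ]
  },
  "ac_z": {
   "dist": "normal",
   "mu": 0.22,
   "sigma": 1.045,
   "clip": [
    -5.0,
    5.0
   ]
  },
  "fl_z": {
   "dist": "normal",
   "mu": 0.03,
   "sigma": 1.023,
   "clip": [
    -5.0,
    5.0
   ]
  }
 },
 "binary_prev": {
  "primiparity": 0.453,
  "smoking": 0.046,
  "malaria_pregnancy": 0.07
 },
 "latent_names": [
  "age",
  "height_m",
  "prepreg_weight_kg",
  "primiparity",
  "smoking",
  "malaria_pregnancy",
  "hc_z",
  "ac_z",
  "fl_z"
 ],
 "latent_corr": [
  [
   1.0,
   0.05,
   0.2,
   -0.6,
   0.1,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.05,
   1.0,
   0.4,
   0.0,
   0.0,
   0.0,
   0.1,
   0.1,
   0.1
  ],
  [
   0.2,
   0.4,
   1.0,
   -0.15,
   0.0,
   0.0,
   0.1,
   0.1,
   0.1
  ],
  [
   -0.6,
   0.0,
   -0.15,
   1.0,
   0.05,
   0.05,
   0.0,
   0.0,
   0.0
  ],
  [
   0.1,
   0.0,
   0.0,
   0.05,
   1.0,
   0.05,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.0,
   0.0,
   0.05,
   0.05,
   1.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.1,
   0.1,
   0.0,
   0.0,
   0.0,
   1.0,
   0.55,
   0.45
  ],
  [
   0.0,
   0.1,
   0.1,
   0.0,
   0.0,
   0.0,
   0.55,
   1.0,
   0.5
  ],
  [
   0.0,
   0.1,
   0.1,
   0.0,
   0.0,
   0.0,
   0.45,
   0.5,
   1.0
  ]
 ],
 "endo_paths": {
  "elevated_bp": {
   "prepreg_weight_kg": 0.004,
   "age": 0.003,
   "primiparity": -0.02,
   "const": -0.15954,
   "omega_gaussian": 0.1204
  },
  "insufficient_gwg": {
   "prepreg_weight_kg": 0.002,
   "primiparity": 0.06,
   "smoking": 0.08,
   "malaria_pregnancy": 0.06,
   "const": 0.15914,
   "omega_gaussian": 0.214279
  }
 },
 "gamma": {
  "age": 0.01,
  "height_cm": 0.02,
  "prepreg_weight_kg": 0.01,
  "elevated_bp": -0.42,
  "primiparity": -0.19,
  "smoking": -0.58,
  "malaria_pregnancy": -0.04,
  "insufficient_gwg": -0.32,
  "hc_z": 0.18,
  "ac_z": 0.28,
  "fl_z": 0.11
 },
 "lam": 0.83,
 "nu": {
  "bwz": -3.740342,
  "blz": -3.087884
 },
 "psi": 0.453583,
 "theta": {
  "bwz": 0.189317,
  "blz": 0.513233
 },
 "outcome_params": {
  "preterm": {
   "a": -2.665571,
   "b": -0.693147
  },
  "reanimation": {
   "a": -3.547151,
   "b": 0.0
  },
  "formula_rx": {
   "a": -1.918759,
   "b": 0.0
  },
  "stay_gt3d": {
   "a": -2.835376,
   "b": -0.693147
  }
 },
 "missingness": {},
 "skewed_residuals": false,
 "gaussian_covariates": false,
 "direct_effects": null
}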