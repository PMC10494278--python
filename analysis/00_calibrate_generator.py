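"""Calibrate and freeze the synthetic-cohort generator defaults.

The cohort analysis pins down the structural coefficients (gamma), the free
loading (lambda) and the explained-variance shares, but not the latent
disturbance psi, the indicator residual variances theta, the indicator
intercepts nu, or the covariate dependence.  This driver chooses those free
quantities once: it draws a very large covariate block from the documented
marginals and copula, computes the empirical determinant covariance Phi,
and solves

    psi    from  gamma' Phi gamma / (gamma' Phi gamma + psi) = R2_latent
    theta1 from  Var(eta) / (Var(eta) + theta1)              = R2_bwz
    theta2 from  lam^2 Var(eta) / (lam^2 Var(eta) + theta2)  = R2_blz
    nu     from  the target indicator means,

then freezes everything into src/latentfetal/data/defaults_<variant>.json.
Rerunning this script reproduces the shipped fixtures byte-for-byte.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from latentfetal.simulate import (  # noqa: E402
    GeneratorConfig, _draw_covariates, _endogenous, _model_scale,
    solve_outcome_intercept,
)
from latentfetal.sem import mimic_spec  # noqa: E402

CALIBRATION_N = 2_000_000
CALIBRATION_SEED = 20150701
OUT_DIR = Path(__file__).resolve().parents[1] / "src" / "latentfetal" / "data"

LOG_HALF = float(np.log(0.5))

COMMON_CONTINUOUS = {
    "age": {"dist": "normal", "mu": 25.0, "sigma": 6.9, "clip": [13.0, 49.0]},
    "height_m": {"dist": "normal", "mu": 1.57, "sigma": 0.0593, "clip": [1.30, 1.95]},
    "prepreg_weight_kg": {
        "dist": "lognormal", "mu": 4.0483, "sigma": 0.18, "clip": [35.0, 150.0],
    },
}

BASE = {
    "population": {
        "n": 1253,
        "binary_prev": {"primiparity": 0.397, "smoking": 0.052,
                        "malaria_pregnancy": 0.075},
        "latent_names": ["age", "height_m", "prepreg_weight_kg",
                         "primiparity", "smoking", "malaria_pregnancy"],
        # copula-scale dependence: primiparity concentrated at younger ages,
        # height-weight anthropometric correlation, weak clustering of the
        # infection/behaviour flags
        "latent_corr": [
            [1.00, 0.05, 0.20, -0.60, 0.10, 0.00],
            [0.05, 1.00, 0.40, 0.00, 0.00, 0.00],
            [0.20, 0.40, 1.00, -0.15, 0.00, 0.00],
            [-0.60, 0.00, -0.15, 1.00, 0.05, 0.05],
            [0.10, 0.00, 0.00, 0.05, 1.00, 0.05],
            [0.00, 0.00, 0.00, 0.05, 0.05, 1.00],
        ],
        "gamma": {
            "age": 0.0, "height_cm": 0.01, "prepreg_weight_kg": 0.02,
            "elevated_bp": -0.22, "primiparity": -0.29, "smoking": -0.55,
            "malaria_pregnancy": -0.17, "insufficient_gwg": -0.36,
        },
        "lam": 0.82,
        "r2_targets": {"latent": 0.185, "bwz": 0.883, "blz": 0.537},
        "indicator_means": {"bwz": 0.08, "blz": 0.05},
        "outcome_prev": {"preterm": 0.075, "reanimation": 0.043,
                         "formula_rx": 0.128, "stay_gt3d": 0.065},
        "ebp_prev": 0.126, "gwg_prev": 0.335,
    },
    "subsample": {
        "n": 499,
        "binary_prev": {"primiparity": 0.453, "smoking": 0.046,
                        "malaria_pregnancy": 0.070},
        "latent_names": ["age", "height_m", "prepreg_weight_kg",
                         "primiparity", "smoking", "malaria_pregnancy",
                         "hc_z", "ac_z", "fl_z"],
        "latent_corr": None,  # filled below: population block + biometry block
        "gamma": {
            "age": 0.01, "height_cm": 0.02, "prepreg_weight_kg": 0.01,
            "elevated_bp": -0.42, "primiparity": -0.19, "smoking": -0.58,
            "malaria_pregnancy": -0.04, "insufficient_gwg": -0.32,
            "hc_z": 0.18, "ac_z": 0.28, "fl_z": 0.11,
        },
        "lam": 0.83,
        "r2_targets": {"latent": 0.438, "bwz": 0.81, "blz": 0.52},
        "indicator_means": {"bwz": -0.02, "blz": 0.00},
        "outcome_prev": {"preterm": 0.078, "reanimation": 0.028,
                         "formula_rx": 0.128, "stay_gt3d": 0.067},
        "ebp_prev": 0.140, "gwg_prev": 0.311,
    },
}

# biometry marginals and their dependence (moderate mutual correlation of
# the three foetal measures, weak link to maternal anthropometry)
BIOMETRY_CONTINUOUS = {
    "hc_z": {"dist": "normal", "mu": -0.25, "sigma": 0.956, "clip": [-5.0, 5.0]},
    "ac_z": {"dist": "normal", "mu": 0.22, "sigma": 1.045, "clip": [-5.0, 5.0]},
    "fl_z": {"dist": "normal", "mu": 0.03, "sigma": 1.023, "clip": [-5.0, 5.0]},
}


def _subsample_corr(pop_corr):
    C = np.eye(9)
    C[:6, :6] = np.asarray(pop_corr)
    bio = np.array([[1.00, 0.55, 0.45],
                    [0.55, 1.00, 0.50],
                    [0.45, 0.50, 1.00]])
    C[6:, 6:] = bio
    for j, name in enumerate(("hc_z", "ac_z", "fl_z")):
        C[1, 6 + j] = C[6 + j, 1] = 0.10  # height
        C[2, 6 + j] = C[6 + j, 2] = 0.10  # weight
    return C.tolist()


def _endo_paths(variant, base):
    # linear-probability paths on the probability scale; intercepts solved
    # so the mean matches the target prevalence at the covariate means
    if variant == "population":
        mean_wt, mean_age, mean_primi = 58.4, 25.0, base["binary_prev"]["primiparity"]
    else:
        mean_wt, mean_age, mean_primi = 58.4, 25.0, base["binary_prev"]["primiparity"]
    ebp = {"prepreg_weight_kg": 0.004, "age": 0.003, "primiparity": -0.02}
    ebp_lin = ebp["prepreg_weight_kg"] * mean_wt + ebp["age"] * mean_age + \
        ebp["primiparity"] * mean_primi
    ebp["const"] = round(base["ebp_prev"] - ebp_lin, 6)
    ebp["omega_gaussian"] = round(base["ebp_prev"] * (1 - base["ebp_prev"]), 6)
    gwg = {"prepreg_weight_kg": 0.002, "primiparity": 0.06, "smoking": 0.08,
           "malaria_pregnancy": 0.06}
    gwg_lin = (gwg["prepreg_weight_kg"] * mean_wt + gwg["primiparity"] * mean_primi
               + gwg["smoking"] * base["binary_prev"]["smoking"]
               + gwg["malaria_pregnancy"] * base["binary_prev"]["malaria_pregnancy"])
    gwg["const"] = round(base["gwg_prev"] - gwg_lin, 6)
    gwg["omega_gaussian"] = round(base["gwg_prev"] * (1 - base["gwg_prev"]), 6)
    return {"elevated_bp": ebp, "insufficient_gwg": gwg}


def calibrate(variant):
    base = BASE[variant]
    continuous = dict(COMMON_CONTINUOUS)
    corr = base["latent_corr"]
    if variant == "subsample":
        continuous.update(BIOMETRY_CONTINUOUS)
        corr = _subsample_corr(BASE["population"]["latent_corr"])
    cfg = GeneratorConfig(
        n=CALIBRATION_N,
        seed=CALIBRATION_SEED,
        variant=variant,
        continuous=continuous,
        binary_prev=base["binary_prev"],
        latent_names=tuple(base["latent_names"]),
        latent_corr=corr,
        endo_paths=_endo_paths(variant, base),
        gamma=base["gamma"],
        lam=base["lam"],
        nu={"bwz": 0.0, "blz": 0.0},
        psi=1.0,
        theta={"bwz": 1.0, "blz": 1.0},
    )
    rng = np.random.default_rng(cfg.seed)
    cols = _draw_covariates(cfg, rng)
    _endogenous(cfg, cols, rng)
    spec = mimic_spec(variant)
    X = np.column_stack([_model_scale(c, cols) for c in spec.determinants])
    gamma = np.array([cfg.gamma[c] for c in spec.determinants])
    Phi = np.cov(X, rowvar=False, ddof=0)
    struct = float(gamma @ Phi @ gamma)
    t = base["r2_targets"]
    psi = struct * (1 - t["latent"]) / t["latent"]
    v_eta = struct + psi
    theta1 = v_eta * (1 - t["bwz"]) / t["bwz"]
    theta2 = cfg.lam**2 * v_eta * (1 - t["blz"]) / t["blz"]
    mean_eta = float((X @ gamma).mean())
    nu1 = base["indicator_means"]["bwz"] - mean_eta
    nu2 = base["indicator_means"]["blz"] - cfg.lam * mean_eta
    outcome_params = {}
    for name, prev in base["outcome_prev"].items():
        b = LOG_HALF if name in ("preterm", "stay_gt3d") else 0.0
        outcome_params[name] = {"a": round(solve_outcome_intercept(prev, b), 6),
                                "b": round(b, 6)}
    payload = {
        "n": base["n"],
        "seed": CALIBRATION_SEED,
        "variant": variant,
        "continuous": continuous,
        "binary_prev": base["binary_prev"],
        "latent_names": list(base["latent_names"]),
        "latent_corr": corr,
        "endo_paths": cfg.endo_paths,
        "gamma": base["gamma"],
        "lam": base["lam"],
        "nu": {"bwz": round(nu1, 6), "blz": round(nu2, 6)},
        "psi": round(psi, 6),
        "theta": {"bwz": round(theta1, 6), "blz": round(theta2, 6)},
        "outcome_params": outcome_params,
        "missingness": {},
        "skewed_residuals": False,
        "gaussian_covariates": False,
        "direct_effects": None,
    }
    print(f"[{variant}] struct var {struct:.4f}  psi {psi:.4f}  "
          f"Var(eta) {v_eta:.4f}  theta ({theta1:.4f}, {theta2:.4f})  "
          f"mean(eta) {mean_eta:.4f}  nu ({nu1:.4f}, {nu2:.4f})")
    return payload


def main():
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    for variant in ("population", "subsample"):
        payload = calibrate(variant)
        out = OUT_DIR / f"defaults_{variant}.json"
        with open(out, "w") as fh:
            json.dump(payload, fh, indent=1)
        print(f"wrote {out}")


if __name__ == "__main__":
    main()
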