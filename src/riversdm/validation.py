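"""Simulation experiments that check the pipeline recovers known truth.

Each function runs the package on synthetic data whose generating
parameters are known and returns the measured recovery or calibration
metric: GLM coefficient coverage, response-curve optimum recovery,
mixed-model fixed-effect error, exact-test type-I rates, the direction of
projected change under warming, and the agreement of stacked-SDM and MEM
richness with ground truth on held-out sites.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import env_predictors, interpretation, pipeline, richness, sdm_ensemble, synthetic

__all__ = [
    "member_a_coefficient_recovery",
    "thermal_optimum_recovery",
    "mixed_model_recovery",
    "site_test_type1",
    "linear_hypothesis_type1",
    "warming_direction_experiment",
    "richness_truth_correlation",
]


def member_a_coefficient_recovery(
    n_sims: int = 50, n: int = 2000, seed: int = 0
) -> dict:
    """Fit the binomial GLM member on data from its own family.

    For each simulation, a degree-2 logit on two environmental predictors
    plus one linear spatial term generates Bernoulli outcomes; the fitted
    orthogonal-polynomial coefficients are compared (in the fitted basis)
    with the true values mapped into that basis.  Returns the fraction of
    coefficients within 2 standard errors of truth.
    """
    rng = np.random.default_rng(seed)
    within = 0
    total = 0
    for s in range(n_sims):
        x1 = rng.uniform(2, 12, n)
        x2 = rng.uniform(0, 3, n)
        z = rng.normal(0, 1, n)
        c1 = np.array([-4.0, 1.1, -0.07])  # quadratic logit in x1 (unimodal)
        c2 = np.array([0.0, 0.8, -0.15])
        bz = 0.5
        eta = c1[0] + c1[1] * x1 + c1[2] * x1**2 + c2[1] * x2 + c2[2] * x2**2 + bz * z
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        X = pd.DataFrame({"e1": x1, "e2": x2, "ev1": z})

        design = sdm_ensemble.PolyDesign(["e1", "e2"], ["ev1"], degree=2).fit(X)
        D = sm.add_constant(design.transform(X), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, D, family=sm.families.Binomial()).fit()

        # map the raw-monomial truth into the fitted orthogonal basis:
        # [1, v, v^2] = B R  =>  ortho coefs (cols 1:2) = (R c)[1:]
        true_coefs = {"ev1": bz}
        for col, c in (("e1", c1), ("e2", c2)):
            R = np.linalg.inv(design._r_inv[col])
            t = R @ c
            true_coefs[f"{col}_p1"] = t[1]
            true_coefs[f"{col}_p2"] = t[2]
        for name, truth in true_coefs.items():
            est, se = res.params[name], res.bse[name]
            total += 1
            if abs(est - truth) <= 2 * se:
                within += 1
    return {"fraction_within_2se": within / total, "n_sims": n_sims, "n": n}


def thermal_optimum_recovery(
    seed: int = 0,
    n_reaches: int = 400,
    n_sites: int = 300,
    n_splits: int = 10,
    n_trees: int = 200,
) -> dict:
    """Recover a virtual species' thermal optimum from its response curve.

    One thermal-specialist species is surveyed on a synthetic riverscape,
    its ensemble SDM fitted, and the peak of the ensemble response curve
    along mean water temperature compared with the species' true niche
    optimum; the error is reported in units of the niche breadth sigma.
    """
    rs = synthetic.generate_riverscape(n_reaches, seed)
    X_true = synthetic.true_predictor_matrix(rs)
    t = X_true["water_temp_mean"]
    mu = float(t.quantile(0.45))
    sigma = float(0.8 * t.std())
    species = synthetic.VirtualSpecies(
        species_id="Therm0", genus="GenT", family="FamT",
        niche={"water_temp_mean": (mu, sigma)}, pmax=0.95,
    )
    surveys = synthetic.simulate_surveys(
        rs, [species], n_sites, {"species": 1.0}, seed + 1, predictors=X_true
    )
    from . import spatial_filters, survey_prep

    occ = survey_prep.build_occurrence_matrix(
        surveys.records, all_sites=surveys.sites["site_id"]
    )
    coords = rs.reaches.set_index("reach_id")[["x", "y"]]
    evs = spatial_filters.approx_spatial_eigenvectors(
        coords, k=5, n_anchors=min(80, len(coords)), seed=seed + 2
    )
    X_base = env_predictors.build_predictor_matrix(rs).join(evs.vectors)
    site_map = surveys.sites[surveys.sites["site_id"].isin(occ.matrix.index)]
    X_sites = X_base.loc[site_map["reach_id"]].set_index(
        pd.Index(site_map["site_id"], name="site_id")
    ).loc[occ.matrix.index]
    splits = sdm_ensemble.make_splits(occ.matrix.index.to_numpy(), n_splits, 0.8, seed + 3)
    ens = sdm_ensemble.fit_sdm(
        X_sites, occ.matrix["Therm0"], splits,
        env_predictors.ENV_PREDICTORS, list(evs.vectors.columns),
        config=sdm_ensemble.SdmConfig(n_trees=n_trees), seed=seed + 4,
    )
    curve = interpretation.response_curve(ens.predict, X_sites, "water_temp_mean", n_points=200)
    peak = float(curve["grid"][curve["response"].idxmax()])
    return {"true_mu": mu, "sigma": sigma, "peak": peak, "error_in_sigma": abs(peak - mu) / sigma}


def mixed_model_recovery(n_sims: int = 50, seed: int = 0) -> dict:
    """Mean absolute fixed-effect error of the water-temperature model.

    Each simulation draws a fresh monitoring network (60 stations, 36
    monthly measures) from the generator's known relation; the error of
    each fixed effect is expressed as a fraction of its true value and
    averaged over simulations.
    """
    truth = np.array(synthetic.TRUE_WATER_TEMP_COEFS)
    rs = synthetic.generate_riverscape(300, seed)
    errs = []
    for s in range(n_sims):
        rec = synthetic.simulate_water_temperature_monitoring(rs, 60, 36, seed + 100 + s)
        m = env_predictors.fit_water_temperature(rec)
        est = np.array([m.beta0, m.beta_air, m.beta_interaction])
        errs.append(np.abs(est - truth) / np.abs(truth))
    errs = np.asarray(errs)
    return {
        "mae_fraction": errs.mean(axis=0).tolist(),
        "max_mae_fraction": float(errs.mean(axis=0).max()),
        "n_sims": n_sims,
    }


def site_test_type1(n_sims: int = 10_000, n_species: int = 20, seed: int = 0,
                    alpha: float = 0.05) -> dict:
    """Empirical type-I rate of the exact Poisson-binomial site test.

    Observed counts are drawn from the null (the Poisson-binomial pmf of a
    random probability vector); the exact two-sided test should reject at
    most alpha of them, up to Monte-Carlo error, and is conservative by
    construction on a discrete support.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        p = rng.uniform(0.05, 0.95, n_species)
        pmf = richness.poisson_binomial_pmf(p)
        obs = rng.choice(len(pmf), p=pmf)
        if richness.richness_site_test(p, obs, alpha=alpha)["reject"]:
            rejections += 1
    return {"type1_rate": rejections / n_sims, "n_sims": n_sims, "alpha": alpha}


def linear_hypothesis_type1(n_sims: int = 5000, n: int = 100, seed: int = 0,
                            alpha: float = 0.05) -> dict:
    """Type-I rate of the joint intercept-0/slope-1 calibration test."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        pred = rng.uniform(2, 20, n)
        obs = pred + rng.normal(0, 2.0, n)  # H0 true: a=0, b=1
        if not richness.linear_hypothesis_test(obs, pred, alpha=alpha)["accepted"]:
            rejections += 1
    return {"type1_rate": rejections / n_sims, "n_sims": n_sims, "alpha": alpha}


def warming_direction_experiment(n_runs: int = 20, seed: int = 0, **kwargs) -> dict:
    """Fraction of seeded runs where projections move the expected way.

    A run is correct when, under a warming-only perturbation, the fitted
    ensembles' mean occurrence probability decreases for cold-adapted
    species and increases for warm-adapted species.
    """
    cold_ok = warm_ok = both_ok = 0
    for r in range(n_runs):
        out = pipeline.warming_direction_run(seed + 37 * r, **kwargs)
        c = out["cold_mean_change"] < 0
        w = out["warm_mean_change"] > 0
        cold_ok += c
        warm_ok += w
        both_ok += c and w
    return {
        "fraction_cold_correct": cold_ok / n_runs,
        "fraction_warm_correct": warm_ok / n_runs,
        "fraction_both_correct": both_ok / n_runs,
        "n_runs": n_runs,
    }


def richness_truth_correlation(seed: int = 0, config=None, holdout_frac: float = 0.25) -> dict:
    """Correlation of predicted with true expected richness on held-out sites.

    Runs the full pipeline on training sites, then compares S-SDM and MEM
    expected richness with the ground-truth expected richness (sum of true
    occurrence probabilities) at reaches never used for training.
    """
    cfg = config or pipeline.PipelineConfig(
        n_reaches=350, n_species=20, n_sites=220, n_splits=10, n_trees=150,
        n_anchors=80, min_occurrences=20,
    )
    res = pipeline.run_pipeline(seed, cfg)

    X_true = synthetic.true_predictor_matrix(res.riverscape)
    truth_all = synthetic.occurrence_probability_matrix(res.pool, X_true)
    modelled = [sp for sp in res.occurrence.matrix.columns]
    true_richness = truth_all[modelled].sum(axis=1)

    used = set(res.site_to_reach["reach_id"])
    heldout = [r for r in X_true.index if r not in used]
    rng = np.random.default_rng(seed + 5)
    heldout = list(rng.permutation(heldout))[: max(30, int(holdout_frac * len(X_true)))]

    X = res.predictor_matrices[("t1", cfg.scenarios[0])].loc[heldout]
    p_stack = np.column_stack([res.sdms[sp].predict(X) for sp in modelled])
    ssdm = richness.stack_sdms(np.clip(p_stack, 0, 1))
    mem = res.mem.predict(X)
    t = true_richness.loc[heldout].to_numpy()
    return {
        "pearson_ssdm_truth": float(np.corrcoef(ssdm, t)[0, 1]),
        "pearson_mem_truth": float(np.corrcoef(mem, t)[0, 1]),
        "pearson_ssdm_mem": float(np.corrcoef(ssdm, mem)[0, 1]),
        "n_heldout": len(heldout),
        "n_species_modelled": len(modelled),
    }
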