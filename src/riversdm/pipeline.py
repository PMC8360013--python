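"""End-to-end pipeline orchestration on synthetic riverscapes.

Chains the full modelling sequence — riverscape and virtual-species
generation, survey simulation and quality filtering, predictor and spatial
eigenvector construction, ensemble SDM and MEM fitting, scenario projection
and summary tables — behind one configuration object, so analysis drivers,
tests and the acceptance script all exercise the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import (
    env_predictors,
    projection,
    richness,
    sdm_ensemble,
    spatial_filters,
    survey_prep,
    synthetic,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "warming_direction_run"]


@dataclass
class PipelineConfig:
    """Study-design sizes and modelling knobs for one synthetic run.

    Defaults are the desk-scale study conditions: 500 reaches, a pool of 30
    virtual species, 300 survey sites, 50 community cross-validation splits.
    """

    n_reaches: int = 500
    n_species: int = 30
    n_sites: int = 300
    n_splits: int = 50
    train_frac: float = 0.8
    n_trees: int = 500
    degree: int = 2
    ident_rates: dict = field(
        default_factory=lambda: {"species": 0.85, "genus": 0.10, "family": 0.05}
    )
    completeness_threshold: float = 0.70
    min_occurrences: int = 25
    snap_tolerance: float = 30.0
    k_eigenvectors: int = 5
    n_anchors: int = 100
    n_wt_stations: int = 60
    n_wt_months: int = 36
    niche_predictors: tuple[str, ...] = ("water_temp_mean", "discharge_logmean", "forest")
    scenarios: tuple[str, ...] = ("RCP2.6", "RCP8.5")
    periods: tuple[str, ...] = ("t1", "t2", "t3")
    riverscape: synthetic.RiverscapeConfig = field(default_factory=synthetic.RiverscapeConfig)


@dataclass
class PipelineResult:
    riverscape: synthetic.Riverscape
    pool: list
    surveys: synthetic.Surveys
    occurrence: survey_prep.OccurrenceMatrix
    site_to_reach: pd.DataFrame
    wt_model: env_predictors.WaterTempModel
    eigenvectors: spatial_filters.EigenvectorSet
    predictor_matrices: dict  # (period, scenario) -> reach-level matrix (env + spatial)
    X_sites: pd.DataFrame
    collinearity: dict
    splits: sdm_ensemble.SplitSet
    sdms: dict
    sdm_summary: pd.DataFrame
    mem: richness.MemEnsemble
    cube: pd.DataFrame
    truth: pd.DataFrame  # site x species true probabilities (baseline)


def _niche_ranges(X: pd.DataFrame, names) -> dict:
    return {
        name: (float(X[name].quantile(0.05)), float(X[name].quantile(0.95))) for name in names
    }


def build_scenario_predictors(
    riverscape: synthetic.Riverscape,
    wt_model: env_predictors.WaterTempModel,
    evs: spatial_filters.EigenvectorSet,
    scenarios=("RCP2.6", "RCP8.5"),
    periods=("t1", "t2", "t3"),
) -> dict:
    """Reach-level predictor matrices (8 env + k spatial) per period/scenario."""
    out = {}
    baseline = None
    for scen in scenarios:
        for period in periods:
            if period == "t1":
                if baseline is None:
                    X = env_predictors.build_predictor_matrix(riverscape, wt_model)
                    baseline = X.join(evs.vectors)
                out[(period, scen)] = baseline
                continue
            perturbed = synthetic.apply_scenario(
                riverscape, synthetic.ScenarioSpec.default(scen, period)
            )
            X = env_predictors.build_predictor_matrix(perturbed, wt_model)
            out[(period, scen)] = X.join(evs.vectors)
    return out


def run_pipeline(seed: int, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full synthetic study once for one master seed."""
    cfg = config or PipelineConfig()
    rs = synthetic.generate_riverscape(cfg.n_reaches, seed, cfg.riverscape)

    X_true = synthetic.true_predictor_matrix(rs)
    pool = synthetic.generate_species_pool(
        cfg.n_species, seed + 1, _niche_ranges(X_true, cfg.niche_predictors)
    )
    surveys = synthetic.simulate_surveys(
        rs, pool, cfg.n_sites, cfg.ident_rates, seed + 2, predictors=X_true
    )

    # survey quality rules: completeness, per-site dedupe, snapping, prevalence
    kept, _ = survey_prep.completeness_filter(surveys.records, cfg.completeness_threshold)
    kept = survey_prep.dedupe_sites(kept)
    mapping, _ = survey_prep.snap_sites_to_reaches(
        surveys.sites, rs.reaches, cfg.snap_tolerance
    )
    kept = kept[kept["site_id"].isin(mapping["site_id"])]
    occ = survey_prep.build_occurrence_matrix(kept)
    occ = survey_prep.select_species(occ, cfg.min_occurrences)
    site_to_reach = mapping[mapping["site_id"].isin(occ.matrix.index)].reset_index(drop=True)
    occ.matrix = occ.matrix.loc[site_to_reach["site_id"]]

    # water-temperature model from a simulated monitoring network
    wt_records = synthetic.simulate_water_temperature_monitoring(
        rs, cfg.n_wt_stations, cfg.n_wt_months, seed + 3
    )
    wt_model = env_predictors.fit_water_temperature(wt_records)

    # spatial eigenvectors on reach coordinates
    coords = rs.reaches.set_index("reach_id")[["x", "y"]]
    evs = spatial_filters.approx_spatial_eigenvectors(
        coords, k=cfg.k_eigenvectors, n_anchors=min(cfg.n_anchors, len(coords)), seed=seed + 4
    )

    predictor_matrices = build_scenario_predictors(
        rs, wt_model, evs, cfg.scenarios, cfg.periods
    )
    baseline = predictor_matrices[("t1", cfg.scenarios[0])]
    X_sites = baseline.loc[site_to_reach["reach_id"]].set_index(
        pd.Index(site_to_reach["site_id"], name="site_id")
    )
    collin = env_predictors.collinearity_check(X_sites)

    env_cols = env_predictors.ENV_PREDICTORS
    spatial_cols = list(evs.vectors.columns)
    splits = sdm_ensemble.make_splits(
        occ.matrix.index.to_numpy(), cfg.n_splits, cfg.train_frac, seed + 5
    )
    sdm_cfg = sdm_ensemble.SdmConfig(degree=cfg.degree, n_trees=cfg.n_trees)
    sdms = {}
    for sp in occ.matrix.columns:
        sdms[sp] = sdm_ensemble.fit_sdm(
            X_sites,
            occ.matrix[sp],
            splits,
            env_cols,
            spatial_cols,
            species_id=sp,
            config=sdm_cfg,
            seed=seed + 6,
        )
    sdm_summary = sdm_ensemble.evaluate_ccv(sdms)

    mem = richness.fit_mem(
        X_sites,
        occ.matrix.sum(axis=1),
        splits,
        env_cols,
        spatial_cols,
        config=richness.MemConfig(degree=cfg.degree, n_trees=cfg.n_trees),
        seed=seed + 7,
    )

    regions = rs.reaches.set_index("reach_id")["region"]
    cube = projection.project(sdms, mem, predictor_matrices, regions=regions)

    return PipelineResult(
        riverscape=rs,
        pool=pool,
        surveys=surveys,
        occurrence=occ,
        site_to_reach=site_to_reach,
        wt_model=wt_model,
        eigenvectors=evs,
        predictor_matrices=predictor_matrices,
        X_sites=X_sites,
        collinearity=collin,
        splits=splits,
        sdms=sdms,
        sdm_summary=sdm_summary,
        mem=mem,
        cube=cube,
        truth=surveys.truth,
    )


def warming_direction_run(
    seed: int,
    n_reaches: int = 200,
    n_sites: int = 150,
    n_splits: int = 5,
    n_trees: int = 100,
    n_cold: int = 4,
    n_warm: int = 4,
    temp_offset: float = 3.0,
) -> dict:
    """One warming-only experiment: do fitted models move the right way?

    Builds thermal-specialist species (cold: optima in the lowest decile of
    reach mean water temperature; warm: highest decile), fits the ensemble
    on baseline surveys, projects onto a warming-only perturbation and
    reports the change in mean occurrence probability per group.
    """
    rs = synthetic.generate_riverscape(n_reaches, seed)
    X_true = synthetic.true_predictor_matrix(rs)
    t = X_true["water_temp_mean"]
    t_sd = float(t.std())
    rng = np.random.default_rng(seed + 11)
    pool = []
    for i in range(n_cold + n_warm):
        cold = i < n_cold
        mu = float(t.quantile(0.08 if cold else 0.92)) + rng.normal(0, 0.2)
        pool.append(
            synthetic.VirtualSpecies(
                species_id=f"{'Cold' if cold else 'Warm'}{i:02d}",
                genus="GenC" if cold else "GenW",
                family="FamT",
                niche={"water_temp_mean": (mu, 0.6 * t_sd)},
                pmax=0.9,
            )
        )
    surveys = synthetic.simulate_surveys(
        rs, pool, n_sites, {"species": 1.0}, seed + 12, predictors=X_true
    )
    occ = survey_prep.build_occurrence_matrix(
        surveys.records, all_sites=surveys.sites["site_id"]
    )
    occ = survey_prep.select_species(occ, max(5, int(0.05 * n_sites)))

    coords = rs.reaches.set_index("reach_id")[["x", "y"]]
    evs = spatial_filters.approx_spatial_eigenvectors(
        coords, k=5, n_anchors=min(60, len(coords)), seed=seed + 13
    )
    X_base = env_predictors.build_predictor_matrix(rs).join(evs.vectors)
    warmed_rs = synthetic.apply_scenario(
        rs, synthetic.ScenarioSpec(rcp="RCP8.5", period="t3", temp_offset=temp_offset)
    )
    X_warm = env_predictors.build_predictor_matrix(warmed_rs).join(evs.vectors)

    site_map = surveys.sites[surveys.sites["site_id"].isin(occ.matrix.index)]
    X_sites = X_base.loc[site_map["reach_id"]].set_index(
        pd.Index(site_map["site_id"], name="site_id")
    ).loc[occ.matrix.index]

    splits = sdm_ensemble.make_splits(occ.matrix.index.to_numpy(), n_splits, 0.8, seed + 14)
    cfg = sdm_ensemble.SdmConfig(n_trees=n_trees)
    out = {"cold": [], "warm": []}
    for sp in occ.matrix.columns:
        ens = sdm_ensemble.fit_sdm(
            X_sites, occ.matrix[sp], splits,
            env_predictors.ENV_PREDICTORS, list(evs.vectors.columns),
            species_id=sp, config=cfg, seed=seed + 15,
        )
        group = "cold" if sp.startswith("Cold") else "warm"
        out[group].append(
            float(ens.predict(X_warm).mean()) - float(ens.predict(X_base).mean())
        )
    return {
        "cold_mean_change": float(np.mean(out["cold"])) if out["cold"] else np.nan,
        "warm_mean_change": float(np.mean(out["warm"])) if out["warm"] else np.nan,
        "n_cold_modelled": len(out["cold"]),
        "n_warm_modelled": len(out["warm"]),
    }
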