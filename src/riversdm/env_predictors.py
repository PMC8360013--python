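"""Environmental predictor construction.

Eight environmental predictors describe each reach or site: mean and
coefficient of variation of monthly water temperature, log-transformed mean
and coefficient of variation of monthly discharge, channel slope, and urban,
forest and agriculture cover in the catchment.  Monthly water temperature at
unmonitored reaches is predicted from air temperature with a linear mixed
model (random intercept and air-temperature slope per monitoring station,
and an air-temperature x glacier/lake-cover interaction in the fixed part).
Future forcings from paired climate simulations are combined by element-wise
averaging, and glacier cover is reduced with a lowest-elevation-first cell
replacement heuristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ENV_PREDICTORS",
    "summarize_monthly",
    "period_average",
    "climate_ensemble",
    "glacier_retreat",
    "WaterTempModel",
    "fit_water_temperature",
    "predict_water_temperature",
    "collinearity_check",
    "build_predictor_matrix",
]

#: canonical order of the eight environmental predictor columns
ENV_PREDICTORS = [
    "water_temp_mean",
    "water_temp_cv",
    "discharge_logmean",
    "discharge_cv",
    "slope",
    "urban",
    "forest",
    "agri",
]

#: predictor type used for grouped variable importance
PREDICTOR_TYPES = {
    "water_temp_mean": "thermal",
    "water_temp_cv": "thermal",
    "discharge_logmean": "hydrological",
    "discharge_cv": "hydrological",
    "slope": "topographic",
    "urban": "land-cover",
    "forest": "land-cover",
    "agri": "land-cover",
}


def summarize_monthly(values: Sequence[float], log_mean: bool = False) -> dict:
    """Summarise a 12-month window as mean, CV and (optionally) log mean.

    CV is the sample standard deviation (n-1 denominator) divided by the
    mean.  ``log_mean`` (natural log of the mean) applies to the hydrological
    series only and requires a strictly positive mean, as does the CV.
    """
    v = np.asarray(values, dtype=float)
    if v.size != 12:
        raise ValueError(f"window must contain exactly 12 monthly values, got {v.size}")
    if not np.isfinite(v).all():
        raise ValueError("window contains non-finite values")
    mean = float(v.mean())
    if mean <= 0 and log_mean:
        raise ValueError("mean must be positive for the log transform")
    if mean == 0:
        raise ValueError("mean is zero; CV undefined")
    cv = float(v.std(ddof=1) / mean)
    out = {"mean": mean, "cv": cv}
    if log_mean:
        out["log_mean"] = float(np.log(mean))
    return out


def period_average(yearly_summaries: Iterable[Mapping[str, float]]) -> dict:
    """Average per-year summaries over a multi-year period.

    Per-year means and CVs are averaged arithmetically; the log transform of
    the hydrological mean is applied per year and averaged on the log scale.
    """
    ys = list(yearly_summaries)
    if not ys:
        raise ValueError("empty period: no yearly summaries")
    keys = ys[0].keys()
    return {k: float(np.mean([y[k] for y in ys])) for k in keys}


def climate_ensemble(series_a: pd.Series, series_b: pd.Series) -> pd.Series:
    """Element-wise mean of two aligned monthly series (two climate models)."""
    if len(series_a) != len(series_b):
        raise ValueError("misaligned series: different lengths")
    if isinstance(series_a, pd.Series) and isinstance(series_b, pd.Series):
        if not series_a.index.equals(series_b.index):
            raise ValueError("misaligned series: indices differ")
    return (series_a + series_b) / 2.0


def glacier_retreat(cells: pd.DataFrame, q) -> pd.DataFrame:
    """Remove the lowest-elevation fraction ``q`` of glacier cells.

    ``cells`` needs columns elevation and cell_id (area_pct and reach_id pass
    through).  The removal count is ``round(q * n)`` (half away from zero);
    ties at the cutoff break by elevation then by cell_id, so the result is
    deterministic.  ``q`` may be a scalar or an object with a
    ``glacier_replace_fraction`` attribute.
    """
    q = getattr(q, "glacier_replace_fraction", q)
    if not (0 <= q <= 1):
        raise ValueError("glacier replacement fraction must be in [0, 1]")
    n = len(cells)
    n_remove = int(np.floor(q * n + 0.5))
    order = cells.sort_values(["elevation", "cell_id"], kind="mergesort")
    kept = order.iloc[n_remove:]
    return kept.sort_index()


# ---------------------------------------------------------------------------
# water-temperature mixed model


@dataclass
class WaterTempModel:
    """Linear mixed model of monthly water temperature.

    Fixed part: intercept + air temperature + air temperature x glacier/lake
    cover.  Random part: per-station intercept and air-temperature slope.
    ``marginal_r2`` is the variance share of the fixed effects and
    ``conditional_r2`` of fixed plus random effects (Nakagawa-style
    decomposition).
    """

    beta0: float
    beta_air: float
    beta_interaction: float
    re_cov: np.ndarray  # 2x2 station-level covariance (intercept, air slope)
    resid_var: float
    marginal_r2: float
    conditional_r2: float
    converged: bool
    singular: bool


def fit_water_temperature(records: pd.DataFrame) -> WaterTempModel:
    """Fit the water-temperature mixed model on station monitoring records.

    ``records`` columns: station, air_temp, glacier_lake_pct, water_temp
    (one row per station-month).  A singular random-effects fit is reported
    on the returned model, never silently absorbed.
    """
    required = {"station", "air_temp", "glacier_lake_pct", "water_temp"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if records["station"].nunique() < 2:
        raise ValueError("need repeated measures from at least 2 stations")

    exog = pd.DataFrame(
        {
            "const": 1.0,
            "air_temp": records["air_temp"].to_numpy(),
            "air_x_cover": (records["air_temp"] * records["glacier_lake_pct"]).to_numpy(),
        }
    )
    exog_re = exog[["const", "air_temp"]]
    model = sm.MixedLM(
        records["water_temp"].to_numpy(), exog, groups=records["station"].to_numpy(),
        exog_re=exog_re,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True, method=["lbfgs", "bfgs"])

    beta = np.asarray(res.fe_params)
    cov_re = np.asarray(res.cov_re)  # already on the response scale
    resid_var = float(res.scale)

    # Nakagawa variance decomposition: fixed-effect variance is the variance
    # of the fixed-part linear predictor; random-effect variance is the mean
    # of z_i' G z_i over observations
    fixed = exog.to_numpy() @ beta
    var_f = float(np.var(fixed))
    Z = exog_re.to_numpy()
    var_r = float(np.mean(np.einsum("ij,jk,ik->i", Z, cov_re, Z)))
    total = var_f + var_r + resid_var
    marginal = var_f / total if total > 0 else 0.0
    conditional = (var_f + var_r) / total if total > 0 else 0.0

    eigvals = np.linalg.eigvalsh(cov_re)
    singular = bool(eigvals.min() < 1e-10 * max(eigvals.max(), 1.0))
    return WaterTempModel(
        beta0=float(beta[0]),
        beta_air=float(beta[1]),
        beta_interaction=float(beta[2]),
        re_cov=cov_re,
        resid_var=resid_var,
        marginal_r2=float(marginal),
        conditional_r2=float(conditional),
        converged=bool(res.converged),
        singular=singular,
    )


def predict_water_temperature(model: WaterTempModel, air_temp, glacier_lake_pct):
    """Fixed-effects-only prediction for unmonitored reaches (°C)."""
    air = np.asarray(air_temp, dtype=float)
    cover = np.asarray(glacier_lake_pct, dtype=float)
    return model.beta0 + model.beta_air * air + model.beta_interaction * air * cover


# ---------------------------------------------------------------------------
# collinearity screens


def collinearity_check(
    X: pd.DataFrame, r_threshold: float = 0.7, vif_threshold: float = 4.0
) -> dict:
    """Pairwise Pearson correlations and variance inflation factors.

    Passes when every absolute pairwise correlation is below ``r_threshold``
    and every VIF (1 / (1 - R^2) from regressing a column on the others) is
    below ``vif_threshold``.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    arr = X.to_numpy(dtype=float)
    if np.any(arr.std(axis=0) == 0):
        const = list(X.columns[arr.std(axis=0) == 0])
        raise ValueError(f"constant column(s): {const}")
    corr = np.corrcoef(arr, rowvar=False)
    abs_off = np.abs(corr - np.eye(X.shape[1]))
    max_abs_pearson = float(abs_off.max())

    vifs = {}
    for j, name in enumerate(X.columns):
        yj = arr[:, j]
        others = np.column_stack([np.ones(len(arr)), np.delete(arr, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        vifs[name] = float(1.0 / (1.0 - r2)) if r2 < 1.0 else float("inf")

    return {
        "max_abs_pearson": max_abs_pearson,
        "vif": vifs,
        "pearson_pass": max_abs_pearson < r_threshold,
        "vif_pass": max(vifs.values()) < vif_threshold,
        "pass": max_abs_pearson < r_threshold and max(vifs.values()) < vif_threshold,
    }


# ---------------------------------------------------------------------------
# predictor matrix assembly


def build_predictor_matrix(
    riverscape, water_temp_model: WaterTempModel | None = None
) -> pd.DataFrame:
    """Assemble the eight environmental predictors per reach.

    Monthly water temperature comes from the mixed model's fixed effects
    applied to monthly air temperature and glacier/lake cover (or from the
    generator's own relation when no model is supplied).  Yearly mean/CV
    summaries are averaged across the riverscape's years; the discharge mean
    is log-transformed per year and averaged on the log scale.
    """
    from . import synthetic  # local import to avoid a cycle at module load

    reaches = riverscape.reaches.set_index("reach_id")
    cover = reaches["glacier_lake_pct"]
    monthly = riverscape.monthly

    rows = {}
    for rid, sub in monthly.groupby("reach_id", sort=True):
        sub = sub.sort_values(["year", "month"])
        yearly = []
        for _, ysub in sub.groupby("year", sort=True):
            air = ysub["air_temp"].to_numpy()
            q = ysub["discharge"].to_numpy()
            if water_temp_model is not None:
                wt = predict_water_temperature(water_temp_model, air, cover[rid])
            else:
                wt = np.asarray(synthetic.true_water_temperature(air, cover[rid]))
            wt = np.clip(wt, 0.0, None)  # freezing floor, keeps the CV well defined
            wt_s = summarize_monthly(wt)
            q_s = summarize_monthly(q, log_mean=True)
            yearly.append(
                {
                    "water_temp_mean": wt_s["mean"],
                    "water_temp_cv": wt_s["cv"],
                    "discharge_logmean": q_s["log_mean"],
                    "discharge_cv": q_s["cv"],
                }
            )
        rows[rid] = period_average(yearly)
    X = pd.DataFrame.from_dict(rows, orient="index")
    X.index.name = "reach_id"
    static = reaches[["slope", "urban_cover", "forest_cover", "agri_cover"]].rename(
        columns={"urban_cover": "urban", "forest_cover": "forest", "agri_cover": "agri"}
    )
    return X.join(static)[ENV_PREDICTORS]
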