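"""Richness modelling: macroecological ensemble and Poisson-binomial stacking.

Community richness is predicted two ways.  The macroecological model (MEM)
regresses site richness directly on the predictors with a Poisson GLM and a
random-forest regressor, combined with weights given by each member's
Spearman correlation between observed and predicted richness on test folds.
The stacked-SDM (S-SDM) route sums the per-species occurrence probabilities
at each site; under independence the realised richness then follows the
Poisson-binomial distribution, whose exact probability mass function
supports a per-site goodness test of the observed count.  Calibration of
either richness prediction is assessed with a joint linear-hypothesis test
of intercept 0 and slope 1 in the observed-on-predicted regression, and
with errors standardised by the mean observed richness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestRegressor

from .sdm_ensemble import PolyDesign, SplitSet

__all__ = [
    "poisson_binomial_pmf",
    "PoissonBinomialPMF",
    "stack_sdms",
    "richness_site_test",
    "linear_hypothesis_test",
    "standardized_error",
    "site_test_summary",
    "MemConfig",
    "MemEnsemble",
    "fit_mem",
]


# ---------------------------------------------------------------------------
# Poisson-binomial distribution


def poisson_binomial_pmf(p) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_i) variables.

    Iterative convolution (dynamic programming): starting from the empty
    product, each success probability shifts mass up by one count.  Returns
    an array of length n+1 over k = 0..n.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d probability vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.zeros(len(p) + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1 - pi) + pmf[0 : i + 1] * pi
        pmf[0] *= 1 - pi
    return pmf


@dataclass
class PoissonBinomialPMF:
    """Probability vector with its exact richness distribution."""

    p: np.ndarray
    pmf: np.ndarray

    @classmethod
    def from_probabilities(cls, p) -> "PoissonBinomialPMF":
        p = np.asarray(p, dtype=float)
        return cls(p=p, pmf=poisson_binomial_pmf(p))

    @property
    def mean(self) -> float:
        return float(self.p.sum())

    @property
    def variance(self) -> float:
        return float((self.p * (1 - self.p)).sum())


def stack_sdms(prob_matrix) -> np.ndarray:
    """Expected richness per site: row sums of the probability matrix."""
    P = np.asarray(prob_matrix, dtype=float)
    if ((P < 0) | (P > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return P.sum(axis=-1)


def richness_site_test(
    p, observed: int, alpha: float = 0.05, method: str = "mass"
) -> dict:
    """Exact two-sided Poisson-binomial test of an observed richness count.

    ``method="mass"`` (default): the p-value sums pmf(k) over all k whose
    mass does not exceed pmf(observed) — the small-probability-mass
    convention for discrete two-sided tests.  ``method="central"`` doubles
    the smaller tail probability (capped at 1).  Rejection at
    ``p_value < alpha``.
    """
    p = np.asarray(p, dtype=float)
    n = len(p)
    if not (0 <= observed <= n):
        raise ValueError(f"observed count {observed} outside [0, {n}]")
    pmf = poisson_binomial_pmf(p)
    if method == "mass":
        p_value = float(pmf[pmf <= pmf[observed] * (1 + 1e-12)].sum())
    elif method == "central":
        lower = float(pmf[: observed + 1].sum())
        upper = float(pmf[observed:].sum())
        p_value = min(1.0, 2.0 * min(lower, upper))
    else:
        raise ValueError(f"unknown method {method!r}")
    p_value = min(p_value, 1.0)
    return {"p_value": p_value, "reject": p_value < alpha}


# ---------------------------------------------------------------------------
# calibration diagnostics


def linear_hypothesis_test(observed, predicted, alpha: float = 0.05) -> dict:
    """Joint F-test of intercept 0 and slope 1 in observed ~ predicted."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) < 3:
        raise ValueError("need at least 3 sites")
    if np.ptp(pred) == 0:
        raise ValueError("predicted values are constant")
    X = sm.add_constant(pred)
    res = sm.OLS(obs, X).fit()
    if res.ssr <= 1e-12 * max(1.0, float((obs**2).sum())):
        return {"F": 0.0, "p_value": 1.0, "accepted": True, "degenerate": True}
    ftest = res.f_test((np.eye(2), np.array([0.0, 1.0])))
    fval = float(np.squeeze(ftest.fvalue))
    pval = float(ftest.pvalue)
    return {"F": fval, "p_value": pval, "accepted": pval >= alpha, "degenerate": False}


def standardized_error(observed, predicted) -> dict:
    """Per-site (prediction - observation) / mean(observation) errors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    mean_obs = obs.mean()
    if mean_obs <= 0:
        raise ValueError("mean observed richness must be positive")
    e = (pred - obs) / mean_obs
    return {"errors": e, "mean": float(e.mean()), "sd": float(e.std(ddof=1))}


def site_test_summary(per_split_results: list[pd.DataFrame]) -> dict:
    """Fraction of sites whose observed richness is compatible per split.

    Each element holds one split's per-site test results with a boolean
    ``reject`` column.  Returns the per-split accepted fractions and their
    min / median / max.
    """
    fractions = [float(1.0 - df["reject"].mean()) for df in per_split_results]
    return {
        "fractions": fractions,
        "min": min(fractions),
        "median": float(np.median(fractions)),
        "max": max(fractions),
    }


# ---------------------------------------------------------------------------
# macroecological model (MEM)


@dataclass
class MemConfig:
    degree: int = 2
    n_trees: int = 500


@dataclass
class _PoissonMember:
    design: PolyDesign
    params: np.ndarray

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        D = sm.add_constant(self.design.transform(X), has_constant="add")
        return np.exp(D.to_numpy() @ self.params)


@dataclass
class MemEnsemble:
    """Poisson GLM + RF regressor with Spearman-correlation weights."""

    glm: _PoissonMember
    rf: RandomForestRegressor
    weights: tuple[float, float]
    eval_records: pd.DataFrame
    config: MemConfig

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        wa, wb = self.weights
        pred = (wa * self.glm.predict(X) + wb * self.rf.predict(X.to_numpy())) / (wa + wb)
        return np.clip(pred, 0.0, None)


def _spearman_weight(obs: np.ndarray, pred: np.ndarray) -> float:
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        warnings.warn("constant richness vector: Spearman undefined, weight 0")
        return 0.0
    rho = spearmanr(obs, pred).statistic
    return max(float(rho), 0.0)


def fit_mem(
    X: pd.DataFrame,
    richness: pd.Series,
    splits: SplitSet,
    env_cols,
    spatial_cols,
    config: MemConfig | None = None,
    seed: int = 0,
) -> MemEnsemble:
    """Fit the MEM ensemble on site richness counts.

    Member weights are each member's mean test-fold Spearman correlation
    between observed and predicted richness, floored at zero; members are
    refit on all sites for projection.
    """
    cfg = config or MemConfig()
    r = pd.Series(richness).loc[X.index]
    rv = r.to_numpy()
    if not np.allclose(rv, np.round(rv)) or (rv < 0).any():
        raise ValueError("richness must be non-negative integer counts")
    rv = rv.astype(int)

    def fit_glm(Xf, yf):
        design = PolyDesign(env_cols, spatial_cols, cfg.degree).fit(Xf)
        D = sm.add_constant(design.transform(Xf), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(yf, D, family=sm.families.Poisson()).fit(maxiter=100)
        return _PoissonMember(design=design, params=np.asarray(res.params))

    records = []
    for i, (train_ids, test_ids) in enumerate(splits):
        y_tr, y_te = r.loc[train_ids].to_numpy(), r.loc[test_ids].to_numpy()
        X_tr, X_te = X.loc[train_ids], X.loc[test_ids]
        rec = {"split": i, "skipped": False}
        try:
            glm = fit_glm(X_tr, y_tr)
        except Exception as exc:
            rec.update(skipped=True, reason=f"glm: {exc}")
            records.append(rec)
            continue
        rf = RandomForestRegressor(n_estimators=cfg.n_trees, random_state=seed * 1013 + i, n_jobs=1)
        rf.fit(X_tr.to_numpy(), y_tr)
        rec["rho_glm"] = _spearman_weight(y_te, glm.predict(X_te))
        rec["rho_rf"] = _spearman_weight(y_te, rf.predict(X_te.to_numpy()))
        records.append(rec)
    eval_records = pd.DataFrame(records)
    ok = eval_records[~eval_records["skipped"]] if len(eval_records) else eval_records
    if len(ok):
        wa, wb = float(ok["rho_glm"].mean()), float(ok["rho_rf"].mean())
    else:
        wa = wb = 0.0
    if wa + wb == 0:
        wa = wb = 0.5
    else:
        wa, wb = wa / (wa + wb), wb / (wa + wb)

    glm_final = fit_glm(X, rv)
    rf_final = RandomForestRegressor(
        n_estimators=cfg.n_trees, random_state=seed * 1013 + 999983, n_jobs=1
    )
    rf_final.fit(X.to_numpy(), rv)
    return MemEnsemble(
        glm=glm_final, rf=rf_final, weights=(wa, wb), eval_records=eval_records, config=cfg
    )
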