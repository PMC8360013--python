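"""Per-species ensemble SDMs: binomial GLM + random-forest classifier.

Each species' occurrence is modelled twice — by a binomial GLM with
degree-2 orthogonal-polynomial terms on the environmental predictors
(linear terms on the spatial eigenvectors) and by a random-forest
classifier — and the two occurrence probabilities are averaged with weights
derived from each member's discrimination (AUC) on repeated community
cross-validation (CCV) splits.  The same splits are reused for every
species so community-level metrics are comparable.  Predictive skill is
summarised by AUC and the true skill statistic (TSS), banded into the
conventional excellent/good/fair/poor categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "SplitSet",
    "make_splits",
    "auc",
    "tss",
    "auc_band",
    "tss_band",
    "SdmConfig",
    "PolyDesign",
    "SdmEnsemble",
    "fit_sdm",
    "predict_ensemble",
    "evaluate_ccv",
]


# ---------------------------------------------------------------------------
# community cross-validation splits


@dataclass
class SplitSet:
    """Repeated 80/20 train/test partitions shared across all models."""

    splits: list[tuple[np.ndarray, np.ndarray]]  # (train ids, test ids)
    seed: int
    train_frac: float

    def __len__(self) -> int:
        return len(self.splits)

    def __iter__(self):
        return iter(self.splits)


def make_splits(
    site_ids, n_splits: int = 50, train_frac: float = 0.8, seed: int = 0
) -> SplitSet:
    """Draw ``n_splits`` random train/test partitions of the sites."""
    ids = np.asarray(site_ids)
    if len(ids) < 10:
        raise ValueError("need at least 10 sites")
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * len(ids)))
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(len(ids))
        splits.append((np.sort(ids[perm[:n_train]]), np.sort(ids[perm[n_train:]])))
    return SplitSet(splits=splits, seed=seed, train_frac=train_frac)


# ---------------------------------------------------------------------------
# evaluation statistics


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("labels contain a single class; AUC/TSS undefined")


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney form, ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    r = rankdata(s)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def tss(scores, labels) -> float:
    """Maximum of sensitivity + specificity - 1 over all thresholds.

    Candidate thresholds are the midpoints between sorted unique scores plus
    one point below and above the score range (classification rule:
    score >= threshold is a predicted presence).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    u = np.unique(s)
    thresholds = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    pred = s[None, :] >= thresholds[:, None]
    pos = y == 1
    sens = pred[:, pos].mean(axis=1)
    spec = (~pred[:, ~pos]).mean(axis=1)
    return float((sens + spec - 1.0).max())


def auc_band(value: float) -> str:
    if value > 0.90:
        return "excellent"
    if value > 0.80:
        return "good"
    if value > 0.70:
        return "fair"
    if value > 0.60:
        return "poor"
    return "fail"


def tss_band(value: float) -> str:
    if value > 0.75:
        return "excellent"
    if value >= 0.40:
        return "good"
    return "poor"


# ---------------------------------------------------------------------------
# GLM design: degree-2 orthogonal polynomials on environmental predictors


class PolyDesign:
    """Orthogonal-polynomial design matrix builder.

    Environmental columns get degree-``degree`` orthogonal polynomial terms
    (computed from the training data via a QR factorisation, as in R's
    ``poly``); spatial eigenvector columns enter linearly.  The fitted
    transform is reused unchanged for prediction data.
    """

    def __init__(self, env_cols, spatial_cols, degree: int = 2):
        self.env_cols = list(env_cols)
        self.spatial_cols = list(spatial_cols)
        self.degree = degree
        self._r_inv: dict[str, np.ndarray] = {}

    def fit(self, X: pd.DataFrame) -> "PolyDesign":
        for col in self.env_cols:
            v = X[col].to_numpy(dtype=float)
            M = np.column_stack([v**d for d in range(self.degree + 1)])
            Q, R = np.linalg.qr(M)
            # scale so each basis column of the training data has unit norm
            self._r_inv[col] = np.linalg.inv(R)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col in self.env_cols:
            v = X[col].to_numpy(dtype=float)
            M = np.column_stack([v**d for d in range(self.degree + 1)])
            B = M @ self._r_inv[col]
            for d in range(1, self.degree + 1):
                out[f"{col}_p{d}"] = B[:, d]
        for col in self.spatial_cols:
            out[col] = X[col].to_numpy(dtype=float)
        return pd.DataFrame(out, index=X.index)

    @property
    def columns(self) -> list[str]:
        return [f"{c}_p{d}" for c in self.env_cols for d in range(1, self.degree + 1)] + list(
            self.spatial_cols
        )


# ---------------------------------------------------------------------------
# ensemble fitting


@dataclass
class SdmConfig:
    degree: int = 2
    n_trees: int = 500
    weight_mode: str = "shifted"  # "shifted": w = max(AUC - 0.5, 0); or "raw"


@dataclass
class _GlmMember:
    design: PolyDesign
    params: np.ndarray

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        D = sm.add_constant(self.design.transform(X), has_constant="add")
        eta = np.clip(D.to_numpy() @ self.params, -35.0, 35.0)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class SdmEnsemble:
    """Fitted member pair with CCV-based weights for one species."""

    species_id: str
    glm: _GlmMember | None
    rf: RandomForestClassifier | None
    weights: tuple[float, float]  # (w_glm, w_rf), sum to 1
    eval_records: pd.DataFrame  # per split: auc/tss per member and ensemble
    config: SdmConfig

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return predict_ensemble(self, X)


def _fit_glm(X: pd.DataFrame, y: np.ndarray, env_cols, spatial_cols, cfg: SdmConfig):
    design = PolyDesign(env_cols, spatial_cols, cfg.degree).fit(X)
    D = sm.add_constant(design.transform(X), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, D, family=sm.families.Binomial()).fit(maxiter=100)
    params = np.asarray(res.params)
    if not np.isfinite(params).all():
        raise RuntimeError("GLM produced non-finite coefficients")
    member = _GlmMember(design=design, params=params)
    return member, res


def _fit_rf(X: pd.DataFrame, y: np.ndarray, cfg: SdmConfig, seed: int):
    rf = RandomForestClassifier(n_estimators=cfg.n_trees, random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(), y)
    return rf


def _rf_predict(rf: RandomForestClassifier, X: pd.DataFrame) -> np.ndarray:
    proba = rf.predict_proba(X.to_numpy())
    classes = list(rf.classes_)
    return proba[:, classes.index(1)] if 1 in classes else np.zeros(len(X))


def _member_weights(auc_a: float, auc_b: float, mode: str) -> tuple[float, float]:
    if mode == "shifted":
        wa, wb = max(auc_a - 0.5, 0.0), max(auc_b - 0.5, 0.0)
    elif mode == "raw":
        wa, wb = max(auc_a, 0.0), max(auc_b, 0.0)
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    total = wa + wb
    if total == 0:  # two no-skill members: fall back to an even average
        return 0.5, 0.5
    return wa / total, wb / total


def fit_sdm(
    X: pd.DataFrame,
    y: pd.Series,
    splits: SplitSet,
    env_cols,
    spatial_cols,
    species_id: str = "species",
    config: SdmConfig | None = None,
    seed: int = 0,
) -> SdmEnsemble:
    """Fit the GLM+RF ensemble for one species under community CV.

    ``X`` is indexed by site id and must contain ``env_cols`` and
    ``spatial_cols``; ``y`` is the 0/1 occurrence vector on the same index.
    Splits whose training or test fold lacks one of the classes, or where
    the GLM fails to converge, are skipped and recorded.  Final members are
    refit on all sites; weights are the mean test-fold AUC of each member
    across usable splits (shifted so a no-skill member gets zero weight).
    """
    cfg = config or SdmConfig()
    y = pd.Series(y).loc[X.index]
    yv = y.to_numpy(dtype=int)
    if yv.min() == yv.max():
        raise ValueError("occurrence vector is constant; both classes required")

    records = []
    for i, (train_ids, test_ids) in enumerate(splits):
        y_tr = y.loc[train_ids].to_numpy(dtype=int)
        y_te = y.loc[test_ids].to_numpy(dtype=int)
        rec = {"split": i, "skipped": False, "reason": ""}
        if y_tr.min() == y_tr.max() or y_te.min() == y_te.max():
            rec.update(skipped=True, reason="single-class fold")
            records.append(rec)
            continue
        X_tr, X_te = X.loc[train_ids], X.loc[test_ids]
        try:
            glm, _ = _fit_glm(X_tr, y_tr, env_cols, spatial_cols, cfg)
        except Exception as exc:  # separation / non-convergence
            rec.update(skipped=True, reason=f"glm: {exc}")
            records.append(rec)
            continue
        rf = _fit_rf(X_tr, y_tr, cfg, seed=seed * 1009 + i)
        p_a, p_b = glm.predict(X_te), _rf_predict(rf, X_te)
        rec["auc_glm"], rec["auc_rf"] = auc(p_a, y_te), auc(p_b, y_te)
        rec["tss_glm"], rec["tss_rf"] = tss(p_a, y_te), tss(p_b, y_te)
        wa, wb = _member_weights(rec["auc_glm"], rec["auc_rf"], cfg.weight_mode)
        p_e = wa * p_a + wb * p_b
        rec["auc_ensemble"], rec["tss_ensemble"] = auc(p_e, y_te), tss(p_e, y_te)
        records.append(rec)
    eval_records = pd.DataFrame(records)

    ok = eval_records[~eval_records["skipped"]] if len(eval_records) else eval_records
    if len(ok):
        weights = _member_weights(
            float(ok["auc_glm"].mean()), float(ok["auc_rf"].mean()), cfg.weight_mode
        )
    else:
        weights = (0.5, 0.5)

    glm_final, _ = _fit_glm(X, yv, env_cols, spatial_cols, cfg)
    rf_final = _fit_rf(X, yv, cfg, seed=seed * 1009 + 999983)
    return SdmEnsemble(
        species_id=species_id,
        glm=glm_final,
        rf=rf_final,
        weights=weights,
        eval_records=eval_records,
        config=cfg,
    )


def predict_ensemble(ensemble: SdmEnsemble, X: pd.DataFrame) -> np.ndarray:
    """AUC-weighted convex combination of the member probabilities."""
    wa, wb = ensemble.weights
    p_a = ensemble.glm.predict(X)
    p_b = _rf_predict(ensemble.rf, X)
    return (wa * p_a + wb * p_b) / (wa + wb)


def evaluate_ccv(ensembles: dict[str, SdmEnsemble]) -> pd.DataFrame:
    """Per-species CCV summary: median AUC/TSS across splits and bands.

    The attached community medians (rows aggregate over species) follow the
    median-of-split-values convention used for the per-species bands.
    """
    rows = []
    for sp, ens in ensembles.items():
        ok = ens.eval_records[~ens.eval_records["skipped"]]
        if not len(ok):
            rows.append({"species_id": sp, "n_splits_used": 0})
            continue
        med_auc = float(ok["auc_ensemble"].median())
        med_tss = float(ok["tss_ensemble"].median())
        rows.append(
            {
                "species_id": sp,
                "n_splits_used": int(len(ok)),
                "median_auc": med_auc,
                "median_tss": med_tss,
                "auc_band": auc_band(med_auc),
                "tss_band": tss_band(med_tss),
            }
        )
    return pd.DataFrame(rows).set_index("species_id")
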