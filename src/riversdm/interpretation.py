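"""Model interpretation: permutation importance and response curves.

Variable importance follows the permutation convention of the classic SDM
toolchains: one minus the Pearson correlation between the model's
predictions on the intact data and on data with the focal column permuted,
averaged over permutations and clipped at zero.  Importances are compared
across predictor *types* (hydrological, thermal, land-cover, topographic,
spatial) after dividing each type's summed importance by its variable
count.  Response curves use an evaluation strip: the focal variable sweeps
an even grid over its observed range while every other column is held at
its training median.
"""

from __future__ import annotations

import warnings
from itertools import permutations

import numpy as np
import pandas as pd

__all__ = [
    "permutation_importance",
    "grouped_importance",
    "response_curve",
]


def permutation_importance(
    predict_fn, X: pd.DataFrame, variable: str, n_perm: int = 10, seed: int = 0
) -> float:
    """Importance of ``variable`` for ``predict_fn`` by random permutation.

    VI = mean over permutations of (1 - r(pred_intact, pred_permuted)),
    clipped at 0.  Constant predictions yield 0 with a warning.
    """
    if variable not in X.columns:
        raise KeyError(f"variable {variable!r} not in X")
    rng = np.random.default_rng(seed)
    base = np.asarray(predict_fn(X), dtype=float)
    if np.ptp(base) == 0:
        warnings.warn("constant predictions: permutation importance defined as 0")
        return 0.0
    vals = []
    for _ in range(n_perm):
        Xp = X.copy()
        Xp[variable] = rng.permutation(Xp[variable].to_numpy())
        perm = np.asarray(predict_fn(Xp), dtype=float)
        if np.ptp(perm) == 0:
            vals.append(1.0)  # permuting destroyed all signal
            continue
        r = np.corrcoef(base, perm)[0, 1]
        vals.append(1.0 - r)
    return float(max(np.mean(vals), 0.0))


def grouped_importance(table: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Standardised per-type importance and pairwise relative differences.

    ``table`` columns: variable, type, importance.  The per-type value is
    the summed importance divided by the number of variables of that type;
    the relative difference of type A over B is 100 * (v_A - v_B) / v_B.
    """
    if table["type"].isna().any():
        raise ValueError("every variable must have a predictor type")
    grouped = table.groupby("type")["importance"].agg(["sum", "count"])
    if (grouped["count"] == 0).any():
        raise ValueError("empty predictor type group")
    values = grouped["sum"] / grouped["count"]
    rows = []
    for a, b in permutations(values.index, 2):
        rows.append(
            {
                "type_a": a,
                "type_b": b,
                "relative_difference_pct": 100.0 * (values[a] - values[b]) / values[b],
            }
        )
    return values, pd.DataFrame(rows)


def response_curve(
    predict_fn,
    X: pd.DataFrame,
    variable: str,
    n_points: int = 100,
    fix: str = "median",
) -> pd.DataFrame:
    """Evaluation-strip response curve for one variable.

    Returns a DataFrame with columns ``grid`` (even grid over the observed
    range of ``variable``) and ``response`` (predictions with all other
    columns fixed at their training median, or mean when ``fix="mean"``).
    """
    if variable not in X.columns:
        raise KeyError(f"variable {variable!r} not in X")
    v = X[variable].to_numpy(dtype=float)
    if np.ptp(v) == 0:
        raise ValueError(f"variable {variable!r} has zero range")
    grid = np.linspace(v.min(), v.max(), n_points)
    fixed = X.median(numeric_only=True) if fix == "median" else X.mean(numeric_only=True)
    strip = pd.DataFrame(
        {c: np.full(n_points, fixed[c]) for c in X.columns}, columns=X.columns
    )
    strip[variable] = grid
    return pd.DataFrame({"grid": grid, "response": np.asarray(predict_fn(strip), dtype=float)})
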