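"""Scenario projection and summary tables.

Fitted species ensembles and richness models are projected onto predictor
matrices for each period (t1 = 2015-2025, t2 = 2055-2065, t3 = 2080-2090)
and emission pathway (RCP2.6, RCP8.5), producing a long-format cube of
per-reach occurrence probabilities and expected richness.  Summaries mirror
the usual reporting layout: per-species mean occurrence probability over
reaches, relative change versus the baseline decade (half-away-from-zero
rounding to one decimal), regional mean richness, and method / scenario
comparison tables.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "round_half_away",
    "relative_change",
    "project",
    "mean_occurrence",
    "summarize_richness",
    "compare",
    "change_table_stats",
    "build_change_table",
]

PERIODS = ("t1", "t2", "t3")
SCENARIOS = ("RCP2.6", "RCP8.5")


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed change tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


def relative_change(p_base: float, p_future: float) -> float:
    """Relative change in percent versus baseline, rounded to one decimal."""
    if p_base <= 0:
        raise ValueError("baseline mean must be positive")
    return round_half_away(100.0 * (p_future - p_base) / p_base, 1)


def project(
    sdm_ensembles: Mapping[str, object],
    mem: object,
    predictor_matrices: Mapping[tuple[str, str], pd.DataFrame],
    regions: pd.Series | None = None,
) -> pd.DataFrame:
    """Project all models onto every (period, scenario) predictor matrix.

    ``predictor_matrices`` maps (period, scenario) -> reach-indexed
    predictor matrix; every requested combination must be present.  Returns
    a long DataFrame with columns reach_id, region, period, scenario,
    target (species id, "richness_ssdm" or "richness_mem") and value.
    """
    frames = []
    for (period, scenario), X in predictor_matrices.items():
        probs = {}
        for sp, ens in sdm_ensembles.items():
            probs[sp] = ens.predict(X)
        block = pd.DataFrame(probs, index=X.index)
        block["richness_ssdm"] = block[list(sdm_ensembles)].sum(axis=1)
        block["richness_mem"] = mem.predict(X) if mem is not None else np.nan
        long = block.reset_index().melt(
            id_vars="reach_id", var_name="target", value_name="value"
        )
        long["period"] = period
        long["scenario"] = scenario
        frames.append(long)
    cube = pd.concat(frames, ignore_index=True)
    if regions is not None:
        cube["region"] = cube["reach_id"].map(regions)
    else:
        cube["region"] = "all"
    return cube


def _scope(cube: pd.DataFrame, target: str, region: str, period: str, scenario: str):
    sel = (
        (cube["target"] == target)
        & (cube["period"] == period)
        & (cube["scenario"] == scenario)
    )
    if region != "all":
        known = set(cube["region"].unique())
        if region not in known:
            raise KeyError(f"unknown region {region!r}")
        sel &= cube["region"] == region
    sub = cube[sel]
    if not len(sub):
        raise KeyError(f"no projections for {(target, region, period, scenario)}")
    return sub["value"]


def mean_occurrence(
    cube: pd.DataFrame, species: str, region: str = "all", period: str = "t1",
    scenario: str = "RCP2.6",
) -> float:
    """Unweighted mean occurrence probability over the reaches in scope."""
    return float(_scope(cube, species, region, period, scenario).mean())


def summarize_richness(
    cube: pd.DataFrame, region: str = "all", period: str = "t1",
    scenario: str = "RCP2.6", method: str = "ssdm",
) -> float:
    """Mean expected richness over the region's reaches for one method."""
    if method not in ("ssdm", "mem"):
        raise KeyError(f"unknown method {method!r}")
    return float(_scope(cube, f"richness_{method}", region, period, scenario).mean())


def compare(summaries_a: pd.Series, summaries_b: pd.Series) -> pd.Series:
    """Relative difference of A over B in percent, per shared key."""
    if not summaries_a.index.equals(summaries_b.index):
        raise ValueError("comparison sides must share the same index")
    return pd.Series(
        {
            key: round_half_away(100.0 * (summaries_a[key] - summaries_b[key]) / summaries_b[key], 1)
            for key in summaries_a.index
        }
    )


def change_table_stats(changes) -> dict:
    """{min, median, max} of a relative-change column."""
    c = np.asarray(changes, dtype=float)
    if c.size == 0:
        raise ValueError("empty change column")
    return {"min": float(c.min()), "median": float(np.median(c)), "max": float(c.max())}


def build_change_table(
    cube: pd.DataFrame, species_ids, scenario: str, region: str = "all"
) -> pd.DataFrame:
    """Per-species mean probabilities by period with relative changes.

    Columns mirror the printed layout: p_t1, p_t2, delta_t2_pct, p_t3,
    delta_t3_pct, ordered by the end-century change.
    """
    rows = []
    for sp in species_ids:
        p1 = mean_occurrence(cube, sp, region, "t1", scenario)
        p2 = mean_occurrence(cube, sp, region, "t2", scenario)
        p3 = mean_occurrence(cube, sp, region, "t3", scenario)
        rows.append(
            {
                "species": sp,
                "p_t1": p1,
                "p_t2": p2,
                "delta_t2_pct": relative_change(p1, p2),
                "p_t3": p3,
                "delta_t3_pct": relative_change(p1, p3),
            }
        )
    return pd.DataFrame(rows).sort_values("delta_t3_pct", ignore_index=True)
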