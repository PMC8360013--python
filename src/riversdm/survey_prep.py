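"""Survey data-quality rules and occurrence-matrix assembly.

Field surveys of EPT larvae are often incompletely identified: some records
stop at genus or family rank.  To limit false absences, a survey's species
list is compared against its *minimum potential richness* — the number of
identified species, plus genus-rank records whose genus contains none of the
identified species, plus family-rank records whose family contains none of
the identified genera — and surveys whose identified-species share falls
below a completeness threshold are discarded.  Remaining duplicates per site
are resolved to the most complete survey, sites are snapped to the nearest
river reach within a distance tolerance, and species below a minimum number
of occurrences are dropped from the final sites x species matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "min_potential_richness",
    "completeness_filter",
    "dedupe_sites",
    "snap_sites_to_reaches",
    "OccurrenceMatrix",
    "build_occurrence_matrix",
    "select_species",
]


def _check_lineage(records: pd.DataFrame) -> None:
    sp = records[records["rank"] == "species"]
    if sp["genus"].isna().any() or sp["family"].isna().any():
        raise ValueError("species-rank record with unresolvable lineage")
    ge = records[records["rank"] == "genus"]
    if ge["family"].isna().any():
        raise ValueError("genus-rank record with unresolvable family")


def min_potential_richness(records: pd.DataFrame) -> int:
    """Minimum potential richness of one site-date survey.

    ``records`` columns: taxon, rank, genus, family (one survey's rows).
    Returns S + G' + F' where S counts unique identified species, G' counts
    genus-rank records whose genus includes no identified species, and F'
    counts family-rank records whose family includes neither a genus-rank
    record nor the genus of an identified species.
    """
    _check_lineage(records)
    sp = records[records["rank"] == "species"]
    ge = records[records["rank"] == "genus"]
    fa = records[records["rank"] == "family"]

    s = sp["taxon"].nunique()
    covered_genera = set(sp["genus"].dropna())
    g_new = ge[~ge["taxon"].isin(covered_genera)]["taxon"].nunique()
    covered_families = set(sp["family"].dropna()) | set(ge["family"].dropna())
    f_new = fa[~fa["taxon"].isin(covered_families)]["taxon"].nunique()
    return int(s + g_new + f_new)


def survey_completeness(records: pd.DataFrame) -> tuple[int, int, float]:
    """(n_species, min_potential_richness, completeness) for one survey."""
    m = min_potential_richness(records)
    s = records[records["rank"] == "species"]["taxon"].nunique()
    return s, m, (s / m if m > 0 else float("nan"))


def completeness_filter(
    surveys: pd.DataFrame, threshold: float = 0.70
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep surveys whose identified-species share is at least ``threshold``.

    ``surveys`` holds all records (site_id, date, taxon, rank, genus,
    family); a survey is one (site_id, date) group.  Surveys with zero
    potential richness are dropped.  Returns (kept records, per-survey
    report with columns site_id, date, n_species, min_potential,
    completeness, kept).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    rows = []
    kept_keys = []
    for (site, date), grp in surveys.groupby(["site_id", "date"], sort=True):
        s, m, c = survey_completeness(grp)
        keep = m > 0 and c >= threshold
        rows.append(
            {
                "site_id": site,
                "date": date,
                "n_species": s,
                "min_potential": m,
                "completeness": c,
                "kept": keep,
            }
        )
        if keep:
            kept_keys.append((site, date))
    report = pd.DataFrame(rows)
    keys = pd.MultiIndex.from_frame(surveys[["site_id", "date"]])
    kept = surveys[keys.isin(kept_keys)].reset_index(drop=True)
    return kept, report


def dedupe_sites(surveys: pd.DataFrame) -> pd.DataFrame:
    """Retain one survey per site: the most complete one.

    Ties break by the most recent date, then by lexicographic (site, date)
    key, so the outcome is deterministic.  No site is removed entirely.
    """
    best = {}
    for (site, date), grp in surveys.groupby(["site_id", "date"], sort=True):
        _, _, c = survey_completeness(grp)
        key = (c, str(date))  # completeness first, then latest date
        if site not in best or key > best[site][0]:
            best[site] = (key, date)
    chosen = {(site, date) for site, (_, date) in best.items()}
    keys = pd.MultiIndex.from_frame(surveys[["site_id", "date"]])
    return surveys[keys.isin(chosen)].reset_index(drop=True)


def snap_sites_to_reaches(
    sites: pd.DataFrame, reaches: pd.DataFrame, tolerance: float = 30.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map each site to its nearest reach point within ``tolerance`` metres.

    Both frames need x and y columns in a shared projected coordinate
    system.  The comparison is inclusive at exactly ``tolerance``.  Returns
    (mapping with site_id, reach_id, distance) and a report of dropped
    sites.
    """
    if len(reaches) == 0:
        raise ValueError("empty reach set")
    tree = cKDTree(reaches[["x", "y"]].to_numpy(dtype=float))
    dist, idx = tree.query(sites[["x", "y"]].to_numpy(dtype=float))
    mapping = pd.DataFrame(
        {
            "site_id": sites["site_id"].to_numpy(),
            "reach_id": reaches["reach_id"].to_numpy()[idx],
            "distance": dist,
        }
    )
    ok = mapping["distance"] <= tolerance
    return mapping[ok].reset_index(drop=True), mapping[~ok].reset_index(drop=True)


@dataclass
class OccurrenceMatrix:
    """Binary sites x species matrix with site and species metadata."""

    matrix: pd.DataFrame  # index site_id, columns species, values {0,1}
    site_meta: pd.DataFrame  # index site_id: reach_id, region (when known)
    species_meta: pd.DataFrame  # index species: prevalence, n_occurrences

    def validate(self) -> None:
        vals = self.matrix.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("occurrence matrix entries must be 0/1")


def _species_meta(matrix: pd.DataFrame) -> pd.DataFrame:
    counts = matrix.sum(axis=0)
    return pd.DataFrame(
        {"n_occurrences": counts.astype(int), "prevalence": matrix.mean(axis=0)}
    )


def build_occurrence_matrix(
    surveys: pd.DataFrame,
    site_meta: pd.DataFrame | None = None,
    all_sites=None,
) -> OccurrenceMatrix:
    """Pivot species-rank records of deduplicated surveys into a 0/1 matrix.

    ``all_sites`` names the surveyed-site universe; a surveyed site with no
    species-rank record is a row of absences, not a missing row.  It
    defaults to the sites present in ``surveys``.
    """
    sp = surveys[surveys["rank"] == "species"]
    matrix = (
        pd.crosstab(sp["site_id"], sp["taxon"]).clip(upper=1).astype(int)
    )
    if all_sites is None:
        all_sites = surveys["site_id"].unique()
    matrix = matrix.reindex(sorted(all_sites), fill_value=0)
    matrix.index.name = "site_id"
    meta = (
        site_meta.loc[matrix.index]
        if site_meta is not None
        else pd.DataFrame(index=matrix.index)
    )
    occ = OccurrenceMatrix(matrix=matrix, site_meta=meta, species_meta=_species_meta(matrix))
    occ.validate()
    return occ


def select_species(occ: OccurrenceMatrix, min_occurrences: int = 25) -> OccurrenceMatrix:
    """Drop species with fewer than ``min_occurrences`` presences."""
    occ.validate()
    counts = occ.matrix.sum(axis=0)
    keep = counts[counts >= min_occurrences].index
    if len(keep) == 0:
        raise ValueError(
            f"no species with at least {min_occurrences} occurrences survive the filter"
        )
    matrix = occ.matrix[keep]
    return OccurrenceMatrix(
        matrix=matrix, site_meta=occ.site_meta, species_meta=_species_meta(matrix)
    )
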