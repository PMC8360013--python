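"""Apply the survey quality rules and build the occurrence matrix.

Completeness filtering against minimum potential richness, per-site survey
deduplication, snapping of sites to reaches (30 m tolerance) and the
25-occurrence species filter.  Writes the final sites x species matrix and
a per-survey completeness report.
"""

import json

from _common import CONFIG, SEED, ensure_results
from riversdm import pipeline, survey_prep, synthetic

results = ensure_results()

rs = synthetic.generate_riverscape(CONFIG.n_reaches, SEED, CONFIG.riverscape)
X_true = synthetic.true_predictor_matrix(rs)
pool = synthetic.generate_species_pool(
    CONFIG.n_species, SEED + 1, pipeline._niche_ranges(X_true, CONFIG.niche_predictors)
)
surveys = synthetic.simulate_surveys(
    rs, pool, CONFIG.n_sites, CONFIG.ident_rates, SEED + 2, predictors=X_true
)

kept, report = survey_prep.completeness_filter(surveys.records, CONFIG.completeness_threshold)
kept = survey_prep.dedupe_sites(kept)
mapping, dropped = survey_prep.snap_sites_to_reaches(surveys.sites, rs.reaches,
                                                     CONFIG.snap_tolerance)
kept = kept[kept["site_id"].isin(mapping["site_id"])]
occ = survey_prep.build_occurrence_matrix(kept)
occ = survey_prep.select_species(occ, CONFIG.min_occurrences)

occ.matrix.to_csv(results / "occurrence_matrix.csv")
occ.species_meta.to_csv(results / "species_prevalence.csv")
mapping.to_csv(results / "site_to_reach.csv", index=False)
report.to_csv(results / "survey_completeness_report.csv", index=False)
with open(results / "survey_filter_summary.json", "w") as fh:
    json.dump(
        {
            "n_surveys": int(len(report)),
            "n_discarded_incomplete": int((~report["kept"]).sum()),
            "n_sites_unsnapped": int(len(dropped)),
            "n_sites_final": int(len(occ.matrix)),
            "n_species_final": int(occ.matrix.shape[1]),
        },
        fh,
        indent=2,
    )

print(f"{(~report['kept']).sum()} of {len(report)} surveys discarded as incomplete "
      f"(<{CONFIG.completeness_threshold:.0%} of minimum potential richness); "
      f"{len(dropped)} sites beyond the {CONFIG.snap_tolerance:.0f} m snap tolerance.")
print(f"Final matrix: {occ.matrix.shape[0]} sites x {occ.matrix.shape[1]} species "
      f"with >= {CONFIG.min_occurrences} occurrences "
      f"(prevalence {occ.species_meta['prevalence'].min():.2f}-"
      f"{occ.species_meta['prevalence'].max():.2f}).")
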