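"""Generate the synthetic study system: riverscape, species pool, surveys.

Writes the species pool with its niche parameters under results/ and the
bulky per-reach tables (reaches, raw survey records with genus/family-rank
identifications) under scratch/.
"""

import pandas as pd

from _common import CONFIG, SEED, ensure_results, scratch
from riversdm import pipeline, synthetic

results = ensure_results()

rs = synthetic.generate_riverscape(CONFIG.n_reaches, SEED, CONFIG.riverscape)
X_true = synthetic.true_predictor_matrix(rs)
pool = synthetic.generate_species_pool(
    CONFIG.n_species, SEED + 1, pipeline._niche_ranges(X_true, CONFIG.niche_predictors)
)
surveys = synthetic.simulate_surveys(
    rs, pool, CONFIG.n_sites, CONFIG.ident_rates, SEED + 2, predictors=X_true
)

rs.reaches.to_csv(scratch() / "reaches.csv", index=False)
surveys.records.to_csv(scratch() / "survey_records.csv", index=False)
surveys.sites.to_csv(scratch() / "survey_sites.csv", index=False)
pd.DataFrame(
    [
        {
            "species_id": sp.species_id,
            "genus": sp.genus,
            "family": sp.family,
            "pmax": sp.pmax,
            **{f"mu_{k}": v[0] for k, v in sp.niche.items()},
            **{f"sigma_{k}": v[1] for k, v in sp.niche.items()},
        }
        for sp in pool
    ]
).to_csv(results / "species_pool.csv", index=False)

prev = surveys.truth.mean()
print(f"Simulated {CONFIG.n_reaches} reaches, elevation "
      f"{rs.reaches['elevation'].min():.0f}-{rs.reaches['elevation'].max():.0f} m, "
      f"{int((rs.reaches['glacier_lake_pct'] > 0).sum())} glaciated.")
print(f"{CONFIG.n_species} virtual species, true prevalence "
      f"{prev.min():.2f}-{prev.max():.2f} (median {prev.median():.2f}).")
print(f"{CONFIG.n_sites} surveys with {len(surveys.records)} records "
      f"({(surveys.records['rank'] != 'species').mean():.0%} at genus/family rank).")
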