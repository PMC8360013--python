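# Methods

`riversdm` implements a complete modelling chain for predicting riverine
EPT (Ephemeroptera, Plecoptera, Trichoptera) species distributions and
species richness under climate scenarios, together with a synthetic
riverscape and virtual-species generator that provides fully known ground
truth for every stage.  This note records the models, the defaults and why
they were chosen, the numerical conventions, and what the synthetic tests
do and do not demonstrate.

## The modelling chain

1. **Survey preparation.**  Field records arrive at species, genus or
   family rank.  A survey's *minimum potential richness* is
   S + G′ + F′: identified species, plus genus-rank records whose genus
   contains no identified species, plus family-rank records whose family
   contains neither a genus-rank record nor the genus of an identified
   species.  Surveys whose identified-species share S/(S+G′+F′) falls
   below 0.70 are discarded (kept when exactly 0.70).  One survey per site
   is retained — the most complete, ties broken by latest date then
   lexicographic key.  Sites snap to the nearest reach within 30 m
   (inclusive); species with fewer than 25 site-level occurrences are
   dropped.
2. **Environmental predictors.**  Eight predictors per reach: mean and
   coefficient of variation (CV) of monthly water temperature, natural-log
   mean and CV of monthly discharge, channel slope, and urban, forest and
   agriculture cover.  CV uses the sample SD (n−1): the common software
   default.  The discharge mean is log-transformed per year and the log
   values averaged over a projection decade; monthly water temperature is
   floored at 0 °C before summarising, which keeps the CV defined and
   finite at cold high-elevation reaches.
3. **Water temperature** at unmonitored reaches comes from a linear mixed
   model fitted to a monitoring network: fixed effects intercept + air
   temperature + air temperature × glacier/lake cover, random intercept
   and random air-temperature slope per station.  Projection uses fixed
   effects only, since station-level random effects do not exist for
   unmonitored reaches.  Marginal and conditional R² follow the
   variance-decomposition convention (fixed variance, mean of z′Gz, and
   residual variance).  A singular random-effects fit is flagged on the
   returned model rather than hidden.
4. **Spatial eigenvectors.**  Five leading eigenvectors of the doubly
   centered matrix of Euclidean distances between reaches are appended as
   covariates.  The default centers the *raw* distance matrix
   (C = −½HDH): for planar coordinates this matrix has a rich positive
   spectrum, so five well-defined large-scale patterns always exist.
   Classical principal-coordinates centering of squared distances is
   available behind `kind="squared"` for sensitivity analysis; for n×2
   coordinates it has rank 2 and cannot supply five eigenvectors, which is
   why it is not the pipeline default.  For large n a Nyström
   approximation anchored on k-means centres of the coordinates is used,
   followed by a Rayleigh–Ritz refinement (the full centered operator is
   applied blockwise to the approximated subspace and re-diagonalised).
   The refinement removes the rotation that anchor sampling introduces
   between near-degenerate eigenvectors; with 100 anchors at n = 1000
   every column correlates with the exact eigenvector at |r| ≥ 0.995, and
   n = 10 000 runs in a few seconds.
5. **Ensemble SDMs.**  Per species, two members: a binomial GLM with
   degree-2 orthogonal-polynomial terms on the eight environmental
   predictors (unimodal responses) and linear terms on the eigenvectors,
   and a 500-tree random-forest classifier (seeded per species × split).
   Fifty community cross-validation splits (80/20), identical for every
   species and for the richness models.  The ensemble probability is the
   convex combination of member probabilities with weights
   w = max(AUC − 0.5, 0) from each member's mean test-fold AUC, so a
   no-skill member gets zero weight; raw-AUC weighting is available via
   `weight_mode="raw"`.  Final members are refit on all sites; CCV serves
   only evaluation and weighting.  AUC is the Mann–Whitney probability
   with ties counted ½; TSS is maximised over all candidate thresholds
   (midpoints of sorted unique scores plus endpoints).  Performance bands
   use the median across splits: AUC >0.90 excellent, 0.80–0.90 good,
   0.70–0.80 fair, 0.60–0.70 poor; TSS >0.75 excellent, 0.40–0.75 good,
   <0.40 poor.
6. **Richness.**  The macroecological model (MEM) pairs a Poisson GLM
   (same design) with a random-forest regressor, weighted by mean
   test-fold Spearman correlation floored at zero (a constant fold yields
   weight 0 with a warning).  Stacked SDMs (S-SDM) sum occurrence
   probabilities per site; under independence the observed richness then
   follows the Poisson-binomial distribution, computed exactly by
   iterative convolution.  The per-site test uses the
   small-probability-mass convention (p-value = total mass of outcomes no
   more likely than the observed one); a central, tail-doubling variant is
   available.  Calibration is tested by the joint F-test of intercept 0
   and slope 1 in the regression of observations on predictions — that
   direction, fixed here, matches testing the predictions' linear
   relationship *with observations*.  Standardised errors are
   (prediction − observation)/mean observation.
7. **Interpretation.**  Permutation importance is 1 − r between
   predictions on intact and column-permuted data, averaged over 10
   permutations and clipped at zero; grouped importance divides each
   predictor type's summed importance by its variable count.  Response
   curves sweep the focal variable over its observed range with all other
   columns at training medians (means behind a flag).
8. **Projection.**  Models are projected onto predictor matrices for
   three decades (t1 baseline, t2 mid-century, t3 end-century) × two
   emission pathways.  Reported statistics are unweighted means over
   reaches (no length weighting), and relative changes
   100·(future − baseline)/baseline are rounded half-away-from-zero to
   one decimal, the convention of the published tables shipped in
   `riversdm/data/`.  A small number of printed cells in those reference
   tables differ by 0.1 point from recomputation (the source rounded
   internal, unrounded means); worked-example checks therefore pin only
   self-consistent cells, and order statistics use the printed change
   column itself.

## The synthetic generator

The generator emulates the statistical structure the chain assumes, not
any particular landscape:

* **Riverscape** — reaches scattered over a 100 km square; elevation
  (200–3000 m) is a mountainous mosaic with only a weak south–north trend,
  so elevation-driven predictors are not proxies for position and the
  predictor set passes the collinearity screens (max |r| < 0.7,
  VIF < 4) that the real predictor set is documented to pass.  Monthly air
  temperature = 15 °C at sea level, lapse rate −6 °C/km, July-peaking
  sinusoid with per-reach amplitude (continentality) drawn from
  0.45–1.55 × 9 °C, noise SD 1 °C.  Discharge is lognormal around an
  elevation-dependent level with a summer-peaking cycle.  Reaches above
  2200 m carry glacier cover discretised into 20 equal-area cells whose
  elevations drive the lowest-first retreat heuristic (replacement
  fractions 0.45/0.50 at mid-century and 0.60/0.90 at end-century for the
  low/high-emission pathways).
* **Water temperature truth** — WT = 1.8 + 0.72·AT − 0.008·AT·cover.  The
  interaction magnitude makes a heavily glacier-fed reach (40 % cover)
  warm about a third less per degree of air warming, a strong but
  physically plausible buffering, and is identifiable from the simulated
  monitoring network (60 stations, half deliberately placed on
  glacier/lake-fed reaches, 36 monthly measures; random intercept SD 0.5,
  random slope SD 0.04, residual SD 0.7).  Fixed effects recover with
  < 10 % mean absolute error over 50 simulated networks.
* **Virtual species** — Gaussian niches on mean water temperature, log
  discharge and forest cover with cap pmax:
  p(x) = pmax·exp(−Σ(xⱼ−μⱼ)²/2σⱼ²).  Breadths 0.2–0.5 of the predictor
  range and pmax 0.6–0.98 give realised prevalences of roughly 0.05–0.45
  (median ≈ 0.16) and a truth-level discriminability (AUC of the true
  probabilities against realised presences) of about 0.86 — matching both
  the prevalence distribution and the discrimination level of the real
  41-species community the pool stands in for.  Low-prevalence species
  falling under the 25-occurrence floor are dropped by the survey filter,
  as in the real study.  Taxonomy is a proper species → genus
  → family tree.
* **Surveys** — one Bernoulli draw per site × species at the true
  probability; each detection is recorded at species/genus/family rank
  with probabilities 0.85/0.10/0.05, coarser records inheriting the true
  lineage.  Site coordinates jitter ≤ 10 m around their reach so snapping
  is exercised.  True probabilities are retained as hidden ground truth.
* **Scenarios** — warming offsets (+1.0 °C for the low-emission pathway;
  +2.5 / +4.2 °C at mid/end-century for the high-emission pathway),
  discharge multipliers (0.97; 0.93/0.88) and the glacier-replacement
  fractions above.  The baseline decade is the identity.

What the generator does **not** emulate: river-network topology and flow
routing (reaches are points, not a connected network), spatially
autocorrelated niche residuals, biotic interactions, dispersal limits,
temporal survey revisits, observer-specific detection bias, and the
dependence of discharge on upstream glacier melt.  Passing tests therefore
demonstrate that the chain recovers truth when its assumptions hold — not
that those assumptions hold in any real river system.

## Problem sizes

The analysis drivers run the desk-scale study: 500 reaches, 30 virtual
species, 300 survey sites, 50 CCV splits, 300 trees per forest.  The
acceptance script uses the same code paths at reduced sizes chosen as
adequate for the quantities it measures: a 350-reach / 20-species /
220-site study with 10 splits and 150 trees for the discrimination and
richness-calibration summaries, 20 seeded 200-reach runs for the
warming-direction experiment, and 50-replicate simulations for the
recovery metrics.

## Known limitations

* The GLM member reports, but does not regularise, quasi-separation;
  affected CCV splits are skipped and logged.
* The exact Poisson-binomial test is conservative on its discrete support;
  empirical type-I error runs at roughly 3–5 % for nominal 5 %.
* Nyström eigenvalues are Ritz values: accurate for the leading block,
  increasingly biased low near the cut-off k.
* The mixed model assumes a common residual variance across stations.
* In the generator, fixed effects dominate the water-temperature variance
  (marginal R² ≈ 0.97), higher than typical field monitoring data; the
  recovery tests are correspondingly easier than a field fit would be.
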