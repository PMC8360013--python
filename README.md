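# riversdm

Ensemble species-distribution and stacked-SDM richness modelling for
riverine insect communities (Ephemeroptera, Plecoptera, Trichoptera — EPT)
under climate scenarios.

Aquatic EPT larvae are standard bioindicators of running-water health, and
their richness (EPTr) is widely used as a proxy for ecological status.
`riversdm` is for freshwater macroecologists who want to project how
occurrence probabilities and EPTr respond to warming, flow change and
glacier retreat across a river network, and to do so with a pipeline whose
every stage is testable: a synthetic riverscape and virtual-species
generator with fully known ground truth stands in for restricted monitoring
data.

## The models

**Per-species ensemble SDMs.**  Each species' presence/absence y over
sites is modelled by two members — a binomial GLM with degree-2
orthogonal-polynomial terms on eight environmental predictors (mean and CV
of monthly water temperature, log-mean and CV of monthly discharge, slope,
urban/forest/agriculture cover) plus five spatial eigenvectors, and a
random-forest classifier.  The ensemble probability is

    p = (w_A p_A + w_B p_B) / (w_A + w_B),   w = max(AUC − 0.5, 0),

with member AUCs estimated on N = 50 community cross-validation splits
(80/20), the same splits for every species.  Skill is summarised by AUC
(Mann–Whitney form) and TSS (max over thresholds of sensitivity +
specificity − 1).

**Richness.**  Two complementary community predictions:

* *S-SDM* — stacked SDMs: expected richness is the per-site sum of the
  species probabilities, EPTr = Σⱼ pⱼ.  Under independence the realised
  richness follows the Poisson-binomial distribution with that probability
  vector; its exact pmf (iterative convolution) gives a per-site test of
  the observed count at α = 0.05.
* *MEM* — a macroecological model: a Poisson GLM + random-forest regressor
  ensemble on the same predictors, weighted by Spearman correlation between
  observed and predicted richness on test folds.

Calibration of either prediction is assessed by the joint F-test of
intercept 0 and slope 1 in observed ~ predicted, and by errors standardised
by mean observed richness.

**Spatial structure** enters through the first five eigenvectors of the
doubly centered matrix of Euclidean distances between reaches, computed
exactly for small n and by an anchor-based Nyström approximation with
Rayleigh–Ritz refinement for large n.

**Scenarios.**  Monthly forcings are perturbed per decade (t1 2015–2025,
t2 2055–2065, t3 2080–2090) and pathway (RCP2.6, RCP8.5): warming offsets,
discharge multipliers and a glacier-retreat heuristic that reclassifies the
lowest-elevation 45/50/60/90 % of glacier cells to bare rock.

## Worked example

The numbered drivers under `analysis/` run the desk-scale study
(500 reaches, 30 virtual species, 300 survey sites, 50 CV splits) and write
their tables under `results/`:

```bash
cd analysis
python 01_simulate.py && python 02_prepare_surveys.py \
  && python 03_build_predictors.py && python 04_fit_and_project.py \
  && python 05_report.py
```

The run prints, among other things:

```
30 virtual species, true prevalence 0.03-0.44 (median 0.16).
25 of 296 surveys discarded as incomplete (<70% of minimum potential richness); ...
Final matrix: 271 sites x 25 species with >= 25 occurrences (prevalence 0.11-0.36).
Water-temperature mixed model (60 stations, 36 monthly measures):
  WT = 1.86 + 0.727*AT -0.00830*AT*cover; marginal R2 = 0.97, conditional R2 = 0.98.
Collinearity screen: max |r| = 0.65 (< 0.7), max VIF = 2.82 (< 4): pass.
25 species modelled on 271 sites; community median AUC = 0.78, TSS = 0.56;
  AUC bands: {'fair': 12, 'good': 8, 'poor': 5}.
Richness calibration: standardized error +0.01±0.23 (S-SDM), +0.00±0.22 (MEM);
  100% of sites pass the exact Poisson-binomial test; MEM-vs-S-SDM correlation 0.98.
RCP2.6: end-century changes in mean occurrence probability span -25.0% to +42.3% (median -3.2%).
RCP8.5: end-century changes in mean occurrence probability span -70.5% to +205.5% (median -25.5%).
End-century national mean richness (S-SDM): 4.3 under RCP8.5 vs 4.8 under RCP2.6 (-10.6%);
  S-SDM vs MEM difference +8.1%.
```

Reading these numbers: the survey filter discards incomplete surveys
(identified species < 70 % of the minimum potential richness) and species
below 25 occurrences; the mixed model recovers the generator's
water-temperature relation; the collinearity screen confirms all pairwise
|r| < 0.7 and VIF < 4; and under the high-emission pathway the virtual
community loses richness by end-century while cold-adapted species decline
and warm-adapted species expand — the qualitative signature the chain is
designed to detect.

A minimal library session:

```python
from riversdm import datasets, projection

ref = datasets.load_reference_changes("RCP8.5").set_index("species")
row = ref.loc["Rhithrogena loyolaea"]
projection.relative_change(row["p_t1"], row["p_t3"])   # -52.1 (%)
projection.change_table_stats(ref["delta_t3_pct"])
# {'min': -52.1, 'median': -5.1, 'max': 86.5}
```

`riversdm/data/` ships a reference table of published national-scale mean
occurrence probabilities for 41 EPT species by decade and pathway; the
change-table arithmetic reproduces its printed relative-change cells.

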