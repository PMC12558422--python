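# urbanfrail

Tools for studying how urban quality relates to frailty, nutrition and blood
markers in older adults. The package bundles four things that such a study
needs:

1. **A raster urban-quality index.** For each of 7 facility types
   (fruit/vegetable shops, senior centers, pharmacies, emergency health
   centers, squares and parks, family health centers, exercise facilities) a
   Euclidean distance surface is computed on a 50-m grid, reclassified into
   close/medium/distant zones scored 3/2/1 with facility-specific distance
   bands (e.g. shops: &lt;300 m / 300–600 m / &gt;600 m), and the layers are
   summed into a summary index *S* ∈ [7, 21] per cell — higher means better
   access. Values are read off at participant locations by cell containment
   and participants are stratified into empirical quartiles Q1–Q4 of *S*.
2. **Clinical scoring.** FTS-5 (Frailty Trait Scale): five domains
   (nutrition, physical activity, nervous system, strength, gait speed) each
   scored 0–10; total 0–50; frail ⇔ total &gt; 25. A configurable FTS-3
   subscale sums three of the domains. CONUT (Controlling Nutritional
   Status): graded subscores for serum albumin (0/2/4/6), lymphocyte count
   (0/1/2/3) and total cholesterol (0/1/2/3); total 0–12 with categories
   normal (0–1), light (2–4), moderate (5–8), severe (≥9).
3. **A calibrated synthetic city-and-cohort generator.** Poisson facility
   layers over a 5 × 5 km grid with 6 socioeconomic clusters; a cohort of
   n = 251 whose frailty prevalence (17.5%), group BMI, handgrip-by-quartile
   gradient and lab-marker rank correlations with the index (Gaussian copula,
   ρ_pearson = 2 sin(πρ_spearman/6)) are calibrated so that every downstream
   analysis can be exercised and tested without any external data.
4. **The statistical report.** Welch t / Mann–Whitney (auto-selected by a
   Shapiro screen), Yates-corrected chi-square with Wilson CIs, Spearman
   correlation panels, OLS fits, assembled into a quartile-stratified
   report (demographics by frailty status, metrics by index quartile with
   Q4-vs-Q1 contrasts, analyte–index correlations, facility-distance
   contrasts).

It is aimed at epidemiologists and urban-health researchers who want a
tested, reproducible reference implementation of this analysis pattern.

## Worked example

```sh
python examples/03_simulate_and_analyze.py
```

prints (seed 1):

```
cohort n=251, frail 44 (17.5%)
BMI frail 30.6 vs nonfrail 28.5 kg/m^2 (p=0.0030)
index -> FTS-5: slope 0.94 points/index unit, r=0.184, p=0.0035 (positive: frailer people cluster in better-served areas)
lab subset n=70: Spearman rho with index — bilirubin 0.21, CONUT 0.21
```

One seeded draw of the default study: 44 of 251 synthetic participants are
frail (FTS-5 total &gt; 25); the frail group carries ~2 BMI units more; the
urban-quality index is positively associated with the FTS-5 score; and in
the 70-person lab subset both bilirubin and the CONUT total rank-correlate
positively with the index. Single-seed correlations scatter around their
calibrated targets (0.33 / 0.25) — `examples/04_replication_batch.py`
averages them over 20 seeds.

The same pipeline is available from the shell:

```sh
urbanfrail all --seed 1 --out out/
# or stage by stage: urbanfrail simulate | index | score | analyze
```

which writes the city bundle (GeoJSON layers + grid.json), the index raster
(ESRI ASCII), the scored cohort CSV and `report.json`.

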