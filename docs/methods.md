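# Methods

## Urban-quality summary index

The index is an additive accessibility score on a regular planar raster
(default 50-m cells, coordinates in meters in a local projected frame; CRS
metadata is an opaque string and nothing is ever reprojected). For each
facility type the distance surface is the exact Euclidean distance from each
cell *center* to the nearest facility point, computed with a k-d tree —
exact nearest neighbours, not a chamfer or other approximate distance
transform, so the brute-force oracle test can demand bitwise equality. Each
surface is reclassified with the facility's two thresholds (near_max,
mid_max):

| zone | rule | score |
|---|---|---|
| close | d &lt; near_max | 3 |
| medium | near_max ≤ d ≤ mid_max | 2 |
| distant | d &gt; mid_max | 1 |

Boundary distances score 2: the band tables are written with strict
inequalities on the outer zones, so both thresholds belong to the middle
band. The summary index is the cellwise sum of the score layers; with the 7
default layers every cell is an integer in [7, 21]. Adding a facility point
can only shrink distances, so scores and index are monotone non-decreasing
under facility addition — this is asserted as a property test.

Participant extraction is a spatial containment join: the value of the cell
whose half-open extent [x0, x0+cs) × [y0, y0+cs) contains the point. No
interpolation — the surface is integer-valued and a spatial join is the
natural operation; the half-open convention makes edge points deterministic.

Quartiles are empirical participant-level quartiles of the extracted index
with right-closed upper bins (Q1 = [min, e25], Qk = (e_{k-1}, e_k]), so tied
values never straddle bins. Because the index is integer-valued and heavily
tied, quartile shares deviate from 25% and an interior bin can occasionally
be empty; consumers of quartile summaries use NaN-aware aggregation.

## Clinical scoring

**FTS-5** consumes the five domain scores directly (each 0–10). The
instrument-specific conversions from raw measures (BMI charts, activity
scales, Romberg stages, dynamometry, walk times) are deliberately out of
scope: they are configurable mappings in the consuming study, and inventing
reference charts here would add unverifiable assumptions. Total = sum of
domains; frail ⇔ total strictly &gt; 25 (so a participant at exactly 25 is
nonfrail). **FTS-3** is a configurable subset, default
{physical_activity, strength, gait_speed} — the functional triad; this
composition is an assumption and is exposed in config. On default synthetic
cohorts the subscale's Spearman concordance with the full scale exceeds 0.8.

**CONUT** uses the graded band defaults
(albumin ≥3.50→0, 3.00–3.49→2, 2.50–2.99→4, &lt;2.50→6;
lymphocytes ≥1600→0, 1200–1599→1, 800–1199→2, &lt;800→3;
cholesterol ≥180→0, 140–179→1, 100–139→2, &lt;100→3). Graded bands are
required for totals to reach the severe range (≥9); the simplified
single-cutoff variant sometimes quoted (albumin &lt;3.5, lymphocytes
&lt;1500, cholesterol &lt;160) is reproducible by overriding the band edges
in `ConutBands`. Categories: 0–1 normal, 2–4 light, 5–8 moderate, ≥9 severe.

## Synthetic city and cohort

The generator exists so that every downstream stage is testable with no
external data; it emulates the *structure* of an observational urban-aging
study, not any particular city's geography.

**City.** Facilities are homogeneous Poisson point processes per type
(intensities in points/km², resampled until each layer has ≥1 point).
Default intensities were chosen once so that each layer's
nearest-distance distribution straddles its own bands
(λπ·near_max² ≈ 0.7, i.e. roughly half the city "close" per layer), which
yields participant index values spanning roughly 12–21 — a realistic spread
for a serviced mid-size city. Clusters are the nearest-seed partition of the
grid around 6 seed positions (defaults are fractions of the grid extent);
cluster labels are cosmetic sociodemographic metadata and do not enter the
generative model.

**Cohort.** With the standardized participant index z:

1. locations: cluster chosen by configured weights, uniform within a random
   cell of that cluster;
2. frailty: Bernoulli(logistic(α + βz)) with β = 0.4 logit/SD and α solved
   by bisection so the cohort-mean probability equals the target prevalence
   0.175 exactly;
3. FTS-5 totals: truncated normal conditional on the label (nonfrail on
   [0, 25], mean 11.5 + z; frail on (25, 50], mean 29 + z), so
   frail ⇔ total &gt; 25 holds by construction; totals are split into 5
   domains by Dirichlet(2) proportions with rejection of splits exceeding
   the 10-point domain cap (a clip-and-redistribute waterfall handles the
   rare near-50 totals);
4. BMI ~ Normal(31.5, 4.4) frail / Normal(28.5, 4.5) nonfrail; age and sex
   per group; gait speed ~ Normal(0.95, 0.25) with a small negative index
   slope;
5. handgrip = base − slope·z + Normal(0, 6.5), with (base, slope) =
   (21.17, 1.46) obtained by moment matching: E[grip|Q] = base − slope·E[z|Q],
   quartile z-means estimated by simulation and the 2×2 system solved for
   the Q1/Q4 targets 22.8/19.1 kg (`calibrate_handgrip`);
6. lab markers: Gaussian copula against the Blom normal scores of the index
   ranks, with latent Pearson correlation 2 sin(πρ_s/6) for target Spearman
   ρ_s (bilirubin 0.33, serum iron 0.27, transferrin saturation 0.24, RBC
   0.26, RDW 0.23), mapped through truncated-normal marginals (truncated at
   0; transferrin saturation also at 100);
7. the CONUT-driving analytes (albumin, lymphocytes, cholesterol) load
   negatively (−0.85) on a latent nutritional-risk factor that is itself
   copula-linked to the index. Because CONUT is a coarse step function of
   the analytes, rank correlation is attenuated; the latent index–risk
   Spearman is therefore calibrated by bisection against simulated cohorts
   (`calibrate_conut_latent`) and frozen at 0.34 for a realised
   Spearman(index, CONUT) ≈ 0.25 on 70-person lab subsets;
8. the lab subset (default 70 of 251) is drawn uniformly without
   replacement.

Everything is driven by one `numpy` Generator per call; a fixed seed gives
byte-identical CSV output. `simulate_study(seed)` derives independent city
and cohort streams from one seed via `SeedSequence.spawn`.

**What the generator does not emulate.** Street networks and route
distances (all distances are Euclidean), spatial autocorrelation of health
outcomes beyond what the shared index induces, inter-analyte dependence
beyond the shared index/risk factors, socioeconomic confounding (cluster
labels are cosmetic), and any causal structure — dependencies are monotone
associations by construction. Passing tests therefore demonstrate that the
pipeline recovers planted associations of realistic magnitude, not that the
real-world associations have those magnitudes.

## Statistics

Two-group comparisons default to `auto`: Mann–Whitney when either group
fails a Shapiro normality screen at α = 0.05, otherwise Welch's t
(unequal-variance by default — the robust choice when the variance ratio is
unknown); every auto decision is logged. Mann–Whitney uses the exact null
distribution for small tie-free samples and the tie-corrected normal
approximation otherwise, so it agrees with full permutation enumeration for
pooled n ≤ 10. Proportions use the 2×2 chi-square with Yates continuity
correction and Wilson 95% intervals (CI method configurable); identical
proportions short-circuit to χ² = 0, p = 1 rather than tripping the
degenerate-margin path. Spearman uses average ranks (exactly
Pearson-on-ranks) with the t-approximation p. Significance is α = 0.05 with
no multiple-testing correction by default, matching the single-study
reporting convention the report mirrors; a Benjamini–Hochberg pass can be
applied downstream by the consumer. The report builder sorts by participant
id before computing anything, making its JSON byte-stable under input row
order.

## Numerical and I/O choices

* Distance computations are exact (k-d tree); no approximate transforms.
* Logistic-intercept bisection runs to an interval of 1e-12 (mean
  probability within ~1e-6 of target).
* Rasters are exchanged as ESRI ASCII grids (text; `repr`-precision floats,
  lossless round trip). GeoJSON point layers carry facility types; reading
  validates geometry type per feature and rejects unknown facility types; a
  missing layer produces a warning and the index bounds follow the layer
  count [n, 3n].
* The pipeline (`simulate → index → score → analyze`) communicates only
  through files, so any stage can be re-run in isolation; provenance JSON
  records configs, seeds and software version.

## Problem sizes

Defaults used throughout: 100×100 cells of 50 m (5 × 5 km), n = 251
participants, 70-person lab subset. The replication batch
(`urbanfrail.replication`) averages 200 seeded studies; with exact
vectorised distance queries this completes in seconds. Calibration
functions (`calibrate_handgrip`, `calibrate_conut_latent`) are shipped and
tested; their outputs are frozen as configuration defaults so ordinary use
never re-runs them.

## Known limitations

* Euclidean distance overstates accessibility where street networks are
  sparse; no network routing.
* The integer-valued index makes quartile strata uneven under ties (see
  above); quartile contrasts on small cohorts can involve very unequal
  group sizes.
* The FTS-3 composition and the raw-measure→domain mappings are
  assumptions exposed as configuration, not validated instruments.
* Frailty status does not directly shift the lab/CONUT distributions (only
  through the shared index), so group contrasts on lab markers are weaker
  than index correlations by design.
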