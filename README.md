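# pelagidiet

Multi-proxy trophic-ecology analytics for small pelagic fish (anchovy
*Engraulis encrasicolus* and sardine *Sardina pilchardus*), combining three
complementary views of diet:

* **gut-content characterization** — per-stomach prey counts converted to
  feeding-intensity and composition metrics,
* **DNA metabarcoding** — OTU read tables (COI zooplankton, rbcL diatom
  markers) reduced to presence/absence diet records after a hygiene filter
  cascade,
* **stable isotopes** — δ¹³C/δ¹⁵N niche geometry via standard ellipses.

The package is aimed at trophic ecologists who want the full downstream
analysis — from raw count tables to a qualitative north-vs-south summary
matrix — as tested, scriptable building blocks, plus a synthetic-study
generator so every stage can be exercised without access to survey data.

## Methods at a glance

**Feeding intensity.** Stomach filling degree
`SFD = Σ prey weight (mg) / fish total length (mm)`; fish below 11 cm
(anchovy) or 13 cm (sardine) are juveniles. Composition is summarised per
prey group as %N (numeric), %B (biomass, counts × unit weights with a
species→genus→family→group fallback), and %FO (occurrence), as site means
within areas.

**Diversity.** Richness S, Shannon–Wiener `H' = −Σ pᵢ ln pᵢ`, and
sample-size-based rarefaction/extrapolation (hypergeometric interpolation,
Chao-style extrapolation, bootstrap bands). Inter-specific diet similarity
uses Whittaker's presence/absence beta-diversity

    β_w = (a + b + c) / ((2a + b + c)/2) − 1

with `a` shared taxa and `b`, `c` exclusive taxa (0 = identical diets,
1 = disjoint).

**Niche overlap.** Pianka's index

    O = Σ p_ij p_ik / sqrt(Σ p_ij² · Σ p_ik²)

on diet-proportion vectors over 11 prey groups, tested against the RA2
randomization null (zero states retained, non-zero utilizations redrawn
from U(0,1); 1000 iterations, add-one p-value).

**Isotopic niche.** After lipid-normalizing δ¹³C when C:N > 3.5
(δ¹³C′ = δ¹³C − 3.32 + 0.99·C:N), each stratum's bivariate isotope cloud is
summarised by the standard ellipse area `SEA = π√det(Σ)` (≈40% of the
data), its small-sample correction `SEA_C = SEA·(n−1)/(n−2)`, the Bayesian
posterior SEA_B (Normal–Inverse-Wishart, 10,000 draws), and directional
ellipse-overlap percentages.

**Regression.** Penalized-spline additive models (cubic basis, dimension 4,
curvature penalty, GCV) with Shapiro–Wilk-driven family choice
(gaussian-identity / gaussian-log / gamma-log), Pearson-correlation and
GVIF collinearity screening, and forward–backward AIC stepwise term
selection.

**Latitudinal verdicts.** For every metric the northern vs southern value is
classified `N > S`, `S > N`, or `NLD` (no latitudinal difference) when the
two differ by less than 30% of their mean.

## Worked example

```python
import numpy as np
from pelagidiet import ra2_null_test

anchovy = np.array([55.2, 8.1, 4.4, 9.6, 7.0, 3.1, 2.2, 5.6, 2.1, 1.4, 1.3])
sardine = np.array([61.0, 9.0, 5.1, 6.2, 4.8, 2.0, 2.5, 4.3, 2.6, 1.5, 1.0])
res = ra2_null_test(anchovy, sardine, iterations=1000, seed=42)
print(f"Pianka O = {res.observed:.3f}, RA2 p = {res.p_value:.4f}")
```

```
Pianka O = 0.996, RA2 p = 0.0010
```

The two diet vectors overlap almost completely (O close to 1) and far more
than expected if each species used its non-empty prey groups at random
(p = 0.001, the smallest value 1000 iterations can resolve).

Running the whole pipeline on the built-in synthetic study:

```python
from pelagidiet.pipeline import run_pipeline
from pelagidiet.synthetic import StudyConfig

bundle = run_pipeline(config=StudyConfig(seed=1), outdir="run1")
lat = bundle["latitudinal"]
print(lat[lat.metric.isin(["%B krill", "d15N"])].round(2).to_string(index=False))
```

```
  metric species  value_north  value_south  percent_difference verdict
%B krill anchovy        50.91        96.52               61.87   S > N
    d15N anchovy         7.17         8.70               19.28     NLD
%B krill sardine        37.68        96.81               87.93   S > N
    d15N sardine         7.48         8.91               17.44     NLD
```

Krill contribute far more biomass to southern diets in both species
(`S > N`), while the mean δ¹⁵N contrast (lower in the north, as configured)
stays under the 30% no-difference threshold of the qualitative matrix.
`run1/` receives every intermediate table (composition, filter logs,
diversity, Pianka triangles, ellipse summaries, model fits) plus a
`manifest.json` recording config hash and seed.

The same pipeline is available from the shell:

```bash
pelagidiet --seed 1 run-all --outdir run1
pelagidiet --seed 1 generate --outdir tables/
pelagidiet filter-otu tables/otu_coi.tsv hosts.tsv --marker COI
```

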