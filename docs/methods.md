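# Methods notes

This note documents the statistical procedures implemented in
`pelagidiet`, the assumptions behind them, the defaults of the
synthetic-study generator, and the numerical choices made where the
design was genuinely open.

## Study structure and data model

The package models a two-species (anchovy, sardine) diet study across an
ordered north→south gradient of three areas (GSA07 ~42.5°N, GSA06-North
~40.0°N, GSA06-South ~37.8°N), each sampled at several sites. Four tables
drive the analysis: per-fish metadata (species, area, site, latitude,
depth, total length), a fish × prey-taxon stomach count matrix with a
taxon→group map (11 prey groups) and a unit-biomass lookup, OTU × sample
read tables per marker (COI zooplankton, rbcL diatoms) with taxonomy and
host species, and a per-fish isotope table (δ¹³C, δ¹⁵N, C:N). All I/O is
tab-delimited text; OTU tables use the BIOM-TSV layout (OTU rows, sample
columns, trailing taxonomy column).

## Gut-content metrics

Ontogenetic stage is derived from total length with strict thresholds:
juvenile below 11 cm (anchovy) / 13 cm (sardine); the boundary length is
adult. Stomach filling degree is total prey wet weight (mg, counts ×
per-individual unit weights) divided by fish length in mm. Unit weights
resolve through a species→genus→family→group fallback chain, and the rank
that resolved is recorded so conversions are auditable. Composition
percentages (%N, %B, %FO) are formed per sampling site and averaged
without weights across sites within an area — each site one vote, since
site sample sizes differ; a pooled per-fish alternative is exposed via
`site_averaged=False`. For %B, per-group biomass is divided by the number
of fish in the stratum before percentage formation, removing the
sample-size effect (inside a single stratum this cancels in the
percentage; it matters when absolute weighted biomasses are compared).
Taxa flagged "parasite" are rejected at the door: parasites are excluded
upstream at the bench, and their appearance in a count table indicates a
data-preparation error.

## OTU-table hygiene

Five filters run in a fixed order, each logged with OTUs/samples/reads
removed:

1. OTUs with whole-dataset read fraction strictly below 0.005% are
   dropped (rare clustering noise);
2. cells with within-sample fraction strictly below 0.01% are zeroed
   (mistagging — reads leaking between multiplexed libraries);
3. taxonomically uninformative OTUs are dropped (unassigned under COI;
   non-diatom under rbcL);
4. predator-genus OTUs (*Engraulis*, *Sardina*) are zeroed in samples of
   the matching host species only;
5. COI samples left with fewer than 20 reads are dropped (this step does
   not apply to the diatom marker).

Both thresholds are strict ("below X"), so ties are retained. Order
matters — the global fraction is computed before per-sample zeroing — and
the cascade is idempotent: surviving fractions only grow as reads are
removed, so a second pass changes nothing. Downstream diet information is
presence/absence only. For diatoms, taxa whose overall occurrence is
strictly below the (linearly interpolated) 70th percentile of the
non-zero occurrence vector are merged as "Other diatom groups" by
presence union; an alternative "share of total occurrences < x%" merge
rule is exposed because both conventions circulate, with the percentile
rule as default. OTUs lacking species-level taxonomy report as "Diatom
remains".

## Diversity and similarity

Richness is the count of detected taxa; Shannon–Wiener H′ uses natural
logarithms (the ln scale is what puts index values for ~40–50-taxon diets
in the 1.2–1.8 range typical of such studies). Diatoms are excluded from
richness/diversity comparisons by the pipeline so microscope and
metabarcoding sources stay comparable. Whittaker's pairwise
beta-diversity operates on presence sets; its 0/1 endpoints (identical /
disjoint prey lists) are exact.

Rarefaction is sample-size-based. Interpolation uses the exact
hypergeometric expectation of richness in a random subsample;
extrapolation adds the Chao lower-bound estimate of undetected richness
(bias-corrected form when doubletons are absent), approached
geometrically, and is capped at twice the reference size by default — a
common convention, configurable. Microscope counts use abundance-based
curves; metabarcoding presence/absence uses incidence-based curves over
samples. Confidence bands come from a bootstrap of the reference sample
(200 replicates by default; the pipeline uses 50 for speed), ±1.96
bootstrap SD so the band always contains the estimate.

## Niche overlap

Pianka's O is the cosine similarity of two diet vectors over the shared
group ordering — invariant to positive rescaling, so %FO-based
"presence proportions" (the default) and %N-based vectors are both valid
inputs. Significance uses the RA2 randomization null: every non-zero
entry of *both* vectors is redrawn from U(0,1) each iteration while zero
states stay zero (prey groups absent from a diet are treated as
unavailable, niche breadth is relaxed). Groups empty in both diets are
dropped first; retained zeros in both vectors contribute nothing. The
p-value is upper-tail — is the observed overlap larger than chance? — with
the add-one estimator (1 + #{O_null ≥ O_obs})/(1 + iterations), so it is
never exactly zero; a two-tailed option exists. 1000 iterations by
default.

## Isotopic niche

δ¹³C is lipid-normalized when C:N strictly exceeds 3.5 using the aquatic
correction δ¹³C′ = δ¹³C − 3.32 + 0.99·C:N. The standard ellipse is the
Mahalanobis-radius-1 contour of the fitted bivariate normal and contains
1 − e^(−1/2) ≈ 39.35% of the data in large samples — the "≈40%" ellipse.
SEA = π√det(Σ) with the unbiased (n−1) sample covariance, the convention
of isotopic-niche practice, and SEA_C = SEA·(n−1)/(n−2); strata with
n < 3 are skipped with a warning since SEA_C is undefined there. The
Bayesian SEA_B uses a conjugate Normal–Inverse-Wishart model with a vague
prior (mean precision 10⁻³, IW degrees of freedom 3 = dimension + 1,
scale 10⁻³·I) and 10,000 posterior draws by default; each covariance draw
maps to an SEA value.

Ellipse overlap is integrated on a 500×500 grid over the joint bounding
box (deterministic; resolution configurable) with a Monte-Carlo
cross-check method, the intersection clamped to min(area A, area B), and
reported as directional percentages of each ellipse's analytic area.
Overlap defaults to the SEA_C scale (small-sample consistent); the SEA
scale sits behind a flag.

## Additive models

Each smooth is a cubic B-spline of basis dimension 4 on the covariate's
range (no interior knots at k = 4), centered to sum to zero over the
training data, with the exact integrated-squared-second-derivative
penalty (Gauss–Legendre quadrature, exact for cubics). The penalty is
normalized to unit spectral norm so smoothing parameters are
dimensionless and fits are invariant to affine rescaling of covariates.
Within the centered block the penalty's null space is the linear trend:
λ→∞ collapses a smooth to a straight line (edf→1), λ→0 saturates the
centered basis (edf→3). Families: gaussian-identity; gaussian-log
(log-transformed response with Gaussian errors — a transformation, not a
log-link GLM); gamma-log via penalized IRLS. Family choice follows a
Shapiro–Wilk path at α = 0.05: raw normal → identity; log-normal → log;
otherwise gamma (positive response required, offending rows reported).

Smoothing parameters are chosen per term by coordinate-wise search of
GCV = n·D/(n − edf)² over a log-spaced grid, with a parsimony rule: among
candidates within 1% of the minimum GCV, the largest λ wins. Plain
argmin-GCV undersmooths when the profile is nearly flat (a known GCV
failure mode); the 1% rule makes linear signals come out linear while
leaving genuinely curved fits (edf ≈ 3) untouched. edf per term is the
trace of the influence map restricted to that term's block; AIC is
−2·loglik + 2(edf_total + 1) with the likelihood at the effective-df
dispersion estimate; D = 100·(1 − deviance/null deviance). The reported
per-smooth F statistics are approximate ratios (smooth contribution per
edf over dispersion) and should be read as descriptive. Stepwise
selection runs a forward then a backward pass; a move is accepted only if
AIC improves by more than 2, ties resolving toward fewer terms.
Collinearity screening (pairwise Pearson r and determinant-ratio GVIF,
flags at |r| ≥ 0.70 and GVIF ≥ 3) is reported separately and not enforced
silently.

## Synthetic-study generator

The generator emulates the *downstream* tables of the study — never raw
reads, chimeras, PCR bias, or survey design. Defaults define the study
conditions:

* 35 fish per species × area stratum across 3 sites per area; GSA07 fish
  are all juveniles (mirroring the observed size structure), other areas
  half juveniles; lengths uniform within per-stratum ranges.
* Prey counts are Dirichlet-multinomial over the 11 groups: stomach
  totals log-normal (median 60 prey, σ = 0.8) with 5% empty stomachs;
  concentrations make copepods dominate numerically everywhere while the
  krill groups (euphausiids, decapods, other malacostracans) are enriched
  southwards (area factors 0.25 / 1 / 5) and in adults (×1.6). Because
  krill unit weights are ~100× copepod weights, krill dominate %B
  strongly in the south — the configured latitudinal signal. Within each
  group the two common taxa are weighted differently per species, and
  six groups carry a rare, near-exclusive taxon per species so that
  inter-specific prey lists do not saturate and beta-diversity stays
  non-trivial.
* OTU tables are built from true per-fish diet presence with ~50k-read
  Poisson depths and Dirichlet read allocation, plus the three noise
  sources the filter cascade exists for: globally rare OTUs (dataset
  totals below the 0.005% threshold), per-sample mistag cells (1–4 reads,
  strictly below 0.01% of the sample by construction; shallow samples
  receive none), and predator OTUs at ~2% of reads in own-host samples.
  Ground-truth labels for every injected cell are retained for recovery
  tests.
* Isotopes are bivariate normal per (species, area) with lower δ¹⁵N in
  the north (7.2‰ vs 8.7‰ for anchovy), a +0.06‰/cm length effect
  centered within stratum, and C:N ~ N(3.4, 0.25²) so a realistic
  fraction of fish crosses the 3.5 lipid threshold.

One seed drives independent child streams per stage (metadata, gut, COI,
rbcL, isotopes), so identical configurations are byte-identical and
adding a stage never perturbs earlier draws.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: taxonomic misassignment, digestion-stage
detectability bias, spatial autocorrelation within sites, prey-size
spectra (unit weights are fixed per taxon), inter-annual variation, and
realistic richness saturation (the default prey list has ~28 taxa, so
pooled richness saturates and area richness contrasts are flat at the
default scale; the paper-scale contrast of 40–120 taxa needs a longer
prey list).

## Problem sizes and determinism

The default pipeline (6 strata × 35 fish) runs in seconds: RA2 with 1000
iterations, SEA_B with 10,000 draws, 50-replicate bootstrap bands, and
stepwise GAMs over three candidate smooths. The test suite uses smaller
sizes where a property does not need scale (e.g. 2000 posterior draws per
calibration replicate, 200 RA2 iterations inside pipeline tests). All
randomized stages take explicit seeds; `run_pipeline` derives per-stage
seeds from one master seed, and rerunning with the same configuration
reproduces every output byte-for-byte.

## Known limitations

* Pianka inputs from %FO are "presence proportions"; whether a given
  published table used presence or numeric proportions is often
  ambiguous, so both modes are supported and must be chosen explicitly.
* The gamma-log AIC uses the effective-df dispersion plug-in, adequate
  for model ranking within a family but not comparable across families.
* Grid-based ellipse overlap has O(resolution²) cost and ~0.05% area
  error at the default 500×500; Monte-Carlo agreement within 1% is
  verified in tests.
* The rbcL pathway reports occurrence only; no diatom biomass or
  abundance is inferred.
* `RunManifest` hashes the configuration, not input files, when running
  synthetically; file digests are only recorded for table-driven runs.
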