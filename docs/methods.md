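# Methods

`isoniche` quantifies the trophic structure of a fish community from
per-individual stable-isotope measurements (δ¹³C, δ¹⁵N), trawl-set
species compositions, and stomach contents. This note documents the
statistical models, the defaults and why they were chosen, the
synthetic-data model used for validation, and known limitations.

## Pre-processing

**Delta notation.** Isotope ratios are expressed as per-mil deviations
from the reference standard, δ = ((R_sample/R_standard) − 1) × 1000,
with R = ¹³C/¹²C or ¹⁵N/¹⁴N (standards: Pee Dee belemnite; atmospheric
N₂).

**Lipid normalization.** Lipids are depleted in ¹³C, so bulk-tissue
δ¹³C is corrected using the tissue C:N ratio as a lipid proxy:
δ¹³C_norm = δ¹³C − 3.32 + 0.99·C:N. The correction vanishes near
C:N ≈ 3.35 (lean marine fish muscle) and matters mainly for lipid-rich
planktivores. Because the correction is affine in C:N, applying it
twice would bias δ¹³C by another (0.99·C:N − 3.32); the pipeline
therefore flags normalized tables and refuses a second pass. The
correction is applied to every sample with a C:N value regardless of
species — it is near-zero where it is irrelevant. Samples without C:N
are flagged and excluded from ellipse fitting rather than guessed.

**Size classes.** Each species' observed length range is split into
three equal-width classes (small/medium/large), with membership at a
break going to the lower class. Published boundary tables can override
the computed thirds — the packaged override file carries the
boundaries in use for the seven Newfoundland/Labrador study species,
three of which deviate slightly from exact thirds of their printed
ranges (the override is authoritative in that case). Fish outside the
scheme's range are classified by extrapolation and logged.

## Standard ellipses

For each group (species × region, size-pooled or per size class) with
n ≥ 3 samples, the bivariate-normal niche is summarized by the sample
mean and covariance (denominator n − 1) of (δ¹³C_norm, δ¹⁵N). The
standard ellipse area is SEA = π·√det(Σ̂) — the area of the 1-SD
contour, identically π·a·b for semi-axes √λ₁, √λ₂ — and the
small-sample-corrected area is SEAc = SEA·(n − 1)/(n − 2). Groups with
n < 3 are excluded with a logged warning naming the group; a singular
covariance collapses the ellipse to a segment and is flagged rather
than silently producing zero overlap.

**Bayesian SEA (SEA_B).** The covariance posterior under the conjugate
Normal–Inverse-Wishart model with a vague mean prior (κ₀ → 0) is
InvWishart(ν₀ + n, Ψ₀ + S), with S the centered sum of squares. The
prior is ν₀ = 2 degrees of freedom and Ψ₀ = 10⁻³·I — weak enough that
at n ≥ 10 the data dominate (the posterior mean SEA at n = 10,000 on
identity-covariance data is within 2 % of π, a tested property). Each
draw contributes SEA_B = π√det(Σ). With n < 4 the posterior is
prior-dominated and a warning is emitted.

## Overlap geometry

Overlap is computed on polygonal approximations of the SEAc ellipses:
vertices at center + √c·(√λ₁ cosθ·v₁ + √λ₂ sinθ·v₂) on a uniform
angle grid, c = (n−1)/(n−2). At the default 360 vertices the polygon
area is within 0.1 % of SEAc; intersection and union (by
inclusion–exclusion) use exact polygon clipping (shapely), chosen over
Monte-Carlo integration for determinism. Percent overlap is
100·|A∩B|/|A∪B|.

Candidate pairs are all unordered pairs of groups belonging to
*different* species — size classes within one species are never
compared with each other. The proportion of overlaps is the fraction
of candidate pairs with positive intersection; the mean percent
overlap averages over **all** candidate pairs by default (zeros
included), with an `overlapping_only` switch, since either reading of
"a mean of these overlapping areas" is defensible; both are computed
and labeled. Overlap uses the maximum-likelihood SEAc ellipses (point
estimates), not per-posterior-draw polygons: the summaries of interest
are single per-region proportions and areas, and posterior-draw
overlap distributions are left as an extension.

## Community distance metrics

The community centroid is the **unweighted mean of the size-pooled
species ellipse centers** within a region — also when the analyzed
groups are size-separated, so that per-class distances are measured
against a common community anchor. Distance to centroid and distance
to nearest neighbour (DNN — the minimum distance from a group's center
to a center of a different species) are Euclidean in the biplot,
treating 1 ‰ of δ¹³C as equal to 1 ‰ of δ¹⁵N (an axis-standardization
switch — unit SD over species centers per axis — exists but is off by
default, matching common practice for biplot-space Layman metrics;
standardized distances cannot be combined with the individual-level
bootstrap, whose resampled centers would need per-replicate rescaling). Mean distances are reported with the
standard error SD/√(number of groups); DNN also with its sample SD
(packing evenness).

**Bootstrap intervals.** Percentile bootstrap (default B = 10,000,
seeded): each replicate resamples individuals with replacement within
every group, recomputes group centers, then the DNN mean and SD; the
2.5/97.5 percentiles form the interval. The resampling unit is the
individual fish (not posterior draws), the natural choice when raw
samples are available. B < 100 triggers an instability warning.
Because percentile intervals of a min-statistic need not contain the
point estimate, only lo ≤ hi is asserted structurally. Coverage of the
95 % interval for mean DNN, measured against the generator's true
centers at n = 30 per group and B = 2,000, is ≈ 97 % over 200
replicates (tested property).

`metrics_from_centroids` recomputes the same per-region metrics
directly from a table of species ellipse centers, for the case where
only published centroids (not raw samples) are available.

**ANCOVA.** Per species, δ¹⁵N (or δ¹³C_norm) is regressed on region
(categorical), length (continuous) and their interaction by OLS;
type-II F-tests (statsmodels `anova_lm`) are reported — the
sums-of-squares type is a deliberate choice where the convention was
open. Under a null with no length effect the length term rejects at
≈ 5 % (tested at α = 0.05 within 3–8 % over 1,000 simulations). A
single region degrades to a simple regression with a warning; a
constant response is flagged degenerate.

## Diversity and diet

Richness is the count of taxa with positive counts; the inverse
Simpson index is 1/Σpᵢ², the effective number of equally common taxa
(1 ≤ index ≤ richness; invariant to rescaling counts). Both are
computed per unit — trawl set, or individual stomach — and averaged
within region with sample (n − 1) SDs, appropriate for the small
numbers of sets involved. Fish-community diversity uses fish species
only; diet diversity includes invertebrate prey. Empty stomachs carry
no diet information and are excluded from per-stomach means (whether
published summaries included them is ambiguous; exclusion is this
package's documented default). Per-stomach diversity uses prey counts
by default, switchable to mass.

**IRI.** Within each predator grouping, for each prey group:
%N = percent by number, %B = percent by biomass, FO = fraction of
non-empty stomachs containing the group (a proportion in [0, 1], not a
percent). The default index is IRI = (%N + %B)/FO — the form as
printed in the source convention this package follows — with
`convention="product"` giving the conventional (%N + %B)·FO for
comparison. Note the quotient form *rewards rarity of occurrence*;
since IRI values are normalized to proportions within each grouping,
the FO scale (proportion vs percent) cancels in the proportions.
Zero total mass yields %B = 0 with a warning.

## Synthetic-data model

The generator exists so every downstream stage is testable without any
survey download; it emulates the survey's statistical structure, not
its actual measurements.

- **Isotope samples**: per species × region, lengths uniform on the
  species' observed range (the sampling aimed for an even size
  spread); (δ¹³C, δ¹⁵N) bivariate normal about μ + drift·(length −
  midpoint); C:N normal truncated above 2.5 so the lipid correction
  stays in its validated range. The ontogenetic shift is linear in
  length — the simplest form consistent with monotone size trends.
- **Trawl sets**: per-set species proportions Dirichlet(α), counts
  multinomial — a Dirichlet-multinomial in which the concentration
  vector is a single evenness knob.
- **Stomachs**: empty with probability p (default 0.24, matching 94 of
  397 stomachs empty in the motivating survey); otherwise
  1 + Poisson item counts, Dirichlet-multinomial taxa, exponential
  per-item masses.

The packaged `survey_community.yaml` scenario describes a 7-species ×
3-region community with the survey's design sizes (21 fish per species
per region, 9 for the two small planktivores; 22/3/4 trawl sets;
146/122/129 stomachs per region). The per-species means and
covariances are **plausible placeholders** (δ¹⁵N ≈ 11–16 ‰, δ¹³C ≈
−21.5…−17.5 ‰, within-group SDs ≈ 0.3–0.6 ‰) — the survey's
within-group moments were never published — arranged so that the
region of highest diversity has the widest niche spread and the
least-diverse region the tightest packing. Drift magnitudes give total
ontogenetic shifts of ≈ 1.4–3.5 ‰ across a species' length range,
matching the strong size trends such communities show (roughly one
trophic-level step of δ¹⁵N over ontogeny); most species drift toward
the community centroid, the top predator away from it, the small
planktivore not at all. The `drift_community` factory provides a
cleaner single-region variant (7 species, n = 21, 0.06 ‰/cm toward the
centroid) used for the pooling-bias and coverage properties.

Passing tests on these communities show the *estimators* behave
correctly under the assumed model (bivariate-normal niches, linear
drift, multinomial composition); they do not validate the model
against real fish, where niches can be skewed, multimodal, or
length-structured nonlinearly.

## Numerical choices and degenerate inputs

- Polygon vertices default to 360 (area error < 0.1 %; the
  circle-lens oracle error halves roughly with 4× vertices).
- Singular covariances: flagged; overlap involving a degenerate
  polygon is reported as 0 with a warning, never NaN.
- Boundary membership at a size-class break goes to the lower class.
- Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives per-stage seeds from the config seed via `SeedSequence`, so
  a run is byte-reproducible from config + seed.
- All CSV output uses 12 significant digits (round-trip ≤ 10⁻⁹
  relative error).

## Known limitations

- The ellipse model assumes bivariate normality per group; no
  kernel-density or convex-hull niche estimators are provided.
- Overlap summaries are point-estimate based; posterior uncertainty is
  available for areas (SEA_B) but not propagated to overlap.
- The ANCOVA assumes homoscedastic Gaussian errors; no mixed effects
  for set- or haul-level clustering.
- The synthetic generator has no spatial/bathymetric structure and no
  correlation between a fish's isotope values and its stomach
  contents.
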