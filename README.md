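# isoniche

Community isotopic-niche analysis for fish assemblages: standard
ellipses and their overlap, Layman community metrics, and diversity
indices — from per-fish stable-isotope tables, trawl-set compositions
and stomach contents to per-region summaries, as a tested, seeded,
reproducible pipeline.

## The problem

A consumer's position in the (δ¹³C, δ¹⁵N) biplot summarizes its carbon
source (benthic vs pelagic) and trophic level; the spread of a
population's points is its *isotopic niche*, a measurable correlate of
the trophic niche. For a community of species sampled across regions,
a handful of metrics describe trophic structure:

- **SEA / SEAc** — the standard ellipse area of a group's bivariate
  normal fit, SEA = π√det Σ̂ (the 1-SD contour, π·a·b), and its
  small-sample correction SEAc = SEA·(n−1)/(n−2). A Bayesian
  counterpart **SEA_B** draws Σ from its inverse-Wishart posterior.
- **Ellipse overlap** — for every pair of groups of different species,
  the intersection of their SEAc ellipses; summarized as the
  proportion of pairs that overlap and the mean percent overlap
  100·|A∩B|/|A∪B|.
- **Distance to centroid** — distance of each species' ellipse center
  to the community centroid (the unweighted mean of size-pooled
  species centers): trophic diversity.
- **DNN** — distance to the nearest center of a *different* species:
  mean measures species packing, SD measures packing evenness;
  uncertainty via an individual-level percentile bootstrap.
- **Inverse Simpson** 1/Σpᵢ² and richness per trawl set or stomach,
  averaged within region; prey importance via the **Index of Relative
  Importance** combining percent-by-number, percent-by-biomass and
  frequency of occurrence.

Analyses run both size-pooled and split into three equal-width length
classes per species, because ontogenetic diet shifts make the pooled
view overstate overlap between species.

A seeded synthetic-community generator (bivariate-normal niches with
length-dependent mean drift, Dirichlet-multinomial trawl sets and
stomachs) stands in for survey data, so the whole pipeline is testable
offline. See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import isoniche as iso

tables = iso.load_scenario().simulate(seed=1)   # packaged 7-species x 3-region survey
fish = iso.assign_size_class(tables["isotopes"])

bc = fish[fish["region"] == "Bonavista Corridor"]
fits = iso.fit_ellipses(bc, mode="pooled")
for f in fits[:3]:
    print(f"{f.group.species:18s} n={f.n:2d} SEAc={f.seac:.3f} permil^2 "
          f"center=({f.center[0]:.2f}, {f.center[1]:.2f})")

summary, pairs = iso.overlap_summary(fits)
print(f"overlap: {summary.n_overlapping}/{summary.n_pairs} pairs, "
      f"mean %-overlap {summary.mean_percent_overlap:.2f}")

centroid = iso.community_centroid(fits)
_, mean_cd, se_cd = iso.distances_to_centroid(fits, centroid)
_, mean_dnn, sd_dnn = iso.nearest_neighbour_stats(fits)
print(f"centroid=({centroid[0]:.2f}, {centroid[1]:.2f})  "
      f"mean CD={mean_cd:.2f} (SE {se_cd:.2f})  "
      f"mean DNN={mean_dnn:.2f} (SD {sd_dnn:.2f})")

ci = iso.bootstrap_dnn(bc, n_boot=2000, seed=1, group_cols=("species", "region"))
print("95%% bootstrap CI for mean DNN: [%.2f, %.2f]" % ci["ci_mean_dnn"])
```

prints

```
Atlantic Cod       n=21 SEAc=2.195 permil^2 center=(-18.98, 15.76)
Greenland Halibut  n=21 SEAc=1.180 permil^2 center=(-18.65, 15.00)
Thorny Skate       n=21 SEAc=1.208 permil^2 center=(-18.49, 13.88)
overlap: 4/21 pairs, mean %-overlap 0.86
centroid=(-19.48, 13.39)  mean CD=1.62 (SE 0.30)  mean DNN=0.94 (SD 0.24)
95% bootstrap CI for mean DNN: [0.77, 1.10]
```

Four of the 21 between-species ellipse pairs overlap in this most
diverse region, and species sit on average 1.6 ‰ from the community
centroid with nearest neighbours ~0.9 ‰ apart — a widely spread, loosely
packed community. (Note the lipid correction: the Greenland halibut
center's δ¹³C is ~0.8 ‰ higher than its raw values because of its high
C:N.)

The same stages are available as a CLI:

```sh
isoniche simulate --seed 1 --out-dir sim
isoniche overlap sim/isotopes.csv --mode size_separated --out overlaps.csv
isoniche metrics sim/isotopes.csv --seed 1 --out metrics.csv
isoniche run-all --seed 1 --out-dir results_full
```

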