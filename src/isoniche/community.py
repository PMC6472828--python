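"""Layman-style community metrics in isotope biplot space.

The community centroid is the unweighted mean of the size-pooled species
ellipse centers within a region. Distance-to-centroid measures trophic
diversity (spread of niches); distance to nearest neighbour (DNN) — the
shortest distance from a group's center to the center of a *different*
species — measures species packing, and its standard deviation packing
evenness. Uncertainty for the DNN statistics comes from a percentile
bootstrap that resamples individuals within every group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .ellipses import EllipseFit, GroupKey

logger = logging.getLogger(__name__)


def community_centroid(pooled_fits: Sequence[EllipseFit]) -> np.ndarray:
    """Unweighted mean of species ellipse centers (sizes pooled)."""
    if len(pooled_fits) < 2:
        raise ValueError("community centroid needs at least 2 species")
    species = [f.group.species for f in pooled_fits]
    if len(set(species)) != len(species):
        raise ValueError("duplicate species among pooled fits")
    return np.mean([f.center for f in pooled_fits], axis=0)


def distances_to_centroid(
    fits: Sequence[EllipseFit], centroid: np.ndarray
) -> tuple[dict[GroupKey, float], float, float]:
    """Euclidean biplot distance from each group center to the community
    centroid; returns the per-group map, their mean, and the standard
    error of the mean (SD / sqrt(number of groups))."""
    d = {f.group: float(np.linalg.norm(f.center - centroid)) for f in fits}
    vals = np.array(list(d.values()))
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return d, mean, se


def nearest_neighbour_stats(
    fits: Sequence[EllipseFit],
) -> tuple[dict[GroupKey, float], float, float]:
    """DNN per group (minimum distance to a center of a different
    species), with mean and sample SD over groups."""
    if len({f.group.species for f in fits}) < 2:
        raise ValueError("DNN needs groups from at least 2 species")
    centers = np.array([f.center for f in fits])
    species = np.array([f.group.species for f in fits])
    diff = centers[:, None, :] - centers[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    same = species[:, None] == species[None, :]
    dist[same] = np.inf
    dnn_vals = dist.min(axis=1)
    dnn = {f.group: float(v) for f, v in zip(fits, dnn_vals)}
    mean = float(dnn_vals.mean())
    sd = float(dnn_vals.std(ddof=1)) if dnn_vals.size > 1 else 0.0
    return dnn, mean, sd


def _dnn_mean_sd_vectorized(
    centers: np.ndarray, species_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """mean/SD of DNN for a (B, G, 2) stack of bootstrap centers."""
    diff = centers[:, :, None, :] - centers[:, None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=3))  # (B, G, G)
    same = species_idx[:, None] == species_idx[None, :]
    dist[:, same] = np.inf
    dnn = dist.min(axis=2)  # (B, G)
    return dnn.mean(axis=1), dnn.std(axis=1, ddof=1)


def bootstrap_dnn(
    samples: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int | None = None,
    group_cols: Sequence[str] = ("species", "region", "size_class"),
    d13c_col: str = "d13c_norm",
    alpha: float = 0.05,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap intervals for mean and SD of DNN.

    Each replicate resamples individuals with replacement within every
    group, recomputes the group centers and the DNN statistics. Returns
    ``{"ci_mean_dnn": (lo, hi), "ci_sd_dnn": (lo, hi)}`` at the
    (1 - alpha) level.
    """
    if n_boot < 100:
        logger.warning("n_boot=%d < 100; percentile intervals will be unstable", n_boot)
    rng = np.random.default_rng(seed)
    groups, species = [], []
    for keys, sub in samples.groupby(list(group_cols), sort=False):
        xy = sub[[d13c_col, "d15n"]].to_numpy(float)
        xy = xy[~np.isnan(xy).any(axis=1)]
        if len(xy) < 3:
            raise ValueError(f"group {keys} has n={len(xy)} < 3; cannot bootstrap")
        groups.append(xy)
        species.append(keys[0] if isinstance(keys, tuple) else keys)
    sp_idx = pd.factorize(np.asarray(species))[0]
    if len(np.unique(sp_idx)) < 2:
        raise ValueError("bootstrap needs at least 2 species")
    centers = np.empty((n_boot, len(groups), 2))
    for g, xy in enumerate(groups):
        idx = rng.integers(0, len(xy), size=(n_boot, len(xy)))
        centers[:, g, :] = xy[idx].mean(axis=1)
    means, sds = _dnn_mean_sd_vectorized(centers, sp_idx)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ci_mean = tuple(np.percentile(means, [lo, hi]))
    ci_sd = tuple(np.percentile(sds, [lo, hi]))
    return {"ci_mean_dnn": ci_mean, "ci_sd_dnn": ci_sd}


@dataclass
class CommunityMetrics:
    """Distance metrics for one region (one size mode)."""

    region: str
    size_mode: str
    centroid: tuple[float, float]
    centroid_distances: dict[GroupKey, float]
    mean_cd: float
    se_cd: float
    dnn: dict[GroupKey, float]
    mean_dnn: float
    sd_dnn: float
    ci_mean_dnn: tuple[float, float] | None = None
    ci_sd_dnn: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("mean_distance_to_centroid", self.mean_cd, self.se_cd, None, None),
            ("mean_dnn", self.mean_dnn, None,
             *(self.ci_mean_dnn or (None, None))),
            ("sd_dnn", self.sd_dnn, None, *(self.ci_sd_dnn or (None, None))),
        ]
        return pd.DataFrame(
            [
                {"region": self.region, "size_mode": self.size_mode,
                 "metric": m, "estimate": est, "se": se,
                 "ci_low": lo, "ci_high": hi}
                for m, est, se, lo, hi in rows
            ]
        )


def _standardized_copies(
    fits: Sequence[EllipseFit], pooled_fits: Sequence[EllipseFit]
) -> tuple[list[EllipseFit], list[EllipseFit]]:
    """Rescale centers so each biplot axis has unit SD over the pooled
    species centers (optional alternative to raw per-mil distances)."""
    import dataclasses
    scale = np.std([f.center for f in pooled_fits], axis=0, ddof=1)
    scale[scale == 0] = 1.0
    rescale = lambda fs: [
        dataclasses.replace(f, center=f.center / scale) for f in fs
    ]
    return rescale(list(fits)), rescale(list(pooled_fits))


def region_metrics(
    fits: Sequence[EllipseFit],
    pooled_fits: Sequence[EllipseFit],
    region: str,
    size_mode: str,
    samples: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
    d13c_col: str = "d13c_norm",
    standardize: bool = False,
) -> CommunityMetrics:
    """Assemble the distance metrics for one region.

    The centroid always comes from the size-pooled fits, even when the
    analyzed ``fits`` are size-separated. If ``samples`` is given, DNN
    bootstrap intervals are computed on it. ``standardize=True``
    rescales the axes to unit center SD before measuring distances
    (default off: 1 per mil of d13C counts the same as 1 per mil of
    d15N, plain biplot-space distance).
    """
    fits, pooled_fits = list(fits), list(pooled_fits)
    if standardize:
        if samples is not None:
            raise ValueError("bootstrap is not supported with standardized axes")
        fits, pooled_fits = _standardized_copies(fits, pooled_fits)
    centroid = community_centroid(pooled_fits)
    cd, mean_cd, se_cd = distances_to_centroid(fits, centroid)
    dnn, mean_dnn, sd_dnn = nearest_neighbour_stats(fits)
    ci_mean = ci_sd = None
    if samples is not None:
        group_cols = ("species", "region") if size_mode == "pooled" else (
            "species", "region", "size_class")
        # bootstrap only the groups that supported an ellipse fit;
        # under-sized groups were already excluded (and logged) there
        sizes = samples.groupby(list(group_cols))[d13c_col].count()
        keep = samples.set_index(list(group_cols)).index.map(sizes) >= 3
        if not keep.all():
            logger.warning(
                "excluding %d sample(s) in groups with n < 3 from the DNN "
                "bootstrap (%s, %s)", int((~keep).sum()), region, size_mode,
            )
        cis = bootstrap_dnn(
            samples[np.asarray(keep)], n_boot=n_boot, seed=seed,
            group_cols=group_cols, d13c_col=d13c_col,
        )
        ci_mean, ci_sd = cis["ci_mean_dnn"], cis["ci_sd_dnn"]
    return CommunityMetrics(
        region, size_mode, tuple(centroid), cd, mean_cd, se_cd,
        dnn, mean_dnn, sd_dnn, ci_mean, ci_sd,
    )


def metrics_from_centroids(centroids: pd.DataFrame) -> pd.DataFrame:
    """Recompute per-region distance metrics from an ellipse-centroid table.

    ``centroids`` needs columns region, species, mu_c, mu_n (one row per
    size-pooled species ellipse). Returns one row per region with the
    community centroid, mean distance to centroid (with SE) and DNN
    mean/SD — the path used when ellipse centers are supplied directly
    rather than refitted from raw samples.
    """
    rows = []
    for region, sub in centroids.groupby("region", sort=False):
        fits = [
            EllipseFit(
                GroupKey(r.species, str(region), "pooled"), 3,
                np.array([r.mu_c, r.mu_n]), np.eye(2), np.pi, np.pi * 2,
            )
            for r in sub.itertuples(index=False)
        ]
        centroid = community_centroid(fits)
        _, mean_cd, se_cd = distances_to_centroid(fits, centroid)
        _, mean_dnn, sd_dnn = nearest_neighbour_stats(fits)
        rows.append(
            {"region": region, "centroid_c": centroid[0], "centroid_n": centroid[1],
             "mean_cd": mean_cd, "se_cd": se_cd,
             "mean_dnn": mean_dnn, "sd_dnn": sd_dnn}
        )
    return pd.DataFrame(rows)


@dataclass
class ModelSummary:
    """ANCOVA of an isotope response on region (categorical) x length."""

    species: str
    response: str
    params: pd.Series
    anova: pd.DataFrame | None
    degenerate: bool = False

    def p_value(self, term: str) -> float:
        if self.anova is None:
            raise ValueError("no ANOVA table for a degenerate/single-region fit")
        return float(self.anova.loc[term, "PR(>F)"])


def fit_region_length_model(
    samples: pd.DataFrame,
    response: Literal["d15n", "d13c_norm"] = "d15n",
    species: str = "",
) -> ModelSummary:
    """OLS of an isotope value on region, length and their interaction,
    with type-II F tests for the main effects (ANCOVA).

    With a single region the model reduces to a simple regression on
    length (warned); a constant response yields a degenerate fit flag.
    """
    df = samples.rename(columns={response: "y", "length_cm": "length"}).dropna(
        subset=["y", "length"]
    )
    n_regions = df["region"].nunique()
    if n_regions < 2:
        logger.warning(
            "single region for %s; region*length ANCOVA reduces to a "
            "simple regression on length", species or "sample",
        )
        formula = "y ~ length"
    else:
        formula = "y ~ C(region) * length"
    if np.ptp(df["y"].to_numpy()) == 0:
        logger.warning("constant response for %s; degenerate fit", species or "sample")
        fit = smf.ols("y ~ 1", data=df).fit()
        return ModelSummary(species, response, fit.params, None, degenerate=True)
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    # expose the length main effect under a stable name
    anova = anova.rename(index={"length": "length", "C(region)": "region",
                                "C(region):length": "region:length"})
    return ModelSummary(species, response, fit.params, anova)
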