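"""Bivariate-normal isotopic niche ellipses and their pairwise overlap.

A group's core isotopic niche is summarized by the standard ellipse of
its (d13C, d15N) samples: the 1-SD contour of the fitted bivariate
normal, with area SEA = pi * sqrt(det(cov)) and small-sample-corrected
area SEAc = SEA * (n-1)/(n-2). A Bayesian counterpart (SEA_B) draws the
covariance from its conjugate inverse-Wishart posterior under a vague
prior. Overlap statistics are computed on polygonal approximations of
the SEAc ellipses.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)


class GroupKey(NamedTuple):
    """Identifies one analysis group: a species within a region, either
    size-pooled or one of its three size classes."""

    species: str
    region: str
    size_class: str = "pooled"


@dataclass
class EllipseFit:
    """Maximum-likelihood bivariate-normal fit for one group."""

    group: GroupKey
    n: int
    center: np.ndarray  # (d13C, d15N) mean, per mil
    cov: np.ndarray     # 2x2 sample covariance, per mil^2
    sea: float          # standard ellipse area, per mil^2
    seac: float         # small-sample-corrected area
    posterior_sea: np.ndarray | None = field(default=None, repr=False)

    @property
    def degenerate(self) -> bool:
        return bool(np.linalg.eigvalsh(self.cov).min() <= 1e-12)


def standard_ellipse_area(cov: np.ndarray) -> float:
    """Area of the 1-SD ellipse of a bivariate normal: pi * sqrt(det cov),
    identically pi*a*b for semi-axes a, b = sqrt(eigenvalues)."""
    det = float(np.linalg.det(cov))
    return float(np.pi * np.sqrt(max(det, 0.0)))


def fit_group_ellipse(
    d13c: Sequence[float], d15n: Sequence[float], group: GroupKey
) -> EllipseFit:
    """Fit the standard ellipse to one group's isotope values.

    Requires n >= 3 so the sample covariance and the (n-1)/(n-2)
    correction are defined.
    """
    x = np.column_stack([np.asarray(d13c, float), np.asarray(d15n, float)])
    x = x[~np.isnan(x).any(axis=1)]
    n = len(x)
    if n < 3:
        raise ValueError(f"group {group} has n={n} < 3; cannot fit an ellipse")
    center = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    sea = standard_ellipse_area(cov)
    seac = sea * (n - 1) / (n - 2)
    return EllipseFit(group, n, center, cov, sea, seac)


def fit_ellipses(
    samples: pd.DataFrame,
    mode: Literal["pooled", "size_separated"] = "pooled",
    d13c_col: str = "d13c_norm",
) -> list[EllipseFit]:
    """Fit one ellipse per species x region group (x size class when
    ``mode="size_separated"``). Groups with fewer than three usable
    samples are excluded with a warning naming the group."""
    keys = ["species", "region"]
    if mode == "size_separated":
        keys.append("size_class")
    fits = []
    for gkeys, sub in samples.groupby(keys, sort=False):
        if mode == "pooled":
            group = GroupKey(gkeys[0], gkeys[1], "pooled")
        else:
            group = GroupKey(*gkeys)
        try:
            fits.append(fit_group_ellipse(sub[d13c_col], sub["d15n"], group))
        except ValueError:
            logger.warning("excluding %s: fewer than 3 samples", (group,))
    return fits


def sample_posterior_sea(
    fit: EllipseFit,
    n_draws: int = 2000,
    seed: int | None = None,
    prior_df: float = 2.0,
    prior_scale: float = 1e-3,
) -> np.ndarray:
    """Draw the Bayesian standard ellipse area SEA_B.

    The covariance posterior under the conjugate Normal-Inverse-Wishart
    model with a vague mean prior is InvWishart(prior_df + n,
    prior_scale*I + S), where S is the centered sum of squares; each
    draw contributes pi * sqrt(det Sigma). At moderate n the vague prior
    (df 2, scale 1e-3) is overwhelmed by the data.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if fit.n < 4:
        logger.warning(
            "group %s has n=%d; the SEA_B posterior is prior-dominated",
            fit.group, fit.n,
        )
    rng = np.random.default_rng(seed)
    scatter = fit.cov * (fit.n - 1)
    post_df = prior_df + fit.n
    post_scale = prior_scale * np.eye(2) + scatter
    draws = stats.invwishart.rvs(
        df=post_df, scale=post_scale, size=n_draws, random_state=rng
    )
    draws = draws.reshape(n_draws, 2, 2)
    det = draws[:, 0, 0] * draws[:, 1, 1] - draws[:, 0, 1] * draws[:, 1, 0]
    return np.pi * np.sqrt(det)


def ellipse_polygon(fit: EllipseFit, n_vertices: int = 360) -> np.ndarray:
    """Vertices of the SEAc ellipse, counter-clockwise.

    Points are center + sqrt(c) * (sqrt(l1) cos(t) v1 + sqrt(l2) sin(t) v2)
    on a uniform angle grid, with (l, v) the covariance eigenpairs and
    c = (n-1)/(n-2), so the enclosed area converges to SEAc. A zero
    eigenvalue collapses the polygon to a segment, which is flagged.
    """
    lam, vec = np.linalg.eigh(fit.cov)
    lam = np.clip(lam, 0.0, None)
    if lam.min() <= 1e-12:
        logger.warning(
            "group %s has a (near-)singular covariance; its ellipse "
            "degenerates to a segment", fit.group,
        )
    c = (fit.n - 1) / (fit.n - 2)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    pts = (
        fit.center
        + np.sqrt(c)
        * (np.sqrt(lam[1]) * np.cos(theta)[:, None] * vec[:, 1]
           + np.sqrt(lam[0]) * np.sin(theta)[:, None] * vec[:, 0])
    )
    # enforce counter-clockwise orientation (shoelace sign)
    area2 = np.sum(pts[:, 0] * np.roll(pts[:, 1], -1) - np.roll(pts[:, 0], -1) * pts[:, 1])
    if area2 < 0:
        pts = pts[::-1]
    return pts


@dataclass(frozen=True)
class OverlapResult:
    pair: tuple[GroupKey, GroupKey]
    intersection_area: float
    union_area: float
    percent_overlap: float  # 100 * intersection / union
    overlaps: bool


def ellipse_overlap(
    a: EllipseFit, b: EllipseFit, n_vertices: int = 360
) -> OverlapResult:
    """Intersection/union of two SEAc ellipse polygons.

    percent_overlap is the overlapping area as a percentage of the total
    area jointly covered by the two ellipses.
    """
    pa, pb = Polygon(ellipse_polygon(a, n_vertices)), Polygon(ellipse_polygon(b, n_vertices))
    if not (pa.is_valid and pb.is_valid) or pa.area == 0 or pb.area == 0:
        logger.warning(
            "degenerate ellipse in pair (%s, %s); overlap reported as 0",
            a.group, b.group,
        )
        inter = 0.0
        union = pa.area + pb.area
    else:
        inter = pa.intersection(pb).area
        union = pa.area + pb.area - inter
    pct = 100.0 * inter / union if union > 0 else 0.0
    return OverlapResult((a.group, b.group), inter, union, pct, inter > 0)


@dataclass(frozen=True)
class OverlapSummary:
    n_pairs: int
    n_overlapping: int
    proportion_overlapping: float
    mean_percent_overlap: float
    se_percent_overlap: float


def candidate_pairs(fits: Sequence[EllipseFit]) -> list[tuple[EllipseFit, EllipseFit]]:
    """All unordered pairs of groups belonging to different species;
    size groups within one species are never compared with each other."""
    return [
        (a, b)
        for a, b in itertools.combinations(fits, 2)
        if a.group.species != b.group.species
    ]


def overlap_summary(
    fits: Sequence[EllipseFit],
    n_vertices: int = 360,
    overlapping_only: bool = False,
) -> tuple[OverlapSummary, pd.DataFrame]:
    """Overlap statistics over all between-species group pairs.

    Returns the summary (proportion of overlapping pairs, mean percent
    overlap with its standard error) and the full pair table. The mean
    percent overlap averages over every candidate pair by default;
    ``overlapping_only=True`` restricts it to pairs that do overlap.
    """
    species = {f.group.species for f in fits}
    if len(species) < 2:
        raise ValueError("overlap summary needs groups from at least 2 species")
    pairs = candidate_pairs(fits)
    results = [ellipse_overlap(a, b, n_vertices) for a, b in pairs]
    pcts = np.array([r.percent_overlap for r in results])
    n_over = int(sum(r.overlaps for r in results))
    basis = pcts[pcts > 0] if overlapping_only else pcts
    if basis.size:
        mean_pct = float(basis.mean())
        se_pct = float(basis.std(ddof=1) / np.sqrt(basis.size)) if basis.size > 1 else 0.0
    else:
        mean_pct, se_pct = 0.0, 0.0
    table = pd.DataFrame(
        {
            "species_a": [r.pair[0].species for r in results],
            "region_a": [r.pair[0].region for r in results],
            "size_class_a": [r.pair[0].size_class for r in results],
            "species_b": [r.pair[1].species for r in results],
            "region_b": [r.pair[1].region for r in results],
            "size_class_b": [r.pair[1].size_class for r in results],
            "intersection_area": [r.intersection_area for r in results],
            "union_area": [r.union_area for r in results],
            "percent_overlap": [r.percent_overlap for r in results],
            "overlaps": [r.overlaps for r in results],
        }
    )
    summary = OverlapSummary(
        len(results), n_over,
        n_over / len(results) if results else 0.0,
        mean_pct, se_pct,
    )
    return summary, table


def fits_to_frame(fits: Iterable[EllipseFit]) -> pd.DataFrame:
    """Tabulate fits for CSV export."""
    fits = list(fits)
    return pd.DataFrame(
        {
            "species": [f.group.species for f in fits],
            "region": [f.group.region for f in fits],
            "size_class": [f.group.size_class for f in fits],
            "n": [f.n for f in fits],
            "mu_c": [f.center[0] for f in fits],
            "mu_n": [f.center[1] for f in fits],
            "cov_cc": [f.cov[0, 0] for f in fits],
            "cov_cn": [f.cov[0, 1] for f in fits],
            "cov_nn": [f.cov[1, 1] for f in fits],
            "sea": [f.sea for f in fits],
            "seac": [f.seac for f in fits],
        }
    )
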