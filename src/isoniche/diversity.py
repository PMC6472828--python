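"""Richness, inverse Simpson diversity and diet composition summaries.

Units of observation are trawl sets (fish-community diversity) and
individual stomachs (diet diversity); indices are computed per unit and
averaged within region. Prey importance across predator groupings is
summarized with the Index of Relative Importance (IRI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def inverse_simpson(counts: Mapping[str, float]) -> float:
    """Inverse Simpson index 1 / sum(p_i^2): the effective number of
    equally common species. Equals 1 for a monoculture and is bounded
    above by richness."""
    vals = np.asarray([c for c in counts.values() if c > 0], dtype=float)
    total = vals.sum()
    if total <= 0:
        raise ValueError("inverse Simpson undefined for all-zero counts")
    p = vals / total
    return float(1.0 / np.sum(p * p))


def richness(counts: Mapping[str, float]) -> int:
    """Number of taxa with a positive count."""
    return int(sum(1 for c in counts.values() if c > 0))


@dataclass(frozen=True)
class DiversitySummary:
    region: str
    n_units: int
    mean_richness: float
    sd_richness: float
    mean_inv_simpson: float
    sd_inv_simpson: float


def _summarize(region: str, rich: Sequence[int], invs: Sequence[float]) -> DiversitySummary:
    r = np.asarray(rich, dtype=float)
    s = np.asarray(invs, dtype=float)
    # sample (n-1) SD; a single unit gives SD 0 rather than NaN
    sd = lambda x: float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return DiversitySummary(
        region, int(r.size), float(r.mean()), sd(r), float(s.mean()), sd(s)
    )


def regional_diversity(sets: pd.DataFrame) -> list[DiversitySummary]:
    """Per-region mean and SD of per-set richness and inverse Simpson.

    ``sets`` is a long table with columns set_id, region, species, count;
    each survey set is one diversity unit.
    """
    out = []
    for region, sub in sets.groupby("region", sort=False):
        rich, invs = [], []
        for _, unit in sub.groupby("set_id", sort=False):
            counts = dict(zip(unit["species"], unit["count"]))
            if sum(counts.values()) <= 0:
                logger.warning("set with zero total count skipped in %s", region)
                continue
            rich.append(richness(counts))
            invs.append(inverse_simpson(counts))
        if not rich:
            logger.warning("region %s has no usable sets; omitted", region)
            continue
        out.append(_summarize(str(region), rich, invs))
    return out


def stomach_diversity(
    stomachs: pd.DataFrame, basis: Literal["count", "mass"] = "count"
) -> list[DiversitySummary]:
    """Per-region diet diversity over non-empty stomachs.

    Each stomach is one unit; richness and inverse Simpson are computed
    on its prey counts (or masses with ``basis="mass"``). Empty stomachs
    carry no diet information and are excluded from the means.
    """
    col = "prey_count" if basis == "count" else "prey_mass_g"
    out = []
    for region, sub in stomachs.groupby("region", sort=False):
        rich, invs = [], []
        for _, unit in sub.groupby("stomach_id", sort=False):
            counts = dict(zip(unit["prey_taxon"], unit[col]))
            if sum(counts.values()) <= 0:
                continue  # empty stomach
            rich.append(richness(counts))
            invs.append(inverse_simpson(counts))
        if not rich:
            logger.warning("region %s has only empty stomachs; omitted", region)
            continue
        out.append(_summarize(str(region), rich, invs))
    return out


def compute_iri(
    stomachs: pd.DataFrame,
    groupby: Sequence[str] = ("predator_species", "region"),
    prey_groups: Mapping[str, str] | None = None,
    convention: Literal["quotient", "product"] = "quotient",
) -> pd.DataFrame:
    """Index of Relative Importance of prey groups per predator grouping.

    Within each predator grouping (default species x region), for each
    prey group g over the non-empty stomachs:

    - %N = 100 * (items of g) / (all items)
    - %B = 100 * (mass of g) / (total mass)
    - FO = fraction of non-empty stomachs containing g (a proportion)

    and IRI = (%N + %B) / FO, following the published form of the index;
    ``convention="product"`` gives the conventional (%N + %B) * FO
    instead. ``iri_proportion`` normalizes IRI to sum to 1 across prey
    groups within each grouping.
    """
    df = stomachs[stomachs["prey_count"] > 0].copy()
    if prey_groups is not None:
        unmapped = set(df["prey_taxon"]) - set(prey_groups)
        if unmapped:
            raise ValueError(f"prey taxa without a group mapping: {sorted(unmapped)}")
        df["prey_group"] = df["prey_taxon"].map(prey_groups)
    else:
        df["prey_group"] = df["prey_taxon"]

    rows = []
    for keys, sub in df.groupby(list(groupby), sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        n_stomachs = sub["stomach_id"].nunique()
        tot_n = sub["prey_count"].sum()
        tot_b = sub["prey_mass_g"].sum()
        if tot_b <= 0:
            logger.warning("zero total prey mass in grouping %s; %%B set to 0", keys)
        for group, g in sub.groupby("prey_group", sort=False):
            pct_n = 100.0 * g["prey_count"].sum() / tot_n
            pct_b = 100.0 * g["prey_mass_g"].sum() / tot_b if tot_b > 0 else 0.0
            fo = g["stomach_id"].nunique() / n_stomachs
            iri = (pct_n + pct_b) / fo if convention == "quotient" else (pct_n + pct_b) * fo
            rows.append(
                dict(zip(groupby, keys))
                | {"prey_group": group, "pct_n": pct_n, "pct_b": pct_b,
                   "fo": fo, "iri": iri}
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["iri_proportion"] = out.groupby(list(groupby))["iri"].transform(
        lambda s: s / s.sum()
    )
    return out
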