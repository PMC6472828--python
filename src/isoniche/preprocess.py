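"""Turn raw isotope measurements into analysis-ready samples.

Three steps live here: expressing isotope ratios in delta (per-mil)
notation, correcting bulk-tissue delta13C for lipid content via the C:N
ratio, and assigning each fish to an ontogenetic size class by splitting
its species' observed length range into three equal-width categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Lipid-normalization coefficients for white muscle tissue:
#: d13C_norm = d13C - 3.32 + 0.99 * C:N
LIPID_INTERCEPT = -3.32
LIPID_SLOPE = 0.99

SIZE_CLASSES = ("small", "medium", "large")


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Per-mil deviation of an isotope ratio from its reference standard.

    Parameters
    ----------
    r_sample
        Heavy/light isotope ratio of the sample (e.g. 13C/12C).
    r_standard
        Ratio of the reference material (Pee Dee belemnite for carbon,
        atmospheric N2 for nitrogen).

    Returns
    -------
    float
        ((r_sample / r_standard) - 1) * 1000, in per mil.
    """
    if r_sample <= 0 or r_standard <= 0:
        raise ValueError(
            f"isotope ratios must be positive, got sample={r_sample}, "
            f"standard={r_standard}"
        )
    return (r_sample / r_standard - 1.0) * 1000.0


def normalize_lipid_d13c(d13c_untreated: float, c_n: float) -> float:
    """Lipid-correct a bulk delta13C value using the tissue C:N ratio.

    The correction is affine in C:N and vanishes near C:N ~ 3.35, the
    value expected for lean marine fish muscle; it matters mainly for
    lipid-rich species.
    """
    if not np.isfinite(c_n) or c_n <= 0:
        raise ValueError(f"C:N ratio must be positive, got {c_n}")
    return d13c_untreated + LIPID_INTERCEPT + LIPID_SLOPE * c_n


@dataclass(frozen=True)
class SizeClassScheme:
    """Equal-width three-way split of a species' observed length range.

    ``lower_break`` and ``upper_break`` are the small/medium and
    medium/large boundaries; membership at a break goes to the lower
    class (small is closed on its upper break).
    """

    species: str
    min_len: float
    max_len: float
    lower_break: float
    upper_break: float

    def __post_init__(self) -> None:
        if not (self.min_len < self.lower_break < self.upper_break < self.max_len):
            raise ValueError(
                f"size scheme for {self.species!r} must satisfy "
                f"min < lower_break < upper_break < max "
                f"(got {self.min_len}, {self.lower_break}, "
                f"{self.upper_break}, {self.max_len})"
            )

    def classify(self, length: float) -> str:
        if length < self.min_len or length > self.max_len:
            logger.warning(
                "length %.2f cm outside observed range [%.2f, %.2f] for %s; "
                "classifying by extrapolation",
                length, self.min_len, self.max_len, self.species,
            )
        if length <= self.lower_break:
            return "small"
        if length <= self.upper_break:
            return "medium"
        return "large"


def build_size_scheme(species: str, lengths: Iterable[float]) -> SizeClassScheme:
    """Derive the equal-thirds size scheme from observed lengths.

    Breaks fall at min + (max-min)/3 and min + 2(max-min)/3. An explicit
    scheme (e.g. from :func:`load_size_overrides`) takes precedence over
    the computed one when both are available.
    """
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size < 2 or np.ptp(arr) == 0:
        raise ValueError(
            f"cannot build a size scheme for {species!r}: need at least two "
            "distinct lengths"
        )
    lo, hi = float(arr.min()), float(arr.max())
    third = (hi - lo) / 3.0
    return SizeClassScheme(species, lo, hi, lo + third, lo + 2.0 * third)


def load_size_overrides(path: str | None = None) -> dict[str, SizeClassScheme]:
    """Load explicit per-species size-class boundaries from CSV.

    The packaged default carries the published boundaries for the seven
    Newfoundland/Labrador study species; a user CSV with columns
    species, min_len, lower_break, upper_break, max_len overrides it.
    """
    if path is None:
        ref = resources.files("isoniche.data") / "size_class_overrides.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"species", "min_len", "lower_break", "upper_break", "max_len"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"override table missing columns: {sorted(missing)}")
    return {
        row.species: SizeClassScheme(
            row.species, row.min_len, row.max_len, row.lower_break, row.upper_break
        )
        for row in df.itertuples(index=False)
    }


def assign_size_class(
    df: pd.DataFrame,
    schemes: Mapping[str, SizeClassScheme] | None = None,
) -> pd.DataFrame:
    """Add a ``size_class`` column to an isotope table.

    Schemes are taken from ``schemes`` where a species is present,
    otherwise computed from that species' observed lengths in ``df``.
    Species whose lengths are all identical are left ``unassigned``.
    """
    out = df.copy()
    out["size_class"] = "unassigned"
    for species, sub in out.groupby("species"):
        scheme = schemes.get(species) if schemes else None
        if scheme is None:
            try:
                scheme = build_size_scheme(species, sub["length_cm"])
            except ValueError:
                logger.warning(
                    "species %s has a degenerate length range; size classes "
                    "left unassigned", species,
                )
                continue
        out.loc[sub.index, "size_class"] = [
            scheme.classify(v) for v in sub["length_cm"]
        ]
    return out


def normalize_table(df: pd.DataFrame, enabled: bool = True) -> pd.DataFrame:
    """Add the lipid-normalized ``d13c_norm`` column to an isotope table.

    The affine correction must be applied exactly once: the result is
    marked via the ``lipid_normalized`` column and a second call on an
    already-normalized table raises. Rows without a usable C:N value are
    flagged (``lipid_normalized`` False, ``d13c_norm`` NaN) and logged,
    not dropped. With ``enabled=False`` the column is a plain copy of
    ``d13c_raw``.
    """
    if "lipid_normalized" in df.columns and df["lipid_normalized"].any():
        raise ValueError(
            "table already lipid-normalized; the C:N correction is affine "
            "and must not be applied twice"
        )
    out = df.copy()
    if not enabled:
        out["d13c_norm"] = out["d13c_raw"]
        out["lipid_normalized"] = False
        return out
    cn = pd.to_numeric(out["c_n"], errors="coerce")
    ok = cn.notna() & (cn > 0)
    out["d13c_norm"] = np.where(
        ok, out["d13c_raw"] + LIPID_INTERCEPT + LIPID_SLOPE * cn, np.nan
    )
    out["lipid_normalized"] = ok
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning(
            "%d sample(s) lack a C:N ratio; lipid normalization skipped for them",
            n_bad,
        )
    return out
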