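"""Table I/O, configuration and the end-to-end pipeline.

All tables travel as long (tidy) CSV. The pipeline runs the stages in
their natural order — lipid normalization, size classes, per-group
ellipse fits, overlap summaries (pooled and size-separated), community
distance metrics with a DNN bootstrap, and diversity/IRI summaries —
and records a manifest so a run is reproducible from its config + seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import community, diversity, ellipses, preprocess

logger = logging.getLogger(__name__)

ISOTOPE_COLUMNS = ["species", "region", "length_cm", "d13c_raw", "d15n", "c_n"]
NUMERIC_ISOTOPE = ["length_cm", "d13c_raw", "d15n", "c_n"]


def read_isotope_table(path: str | Path) -> pd.DataFrame:
    """Read a per-fish isotope CSV, rejecting malformed numeric rows.

    Mandatory columns: species, region, length_cm, d13c_raw, d15n, c_n
    (c_n may be empty). Rows whose length, d13c_raw or d15n fail to
    parse are reported with their line number and skipped.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ISOTOPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    if df.empty:
        logger.warning("%s: header-only file, no samples", path)
    for col in NUMERIC_ISOTOPE:
        df[col] = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
    # a row is malformed if any required numeric failed to parse
    required_bad = df[["length_cm", "d13c_raw", "d15n"]].isna().any(axis=1)
    if required_bad.any():
        for i in df.index[required_bad]:
            logger.warning(
                "%s: line %d has unparseable numeric fields; row skipped",
                path, i + 2,  # header + 1-based
            )
        df = df[~required_bad]
    if "d13c_norm" in df.columns:
        df["d13c_norm"] = pd.to_numeric(
            df["d13c_norm"].replace("", np.nan), errors="coerce"
        )
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CSV at full float precision (lossless round-trip)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")


def default_prey_groups() -> dict[str, str]:
    """Packaged map from prey taxon to major prey group."""
    ref = resources.files("isoniche.data") / "prey_groups.csv"
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    return dict(zip(df["prey_taxon"], df["prey_group"]))


def read_prey_groups(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]], df[cols[1]]))


def read_workbook_table(
    path: str | Path,
    sheet: str | int = 0,
    aliases: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Ingest a supplementary XLSX sheet as an analysis table.

    ``aliases`` maps workbook column headers to this package's column
    names (e.g. ``{"d13C": "d13c_raw", "Length (cm)": "length_cm"}``),
    since supplementary workbooks rarely share a fixed layout. Requires
    openpyxl.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    if aliases:
        df = df.rename(columns=dict(aliases))
    return df


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs, loadable from YAML."""

    isotopes: str | None = None          # isotope CSV path
    trawl_sets: str | None = None        # set-composition CSV path
    stomachs: str | None = None          # stomach-content CSV path
    scenario: str | None = None          # simulate inputs instead of reading
    out_dir: str = "isoniche_out"
    seed: int = 0
    normalize: bool = True
    size_overrides: str | None = None    # CSV of explicit class boundaries
    use_packaged_overrides: bool = False
    n_vertices: int = 360
    overlapping_only: bool = False
    posterior_draws: int = 0          # >0 writes SEA_B draws per group
    n_boot: int = 10_000
    iri_convention: str = "quotient"
    prey_groups: str | None = None
    ancova: bool = True               # per-species region*length models

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write the result bundle under ``out_dir``.

    Identical config + seed produce byte-identical outputs. Returns the
    in-memory tables keyed by output name.
    """
    from .simulate import load_scenario

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}

    # --- inputs ---
    if config.scenario is not None or config.isotopes is None:
        scenario = load_scenario(
            None if config.scenario in (None, "packaged") else config.scenario
        )
        tables = scenario.simulate(config.seed)
        iso = tables["isotopes"]
        trawls, stomachs = tables["trawl_sets"], tables["stomachs"]
        if not config.normalize:
            iso = iso.drop(columns=["d13c_norm", "lipid_normalized"])
            iso = preprocess.normalize_table(iso, enabled=False)
    else:
        iso = read_isotope_table(config.isotopes)
        iso = preprocess.normalize_table(iso, enabled=config.normalize)
        trawls = pd.read_csv(config.trawl_sets) if config.trawl_sets else pd.DataFrame()
        stomachs = pd.read_csv(config.stomachs) if config.stomachs else pd.DataFrame()

    # --- size classes ---
    schemes = None
    if config.size_overrides:
        schemes = preprocess.load_size_overrides(config.size_overrides)
    elif config.use_packaged_overrides:
        schemes = preprocess.load_size_overrides()
    iso = preprocess.assign_size_class(iso, schemes)
    results["isotopes"] = iso
    write_table(iso, out / "isotopes.csv")

    # --- ellipse fits and overlaps, both modes, per region ---
    rng = np.random.SeedSequence(config.seed)
    boot_seeds = iter(int(s.generate_state(1)[0] % 2**31) for s in rng.spawn(64))
    fit_rows, overlap_tables, summary_rows, metric_frames = [], [], [], []
    posterior_rows = []
    for region, sub in iso.groupby("region", sort=False):
        pooled = ellipses.fit_ellipses(sub, mode="pooled")
        separated = ellipses.fit_ellipses(sub, mode="size_separated")
        fit_rows += [ellipses.fits_to_frame(pooled), ellipses.fits_to_frame(separated)]
        if config.posterior_draws > 0:
            for fit in pooled:
                draws = ellipses.sample_posterior_sea(
                    fit, config.posterior_draws, next(boot_seeds))
                posterior_rows.append(pd.DataFrame({
                    "species": fit.group.species, "region": fit.group.region,
                    "size_class": fit.group.size_class,
                    "draw_index": np.arange(len(draws)), "sea_b": draws,
                }))
        for mode, fits in (("pooled", pooled), ("size_separated", separated)):
            summ, table = ellipses.overlap_summary(
                fits, n_vertices=config.n_vertices,
                overlapping_only=config.overlapping_only,
            )
            table.insert(0, "size_mode", mode)
            table.insert(0, "region", region)
            overlap_tables.append(table)
            summary_rows.append(
                {"region": region, "size_mode": mode,
                 "n_pairs": summ.n_pairs, "n_overlapping": summ.n_overlapping,
                 "proportion_overlapping": summ.proportion_overlapping,
                 "mean_percent_overlap": summ.mean_percent_overlap,
                 "se_percent_overlap": summ.se_percent_overlap}
            )
            cm = community.region_metrics(
                fits, pooled, str(region), mode, samples=sub,
                n_boot=config.n_boot, seed=next(boot_seeds),
            )
            metric_frames.append(cm.to_frame())
    results["ellipse_fits"] = pd.concat(fit_rows, ignore_index=True)
    results["overlap_pairs"] = pd.concat(overlap_tables, ignore_index=True)
    results["overlap_summary"] = pd.DataFrame(summary_rows)
    results["community_metrics"] = pd.concat(metric_frames, ignore_index=True)
    if posterior_rows:
        results["posterior_sea"] = pd.concat(posterior_rows, ignore_index=True)
    if config.ancova:
        model_rows = []
        for species, sub in iso.groupby("species", sort=False):
            for response in ("d15n", "d13c_norm"):
                m = community.fit_region_length_model(sub, response, species)
                if m.anova is None:
                    continue
                for term in m.anova.index:
                    if term == "Residual":
                        continue
                    model_rows.append({
                        "species": species, "response": response, "term": term,
                        "F": m.anova.loc[term, "F"],
                        "p_value": m.anova.loc[term, "PR(>F)"],
                    })
        results["ancova"] = pd.DataFrame(model_rows)
    for name in results:
        if name != "isotopes":
            write_table(results[name], out / f"{name}.csv")

    # --- diversity and diet ---
    if not trawls.empty:
        results["set_diversity"] = pd.DataFrame(
            [asdict(s) for s in diversity.regional_diversity(trawls)]
        )
        write_table(results["set_diversity"], out / "set_diversity.csv")
    if not stomachs.empty:
        results["diet_diversity"] = pd.DataFrame(
            [asdict(s) for s in diversity.stomach_diversity(stomachs)]
        )
        groups = (read_prey_groups(config.prey_groups) if config.prey_groups
                  else default_prey_groups())
        results["iri"] = diversity.compute_iri(
            stomachs, prey_groups=groups,
            convention=config.iri_convention,  # type: ignore[arg-type]
        )
        write_table(results["diet_diversity"], out / "diet_diversity.csv")
        write_table(results["iri"], out / "iri.csv")

    manifest = {
        "isoniche_version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "outputs": sorted(results),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results
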