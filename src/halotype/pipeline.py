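"""Config-driven end-to-end analysis run.

Reproduces the full phenotyping sequence on either real input files or
a generated trial: spectra -> band masking -> 20 SRIs -> descriptive
statistics -> per-year split-plot ANOVA on grain yield -> STI table ->
Ward grouping with semantic labels -> SRI/trait correlation screen ->
stepwise index selection per treatment -> per-group best curve fits.

Every stage is an importable function; ``run_pipeline`` only chains
them, logs row counts, and writes delimited-text tables plus a JSON
manifest to the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import splitplot_anova
from .association import correlation_table
from .grid import DEFAULT_MASK_WINDOWS, apply_mask
from .grouping import cluster_and_label, linkage_to_newick
from .indices import ALL_INDICES, REGISTRY, VEGETATION_INDICES, WATER_INDICES, compute_all
from .io import KEY_COLS, YIELD_COL, read_spectra, read_yields, write_table
from .regression import best_group_fit, smlr
from .synth import SynthConfig, generate_trial
from .tolerance import STI_FEATURES, sti_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run configuration (JSON-serializable)."""

    spectra_path: str | None = None
    yields_path: str | None = None
    synth: SynthConfig | None = None
    seed: int = 0
    mask_windows: tuple = DEFAULT_MASK_WINDOWS
    indices: tuple = ALL_INDICES
    k_groups: int = 3
    alpha: float = 0.05
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10
    out_dir: str = "halotype_out"

    def __post_init__(self):
        has_files = self.spectra_path is not None and self.yields_path is not None
        if not has_files and self.synth is None:
            raise ValueError("config needs input files or a synth section")
        unknown = [n for n in self.indices if n not in REGISTRY]
        if unknown:
            raise ValueError(f"unknown index name(s): {unknown}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        synth = doc.pop("synth", None)
        if synth is not None:
            for key in ("group_sizes", "group_gyc_mean", "group_ysi_mean",
                        "ysi_bounds", "year_offsets", "trait_intercepts",
                        "trait_slopes", "salinity_trait_factors"):
                if key in synth:
                    synth[key] = tuple(synth[key])
            synth = SynthConfig(**synth)
        if "mask_windows" in doc:
            doc["mask_windows"] = tuple(tuple(w) for w in doc["mask_windows"])
        if "indices" in doc:
            doc["indices"] = tuple(doc["indices"])
        return cls(synth=synth, **doc)

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        return doc


def descriptive_stats(values: pd.DataFrame, value_col: str,
                      bin_width: float = 0.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Min/max/mean of genotype means per treatment x year, plus histogram.

    Histogram bins have fixed width and edges aligned to multiples of
    ``bin_width``; counts per treatment sum to the number of genotypes.
    """
    if values.empty:
        raise ValueError("empty value table")
    geno_means = (
        values.groupby(["treatment", "year", "genotype"], observed=True)[value_col]
        .mean()
        .reset_index()
    )
    stats = (
        geno_means.groupby(["treatment", "year"], observed=True)[value_col]
        .agg(["min", "max", "mean"])
        .reset_index()
    )
    two_year = geno_means.groupby(["treatment", "genotype"], observed=True)[value_col].mean()
    lo = np.floor(two_year.min() / bin_width) * bin_width
    hi = np.ceil(two_year.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    hists = []
    for treatment, sub in two_year.groupby(level="treatment"):
        counts, _ = np.histogram(sub.to_numpy(), bins=edges)
        for left, c in zip(edges[:-1], counts):
            hists.append((treatment, float(left), float(left + bin_width), int(c)))
    hist = pd.DataFrame(hists, columns=["treatment", "bin_lo", "bin_hi", "count"])
    return stats, hist


def _genotype_mean_sri(sri_values: pd.DataFrame, treatment: str) -> pd.DataFrame:
    """Across-year genotype means of every index from one treatment's spectra."""
    sub = sri_values[sri_values["treatment"] == treatment]
    index_cols = [c for c in sri_values.columns if c not in KEY_COLS]
    return sub.groupby("genotype")[index_cols].mean()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the report bundle as a dict.

    The bundle maps stage names to DataFrames (written as CSV under
    ``config.out_dir`` along with ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # --- inputs -----------------------------------------------------------
    if config.synth is not None:
        spectra, yields, planted = generate_trial(config.synth, config.seed)
        bundle["planted_groups"] = planted.to_frame()
        logger.info("stage synth: %d spectra, %d yield rows", len(spectra), len(yields))
    else:
        spectra = read_spectra(config.spectra_path)
        yields = read_yields(config.yields_path)
        logger.info("stage load: %d spectra, %d yield rows", len(spectra), len(yields))

    checksum = pd.util.hash_pandas_object(yields).sum()

    # --- spectra -> SRIs --------------------------------------------------
    masked_grid = apply_mask(spectra.grid, config.mask_windows)
    spectra = dataclasses.replace(
        spectra,
        grid=masked_grid,
        records=[dataclasses.replace(r, grid=masked_grid) for r in spectra.records],
    )
    sri_values = compute_all(spectra, indices=config.indices)
    bundle["sri_values"] = sri_values
    logger.info("stage sri: %d plots x %d indices", len(sri_values), len(config.indices))

    # --- descriptive statistics ------------------------------------------
    gy_stats, gy_hist = descriptive_stats(yields, YIELD_COL)
    bundle["gy_descriptive"] = gy_stats
    bundle["gy_histogram"] = gy_hist

    # --- per-year split-plot ANOVA on grain yield ------------------------
    anova_tables = []
    for year, sub in yields.groupby("year"):
        tab = splitplot_anova(sub, YIELD_COL)
        tab = tab.reset_index().assign(year=year)
        anova_tables.append(tab)
    bundle["anova_gy"] = pd.concat(anova_tables, ignore_index=True)
    logger.info("stage anova: %d per-year tables", len(anova_tables))

    # --- STIs and grouping ------------------------------------------------
    sti = sti_table(yields)
    bundle["sti_table"] = sti.reset_index()
    grouping = cluster_and_label(sti[list(STI_FEATURES)], k=config.k_groups)
    bundle["groups"] = grouping.labels.to_frame().reset_index()
    bundle["group_means"] = grouping.group_means.reset_index()
    bundle["dendrogram_newick"] = linkage_to_newick(
        grouping.linkage_matrix, sti.index
    )
    logger.info("stage grouping: %d groups", grouping.k)

    # --- correlation screen ----------------------------------------------
    corr_frames = []
    for treatment in ("control", "salinity"):
        sri_means = _genotype_mean_sri(sri_values, treatment)
        tab = correlation_table(sri_means, sti, alpha=config.alpha)
        corr_frames.append(tab.assign(spectra_treatment=treatment))
    bundle["correlations"] = pd.concat(corr_frames, ignore_index=True)

    # --- stepwise index selection ----------------------------------------
    smlr_rows = []
    fits = []
    for treatment in ("control", "salinity"):
        sri_means = _genotype_mean_sri(sri_values, treatment)
        for family, names in (("vegetation", VEGETATION_INDICES),
                              ("water", WATER_INDICES)):
            cols = [n for n in names if n in sri_means.columns]
            cand = sri_means[cols].dropna(axis=1)
            for dep in ("GYc", "GYs"):
                rep = smlr(cand, sti[dep], alpha_enter=config.alpha_enter,
                           alpha_remove=config.alpha_remove, dependent_name=dep)
                smlr_rows.append({
                    "spectra_treatment": treatment,
                    "family": family,
                    "dependent": dep,
                    "equation": rep.equation(),
                    "selected": ",".join(rep.selected),
                    "r_squared": rep.r_squared,
                    "rmse": rep.rmse,
                    "n": rep.n,
                })
                # per-group best L/Q fits for each selected index
                for name in rep.selected:
                    for grp, members in grouping.labels.groupby(grouping.labels):
                        idx = members.index
                        if len(idx) < 4:
                            continue
                        gf = best_group_fit(
                            cand.loc[idx, name], sti.loc[idx, dep],
                            group=str(grp), x_name=name, y_name=dep,
                        )
                        fits.append({
                            "spectra_treatment": treatment,
                            "group": gf.group, "sri": gf.x_name,
                            "dependent": gf.y_name, "form": gf.form,
                            "r_squared": gf.r_squared,
                            "significance": gf.significance,
                        })
    bundle["smlr"] = pd.DataFrame(smlr_rows)
    bundle["group_fits"] = pd.DataFrame(fits)
    logger.info("stage smlr: %d models, %d group fits", len(smlr_rows), len(fits))

    if pd.util.hash_pandas_object(yields).sum() != checksum:
        raise RuntimeError("pipeline stage mutated the input yield table")

    # --- write bundle -----------------------------------------------------
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            write_table(obj, out / f"{name}.csv")
    (out / "dendrogram.nwk").write_text(bundle["dendrogram_newick"] + "\n")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": _jsonable(config.to_dict()),
        "tables": sorted(k for k, v in bundle.items() if isinstance(v, pd.DataFrame)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
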