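"""End-to-end orchestration: records -> per-cell diversity -> congruence ->
spatially aware regression, plus the robustness sweep over cell filters.

The stages mirror the analysis workflow: filter barcode records, assign
sequences to equal-area grid cells, estimate per-species nucleotide
diversity per cell, average to per-cell genetic diversity (GD), rasterize
species richness from occurrence ranges, test GD-richness congruence with
the spatially corrected t-test, then model transformed GD against
environmental, geographic (region + spatial autocovariate residual) and
forced sampling factors with VIF screening and AIC-stepwise selection,
partition the explained variance hierarchically, and check model residuals
for leftover spatial autocorrelation with a permutation Moran test.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import barcode_io, diversity, regression, richness as richness_mod, spatial
from . import grid as gridmod
from .grid import GridSpec

log = logging.getLogger("macrodiv")

_RESERVED_ENV_COLS = {
    "cell_id", "ix", "iy", "centroid_lon", "centroid_lat", "x_m", "y_m", "region",
}


@dataclasses.dataclass
class AnalysisSettings:
    """Statistical settings shared by the pipeline stages."""

    marker: str = barcode_io.DEFAULT_MARKER
    min_length: int = barcode_io.MIN_UNGAPPED_LENGTH
    min_overlap: float = 0.5
    divisor: str = "used"
    min_sequences: int = 2
    min_species: int = 2
    min_coverage_pct: float = 0.0
    n_distance_classes: int = 13
    n_perm: int = 1000
    vif_threshold: float = 5.0
    autocov_radius_m: float = 200_000.0
    autocov_weighting: str = "inverse_distance"
    knn_k: int = 1
    seed: int = 0


@dataclasses.dataclass
class CongruenceResult:
    r: float
    modified_ttest: spatial.ModifiedTTestResult
    classification: pd.DataFrame  # cell_id + class label (2x2 median split)


@dataclasses.dataclass
class AnalysisResult:
    filter_report: barcode_io.FilterReport
    species_pi: pd.DataFrame
    cells: pd.DataFrame  # filtered per-cell table joined with environment
    bands: pd.DataFrame
    congruence: CongruenceResult | None
    full_model: regression.ModelResult | None
    selected_model: regression.ModelResult | None
    hier_part: regression.HierPartResult | None
    residual_moran: spatial.MoranResult | None
    vif_report: pd.DataFrame | None
    model_terms: list[str]
    n_isolated_cells: int = 0


def assemble_species_cell_alignments(
    records: list[barcode_io.SequenceRecord],
    alignments: dict[str, dict[str, str]] | None,
    spec: GridSpec,
) -> dict[tuple[str, str], list[str]]:
    """Group aligned sequences of each species by the grid cell of their
    collection point.

    When a species has an aligned FASTA, each record's aligned sequence is
    looked up by record id; records without an aligned counterpart fall
    back to their raw (gap-free) table sequence.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for rec in records:
        ixy = gridmod.cell_of(rec.lon, rec.lat, spec)
        cid = gridmod.cell_id(*ixy)
        seq = rec.sequence
        if alignments and rec.species in alignments:
            seq = alignments[rec.species].get(rec.record_id, seq)
        groups.setdefault((rec.species, cid), []).append(seq)
    return groups


def _transform_counts(x: np.ndarray) -> np.ndarray:
    return regression.standardize(np.log1p(np.asarray(x, dtype=float)))


def congruence(
    cells: pd.DataFrame,
    settings: AnalysisSettings,
    richness_col: str = "n_species_total",
) -> CongruenceResult:
    """GD-richness congruence: Pearson r, spatially corrected p, and the
    2x2 median-split classification used for bivariate mapping.

    Both metrics are log-transformed and standardized before correlation.
    Falls back to the genetically sampled species count when no range-based
    richness is available.
    """
    if richness_col not in cells.columns or cells[richness_col].isna().all():
        richness_col = "n_species_genetic"
    df = cells.dropna(subset=["gd", richness_col])
    if len(df) < 10:
        raise ValueError("need at least 10 cells with both diversity metrics")
    gd_t = regression.transform_response(df["gd"].to_numpy())
    sr_t = regression.transform_response(df[richness_col].to_numpy(dtype=float))
    coords = np.column_stack([df["x_m"], df["y_m"]])
    fx = spatial.SpatialField(df["cell_id"].to_numpy(), coords, gd_t)
    fy = spatial.SpatialField(df["cell_id"].to_numpy(), coords, sr_t)
    mtt = spatial.modified_ttest(fx, fy, n_classes=settings.n_distance_classes)
    gd_med = df["gd"].median()
    sr_med = df[richness_col].median()
    labels = np.where(
        df["gd"] >= gd_med,
        np.where(df[richness_col] >= sr_med, "high_gd_high_sr", "high_gd_low_sr"),
        np.where(df[richness_col] >= sr_med, "low_gd_high_sr", "low_gd_low_sr"),
    )
    classification = pd.DataFrame({"cell_id": df["cell_id"], "class": labels})
    return CongruenceResult(r=mtt.r, modified_ttest=mtt, classification=classification)


def build_cell_table(
    records: list[barcode_io.SequenceRecord],
    alignments: dict[str, dict[str, str]] | None,
    environment: pd.DataFrame,
    richness_map: dict[str, int] | None,
    settings: AnalysisSettings,
    spec: GridSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species-cell diversity and the unfiltered per-cell table."""
    groups = assemble_species_cell_alignments(records, alignments, spec)
    species_pi = diversity.species_cell_table(
        groups, min_overlap=settings.min_overlap, divisor=settings.divisor
    )
    cells = diversity.cell_genetic_diversity(species_pi, richness=richness_map)
    cells = cells.merge(environment, on="cell_id", how="inner")
    if "x_m" not in cells.columns:
        x, y = gridmod.cell_centroid(
            cells["ix"].to_numpy(), cells["iy"].to_numpy(), spec
        )
        cells["x_m"], cells["y_m"] = x, y
    return species_pi, cells


def model_genetic_diversity(
    cells: pd.DataFrame, settings: AnalysisSettings
) -> tuple[
    regression.ModelResult, regression.ModelResult, regression.HierPartResult,
    spatial.MoranResult, pd.DataFrame, list[str], int,
]:
    """Fit the determinants model on a filtered cell table.

    Builds the design (standardized environmental fields, categorical
    region, the environment-residualized spatial autocovariate "autocor",
    log-standardized forced sampling factors), screens environmental
    collinearity by VIF, runs AIC-stepwise selection with the sampling
    terms forced, partitions variance, and tests residual spatial
    autocorrelation.
    """
    env_cols = [
        c for c in cells.columns
        if c not in _RESERVED_ENV_COLS
        and c not in ("gd", "n_sequences", "n_species_genetic", "n_species_total",
                      "taxonomic_coverage")
        and pd.api.types.is_numeric_dtype(cells[c])
    ]
    df = cells.copy()
    df["z_gd"] = regression.transform_response(df["gd"].to_numpy())
    for c in env_cols:
        df[c] = regression.standardize(df[c].to_numpy(dtype=float))
    df["s_sequences"] = _transform_counts(df["n_sequences"].to_numpy())
    df["s_species"] = _transform_counts(df["n_species_genetic"].to_numpy())

    kept_env, vif_report = regression.vif_screen(
        df[env_cols], threshold=settings.vif_threshold
    ) if len(env_cols) > 1 else (env_cols, pd.DataFrame(columns=["dropped", "vif"]))

    coords = np.column_stack([df["x_m"], df["y_m"]])
    field = spatial.SpatialField(df["cell_id"].to_numpy(), coords, df["z_gd"].to_numpy())
    autocov = spatial.autocovariate(
        field, radius_m=settings.autocov_radius_m, weighting=settings.autocov_weighting
    )
    isolated = ~np.isfinite(autocov.values)
    n_isolated = int(isolated.sum())
    if n_isolated:
        log.info("dropping %d isolated cells (no neighbour within radius)", n_isolated)
        df = df.loc[~isolated].reset_index(drop=True)
        coords = coords[~isolated]
        autocov = spatial.SpatialField(
            df["cell_id"].to_numpy(), coords, autocov.values[~isolated]
        )
    env_matrix = df[kept_env].to_numpy(dtype=float) if kept_env else np.empty((len(df), 0))
    autocor = (
        spatial.residualize(autocov, env_matrix) if kept_env else autocov
    )
    df["autocor"] = regression.standardize(autocor.values)

    terms = list(kept_env)
    if "region" in df.columns and df["region"].nunique() > 1:
        terms.append("C(region)")
    terms.append("autocor")
    forced = ["s_sequences", "s_species"]
    terms += forced

    full = regression.fit_lm(df, "z_gd", terms)
    selected = regression.step_aic(df, "z_gd", terms, forced=forced)
    hp = regression.hier_part(df, "z_gd", selected.terms)
    resid_field = spatial.SpatialField(
        df["cell_id"].to_numpy(),
        np.column_stack([df["x_m"], df["y_m"]]),
        selected.residuals,
    )
    moran = spatial.moran_permutation_test(
        resid_field, k_nearest=settings.knn_k, n_perm=settings.n_perm,
        seed=settings.seed,
    )
    return full, selected, hp, moran, vif_report, terms, n_isolated


def analyze(
    records: list[barcode_io.SequenceRecord],
    alignments: dict[str, dict[str, str]] | None,
    environment: pd.DataFrame,
    richness_map: dict[str, int] | None = None,
    settings: AnalysisSettings | None = None,
    spec: GridSpec | None = None,
    report: barcode_io.FilterReport | None = None,
    run_model: bool = True,
) -> AnalysisResult:
    """Run the full analysis in memory and return every artefact."""
    settings = settings or AnalysisSettings()
    spec = spec or GridSpec()
    filtered, report = barcode_io.filter_records(
        records, marker=settings.marker, min_length=settings.min_length, report=report
    )
    species_pi, cells_all = build_cell_table(
        filtered, alignments, environment, richness_map, settings, spec
    )
    cells = diversity.apply_cell_filters(
        cells_all,
        min_sequences=settings.min_sequences,
        min_species=settings.min_species,
        min_coverage_pct=settings.min_coverage_pct,
    )
    bands = diversity.band_aggregate(cells)
    cong = None
    full = selected = hp = moran = vif_report = None
    terms: list[str] = []
    n_isolated = 0
    if run_model and len(cells) >= 10:
        try:
            cong = congruence(cells, settings)
        except ValueError as exc:
            log.warning("congruence skipped: %s", exc)
        full, selected, hp, moran, vif_report, terms, n_isolated = (
            model_genetic_diversity(cells, settings)
        )
    return AnalysisResult(
        filter_report=report,
        species_pi=species_pi,
        cells=cells,
        bands=bands,
        congruence=cong,
        full_model=full,
        selected_model=selected,
        hier_part=hp,
        residual_moran=moran,
        vif_report=vif_report,
        model_terms=terms,
        n_isolated_cells=n_isolated,
    )


def robustness_sweep(
    records: list[barcode_io.SequenceRecord],
    alignments: dict[str, dict[str, str]] | None,
    environment: pd.DataFrame,
    richness_map: dict[str, int] | None,
    settings: AnalysisSettings,
    threshold_grid: list[tuple[int, int, float]],
    spec: GridSpec | None = None,
    min_cells: int = 30,
) -> pd.DataFrame:
    """Re-run congruence and the model under each cell-filter combination.

    One row per (min_sequences, min_species, min_coverage_pct) combination;
    combinations retaining fewer than ``min_cells`` cells are flagged
    ``insufficient`` and their statistics left missing.
    """
    spec = spec or GridSpec()
    filtered, _ = barcode_io.filter_records(
        records, marker=settings.marker, min_length=settings.min_length
    )
    _, cells_all = build_cell_table(
        filtered, alignments, environment, richness_map, settings, spec
    )
    rows = []
    for min_seq, min_sp, min_cov in threshold_grid:
        sub = diversity.apply_cell_filters(
            cells_all, min_sequences=min_seq, min_species=min_sp,
            min_coverage_pct=min_cov,
        )
        row = {
            "min_sequences": min_seq, "min_species": min_sp,
            "min_coverage_pct": min_cov, "n_cells": len(sub),
            "status": "ok", "congruence_r": np.nan, "congruence_p": np.nan,
            "adj_r2": np.nan,
        }
        if len(sub) < min_cells:
            row["status"] = "insufficient"
            rows.append(row)
            continue
        try:
            cong = congruence(sub, settings)
            row["congruence_r"] = cong.r
            row["congruence_p"] = cong.modified_ttest.p
        except ValueError as exc:
            log.warning("congruence failed for %s: %s", row, exc)
        try:
            _, selected, *_ = model_genetic_diversity(sub, settings)
            row["adj_r2"] = selected.adj_r2
        except ValueError as exc:
            log.warning("model failed for %s: %s", row, exc)
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# File-based front end


@dataclasses.dataclass
class PipelineConfig:
    """Validated file-based pipeline configuration (YAML-loadable)."""

    records: str
    environment: str
    outdir: str
    alignments_dir: str | None = None
    occurrences: str | None = None
    cell_km: float = 200.0
    settings: AnalysisSettings = dataclasses.field(default_factory=AnalysisSettings)
    robustness_grid: list[tuple[int, int, float]] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        settings_raw = raw.pop("settings", {}) or {}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        s_known = {f.name for f in dataclasses.fields(AnalysisSettings)}
        s_unknown = set(settings_raw) - s_known
        if s_unknown:
            raise ValueError(f"unknown settings keys: {sorted(s_unknown)}")
        grid_raw = raw.pop("robustness_grid", None)
        cfg = cls(settings=AnalysisSettings(**settings_raw), **raw)
        if grid_raw is not None:
            cfg.robustness_grid = [tuple(g) for g in grid_raw]
        return cfg


def _load_alignments(aln_dir: str | Path) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    for path in sorted(Path(aln_dir).glob("*.fasta")):
        groups = barcode_io.read_alignment(path)
        for stem, seqs in groups.items():
            out[stem.replace("_", " ")] = seqs
    return out


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """Run every stage from files and write all artefact tables to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = GridSpec(cell_km=config.cell_km)
    records, report = barcode_io.read_records(config.records)
    environment = pd.read_csv(config.environment, sep="\t")
    alignments = (
        _load_alignments(config.alignments_dir) if config.alignments_dir else None
    )
    richness_map = None
    if config.occurrences:
        occ = richness_mod.read_occurrences(config.occurrences)
        rich = richness_mod.richness_from_occurrences(occ, spec)
        richness_map = dict(zip(rich["cell_id"], rich["n_species_total"]))
    result = analyze(
        records, alignments, environment, richness_map,
        settings=config.settings, spec=spec, report=report,
    )

    result.filter_report.write(outdir / "filter_report.tsv")
    result.species_pi.to_csv(outdir / "species_pi.tsv", sep="\t", index=False)
    result.cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    result.bands.to_csv(outdir / "bands.tsv", sep="\t", index=False)
    if result.congruence is not None:
        mtt = result.congruence.modified_ttest
        pd.DataFrame(
            [{"r": mtt.r, "ess": mtt.ess, "f_stat": mtt.f_stat, "p": mtt.p, "n": mtt.n}]
        ).to_csv(outdir / "congruence.tsv", sep="\t", index=False)
        result.congruence.classification.to_csv(
            outdir / "congruence_classes.tsv", sep="\t", index=False
        )
    if result.selected_model is not None:
        coefs = pd.DataFrame(
            {"coef": result.selected_model.params,
             "ci_low": result.selected_model.conf_int["low"],
             "ci_high": result.selected_model.conf_int["high"]}
        )
        coefs.index.name = "term"
        coefs.to_csv(outdir / "model_coefficients.tsv", sep="\t")
        pd.DataFrame(
            [{"aic": result.selected_model.aic,
              "adj_r2": result.selected_model.adj_r2,
              "r2": result.selected_model.r2,
              "n_cells": result.selected_model.nobs}]
        ).to_csv(outdir / "model_summary.tsv", sep="\t", index=False)
    if result.hier_part is not None:
        pd.DataFrame(
            {"term": result.hier_part.terms,
             "independent": result.hier_part.independent,
             "joint": result.hier_part.joint,
             "relative_pct": result.hier_part.relative_pct}
        ).to_csv(outdir / "hier_part.tsv", sep="\t", index=False)
    if result.residual_moran is not None:
        m = result.residual_moran
        pd.DataFrame(
            [{"moran_i": m.i, "expected": m.expected, "p_perm": m.p_perm,
              "n_perm": m.n_perm}]
        ).to_csv(outdir / "residual_moran.tsv", sep="\t", index=False)
    if config.robustness_grid:
        sweep = robustness_sweep(
            records, alignments, environment, richness_map,
            config.settings, config.robustness_grid, spec=spec,
        )
        sweep.to_csv(outdir / "robustness.tsv", sep="\t", index=False)
    return result
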