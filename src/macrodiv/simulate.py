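"""Synthetic georeferenced barcode worlds with known ground truth.

Every downstream stage of the pipeline (filtering, gridding, diversity
estimation, spatial statistics, regression) is exercised on data from this
module, so each generated dataset carries its generating parameters:

* per-cell expected pairwise diversity follows a log-linear link,
  ``theta_cell = exp(alpha + beta_env . env_cell + region_offset)``, from
  spatially autocorrelated environmental fields (Gaussian random fields);
* species are sampled in random discs of cells (range-restricted,
  spatially clustered sampling);
* sequences within a species-cell come from a star genealogy — a common
  random ancestor with independent per-site substitution on each tip
  lineage, with the per-lineage rate calibrated so the *expected pairwise*
  difference fraction equals theta exactly;
* emitted records pass the barcode filter chain by construction
  (marker "COI-5P", pure A/C/G/T, length > 500, >= 2 sequences/species).

Lognormal species- and cell-level noise terms model unexplained variation
in observed diversity; they are a modelling choice, not an estimate of any
real error structure.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import barcode_io
from . import grid as gridmod
from .grid import GridSpec

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

ENV_FIELDS = ["temperature", "chlorophyll", "slope"]
REGIONS = ("atlantic", "indo_pacific")


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one synthetic world.

    Defaults give a world of 24 x 14 = 336 equal-area cells centred on the
    equator, 200 species (70% marine), ~650-bp barcodes, a baseline
    diversity of 0.008 per site with a positive temperature effect and an
    Indo-Pacific region offset on the log scale.
    """

    n_species: int = 200
    n_cells_x: int = 24
    n_cells_y: int = 14
    cell_km: float = 200.0
    seq_length: int = 650
    theta_range: tuple[float, float] = (0.0005, 0.15)
    #: True effects of (temperature, chlorophyll, slope) on log diversity.
    beta_env: tuple[float, ...] = (0.25, 0.0, 0.0)
    env_autocorr_length_km: float = 600.0
    habitat_split: float = 0.7
    seed: int = 0
    #: Baseline per-site diversity exp(alpha) at average environment.
    theta_baseline: float = 0.008
    #: Additive log-scale offset of the second region vs the first.
    region_effect: float = 0.25
    #: Lognormal noise SDs: between species, and species-by-cell.
    sigma_species: float = 0.4
    sigma_cell: float = 0.2
    #: Sampling clustering: disc radius (cells) and mean cells per species.
    disc_radius_cells: float = 4.0
    mean_cells_per_species: float = 8.0
    #: Richness-temperature coupling: species range centres are drawn with
    #: weight exp(effect * temperature), so warm cells host more species and
    #: genetic and species diversity share a (weak) common driver.
    richness_env_effect: float = 0.75
    #: Sequences per species-cell: 2 + Poisson(mean_extra_seqs).
    mean_extra_seqs: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_species", "n_cells_x", "n_cells_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seq_length <= barcode_io.MIN_UNGAPPED_LENGTH:
            raise ValueError(
                f"seq_length must exceed {barcode_io.MIN_UNGAPPED_LENGTH} bp or the "
                "length filter would silently erase every record"
            )
        lo, hi = self.theta_range
        if not (0 < lo < hi < 0.2):
            raise ValueError("theta_range must lie within (0, 0.2)")
        if not 0 <= self.habitat_split <= 1:
            raise ValueError("habitat_split must be in [0, 1]")
        if not (0 < self.theta_baseline < 0.2):
            raise ValueError("theta_baseline must be in (0, 0.2)")
        if self.env_autocorr_length_km <= 0:
            raise ValueError("env_autocorr_length_km must be positive")


@dataclasses.dataclass
class GroundTruth:
    """Generating parameters recorded alongside a synthetic dataset."""

    alpha: float
    beta_env: np.ndarray
    region_effect: float
    cell_latent: pd.DataFrame  # cell_id, latent_theta (link-scale expectation)
    species: pd.DataFrame  # species, habitat, species_effect
    theta_by_species_cell: pd.DataFrame  # species, cell_id, theta


@dataclasses.dataclass
class SimulatedDataset:
    config: SimulationConfig
    records: pd.DataFrame  # BOLD-style record table
    alignments: dict[str, dict[str, str]]  # species -> {record_id: sequence}
    occurrences: pd.DataFrame
    environment: pd.DataFrame  # per-cell env table
    truth: GroundTruth


def substitution_probability(theta: float) -> float:
    """Per-lineage, per-site substitution probability for a target theta.

    Two tips differ at a site when exactly one lineage substituted, or both
    did and landed on different bases: ``P = 2p(1-p) + (2/3)p^2``.  Solving
    for p makes the expected pairwise difference fraction equal theta
    exactly (p ~ theta/2 for small theta).
    """
    if not 0 <= theta < 0.2:
        raise ValueError(f"theta must be in [0, 0.2), got {theta}")
    return 0.75 * (1.0 - math.sqrt(1.0 - 4.0 * theta / 3.0))


def simulate_species_sequences(
    theta: float, n_seq: int, seq_length: int, rng: np.random.Generator,
    ancestor: np.ndarray | None = None,
) -> list[str]:
    """Gap-free equal-length sequences from a star genealogy.

    Every tip descends independently from a common random ancestor; each
    site substitutes with the calibrated probability to one of the three
    other bases uniformly.  ``theta = 0`` yields identical copies.
    """
    if n_seq < 2:
        raise ValueError("need at least 2 sequences (no pair exists otherwise)")
    p = substitution_probability(theta)
    if ancestor is None:
        ancestor = rng.integers(0, 4, size=seq_length)
    mutate = rng.random((n_seq, seq_length)) < p
    offsets = rng.integers(1, 4, size=(n_seq, seq_length))
    tips = (ancestor[None, :] + offsets * mutate) % 4
    codes = _BASES[tips]
    return [bytes(row).decode("ascii") for row in codes]


def simulate_env_field(
    shape: tuple[int, int],
    correlation_length_km: float,
    cell_km: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field on a (ny, nx) grid.

    White noise smoothed with a Gaussian kernel of scale
    ``correlation_length_km / cell_km`` cells, then restandardized; a
    correlation length at or below ~zero degenerates to white noise.
    """
    if correlation_length_km < 0:
        raise ValueError("correlation length must be non-negative")
    noise = rng.standard_normal(shape)
    sigma = correlation_length_km / cell_km
    if sigma < 1e-9:
        field = noise
    else:
        field = gaussian_filter(noise, sigma=sigma, mode="reflect")
    field = field - field.mean()
    sd = field.std()
    if sd == 0:  # pathological single-cell grid
        return field
    return field / sd


def correlated_field(
    coords: np.ndarray,
    range_m: float,
    rng: np.random.Generator,
    model: str = "exponential",
) -> np.ndarray:
    """Exact zero-mean unit-variance Gaussian random field at given points.

    Draws from a multivariate normal with correlation ``exp(-d / range)``
    (``model="exponential"``, the workhorse geostatistical covariance) or
    ``exp(-(d / range)^2)`` (``model="gaussian"``, much smoother) via a
    Cholesky factor.  O(n^3): intended for validity simulations at a few
    hundred points, not for world-sized grids.
    """
    coords = np.asarray(coords, dtype=float)
    if range_m <= 0:
        raise ValueError("range must be positive")
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    if model == "exponential":
        corr = np.exp(-d / range_m)
    elif model == "gaussian":
        corr = np.exp(-((d / range_m) ** 2))
    else:
        raise ValueError(f"unknown covariance model: {model!r}")
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(coords)))
    return chol @ rng.standard_normal(len(coords))


def _cell_indices(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """ix, iy arrays of the synthetic world, centred on the equator."""
    iy0 = -(config.n_cells_y // 2)
    ix, iy = np.meshgrid(
        np.arange(config.n_cells_x), np.arange(iy0, iy0 + config.n_cells_y)
    )
    return ix.ravel(), iy.ravel()


def _random_point_in_cell(
    ix: int, iy: int, spec: GridSpec, rng: np.random.Generator
) -> tuple[float, float]:
    margin = 1.0  # metres, keeps the point off the half-open edge
    x = spec.x_origin_m + ix * spec.cell_m + rng.uniform(margin, spec.cell_m - margin)
    y = spec.y_origin_m + iy * spec.cell_m + rng.uniform(margin, spec.cell_m - margin)
    return gridmod.unproject(x, y)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one synthetic world under ``config``.

    Returns the record table, per-species alignments, occurrence table,
    per-cell environment table, and the full ground truth.  A single RNG is
    seeded once from ``config.seed``; all randomness derives from it.
    """
    rng = np.random.default_rng(config.seed)
    spec = GridSpec(cell_km=config.cell_km)
    ix, iy = _cell_indices(config)
    n_cells = ix.size
    shape = (config.n_cells_y, config.n_cells_x)

    env = {
        name: simulate_env_field(
            shape, config.env_autocorr_length_km, config.cell_km, rng
        ).ravel()
        for name in ENV_FIELDS
    }
    # Region split: western half vs eastern half of the world.
    region = np.where(ix < config.n_cells_x // 2, REGIONS[0], REGIONS[1])
    region_term = np.where(region == REGIONS[1], config.region_effect, 0.0)

    alpha = math.log(config.theta_baseline)
    beta = np.asarray(config.beta_env, dtype=float)
    if beta.size != len(ENV_FIELDS):
        raise ValueError(f"beta_env must have {len(ENV_FIELDS)} entries")
    env_matrix = np.column_stack([env[name] for name in ENV_FIELDS])
    log_theta_cell = alpha + env_matrix @ beta + region_term
    latent_theta = np.exp(log_theta_cell)

    cell_ids = [gridmod.cell_id(a, b) for a, b in zip(ix, iy)]
    cent_x, cent_y = gridmod.cell_centroid(ix, iy, spec)
    cent_lon, cent_lat = gridmod.unproject(cent_x, cent_y)
    environment = pd.DataFrame(
        {
            "cell_id": cell_ids, "ix": ix, "iy": iy,
            "centroid_lon": cent_lon, "centroid_lat": cent_lat,
            "region": region,
            **{name: env[name] for name in ENV_FIELDS},
        }
    )
    cell_index = {cid: i for i, cid in enumerate(cell_ids)}

    w = np.exp(config.richness_env_effect * env["temperature"])
    centre_weights = w / w.sum()

    lo, hi = config.theta_range
    records_rows = []
    alignments: dict[str, dict[str, str]] = {}
    occ_rows = []
    species_rows = []
    theta_rows = []
    for s in range(config.n_species):
        species = f"Synthetica sp{s:04d}"
        habitat = "marine" if rng.random() < config.habitat_split else "freshwater"
        species_effect = rng.normal(0.0, config.sigma_species)
        # Disc of cells around a random centre: the species' sampled range.
        # Centres are biased toward warm cells by richness_env_effect.
        centre = rng.choice(n_cells, p=centre_weights)
        d2 = (ix - ix[centre]) ** 2 + (iy - iy[centre]) ** 2
        disc = np.flatnonzero(d2 <= config.disc_radius_cells**2)
        n_cells_s = min(
            len(disc), 1 + rng.poisson(max(config.mean_cells_per_species - 1, 0))
        )
        sampled = rng.choice(disc, size=n_cells_s, replace=False)
        species_rows.append(
            {"species": species, "habitat": habitat, "species_effect": species_effect}
        )
        depth_min, depth_max = (0.0, float(rng.uniform(100, 4000))) if habitat == "marine" else (np.nan, np.nan)
        ancestor = rng.integers(0, 4, size=config.seq_length)
        aln: dict[str, str] = {}
        for c in disc:  # occurrences cover the whole disc (the species' range)
            occ_rows.append(
                {"species": species, "lat": cent_lat[c], "lon": cent_lon[c],
                 "depth_min": depth_min, "depth_max": depth_max, "habitat": habitat}
            )
        for c in sampled:
            noise = rng.normal(0.0, config.sigma_cell)
            theta_sc = float(np.clip(
                math.exp(log_theta_cell[c] + species_effect + noise), lo, hi
            ))
            n_seq = 2 + rng.poisson(config.mean_extra_seqs)
            seqs = simulate_species_sequences(
                theta_sc, n_seq, config.seq_length, rng, ancestor=ancestor
            )
            theta_rows.append(
                {"species": species, "cell_id": cell_ids[c], "theta": theta_sc}
            )
            for i, seq in enumerate(seqs):
                rid = f"SYN{s:04d}-{cell_ids[c]}-{i:03d}"
                lon, lat = _random_point_in_cell(ix[c], iy[c], spec, rng)
                records_rows.append(
                    {"processid": rid, "species_name": species,
                     "marker_code": barcode_io.DEFAULT_MARKER,
                     "lat": lat, "lon": lon, "nucleotides": seq}
                )
                aln[rid] = seq
        alignments[species] = aln

    records = pd.DataFrame(
        records_rows, columns=barcode_io.RECORD_COLUMNS
    ).rename(columns={})
    truth = GroundTruth(
        alpha=alpha,
        beta_env=beta,
        region_effect=config.region_effect,
        cell_latent=pd.DataFrame({"cell_id": cell_ids, "latent_theta": latent_theta}),
        species=pd.DataFrame(species_rows),
        theta_by_species_cell=pd.DataFrame(
            theta_rows, columns=["species", "cell_id", "theta"]
        ),
    )
    return SimulatedDataset(
        config=config,
        records=records,
        alignments=alignments,
        occurrences=pd.DataFrame(occ_rows, columns=[
            "species", "lat", "lon", "depth_min", "depth_max", "habitat"]),
        environment=environment,
        truth=truth,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write a dataset in the exact formats the readers consume.

    ``records.tsv`` (BOLD-style table), ``alignments/<species>.fasta`` (one
    aligned FASTA per species, headers = record ids), ``occurrences.tsv``
    and ``environment.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.records.to_csv(outdir / "records.tsv", sep="\t", index=False)
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for species, seqs in dataset.alignments.items():
        if not seqs:
            continue
        fname = species.replace(" ", "_") + ".fasta"
        barcode_io.write_alignment(seqs, aln_dir / fname)
    dataset.occurrences.to_csv(outdir / "occurrences.tsv", sep="\t", index=False)
    dataset.environment.to_csv(outdir / "environment.tsv", sep="\t", index=False)
    dataset.truth.cell_latent.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
    dataset.truth.species.to_csv(outdir / "truth_species.tsv", sep="\t", index=False)
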