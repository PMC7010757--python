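"""Per-species nucleotide diversity and per-cell genetic diversity.

The central statistic is the mean pairwise nucleotide diversity of one
species' aligned sequences within one grid cell::

    Pi = (1 / n_pairs) * sum_{i<j} k_ij / m_ij

where ``k_ij`` counts aligned columns at which sequences i and j carry
different bases, and ``m_ij`` counts columns at which both carry a base
(both non-gap).  Pairs whose shared-site fraction ``m_ij / L`` (L the
aligned length) is not strictly greater than 0.5 are discarded; by default
the divisor is the number of pairs actually used, so Pi stays a well-defined
mean (``divisor="all_pairs"`` restores the literal C(n,2) denominator).

Cell-level genetic diversity GD is the unweighted mean of Pi across the
species present in that cell — every species counts once, regardless of how
many sequences it contributed.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import band_of

GAP_CHARS = frozenset("-.")


@dataclasses.dataclass(frozen=True)
class PairwiseComparison:
    """Shared/differing site counts for one aligned sequence pair."""

    k: int  # differing shared sites
    m: int  # shared (both non-gap) sites
    overlap_fraction: float  # m / aligned length

    @property
    def usable(self) -> bool:
        return self.m > 0


@dataclasses.dataclass(frozen=True)
class SpeciesCellDiversity:
    species: str
    cell_id: str
    n: int
    pi: float
    n_pairs_used: int


@dataclasses.dataclass(frozen=True)
class BandSummary:
    lower: float
    upper: float
    mean_gd: float
    ci: float | None  # sd across cells / sqrt(n_cells); None when n_cells < 2
    n_cells: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


_GAP_CODES = np.frombuffer(b"-.", dtype=np.uint8)


def pairwise_stats(seq_i: str, seq_j: str) -> PairwiseComparison:
    """Count shared and differing sites between two aligned sequences.

    Columns where either sequence has a gap ('-' or '.') contribute to
    neither ``k`` nor ``m``.
    """
    if len(seq_i) != len(seq_j):
        raise ValueError(
            f"aligned lengths differ: {len(seq_i)} vs {len(seq_j)}"
        )
    if len(seq_i) == 0:
        raise ValueError("empty alignment")
    a = _encode(seq_i)
    b = _encode(seq_j)
    shared = ~(np.isin(a, _GAP_CODES) | np.isin(b, _GAP_CODES))
    m = int(shared.sum())
    k = int(((a != b) & shared).sum())
    return PairwiseComparison(k=k, m=m, overlap_fraction=m / len(seq_i))


def nucleotide_diversity(
    seqs: Sequence[str],
    *,
    species: str = "",
    cell_id: str = "",
    min_overlap: float = 0.5,
    divisor: str = "used",
) -> SpeciesCellDiversity | None:
    """Mean pairwise nucleotide diversity of one species-cell alignment.

    Parameters
    ----------
    seqs:
        Equal-length aligned sequences (gaps allowed); at least two.
    min_overlap:
        Pairs with shared-site fraction <= this value are discarded
        (strict inequality, i.e. the ">50%" rule at the default).
    divisor:
        ``"used"`` divides by the number of retained pairs; ``"all_pairs"``
        divides by C(n, 2) regardless of how many pairs were discarded.

    Returns ``None`` when no usable pair remains (undefined diversity; the
    caller logs and drops the species-cell).
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("nucleotide diversity requires at least 2 sequences")
    if divisor not in ("used", "all_pairs"):
        raise ValueError(f"unknown divisor mode: {divisor!r}")
    length = len(seqs[0])
    mat = np.empty((n, length), dtype=np.uint8)
    for i, s in enumerate(seqs):
        enc = _encode(s)
        if enc.size != length:
            raise ValueError("aligned lengths differ within the set")
        mat[i] = enc
    nongap = ~np.isin(mat, _GAP_CODES)

    # ratios accumulated in (i, j) pair order so the mean is the plain
    # sequential sum over pairs
    ratios: list[float] = []
    for i in range(n - 1):
        shared = nongap[i] & nongap[i + 1 :]
        m = shared.sum(axis=1)
        k = ((mat[i] != mat[i + 1 :]) & shared).sum(axis=1)
        ok = (m / length) > min_overlap
        # m > 0 is implied by the overlap rule for any min_overlap >= 0
        for kk, mm, keep in zip(k, m, ok):
            if keep:
                ratios.append(int(kk) / int(mm))

    if not ratios:
        return None
    denom = len(ratios) if divisor == "used" else math.comb(n, 2)
    return SpeciesCellDiversity(
        species=species, cell_id=cell_id, n=n, pi=sum(ratios) / denom,
        n_pairs_used=len(ratios),
    )


def species_cell_table(
    alignments: Mapping[tuple[str, str], Sequence[str]],
    *,
    min_overlap: float = 0.5,
    divisor: str = "used",
) -> pd.DataFrame:
    """Compute Pi for every (species, cell_id) alignment with >= 2 sequences.

    Species-cells with no usable pair are silently excluded (they have
    undefined diversity).
    """
    rows = []
    for (species, cid), seqs in alignments.items():
        if len(seqs) < 2:
            continue
        d = nucleotide_diversity(
            list(seqs), species=species, cell_id=cid,
            min_overlap=min_overlap, divisor=divisor,
        )
        if d is None:
            continue
        rows.append(
            {"species": species, "cell_id": cid, "n_sequences": d.n,
             "pi": d.pi, "n_pairs_used": d.n_pairs_used}
        )
    return pd.DataFrame(
        rows, columns=["species", "cell_id", "n_sequences", "pi", "n_pairs_used"]
    )


def cell_genetic_diversity(
    species_table: pd.DataFrame,
    richness: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Aggregate species-level Pi into per-cell genetic diversity.

    GD is the unweighted mean of Pi across species.  When a per-cell species
    pool size is supplied (``richness``, from range maps), taxonomic coverage
    is reported as ``100 * n_species_genetic / n_species_total``.
    """
    if species_table.empty:
        return pd.DataFrame(
            columns=["cell_id", "gd", "n_sequences", "n_species_genetic",
                     "n_species_total", "taxonomic_coverage"]
        )
    g = species_table.groupby("cell_id")
    out = pd.DataFrame(
        {
            "gd": g["pi"].mean(),
            "n_sequences": g["n_sequences"].sum(),
            "n_species_genetic": g["species"].nunique(),
        }
    ).reset_index()
    if richness is not None:
        out["n_species_total"] = out["cell_id"].map(richness)
        with np.errstate(invalid="ignore", divide="ignore"):
            out["taxonomic_coverage"] = np.where(
                out["n_species_total"].to_numpy(dtype=float) > 0,
                100.0 * out["n_species_genetic"] / out["n_species_total"],
                np.nan,
            )
    else:
        out["n_species_total"] = np.nan
        out["taxonomic_coverage"] = np.nan
    return out


def apply_cell_filters(
    cells: pd.DataFrame,
    min_sequences: int = 2,
    min_species: int = 2,
    min_coverage_pct: float = 0.0,
) -> pd.DataFrame:
    """Retain cells meeting all thresholds simultaneously.

    The coverage threshold is skipped for cells whose species pool size is
    unknown (NaN coverage), matching the main analysis where no taxonomic
    coverage filter was applied.
    """
    keep = (cells["n_sequences"] >= min_sequences) & (
        cells["n_species_genetic"] >= min_species
    )
    if min_coverage_pct > 0:
        cov = cells["taxonomic_coverage"]
        keep &= cov.isna() | (cov >= min_coverage_pct)
    return cells.loc[keep].reset_index(drop=True)


def band_aggregate(cells: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-cell GD into 10-degree latitude bands.

    Returns one row per non-empty band with mean GD, the across-cell
    dispersion ``ci = sd / sqrt(n_cells)`` (NaN when a band holds a single
    cell) and the cell count.  ``cells`` must carry ``centroid_lat``.
    """
    if cells.empty:
        return pd.DataFrame(columns=["band_lower", "band_upper", "mean_gd", "ci", "n_cells"])
    bands = [band_of(lat) for lat in cells["centroid_lat"]]
    df = cells.assign(
        band_lower=[b.lower for b in bands], band_upper=[b.upper for b in bands]
    )
    rows = []
    for (lo, hi), grp in df.groupby(["band_lower", "band_upper"]):
        n = len(grp)
        ci = float(grp["gd"].std(ddof=1) / math.sqrt(n)) if n >= 2 else np.nan
        rows.append(
            {"band_lower": lo, "band_upper": hi,
             "mean_gd": float(grp["gd"].mean()), "ci": ci, "n_cells": n}
        )
    return pd.DataFrame(rows).sort_values("band_lower").reset_index(drop=True)
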