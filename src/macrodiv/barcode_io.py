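"""Reading, writing and filtering BOLD-style barcode record tables.

A record table is tab-separated with columns ``processid, species_name,
marker_code, lat, lon, nucleotides``.  The filter chain mirrors standard
barcode curation: keep only the configured marker, drop any sequence with a
non-ACGT (IUPAC ambiguity) letter, keep sequences strictly longer than
500 ungapped bases, and drop species left with a single sequence (no pair
to compare).  Counts surviving each step are reported.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter
from collections.abc import Iterable, Mapping
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RECORD_COLUMNS = ["processid", "species_name", "marker_code", "lat", "lon", "nucleotides"]

DEFAULT_MARKER = "COI-5P"
MIN_UNGAPPED_LENGTH = 500  # strict: kept sequences are LONGER than this


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """One georeferenced barcode sequence."""

    record_id: str
    species: str
    marker: str
    lat: float
    lon: float
    sequence: str

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species must be non-empty")
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")


@dataclasses.dataclass
class FilterReport:
    """Records/species counts surviving each named filter step, in order."""

    steps: list[tuple[str, int, int]] = dataclasses.field(default_factory=list)
    n_dropped_rows: int = 0  # unparseable/incomplete rows dropped at read time

    def add(self, name: str, records: Iterable[SequenceRecord]) -> None:
        recs = list(records)
        self.steps.append((name, len(recs), len({r.species for r in recs})))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_records", "n_species"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class FormatError(ValueError):
    """Malformed input file."""


def _clean_species(name: str) -> str:
    return " ".join(str(name).split())


def read_records(path: str | Path) -> tuple[list[SequenceRecord], FilterReport]:
    """Read a tab-separated record table.

    Rows missing species, coordinates or sequence — or with unparseable
    coordinates — are dropped with a warning and counted in the report.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"record table missing columns: {missing}")
    records: list[SequenceRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        species = _clean_species(row.species_name)
        seq = row.nucleotides.strip()
        try:
            lat = float(row.lat)
            lon = float(row.lon)
        except ValueError:
            dropped += 1
            continue
        if not species or not seq:
            dropped += 1
            continue
        try:
            records.append(
                SequenceRecord(
                    record_id=str(row.processid), species=species,
                    marker=str(row.marker_code), lat=lat, lon=lon, sequence=seq,
                )
            )
        except ValueError:
            dropped += 1
    if dropped:
        warnings.warn(f"{dropped} record rows dropped (missing/invalid fields)")
    report = FilterReport(n_dropped_rows=dropped)
    report.add("parsed", records)
    return records, report


def records_from_frame(df: pd.DataFrame) -> list[SequenceRecord]:
    """Convert an in-memory BOLD-style table to records (strict: raises on
    any invalid row; use :func:`read_records` for tolerant file reading)."""
    return [
        SequenceRecord(
            record_id=str(r.processid), species=_clean_species(r.species_name),
            marker=str(r.marker_code), lat=float(r.lat), lon=float(r.lon),
            sequence=str(r.nucleotides),
        )
        for r in df.itertuples(index=False)
    ]


def write_records(records: Iterable[SequenceRecord], path: str | Path) -> None:
    rows = [
        {"processid": r.record_id, "species_name": r.species, "marker_code": r.marker,
         "lat": r.lat, "lon": r.lon, "nucleotides": r.sequence}
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, sep="\t", index=False)


def _ungapped_length(seq: str) -> int:
    return sum(1 for c in seq if c not in "-.")


def _is_unambiguous(seq: str) -> bool:
    return all(c in "ACGT" for c in seq.upper())


def filter_records(
    records: Iterable[SequenceRecord],
    marker: str = DEFAULT_MARKER,
    min_length: int = MIN_UNGAPPED_LENGTH,
    report: FilterReport | None = None,
) -> tuple[list[SequenceRecord], FilterReport]:
    """Apply the four-step filter chain, in order.

    1. marker equals ``marker``;
    2. sequence contains only A/C/G/T (case-folded; any other IUPAC letter
       removes the record);
    3. ungapped length strictly greater than ``min_length``;
    4. species represented by at least 2 surviving sequences.
    """
    if report is None:
        report = FilterReport()
    recs = list(records)

    recs = [r for r in recs if r.marker == marker]
    report.add("marker", recs)

    recs = [r for r in recs if _is_unambiguous(r.sequence)]
    report.add("no_ambiguity", recs)

    recs = [r for r in recs if _ungapped_length(r.sequence) > min_length]
    report.add(f"length_gt_{min_length}", recs)

    counts = Counter(r.species for r in recs)
    recs = [r for r in recs if counts[r.species] >= 2]
    report.add("species_ge_2_sequences", recs)

    return recs, report


def read_alignment(
    path: str | Path,
    species_by_record: Mapping[str, str] | None = None,
) -> dict[str, dict[str, str]]:
    """Read an aligned FASTA into species-keyed sets of aligned sequences.

    Headers are record ids.  When ``species_by_record`` is given it maps each
    record id to its species; otherwise the whole file is taken to be a
    single species named after the file stem (the one-FASTA-per-species
    layout).  Within each species all aligned lengths must agree.
    """
    path = Path(path)
    groups: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if species_by_record is not None:
            if rid not in species_by_record:
                raise FormatError(f"alignment header {rid!r} not in record table")
            sp = species_by_record[rid]
        else:
            sp = path.stem
        groups.setdefault(sp, {})[rid] = str(rec.seq).upper()
    for sp, seqs in groups.items():
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise FormatError(
                f"unequal aligned lengths for species {sp!r}: {sorted(lengths)}"
            )
    return groups


def write_alignment(seqs: Mapping[str, str], path: str | Path) -> None:
    """Write one aligned set as FASTA (headers = record ids)."""
    records = [
        SeqRecord(Seq(s), id=rid, description="") for rid, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
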