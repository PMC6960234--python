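"""Sequence records and file I/O.

A :class:`SequenceRecord` couples one marker sequence for one specimen with
its metadata (morphospecies hypothesis, expected amplicon length) and, when
the input was FASTQ, per-base Phred qualities.  Gap characters (``-``) are
preserved so that pre-aligned marker sets round-trip through FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

MARKERS = ("COI", "16S")

METADATA_COLUMNS = ["specimen_id", "marker", "morphospecies", "expected_length"]


@dataclass
class SequenceRecord:
    """One marker sequence for one specimen.

    Parameters
    ----------
    specimen_id : str
        Specimen voucher identifier; unique per (specimen, marker).
    marker : str
        ``"COI"`` (protein-coding) or ``"16S"`` (rRNA, may carry indels).
    residues : str
        Uppercase IUPAC DNA, ``-`` allowed for alignment gaps.
    qualities : list of int, optional
        Per-base Phred scores for the ungapped residues (FASTQ input only).
    morphospecies : str, optional
        Morphology-based species hypothesis (may be genus-level, e.g.
        ``"Alpheus sp."``).
    expected_length : int, optional
        Expected amplicon length in bases, used by the length filter.
    """

    specimen_id: str
    marker: str
    residues: str
    qualities: Optional[list[int]] = None
    morphospecies: Optional[str] = None
    expected_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        self.residues = self.residues.upper()
        if self.qualities is not None and len(self.qualities) != len(self.ungapped):
            raise ValueError(
                f"{self.specimen_id}/{self.marker}: {len(self.qualities)} quality "
                f"scores for {len(self.ungapped)} ungapped bases"
            )

    @property
    def ungapped(self) -> str:
        """Residues with alignment gaps removed."""
        return self.residues.replace("-", "")

    def copy(self, **changes) -> "SequenceRecord":
        return replace(self, **changes)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the specimen metadata TSV (specimen_id, marker, morphospecies,
    expected_length), validating the header."""
    meta = pd.read_csv(path, sep="\t", dtype={"specimen_id": str, "morphospecies": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata {path} lacks column(s): {', '.join(missing)}")
    return meta


def read_sequences(
    path: str | Path,
    format: str,
    metadata: pd.DataFrame,
) -> list[SequenceRecord]:
    """Read a FASTA or FASTQ file and join each record to its metadata row.

    Record IDs must be ``specimen_id`` values present in *metadata* for the
    file's marker; the marker is taken from the metadata row.  FASTQ
    qualities are decoded at the Sanger offset (33).  Unknown IDs and
    duplicate (specimen, marker) pairs are hard errors.
    """
    fmt = format.lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"format must be FASTA or FASTQ, got {format!r}")
    by_id: dict[tuple[str, str], pd.Series] = {}
    for _, row in metadata.iterrows():
        by_id[(str(row["specimen_id"]), str(row["marker"]))] = row

    records: list[SequenceRecord] = []
    seen: set[tuple[str, str]] = set()
    for bio in SeqIO.parse(str(path), fmt):
        hits = [key for key in by_id if key[0] == bio.id]
        if not hits:
            raise KeyError(f"record {bio.id!r} in {path} is absent from the metadata")
        if len(hits) > 1:
            # same specimen sequenced for both markers: disambiguate by file
            raise KeyError(
                f"record {bio.id!r} matches multiple metadata rows; "
                "provide per-marker files"
            )
        key = hits[0]
        if key in seen:
            raise ValueError(f"duplicate record for specimen {key[0]!r} marker {key[1]}")
        seen.add(key)
        row = by_id[key]
        quals = None
        if fmt == "fastq":
            quals = list(bio.letter_annotations["phred_quality"])
        records.append(
            SequenceRecord(
                specimen_id=str(bio.id),
                marker=str(row["marker"]),
                residues=str(bio.seq),
                qualities=quals,
                morphospecies=(None if pd.isna(row["morphospecies"]) else str(row["morphospecies"])),
                expected_length=int(row["expected_length"]),
            )
        )
    return records


def read_marker_file(path: str | Path, format: str, metadata: pd.DataFrame, marker: str) -> list[SequenceRecord]:
    """Read one per-marker file, joining against the metadata rows of *marker* only."""
    sub = metadata[metadata["marker"] == marker]
    return read_sequences(path, format, sub)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [_BioRecord(Seq(r.residues), id=r.specimen_id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = []
    for r in records:
        if r.qualities is None:
            raise ValueError(f"{r.specimen_id}/{r.marker} has no qualities; cannot write FASTQ")
        rec = _BioRecord(Seq(r.ungapped), id=r.specimen_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        bio.append(rec)
    SeqIO.write(bio, str(path), "fastq")


def write_metadata(records: Sequence[SequenceRecord], path: str | Path) -> None:
    rows = [
        {
            "specimen_id": r.specimen_id,
            "marker": r.marker,
            "morphospecies": r.morphospecies or "",
            "expected_length": r.expected_length,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)
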