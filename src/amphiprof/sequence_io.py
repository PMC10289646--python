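"""Labeled AH sequence I/O and feature tables.

FASTA has no standard for group labels, so records carry them in a structured
header, ``id|family|phylum`` by default (delimiter configurable). Coordinates
of helix subregions are 1-based inclusive, matching the span notation used
for protein segments (e.g. "residues 1 to 24").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .physchem import AMINO_ACIDS, PhyschemProfile, UnknownResidueError

__all__ = [
    "AHRecord",
    "MalformedHeaderError",
    "read_fasta",
    "write_fasta",
    "extract_region",
    "write_feature_table",
    "read_feature_table",
    "profiles_to_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_HEADER_FIELDS = ("id", "family", "phylum")


class MalformedHeaderError(ValueError):
    """FASTA header does not match the expected labeled schema."""


@dataclass(frozen=True)
class AHRecord:
    """One labeled amphipathic-helix peptide sequence.

    ``source_span`` is the 1-based inclusive (start, end) location of the
    helix in its parent protein, when known.
    """

    id: str
    sequence: str
    family: str = ""
    phylum: str = ""
    source_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        for ch in self.sequence:
            if ch not in AMINO_ACIDS:
                raise UnknownResidueError(
                    f"record {self.id!r}: non-standard residue {ch!r}"
                )
        if self.source_span is not None:
            start, end = self.source_span
            if end - start + 1 != len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: source_span {self.source_span} does "
                    f"not match sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(
    path: str | Path,
    header_fields: Sequence[str] = DEFAULT_HEADER_FIELDS,
    delimiter: str = "|",
) -> list[AHRecord]:
    """Read labeled AH records from FASTA.

    Headers must carry ``len(header_fields)`` delimiter-separated fields;
    sequences are uppercased and a terminal '*' stop is stripped. A record
    with a non-standard residue letter raises, naming the letter and the
    record id. An empty file yields an empty list with a logged warning.
    """
    path = Path(path)
    records: list[AHRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        fields = entry.description.split(delimiter)
        if len(fields) != len(header_fields):
            raise MalformedHeaderError(
                f"header {entry.description!r}: expected "
                f"{len(header_fields)} {delimiter!r}-separated fields "
                f"({'|'.join(header_fields)}), got {len(fields)}"
            )
        meta = {k: v.strip() for k, v in zip(header_fields, fields)}
        seq = str(entry.seq).upper().rstrip("*")
        records.append(
            AHRecord(
                id=meta.get("id", entry.id),
                sequence=seq,
                family=meta.get("family", ""),
                phylum=meta.get("phylum", ""),
            )
        )
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(
    records: Iterable[AHRecord], path: str | Path, delimiter: str = "|"
) -> None:
    """Write records as FASTA with ``id|family|phylum`` headers."""
    entries = [
        SeqRecord(
            Seq(r.sequence),
            id=delimiter.join((r.id, r.family, r.phylum)),
            description="",
        )
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def extract_region(record: AHRecord, start: int, end: int) -> AHRecord:
    """Extract the 1-based inclusive subregion [start, end] of a record.

    The returned ``source_span`` is expressed in the coordinates of the
    original parent protein, so nested extractions compose: extracting
    (a, b) then (c, d) equals extracting (a+c−1, a+d−1) from the original.
    """
    if not (1 <= start <= end <= len(record.sequence)):
        raise ValueError(
            f"record {record.id!r}: span ({start}, {end}) out of range "
            f"for length {len(record.sequence)}"
        )
    if record.source_span is not None:
        parent_start = record.source_span[0]
        span = (parent_start + start - 1, parent_start + end - 1)
    else:
        span = (start, end)
    return replace(record, sequence=record.sequence[start - 1 : end], source_span=span)


def profiles_to_frame(profiles: Sequence[PhyschemProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame indexed by id, columns in canonical order."""
    if not profiles:
        cols = list(PhyschemProfile.SUMMARY_FEATURES) + [
            f"count_{aa}" for aa in AMINO_ACIDS
        ]
        return pd.DataFrame(columns=cols, index=pd.Index([], name="id"))
    rows = [p.to_dict() for p in profiles]
    feature_sets = {tuple(d) for d in rows}
    if len(feature_sets) != 1:
        raise ValueError("profiles have heterogeneous feature sets")
    df = pd.DataFrame(rows, index=pd.Index([p.id for p in profiles], name="id"))
    return df


def write_feature_table(
    profiles: Sequence[PhyschemProfile], path: str | Path, sep: str = "\t"
) -> None:
    """Write a delimited feature table, one row per AH plus a header row."""
    profiles_to_frame(profiles).to_csv(path, sep=sep)


def read_feature_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    return pd.read_csv(path, sep=sep, index_col="id")
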