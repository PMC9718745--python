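"""Promoter sequence, expression-table and interval I/O.

Coordinate convention
---------------------
Promoters are handled as TSS-anchored windows. The default window is
-2000..+1000 relative to the transcription start site, i.e. a 3001-nt
sense-strand sequence. Internally everything is 0-based half-open: the
TSS-relative position ``p`` of a record maps to string index
``p - rel_start``, so the TSS base of a default record sits at index 2000.
BED intervals are 0-based half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PromoterRecord",
    "GeneExpressionRecord",
    "GenomicInterval",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "extract_relative_region",
    "read_bed",
    "write_bed",
]

_ALPHABET = frozenset("ACGTN")


@dataclass
class PromoterRecord:
    """One gene's TSS-anchored promoter sequence.

    ``sequence`` is the sense strand 5'->3', uppercase over {A,C,G,T,N}.
    ``rel_start``/``rel_end`` are the TSS-relative offsets of the first base
    and one past the last base (default -2000 / +1001, a 3001-nt window with
    the TSS inside it).
    """

    gene_id: str
    sequence: str
    rel_start: int = -2000
    rel_end: int = 1001
    sense_strand: bool = True

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if len(self.sequence) != self.rel_end - self.rel_start:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"rel_end - rel_start = {self.rel_end - self.rel_start}"
            )
        bad = set(self.sequence) - _ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValueError(
                f"{self.gene_id}: non-ACGTN character {self.sequence[pos]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def tss_index(self) -> int:
        """String index of the TSS base (position 0)."""
        return -self.rel_start


@dataclass
class GeneExpressionRecord:
    """A gene's expression change as a dimensionless microarray z statistic.

    ``z_magnitude`` is the absolute magnitude of downregulation; the sign
    convention of the source table is normalized away at parse time.
    """

    gene_id: str
    z_magnitude: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.z_magnitude):
            raise ValueError(f"{self.gene_id}: non-finite z score")


@dataclass
class GenomicInterval:
    """A 0-based half-open interval, BED-style."""

    seq_id: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[int] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def read_fasta(
    path, rel_start: int = -2000, rel_end: int = 1001, permissive: bool = False
) -> list[PromoterRecord]:
    """Read promoter FASTA into :class:`PromoterRecord` objects.

    The first whitespace-delimited token of each header is the gene id.
    In strict mode (default) every sequence must have length
    ``rel_end - rel_start``; with ``permissive=True`` the record's
    ``rel_end`` is adjusted instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        gene_id = entry.id
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id in FASTA: {gene_id!r}")
        seen.add(gene_id)
        seq = str(entry.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {gene_id!r}")
        end = rel_end
        if len(seq) != rel_end - rel_start:
            if permissive:
                end = rel_start + len(seq)
            else:
                raise ValueError(
                    f"{gene_id}: length {len(seq)} != expected "
                    f"{rel_end - rel_start} (strict mode)"
                )
        records.append(PromoterRecord(gene_id, seq, rel_start, end))
    return records


def write_fasta(records: Iterable[PromoterRecord], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.gene_id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_gene_table(path) -> list[GeneExpressionRecord]:
    """Read a TSV with columns ``gene_id`` and ``z_score``.

    z is normalized to absolute magnitude (microarray tables report
    downregulation with either sign convention).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "z_score"):
        if col not in df.columns:
            raise ValueError(f"gene table missing column {col!r}")
    out = []
    for idx, row in df.iterrows():
        z = pd.to_numeric(pd.Series([row["z_score"]]), errors="coerce").iloc[0]
        if pd.isna(z):
            # +2 accounts for header line and 1-based numbering
            raise ValueError(f"unparseable z_score at row {idx + 2}: {row['z_score']!r}")
        out.append(GeneExpressionRecord(str(row["gene_id"]), abs(float(z))))
    return out


def extract_relative_region(record: PromoterRecord, a: int, b: int) -> str:
    """Subsequence covering TSS-relative positions ``a..b`` inclusive.

    Length is ``b - a + 1``; position ``p`` maps to index ``p - rel_start``.
    """
    if not (record.rel_start <= a <= b < record.rel_end):
        raise ValueError(
            f"{record.gene_id}: requested region [{a}, {b}] outside available "
            f"[{record.rel_start}, {record.rel_end - 1}]"
        )
    i = a - record.rel_start
    return record.sequence[i : i + (b - a + 1)]


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ into intervals (0-based half-open, coordinates preserved)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BED not found: {path}")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            seq_id = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 else None
            score = int(fields[4]) if len(fields) > 4 else None
            strand = fields[5] if len(fields) > 5 else None
            intervals.append(GenomicInterval(seq_id, start, end, name, score, strand))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED; column count follows the widest record."""
    intervals = list(intervals)
    ncols = 3
    for iv in intervals:
        if iv.strand is not None:
            ncols = max(ncols, 6)
        elif iv.score is not None:
            ncols = max(ncols, 5)
        elif iv.name is not None:
            ncols = max(ncols, 4)
    with open(path, "w", newline="\n") as fh:
        for iv in intervals:
            fields = [iv.seq_id, str(iv.start), str(iv.end)]
            if ncols >= 4:
                fields.append(iv.name if iv.name is not None else ".")
            if ncols >= 5:
                fields.append(str(iv.score if iv.score is not None else 0))
            if ncols >= 6:
                fields.append(iv.strand if iv.strand is not None else ".")
            fh.write("\t".join(fields) + "\n")
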