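"""Sequence and interval I/O with soft-masking semantics preserved.

Genome FASTA files mark repetitive elements in lowercase (soft-masking).
That case information is *data* here — it decides which fragments qualify
as repeat-free controls — so records round-trip with residue case intact.

Coordinates are BED-style 0-based half-open everywhere in this package;
1-based VCF positions are converted on ingest (see :mod:`ucnescan.clinvar_mc`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Residues accepted anywhere in the package.  Anything else is rejected
#: rather than coerced so downstream window counts are unambiguous.
ALPHABET = frozenset("ACGTNacgtn")

_ILLEGAL = re.compile(r"[^ACGTNacgtn]")


class FastaParseError(ValueError):
    """Raised when a FASTA file contains residues outside {A,C,G,T,N} (any case)."""


@dataclass(frozen=True)
class MaskedSequence:
    """A DNA record whose lowercase (soft-masked) runs are preserved."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = _ILLEGAL.search(self.residues)
        if bad is not None:
            raise FastaParseError(
                f"record {self.id!r}: illegal residue {bad.group()!r} "
                f"at position {bad.start()}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def upper(self) -> str:
        """Residues uppercased (counting is case-insensitive)."""
        return self.residues.upper()

    def is_repeat_free(self) -> bool:
        """True if the record has no soft-masked (lowercase) and no N residues."""
        return self.residues.isupper() and "N" not in self.residues


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval, BED style."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        """Membership of a 0-based position."""
        return self.start <= pos0 < self.end


def read_fasta(path: str | Path) -> list[MaskedSequence]:
    """Read a (possibly soft-masked) FASTA file.

    Residues are kept verbatim, including case; record order is preserved.
    Residues outside {A,C,G,T,N}/{a,c,g,t,n} raise :class:`FastaParseError`.
    """
    records = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        records.append(MaskedSequence(id=rec.id, residues=str(rec.seq)))
    return records


def write_fasta(records: Iterable[MaskedSequence], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, wrapping lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 intervals (tab-separated, 0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            try:
                intervals.append(GenomicInterval(chrom, start, end, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED4 (BED3 when no interval has a name)."""
    intervals = list(intervals)
    with_names = any(iv.name for iv in intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if with_names:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")
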