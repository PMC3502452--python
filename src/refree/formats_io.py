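"""Readers and writers for the pipeline's on-disk artifacts.

FASTA and FASTQ parsing is delegated to Biopython with a validation layer
on top (case normalization, alphabet checks, quality-length checks).  The
k-mer table and taxonomy formats are plain TSV dialects of this package:

* k-mer table — a ``#``-prefixed header line ``genome_id<TAB>k<TAB>threshold``
  followed by one ``kmer<TAB>count`` line per canonical k-mer in strict
  ascending lexicographic order.  Sortedness is a format guarantee: it is
  what allows downstream single-pass multiway merging of many genomes.
* taxonomy — ``genome_id<TAB>lineage`` with the lineage as semicolon-joined
  taxon names ordered root to tip.

All writers/readers round-trip exactly, and gzip compression is handled
transparently for ``.gz`` paths.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FormatError",
    "SequenceRecord",
    "TaxonomyTable",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_kmer_table",
    "write_kmer_table",
    "read_taxonomy",
    "write_taxonomy",
]

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A malformed or invariant-violating on-disk artifact."""


@dataclass
class SequenceRecord:
    """A named DNA sequence, optionally with per-base qualities and mate info.

    ``sequence`` is upper-case over {A,C,G,T,N}; ``mate`` is 1 or 2 for
    paired reads and ``pair_id`` names the fragment both mates share.
    """

    id: str
    sequence: str
    quality: Optional[str] = None
    description: str = ""
    mate: Optional[int] = None
    pair_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid characters {sorted(bad)}; "
                "only A/C/G/T/N are accepted (IUPAC ambiguity codes are not)"
            )
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a (possibly gzipped) FASTA file into :class:`SequenceRecord`\\ s.

    Sequences are upper-cased; the description after the first whitespace
    of the header is kept separately from the id.  An empty file yields an
    empty list; text before the first header is an error naming its line.
    """
    with _open_text(path) as fh:
        # Locate the first non-blank line so malformed headers can be
        # reported with a line number (Biopython is silent about them).
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FormatError(
                f"{path}: line {lineno}: expected FASTA header starting "
                f"with '>', got {line[:30]!r}"
            )
        break
    else:
        return []

    records = []
    from io import StringIO

    for rec in SeqIO.parse(StringIO("\n".join(lines)), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path) -> list[SequenceRecord]:
    """Parse 4-line-per-record FASTQ (Sanger offset qualities kept verbatim)."""
    records = []
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                rid = title.split(None, 1)[0]
                desc = title[len(rid):].strip()
                mate = None
                pair_id = None
                if rid.endswith("/1") or rid.endswith("/2"):
                    mate = int(rid[-1])
                    pair_id = rid[:-2]
                records.append(
                    SequenceRecord(
                        id=rid,
                        sequence=seq.upper(),
                        quality=qual,
                        description=desc,
                        mate=mate,
                        pair_id=pair_id,
                    )
                )
        except ValueError as exc:  # Biopython signals length mismatches etc.
            raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
            if len(qual) != len(rec.sequence):
                raise FormatError(
                    f"record {rec.id!r}: quality length != sequence length"
                )
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f"@{header}\n{rec.sequence}\n+\n{qual}\n")


def write_kmer_table(table, path) -> None:
    """Serialize a :class:`~refree.kmer_core.KmerTable` (sorted TSV)."""
    with _open_text(path, "wt") as fh:
        fh.write(f"#{table.genome_id}\t{table.k}\t{table.threshold}\n")
        prev = None
        for kmer, count in table.entries.items():
            if prev is not None and kmer <= prev:
                raise FormatError(
                    f"k-mer table {table.genome_id!r} entries not strictly "
                    f"ascending at {kmer!r}"
                )
            prev = kmer
            fh.write(f"{kmer}\t{count}\n")


def read_kmer_table(path):
    """Read a k-mer table TSV, enforcing the sortedness guarantee."""
    from .kmer_core import KmerTable  # local import to avoid a cycle

    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing '#' header line")
        parts = header[1:].split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}: header must be genome_id<TAB>k<TAB>threshold")
        genome_id, k, threshold = parts[0], int(parts[1]), int(parts[2])
        entries: dict[str, int] = {}
        prev = None
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                kmer, count = line.split("\t")
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: expected kmer<TAB>count")
            if prev is not None and kmer <= prev:
                raise FormatError(
                    f"{path}: line {lineno}: table not sorted ({kmer!r} after {prev!r})"
                )
            prev = kmer
            entries[kmer] = int(count)
    return KmerTable(genome_id=genome_id, k=k, threshold=threshold, entries=entries)


@dataclass
class TaxonomyTable:
    """Genome id -> lineage (root-to-tip ordered taxon names)."""

    rows: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = {lineage[0] for lineage in self.rows.values() if lineage}
        for gid, lineage in self.rows.items():
            if not lineage:
                raise FormatError(f"taxonomy: genome {gid!r} has an empty lineage")
        if len(roots) > 1:
            raise FormatError(
                f"taxonomy: all lineages must share one root taxon, got {sorted(roots)}"
            )

    @property
    def genome_ids(self) -> set[str]:
        return set(self.rows)

    def lineage(self, genome_id: str) -> tuple[str, ...]:
        return self.rows[genome_id]


def read_taxonomy(path) -> TaxonomyTable:
    rows: dict[str, tuple[str, ...]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected genome_id<TAB>lineage"
                )
            gid, lineage_txt = parts
            if gid in rows:
                raise FormatError(f"{path}: line {lineno}: duplicate genome id {gid!r}")
            lineage = tuple(t.strip() for t in lineage_txt.split(";") if t.strip())
            if not lineage:
                raise FormatError(f"{path}: line {lineno}: empty lineage for {gid!r}")
            rows[gid] = lineage
    return TaxonomyTable(rows=rows)


def write_taxonomy(table: TaxonomyTable, path) -> None:
    with _open_text(path, "wt") as fh:
        for gid in sorted(table.rows):
            fh.write(f"{gid}\t{';'.join(table.rows[gid])}\n")
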