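"""Canonical k-mer extraction and per-genome frequency tables.

A canonical k-mer equates a DNA word with its reverse complement by keeping
whichever of the pair sorts first alphabetically (A < C < G < T).  The k-mer
length must be odd so that no word is its own reverse complement and the
choice is always strict.  Counting sums occurrences of both orientations,
and a frequency threshold screens out most k-mers created by random
sequencing error before tables are compared across genomes.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .formats_io import SequenceRecord

__all__ = [
    "KmerTable",
    "reverse_complement",
    "canonicalize",
    "iter_canonical_kmers",
    "count_kmers",
    "count_kmers_from_sequence",
    "distinct_kmer_count",
]

_RC = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N.

    Involution: applying it twice returns the input.
    """
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"cannot reverse-complement characters {sorted(bad)}; alphabet is ACGTN"
        )
    return seq.translate(_RC)[::-1]


def canonicalize(kmer: str) -> str:
    """Return the alphabetically smaller of a k-mer and its reverse complement.

    Idempotent.  Windows containing N have no canonical form and are
    rejected; callers must skip them.
    """
    if "N" in kmer:
        raise ValueError("k-mer contains N: no canonical form, skip the window")
    return min(kmer, reverse_complement(kmer))


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError(
            f"k={k} is even: palindromic canonicalization ambiguity (use odd k)"
        )
    if k < 3:
        raise ValueError(f"k={k} too small; k must be an odd integer >= 3")


def iter_canonical_kmers(seq: str, k: int) -> Iterator[str]:
    """Yield the canonical form of every length-k window, skipping N windows.

    The whole sequence is reverse-complemented once so each window costs two
    slices and a comparison.
    """
    L = len(seq)
    if L < k:
        return
    rc = reverse_complement(seq)
    if "N" not in seq:
        for i in range(L - k + 1):
            f = seq[i : i + k]
            r = rc[L - k - i : L - i]
            yield f if f <= r else r
    else:
        i = 0
        while i <= L - k:
            j = seq.find("N", i, i + k)
            if j != -1:
                i = j + 1
                continue
            f = seq[i : i + k]
            r = rc[L - k - i : L - i]
            yield f if f <= r else r
            i += 1


@dataclass
class KmerTable:
    """Sorted canonical k-mer -> count map for one genome.

    Every retained count is >= ``threshold`` and keys are strictly
    ascending (the serialization order contract).
    """

    genome_id: str
    k: int = 21
    threshold: int = 3
    entries: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        _check_k(self.k)
        prev = None
        for kmer, count in self.entries.items():
            if len(kmer) != self.k:
                raise ValueError(f"{self.genome_id}: k-mer {kmer!r} has wrong length")
            if count < self.threshold:
                raise ValueError(
                    f"{self.genome_id}: count {count} below threshold {self.threshold}"
                )
            if kmer != canonicalize(kmer):
                raise ValueError(f"{self.genome_id}: {kmer!r} is not canonical")
            if prev is not None and kmer <= prev:
                raise ValueError(f"{self.genome_id}: entries not sorted at {kmer!r}")
            prev = kmer

    def __len__(self) -> int:
        return len(self.entries)


def count_kmers(
    records: Iterable[SequenceRecord],
    k: int = 21,
    threshold: int = 3,
    circular: bool = False,
    genome_id: str = "genome",
) -> KmerTable:
    """Count canonical k-mers across records from one genome.

    Every N-free window contributes one count to its canonical form; windows
    containing N are skipped.  Thresholding removes low-count entries *after*
    the full count, so surviving counts are exact.  With ``circular`` the
    first k-1 bases are appended to each record before counting, adding the
    k-1 origin-spanning windows of a circular molecule.
    """
    _check_k(k)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    counts: Counter[str] = Counter()
    n_short = 0
    for rec in records:
        seq = rec.sequence
        if len(seq) < k:
            n_short += 1
            continue
        if circular:
            seq = seq + seq[: k - 1]
        counts.update(iter_canonical_kmers(seq, k))
    if n_short:
        warnings.warn(
            f"{genome_id}: {n_short} record(s) shorter than k={k} contributed nothing",
            stacklevel=2,
        )
    entries = {km: counts[km] for km in sorted(counts) if counts[km] >= threshold}
    return KmerTable(genome_id=genome_id, k=k, threshold=threshold, entries=entries)


def count_kmers_from_sequence(
    sequence: str,
    k: int = 21,
    threshold: int = 1,
    circular: bool = False,
    genome_id: str = "genome",
) -> KmerTable:
    """Count directly from an assembled genome sequence (threshold 1 default)."""
    rec = SequenceRecord(id=genome_id, sequence=sequence)
    return count_kmers([rec], k=k, threshold=threshold, circular=circular,
                       genome_id=genome_id)


def distinct_kmer_count(table: KmerTable) -> int:
    """Number of distinct canonical k-mers in the table (its k-mer diversity)."""
    return len(table.entries)
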