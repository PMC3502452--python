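"""Recruit the reads carrying any k-mer of a target tip or group set.

A read is selected iff at least one of its length-k windows, canonicalized
(N windows skipped), is in the target set — matching is therefore
strand-insensitive.  Reads from each genome are kept separate.  Optional
mate rescue additionally pulls in the unselected mate of any selected
paired read, flagged as rescued; it defaults off, which is the conservative
behavior (rescue only improves assembly contiguity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .formats_io import SequenceRecord
from .kmer_core import reverse_complement
from .partition_groups import GroupKey

__all__ = ["ReadSubset", "select_reads", "select_reads_multi"]


@dataclass
class ReadSubset:
    """Reads of one genome recruited by one tip or group k-mer set."""

    genome_id: str
    group_key: GroupKey
    reads: list[SequenceRecord] = field(default_factory=list)
    rescued_ids: frozenset = frozenset()
    n_too_short: int = 0

    def __len__(self) -> int:
        return len(self.reads)


def _read_matches(seq: str, kset: frozenset, k: int) -> bool:
    L = len(seq)
    rc = reverse_complement(seq)
    if "N" not in seq:
        for i in range(L - k + 1):
            f = seq[i : i + k]
            r = rc[L - k - i : L - i]
            if (f if f <= r else r) in kset:
                return True
        return False
    i = 0
    while i <= L - k:
        j = seq.find("N", i, i + k)
        if j != -1:
            i = j + 1
            continue
        f = seq[i : i + k]
        r = rc[L - k - i : L - i]
        if (f if f <= r else r) in kset:
            return True
        i += 1
    return False


def select_reads(
    reads: Iterable[SequenceRecord],
    kmers: Iterable[str],
    k: int,
    genome_id: str = "genome",
    group_key: Optional[GroupKey] = None,
    rescue_mates: bool = False,
) -> ReadSubset:
    """Select reads containing any canonical k-mer of the target set.

    Output preserves input order with no duplicates.  An empty k-mer set
    selects nothing.  Reads shorter than k are never selected (counted in
    ``n_too_short``).
    """
    kset = kmers if isinstance(kmers, frozenset) else frozenset(kmers)
    if group_key is None:
        group_key = GroupKey([genome_id])
    reads = list(reads)
    hit = [False] * len(reads)
    n_short = 0
    if kset:
        for idx, rec in enumerate(reads):
            if len(rec.sequence) < k:
                n_short += 1
                continue
            if _read_matches(rec.sequence, kset, k):
                hit[idx] = True
    rescued: set[str] = set()
    if rescue_mates and kset:
        by_pair: dict[str, list[int]] = {}
        for idx, rec in enumerate(reads):
            if rec.pair_id is not None:
                by_pair.setdefault(rec.pair_id, []).append(idx)
        for idxs in by_pair.values():
            if any(hit[i] for i in idxs):
                for i in idxs:
                    if not hit[i]:
                        hit[i] = True
                        rescued.add(reads[i].id)
    if n_short:
        warnings.warn(
            f"{genome_id}: {n_short} read(s) shorter than k={k} never selected",
            stacklevel=2,
        )
    return ReadSubset(
        genome_id=genome_id,
        group_key=group_key,
        reads=[rec for idx, rec in enumerate(reads) if hit[idx]],
        rescued_ids=frozenset(rescued),
        n_too_short=n_short,
    )


def select_reads_multi(
    reads: Iterable[SequenceRecord],
    targets: Mapping[str, Iterable[str]],
    k: int,
    genome_id: str = "genome",
    group_keys: Optional[Mapping[str, GroupKey]] = None,
) -> dict[str, ReadSubset]:
    """Select reads for several k-mer sets in one pass over the reads.

    Equivalent to calling :func:`select_reads` once per target (a read may
    land in several subsets) but scans each read only once — the per-genome
    tip set and all group sets of that genome are typically recruited
    together.
    """
    index: dict[str, tuple[str, ...]] = {}
    for name, kmers in targets.items():
        for kmer in kmers:
            prev = index.get(kmer)
            index[kmer] = (name,) if prev is None else prev + (name,)
    subsets = {
        name: ReadSubset(
            genome_id=genome_id,
            group_key=(group_keys or {}).get(name, GroupKey([genome_id])),
        )
        for name in targets
    }
    n_targets = len(targets)
    n_short = 0
    for rec in reads:
        seq = rec.sequence
        L = len(seq)
        if L < k:
            n_short += 1
            continue
        rc = reverse_complement(seq)
        hits: set[str] = set()
        i = 0
        while i <= L - k:
            j = seq.find("N", i, i + k)
            if j != -1:
                i = j + 1
                continue
            f = seq[i : i + k]
            r = rc[L - k - i : L - i]
            names = index.get(f if f <= r else r)
            if names:
                hits.update(names)
                if len(hits) == n_targets:
                    break
            i += 1
        for name in hits:
            subsets[name].reads.append(rec)
    for sub in subsets.values():
        sub.n_too_short = n_short
    return subsets
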