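"""Partition k-mers into per-genome tip sets and a shared table with group
membership, and enumerate taxonomically congruent groups.

A k-mer observed in exactly one genome is a "tip" k-mer of that genome; a
k-mer observed in two or more genomes goes into the shared table, annotated
with the exact set of genomes carrying it (its membership).  A group of
genomes can then be queried in two modes: *exclusive* (k-mers whose
membership equals the group exactly — absent from every non-member) or
*inclusive* (k-mers present in all members, regardless of other genomes;
the intersection of the member tables).

Membership is stored once per shared k-mer rather than materializing one
file per group; group k-mer sets are extracted on demand, which avoids the
storage blowup of precomputing all intersections.
"""

from __future__ import annotations

import heapq
from collections import Counter
from dataclasses import dataclass, field
from itertools import groupby
from operator import itemgetter
from typing import Iterable, Mapping

from .formats_io import TaxonomyTable
from .kmer_core import KmerTable

__all__ = [
    "GroupKey",
    "SharedKmerTable",
    "build_tip_and_shared",
    "extract_group",
    "group_sharing_counts",
    "enumerate_congruent_groups",
]


class GroupKey:
    """An immutable, order-free set of genome ids.

    Size 1 denotes a tip; size >= 2 a group.  Serialized deterministically
    as the sorted ids joined by ``+``.
    """

    __slots__ = ("members",)

    def __init__(self, members: Iterable[str]):
        ms = frozenset(members)
        if not ms:
            raise ValueError("GroupKey must have at least one member")
        object.__setattr__(self, "members", ms)

    def __setattr__(self, *_):
        raise AttributeError("GroupKey is immutable")

    @classmethod
    def parse(cls, text: str) -> "GroupKey":
        return cls(part for part in text.split("+") if part)

    @property
    def size(self) -> int:
        return len(self.members)

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    def __eq__(self, other) -> bool:
        return isinstance(other, GroupKey) and self.members == other.members

    def __hash__(self) -> int:
        return hash(self.members)

    def __lt__(self, other: "GroupKey") -> bool:
        return str(self) < str(other)

    def __str__(self) -> str:
        return "+".join(sorted(self.members))

    def __repr__(self) -> str:
        return f"GroupKey({str(self)!r})"


@dataclass
class SharedKmerTable:
    """Sorted map of shared canonical k-mers to their membership group."""

    k: int
    entries: dict[str, GroupKey] = field(default_factory=dict)

    def validate(self) -> None:
        prev = None
        for kmer, key in self.entries.items():
            if key.size < 2:
                raise ValueError(f"shared k-mer {kmer!r} has membership of size 1")
            if prev is not None and kmer <= prev:
                raise ValueError(f"shared table not sorted at {kmer!r}")
            prev = kmer

    def __len__(self) -> int:
        return len(self.entries)


def build_tip_and_shared(
    tables: list[KmerTable],
) -> tuple[dict[str, set[str]], SharedKmerTable]:
    """Split the union of per-genome tables into tip sets and a shared table.

    Implemented as a single-pass multiway merge over the (sorted) input
    tables, so memory beyond the outputs is proportional to the number of
    genomes.  Tip sets and the shared keys partition the union of all keys.
    """
    if len(tables) < 2:
        raise ValueError("need at least two genome tables to partition")
    ks = {t.k for t in tables}
    if len(ks) != 1:
        raise ValueError(f"mismatched k across tables: {sorted(ks)}")
    ids = [t.genome_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_id among tables")

    def _stream(table: KmerTable):
        gid = table.genome_id
        for kmer in table.entries:
            yield kmer, gid

    streams = [_stream(t) for t in tables]
    tips: dict[str, set[str]] = {gid: set() for gid in ids}
    shared: dict[str, GroupKey] = {}
    key_cache: dict[frozenset, GroupKey] = {}
    for kmer, pairs in groupby(heapq.merge(*streams), key=itemgetter(0)):
        carriers = frozenset(gid for _, gid in pairs)
        if len(carriers) == 1:
            tips[next(iter(carriers))].add(kmer)
        else:
            key = key_cache.get(carriers)
            if key is None:
                key = key_cache[carriers] = GroupKey(carriers)
            shared[kmer] = key
    return tips, SharedKmerTable(k=ks.pop(), entries=shared)


def extract_group(
    shared: SharedKmerTable,
    tables: Mapping[str, KmerTable] | list[KmerTable],
    group: GroupKey,
    mode: str = "exclusive",
) -> set[str]:
    """K-mers of a group under the exclusive or inclusive intersection.

    ``exclusive``: membership equals the group exactly (absent from all
    other genomes).  ``inclusive``: present in every member, other genomes
    ignored — the intersection of the member tables' key sets.  For any
    group, the exclusive set is contained in the inclusive set.
    """
    if isinstance(tables, list):
        tables = {t.genome_id: t for t in tables}
    unknown = group.members - set(tables)
    if unknown:
        raise ValueError(f"unknown genome(s) in group: {sorted(unknown)}")
    if group.size < 2:
        raise ValueError("group extraction needs a group of size >= 2")
    if mode == "exclusive":
        return {kmer for kmer, key in shared.entries.items() if key == group}
    if mode == "inclusive":
        members = sorted(group.members, key=lambda g: len(tables[g].entries))
        result = set(tables[members[0]].entries)
        for gid in members[1:]:
            result &= tables[gid].entries.keys()
        return result
    raise ValueError(f"mode must be 'exclusive' or 'inclusive', got {mode!r}")


def group_sharing_counts(shared: SharedKmerTable) -> dict[GroupKey, int]:
    """Number of shared k-mers carrying each distinct membership set.

    The counts sum to the shared-table size; filtering by a minimum count
    reproduces the "groups sharing at least m k-mers" summaries.
    """
    counts: Counter[GroupKey] = Counter(shared.entries.values())
    return dict(sorted(counts.items()))


def enumerate_congruent_groups(
    taxonomy: TaxonomyTable, sampled: Iterable[str] | None = None
) -> list[GroupKey]:
    """Groups of sampled genomes that coincide with a taxonomy node.

    For every taxon name occurring in any lineage, the set of sampled
    genomes whose lineage contains it forms a candidate group; candidates
    of size >= 2 are kept and identical leaf sets (taxa that collapse after
    sampling) are deduplicated.  The root taxon yields the group uniting
    all sampled genomes.
    """
    sampled_set = set(sampled) if sampled is not None else taxonomy.genome_ids
    unknown = sampled_set - taxonomy.genome_ids
    if unknown:
        raise ValueError(f"sampled genomes not in taxonomy: {sorted(unknown)}")
    taxa: dict[str, set[str]] = {}
    for gid in sampled_set:
        for taxon in taxonomy.lineage(gid):
            taxa.setdefault(taxon, set()).add(gid)
    groups = {frozenset(members) for members in taxa.values() if len(members) >= 2}
    return sorted(GroupKey(g) for g in groups)
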