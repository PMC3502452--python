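"""Localized de novo assembly of recruited read subsets.

Because read recruitment confines each subset to the neighbourhood of a few
informative k-mers, assembly is deliberately simple: a de Bruijn graph over
canonical k-mers, nodes below a coverage floor removed, and maximal
unambiguous paths (unitigs) emitted as contigs.  Removing low-coverage
nodes both suppresses residual error k-mers and trims the shallow contig
ends, which is why contigs centred on a single isolated variant come out
slightly shorter than twice the read length.  No bubble popping or
scaffolding is attempted — a bubble surfaces as two contigs.

Contigs are emitted in canonical orientation (the lexicographically smaller
of the sequence and its reverse complement) and the whole procedure is
deterministic given the reads and parameters.
"""

from __future__ import annotations

import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import edlib

from .formats_io import SequenceRecord
from .kmer_core import canonicalize, iter_canonical_kmers, reverse_complement
from .partition_groups import GroupKey
from .read_selection import ReadSubset

__all__ = [
    "AssemblyParams",
    "Contig",
    "ContigValidation",
    "ValidationReport",
    "assemble",
    "classify_contigs",
    "validate_contigs",
]


@dataclass
class AssemblyParams:
    """Assembly knobs.

    ``k_asm`` — odd de Bruijn word size (default: the pipeline k).
    ``min_node_coverage`` — nodes seen fewer times are removed (default 2).
    ``min_contig_length`` — shorter unitigs are discarded (default 80 bp).
    """

    k_asm: int = 21
    min_node_coverage: int = 2
    min_contig_length: int = 80

    def __post_init__(self) -> None:
        if self.k_asm % 2 == 0 or self.k_asm < 3:
            raise ValueError("k_asm must be an odd integer >= 3")
        if self.min_node_coverage < 1:
            raise ValueError("min_node_coverage must be >= 1")


@dataclass
class Contig:
    """A localized de novo assembly product."""

    sequence: str
    genome_id: str
    group_key: GroupKey
    mean_kmer_coverage: float = 0.0
    label: Optional[str] = None  # single_feature | long | other

    @property
    def length(self) -> int:
        return len(self.sequence)


_BASES = "ACGT"


def _successors(w: str, nodes: Mapping[str, int]) -> list[str]:
    stem = w[1:]
    out = []
    for b in _BASES:
        u = stem + b
        if canonicalize(u) in nodes:
            out.append(u)
    return out


def _predecessors(w: str, nodes: Mapping[str, int]) -> list[str]:
    stem = w[:-1]
    out = []
    for b in _BASES:
        u = b + stem
        if canonicalize(u) in nodes:
            out.append(u)
    return out


def _walk(w: str, nodes: Mapping[str, int], claimed: set) -> list[str]:
    """Extend w forward through unambiguous nodes, claiming canonical forms."""
    path = []
    while True:
        succ = _successors(w, nodes)
        if len(succ) != 1:
            break
        u = succ[0]
        if len(_predecessors(u, nodes)) != 1:
            break
        cu = canonicalize(u)
        if cu in claimed:
            break
        claimed.add(cu)
        path.append(u)
        w = u
    return path


def assemble(subset: ReadSubset, params: AssemblyParams | None = None) -> list[Contig]:
    """Assemble a read subset into unitig contigs.

    Builds the canonical de Bruijn graph at ``k_asm`` over the subset's
    reads, drops nodes with coverage below ``min_node_coverage``, and emits
    every maximal non-branching path whose sequence is at least
    ``min_contig_length`` long.  Deterministic given input order and params.
    """
    params = params or AssemblyParams()
    k = params.k_asm
    cov: Counter[str] = Counter()
    any_long_enough = False
    for rec in subset.reads:
        if len(rec.sequence) >= k:
            any_long_enough = True
            cov.update(iter_canonical_kmers(rec.sequence, k))
    if subset.reads and not any_long_enough:
        warnings.warn(
            f"{subset.genome_id}/{subset.group_key}: all reads shorter than "
            f"k_asm={k}; nothing to assemble",
            stacklevel=2,
        )
        return []
    nodes = {km: c for km, c in cov.items() if c >= params.min_node_coverage}
    contigs: list[Contig] = []
    claimed: set[str] = set()
    for seed in sorted(nodes):
        if seed in claimed:
            continue
        claimed.add(seed)
        fwd = _walk(seed, nodes, claimed)
        bwd = _walk(reverse_complement(seed), nodes, claimed)
        seq = (
            reverse_complement("".join(u[-1] for u in bwd))
            + seed
            + "".join(u[-1] for u in fwd)
        )
        if len(seq) < params.min_contig_length:
            continue
        path_nodes = [seed] + [canonicalize(u) for u in fwd + bwd]
        mean_cov = sum(nodes[n] for n in path_nodes) / len(path_nodes)
        rc = reverse_complement(seq)
        contigs.append(
            Contig(
                sequence=min(seq, rc),
                genome_id=subset.genome_id,
                group_key=subset.group_key,
                mean_kmer_coverage=mean_cov,
            )
        )
    return contigs


def classify_contigs(
    contigs: list[Contig],
    read_length: int,
    class_of_genome: Mapping[str, str] | None = None,
    long_fraction: float = 0.05,
    single_feature_slack: int = 10,
) -> dict[str, int]:
    """Label contigs as long / single_feature / other; return long cutoffs.

    Within each taxonomic class, the longest ``ceil(long_fraction * N)``
    contigs are "long" (hot-spots of locally dense variation).  Of the
    remainder, contigs no longer than twice the read length plus a small
    slack are "single_feature" — the signature of one isolated variant —
    and everything else is "other".  Returns the per-class minimum length
    among the long contigs.
    """
    by_class: dict[str, list[Contig]] = {}
    for contig in contigs:
        cls = (class_of_genome or {}).get(contig.genome_id, "all")
        by_class.setdefault(cls, []).append(contig)
    cutoffs: dict[str, int] = {}
    sf_max = 2 * read_length + single_feature_slack
    for cls, group in by_class.items():
        n_long = math.ceil(long_fraction * len(group))
        ranked = sorted(group, key=lambda c: (-c.length, c.sequence))
        for contig in ranked[:n_long]:
            contig.label = "long"
        for contig in ranked[n_long:]:
            contig.label = "single_feature" if contig.length <= sf_max else "other"
        if n_long:
            cutoffs[cls] = ranked[n_long - 1].length
    return cutoffs


@dataclass
class ContigValidation:
    contig: Contig
    identity: float  # percent, matches / alignment columns
    edit_distance: int
    exact: bool


@dataclass
class ValidationReport:
    rows: list[ContigValidation] = field(default_factory=list)

    @property
    def fraction_exact(self) -> float:
        if not self.rows:
            raise ValueError("no contigs to report on")
        return sum(r.exact for r in self.rows) / len(self.rows)

    @property
    def min_identity(self) -> float:
        if not self.rows:
            raise ValueError("no contigs to report on")
        return min(r.identity for r in self.rows)


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _identity_from_cigar(cigar: str) -> tuple[float, int]:
    matches = columns = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
    return 100.0 * matches / columns, columns


def validate_contigs(
    contigs: Iterable[Contig],
    reference: SequenceRecord,
    circular: bool = False,
) -> ValidationReport:
    """Best local-alignment identity of each contig against a reference.

    Both strands are tried (infix alignment, so a contig longer than the
    reference still gets its best overlap scored); identity is matches over
    alignment columns.  A contig is "exact" iff its best alignment has zero
    mismatches and zero gaps.  For circular references the target is
    extended across the origin so wrap-spanning contigs align contiguously.
    """
    contigs = list(contigs)
    target = reference.sequence
    if circular and contigs:
        target = target + target[: max(len(c.sequence) for c in contigs) - 1]
    report = ValidationReport()
    for contig in contigs:
        best = None
        for query in (contig.sequence, reverse_complement(contig.sequence)):
            res = edlib.align(query, target, mode="HW", task="path")
            if best is None or res["editDistance"] < best["editDistance"]:
                best = res
            if best["editDistance"] == 0:
                break
        identity, _ = _identity_from_cigar(best["cigar"])
        report.rows.append(
            ContigValidation(
                contig=contig,
                identity=identity,
                edit_distance=best["editDistance"],
                exact=best["editDistance"] == 0,
            )
        )
    return report
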