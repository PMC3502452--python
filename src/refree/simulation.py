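"""Synthetic quadripartite genomes, planted variants, and short-read
simulation with a ground-truth ledger.

The genome model mimics the circular chloroplast architecture: a large and
a small single-copy region separated by two inverted-repeat copies, with
IRB the exact reverse complement of IRA (so one IR copy contributes almost
no new canonical k-mers — only the handful spanning the junctions).
Genomes descend along a user-supplied phylogeny by planted substitutions,
indels and translocations, every one of which is recorded in a ledger of
exact coordinates and local contexts; replaying the ledger from the root
reproduces each leaf exactly, which is what makes the ledger usable as the
oracle in recovery tests.

Reads are uniform-start fragments (wrapping across the origin for circular
genomes) with a per-base substitution error model; no indel errors, GC
bias or quality profile are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import dendropy
import numpy as np

from .formats_io import SequenceRecord
from .kmer_core import reverse_complement

__all__ = [
    "GenomeModel",
    "VariantSpec",
    "LedgerEntry",
    "VariantLedger",
    "SimulationConfig",
    "make_genome",
    "apply_variant",
    "random_variant",
    "evolve_on_tree",
    "simulate_reads",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _ALPHABET[rng.integers(0, 4, n)].tobytes().decode()


@dataclass
class GenomeModel:
    """A synthetic genome with the quadripartite layout LSC+IRA+SSC+IRB.

    The region lengths describe the ancestral layout at construction time;
    after variants are applied they are kept as metadata only.
    """

    genome_id: str
    sequence: str
    lsc_len: int
    ssc_len: int
    ir_len: int
    circular: bool = True

    def __len__(self) -> int:
        return len(self.sequence)


def make_genome(
    lsc_len: int,
    ssc_len: int,
    ir_len: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    genome_id: str = "root",
    circular: bool = True,
) -> GenomeModel:
    """Build a random quadripartite genome; IRB is derived from IRA.

    Deterministic per seed; total length is lsc+ssc+2*ir.
    """
    if min(lsc_len, ssc_len, ir_len) < 0:
        raise ValueError("region lengths must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    lsc = _random_dna(rng, lsc_len)
    ira = _random_dna(rng, ir_len)
    ssc = _random_dna(rng, ssc_len)
    sequence = lsc + ira + ssc + reverse_complement(ira)
    return GenomeModel(
        genome_id=genome_id,
        sequence=sequence,
        lsc_len=lsc_len,
        ssc_len=ssc_len,
        ir_len=ir_len,
        circular=circular,
    )


@dataclass(frozen=True)
class VariantSpec:
    """A concrete planted variant (0-based position, half-open intervals).

    ``length`` is the inserted/deleted length for indels and the segment
    length for translocations; ``dest`` is the destination offset of a
    translocated segment, interpreted on the sequence after excision.
    """

    vtype: str  # snp | insertion | deletion | translocation
    position: int
    length: Optional[int] = None
    alt_base: Optional[str] = None
    insert_seq: Optional[str] = None
    dest: Optional[int] = None

    def __post_init__(self) -> None:
        if self.vtype not in {"snp", "insertion", "deletion", "translocation"}:
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if self.vtype in {"insertion", "deletion", "translocation"}:
            if self.length is None or self.length < 1:
                raise ValueError(f"{self.vtype} requires length >= 1")


@dataclass
class LedgerEntry:
    node_id: str
    variant: VariantSpec
    before_context: str
    after_context: str


@dataclass
class VariantLedger:
    """Ground truth: every planted variant plus the root-to-leaf paths.

    ``paths`` maps each leaf to the ordered node ids of its root-to-leaf
    path; entries applied along that path, in order, transform the root
    sequence into the leaf sequence exactly (see :meth:`replay`).
    """

    entries: list[LedgerEntry] = field(default_factory=list)
    paths: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def entries_for(self, node_id: str) -> list[LedgerEntry]:
        return [e for e in self.entries if e.node_id == node_id]

    def replay(self, root: GenomeModel) -> dict[str, GenomeModel]:
        leaves = {}
        for leaf, path in self.paths.items():
            genome = replace(root, genome_id=leaf)
            for node_id in path:
                for entry in self.entries_for(node_id):
                    genome, _ = apply_variant(genome, entry.variant)
            leaves[leaf] = genome
        return leaves


_CONTEXT_FLANK = 30


def _context(seq: str, lo: int, hi: int) -> str:
    return seq[max(0, lo - _CONTEXT_FLANK) : hi + _CONTEXT_FLANK]


def apply_variant(
    genome: GenomeModel, variant: VariantSpec
) -> tuple[GenomeModel, LedgerEntry]:
    """Apply one variant, returning the mutated genome and a ledger entry.

    SNPs substitute to a different base; insertions add ``insert_seq`` at
    the position; deletions remove ``length`` bases; translocations excise
    a segment and reinsert it at ``dest``, creating novel junctions at both
    sites.  Deleting then reinserting the same bases is the identity.
    """
    seq = genome.sequence
    p = variant.position
    if not 0 <= p < len(seq):
        raise ValueError(f"position {p} outside genome of length {len(seq)}")
    if variant.vtype == "snp":
        alt = variant.alt_base
        if alt is None or alt == seq[p]:
            raise ValueError("snp requires alt_base different from the reference base")
        new = seq[:p] + alt + seq[p + 1 :]
        entry = LedgerEntry("", variant, _context(seq, p, p + 1), _context(new, p, p + 1))
    elif variant.vtype == "insertion":
        ins = variant.insert_seq
        if ins is None or len(ins) != variant.length:
            raise ValueError("insertion requires insert_seq of the stated length")
        new = seq[:p] + ins + seq[p:]
        entry = LedgerEntry(
            "", variant, _context(seq, p, p), _context(new, p, p + len(ins))
        )
    elif variant.vtype == "deletion":
        if p + variant.length > len(seq):
            raise ValueError("deletion runs off the end of the genome")
        new = seq[:p] + seq[p + variant.length :]
        entry = LedgerEntry(
            "", variant, _context(seq, p, p + variant.length), _context(new, p, p)
        )
    else:  # translocation
        if p + variant.length > len(seq):
            raise ValueError("translocated segment runs off the end of the genome")
        if variant.dest is None:
            raise ValueError("translocation requires dest")
        segment = seq[p : p + variant.length]
        remainder = seq[:p] + seq[p + variant.length :]
        d = variant.dest
        if not 0 <= d <= len(remainder):
            raise ValueError(f"dest {d} outside post-excision sequence")
        new = remainder[:d] + segment + remainder[d:]
        entry = LedgerEntry(
            "",
            variant,
            _context(seq, p, p + variant.length),
            _context(new, d, d + variant.length),
        )
    return replace(genome, sequence=new), entry


def random_variant(
    rng: np.random.Generator,
    genome: GenomeModel,
    vtype: str,
    indel_len: tuple[int, int] = (1, 8),
    position: Optional[int] = None,
) -> VariantSpec:
    """Draw a concrete, legal variant of the given type."""
    G = len(genome.sequence)
    if vtype == "snp":
        p = int(rng.integers(0, G)) if position is None else position
        ref = genome.sequence[p]
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        return VariantSpec("snp", p, alt_base=alt)
    i = int(rng.integers(indel_len[0], indel_len[1] + 1))
    if vtype == "insertion":
        p = int(rng.integers(0, G)) if position is None else position
        return VariantSpec("insertion", p, length=i, insert_seq=_random_dna(rng, i))
    if vtype == "deletion":
        p = int(rng.integers(0, G - i)) if position is None else position
        return VariantSpec("deletion", p, length=i)
    if vtype == "translocation":
        seg = int(rng.integers(200, 1001))
        p = int(rng.integers(0, G - seg)) if position is None else position
        d = int(rng.integers(0, G - seg))
        return VariantSpec("translocation", p, length=seg, dest=d)
    raise ValueError(f"unknown variant type {vtype!r}")


def _node_id(node: dendropy.Node, counter: list[int]) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    counter[0] += 1
    return f"node{counter[0]}"


def evolve_on_tree(
    root: GenomeModel,
    tree: str,
    variants_per_branch: int | Mapping[str, int],
    seed: Optional[int] = None,
    vtype_weights: Mapping[str, float] | None = None,
    indel_len: tuple[int, int] = (1, 8),
    min_spacing: int = 0,
) -> tuple[dict[str, GenomeModel], VariantLedger]:
    """Descend the root genome along a newick tree with planted variants.

    ``variants_per_branch`` is a count applied to every branch, or a map
    from (child) node id to count.  ``min_spacing`` keeps planted positions
    at least that many bases apart across the *whole* tree — exact when
    only substitutions are drawn (coordinates are stable), best-effort once
    indels or translocations shift coordinates.  Deterministic per seed.
    """
    try:
        phylo = dendropy.Tree.get(data=tree, schema="newick")
    except Exception as exc:
        raise ValueError(f"malformed newick tree: {exc}") from exc
    rng = np.random.default_rng(seed)
    weights = dict(vtype_weights or {"snp": 1.0})
    vtypes = sorted(weights)
    probs = np.array([weights[v] for v in vtypes], dtype=float)
    probs /= probs.sum()

    counter = [0]
    ids: dict[int, str] = {}
    for node in phylo.preorder_node_iter():
        ids[id(node)] = _node_id(node, counter)

    used_positions: list[int] = []

    def draw_position(rng, G) -> int:
        for _ in range(10_000):
            p = int(rng.integers(0, G))
            if all(abs(p - q) >= min_spacing for q in used_positions):
                used_positions.append(p)
                return p
        raise RuntimeError("could not place a variant respecting min_spacing")

    ledger = VariantLedger()
    genomes: dict[int, GenomeModel] = {id(phylo.seed_node): root}
    leaves: dict[str, GenomeModel] = {}
    for node in phylo.preorder_node_iter():
        nid = ids[id(node)]
        if node.parent_node is None:
            genome = root
        else:
            genome = genomes[id(node.parent_node)]
            if isinstance(variants_per_branch, Mapping):
                n_var = variants_per_branch.get(nid, 0)
            else:
                n_var = variants_per_branch
            for _ in range(n_var):
                vtype = vtypes[rng.choice(len(vtypes), p=probs)]
                pos = draw_position(rng, len(genome.sequence)) if min_spacing else None
                variant = random_variant(rng, genome, vtype, indel_len, position=pos)
                genome, entry = apply_variant(genome, variant)
                entry.node_id = nid
                ledger.entries.append(entry)
        genomes[id(node)] = genome
        if node.is_leaf():
            leaves[nid] = replace(genome, genome_id=nid)
            path = []
            n = node
            while n.parent_node is not None:
                path.append(ids[id(n)])
                n = n.parent_node
            ledger.paths[nid] = tuple(reversed(path))
    return leaves, ledger


@dataclass
class SimulationConfig:
    """Short-read simulation settings (51 bp at 20x by default)."""

    read_len: int = 51
    coverage: float = 20.0
    error_rate: float = 0.05
    paired: bool = False
    insert_mean: int = 300
    insert_sd: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.paired and self.insert_mean < self.read_len:
            raise ValueError("insert_mean must be at least read_len in paired mode")


def _decode_rows(mat: np.ndarray) -> list[str]:
    raw = _ALPHABET[mat].tobytes()
    L = mat.shape[1]
    return [raw[i * L : (i + 1) * L].decode() for i in range(mat.shape[0])]


def _apply_errors(mat: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return mat
    mask = rng.random(mat.shape) < rate
    shift = rng.integers(1, 4, mat.shape)
    return np.where(mask, (mat + shift) % 4, mat)


def simulate_reads(
    genome: GenomeModel, config: SimulationConfig
) -> list[SequenceRecord]:
    """Simulate uniform-coverage short reads from a genome.

    The read count is round(G * coverage / read_len); paired mode emits
    half that many fragments, two reads each.  Start positions are uniform
    (wrapping across the origin when the genome is circular), strands are
    random, and each base is substituted with probability ``error_rate`` to
    a uniformly chosen different base.  Reverse-strand reads are emitted as
    reverse complements.  Read descriptions carry the true start/strand for
    provenance-based tests.
    """
    rng = np.random.default_rng(config.seed)
    seq = genome.sequence
    G = len(seq)
    L = config.read_len
    if G < L:
        raise ValueError("genome shorter than read length")
    code = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n_reads = round(G * config.coverage / L)
    records: list[SequenceRecord] = []
    offsets = np.arange(L)

    if not config.paired:
        starts = rng.integers(0, G if genome.circular else G - L + 1, n_reads)
        strands = rng.integers(0, 2, n_reads)
        mat = code[(starts[:, None] + offsets) % G]
        rev = strands == 1
        mat[rev] = 3 - mat[rev][:, ::-1]
        mat = _apply_errors(mat, config.error_rate, rng)
        for i, read in enumerate(_decode_rows(mat)):
            records.append(
                SequenceRecord(
                    id=f"{genome.genome_id}_r{i}",
                    sequence=read,
                    quality="I" * L,
                    description=f"start={starts[i]};strand={'-' if strands[i] else '+'}",
                )
            )
        return records

    n_pairs = n_reads // 2
    inserts = np.rint(rng.normal(config.insert_mean, config.insert_sd, n_pairs))
    inserts = np.clip(inserts, L, G).astype(np.int64)
    if genome.circular:
        starts = rng.integers(0, G, n_pairs)
    else:
        starts = rng.integers(0, np.maximum(G - inserts + 1, 1))
    strands = rng.integers(0, 2, n_pairs)
    end1 = code[(starts[:, None] + offsets) % G]
    tail = starts + inserts - L
    end2 = 3 - code[(tail[:, None] + offsets) % G][:, ::-1]
    flip = strands == 1
    end1[flip], end2[flip] = end2[flip], end1[flip].copy()
    end1 = _apply_errors(end1, config.error_rate, rng)
    end2 = _apply_errors(end2, config.error_rate, rng)
    reads1 = _decode_rows(end1)
    reads2 = _decode_rows(end2)
    for i in range(n_pairs):
        pid = f"{genome.genome_id}_p{i}"
        desc = (
            f"start={starts[i]};insert={inserts[i]};"
            f"strand={'-' if strands[i] else '+'}"
        )
        for mate, read in ((1, reads1[i]), (2, reads2[i])):
            records.append(
                SequenceRecord(
                    id=f"{pid}/{mate}",
                    sequence=read,
                    quality="I" * L,
                    description=desc,
                    mate=mate,
                    pair_id=pid,
                )
            )
    return records
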