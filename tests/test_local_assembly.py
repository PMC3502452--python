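"""Unitig assembly, contig classification and reference validation."""

import numpy as np
import pytest

from refree.formats_io import SequenceRecord
from refree.kmer_core import reverse_complement
from refree.local_assembly import (
    AssemblyParams,
    Contig,
    assemble,
    classify_contigs,
    validate_contigs,
)
from refree.partition_groups import GroupKey, build_tip_and_shared
from refree.read_selection import ReadSubset, select_reads
from refree.simulation import (
    SimulationConfig,
    VariantSpec,
    apply_variant,
    make_genome,
    simulate_reads,
)


def _subset(seqs, gid="g"):
    return ReadSubset(
        genome_id=gid,
        group_key=GroupKey([gid]),
        reads=[SequenceRecord(id=f"r{i}", sequence=s) for i, s in enumerate(seqs)],
    )


def _params(**kw):
    defaults = dict(k_asm=5, min_node_coverage=1, min_contig_length=5)
    defaults.update(kw)
    return AssemblyParams(**defaults)


class TestAssemble:
    def test_tiling_reads_reconstruct_source(self):
        source = "ACGGTCCAT"
        reads = [source[i : i + 5] for i in range(5)]
        contigs = assemble(_subset(reads), _params(k_asm=4 + 1))
        assert len(contigs) == 1
        assert contigs[0].sequence in (source, reverse_complement(source))

    def test_two_disjoint_loci_give_two_contigs(self):
        # loci chosen with no canonical (k-1)-overlap between their k-mers,
        # so the graph has exactly two components
        locus1 = "GGTTCCCTAC"
        locus2 = "ACTGCTGTAC"
        reads = [locus1[i : i + 5] for i in range(6)] + \
                [locus2[i : i + 5] for i in range(6)]
        contigs = assemble(_subset(reads), _params())
        assert len(contigs) == 2
        recovered = {c.sequence for c in contigs}
        expected = {min(s, reverse_complement(s)) for s in (locus1, locus2)}
        assert recovered == expected

    def test_low_coverage_nodes_trimmed(self):
        # middle of the locus covered twice, ends only once
        locus = "ACGGTCCATAGTT"
        reads = [locus[0:9], locus[2:11], locus[4:13]]
        contigs = assemble(
            _subset(reads), _params(min_node_coverage=2, min_contig_length=5)
        )
        assert len(contigs) == 1
        inner = contigs[0].sequence
        assert inner in locus or reverse_complement(inner) in locus
        assert len(inner) < len(locus)

    def test_all_reads_shorter_than_k_warns(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert assemble(_subset(["ACG", "TTT"]), _params()) == []

    def test_min_contig_length_filter(self):
        reads = ["ACGGTCCAT"]
        assert assemble(_subset(reads), _params(min_contig_length=50)) == []

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(30)]
        reads = [s[i : i + 12] for s in seqs for i in range(0, 25, 3)]
        a = assemble(_subset(reads), _params(k_asm=7))
        b = assemble(_subset(list(reads)), _params(k_asm=7))
        assert [(c.sequence, c.mean_kmer_coverage) for c in a] == [
            (c.sequence, c.mean_kmer_coverage) for c in b
        ]

    def test_emitted_contig_kmers_meet_coverage_floor(self):
        rng = np.random.default_rng(1)
        source = "".join(rng.choice(list("ACGT"), size=200))
        reads = [source[i : i + 30] for i in range(0, 170, 4)]
        params = _params(k_asm=11, min_node_coverage=2, min_contig_length=20)
        cov = {}
        from refree.kmer_core import iter_canonical_kmers

        for r in reads:
            for km in iter_canonical_kmers(r, 11):
                cov[km] = cov.get(km, 0) + 1
        for contig in assemble(_subset(reads), params):
            for km in iter_canonical_kmers(contig.sequence, 11):
                assert cov[km] >= 2

    def test_single_feature_contig_around_planted_snp(self):
        """20x error-free 51 bp reads around one isolated SNP assemble into
        one tip contig containing the alt allele, at most 2*51-1 bp long."""
        genome = make_genome(4000, 1000, 1200, seed=13, genome_id="A")
        pos = 2500
        ref = genome.sequence[pos]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        mutant, entry = apply_variant(genome, VariantSpec("snp", pos, alt_base=alt))
        reads_a = simulate_reads(
            mutant, SimulationConfig(read_len=51, coverage=20.0, error_rate=0.0,
                                     paired=False, seed=21),
        )
        reads_b = simulate_reads(
            genome, SimulationConfig(read_len=51, coverage=20.0, error_rate=0.0,
                                     paired=False, seed=22),
        )
        from refree.kmer_core import count_kmers

        tables = [count_kmers(reads_a, genome_id="A"),
                  count_kmers(reads_b, genome_id="B")]
        tips, _ = build_tip_and_shared(tables)
        subset = select_reads(reads_a, tips["A"], k=21, genome_id="A")
        contigs = assemble(subset, AssemblyParams())
        snp_contigs = [c for c in contigs if entry.after_context[10:-10] in c.sequence
                       or entry.after_context[10:-10]
                       in reverse_complement(c.sequence)]
        assert len(snp_contigs) == 1
        assert snp_contigs[0].length <= 2 * 51 - 1


class TestClassifyContigs:
    def _contigs(self, lengths, gid="g"):
        return [
            Contig(sequence="A" * n, genome_id=gid, group_key=GroupKey([gid]))
            for n in lengths
        ]

    def test_longest_five_percent_are_long(self):
        contigs = self._contigs(range(1, 101))
        cutoffs = classify_contigs(contigs, read_length=51)
        longs = sorted(c.length for c in contigs if c.label == "long")
        assert longs == [96, 97, 98, 99, 100]
        assert cutoffs == {"all": 96}

    def test_single_contig_class_is_long_by_ceiling(self):
        contigs = self._contigs([90])
        classify_contigs(contigs, read_length=51)
        assert contigs[0].label == "long"

    def test_short_contig_is_single_feature(self):
        contigs = self._contigs([102, 150, 400])
        classify_contigs(contigs, read_length=51)
        by_len = {c.length: c.label for c in contigs}
        assert by_len[400] == "long"
        assert by_len[102] == "single_feature"  # <= 2*51 + slack
        assert by_len[150] == "other"

    def test_classes_ranked_independently(self):
        contigs = self._contigs([100, 200], gid="g1") + \
                  self._contigs([300, 400], gid="g2")
        cutoffs = classify_contigs(
            contigs, read_length=51,
            class_of_genome={"g1": "mosses", "g2": "ferns"},
        )
        assert cutoffs == {"mosses": 200, "ferns": 400}


class TestValidateContigs:
    def _contig(self, seq):
        return Contig(sequence=seq, genome_id="g", group_key=GroupKey(["g"]))

    def test_exact_substring_is_100_percent(self, small_genome):
        ref = SequenceRecord(id="r", sequence=small_genome.sequence)
        sub = small_genome.sequence[100:300]
        report = validate_contigs([self._contig(sub)], ref)
        assert report.rows[0].identity == 100.0 and report.rows[0].exact

    def test_reverse_complement_also_exact(self, small_genome):
        ref = SequenceRecord(id="r", sequence=small_genome.sequence)
        sub = reverse_complement(small_genome.sequence[100:300])
        report = validate_contigs([self._contig(sub)], ref)
        assert report.rows[0].exact

    def test_single_mismatch_in_100_is_99_percent(self, small_genome):
        ref = SequenceRecord(id="r", sequence=small_genome.sequence)
        sub = list(small_genome.sequence[500:600])
        sub[50] = "A" if sub[50] != "A" else "C"
        report = validate_contigs([self._contig("".join(sub))], ref)
        assert report.rows[0].identity == pytest.approx(99.0)
        assert not report.rows[0].exact
        assert report.min_identity == pytest.approx(99.0)

    def test_contig_longer_than_reference_still_scored(self):
        ref = SequenceRecord(id="r", sequence="ACGGTCCATT")
        report = validate_contigs([self._contig("ACGGTCCATT" + "AAAAA")], ref)
        assert 0 < report.rows[0].identity < 100

    def test_circular_wrap_contig_aligns_contiguously(self, small_genome):
        seq = small_genome.sequence
        wrap = seq[-80:] + seq[:80]
        ref = SequenceRecord(id="r", sequence=seq)
        linear = validate_contigs([self._contig(wrap)], ref, circular=False)
        circular = validate_contigs([self._contig(wrap)], ref, circular=True)
        assert circular.rows[0].exact
        assert circular.rows[0].identity >= linear.rows[0].identity
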