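"""Quadripartite genome construction, variant planting, descent along a
tree with a replayable ledger, and read-simulation calibration."""

import pytest
from scipy import stats

from refree.kmer_core import (
    count_kmers_from_sequence,
    distinct_kmer_count,
    reverse_complement,
)
from refree.simulation import (
    SimulationConfig,
    VariantSpec,
    apply_variant,
    evolve_on_tree,
    make_genome,
    simulate_reads,
)

TREE = "((A:1,B:1):1,(C:1,D:1):1);"


class TestMakeGenome:
    def test_quadripartite_layout(self):
        g = make_genome(50000, 14000, 18000, seed=1)
        assert len(g.sequence) == 50000 + 14000 + 2 * 18000
        ira = g.sequence[50000 : 50000 + 18000]
        irb = g.sequence[-18000:]
        assert irb == reverse_complement(ira)

    def test_deterministic_per_seed(self):
        assert make_genome(1000, 300, 400, seed=5).sequence == \
               make_genome(1000, 300, 400, seed=5).sequence
        assert make_genome(1000, 300, 400, seed=5).sequence != \
               make_genome(1000, 300, 400, seed=6).sequence

    def test_ir_duplication_suppresses_kmer_diversity(self):
        """One IR copy contributes only junction k-mers: distinct 21-mers
        ~= G - ir_len, the duplicated-fraction regime."""
        g = make_genome(50000, 14000, 18000, seed=2)
        table = count_kmers_from_sequence(g.sequence, k=21)
        expected = 50000 + 14000 + 18000  # single-copy content
        assert abs(distinct_kmer_count(table) - expected) <= 2 * 20 + 10

    def test_no_ir_gives_one_to_one_ratio(self):
        g = make_genome(5000, 1400, 0, seed=3)
        table = count_kmers_from_sequence(g.sequence, k=21)
        assert distinct_kmer_count(table) == len(g.sequence) - 20


class TestApplyVariant:
    def test_snp_is_hamming_one(self, small_genome):
        ref = small_genome.sequence[100]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        mutant, entry = apply_variant(
            small_genome, VariantSpec("snp", 100, alt_base=alt)
        )
        diffs = sum(a != b for a, b in zip(mutant.sequence, small_genome.sequence))
        assert diffs == 1 and len(mutant.sequence) == len(small_genome.sequence)
        assert entry.after_context != entry.before_context

    def test_insertion_grows_by_i(self, small_genome):
        mutant, _ = apply_variant(
            small_genome, VariantSpec("insertion", 50, length=5, insert_seq="ACGTA")
        )
        assert len(mutant.sequence) == len(small_genome.sequence) + 5

    def test_deletion_insertion_inverse_pair(self, small_genome):
        deleted, entry = apply_variant(
            small_genome, VariantSpec("deletion", 200, length=7)
        )
        removed = small_genome.sequence[200:207]
        restored, _ = apply_variant(
            deleted, VariantSpec("insertion", 200, length=7, insert_seq=removed)
        )
        assert restored.sequence == small_genome.sequence

    def test_translocation_moves_segment(self, small_genome):
        mutant, _ = apply_variant(
            small_genome, VariantSpec("translocation", 100, length=50, dest=3000)
        )
        assert len(mutant.sequence) == len(small_genome.sequence)
        assert mutant.sequence != small_genome.sequence
        assert sorted(mutant.sequence) == sorted(small_genome.sequence)

    def test_out_of_range_rejected(self, small_genome):
        with pytest.raises(ValueError):
            apply_variant(small_genome, VariantSpec("snp", 10**7, alt_base="A"))


class TestEvolveOnTree:
    def test_zero_rates_leaves_identical(self, small_genome):
        leaves, ledger = evolve_on_tree(small_genome, TREE, 0, seed=1)
        assert set(leaves) == {"A", "B", "C", "D"}
        assert all(g.sequence == small_genome.sequence for g in leaves.values())
        assert ledger.entries == []

    def test_single_snp_gains_k_tip_kmers(self):
        """One SNP on A's branch creates exactly k new k-mers in A, and the
        k replaced k-mers become exclusive to the other genomes.  (The root
        has no IR so every position is single-copy.)"""
        from refree.kmer_core import count_kmers_from_sequence
        from refree.partition_groups import GroupKey, build_tip_and_shared

        k = 21
        root = make_genome(5000, 1400, 0, seed=7)
        leaves, ledger = evolve_on_tree(
            root, TREE, {"A": 1}, seed=8, min_spacing=1
        )
        tables = [
            count_kmers_from_sequence(leaves[g].sequence, k=k, circular=True,
                                      genome_id=g)
            for g in sorted(leaves)
        ]
        tips, shared = build_tip_and_shared(tables)
        assert len(tips["A"]) == k
        assert tips["B"] == tips["C"] == tips["D"] == set()
        replaced = [km for km, key in shared.entries.items()
                    if key == GroupKey("BCD")]
        assert len(replaced) == k

    def test_internal_branch_variant_lands_in_descendant_group(self):
        from refree.kmer_core import count_kmers_from_sequence
        from refree.partition_groups import GroupKey, build_tip_and_shared

        # one SNP on the internal branch above (A,B); IR-free root
        root = make_genome(5000, 1400, 0, seed=7)
        leaves, ledger = evolve_on_tree(
            root, "((A:1,B:1)ab:1,(C:1,D:1)cd:1);", {"ab": 1}, seed=9
        )
        assert len(ledger.entries) == 1
        tables = [
            count_kmers_from_sequence(leaves[g].sequence, k=21, circular=True,
                                      genome_id=g)
            for g in sorted(leaves)
        ]
        tips, shared = build_tip_and_shared(tables)
        ab_excl = {km for km, key in shared.entries.items() if key == GroupKey("AB")}
        assert len(ab_excl) == 21
        assert all(len(tips[g]) == 0 for g in "ABCD")

    def test_ledger_replay_reproduces_leaves(self, small_genome):
        leaves, ledger = evolve_on_tree(
            small_genome, TREE, 5, seed=10,
            vtype_weights={"snp": 0.6, "insertion": 0.2, "deletion": 0.2},
        )
        replayed = ledger.replay(small_genome)
        for gid, genome in leaves.items():
            assert replayed[gid].sequence == genome.sequence

    def test_malformed_newick_rejected(self, small_genome):
        with pytest.raises(ValueError, match="newick"):
            evolve_on_tree(small_genome, "((A,B);;", 1, seed=1)

    def test_min_spacing_respected_for_snps(self, small_genome):
        _, ledger = evolve_on_tree(
            small_genome, TREE, 5, seed=11, min_spacing=150
        )
        positions = sorted(e.variant.position for e in ledger.entries)
        gaps = [b - a for a, b in zip(positions, positions[1:])]
        assert min(gaps) >= 150


class TestSimulateReads:
    def test_read_count_formula(self, small_genome):
        cfg = SimulationConfig(read_len=51, coverage=20.0, error_rate=0.0,
                               paired=True, seed=1)
        reads = simulate_reads(small_genome, cfg)
        G = len(small_genome.sequence)
        assert len(reads) == 2 * (round(G * 20.0 / 51) // 2)
        total = sum(len(r.sequence) for r in reads)
        assert abs(total / G - 20.0) / 20.0 < 0.01  # coverage conservation

    def test_error_free_reads_are_substrings(self, small_genome, small_reads):
        doubled = small_genome.sequence * 2
        doubled_rc = reverse_complement(doubled)
        for read in small_reads[:500]:
            assert read.sequence in doubled or read.sequence in doubled_rc

    def test_mates_and_pair_ids(self, small_reads):
        assert small_reads[0].mate == 1 and small_reads[1].mate == 2
        assert small_reads[0].pair_id == small_reads[1].pair_id

    def test_deterministic_per_seed(self, small_genome):
        cfg = SimulationConfig(seed=42, error_rate=0.05)
        a = simulate_reads(small_genome, cfg)
        b = simulate_reads(small_genome, cfg)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_error_rate_calibration_within_binomial_ci(self, small_genome):
        """Observed mismatch fraction against the source must sit inside the
        99% binomial interval around the nominal 5% substitution rate."""
        cfg = SimulationConfig(read_len=51, coverage=20.0, error_rate=0.05,
                               paired=False, seed=33)
        reads = simulate_reads(small_genome, cfg)
        G = len(small_genome.sequence)
        doubled = small_genome.sequence + small_genome.sequence
        mismatches = bases = 0
        for read in reads:
            fields = dict(f.split("=") for f in read.description.split(";"))
            start = int(fields["start"])
            truth = doubled[start : start + 51]
            if fields["strand"] == "-":
                truth = reverse_complement(truth)
            mismatches += sum(a != b for a, b in zip(read.sequence, truth))
            bases += 51
        lo, hi = stats.binom.interval(0.99, bases, 0.05)
        assert lo <= mismatches <= hi

    def test_paired_insert_shorter_than_read_rejected(self, small_genome):
        with pytest.raises(ValueError, match="insert_mean"):
            SimulationConfig(read_len=51, paired=True, insert_mean=30)
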