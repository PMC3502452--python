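# Methods

## The model

`refree` compares many genomes directly from unassembled short-read data.
All analysis is carried out on canonical k-mers: a length-k word and its
reverse complement are equated by keeping whichever sorts first
alphabetically (A < C < G < T).  k must be odd, so no word equals its own
reverse complement and the choice is always strict.  The pipeline has four
stages:

1. **Count.**  Each genome's reads become a sorted frequency table of
   canonical k-mers (default k = 21).  Counts sum occurrences of both
   orientations; windows containing N are skipped.  A frequency threshold
   (default 3) is applied after counting and screens out most k-mers
   created by random sequencing error: at ~20x coverage a true k-mer is
   seen ~12 times while a one-off error k-mer is seen once or twice.
2. **Partition.**  A single-pass multiway merge over the sorted tables
   splits the union of k-mers into per-genome *tip* sets (k-mers observed
   in exactly one genome) and a *shared* table annotating every remaining
   k-mer with its exact membership — the set of genomes carrying it.
   Groups of genomes can be queried in two modes: *exclusive* (membership
   equals the group; absent from all non-members) or *inclusive* (present
   in all members, other genomes ignored; the intersection of member
   tables, so results for larger groups can be composed from pairwise
   ones).  Membership is stored once per k-mer and group files are
   materialized on demand, avoiding the storage blowup of precomputing all
   intersections.
3. **Select.**  For each tip or group k-mer set, the reads containing at
   least one canonical k-mer of the set are recruited, keeping each
   genome's reads separate.  Matching is strand-insensitive; a single hit
   suffices.  Optional mate rescue pulls in the partner of a selected
   paired read (off by default — it only improves contiguity and the
   conservative behaviour is easier to reason about).
4. **Assemble.**  Each recruited subset is assembled by a small canonical
   de Bruijn unitig assembler: nodes below a coverage floor
   (`min_node_coverage`, default 2) are removed, maximal non-branching
   paths are emitted, and contigs shorter than `min_contig_length`
   (default 80 bp) are discarded.  No bubble popping or scaffolding: read
   subsets are tiny and locally simple, and a bubble simply surfaces as
   two contigs.  Contigs are emitted in canonical orientation
   (lexicographically smaller of sequence/reverse complement), making the
   whole stage deterministic.  Removing low-coverage end nodes is what
   makes a contig centred on one isolated variant come out slightly
   shorter than twice the read length (~90–110 bp for 51 bp reads).

### Variant k-mer arithmetic

For a variant with non-repetitive flanks the number of k-mers that
distinguish the mutant from the reference has closed forms: a substitution
is covered by exactly k windows, with per-base window coverage peaking at
k on the variant base; a novel junction (translocation or inversion
breakpoint, or a deletion seen from the deleted genome) by k−1 windows
with a two-base plateau at the maximum; an insertion of length i by
k+i−1 windows, the coverage plateau of height k extending across the i
inserted bases.  These formulas presuppose an unambiguous placement: if an
insertion begins with the same base as the sequence that follows it (or a
junction juxtaposes a base identical to the original neighbour), the
placement can slide and one of the "novel" windows already exists in the
reference.  Repetitive flanks can likewise collide novel windows away.
The package therefore also provides the empirical enumeration
(`novel_kmer_windows`), which is the ground truth in such contexts and the
oracle the test suite checks the formulas against.

### Genome size and k-mer diversity

For a genome whose only large duplication is the inverted repeat, the
distinct-k-mer count is ≈ G − ir (the second IR copy contributes only the
≤ 2(k−1) windows spanning its junctions), so plotting diversity against
genome size for many genomes gives a line whose slope is one minus the
duplicated fraction.  `diversity_regression` fits this by ordinary least
squares over the IR-carrying genomes only (genomes without an IR sit on
the 1:1 line) and reports residuals for every point so outliers can be
flagged.  `frequency_spectrum_summary` reports mean, max and max/mean of
table counts — a large ratio indicates proliferation of repeats shorter
than k, a ratio near 1 indicates long duplications.

## The synthetic-data generator

`make_genome` builds a circular quadripartite genome — LSC + IRA + SSC +
IRB with IRB the exact reverse complement of IRA — from uniform random
single-copy sequence.  The default study genome is 100 kb: 50 kb LSC,
14 kb SSC and 18 kb IR (18% of the genome duplicated, the conserved
chloroplast regime).  `evolve_on_tree` descends the root along a newick
phylogeny, planting substitutions, indels and translocations per branch;
every event is recorded in a ledger with exact coordinates and before/after
contexts, and replaying the ledger from the root reproduces each leaf
exactly — which is what makes the ledger usable as the oracle in recovery
tests.  A `min_spacing` option keeps planted positions pairwise separated
(exact for substitution-only histories, where coordinates are stable;
best-effort once indels shift coordinates).

`simulate_reads` draws round(G·coverage/read_len) reads (half that many
fragments in paired mode) with uniform starts, wrapping across the origin
of circular genomes, random strand, and a uniform per-base substitution
error: each base is replaced with probability `error_rate` by a uniformly
chosen different base.  Defaults are 51 bp, 20x, paired with a 300 ± 30 bp
insert.  Deliberately not modelled: indel errors, quality ramps, GC bias,
amplification artifacts, heteroplasmy.  Tests passing on this generator
therefore demonstrate the pipeline's behaviour under idealized uniform
noise, not under a real instrument's error profile (see Limitations).

## Benchmark conditions

`pipeline.synthetic_validation_run` — used by `scripts/acceptance.py` and
the acceptance tests — fixes the desk-scale study: four 100 kb genomes on
a balanced 4-leaf tree, 50 isolated substitutions per terminal branch at
min spacing 120 bp (more than two read lengths, so single-feature contigs
cannot merge), 51 bp pairs at 20x, k = 21, threshold 3, assembly floor 2,
minimum contig 80 bp; three seeded replicates per condition.  Group
contigs are assembled for every observed membership sharing at least 100
exclusive k-mers — at this scale that is the all-genomes backbone plus the
three-genome complement of each terminal branch (a filter of the same kind
as the shared-k-mer cutoff used for large real comparisons, scaled to four
genomes).  Every contig is aligned back to its known source genome with
edlib (infix alignment, both strands, origin-extended target for circular
sources); identity is matches over alignment columns and "exact" means
zero mismatches and zero gaps.

## Numerical and design choices

- Thresholding after full counting (not during) keeps surviving counts
  exact and deterministic.
- Ties at branch nodes stop the unitig; no greedy extension, so emitted
  paths are unambiguous by construction.
- Unitig seeds are visited in sorted k-mer order; with the canonical
  orientation rule the contig FASTA is byte-identical across reruns.
- Coordinates are 0-based with half-open intervals throughout the ledger;
  positions refer to the genome state at the moment a variant is applied.
- Deletion spans are reported junction-like (k−1) from the carrier's side;
  the k+i−1 form describes the genome retaining the insertion.
- Circular k-mer counting appends the first k−1 bases before counting,
  adding exactly the origin-spanning windows.
- An `--external-assembler` style hook is deliberately absent from v1;
  the internal unitig assembler is the contract, and any de novo
  assembler could be substituted upstream of `validate_contigs`.

## Limitations

- **Uniform high error fragments single-feature contigs.**  Under the 5%
  uniform substitution model, the probability that a 21-mer window is
  error-free is 0.95²¹ ≈ 0.34, so clean-k-mer coverage at 20x is only
  ~4x.  With a node floor of 2 the de Bruijn path across an isolated
  variant breaks wherever clean coverage dips below 2; most variant
  contigs then fall under the 80 bp floor, and recurrent errors (the same
  substitution in two or three overlapping reads) occasionally survive
  into a contig as a single mismatch.  In the packaged benchmark this
  reduces surviving tip contigs from ~195 (error-free) to ~12–22 and
  yields 67–95% exact tip contigs and 96.6–98.7% minimum identity across
  seeds, versus 98–100% exact and 99.3–100% minimum identity without
  error.  Milder or end-weighted error profiles (as real instruments
  produce) would sit between these extremes.
- Spurious tip k-mers can arise from coverage dropout (a conserved k-mer
  falling below threshold in all genomes but one) and, with error, from
  recurrent identical miscalls; both recruit a handful of reads and
  mostly assemble below the 80 bp floor.
- The assembler performs no repeat resolution; loci sharing a canonical
  (k−1)-mer can terminate each other's unitigs, and k-mer-scale repeats
  collapse.
- Congruent-group enumeration defines a group as a taxonomy node's
  sampled-leaf set (size ≥ 2, deduplicated after sampling); taxa that
  collapse to identical leaf sets count once.

## Problem sizes

The default test suite simulates genomes of 7–30 kb for unit and property
tests and runs the full 4 × 100 kb benchmark three times per error
condition; the whole suite takes a few minutes on one CPU, and
`scripts/acceptance.py` about the same.
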