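# Methods

## Model and assumptions

The pipeline searches for a spliced leader (SL) without knowing its sequence,
under five assumptions: (1) the SL sits at the 5′ end of mature transcripts;
(2) it is attached to transcripts of many genes; (3) it is not a palindrome;
(4) it occurs at most once per transcript; (5) its genomic copy is
immediately followed by a canonical `GT` splice donor. The input contract
starts at assembled contigs (Trinity-style ids, `<prefix>_c<int>_g<int>_i<int>`);
read QC, trimming and assembly are upstream of this tool. Because standard
poly-A libraries lose strand information, every contig may represent the
mRNA or its reverse complement, and all statistics are built to be invariant
under that ambiguity: k-mers are counted canonically (lexicographic minimum
of a word and its reverse complement), Hooks are searched on both strands,
and the coi index treats the two valid strand/position configurations
symmetrically.

All internal coordinates are 0-based half-open; conversion to 1-based
inclusive happens only when GFF3/TSV is written.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `end_length` | 50 bp | terminal region cut from each retained contig. Chosen to cover the longest SL of interest (~36 bp) plus the low-quality leader bases that precede SLs in real assemblies. |
| `k` / `assembly_k` | 20 / 19 | counting and assembly k-mer sizes. 20 suits SLs of ~22–36 bp; a 16-bp SL needs the short-SL regime (15/14, occ off). `assembly_k < k` is enforced. |
| `min_kmer_fraction` | 5 × 10⁻⁶ | k-mer count threshold as a fraction of filtered contigs (0.0005 %); the effective cutoff is `max(2, ceil(fraction × contigs))`, about 10 contigs at production scale. |
| `coi_cutoff` | 0.95 | Hooks must have coi strictly above this. |
| `apply_occ` | on | discard Hooks whose hit count is below the median over all Hooks; turned off in the short-SL regime, where the SL Hook's counts are low. |
| `min_identity`, `min_cov`, `seed_len` | 0.90, 0.80, 7 | transcriptome hit qualification: ungapped window with ≥ 90 % identity spanning ≥ 80 % of the Hook, found from exact 7-mer seeds. |
| `variant_identity` | 1.0 | Step2 deduplication: exact-containment clustering only. |
| `gap_fraction`, `min_block` | 0.1, 5 | alignment trimming: a column survives with < 10 % gaps, and only runs of ≥ 5 surviving columns are kept. |
| `genome_min_cov` | 0.90 | genome search: a contiguous exact match must cover ≥ 90 % of the variant; only terminal bases may go unmatched. |
| `clear_fraction` | 0.80 | a locus is Clear when ≥ 80 % of its matching variants see a donor ("fewer than 80 %" reports Unclear). |
| `annotation_distance` | 100 bp | loci with a protein/cDNA reference match within this distance (inclusive) are discarded. |

## Numerical and algorithmic choices

**Transcriptome hit search.** Instead of an E-value criterion — which
depends on database size and makes runs irreproducible across datasets —
hits are defined combinatorially: exact seed words select diagonals; on each
diagonal the maximum-score ungapped window (+1 match / −2 mismatch) is
taken. Among equal-score windows the *longest* is preferred (maximal
extension at no score cost); a positional preference here would break the
strand symmetry the whole method relies on, because "leftmost" is not
invariant under reverse complementation. The result is provably identical to
an exhaustive all-offsets scorer, which the test suite checks on hundreds of
random instances. Per transcript only the best hit is reported; transcripts
with two or more disjoint qualifying hits are excluded and listed for
inspection (possible assembly chimeras).

**Hook assembly.** Greedy contig building over canonical assembly-k-mers:
seed at the highest-count unused word, extend right then left, always taking
the highest-count unused overlap (ties lexicographic), discard contigs
shorter than `assembly_k + 2`. Deterministic; no randomness anywhere in the
pipeline. Near-duplicate and truncated Hooks are an expected by-product of
k-mer consumption (the occ filter removes most of the low-count ones).

**End retrieval.** For a selected Hook, only hits in its majority valid
configuration are used; Start hits contribute `transcript[0 : match_end+2]`,
End hits the reverse complement of `transcript[match_start-2 :]`, so every
retrieved end reads 5′→3′ in SL sense and carries up to two bases past the
match — deliberately over-retrieving so the donor boundary is recoverable.

**Alignment.** Guide tree by UPGMA on shared 4-mer distance; profiles merged
with an affine-gap Gotoh DP (match +2, mismatch −1, gap open −4, extend −1).
Two departures from a plain global aligner matter for stability: terminal
gap runs are discounted (open −2, extend −1), so ragged 5′ junk and 3′
overhangs stack against the conserved core instead of misaligning into it;
and a deterministic polish pass slides gap runs sideways wherever that
strictly improves a sum-of-pairs score with a −0.5 gap-pair term, resolving
the indel-placement degeneracy that homopolymers at the core's edges
otherwise turn into unstable column gap fractions (and hence unstable
trimming). Both choices are validated against exhaustive pairwise alignment
enumeration in the tests; determinism, not equivalence to any particular
aligner, is the contract.

**Donor window.** The 4-bp window is the last two *matched* bases plus the
two genomic bases past the 3′ boundary, read in SL sense on the hit strand.
`GT` at the fully-downstream offset is the canonical case; a `GT` starting
at or before the last matched base means the variant itself ends in `G` or
`GT` and raises the `*` (manual inspection) flag — this is the only window
geometry consistent with both behaviours. Plus-strand hits are labelled
`3prima`, minus-strand `5prima`. A window running off the chromosome end
reports no donor and an "incomplete" flag. Loci supported only by Hooks with
undetermined orientation are labelled Undetermined and skip donor analysis —
without an orientation the 3′ end is unknown.

**Annotation filter.** The flank searched extends `annotation_distance` plus
a 100-bp margin so a qualifying match sitting exactly at the cutoff is still
findable; the recorded distance is the gap between locus and nearest match
(0 if overlapping) and the discard test is inclusive. Nucleotide mode uses
the same seeded diagonal machinery (seed 11, ≥ 30 bp at ≥ 80 % identity);
protein mode six-frame-translates the flank and requires an exact 8-residue
seed extended to ≥ 20 residues at ≥ 50 % identity. The contract is "detect a
coding neighbour", not BLAST-score equivalence.

**Locus grouping.** Hits on one chromosome and strand merge when overlapping
or within 5 bp — a small abutment tolerance that keeps one tandem-repeat
copy from splitting across staggered variant hits, while genuine tandem
copies (hundreds of bases apart) stay separate.

## Synthetic data

The generator emulates what the pipeline consumes, not reads: a genome with
each SL class planted as a tandem array (exon + `GT` + fixed 60-bp intron +
200-bp spacers), protein-coding segments (30-bp 5′UTR + intact 78-codon ORF
+ 45-bp 3′UTR) separated by short spacers, and a Trinity-style transcriptome
in which a contig carries an SL with its class prevalence, behind 0–8 random
leader bases and a 5′ truncation, with substitutions at 0.5 % and reverse
complementation with probability 0.5. Per-gene random UTRs are essential
realism: they keep k-mers spanning the SL/mRNA junction private to one gene.
A background of three pervasive repeated elements (60 bp, inserted into half
the gene 3′UTRs at random strand) emulates the rRNA/transposon content of
real assemblies; it is what gives the coi and occ filters real work to do —
on SL-free data Hooks *are* generated and must fail coi, and the occ median
sits among genuinely repeated sequences. Everything is driven by one
`random.Random(seed)` and is byte-identical across runs.

Scenario presets: `no-sl` (negative control, 300 genes / 100 kb, lighter
repeats to fit), `one-long-sl` (36-bp exon, prevalence 0.4, 8 copies),
`one-short-sl` (16-bp exon, no 5′ truncation — a 16-mer missing 10 leading
bases would be unidentifiable at any usable k), and `multi-sl` (two 26-bp
classes sharing a 12-bp 3′ terminus, prevalence 0.3 each). The documented
study-condition seed is 42. Problem sizes (hundreds of genes, 100–130-kb
genomes) keep a full pipeline run in seconds while preserving the count
ratios the filters depend on.

What passing tests on these fixtures do **not** show: robustness to
coverage-dependent assembly fragmentation, sequencing-platform error
profiles, heterozygosity, or genome mis-assembly; and the borderline
donor-vote arithmetic (the 80 % rule over equal-weighted variants) can tip
either way on real data where variant families are larger and noisier — the
published analyses of this method show the same sensitivity (Clear versus
Unclear donor calls, and donor sites overlapping variant ends).

## Known limitations

* The per-variant donor vote weights a singleton error variant equally with
  a dominant one; loci sit near the 0.8 boundary whenever truncated Hook
  families are abundant.
* Short SLs (≈16 bp) are reported reliably, but often with donor-overlap
  ambiguity (`*`, or Unclear loci), because retrieved ends extend past the
  exon into per-gene sequence.
* Hook assembly consumes k-mers greedily; allele- or error-variants of one
  SL emerge as separate Hooks rather than a single consensus.
* SL-RNA functional features (Sm site, secondary structure) are out of
  scope; candidates need experimental validation.
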