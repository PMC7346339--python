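import random

import pytest

from oracles import brute_genome_hits
from slfinder.core_io import GenomeSequence, revcomp
from slfinder.hook_discovery import Orientation
from slfinder.locus_mapper import (
    GenomeLocus,
    VariantHit,
    annotate_and_filter,
    call_locus_status,
    cluster_psl,
    detect_donor_site,
    group_hits_into_loci,
    map_variants_to_genome,
    run_step3,
    translate,
)
from slfinder.variant_builder import HookVariant


def variant(seq, vid="v1", hook="h1"):
    return HookVariant(hook, vid, seq, 1, ())


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestGenomeSearch:
    def test_exact_planting(self):
        rng = random.Random(0)
        v = rand_seq(rng, 30)
        g = rand_seq(rng, 2000) + v + rand_seq(rng, 2000)
        hits = map_variants_to_genome([variant(v)], [GenomeSequence("c", g)])
        spans = {(h.start, h.end, h.strand, h.matched_span) for h in hits}
        assert (2000, 2030, "+", 30) in spans

    def test_terminal_mismatches_allowed(self):
        rng = random.Random(1)
        core = rand_seq(rng, 28)
        g = rand_seq(rng, 1000) + core + rand_seq(rng, 1000)
        v = "CC" + core  # two non-matching 5' bases
        if g[998:1000] == "CC":  # avoid accidental extension
            g = g[:998] + "AA" + g[1000:]
        hits = map_variants_to_genome([variant(v)], [GenomeSequence("c", g)])
        assert any(h.matched_span == 28 and h.query_start == 2 for h in hits)

    def test_central_mismatch_kills_the_hit(self):
        rng = random.Random(2)
        v = rand_seq(rng, 30)
        mutated = v[:15] + ("A" if v[15] != "A" else "C") + v[16:]
        g = rand_seq(rng, 5000) + v + rand_seq(rng, 5000)
        hits = map_variants_to_genome([variant(mutated)], [GenomeSequence("c", g)])
        assert hits == []

    def test_matches_brute_force_scan(self):
        rng = random.Random(3)
        g = rand_seq(rng, 8000)
        variants = []
        for i in range(4):
            pos = rng.randint(0, len(g) - 40)
            frag = g[pos : pos + 30]
            if i % 2:  # plant the reverse complement query
                frag = revcomp(frag)
            if i == 3:  # two mismatching 5' terminal bases
                frag = "NN".replace("N", rng.choice("ACGT")) + frag[2:]
            variants.append(variant(frag, vid=f"v{i}"))
        genome = [GenomeSequence("chr", g)]
        got = {
            (h.variant_id, h.chrom, h.start, h.end, h.strand, h.query_start, h.query_end)
            for h in map_variants_to_genome(variants, genome)
        }
        expected = set()
        for v in variants:
            for rec in brute_genome_hits(v.sequence, "chr", g):
                expected.add((v.variant_id, *rec))
        assert got == expected

    def test_short_variant_rejected(self):
        with pytest.raises(ValueError):
            map_variants_to_genome([variant("ACGTACG")], [GenomeSequence("c", "A" * 100)])


class TestLociGrouping:
    def h(self, start, end, strand="+", vid="v1"):
        return VariantHit(vid, "h1", "chr", start, end, strand, end - start, 0, end - start)

    def test_overlapping_hits_merge(self):
        loci = group_hits_into_loci([self.h(100, 130), self.h(102, 131)])
        assert len(loci) == 1 and (loci[0].start, loci[0].end) == (100, 131)

    def test_opposite_strands_stay_apart(self):
        loci = group_hits_into_loci([self.h(100, 130, "+"), self.h(100, 130, "-")])
        assert len(loci) == 2

    def test_distant_hits_stay_apart(self):
        loci = group_hits_into_loci([self.h(100, 130), self.h(230, 260)])
        assert len(loci) == 2

    def test_abutting_within_five_bp_merge(self):
        loci = group_hits_into_loci([self.h(100, 130), self.h(134, 160)])
        assert len(loci) == 1


class TestDonorSite:
    def make(self, matched, downstream, strand="+"):
        # genome: pad + matched + downstream + pad
        pad = "CCCC"
        if strand == "+":
            g = pad + matched + downstream + pad
            hit = VariantHit("v1", "h1", "c", 4, 4 + len(matched), "+", len(matched), 0, len(matched))
        else:
            fwd = pad + revcomp(matched + downstream)[::1] + pad
            # build so that revcomp(genome[start-2:start+2]) == last2+down2
            g = pad + revcomp(downstream) + revcomp(matched) + pad
            hit = VariantHit(
                "v1", "h1", "c", 4 + len(downstream), 4 + len(downstream) + len(matched),
                "-", len(matched), 0, len(matched),
            )
        return hit, {"c": g}

    def test_canonical_downstream_gt(self):
        hit, g = self.make("ACGTAC", "GT")
        call = detect_donor_site(hit, g)
        assert call.donor_found and not call.overlap_star and call.label == "3prima"

    def test_overlap_star_when_match_ends_in_g(self):
        hit, g = self.make("ACGTAG", "TT")
        call = detect_donor_site(hit, g)
        assert call.donor_found and call.overlap_star

    def test_no_gt_anywhere(self):
        hit, g = self.make("ACGTAC", "CC")
        assert not detect_donor_site(hit, g).donor_found

    def test_minus_strand_label_swaps(self):
        hit, g = self.make("ACGTAC", "GT", strand="-")
        call = detect_donor_site(hit, g)
        assert call.donor_found and call.label == "5prima"

    def test_chromosome_edge_flags_incomplete(self):
        g = {"c": "AAAACGTAC"}  # match ends at the chromosome edge
        hit = VariantHit("v1", "h1", "c", 3, 9, "+", 6, 0, 6)
        call = detect_donor_site(hit, g)
        assert not call.donor_found and call.incomplete


class TestLocusStatus:
    def build_locus(self, n_with_donor, n_without):
        # variants ending right before a GT (donor) or inside a GT-free zone
        g = "C" * 30 + "AAGATTACAGCAT" + "GT" + "C" * 30
        hits = []
        for i in range(n_with_donor):
            hits.append(VariantHit(f"d{i}", "h1", "c", 32, 43, "+", 11, 0, 11))
        for i in range(n_without):
            hits.append(VariantHit(f"n{i}", "h1", "c", 32, 40, "+", 8, 0, 8))
        locus = GenomeLocus("L1", "c", 32, 43, "+", variant_hits=hits)
        call_locus_status(locus, {"c": g}, {"h1": Orientation.SENSE})
        return locus

    def test_all_variants_with_donor_is_clear(self):
        assert self.build_locus(5, 0).status == "Clear"

    def test_three_of_five_is_unclear(self):
        assert self.build_locus(3, 2).status == "Unclear"

    def test_four_of_five_boundary_is_clear(self):
        assert self.build_locus(4, 1).status == "Clear"

    def test_no_donor_at_all(self):
        assert self.build_locus(0, 3).status == "NoDonor"

    def test_undetermined_hook_orientation_propagates(self):
        g = "C" * 60
        hits = [VariantHit("v1", "h1", "c", 10, 30, "+", 20, 0, 20)]
        locus = GenomeLocus("L1", "c", 10, 30, "+", variant_hits=hits)
        call_locus_status(locus, {"c": g}, {"h1": Orientation.UNDETERMINED})
        assert locus.status == "Undetermined" and locus.donor_calls == []


class TestAnnotationFilter:
    def test_distance_boundary_inclusive(self):
        rng = random.Random(5)
        cdna = rand_seq(rng, 200)
        for gap, expect_discard in ((100, True), (101, False), (50, True)):
            g = rand_seq(rng, 500)
            genome = g[:300] + "GATTACA" * 5 + g[300:]
            locus_start, locus_end = 300, 335
            chrom = genome[:locus_end] + rand_seq(rng, gap) + cdna + rand_seq(rng, 300)
            loci = [GenomeLocus("L1", "c", locus_start, locus_end, "+")]
            annotate_and_filter(loci, {"c": chrom}, [("g1", cdna)], distance_bp=100)
            assert loci[0].discarded == expect_discard, (gap, loci[0].annotation_distance)
            assert loci[0].annotation_distance == gap

    def test_far_locus_retained(self):
        rng = random.Random(6)
        cdna = rand_seq(rng, 150)
        chrom = rand_seq(rng, 400) + cdna + rand_seq(rng, 2000)
        loci = [GenomeLocus("L1", "c", 2300, 2340, "+")]
        annotate_and_filter(loci, {"c": chrom}, [("g1", cdna)], distance_bp=100)
        assert not loci[0].discarded

    def test_empty_reference_keeps_everything(self):
        loci = [GenomeLocus("L1", "c", 10, 40, "+")]
        annotate_and_filter(loci, {"c": "A" * 100}, [], distance_bp=100)
        assert not loci[0].discarded and loci[0].annotation_distance is None

    def test_protein_mode_finds_translated_neighbor(self):
        rng = random.Random(7)
        cdna = "ATG" + "".join(
            c for c in [rand_seq(rng, 3) for _ in range(60)] if c not in ("TAA", "TAG", "TGA")
        )[:180] + "TAA"
        protein = translate(cdna).rstrip("*")
        chrom = rand_seq(rng, 300) + cdna + rand_seq(rng, 300)
        loci = [GenomeLocus("L1", "c", 310 + len(cdna), 340 + len(cdna), "+")]
        annotate_and_filter(loci, {"c": chrom}, [("p1", protein)], distance_bp=100, mode="protein")
        assert loci[0].discarded


class TestPslClustering:
    def locus(self, lid, seq_pos, status="Clear", genome=None):
        start, end = seq_pos
        return GenomeLocus(lid, "c", start, end, "+", status=status)

    def test_identical_loci_cluster_together(self):
        g = "TTTT" + "GATTACAGATTACAGATTACA" + "CCCC"
        loci = [GenomeLocus(f"L{i}", "c", 4, 25, "+", status="Clear") for i in range(10)]
        psl = cluster_psl(loci, {"c": g})
        assert len(psl) == 1 and len(psl[0].member_loci) == 10

    def test_unclear_identical_to_clear_stays_separate(self):
        g = "TTTT" + "GATTACAGATTACAGATTACA" + "CCCC"
        loci = [
            GenomeLocus("L1", "c", 4, 25, "+", status="Clear"),
            GenomeLocus("L2", "c", 4, 25, "+", status="Unclear"),
        ]
        psl = cluster_psl(loci, {"c": g})
        assert {p.psl_id for p in psl} == {"pSL-1", "UnpSL-1"}
        clear, unclear = sorted(psl, key=lambda p: p.donor_class)
        assert clear.sequence == unclear.sequence

    def test_one_base_difference_splits(self):
        g = "TTTT" + "GATTACAGATTACAGATTACA" + "GGTTACAGATTACAGATTACA" + "CCCC"
        loci = [
            GenomeLocus("L1", "c", 4, 25, "+", status="Clear"),
            GenomeLocus("L2", "c", 25, 46, "+", status="Clear"),
        ]
        psl = cluster_psl(loci, {"c": g})
        assert len(psl) == 2


class TestPlantedLocusRecovery:
    def test_tandem_copies_all_recovered_and_cluster_to_one(self):
        from slfinder.synth import SLClass, generate_genome

        exon = "CTAGCGTTACCGATTAGCAAGCTTAGGACCTTACAA"
        genome, truth = generate_genome(
            11, sl_classes=[SLClass("SL", exon, 0.4)], copies_per_class=5,
            n_genes=20, chrom_len=30_000, n_repeat_families=0,
        )
        v = variant(exon[8:] + "GT", vid="v1")
        loci, psl = run_step3(
            [v], genome, [], {"h1": Orientation.SENSE},
        )
        assert len(loci) == 5 and all(l.status == "Clear" for l in loci)
        assert len(psl) == 1 and len(psl[0].member_loci) == 5

    def test_mutated_donor_flips_exactly_that_locus(self):
        from slfinder.synth import SLClass, generate_genome

        exon = "CTAGCGTTACCGATTAGCAAGCTTAGGACCTTACAA"
        genome, truth = generate_genome(
            11, sl_classes=[SLClass("SL", exon, 0.4)], copies_per_class=5,
            n_genes=20, chrom_len=30_000, n_repeat_families=0,
            mutate_donor_copies=(2,),
        )
        v = variant(exon[8:], vid="v1")
        loci, _ = run_step3([v], genome, [], {"h1": Orientation.SENSE})
        statuses = [l.status for l in sorted(loci, key=lambda l: l.start)]
        assert statuses == ["Clear", "Clear", "NoDonor", "Clear", "Clear"]

    def test_status_invariant_under_genome_revcomp(self):
        from slfinder.synth import SLClass, generate_genome

        exon = "CTAGCGTTACCGATTAGCAAGCTTAGGACCTTACAA"
        genome, _ = generate_genome(
            12, sl_classes=[SLClass("SL", exon, 0.4)], copies_per_class=3,
            n_genes=10, chrom_len=20_000, n_repeat_families=0,
        )
        v = variant(exon[8:], vid="v1")
        loci_f, _ = run_step3([v], genome, [], {"h1": Orientation.SENSE})
        flipped = [GenomeSequence(g.chrom_id, revcomp(g.sequence)) for g in genome]
        loci_r, _ = run_step3([v], flipped, [], {"h1": Orientation.SENSE})
        L = len(genome[0].sequence)
        mirrored = sorted(
            (L - l.end, L - l.start, {"+": "-", "-": "+"}[l.strand], l.status) for l in loci_r
        )
        original = sorted((l.start, l.end, l.strand, l.status) for l in loci_f)
        assert mirrored == original
        labels_f = {c.label for l in loci_f for c in l.donor_calls if c.donor_found}
        labels_r = {c.label for l in loci_r for c in l.donor_calls if c.donor_found}
        assert labels_f == {"3prima"} and labels_r == {"5prima"}
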