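"""ORF scan, overlap junction, SD motifs, promoter/TF scans, operon grouping,
in-silico PCR, and the closed loop against the operon generator."""

import pytest

from phrkit.operon import (PrimerPair, detect_overlaps, find_orfs,
                           find_sd_motifs, in_silico_pcr, predict_operons,
                           revcomp, scan_promoter, scan_tf_sites)
from phrkit.records import GeneFeature
from phrkit.synthetic import OperonDesign, gen_operon_sequence


class TestOrfs:
    def test_minimal_orf(self):
        orfs = find_orfs("ATGAAATAA", min_len_nt=9)
        assert len(orfs) == 1 and (orfs[0].start, orfs[0].end) == (1, 9)
        assert orfs[0].length == 9 and orfs[0].strand == "+"

    def test_strand_symmetry(self):
        seq = "ATGAAATAA"
        rc = revcomp(seq)
        orfs = find_orfs(rc, min_len_nt=9)
        assert len(orfs) == 1
        assert (orfs[0].start, orfs[0].end, orfs[0].strand) == (1, 9, "-")

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError, match="position 3"):
            find_orfs("ATXGAA")

    def test_planted_genes_found_at_truth_coordinates(self, operon_truth):
        _, seq, truth = operon_truth
        found = {(f.start, f.end, f.strand) for f in find_orfs(seq)}
        for gene in truth.genes:
            assert (gene.start, gene.end, gene.strand) in found


class TestOverlaps:
    def test_planted_junction(self, operon_truth):
        _, seq, truth = operon_truth
        recs = detect_overlaps(truth.genes, seq)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.overlap_length == 11
        assert rec.junction_sequence == "ATGTCAGTTGA"
        assert rec.junction_sequence[:3] == "ATG" and rec.junction_sequence[-3:] == "TGA"
        assert rec.frames_differ

    def test_abutting_genes_no_record(self):
        feats = [GeneFeature("a", 1, 9, "+"), GeneFeature("b", 10, 18, "+")]
        assert detect_overlaps(feats, "ATGAAATAAATGAAATAA") == []

    def test_gapped_genes_no_record(self):
        feats = [GeneFeature("a", 1, 9, "+"), GeneFeature("b", 15, 23, "+")]
        assert detect_overlaps(feats, "ATGAAATAAGGGGGATGAAATAA") == []

    def test_opposite_strands_excluded(self):
        feats = [GeneFeature("a", 1, 12, "+"), GeneFeature("b", 8, 20, "-")]
        assert detect_overlaps(feats, "A" * 20) == []


class TestShineDalgarno:
    def test_planted_sd_spacer_seven(self, operon_truth):
        _, seq, truth = operon_truth
        hits = [h for h in find_sd_motifs(seq, truth.genes)
                if h.target_gene == "cpd64_phr_like"]
        exact = [h for h in hits if h.motif_end == truth.sd.motif_end]
        assert exact and exact[0].spacer == 7 and exact[0].motif == "AGGAG"

    def test_leading_gene_has_no_sd(self, operon_truth):
        _, seq, truth = operon_truth
        assert not [h for h in find_sd_motifs(seq, truth.genes)
                    if h.target_gene == "phr_upstream"]

    def test_no_motif_no_hit(self):
        seq = "C" * 30 + "ATGAAATAA"
        feats = [GeneFeature("g", 31, 39, "+")]
        assert find_sd_motifs(seq, feats) == []

    def test_longest_motif_preferred_at_same_end(self):
        # AGGAGG ending 7 nt before ATG; AGGAG is its suffix-shifted cousin
        seq = "C" * 10 + "AGGAGG" + "T" * 7 + "ATGAAATAA" + "C" * 5
        feats = [GeneFeature("g", 24, 32, "+")]
        hits = [h for h in find_sd_motifs(seq, feats) if h.spacer == 7]
        assert hits[0].motif == "AGGAGG"


class TestPromoterAndTf:
    def test_perfect_consensus_max_score(self):
        seq = "G" * 10 + "TTGACA" + "C" * 17 + "TATAAT" + "G" * 10
        hits = scan_promoter(seq, (1, len(seq)))
        assert hits[0].score == 12 and hits[0].spacing == 17
        assert hits[0].minus35 == "TTGACA" and hits[0].minus10 == "TATAAT"

    def test_planted_boxes_recovered(self, operon_truth):
        _, seq, truth = operon_truth
        win = (1, truth.genes[0].start - 1)
        hits = scan_promoter(seq, win, min_score=8)
        m35_start, m10_start = truth.minus35[1], truth.minus10[1]
        # the planted -10 string carries the TATACA core 3 nt in
        assert any(h.minus35_start == m35_start and h.minus10_start == m10_start + 3
                   for h in hits)

    def test_window_validated(self):
        with pytest.raises(ValueError, match="window"):
            scan_promoter("ACGT", (2, 10))

    def test_random_sequence_high_threshold_empty(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        assert scan_promoter(seq, (1, 300), min_score=12) == []

    def test_planted_tf_sites_exact(self, operon_truth):
        _, seq, truth = operon_truth
        found = {(t.name, t.start, t.end, t.strand, t.mismatches)
                 for t in scan_tf_sites(seq)}
        for t in truth.tf_sites:
            assert (t.name, t.start, t.end, t.strand, 0) in found

    def test_mutated_site_needs_mismatch_budget(self):
        seq = "G" * 5 + "TCACAATA" + "G" * 5  # CRP site with 1 mismatch
        assert not [h for h in scan_tf_sites(seq, max_mismatch=0) if h.name == "CRP"]
        hits = [h for h in scan_tf_sites(seq, max_mismatch=1) if h.name == "CRP"
                and h.strand == "+"]
        assert hits and hits[0].mismatches == 1

    def test_reverse_complement_site_found_on_minus(self):
        seq = "G" * 5 + revcomp("TCACAATT") + "G" * 5
        hits = [h for h in scan_tf_sites(seq) if h.name == "CRP"]
        assert hits and hits[0].strand == "-" and hits[0].start == 6


class TestOperonGrouping:
    def test_overlapping_pair_grouped(self, operon_truth):
        _, _, truth = operon_truth
        groups = predict_operons(truth.genes, max_gap=50)
        assert len(groups) == 1 and len(groups[0]) == 2

    def test_distant_genes_not_grouped(self):
        feats = [GeneFeature("a", 1, 90, "+"), GeneFeature("b", 600, 700, "+")]
        assert predict_operons(feats, max_gap=50) == []

    def test_convergent_genes_never_grouped(self):
        feats = [GeneFeature("a", 1, 90, "+"), GeneFeature("b", 95, 200, "-")]
        assert predict_operons(feats, max_gap=50) == []


class TestInSilicoPcr:
    def test_planted_233_nt_amplicon(self, operon_truth):
        _, seq, truth = operon_truth
        g1 = truth.genes[0]
        start = g1.end - 100
        fwd = seq[start - 1:start + 19]
        rev = revcomp(seq[start + 233 - 21:start + 233 - 1])
        hits = in_silico_pcr(seq, PrimerPair("intergenic", fwd, rev))
        assert len(hits) == 1 and hits[0].length == 233

    def test_forward_only_no_product(self):
        seq = "ATGAAACCCGGGTTT" * 10
        hits = in_silico_pcr(seq, PrimerPair("p", seq[:18], "A" * 18))
        assert hits == []

    def test_duplicated_binding_site_two_products(self):
        core = "ATTCGATCGATCGGCTAGCA"
        mid = "GGCCGGCCAAGGTTAACCGG"
        tail = "TTACGCGTACGTTAGCATGC"
        seq = core + mid + tail + mid + tail
        fwd = core[:12]
        rev = revcomp(tail[-12:])
        hits = in_silico_pcr(seq, PrimerPair("dup", fwd, rev))
        assert len(hits) == 2

    def test_coordinate_sanity(self, operon_truth):
        _, seq, truth = operon_truth
        for feats in ([truth.overlap], truth.tf_sites, truth.genes):
            for f in feats:
                if hasattr(f, "start"):
                    assert 1 <= f.start <= f.end <= len(seq)


class TestClosedLoop:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_hundred_random_designs_recovered(self, strand):
        """All planted features recovered, no spurious overlaps, both strands."""
        for seed in range(50):
            seq, truth = gen_operon_sequence(OperonDesign(seed=seed, strand=strand))
            coords = {(f.start, f.end, f.strand) for f in find_orfs(seq)}
            for g in truth.genes:
                assert (g.start, g.end, g.strand) in coords
            overlaps = detect_overlaps(truth.genes, seq)
            assert len(overlaps) == 1
            assert overlaps[0].overlap_length == 11
            assert overlaps[0].junction_sequence == "ATGTCAGTTGA"
            sd = find_sd_motifs(seq, truth.genes)
            assert any(h.target_gene == "cpd64_phr_like" and h.spacer == 7
                       and h.motif_end == truth.sd.motif_end for h in sd)
            assert not [h for h in sd if h.target_gene == "phr_upstream"]
            tf = {(t.name, t.start, t.end, t.strand) for t in scan_tf_sites(seq)}
            for t in truth.tf_sites:
                assert (t.name, t.start, t.end, t.strand) in tf

    def test_strand_mirroring_equivalence(self):
        """A minus-strand design is the coordinate mirror of the plus design."""
        plus, t_plus = gen_operon_sequence(OperonDesign(seed=4, strand="+"))
        minus, t_minus = gen_operon_sequence(OperonDesign(seed=4, strand="-"))
        assert revcomp(minus) == plus
        n = len(plus)
        for gp, gm in zip(t_plus.genes, t_minus.genes):
            assert (gm.start, gm.end) == (n - gp.end + 1, n - gp.start + 1)
            assert gm.strand == "-"
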