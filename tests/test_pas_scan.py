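"""PAS hexamer scanning, clustering, cleavage prediction and ORF extension."""

import numpy as np
import pytest
from Bio.SeqUtils import molecular_weight
from hypothesis import given, settings
from hypothesis import strategies as st

from ipastrace import pas_scan as ps
from ipastrace import synthetic_data as sd
from ipastrace.intervals import DictGenome, GeneModel, GenomicInterval, revcomp


def naive_scan(seq: str, motifs) -> list[int]:
    """Brute-force O(n*m) substring oracle (overlap allowed)."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - 5):
        if seq[i : i + 6] in motifs:
            out.append(i)
    return sorted(out)


class TestScan:
    def test_no_match(self):
        assert ps.scan_pas("CCCCCCCC") == []

    def test_overlapping_run(self):
        hits = ps.scan_pas("AATAAATAAATAAA")
        assert [h.interval.start for h in hits] == [0, 4, 8]
        assert all(h.motif_class == "canonical" for h in hits)

    def test_non_overlap_mode(self):
        hits = ps.scan_pas("AATAAATAAATAAA", allow_overlap=False)
        starts = [h.interval.start for h in hits]
        assert starts == [0, 8]  # greedy left-to-right non-overlapping

    def test_soft_masked_matches_n_does_not(self):
        assert len(ps.scan_pas("aataaa")) == 1
        assert ps.scan_pas("AATAAN") == []

    def test_invalid_character_names_offset(self):
        with pytest.raises(ValueError, match="offset 3"):
            ps.scan_pas("AATXAA")

    def test_empty_sequence(self):
        assert ps.scan_pas("") == []

    def test_variant_motifs(self):
        hits = ps.scan_pas("ATTAAA", motifs=ps.PAS_VARIANTS)
        assert hits[0].motif_class == "variant"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=80))
    def test_matches_naive_oracle(self, seq):
        hits = ps.scan_pas(seq)
        assert [h.interval.start for h in hits] == naive_scan(seq, {"AATAAA"})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=6, max_size=60))
    def test_strand_symmetry(self, seq):
        """Minus-strand scan of a region equals a plus scan of its reverse
        complement with mirrored coordinates."""
        genome = DictGenome({"c": seq})
        region_minus = GenomicInterval("c", 0, len(seq), "-")
        minus_hits = ps.scan_region(genome, region_minus)
        plus_hits = ps.scan_pas(revcomp(seq))
        mirrored = sorted(len(seq) - h.interval.start - 6 for h in plus_hits)
        assert sorted(h.interval.start for h in minus_hits) == mirrored


class TestCluster:
    def _hits(self, starts):
        return [
            ps.PasHit(GenomicInterval("c", s, s + 6, "+"), "AATAAA", "canonical")
            for s in starts
        ]

    def test_overlapping_triplet_forms_one_cluster(self):
        clusters = ps.cluster_hits(self._hits([0, 4, 8]))
        assert len(clusters) == 1 and clusters[0].n_signals == 3

    def test_disjoint_hits_stay_singletons(self):
        clusters = ps.cluster_hits(self._hits([0, 100]))
        assert [c.n_signals for c in clusters] == [1, 1]

    def test_empty(self):
        assert ps.cluster_hits([]) == []

    def test_partition_and_idempotence(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            starts = sorted(rng.choice(200, size=12, replace=False))
            hits = self._hits(starts)
            clusters = ps.cluster_hits(hits)
            # partition: every hit in exactly one cluster
            assert sorted(
                h.interval.start for c in clusters for h in c.hits
            ) == sorted(starts)
            # idempotent: re-clustering the members changes nothing
            again = ps.cluster_hits([h for c in clusters for h in c.hits])
            assert [c.n_signals for c in again] == [c.n_signals for c in clusters]


class TestCleavage:
    def test_plus_strand_offset(self):
        cl = ps.PasCluster(
            hits=[ps.PasHit(GenomicInterval("c", 100, 106, "+"), "AATAAA", "canonical")]
        )
        assert ps.predict_cleavage_site(cl, 20) == 126

    def test_minus_strand_mirror(self):
        cl = ps.PasCluster(
            hits=[ps.PasHit(GenomicInterval("c", 100, 106, "-"), "AATAAA", "canonical")]
        )
        assert ps.predict_cleavage_site(cl, 20) == 80

    def test_uses_five_prime_most_hexamer(self):
        cl = ps.cluster_hits(
            [
                ps.PasHit(GenomicInterval("c", s, s + 6, "+"), "AATAAA", "canonical")
                for s in (50, 54, 58)
            ]
        )[0]
        assert ps.predict_cleavage_site(cl, 20) == 56 + 20

    def test_empty_cluster_is_error(self):
        with pytest.raises(ValueError):
            ps.predict_cleavage_site(ps.PasCluster(hits=[]))


class TestRepeatOverlap:
    def _cluster(self, start, end):
        return ps.PasCluster(
            hits=[
                ps.PasHit(GenomicInterval("c", s, s + 6, "+"), "AATAAA", "canonical")
                for s in range(start, end - 5, 4)
            ]
        )

    def test_flam_annotation(self):
        cl = self._cluster(150, 170)
        rep = ps.RepeatAnnotation(
            GenomicInterval("c", 40, 172, "+"), "FLAM-C", "SINE/Alu"
        )
        out = ps.annotate_repeat_overlap([cl], [rep])
        assert out[0].repeat_name == "FLAM-C" and out[0].repeat_class == "SINE/Alu"

    def test_no_overlap_unannotated(self):
        out = ps.annotate_repeat_overlap([self._cluster(150, 170)], [])
        assert out[0].repeat_name is None

    def test_largest_overlap_wins(self):
        cl = self._cluster(100, 120)
        small = ps.RepeatAnnotation(GenomicInterval("c", 117, 140, "+"), "small", "X")
        big = ps.RepeatAnnotation(GenomicInterval("c", 90, 110, "+"), "big", "Y")
        out = ps.annotate_repeat_overlap([cl], [small, big])
        assert out[0].repeat_name == "big"


class TestOrfExtension:
    def _toy_model(self, intron: str, strand="+"):
        # one exon of 9 nt CDS ending on a codon boundary, then the intron
        exon = "ATGGCTGAA"
        if strand == "+":
            seq = exon + intron
            genome = DictGenome({"c": seq})
            iv = [GenomicInterval("c", 0, 9, "+")]
        else:
            seq = revcomp(exon + intron)
            genome = DictGenome({"c": seq})
            n = len(seq)
            iv = [GenomicInterval("c", n - 9, n, "-")]
        return GeneModel("g", strand, exons=iv, cds=list(iv), genome=genome)

    def test_single_codon_tail(self):
        model = self._toy_model("AAATGACCCCCCCCCCCCCCCCCCCCCCCC")
        pred = ps.extend_orf_into_intron(model, 0, cleavage_site=30)
        assert pred.tail_peptide == "K"
        assert pred.tail_length == 1
        assert pred.protein == "MAEK"

    def test_minus_strand_tail(self):
        model = self._toy_model("AAATGACCCCCCCCCCCCCCCCCCCCCCCC", strand="-")
        n = 39
        pred = ps.extend_orf_into_intron(model, 0, cleavage_site=n - 30)
        assert pred.tail_peptide == "K"

    def test_partial_codon_carried_across_junction(self):
        # 10-nt CDS: the junction codon completes with two intronic bases
        seq = "ATGGCTGAAA" + "AATGACCCCCCCCCCCCC"
        genome = DictGenome({"c": seq})
        iv = [GenomicInterval("c", 0, 10, "+")]
        model = GeneModel("g", "+", exons=iv, cds=list(iv), genome=genome)
        pred = ps.extend_orf_into_intron(model, 0, cleavage_site=25)
        assert pred.protein.startswith("MAE")
        assert pred.tail_peptide == "K"  # AAA split across the junction

    def test_no_stop_raises(self):
        model = self._toy_model("AAAGCTGCTGCTGCTGCTGCTGCTGCTGCT")
        with pytest.raises(ps.NonStopError):
            ps.extend_orf_into_intron(model, 0, cleavage_site=30)

    def test_utr3_spans_stop_to_cleavage(self):
        model = self._toy_model("AAATGA" + "C" * 40)
        pred = ps.extend_orf_into_intron(model, 0, cleavage_site=45)
        assert pred.utr3.start == 15 and pred.utr3.end == 45
        assert pred.utr3_length == 30

    def test_full_protein_has_no_internal_stop_and_correct_prefix(self):
        sim = sd.gen_locus(11, tail_residues=7)
        site = sim.truth.params["expected_cleavage_site"]
        pred = ps.extend_orf_into_intron(sim.model, 4, site)
        assert "*" not in pred.protein
        assert pred.tail_length == 7
        common = sim.model.cds_sequence(through_exon=4)
        assert pred.protein.startswith(pred.protein[: len(common) // 3])
        assert pred.protein_length == pred.common_residues + pred.tail_length

    def test_glycine_mw_matches_free_glycine(self):
        assert molecular_weight("G", seq_type="protein") == pytest.approx(
            75.07, abs=0.01
        )
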