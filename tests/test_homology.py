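"""Local alignment, E-values, family clustering and mlncRNA-coding relations."""

import math

import numpy as np
import pytest

from mlncforge.homology import (
    Family,
    NucleotideScoring,
    align_score,
    cluster_families,
    conservation_screen,
    estimate_evalue,
    local_align,
    relate_mlnc_to_coding,
)
from mlncforge.seq_core import Transcript, find_orfs, reverse_complement

from oracles import sw_score


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestLocalAlign:
    def test_identical_sequences_full_span(self):
        rng = np.random.default_rng(0)
        s = _rand(rng, 50)
        hit = local_align(s, s)
        assert hit.score == 100.0  # 50 matches x +2
        assert hit.identity == 1.0
        assert (hit.q_start, hit.q_end) == (0, 50)

    def test_disjoint_alphabets_no_hit(self):
        assert local_align("AAAA", "GGGG") is None

    def test_score_symmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = _rand(rng, int(rng.integers(5, 40))), _rand(rng, int(rng.integers(5, 40)))
            assert align_score(a, b) == align_score(b, a)

    def test_matches_exhaustive_dp_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a = _rand(rng, int(rng.integers(1, 13)))
            b = _rand(rng, int(rng.integers(1, 13)))
            assert align_score(a, b) == pytest.approx(sw_score(a, b))


class TestEvalue:
    def test_closed_form(self):
        # E = K m n exp(-lambda S), K=0.41, lambda=0.625
        expected = 0.41 * 400 * 1e6 * math.exp(-0.625 * 60)
        assert estimate_evalue(60, 400, 10**6) == pytest.approx(expected, rel=1e-12)

    def test_linear_in_database_size(self):
        assert estimate_evalue(50, 100, 2000) == pytest.approx(
            2 * estimate_evalue(50, 100, 1000)
        )

    def test_score_decay(self):
        ratio = estimate_evalue(70, 100, 1000) / estimate_evalue(60, 100, 1000)
        assert ratio == pytest.approx(math.exp(-0.625 * 10))

    @pytest.mark.parametrize("score,m,n", [(0, 10, 10), (5, 0, 10), (5, 10, -1)])
    def test_domain_errors(self, score, m, n):
        with pytest.raises(ValueError):
            estimate_evalue(score, m, n)


class TestFamilies:
    def test_three_identical_plus_two_randoms(self):
        rng = np.random.default_rng(3)
        core = _rand(rng, 300)
        seqs = {"a": core, "b": core, "c": core,
                "x": _rand(rng, 300), "y": _rand(rng, 300)}
        fams, singles = cluster_families(seqs)
        assert len(fams) == 1 and fams[0].member_ids == frozenset("abc")
        assert sorted(singles) == ["x", "y"]

    def test_single_linkage_chain(self):
        rng = np.random.default_rng(4)
        a = _rand(rng, 400)
        b = _rand(rng, 100) + a[200:] + _rand(rng, 100)  # shares a's tail
        c = a[:200] + _rand(rng, 200)  # shares a's head, not b's region
        fams, _ = cluster_families({"a": a, "b": b, "c": c})
        assert len(fams) == 1 and fams[0].member_ids == frozenset("abc")

    def test_partition_property(self, transcriptome, transcripts_by_id):
        members = {tid: transcripts_by_id[tid].seq for tid in transcriptome.family_truth}
        fams, singles = cluster_families(members)
        seen = [m for f in fams for m in f.member_ids] + singles
        assert sorted(seen) == sorted(members)

    def test_family_needs_two_members(self):
        with pytest.raises(ValueError):
            Family("f", frozenset({"only"}))


class TestConservation:
    def test_embedded_reference_found_and_shuffle_not(self):
        rng = np.random.default_rng(5)
        ref = _rand(rng, 120)
        mlnc = _rand(rng, 100) + ref + _rand(rng, 100)
        shuffled = "".join(rng.permutation(list(mlnc)))
        hits = conservation_screen({"real": mlnc, "shuf": shuffled}, {"ncref": ref})
        assert [h.query_id for h in hits] == ["real"]

    def test_empty_db(self):
        assert conservation_screen({"a": "ACGT" * 100}, {}) == []


class TestRelations:
    @pytest.fixture()
    def coding_gene(self):
        rng = np.random.default_rng(6)
        # pyrimidine-only UTRs keep the planted ORF the longest on both strands
        utr5 = "".join(rng.choice(list("CT"), 120))
        # shifted frames of the repeat hit stops, so no longer partial ORF exists
        orf = "ATG" + "GCAATAAGC" * 40 + "TAA"
        utr3 = "".join(rng.choice(list("CT"), 120))
        t = Transcript("gene1", utr5 + orf + utr3)
        orfs = find_orfs(t)
        assert orfs[0].start == 120
        return t, orfs[0], utr5, orf, utr3

    def test_sense_utr5(self, coding_gene):
        t, orf, utr5, *_ = coding_gene
        rels = relate_mlnc_to_coding({"m": utr5}, [(t, orf)])
        assert [(r.orientation, r.region) for r in rels] == [("sense", "UTR5")]

    def test_antisense_utr5(self, coding_gene):
        t, orf, utr5, *_ = coding_gene
        rels = relate_mlnc_to_coding({"m": reverse_complement(utr5)}, [(t, orf)])
        assert [(r.orientation, r.region) for r in rels] == [("antisense", "UTR5")]

    def test_sense_cds_and_utr3(self, coding_gene):
        t, orf, _utr5, orf_seq, utr3 = coding_gene
        rels = relate_mlnc_to_coding(
            {"cds_copy": orf_seq[3:-3], "utr3_copy": utr3}, [(t, orf)]
        )
        by_id = {r.mlnc_id: r.region for r in rels}
        assert by_id == {"cds_copy": "CDS", "utr3_copy": "UTR3"}

    def test_junction_spanning_start_codon(self, coding_gene):
        t, orf, utr5, orf_seq, _ = coding_gene
        spanning = utr5[-60:] + orf_seq[:60]
        rels = relate_mlnc_to_coding({"m": spanning}, [(t, orf)])
        assert rels[0].region == "junction"

    def test_coding_without_orf_skipped(self, coding_gene, caplog):
        t, _orf, utr5, *_ = coding_gene
        with caplog.at_level("WARNING"):
            rels = relate_mlnc_to_coding({"m": utr5}, [(t, None)])
        assert rels == [] and "no ORF" in caplog.text
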