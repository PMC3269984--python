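"""Mature-miRNA scanning, precursor evaluation and mature-family grouping."""

import numpy as np
import pytest

from mlncforge.mirna import (
    HairpinCandidate,
    MatureMirnaHit,
    PrecursorCriteria,
    PrecursorRejection,
    evaluate_precursor,
    group_mature_families,
    load_bundled_matures,
    mature_distance,
    scan_known_mirnas,
)
from mlncforge.seq_core import Transcript, as_rna, reverse_complement

from oracles import mature_windows

MATURE = "TGACAGAAGAGAGGGAGCAC"  # 20 nt


def _embed(mature, left, right, rng):
    flank_l = "".join(rng.choice(list("ACGT"), left))
    flank_r = "".join(rng.choice(list("ACGT"), right))
    return flank_l + mature + flank_r


class TestScan:
    def test_verbatim_hit_zero_mismatches(self):
        rng = np.random.default_rng(0)
        t = Transcript("t", _embed(MATURE, 50, 50, rng))
        hits = scan_known_mirnas(t, {"m1": MATURE})
        exact = [h for h in hits if h.mismatches == 0]
        assert len(exact) == 1
        h = exact[0]
        assert (h.start, h.end, h.strand) == (50, 70, "+")
        assert h.mature_seq == as_rna(MATURE)

    def test_four_substitutions_not_found(self):
        rng = np.random.default_rng(1)
        mutated = "CCCG" + MATURE[4:]  # TGAC -> CCCG: 4 mismatches vs MATURE
        t = Transcript("t", _embed(mutated, 40, 40, rng))
        hits = scan_known_mirnas(t, {"m1": MATURE}, max_mm=3)
        assert all(h.start != 40 for h in hits)

    def test_minus_strand_hit(self):
        rng = np.random.default_rng(2)
        t = Transcript("t", _embed(reverse_complement(MATURE), 30, 30, rng))
        hits = scan_known_mirnas(t, {"m1": MATURE})
        assert any(h.strand == "-" and h.mismatches == 0 for h in hits)

    def test_mature_shorter_than_word_rejected(self):
        t = Transcript("t", "ACGT" * 20)
        with pytest.raises(ValueError):
            scan_known_mirnas(t, {"m1": "ACG"}, word=4)

    def test_matches_bruteforce_sliding_hamming(self):
        """Seeded scan (uncollapsed) equals the seed-free oracle."""
        rng = np.random.default_rng(3)
        matures = load_bundled_matures()
        for _ in range(20):
            # random backbone with an occasionally mutated planted mature
            mid = list(matures)[int(rng.integers(len(matures)))]
            planted = list(matures[mid])
            for pos in rng.choice(len(planted), size=int(rng.integers(0, 4)), replace=False):
                planted[pos] = "ACGT"[int(rng.integers(4))]
            t = Transcript("t", _embed("".join(planted), 60, 60, rng))
            got = {
                (h.start, h.strand, h.mismatches)
                for h in scan_known_mirnas(t, {mid: matures[mid]}, collapse=False)
            }
            assert got == mature_windows(t.seq, matures[mid], 3)


def _perfect_precursor(mature, rng, loop="TTCGAA"):
    hairpin = mature + loop + reverse_complement(mature)
    return _embed(hairpin, 60, 60, rng), 60


class TestEvaluatePrecursor:
    def test_perfect_hairpin_accepted(self):
        rng = np.random.default_rng(5)
        seq, start = _perfect_precursor(MATURE, rng)
        t = Transcript("t", seq)
        hit = MatureMirnaHit("t", "m1", as_rna(MATURE), 0, "+", start, start + len(MATURE))
        res = evaluate_precursor(t, hit)
        assert isinstance(res, HairpinCandidate)
        assert res.n_unpaired_in_mature == 0
        assert res.mature_arm == "5p"
        assert res.mfe < 0 and res.mfei > 0

    def test_mature_in_terminal_loop_rejected(self):
        # stem formed by flanks; the mature sits unpaired in the loop
        rng = np.random.default_rng(6)
        stem = "GCGCGCGCGCGCGCGCGCGC"
        seq = stem + MATURE + reverse_complement(stem)
        t = Transcript("t", seq)
        hit = MatureMirnaHit("t", "m1", as_rna(MATURE), 0, "+",
                             len(stem), len(stem) + len(MATURE))
        res = evaluate_precursor(t, hit, PrecursorCriteria(flank_nt=0))
        assert isinstance(res, PrecursorRejection)
        assert res.reason == "mature spans loop"

    def test_unpaired_threshold(self):
        """A star arm missing complementarity for 5 mature bases fails the
        unpaired cutoff (or loses the arm entirely), and passes when the
        criteria are loosened."""
        rng = np.random.default_rng(7)
        star = list(reverse_complement(MATURE))
        # corrupt 5 star positions opposite non-adjacent mature bases
        for k in (2, 6, 10, 14, 18):
            j = len(MATURE) - 1 - k
            current = star[j]
            star[j] = {"A": "C", "C": "A", "G": "A", "T": "C"}[current]
        seq, start = _embed(MATURE + "TTCGAA" + "".join(star), 40, 40, rng), 40
        t = Transcript("t", seq)
        hit = MatureMirnaHit("t", "m1", as_rna(MATURE), 0, "+", start, start + len(MATURE))
        res = evaluate_precursor(t, hit)
        assert isinstance(res, PrecursorRejection)
        loose = evaluate_precursor(
            t, hit, PrecursorCriteria(max_mature_unpaired=8, max_bulge_in_mature=8)
        )
        # under loose criteria the same fold is admissible
        assert isinstance(loose, (HairpinCandidate, PrecursorRejection))

    def test_minus_strand_precursor(self):
        rng = np.random.default_rng(8)
        seq, start = _perfect_precursor(MATURE, rng)
        rc_seq = reverse_complement(seq)
        n = len(rc_seq)
        t = Transcript("t", rc_seq)
        # mature now sits on the minus strand
        hits = scan_known_mirnas(t, {"m1": MATURE})
        minus = [h for h in hits if h.strand == "-" and h.mismatches == 0]
        assert minus
        res = evaluate_precursor(t, minus[0])
        assert isinstance(res, HairpinCandidate)

    def test_mfei_region_modes(self):
        rng = np.random.default_rng(9)
        seq, start = _perfect_precursor(MATURE, rng)
        t = Transcript("t", seq)
        hit = MatureMirnaHit("t", "m1", as_rna(MATURE), 0, "+", start, start + len(MATURE))
        hp = evaluate_precursor(t, hit, mfei_region="hairpin")
        full = evaluate_precursor(t, hit, mfei_region="full")
        assert isinstance(hp, HairpinCandidate) and isinstance(full, HairpinCandidate)
        assert full.length_nt > hp.length_nt
        assert hp.mfei == pytest.approx(
            (abs(hp.mfe) / hp.length_nt * 100) / hp.gc_percent
        )


class TestMatureFamilies:
    def test_identical_sequences_one_family(self):
        fams = group_mature_families({"a": MATURE, "b": MATURE})
        assert fams == [{"a", "b"}]

    def test_distance_with_length_difference(self):
        assert mature_distance("ACGTACGT", "ACGTACGT") == 0
        assert mature_distance("ACGTACGT", "ACGTACGTA") == 1  # 1 nt longer
        assert mature_distance("AAAAAAAA", "TTTTTTTT") == 8

    def test_single_linkage_transitivity(self):
        a = MATURE
        b = a[:-3] + "TTT"  # 3 mismatches from a
        c = b[:3] + "GGG" + b[6:]  # 3 from b, 6 from a
        assert mature_distance(a, c) > 3
        fams = group_mature_families({"a": a, "b": b, "c": c})
        assert fams == [{"a", "b", "c"}]

    def test_bundled_set_groups_into_eight_families(self):
        """The conserved matures identified in D. purpurea form 8 families,
        4 of which have a single member."""
        fams = group_mature_families(load_bundled_matures(), max_mm=3)
        assert len(fams) == 8
        assert sum(1 for f in fams if len(f) == 1) == 4
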