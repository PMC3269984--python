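"""The unigene decision tree: homology annotation, housekeeping screen and
the five-way partition."""

import numpy as np
import pytest

from mlncforge.classify import (
    ClassifyParams,
    TranscriptClass,
    annotate_by_protein_homology,
    classify_set,
    classify_transcript,
    screen_housekeeping,
)
from mlncforge.seq_core import Transcript, find_orfs


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(2024)


class TestAnnotation:
    def test_exact_protein_segment_annotated(self, rng):
        # transcript carrying the exact coding sequence of a 60-aa segment
        codons = ["GCT", "GAA", "GAT", "TGG", "CAT", "AAG"] * 10
        cds = "".join(codons)
        t = Transcript("t", _rand(rng, 80) + cds + _rand(rng, 80))
        from Bio.Seq import Seq

        protein = str(Seq(cds).translate())
        annotated, evidence = annotate_by_protein_homology(t, {"P1": protein})
        assert annotated and evidence.startswith("P1")

    def test_random_sequence_not_annotated(self, rng):
        proteins = {
            f"P{i}": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 150))
            for i in range(10)
        }
        t = Transcript("t", _rand(rng, 400))
        annotated, _ = annotate_by_protein_homology(t, proteins)
        assert not annotated

    def test_annotation_table_override(self, rng):
        t = Transcript("t", _rand(rng, 350))
        annotated, evidence = annotate_by_protein_homology(
            t, None, annotation_table={"t"}
        )
        assert annotated and evidence == "annotation_table"

    def test_no_reference_is_config_error(self, rng):
        with pytest.raises(ValueError):
            annotate_by_protein_homology(Transcript("t", _rand(rng, 350)), None)


class TestHousekeepingScreen:
    def test_embedded_reference_hits(self, rng):
        ref = _rand(rng, 120)
        t = Transcript("t", _rand(rng, 100) + ref + _rand(rng, 100))
        hit = screen_housekeeping(t, {"sno1": ref})
        assert hit is not None and hit.subject_id == "sno1"

    def test_shuffled_control_misses(self, rng):
        ref = _rand(rng, 120)
        shuffled = "".join(rng.permutation(list(ref)))
        t = Transcript("t", _rand(rng, 100) + shuffled + _rand(rng, 100))
        # same composition, destroyed order: no hit at E <= 1e-5
        assert screen_housekeeping(t, {"sno1": ref}) is None

    def test_empty_db_passes_everyone(self, rng):
        assert screen_housekeeping(Transcript("t", _rand(rng, 400)), {}) is None


class TestDecisionTree:
    @pytest.mark.parametrize(
        "length,annotated,best_orf_aa,hk,expected",
        [
            (250, False, 0, None, TranscriptClass.SHORT_UNANNOTATED),
            (400, True, 0, None, TranscriptClass.ANNOTATED_CODING),
            (400, False, 120, None, TranscriptClass.NOVEL_CODING),
            (400, False, 40, "hit", TranscriptClass.HOUSEKEEPING_NPCRNA),
            (400, False, 40, None, TranscriptClass.MLNC_CANDIDATE),
            (299, False, 120, None, TranscriptClass.SHORT_UNANNOTATED),
            (300, False, 99, None, TranscriptClass.MLNC_CANDIDATE),
            (300, False, 100, None, TranscriptClass.NOVEL_CODING),
        ],
    )
    def test_rules(self, rng, length, annotated, best_orf_aa, hk, expected):
        if best_orf_aa:
            orf_nt = "ATG" + "GCT" * (best_orf_aa - 1) + "TAA"
            pad = length - len(orf_nt)
            seq = orf_nt + "".join(rng.choice(list("CT"), max(pad, 0)))
            seq = seq[:length] if len(seq) > length else seq
        else:
            seq = "".join(rng.choice(list("CT"), length))  # pyrimidines: no ATG
        t = Transcript("t", seq)
        orfs = find_orfs(t)
        cls = classify_transcript(t, annotated, hk, orfs)
        assert cls == expected

    def test_monotonicity_in_orf_cutoff(self, transcriptome):
        """Raising the ORF cutoff can only grow the mlncRNA candidate set."""
        counts = []
        for cutoff in (60, 100, 160):
            params = ClassifyParams(orf_cutoff_aa=cutoff)
            _, c = classify_set(
                transcriptome.transcripts[:60],
                transcriptome.proteins,
                None,
                transcriptome.hk_db,
                params,
            )
            counts.append(c["MLNC_CANDIDATE"])
        assert counts == sorted(counts)


class TestClassifySet:
    def test_empty_input(self):
        table, counts = classify_set([], annotation_table=set())
        assert table.empty and counts.sum() == 0

    def test_duplicate_ids_rejected(self, rng):
        t = Transcript("dup", _rand(rng, 400))
        with pytest.raises(ValueError):
            classify_set([t, t], annotation_table=set())

    def test_all_annotated(self, rng):
        ts = [Transcript(f"t{i}", _rand(rng, 350)) for i in range(4)]
        table, counts = classify_set(ts, annotation_table={t.id for t in ts})
        assert set(table["class"]) == {"ANNOTATED_CODING"}
        assert counts["ANNOTATED_CODING"] == 4

    def test_partition_covers_input(self, transcriptome):
        sub = transcriptome.transcripts[:50]
        table, counts = classify_set(
            sub, transcriptome.proteins, None, transcriptome.hk_db
        )
        assert len(table) == 50
        assert counts.sum() == 50
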