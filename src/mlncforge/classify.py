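"""Decision-tree classification of unigenes.

The tree partitions a transcript set into five classes: transcripts with
protein homology (annotated coding), short unannotated transcripts
(< 300 bp, set aside), unannotated transcripts whose longest ORF reaches
the coding-potential cutoff (novel coding, 100 aa), transcripts matching a
housekeeping ncRNA reference (tRNA/snoRNA class), and the remainder:
mRNA-like long non-coding RNA candidates.  The housekeeping screen runs
after the ORF test, so a long-ORF transcript is never called housekeeping.

Protein homology is a translated local-alignment search (six-frame
translation split at stops, BLOSUM62 scoring) against a user-supplied
protein FASTA, or a precomputed annotation table; both stand in for a
full-scale Nr search.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .homology import NucleotideScoring, local_align
from .seq_core import OrfCall, Transcript, find_orfs, max_orf_aa, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptClass",
    "ClassifyParams",
    "annotate_by_protein_homology",
    "screen_housekeeping",
    "classify_transcript",
    "classify_set",
]


class TranscriptClass(str, Enum):
    ANNOTATED_CODING = "ANNOTATED_CODING"
    SHORT_UNANNOTATED = "SHORT_UNANNOTATED"
    NOVEL_CODING = "NOVEL_CODING"
    MLNC_CANDIDATE = "MLNC_CANDIDATE"
    HOUSEKEEPING_NPCRNA = "HOUSEKEEPING_NPCRNA"


@dataclass
class ClassifyParams:
    min_length: int = 300
    orf_cutoff_aa: int = 100
    annotation_evalue: float = 1e-5
    housekeeping_evalue: float = 1e-5
    count_partial_orfs: bool = True  # 3'-open partials count toward the cutoff
    # ungapped Karlin-Altschul constants for BLOSUM62
    protein_karlin_k: float = 0.134
    protein_karlin_lambda: float = 0.3176
    min_translated_segment: int = 15  # aa; shorter stop-free segments skipped

    def __post_init__(self) -> None:
        if min(self.min_length, self.orf_cutoff_aa) <= 0:
            raise ValueError("thresholds must be positive")
        if min(self.annotation_evalue, self.housekeeping_evalue) <= 0:
            raise ValueError("E-value cutoffs must be positive")


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _six_frame_segments(t: Transcript, min_len: int) -> list[str]:
    """Stop-free translated segments of all six frames."""
    segments: list[str] = []
    for seq in (t.seq, reverse_complement(t.seq)):
        for frame in range(3):
            trimmed = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
            if len(trimmed) < 3:
                continue
            aa = str(Seq(trimmed).translate())
            segments.extend(s for s in aa.split("*") if len(s) >= min_len)
    return segments


def annotate_by_protein_homology(
    t: Transcript,
    proteins: dict[str, str] | None,
    params: ClassifyParams | None = None,
    annotation_table: set[str] | None = None,
) -> tuple[bool, str | None]:
    """Is the transcript homologous to a known protein?

    A precomputed annotation table (set of annotated transcript ids) takes
    precedence; otherwise every stop-free six-frame translation segment is
    locally aligned (BLOSUM62) to each reference protein and the best
    Karlin-Altschul E-value is compared with ``annotation_evalue``.
    Returns (annotated, evidence).
    """
    params = params or ClassifyParams()
    if annotation_table is not None and t.id in annotation_table:
        return True, "annotation_table"
    if not proteins:
        if annotation_table is not None:
            return False, None
        raise ValueError("neither a protein set nor an annotation table provided")
    segments = _six_frame_segments(t, params.min_translated_segment)
    if not segments:
        return False, None
    aligner = _protein_aligner()
    db_len = sum(len(p) for p in proteins.values())
    best_e, best_id = math.inf, None
    for pid in sorted(proteins):
        pseq = proteins[pid]
        for seg in segments:
            score = float(aligner.score(seg, pseq))
            if score <= 0:
                continue
            e = (
                params.protein_karlin_k
                * len(seg)
                * db_len
                * math.exp(-params.protein_karlin_lambda * score)
            )
            if e < best_e:
                best_e, best_id = e, pid
    if best_e <= params.annotation_evalue:
        return True, f"{best_id}:E={best_e:.2e}"
    return False, None


def screen_housekeeping(
    t: Transcript,
    hk_db: dict[str, str] | None,
    params: ClassifyParams | None = None,
    scoring: NucleotideScoring | None = None,
):
    """Best nucleotide hit against the housekeeping ncRNA reference set.

    Returns the qualifying AlignmentHit (E <= housekeeping_evalue) or None;
    an empty database passes everyone through.
    """
    params = params or ClassifyParams()
    if not hk_db:
        return None
    scoring = scoring or NucleotideScoring()
    db_len = sum(len(s) for s in hk_db.values())
    best = None
    for hid in sorted(hk_db):
        hit = local_align(
            t.seq, hk_db[hid], scoring, query_id=t.id, subject_id=hid, db_len=db_len
        )
        if hit and (best is None or hit.evalue < best.evalue):
            best = hit
    if best is not None and best.evalue <= params.housekeeping_evalue:
        return best
    return None


def classify_transcript(
    t: Transcript,
    annotated: bool,
    hk_hit,
    orfs: list[OrfCall],
    params: ClassifyParams | None = None,
) -> TranscriptClass:
    """Apply the decision tree to one transcript."""
    params = params or ClassifyParams()
    if annotated:
        return TranscriptClass.ANNOTATED_CODING
    if t.length < params.min_length:
        return TranscriptClass.SHORT_UNANNOTATED
    if max_orf_aa(orfs, include_partials=params.count_partial_orfs) >= params.orf_cutoff_aa:
        return TranscriptClass.NOVEL_CODING
    if hk_hit is not None:
        return TranscriptClass.HOUSEKEEPING_NPCRNA
    return TranscriptClass.MLNC_CANDIDATE


def classify_set(
    transcripts: list[Transcript],
    proteins: dict[str, str] | None = None,
    annotation_table: set[str] | None = None,
    hk_db: dict[str, str] | None = None,
    params: ClassifyParams | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify a transcript set; returns (per-transcript table, class counts).

    The table columns are id, length, class, best_orf_aa, hk_hit_id and
    annotation_evidence; counts cover all five classes (zeros included).
    Deterministic for fixed inputs.
    """
    params = params or ClassifyParams()
    ids = [t.id for t in transcripts]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids")
    if proteins is None and annotation_table is None:
        annotation_table = set()  # nothing annotated
    rows = []
    for t in transcripts:
        orfs = find_orfs(t) if t.length >= 3 else []
        annotated, evidence = annotate_by_protein_homology(
            t, proteins, params, annotation_table
        )
        hk_hit = None
        if not annotated and t.length >= params.min_length:
            best_aa = max_orf_aa(orfs, include_partials=params.count_partial_orfs)
            if best_aa < params.orf_cutoff_aa:
                hk_hit = screen_housekeeping(t, hk_db, params)
        cls = classify_transcript(t, annotated, hk_hit, orfs, params)
        rows.append(
            {
                "id": t.id,
                "length": t.length,
                "class": cls.value,
                "best_orf_aa": max_orf_aa(orfs, include_partials=params.count_partial_orfs),
                "hk_hit_id": hk_hit.subject_id if hk_hit else "",
                "annotation_evidence": evidence or "",
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["id", "length", "class", "best_orf_aa", "hk_hit_id", "annotation_evidence"],
    )
    counts = (
        table["class"].value_counts().reindex([c.value for c in TranscriptClass], fill_value=0)
    )
    return table, counts
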