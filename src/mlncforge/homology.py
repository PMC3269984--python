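"""Local alignment with E-value estimation, mlncRNA family clustering,
conservation screening, and mlncRNA <-> protein-coding gene relations.

The nucleotide search is a desk-scale stand-in for BLASTN: optimal
Smith-Waterman local alignment (Biopython's PairwiseAligner engine) under
+2/-3 match/mismatch with affine gaps (-5 first gap position, -2 each
additional), and Karlin-Altschul E-values E = K m n exp(-lambda S) with the
standard ungapped-approximation constants K = 0.41, lambda = 0.625 for this
scoring.  The constants parameterise threshold behaviour only; absolute
E-values at BLAST scale are not the goal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from Bio import Align

from .seq_core import OrfCall, Transcript, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "NucleotideScoring",
    "AlignmentHit",
    "Family",
    "HomologyRelation",
    "local_align",
    "estimate_evalue",
    "cluster_families",
    "conservation_screen",
    "relate_mlnc_to_coding",
]


@dataclass(frozen=True)
class NucleotideScoring:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0  # score of the first position of a gap
    gap_extend: float = -2.0
    karlin_k: float = 0.41
    karlin_lambda: float = 0.625


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    evalue: float
    identity: float
    strand: str  # subject strand relative to query
    q_start: int
    q_end: int
    s_start: int
    s_end: int

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end and self.s_start < self.s_end):
            raise ValueError("alignment spans must be non-empty")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity outside [0, 1]")


@dataclass(frozen=True)
class Family:
    family_id: str
    member_ids: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("a family needs at least 2 members")


@dataclass(frozen=True)
class HomologyRelation:
    mlnc_id: str
    coding_id: str
    orientation: str  # sense | antisense
    region: str  # CDS | UTR5 | UTR3 | junction
    identity: float
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int


def _make_aligner(scoring: NucleotideScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # Biopython's open_gap_score is the score of the first gap position
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_score(a: str, b: str, scoring: NucleotideScoring | None = None) -> float:
    """Optimal local alignment score only (no traceback; fast path)."""
    scoring = scoring or NucleotideScoring()
    if not a or not b:
        raise ValueError("empty sequence")
    return float(_make_aligner(scoring).score(a, b))


def local_align(
    a: str,
    b: str,
    scoring: NucleotideScoring | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    strand: str = "+",
    db_len: int | None = None,
) -> AlignmentHit | None:
    """Best Smith-Waterman local alignment of ``a`` vs ``b``.

    Returns None when no positive-scoring alignment exists.  ``db_len``
    (total subject database length) feeds the E-value; defaults to len(b).
    Among co-optimal alignments the engine's first traceback is reported;
    it starts at the smallest (q_start, s_start) in the engine's fixed
    decision order.
    """
    scoring = scoring or NucleotideScoring()
    aligner = _make_aligner(scoring)
    if not a or not b:
        raise ValueError("empty sequence")
    score = float(aligner.score(a, b))
    if score <= 0:
        return None
    aln = next(iter(aligner.align(a, b)))
    (q_blocks, s_blocks) = aln.aligned
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    s_start, s_end = int(s_blocks[0][0]), int(s_blocks[-1][1])
    matches = 0
    columns = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        for qi, si in zip(range(qs, qe), range(ss, se)):
            columns += 1
            if a[qi] == b[si]:
                matches += 1
    # count gap columns between blocks
    for k in range(1, len(q_blocks)):
        columns += (q_blocks[k][0] - q_blocks[k - 1][1]) + (s_blocks[k][0] - s_blocks[k - 1][1])
    evalue = estimate_evalue(
        score, len(a), db_len if db_len is not None else len(b), scoring
    )
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        score=score,
        evalue=evalue,
        identity=matches / columns if columns else 0.0,
        strand=strand,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
    )


def estimate_evalue(
    score: float, m: int, n: int, scoring: NucleotideScoring | None = None
) -> float:
    """Karlin-Altschul E = K m n exp(-lambda S)."""
    scoring = scoring or NucleotideScoring()
    if m <= 0 or n <= 0:
        raise ValueError("sequence/database lengths must be positive")
    if score <= 0:
        raise ValueError("score must be positive")
    return scoring.karlin_k * m * n * math.exp(-scoring.karlin_lambda * score)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def cluster_families(
    seqs: dict[str, str],
    e_cutoff: float = 1e-5,
    scoring: NucleotideScoring | None = None,
) -> tuple[list[Family], list[str]]:
    """Single-linkage families from all-vs-all local alignment.

    Two sequences are linked when their best local alignment has
    E <= e_cutoff against a database of total length sum(len(s)).
    Components of size >= 2 become families, numbered in order of their
    lexicographically smallest member; the rest are singletons.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    scoring = scoring or NucleotideScoring()
    ids = sorted(seqs)
    db_len = sum(len(s) for s in seqs.values())
    uf = _UnionFind(ids)
    for i, qid in enumerate(ids):
        for sid in ids[i + 1 :]:
            score = align_score(seqs[qid], seqs[sid], scoring)
            if score <= 0:
                continue
            e = estimate_evalue(score, len(seqs[qid]), db_len, scoring)
            if e <= e_cutoff:
                uf.union(qid, sid)
    comps: dict[str, list[str]] = {}
    for x in ids:
        comps.setdefault(uf.find(x), []).append(x)
    multi = sorted((sorted(members) for members in comps.values() if len(members) >= 2),
                   key=lambda m: m[0])
    families = [
        Family(family_id=f"FAM{k + 1:04d}", member_ids=frozenset(members))
        for k, members in enumerate(multi)
    ]
    in_family = {m for f in families for m in f.member_ids}
    singletons = [x for x in ids if x not in in_family]
    return families, singletons


def conservation_screen(
    mlncs: dict[str, str],
    known_db: dict[str, str],
    e_cutoff: float = 1e-5,
    scoring: NucleotideScoring | None = None,
) -> list[AlignmentHit]:
    """mlncRNAs conserved in a known-npcRNA database (best hit E <= cutoff)."""
    scoring = scoring or NucleotideScoring()
    hits: list[AlignmentHit] = []
    if not known_db:
        return hits
    db_len = sum(len(s) for s in known_db.values())
    for qid in sorted(mlncs):
        best: AlignmentHit | None = None
        for sid in sorted(known_db):
            score = align_score(mlncs[qid], known_db[sid], scoring)
            if score <= 0:
                continue
            hit = local_align(
                mlncs[qid], known_db[sid], scoring,
                query_id=qid, subject_id=sid, db_len=db_len,
            )
            if hit and (best is None or hit.evalue < best.evalue):
                best = hit
        if best is not None and best.evalue <= e_cutoff:
            hits.append(best)
    return hits


def _classify_region(s_start: int, s_end: int, orf: OrfCall, n: int) -> str:
    """Locate a subject interval relative to the ORF: CDS, UTR or junction."""
    left = (0, orf.start)
    cds = (orf.start, orf.end)
    right = (orf.end, n)
    if orf.strand == "+":
        utr5, utr3 = left, right
    else:
        utr5, utr3 = right, left
    if cds[0] <= s_start and s_end <= cds[1]:
        return "CDS"
    if utr5[0] <= s_start and s_end <= utr5[1]:
        return "UTR5"
    if utr3[0] <= s_start and s_end <= utr3[1]:
        return "UTR3"
    return "junction"


def relate_mlnc_to_coding(
    mlncs: dict[str, str],
    coding: list[tuple[Transcript, OrfCall]],
    e_cutoff: float = 1e-5,
    scoring: NucleotideScoring | None = None,
) -> list[HomologyRelation]:
    """Sense/antisense relations between mlncRNAs and coding transcripts.

    Each coding transcript is searched on both strands; qualifying hits
    (E <= cutoff) yield one relation with orientation from the hit strand
    and region from the overlap of the subject interval with the coding
    gene's ORF (CDS, UTR5, UTR3, or junction).
    """
    scoring = scoring or NucleotideScoring()
    relations: list[HomologyRelation] = []
    db_len = sum(t.length for t, _ in coding)
    for qid in sorted(mlncs):
        q = mlncs[qid]
        for t, orf in coding:
            if orf is None:
                logger.warning("coding transcript %s has no ORF; skipped", t.id)
                continue
            best: AlignmentHit | None = None
            for strand, subject in (("+", t.seq), ("-", reverse_complement(t.seq))):
                score = align_score(q, subject, scoring)
                if score <= 0:
                    continue
                hit = local_align(
                    q, subject, scoring,
                    query_id=qid, subject_id=t.id, strand=strand, db_len=db_len,
                )
                if hit and (best is None or hit.score > best.score):
                    best = hit
            if best is None or best.evalue > e_cutoff:
                continue
            if best.strand == "-":  # map subject interval back to forward strand
                s_start = t.length - best.s_end
                s_end = t.length - best.s_start
            else:
                s_start, s_end = best.s_start, best.s_end
            relations.append(
                HomologyRelation(
                    mlnc_id=qid,
                    coding_id=t.id,
                    orientation="sense" if best.strand == "+" else "antisense",
                    region=_classify_region(s_start, s_end, orf, t.length),
                    identity=best.identity,
                    evalue=best.evalue,
                    q_start=best.q_start,
                    q_end=best.q_end,
                    s_start=s_start,
                    s_end=s_end,
                )
            )
    return relations
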