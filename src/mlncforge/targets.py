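"""miRNA target prediction by penalty scoring of miRNA:mRNA duplexes.

A target site is scored by a weighted count of imperfections in the
anti-parallel duplex between the miRNA (5'->3') and a transcript window:
Watson-Crick pairs are free, G:U wobbles cost ``gu_penalty``, mismatches
``mismatch_penalty`` and each gapped position ``gap_penalty``; penalties at
miRNA positions in the seed range (2-13 from the 5' end, 1-based) are
doubled.  Sites scoring at or below the cutoff (default 3) are reported.

Windows slide by 1 nt along the transcript forward strand and have the
miRNA's own length (nominally the 20-base scale of the scoring window), so
a perfect reverse-complement site scores exactly 0.  The optimal gapped
pairing (at most ``max_gaps`` gap positions) is found by dynamic
programming; a numba kernel accelerates the genome-scale scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit

from .seq_core import Transcript, as_rna, normalize_seq

INF = 1e18

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

__all__ = ["PenaltySchema", "TargetHit", "score_duplex", "predict_targets"]


@dataclass
class PenaltySchema:
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    gap_penalty: float = 2.0
    seed_start: int = 2  # 1-based, inclusive, from miRNA 5' end
    seed_end: int = 13
    seed_multiplier: float = 2.0
    max_score: float = 3.0
    window_nt: int = 20
    max_gaps: int = 2

    def weight(self, i: int) -> float:
        """Multiplier for 0-based miRNA index ``i`` (position i+1)."""
        return self.seed_multiplier if self.seed_start <= i + 1 <= self.seed_end else 1.0


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    t_start: int  # 0-based half-open on the transcript
    t_end: int
    penalty: float
    duplex: tuple[str, str, str]  # miRNA 5'->3', pairing line, site 3'->5'


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq], dtype=np.int64)


def _pair_class(mi: int, sj: int) -> int:
    """0 = Watson-Crick, 1 = G:U wobble, 2 = mismatch."""
    if mi > 3 or sj > 3:
        return 2
    if (mi, sj) in ((0, 3), (3, 0), (1, 2), (2, 1)):
        return 0
    if (mi, sj) in ((2, 3), (3, 2)):
        return 1
    return 2


def _dp(m: np.ndarray, s: np.ndarray, schema: PenaltySchema):
    """Minimum-penalty global anti-parallel pairing; returns (penalty, table).

    ``s`` must already be reversed (site 3'->5'), so m[i] pairs s[j].
    """
    Lm, Ls = len(m), len(s)
    G = schema.max_gaps
    D = np.full((Lm + 1, Ls + 1, G + 1), INF)
    D[0, 0, 0] = 0.0
    for i in range(Lm + 1):
        wi = schema.weight(i) if i < Lm else 1.0
        for j in range(Ls + 1):
            for g in range(G + 1):
                cur = D[i, j, g]
                if cur >= INF:
                    continue
                if i < Lm and j < Ls:
                    cls = _pair_class(m[i], s[j])
                    cost = (
                        0.0
                        if cls == 0
                        else (schema.gu_penalty if cls == 1 else schema.mismatch_penalty)
                    ) * schema.weight(i)
                    if cur + cost < D[i + 1, j + 1, g]:
                        D[i + 1, j + 1, g] = cur + cost
                if g < G:
                    if i < Lm:  # miRNA base unpaired (gap in site)
                        cost = schema.gap_penalty * schema.weight(i)
                        if cur + cost < D[i + 1, j, g + 1]:
                            D[i + 1, j, g + 1] = cur + cost
                    if j < Ls:  # site base bulged (gap in miRNA)
                        cost = schema.gap_penalty * wi
                        if cur + cost < D[i, j + 1, g + 1]:
                            D[i, j + 1, g + 1] = cur + cost
    return float(D[Lm, Ls, :].min()), D


def score_duplex(
    mirna: str, site: str, schema: PenaltySchema | None = None
) -> tuple[float, tuple[str, str, str]]:
    """Penalty and rendered duplex for a miRNA against one candidate site.

    ``site`` is the transcript window 5'->3' on the forward strand; the
    duplex is anti-parallel, so the miRNA 5' end faces the site 3' end.
    """
    schema = schema or PenaltySchema()
    if not mirna or not site:
        raise ValueError("empty sequence")
    m_seq = normalize_seq(mirna)
    s_seq = normalize_seq(site)[::-1]  # 3'->5'
    if abs(len(m_seq) - len(s_seq)) > schema.max_gaps:
        raise ValueError("site length incompatible with the gap cap")
    m, s = _encode(m_seq), _encode(s_seq)
    penalty, D = _dp(m, s, schema)
    # traceback (first-match in a fixed order: pair, miRNA-gap, site-gap)
    Lm, Ls = len(m), len(s)
    g = int(np.argmin(D[Lm, Ls, :]))
    i, j = Lm, Ls
    ops: list[str] = []
    while i > 0 or j > 0:
        cur = D[i, j, g]
        done = False
        if i > 0 and j > 0:
            cls = _pair_class(m[i - 1], s[j - 1])
            cost = (
                0.0 if cls == 0 else (schema.gu_penalty if cls == 1 else schema.mismatch_penalty)
            ) * schema.weight(i - 1)
            if abs(D[i - 1, j - 1, g] + cost - cur) < 1e-9:
                ops.append("P")
                i, j = i - 1, j - 1
                done = True
        if not done and g > 0 and i > 0:
            cost = schema.gap_penalty * schema.weight(i - 1)
            if abs(D[i - 1, j, g - 1] + cost - cur) < 1e-9:
                ops.append("D")
                i, g = i - 1, g - 1
                done = True
        if not done and g > 0 and j > 0:
            wi = schema.weight(i) if i < Lm else 1.0
            cost = schema.gap_penalty * wi
            if abs(D[i, j - 1, g - 1] + cost - cur) < 1e-9:
                ops.append("I")
                j, g = j - 1, g - 1
                done = True
        if not done:  # pragma: no cover - defensive
            raise RuntimeError("duplex traceback failed")
    ops.reverse()
    m_rna, s_rev = as_rna(m_seq), as_rna(s_seq[::-1])[::-1]
    mi = si = 0
    top, mid, bot = [], [], []
    for op in ops:
        if op == "P":
            a, b = m_rna[mi], s_rev[si]
            cls = _pair_class(m[mi], s[si])
            top.append(a)
            bot.append(b)
            mid.append("|" if cls == 0 else ("o" if cls == 1 else " "))
            mi += 1
            si += 1
        elif op == "D":
            top.append(m_rna[mi])
            bot.append("-")
            mid.append(" ")
            mi += 1
        else:
            top.append("-")
            bot.append(s_rev[si])
            mid.append(" ")
            si += 1
    return penalty, ("".join(top), "".join(mid), "".join(bot))


@njit(cache=True)
def _scan_kernel(t_codes, m_codes, weights, mismatch, gu, gap, max_gaps):
    """Per-start minimum duplex penalty of the miRNA against each window."""
    Lm = m_codes.shape[0]
    n = t_codes.shape[0]
    n_starts = n - Lm + 1
    out = np.full(max(n_starts, 0), np.inf)
    D = np.empty((Lm + 1, Lm + 1, max_gaps + 1))
    for start in range(n_starts):
        Ls = Lm
        for i in range(Lm + 1):
            for j in range(Ls + 1):
                for g in range(max_gaps + 1):
                    D[i, j, g] = 1e18
        D[0, 0, 0] = 0.0
        for i in range(Lm + 1):
            wi = weights[i] if i < Lm else 1.0
            for j in range(Ls + 1):
                for g in range(max_gaps + 1):
                    cur = D[i, j, g]
                    if cur >= 1e18:
                        continue
                    if i < Lm and j < Ls:
                        mi = m_codes[i]
                        sj = t_codes[start + Ls - 1 - j]  # site read 3'->5'
                        if mi > 3 or sj > 3:
                            cost = mismatch
                        elif (
                            (mi == 0 and sj == 3)
                            or (mi == 3 and sj == 0)
                            or (mi == 1 and sj == 2)
                            or (mi == 2 and sj == 1)
                        ):
                            cost = 0.0
                        elif (mi == 2 and sj == 3) or (mi == 3 and sj == 2):
                            cost = gu
                        else:
                            cost = mismatch
                        cost *= weights[i]
                        if cur + cost < D[i + 1, j + 1, g]:
                            D[i + 1, j + 1, g] = cur + cost
                    if g < max_gaps:
                        if i < Lm:
                            cost = gap * weights[i]
                            if cur + cost < D[i + 1, j, g + 1]:
                                D[i + 1, j, g + 1] = cur + cost
                        if j < Ls:
                            cost = gap * wi
                            if cur + cost < D[i, j + 1, g + 1]:
                                D[i, j + 1, g + 1] = cur + cost
        best = 1e18
        for g in range(max_gaps + 1):
            if D[Lm, Ls, g] < best:
                best = D[Lm, Ls, g]
        out[start] = best
    return out


def scan_penalties(mirna: str, transcript_seq: str, schema: PenaltySchema | None = None) -> np.ndarray:
    """Duplex penalty for every window start along the transcript."""
    schema = schema or PenaltySchema()
    m = _encode(normalize_seq(mirna))
    t = _encode(normalize_seq(transcript_seq))
    weights = np.array([schema.weight(i) for i in range(len(m))], dtype=np.float64)
    return _scan_kernel(
        t, m, weights,
        schema.mismatch_penalty, schema.gu_penalty, schema.gap_penalty, schema.max_gaps,
    )


def predict_targets(
    mirnas: dict[str, str],
    transcripts: list[Transcript],
    schema: PenaltySchema | None = None,
) -> list[TargetHit]:
    """All target sites scoring <= ``schema.max_score``.

    Overlapping qualifying windows per (miRNA, transcript) collapse to the
    local penalty minimum (ties to the leftmost).  Sorted by penalty, then
    miRNA, transcript and coordinate.
    """
    schema = schema or PenaltySchema()
    hits: list[TargetHit] = []
    for mid in sorted(mirnas):
        m_seq = normalize_seq(mirnas[mid])
        L = len(m_seq)
        for t in transcripts:
            if t.length < L:
                continue
            pen = scan_penalties(m_seq, t.seq, schema)
            qual = np.flatnonzero(pen <= schema.max_score)
            if qual.size == 0:
                continue
            # collapse runs of overlapping qualifying windows
            groups: list[list[int]] = [[int(qual[0])]]
            for p in qual[1:]:
                if int(p) < groups[-1][-1] + L:
                    groups[-1].append(int(p))
                else:
                    groups.append([int(p)])
            for grp in groups:
                best = min(grp, key=lambda p: (pen[p], p))
                site = t.seq[best : best + L]
                penalty, duplex = score_duplex(m_seq, site, schema)
                hits.append(
                    TargetHit(
                        mirna_id=mid,
                        transcript_id=t.id,
                        t_start=best,
                        t_end=best + L,
                        penalty=penalty,
                        duplex=duplex,
                    )
                )
    hits.sort(key=lambda h: (h.penalty, h.mirna_id, h.transcript_id, h.t_start))
    return hits


def hits_table(hits: list[TargetHit]) -> "object":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "mirna_id": h.mirna_id,
                "transcript_id": h.transcript_id,
                "start1": h.t_start + 1,
                "end1": h.t_end,
                "penalty": h.penalty,
            }
            for h in hits
        ]
    )
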