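"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written straight from the definitions (exhaustive
enumeration or naive recursion), deliberately sharing no code with the
package internals.
"""

from __future__ import annotations

from functools import lru_cache

NEG = -1e18
INF = 1e18

# ---------------------------------------------------------------- alignment

def sw_score(a: str, b: str, match=2.0, mismatch=-3.0, gap_open=-5.0, gap_ext=-2.0) -> float:
    """Smith-Waterman local score with affine gaps (first gap position costs
    ``gap_open``, each further position ``gap_ext``); naive three-state DP."""
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_ext)
            Iy[i][j] = max(M[i][j - 1] + gap_open, Iy[i][j - 1] + gap_ext)
            best = max(best, M[i][j])
    return best


# ------------------------------------------------------------------ folding

_CAN_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def all_structures(seq: str, min_loop: int = 3) -> list[str]:
    """Every nested secondary structure over allowed pairs (WC + G:U) with
    hairpin loops of at least ``min_loop`` unpaired bases."""
    rna = seq.upper().replace("T", "U")

    @lru_cache(maxsize=None)
    def structs(i: int, j: int) -> tuple[str, ...]:
        if j - i < 1:
            return ("." * max(0, j - i),)
        out = ["." + rest for rest in structs(i + 1, j)]
        for k in range(i + min_loop + 1, j):
            if (rna[i], rna[k]) in _CAN_PAIR:
                for inner in structs(i + 1, k):
                    for after in structs(k + 1, j):
                        out.append("(" + inner + ")" + after)
        return tuple(out)

    return list(structs(0, len(rna)))


def min_energy_structure(seq: str, energy_fn) -> tuple[str, float]:
    """Exhaustive minimum over all structures under an energy evaluator."""
    best_s, best_e = "." * len(seq), 0.0
    for st in all_structures(seq):
        try:
            e = energy_fn(seq, st)
        except ValueError:
            continue
        if e < best_e - 1e-12:
            best_s, best_e = st, e
    return best_s, best_e


# --------------------------------------------------------------------- ORFs

_STOPS = {"TAA", "TAG", "TGA"}
_RC = str.maketrans("ACGTN", "TGCAN")


def orf_calls(seq: str) -> set[tuple[str, int, int, int, int, bool]]:
    """All maximal ORFs as (strand, frame, fwd_start, fwd_end, aa, complete).

    Enumerates every (strand, frame, ATG) triple, takes the first in-frame
    stop (or the last full codon for 3'-open partials) and keeps the
    longest ORF per terminus.
    """
    n = len(seq)
    results: dict[tuple, tuple] = {}
    for strand in ("+", "-"):
        s = seq if strand == "+" else seq.translate(_RC)[::-1]
        for frame in range(3):
            for atg in range(frame, n - 2, 3):
                if s[atg : atg + 3] != "ATG":
                    continue
                end = None
                for k in range(atg, n - 2, 3):
                    if s[k : k + 3] in _STOPS:
                        end = k + 3
                        break
                if end is not None:
                    complete = True
                else:
                    end = atg + 3 * ((n - atg) // 3)
                    complete = False
                aa = (end - atg) // 3 - (1 if complete else 0)
                if aa <= 0:
                    continue
                key = (strand, frame, end, complete)
                if key not in results or results[key][0] > atg:
                    results[key] = (atg, aa)
    out = set()
    for (strand, frame, end, complete), (start, aa) in results.items():
        if strand == "+":
            fs, fe = start, end
        else:
            fs, fe = n - end, n - start
        out.add((strand, frame, fs, fe, aa, complete))
    return out


# ------------------------------------------------------------ duplex penalty

def duplex_penalty(
    mirna: str,
    site: str,
    mismatch=1.0,
    gu=0.5,
    gap=2.0,
    seed_start=2,
    seed_end=13,
    seed_mult=2.0,
    max_gaps=2,
) -> float:
    """Minimum-penalty anti-parallel gapped pairing by naive recursion.

    ``site`` is the transcript window 5'->3'; the miRNA 5' end faces the
    site 3' end.  Penalties at miRNA positions ``seed_start..seed_end``
    (1-based) are multiplied by ``seed_mult``.
    """
    m = mirna.upper().replace("U", "T")
    s = site.upper().replace("U", "T")[::-1]
    Lm, Ls = len(m), len(s)
    wc = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
    wobble = {("G", "T"), ("T", "G")}

    def weight(i: int) -> float:
        return seed_mult if seed_start <= i + 1 <= seed_end else 1.0

    def pair_cost(i: int, j: int) -> float:
        duo = (m[i], s[j])
        if duo in wc:
            return 0.0
        if duo in wobble:
            return gu * weight(i)
        return mismatch * weight(i)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, g: int) -> float:
        if i == Lm and j == Ls:
            return 0.0
        out = INF
        if i < Lm and j < Ls:
            out = min(out, pair_cost(i, j) + best(i + 1, j + 1, g))
        if g < max_gaps:
            if i < Lm:
                out = min(out, gap * weight(i) + best(i + 1, j, g + 1))
            if j < Ls:
                w = weight(i) if i < Lm else 1.0
                out = min(out, gap * w + best(i, j + 1, g + 1))
        return out

    return best(0, 0, 0)


# ---------------------------------------------------------------- sliding Hamming

def mature_windows(transcript: str, mature: str, max_mm: int) -> set[tuple[int, str, int]]:
    """Seed-free sliding-Hamming scan on both strands.

    Returns (forward_start, strand, mismatches) for every qualifying
    equal-length window.
    """
    t = transcript.upper().replace("U", "T")
    m = mature.upper().replace("U", "T")
    rc = t.translate(_RC)[::-1]
    n, L = len(t), len(m)
    out = set()
    for strand, s in (("+", t), ("-", rc)):
        for start in range(n - L + 1):
            mm = sum(1 for x, y in zip(m, s[start : start + L]) if x != y)
            if mm <= max_mm:
                fwd = start if strand == "+" else n - (start + L)
                out.add((fwd, strand, mm))
    return out
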