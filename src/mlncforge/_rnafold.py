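"""Minimum-free-energy RNA secondary structure prediction.

A Zuker-style dynamic program over a simplified Turner-like
nearest-neighbour model: Watson-Crick and G:U stacks, size-dependent
hairpin / bulge / internal loop penalties (with an asymmetry term), and an
affine multiloop cost.  No pseudoknots, no dangling ends, no terminal-AU
penalty, no special-case tetraloops; interior loops are capped at 30
unpaired bases as usual.  Parameters live in ``data/rna_energy_params.json``
and are deliberately editable: the procedure, not the parameter file, is
the point.

The O(n^3) fill runs under numba; traceback re-derives decisions in Python
from the filled matrices.  ``energy_of_structure`` evaluates any dot-bracket
structure under the same model and is what the exhaustive-enumeration
oracle in the test-suite compares against.
"""

from __future__ import annotations

import json
import math
from functools import lru_cache
from importlib import resources

import numpy as np
from numba import njit

INF = 1e9

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": -1}

# pair order AU, UA, GC, CG, GU, UG to match the parameter file
_PAIR_CODE = -np.ones((4, 4), dtype=np.int64)
_PAIR_CODE[0, 3] = 0  # A-U
_PAIR_CODE[3, 0] = 1  # U-A
_PAIR_CODE[2, 1] = 2  # G-C
_PAIR_CODE[1, 2] = 3  # C-G
_PAIR_CODE[2, 3] = 4  # G-U
_PAIR_CODE[3, 2] = 5  # U-G


class FoldError(ValueError):
    pass


class EnergyModel:
    """Loaded nearest-neighbour parameter set with loop-size extrapolation."""

    def __init__(self, params: dict):
        self.params = params
        self.stack = np.array(params["stack"], dtype=np.float64)
        self.hairpin_min = int(params["hairpin_min"])
        self.rt = float(params["rt"])
        self._hairpin = list(params["hairpin"])
        self._bulge = list(params["bulge"])
        self._internal = list(params["internal"])
        self.asym = float(params["internal_asymmetry"])
        self.asym_max = float(params["internal_asymmetry_max"])
        self.ml_a = float(params["multiloop_closing"])
        self.ml_b = float(params["multiloop_unpaired"])
        self.ml_c = float(params["multiloop_branch"])
        self.max_interior = int(params["max_interior_size"])

    def _extrapolate(self, table: list[float], first_size: int, size: int) -> float:
        last_size = first_size + len(table) - 1
        if size <= last_size:
            return table[size - first_size]
        return table[-1] + 1.75 * self.rt * math.log(size / last_size)

    def hairpin_energy(self, size: int) -> float:
        if size < self.hairpin_min:
            return INF
        return self._extrapolate(self._hairpin, 3, size)

    def bulge_energy(self, size: int) -> float:
        return self._extrapolate(self._bulge, 1, size)

    def internal_energy(self, l1: int, l2: int) -> float:
        base = self._extrapolate(self._internal, 2, l1 + l2)
        return base + min(self.asym_max, self.asym * abs(l1 - l2))

    def loop_tables(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense per-size lookup arrays for the numba fill (sizes 0..n)."""
        hp = np.full(n + 1, INF)
        bu = np.full(n + 1, INF)
        inn = np.full(n + 1, INF)
        for s in range(n + 1):
            if s >= self.hairpin_min:
                hp[s] = self.hairpin_energy(s)
            if s >= 1:
                bu[s] = self.bulge_energy(s)
            if s >= 2:
                inn[s] = self._extrapolate(self._internal, 2, s)
        return hp, bu, inn


@lru_cache(maxsize=1)
def default_model() -> EnergyModel:
    text = resources.files("mlncforge.data").joinpath("rna_energy_params.json").read_text()
    return EnergyModel(json.loads(text))


def encode(seq: str) -> np.ndarray:
    codes = np.array([_BASE_CODE[b] for b in seq.upper().replace("U", "T")], dtype=np.int64)
    return codes


def pair_code(a: int, b: int) -> int:
    if a < 0 or b < 0:
        return -1
    return int(_PAIR_CODE[a, b])


@njit(cache=True)
def _fill(codes, pairmat, stack, hp, bu, inn, asym, asym_max, ml_a, ml_b, ml_c, max_int, min_hp):
    n = codes.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for d in range(min_hp + 1, n):
        for i in range(0, n - d):
            j = i + d
            ci = codes[i]
            cj = codes[j]
            pc = -1
            if ci >= 0 and cj >= 0:
                pc = pairmat[ci, cj]
            if pc >= 0:
                best = hp[d - 1] if d - 1 <= n else INF
                # stack / bulge / interior loops
                for p in range(i + 1, j - min_hp - 1):
                    l1 = p - i - 1
                    if l1 > max_int:
                        break
                    for q in range(p + min_hp + 1, j):
                        l2 = j - q - 1
                        if l1 + l2 > max_int:
                            continue
                        v = V[p, q]
                        if v >= INF:
                            continue
                        cp = codes[p]
                        cq = codes[q]
                        pc2 = pairmat[cp, cq] if (cp >= 0 and cq >= 0) else -1
                        if pc2 < 0:
                            continue
                        if l1 == 0 and l2 == 0:
                            e = stack[pc, pc2]
                        elif l1 == 0 or l2 == 0:
                            e = bu[l1 + l2]
                        else:
                            a = asym * abs(l1 - l2)
                            if a > asym_max:
                                a = asym_max
                            e = inn[l1 + l2] + a
                        cand = e + v
                        if cand < best:
                            best = cand
                # multiloop: >=2 branches inside
                for k in range(i + 1, j - 1):
                    w1 = WM[i + 1, k]
                    if w1 >= INF:
                        continue
                    w2 = WM[k + 1, j - 1]
                    if w2 >= INF:
                        continue
                    cand = ml_a + ml_c + w1 + w2
                    if cand < best:
                        best = cand
                V[i, j] = best
            # WM: segment of a multiloop with >= 1 branch
            best_wm = INF
            if V[i, j] < INF:
                best_wm = V[i, j] + ml_c
            if WM[i + 1, j] + ml_b < best_wm:
                best_wm = WM[i + 1, j] + ml_b
            if WM[i, j - 1] + ml_b < best_wm:
                best_wm = WM[i, j - 1] + ml_b
            for k in range(i + 1, j):
                w1 = WM[i, k - 1]
                if w1 >= INF:
                    continue
                w2 = WM[k, j]
                if w1 + w2 < best_wm:
                    best_wm = w1 + w2
            WM[i, j] = best_wm
    return V, WM


def _exterior(V: np.ndarray) -> np.ndarray:
    n = V.shape[0]
    W = np.zeros(n + 1)
    for j in range(n):
        best = W[j]
        col = W[: j + 1] + V[: j + 1, j]
        m = col.min() if j >= 0 else INF
        if m < best:
            best = m
        W[j + 1] = min(best, W[j])
    return W


def _close(a: float, b: float, tol: float = 1e-6) -> bool:
    return abs(a - b) <= tol


class _Traceback:
    def __init__(self, codes, model: EnergyModel, V, WM):
        self.codes = codes
        self.m = model
        self.V = V
        self.WM = WM
        self.pairs: list[tuple[int, int]] = []

    def pc(self, i, j):
        return pair_code(self.codes[i], self.codes[j])

    def trace_W(self, W):
        j = len(self.codes) - 1
        while j >= 0:
            if _close(W[j + 1], W[j]):
                j -= 1
                continue
            target = W[j + 1]
            for i in range(j + 1):
                if _close(W[i] + self.V[i, j], target):
                    self.trace_V(i, j)
                    j = i - 1
                    break
            else:  # pragma: no cover - defensive
                raise FoldError("traceback failed in exterior loop")

    def trace_V(self, i, j):
        self.pairs.append((i, j))
        m = self.m
        target = self.V[i, j]
        if _close(target, m.hairpin_energy(j - i - 1)):
            return
        min_hp = m.hairpin_min
        for p in range(i + 1, j - min_hp - 1):
            l1 = p - i - 1
            if l1 > m.max_interior:
                break
            for q in range(p + min_hp + 1, j):
                l2 = j - q - 1
                if l1 + l2 > m.max_interior or self.V[p, q] >= INF:
                    continue
                pc2 = self.pc(p, q)
                if pc2 < 0:
                    continue
                if l1 == 0 and l2 == 0:
                    e = m.stack[self.pc(i, j), pc2]
                elif l1 == 0 or l2 == 0:
                    e = m.bulge_energy(l1 + l2)
                else:
                    e = m.internal_energy(l1, l2)
                if _close(e + self.V[p, q], target):
                    self.trace_V(p, q)
                    return
        for k in range(i + 1, j - 1):
            if self.WM[i + 1, k] >= INF or self.WM[k + 1, j - 1] >= INF:
                continue
            if _close(m.ml_a + m.ml_c + self.WM[i + 1, k] + self.WM[k + 1, j - 1], target):
                self.trace_WM(i + 1, k)
                self.trace_WM(k + 1, j - 1)
                return
        raise FoldError("traceback failed in paired state")  # pragma: no cover

    def trace_WM(self, i, j):
        m = self.m
        target = self.WM[i, j]
        if self.V[i, j] < INF and _close(self.V[i, j] + m.ml_c, target):
            self.trace_V(i, j)
            return
        if i + 1 <= j and _close(self.WM[i + 1, j] + m.ml_b, target):
            self.trace_WM(i + 1, j)
            return
        if i <= j - 1 and _close(self.WM[i, j - 1] + m.ml_b, target):
            self.trace_WM(i, j - 1)
            return
        for k in range(i + 1, j):
            if self.WM[i, k - 1] < INF and _close(self.WM[i, k - 1] + self.WM[k, j], target):
                self.trace_WM(i, k - 1)
                self.trace_WM(k, j)
                return
        raise FoldError("traceback failed in multiloop state")  # pragma: no cover


def fold(seq: str, model: EnergyModel | None = None,
         min_len: int = 10, max_len: int = 1000) -> tuple[str, float]:
    """Predict the MFE secondary structure of ``seq``.

    Returns ``(dot_bracket, mfe)`` with mfe <= 0 (the open chain, energy 0,
    is always admissible).  Deterministic: ties resolve to the first option
    in a fixed decision order.
    """
    if not (min_len <= len(seq) <= max_len):
        raise FoldError(f"sequence length {len(seq)} outside [{min_len}, {max_len}]")
    m = model or default_model()
    codes = encode(seq)
    n = len(codes)
    hp, bu, inn = m.loop_tables(n)
    V, WM = _fill(
        codes, _PAIR_CODE, m.stack, hp, bu, inn,
        m.asym, m.asym_max, m.ml_a, m.ml_b, m.ml_c,
        m.max_interior, m.hairpin_min,
    )
    W = _exterior(V)
    mfe = float(W[n])
    if mfe >= 0:
        return "." * n, 0.0
    tb = _Traceback(codes, m, V, WM)
    tb.trace_W(W)
    db = ["."] * n
    for i, j in tb.pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db), mfe


def parse_dot_bracket(structure: str) -> dict[int, int]:
    """Pair table {i: j, j: i} from a dot-bracket string."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced structure")
    return pairs


def energy_of_structure(seq: str, structure: str, model: EnergyModel | None = None) -> float:
    """Free energy of an explicit structure under the same loop decomposition.

    Raises if the structure contains a disallowed pair or a hairpin loop
    shorter than the model minimum.
    """
    m = model or default_model()
    codes = encode(seq)
    if len(structure) != len(codes):
        raise ValueError("structure length != sequence length")
    table = parse_dot_bracket(structure)
    opening = sorted(i for i, j in table.items() if i < j)

    def children_of(i: int, j: int) -> list[tuple[int, int]]:
        kids = []
        k = i + 1
        while k < j:
            if k in table and table[k] > k:
                kids.append((k, table[k]))
                k = table[k] + 1
            else:
                k += 1
        return kids

    total = 0.0
    for i in opening:
        j = table[i]
        if pair_code(codes[i], codes[j]) < 0:
            raise ValueError(f"disallowed pair at ({i}, {j})")
        kids = children_of(i, j)
        if not kids:
            size = j - i - 1
            if size < m.hairpin_min:
                raise ValueError("hairpin loop below minimum size")
            total += m.hairpin_energy(size)
        elif len(kids) == 1:
            (p, q) = kids[0]
            l1, l2 = p - i - 1, j - q - 1
            if l1 == 0 and l2 == 0:
                total += float(m.stack[pair_code(codes[i], codes[j]), pair_code(codes[p], codes[q])])
            elif l1 == 0 or l2 == 0:
                total += m.bulge_energy(l1 + l2)
            else:
                total += m.internal_energy(l1, l2)
        else:
            unpaired = (j - i - 1) - sum(q - p + 1 for p, q in kids)
            total += m.ml_a + m.ml_c * (1 + len(kids)) + m.ml_b * unpaired
    return total
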