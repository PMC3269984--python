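"""Conserved-miRNA discovery.

Pipeline: mismatch-limited scan of unigenes for regions matching known
mature miRNAs (<=3 mismatches, exact 4-mer seeding), hairpin folding of the
surrounding context, acceptance against plant-miRNA annotation criteria
(mature on one arm of a single stem-loop, limited unpaired bases and
bulges in the mature:star duplex), MFEI computation, and single-linkage
grouping of mature sequences into families.

The 4-mer seed is lossless here: a window of length >= 19 with at most 3
mismatches always contains an exact match of length >= 4 (pigeonhole), so
the scan is equivalent to a full sliding Hamming comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from . import seq_core
from ._rnafold import EnergyModel, default_model, energy_of_structure, fold, parse_dot_bracket
from .seq_core import Transcript, as_rna, gc_fraction, normalize_seq, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "MatureMirnaHit",
    "HairpinCandidate",
    "PrecursorCriteria",
    "PrecursorRejection",
    "fold",
    "mfei",
    "load_bundled_matures",
    "load_matures",
    "scan_known_mirnas",
    "evaluate_precursor",
    "mature_distance",
    "group_mature_families",
]


@dataclass(frozen=True)
class MatureMirnaHit:
    """A transcript region within ``mismatches`` of a known mature miRNA.

    ``start``/``end`` are 0-based half-open on the transcript forward
    strand; ``mature_seq`` is the transcript window rendered as RNA in the
    mature's own 5'->3' orientation.
    """

    transcript_id: str
    known_mirna_id: str
    mature_seq: str
    mismatches: int
    strand: str
    start: int
    end: int


@dataclass
class PrecursorCriteria:
    """Operationalised plant-miRNA precursor annotation thresholds."""

    max_mature_unpaired: int = 4
    max_bulge_in_mature: int = 2
    require_single_arm: bool = True
    flank_nt: int = 150


@dataclass
class HairpinCandidate:
    transcript_id: str
    precursor_seq: str
    structure: str
    mfe: float
    length_nt: int
    gc_percent: float
    mfei: float
    mature_arm: str  # 5p | 3p
    mature_offset: int
    n_unpaired_in_mature: int
    largest_bulge_in_duplex: int
    known_mirna_id: str = ""
    full_structure: str = ""
    full_mfe: float = 0.0


@dataclass(frozen=True)
class PrecursorRejection:
    transcript_id: str
    known_mirna_id: str
    reason: str


def mfei(mfe: float, length_nt: int, gc_percent: float) -> float:
    """Minimal folding free energy index: (|MFE|/L x 100) / GC%."""
    if length_nt <= 0:
        raise ValueError("length_nt must be positive")
    if not (0 < gc_percent <= 100):
        raise ValueError("gc_percent must be in (0, 100]")
    if mfe > 0:
        raise ValueError("mfe must be <= 0")
    return (abs(mfe) / length_nt * 100.0) / gc_percent


def load_matures(path: str | Path, min_len: int = 19, max_len: int = 24) -> dict[str, str]:
    """Known mature miRNAs (miRBase-style FASTA, RNA or DNA) -> DNA dict."""
    matures: dict[str, str] = {}
    for t in seq_core.read_fasta(path, source="synthetic"):
        if not (min_len <= t.length <= max_len):
            raise ValueError(
                f"mature {t.id}: length {t.length} outside [{min_len}, {max_len}]"
            )
        matures[t.id] = t.seq
    return matures


def load_bundled_matures() -> dict[str, str]:
    """The bundled set of conserved plant mature miRNAs found in D. purpurea
    (miR156/160/166/167/172/396/397/408 variants)."""
    with resources.as_file(
        resources.files("mlncforge.data").joinpath("mature_mirnas.fasta")
    ) as p:
        return load_matures(p)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _seeded_starts(window_len: int, mature: str, seq: str, word: int) -> set[int]:
    """Candidate window starts sharing an exact word with the mature at the
    corresponding offset."""
    index: dict[str, list[int]] = {}
    for p in range(len(seq) - word + 1):
        index.setdefault(seq[p : p + word], []).append(p)
    starts: set[int] = set()
    for off in range(len(mature) - word + 1):
        for p in index.get(mature[off : off + word], ()):
            s = p - off
            if 0 <= s <= len(seq) - window_len:
                starts.add(s)
    return starts


def scan_known_mirnas(
    t: Transcript,
    matures: dict[str, str],
    max_mm: int = 3,
    word: int = 4,
    collapse: bool = True,
) -> list[MatureMirnaHit]:
    """All transcript windows within ``max_mm`` of a known mature, both strands.

    Equal-length windows only (no indels); overlapping hits for the same
    mature collapse to the minimum-mismatch window (ties to the leftmost)
    unless ``collapse`` is False, which reports every qualifying window.
    """
    hits: list[MatureMirnaHit] = []
    n = t.length
    rc = reverse_complement(t.seq)
    for mid, mature in matures.items():
        if len(mature) < word:
            raise ValueError(f"mature {mid} shorter than seed word {word}")
        L = len(mature)
        if L > n:
            continue
        raw: list[tuple[int, str, int]] = []  # (fwd_start, strand, mismatches)
        for strand, seq in (("+", t.seq), ("-", rc)):
            for s in sorted(_seeded_starts(L, mature, seq, word)):
                mm = _hamming(mature, seq[s : s + L])
                if mm <= max_mm:
                    fwd_start = s if strand == "+" else n - (s + L)
                    raw.append((fwd_start, strand, mm))
        raw.sort()

        def emit(s: int, strand: str, mm: int) -> None:
            window = t.seq[s : s + L]
            mseq = window if strand == "+" else reverse_complement(window)
            hits.append(
                MatureMirnaHit(
                    transcript_id=t.id,
                    known_mirna_id=mid,
                    mature_seq=as_rna(mseq),
                    mismatches=mm,
                    strand=strand,
                    start=s,
                    end=s + L,
                )
            )

        if not collapse:
            for s, strand, mm in raw:
                emit(s, strand, mm)
            continue
        # collapse overlapping windows (same mature) to the best one
        cluster: list[tuple[int, str, int]] = []
        last_end = -1
        for s, strand, mm in raw:
            if cluster and s >= last_end:
                best = min(cluster, key=lambda r: (r[2], r[0], r[1]))
                emit(*best)
                cluster = []
            cluster.append((s, strand, mm))
            last_end = max(last_end, s + L)
        if cluster:
            best = min(cluster, key=lambda r: (r[2], r[0], r[1]))
            emit(*best)
    hits.sort(key=lambda h: (h.start, h.known_mirna_id, h.strand))
    return hits


def _duplex_geometry(pairs: dict[int, int], mo: int, me: int) -> tuple[str, int, int, list[int]]:
    """Arm, unpaired count and largest bulge for the mature at [mo, me)."""
    paired = [p for p in range(mo, me) if p in pairs]
    n_unpaired = (me - mo) - len(paired)
    for p in paired:
        if mo <= pairs[p] < me:
            raise _SpansLoop()
    partners = [pairs[p] for p in paired]
    if not paired:
        raise _SpansLoop()
    if all(q >= me for q in partners):
        arm = "5p"
    elif all(q < mo for q in partners):
        arm = "3p"
    else:
        raise _SpansLoop()
    largest_bulge = 0
    for a, b in zip(paired, paired[1:]):
        d_m = b - a - 1
        d_s = abs(pairs[a] - pairs[b]) - 1
        largest_bulge = max(largest_bulge, d_m, d_s)
    return arm, n_unpaired, largest_bulge, paired


class _SpansLoop(Exception):
    pass


def _trim_stem_loop(pairs: dict[int, int], paired: list[int]) -> tuple[int, int]:
    """First-to-last paired base of the stem-loop containing the mature,
    extending outward along the enclosing helix."""
    positions = paired + [pairs[p] for p in paired]
    lo, hi = min(positions), max(positions)
    while lo - 1 >= 0 and pairs.get(lo - 1) == hi + 1:
        lo -= 1
        hi += 1
    return lo, hi


def _count_hairpins_within(pairs: dict[int, int], lo: int, hi: int) -> int:
    count = 0
    for i, j in pairs.items():
        if i < j and lo <= i and j <= hi:
            # hairpin-closing pair: nothing paired strictly inside
            if all(k not in pairs for k in range(i + 1, j)):
                count += 1
    return count


def evaluate_precursor(
    t: Transcript,
    hit: MatureMirnaHit,
    criteria: PrecursorCriteria | None = None,
    model: EnergyModel | None = None,
    mfei_region: str = "hairpin",
) -> HairpinCandidate | PrecursorRejection:
    """Fold the mature +/- flank context and test precursor plausibility.

    Accepts iff the mature lies entirely on one arm of a single stem-loop,
    with at most ``max_mature_unpaired`` unpaired mature bases and no bulge
    larger than ``max_bulge_in_mature`` in the mature:star duplex.  MFEI is
    computed over the trimmed stem-loop (``mfei_region='hairpin'``, the
    default) or the whole folded context (``'full'``).
    """
    criteria = criteria or PrecursorCriteria()
    if mfei_region not in ("hairpin", "full"):
        raise ValueError("mfei_region must be 'hairpin' or 'full'")
    n = t.length
    ws = max(0, hit.start - criteria.flank_nt)
    we = min(n, hit.end + criteria.flank_nt)
    window = t.seq[ws:we]
    if hit.strand == "+":
        mo, me = hit.start - ws, hit.end - ws
    else:
        window = reverse_complement(window)
        mo, me = we - hit.end, we - hit.start

    def reject(reason: str) -> PrecursorRejection:
        return PrecursorRejection(t.id, hit.known_mirna_id, reason)

    structure, mfe_full = fold(window, model=model)
    pairs = parse_dot_bracket(structure)
    try:
        arm, n_unpaired, largest_bulge, paired = _duplex_geometry(pairs, mo, me)
    except _SpansLoop:
        return reject("mature spans loop")
    if n_unpaired > criteria.max_mature_unpaired:
        return reject(f"unpaired>{criteria.max_mature_unpaired}")
    if largest_bulge > criteria.max_bulge_in_mature:
        return reject(f"bulge>{criteria.max_bulge_in_mature}")
    lo, hi = _trim_stem_loop(pairs, paired)
    if criteria.require_single_arm and _count_hairpins_within(pairs, lo, hi) > 1:
        return reject("not a single stem-loop")

    if mfei_region == "hairpin":
        sub_seq = window[lo : hi + 1]
        sub_struct = structure[lo : hi + 1]
        mfe_val = energy_of_structure(sub_seq, sub_struct, model=model)
        region_seq, region_struct = sub_seq, sub_struct
        offset = mo - lo
    else:
        mfe_val = mfe_full
        region_seq, region_struct = window, structure
        offset = mo
    gc_pct = gc_fraction(region_seq) * 100.0
    return HairpinCandidate(
        transcript_id=t.id,
        precursor_seq=region_seq,
        structure=region_struct,
        mfe=round(mfe_val, 6),
        length_nt=len(region_seq),
        gc_percent=gc_pct,
        mfei=mfei(min(mfe_val, 0.0), len(region_seq), gc_pct),
        mature_arm=arm,
        mature_offset=offset,
        n_unpaired_in_mature=n_unpaired,
        largest_bulge_in_duplex=largest_bulge,
        known_mirna_id=hit.known_mirna_id,
        full_structure=structure,
        full_mfe=mfe_full,
    )


def mature_distance(a: str, b: str) -> int:
    """Hamming distance at the best ungapped offset; the length difference
    counts as mismatches."""
    a, b = normalize_seq(a), normalize_seq(b)
    if len(a) > len(b):
        a, b = b, a
    diff = len(b) - len(a)
    best = min(_hamming(a, b[off : off + len(a)]) for off in range(diff + 1))
    return best + diff


def group_mature_families(
    matures: dict[str, str], max_mm: int = 3
) -> list[set[str]]:
    """Single-linkage families of mature sequences (distance <= max_mm).

    Returns families (including singletons) sorted by smallest member id.
    """
    if not matures:
        raise ValueError("no mature sequences to group")
    ids = sorted(matures)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if mature_distance(matures[a], matures[b]) <= max_mm:
                parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda g: min(g))


def candidates_table(candidates: list[HairpinCandidate]) -> "object":
    """Candidates as a pandas DataFrame matching the TSV report layout."""
    import pandas as pd

    rows = []
    for c in candidates:
        rows.append(
            {
                "transcript_id": c.transcript_id,
                "known_mirna_id": c.known_mirna_id,
                "arm": c.mature_arm,
                "precursor_len": c.length_nt,
                "mfe": c.mfe,
                "gc_percent": round(c.gc_percent, 2),
                "mfei": round(c.mfei, 4),
                "unpaired_in_mature": c.n_unpaired_in_mature,
                "largest_bulge": c.largest_bulge_in_duplex,
            }
        )
    return pd.DataFrame(rows)
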