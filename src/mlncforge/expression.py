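"""qPCR analytics: reference-gene stability, relative quantification and
rule-based stress-response classification.

Relative expression uses the comparative Cq method (fold = 2^-ddCq against
a reference gene and a calibrator sample).  Reference stability follows
the geNorm approach: for each candidate pair the pairwise variation V is
the standard deviation of log2 expression ratios across samples, and a
gene's M value is the mean V over all partners (lower = more stable).

Stress-response classes formalise the qualitative time-course patterns at
0/1/5/10/24 h: a gene is responsive when some pair of time-points differs
by more than 2-fold.  Cold types: A = not responsive; B = immediate
decrease (fold at 1 h <= 1/2); C = rapid increase (peak >= 2-fold at 1, 5
or 10 h, declining afterwards).  Dehydration groups: II = rapid decrease
at 1 h; III = induction at 1 h (>= 2-fold) then down-regulation to below
half the peak by 24 h; I = flat through 10 h then >= 2-fold at 24 h.
Rules are checked in the order B/II before C/III; anything responsive that
fits no rule is reported as responsive-unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TIME_POINTS = (0, 1, 5, 10, 24)
UNDETECTED_CQ = 40.0

__all__ = [
    "read_cq",
    "cq_matrix",
    "genorm_m",
    "delta_delta_cq",
    "ResponseClass",
    "classify_cold",
    "classify_dehydration",
    "classify_series",
    "correlate_pair",
]


@dataclass(frozen=True)
class ResponseClass:
    gene: str
    stress: str  # cold | dehydration
    responsive: bool
    subclass: str  # A/B/C, I/II/III, 'unclassified' or 'undetected'


def read_cq(path: str | Path) -> pd.DataFrame:
    """Long-format Cq TSV (gene, sample, cq, replicate) -> tidy frame.

    Cq values at or beyond the no-amplification cycle (40) are treated as
    undetected (NaN).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "sample", "cq"}
    if not required.issubset(df.columns):
        raise ValueError(f"Cq table must have columns {sorted(required)}")
    df.loc[df["cq"] >= UNDETECTED_CQ, "cq"] = np.nan
    return df


def cq_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """genes x samples matrix, technical replicates averaged.

    A (gene, sample) cell whose replicates are all undetected stays NaN
    rather than being dropped.
    """
    return df.groupby(["gene", "sample"])["cq"].mean().unstack("sample")


def genorm_m(cq: pd.DataFrame, candidates: list[str] | None = None) -> pd.Series:
    """geNorm expression-stability value M per candidate reference gene.

    Cq values convert to relative quantities 2^(Cq_min - Cq) per gene; for
    each gene pair, V = SD (ddof=1) of the log2 ratios across samples, and
    M_g = mean V over partners.  Candidates undetected in any sample are
    excluded with a warning.  Sorted ascending (most stable first).
    """
    candidates = list(candidates) if candidates is not None else list(cq.index)
    if len(candidates) < 2:
        raise ValueError("geNorm needs at least two candidate genes")
    if cq.shape[1] < 2:
        raise ValueError("geNorm needs at least two samples")
    usable = []
    for g in candidates:
        if g not in cq.index:
            raise KeyError(f"candidate {g!r} not in the Cq matrix")
        if cq.loc[g].isna().any():
            logger.warning("geNorm: %s undetected in some sample; excluded", g)
        else:
            usable.append(g)
    if len(usable) < 2:
        raise ValueError("fewer than two fully detected candidates")
    # log2 relative quantity; per-gene constant offsets cancel in ratios
    log_q = cq.loc[usable].rsub(cq.loc[usable].min(axis=1), axis=0)
    m = {}
    for g in usable:
        variations = [
            (log_q.loc[g] - log_q.loc[h]).std(ddof=1) for h in usable if h != g
        ]
        m[g] = float(np.mean(variations))
    return pd.Series(m, name="M").sort_values(kind="stable")


def delta_delta_cq(
    cq: pd.DataFrame, target_gene: str, ref_gene: str, calibrator_sample: str
) -> pd.Series:
    """Fold change 2^-ddCq per sample, relative to the calibrator.

    The calibrator sample has fold 1 by construction; samples where the
    target is undetected come back NaN (never zero).
    """
    for g in (target_gene, ref_gene):
        if g not in cq.index:
            raise KeyError(f"gene {g!r} not in Cq matrix")
    if calibrator_sample not in cq.columns:
        raise KeyError(f"calibrator sample {calibrator_sample!r} not in Cq matrix")
    d_cq = cq.loc[target_gene] - cq.loc[ref_gene]
    if np.isnan(d_cq[calibrator_sample]):
        raise ValueError("target or reference undetected in the calibrator sample")
    dd_cq = d_cq - d_cq[calibrator_sample]
    fold = np.power(2.0, -dd_cq)
    fold.name = target_gene
    return fold


def _check_series(series: pd.Series) -> pd.Series:
    s = series.reindex(list(TIME_POINTS))
    if s.isna().any():
        missing = [t for t in TIME_POINTS if pd.isna(s.get(t))]
        raise ValueError(f"missing time-points {missing}; classification refused")
    return s.astype(float)


def classify_cold(gene: str, series: pd.Series) -> ResponseClass:
    """Cold-stress type (A/B/C) from a fold-change time-course."""
    s = _check_series(series)
    responsive = s.max() / s.min() > 2.0
    if not responsive:
        return ResponseClass(gene, "cold", False, "A")
    if s[1] <= 0.5:
        return ResponseClass(gene, "cold", True, "B")
    peak_t = s.idxmax()
    if peak_t in (1, 5, 10) and s[peak_t] >= 2.0 and s[24] < s[peak_t]:
        return ResponseClass(gene, "cold", True, "C")
    return ResponseClass(gene, "cold", True, "unclassified")


def classify_dehydration(gene: str, series: pd.Series) -> ResponseClass:
    """Dehydration-stress group (I/II/III) from a fold-change time-course."""
    s = _check_series(series)
    responsive = s.max() / s.min() > 2.0
    if not responsive:
        return ResponseClass(gene, "dehydration", False, "unclassified")
    if s[1] <= 0.5:
        return ResponseClass(gene, "dehydration", True, "II")
    if s[1] >= 2.0 and s[24] < s[1] / 2.0:
        return ResponseClass(gene, "dehydration", True, "III")
    if all(0.5 < s[t] < 2.0 for t in (1, 5, 10)) and s[24] >= 2.0:
        return ResponseClass(gene, "dehydration", True, "I")
    return ResponseClass(gene, "dehydration", True, "unclassified")


def classify_series(gene: str, series: pd.Series, stress: str) -> ResponseClass:
    if stress == "cold":
        return classify_cold(gene, series)
    if stress == "dehydration":
        return classify_dehydration(gene, series)
    raise ValueError(f"unknown stress {stress!r}")


def correlate_pair(
    series_a: pd.Series,
    series_b: pd.Series,
    time_points: list[int] | None = None,
    threshold: float = 0.5,
) -> tuple[str, float]:
    """Pearson correlation of log2 fold changes over shared time-points.

    Returns (sign, r) where sign is 'positive', 'negative' or 'none'
    (|r| < threshold, or undefined because one series has zero variance).
    """
    idx = [t for t in (time_points or list(series_a.index)) if t in series_b.index]
    if len(idx) < 3:
        raise ValueError("need at least three shared time-points")
    a = np.log2(series_a.loc[idx].astype(float).values)
    b = np.log2(series_b.loc[idx].astype(float).values)
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        return "none", float("nan")
    r = float(stats.pearsonr(a, b).statistic)
    if abs(r) < threshold:
        return "none", r
    return ("positive" if r > 0 else "negative"), r
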