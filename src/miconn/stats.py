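"""Nonparametric group statistics: Wilcoxon signed-rank and BH-FDR contrasts.

The signed-rank test uses the exact null distribution (all 2^n sign
assignments, ties mid-ranked) for n <= 25 and a continuity-corrected normal
approximation with tie correction above. Multiple testing across the 72
directed channel pairs is handled per family (one family per band x hand x
contrast) with Benjamini-Hochberg step-up FDR.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, norm
from statsmodels.stats.multitest import multipletests

EXACT_LIMIT = 25  # exact enumeration up to this n; normal approximation above


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    pvalue: float  # two-sided
    n_used: int  # pairs remaining after dropping zero differences
    n_zero: int  # zero differences dropped
    exact: bool


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by dynamic programming over sign assignments.

    Mid-ranks may be half-integral, so the distribution is built on doubled
    ranks (integers). Equivalent to enumerating all 2^n sign patterns.
    """
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    cdf = dist[: w2 + 1].sum()
    sf = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(a, b=None) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Pass two paired vectors, or a single vector of differences. Zero
    differences are dropped (their count is reported); ties get mid-ranks.
    If every difference is zero the test is degenerate: p = 1 with a warning.
    """
    d = np.asarray(a, dtype=float)
    if b is not None:
        d = d - np.asarray(b, dtype=float)
    if d.ndim != 1:
        raise ValueError("expected 1-D paired data")
    nonzero = d[d != 0]
    n_zero = d.size - nonzero.size
    n = nonzero.size
    if n == 0:
        warnings.warn("all paired differences are zero; test is degenerate", UserWarning)
        return WilcoxonResult(statistic=0.0, pvalue=1.0, n_used=0, n_zero=n_zero, exact=True)
    ranks = rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    if n <= EXACT_LIMIT:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(w_plus, p, n, n_zero, exact=True)
    mean = n * (n + 1) / 4.0
    # tie correction: sum over tie groups of (t^3 - t) / 48
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    diff = w_plus - mean
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z = (diff - cc) / np.sqrt(var) if var > 0 else 0.0
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, n_zero, exact=False)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-D vector of p-values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ConnectivityContrast:
    """Per-pair statistics of a condition contrast over directed TE edges.

    ``table`` has one row per directed (source, sink) pair with columns:
    source, sink, statistic, p, p_adj, direction ('A' or 'B': which condition
    had the larger median relative TE; '0' on exact ties), retained.
    """

    table: pd.DataFrame
    band: str
    hand: str
    contrast: str  # e.g. "rmMI-tMI": condition A minus condition B
    alpha: float = 0.05
    family_size: int = field(init=False)

    def __post_init__(self) -> None:
        self.family_size = len(self.table)

    @property
    def retained_edges(self) -> list[tuple[str, str]]:
        kept = self.table[self.table["retained"]]
        return list(zip(kept["source"], kept["sink"]))


def contrast_conditions(te_a: list, te_b: list, alpha: float = 0.05) -> ConnectivityContrast:
    """Across-subject contrast of two relative-TE conditions.

    ``te_a`` and ``te_b`` are per-subject TEMatrix lists (same subjects, same
    montage/band/hand). Per directed pair: two-sided Wilcoxon signed-rank on
    the per-subject values, BH adjustment over the pair family, retained if
    adjusted p < alpha; effect direction from the sign of the median
    difference.
    """
    if len(te_a) != len(te_b) or len(te_a) == 0:
        raise ValueError("condition lists must be non-empty and the same length (same subjects)")
    ref = te_a[0]
    for m in list(te_a) + list(te_b):
        if m.channels != ref.channels:
            raise ValueError("montage mismatch between TE matrices")
        if m.band != ref.band or m.hand != ref.hand:
            raise ValueError("band/hand mismatch between TE matrices")
    channels = ref.channels
    rows = []
    pvals = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # degenerate all-zero pairs -> p = 1
        for i, src in enumerate(channels):
            for j, snk in enumerate(channels):
                if i == j:
                    continue
                va = np.array([m.values[i, j] for m in te_a])
                vb = np.array([m.values[i, j] for m in te_b])
                res = wilcoxon_signed_rank(va, vb)
                med = float(np.median(va - vb))
                direction = "A" if med > 0 else ("B" if med < 0 else "0")
                rows.append((src, snk, res.statistic, res.pvalue, direction))
                pvals.append(res.pvalue)
    p_adj = fdr_adjust(pvals)
    table = pd.DataFrame(rows, columns=["source", "sink", "statistic", "p", "direction"])
    table["p_adj"] = p_adj
    table["retained"] = table["p_adj"] < alpha
    table = table[["source", "sink", "statistic", "p", "p_adj", "direction", "retained"]]
    contrast_name = f"{getattr(ref, 'condition', 'A')}-{getattr(te_b[0], 'condition', 'B')}"
    return ConnectivityContrast(
        table=table, band=ref.band, hand=ref.hand, contrast=contrast_name, alpha=alpha
    )
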