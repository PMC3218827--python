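"""Sliding-window series and Spearman rank-correlation significance rules.

Non-overlapping 25-codon windows are moved across each gene; per window the
disorder (or structure) content and either the count of positively selected
codons or a window-level fixation index is recorded.  The per-gene
association between the two window series is measured by Spearman's rank
correlation with midranks for ties.  Significance follows sample-size-
dependent rules: for n > 30 a normal approximation z = r_s * sqrt(n - 1)
(two-tailed); for 5 < n <= 30 a table of two-tailed alpha = 0.05 critical
values; for n <= 5 no verdict is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .alignment import CodonAlignment
from .mk import fixation_index, mk_counts

#: Two-tailed alpha = 0.05 critical values of Spearman's r_s (Zar's table),
#: indexed by the number of paired observations.
SPEARMAN_CRITICAL_05 = {
    6: 0.886, 7: 0.786, 8: 0.738, 9: 0.700, 10: 0.648,
    11: 0.618, 12: 0.587, 13: 0.560, 14: 0.538, 15: 0.521,
    16: 0.503, 17: 0.485, 18: 0.472, 19: 0.460, 20: 0.447,
    21: 0.435, 22: 0.425, 23: 0.415, 24: 0.406, 25: 0.398,
    26: 0.390, 27: 0.382, 28: 0.375, 29: 0.368, 30: 0.362,
}


@dataclass
class SpearmanVerdict:
    rs: float  # nan for constant series
    n: int
    method: str  # normal | table | not_assessed | undefined
    p: float  # nan when the table method or no method applies
    significant: bool


def spearman_rs(x, y) -> float:
    """Spearman's r_s with midranks for ties (nan for a constant series)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length series of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rx, ry = rankdata(x), rankdata(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman_significance(x, y, alpha: float = 0.05) -> SpearmanVerdict:
    """Correlation verdict under the sample-size-dependent significance rules."""
    n = len(x)
    rs = spearman_rs(x, y)
    if math.isnan(rs):
        return SpearmanVerdict(rs, n, "undefined", float("nan"), False)
    if n <= 5:
        return SpearmanVerdict(rs, n, "not_assessed", float("nan"), False)
    if n <= 30:
        crit = SPEARMAN_CRITICAL_05[n]
        return SpearmanVerdict(rs, n, "table", float("nan"), abs(rs) >= crit)
    z = rs * math.sqrt(n - 1)
    p = float(2 * norm.sf(abs(z)))
    return SpearmanVerdict(rs, n, "normal", p, p <= alpha)


@dataclass
class WindowSeries:
    gene_id: str
    window_size: int
    kind: str  # selection | fi
    windows: pd.DataFrame  # window_index, class_fraction, and positive_count or fi
    verdict: SpearmanVerdict | None = None
    informative_windows: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def assessed(self) -> bool:
        return self.verdict is not None and self.verdict.method in ("normal", "table")


def sliding_window_selection_series(
    calls: np.ndarray,
    mask_classes: np.ndarray,
    gene_id: str = "gene",
    window: int = 25,
    cls: str = "idr",
    require_positive: bool = True,
    min_points: int = 5,
    alpha: float = 0.05,
) -> WindowSeries:
    """Windowed class content vs positively-selected-site counts for one gene.

    Windows with no positive site are discarded when ``require_positive``; a
    correlation verdict is attempted when at least ``min_points`` data points
    remain.
    """
    calls = np.asarray(calls)
    mask_classes = np.asarray(mask_classes, dtype=object)
    n = min(len(calls), len(mask_classes))
    rows = []
    for w in range(n // window):
        sl = slice(w * window, (w + 1) * window)
        pos = int(np.sum(calls[sl] == "positive"))
        frac = float(np.mean(mask_classes[sl] == cls))
        rows.append({"window_index": w, "class_fraction": frac, "positive_count": pos})
    df = pd.DataFrame(rows, columns=["window_index", "class_fraction", "positive_count"])
    if require_positive and not df.empty:
        df = df[df["positive_count"] > 0].reset_index(drop=True)
    series = WindowSeries(gene_id, window, "selection", df, informative_windows=len(df))
    if len(df) >= max(min_points, 2):
        series.verdict = spearman_significance(
            df["class_fraction"].to_numpy(), df["positive_count"].to_numpy(), alpha
        )
    return series


def sliding_window_fi_series(
    aln: CodonAlignment,
    mask_classes: np.ndarray,
    window: int = 25,
    cls: str = "idr",
    min_informative: int = 6,
    alpha: float = 0.05,
) -> WindowSeries:
    """Windowed class content vs window fixation index for one gene.

    Windows with undefined FI are non-informative and dropped; with five or
    fewer informative windows no correlation verdict is attempted.
    """
    mask_classes = np.asarray(mask_classes, dtype=object)
    n = min(aln.n_codons, len(mask_classes))
    rows = []
    for w in range(n // window):
        idx = set(range(w * window, (w + 1) * window))
        try:
            counts = mk_counts(aln, codon_indices=idx, scope_id=f"{aln.gene_id}:w{w}")
        except ValueError:
            continue
        fi = fixation_index(counts).fi
        if math.isnan(fi):
            continue
        frac = float(np.mean(mask_classes[w * window : (w + 1) * window] == cls))
        rows.append({"window_index": w, "class_fraction": frac, "fi": fi})
    df = pd.DataFrame(rows, columns=["window_index", "class_fraction", "fi"])
    series = WindowSeries(aln.gene_id, window, "fi", df, informative_windows=len(df))
    if len(df) >= max(min_informative, 2):
        series.verdict = spearman_significance(
            df["class_fraction"].to_numpy(), df["fi"].to_numpy(), alpha
        )
    return series


def genewise_correlation_census(series_list: list[WindowSeries]) -> tuple[int, int]:
    """Counts of genes with significantly positive and negative correlations."""
    n_pos = sum(1 for s in series_list if s.assessed and s.verdict.significant and s.verdict.rs > 0)
    n_neg = sum(1 for s in series_list if s.assessed and s.verdict.significant and s.verdict.rs < 0)
    return n_pos, n_neg
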