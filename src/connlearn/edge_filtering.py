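"""Per-edge run contrasts: which connections strengthened or weakened?

Each upper-triangle edge weight is modelled by a one-way ANOVA on the run
factor across subjects, followed by a Tukey HSD post-hoc p-value for the
run pair (with two groups the Tukey test coincides with the pooled t test).
Edges significant at 0.05 are then filtered for magnitude: only differences
above the 95th or below the 5th percentile of the all-edge mean-difference
distribution are selected as strengthened / weakened connections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import AtlasTable
from .connectome import Connectome

__all__ = ["EdgeDifferenceReport", "edge_anova", "percentile_filter", "report_frame"]

ALPHA = 0.05


@dataclass
class EdgeDifferenceReport:
    """Per-edge ANOVA results plus (after filtering) the selected edge sets."""

    table: pd.DataFrame  # columns: roi_i, roi_j, diff, F, p, tukey_p, degenerate
    n_rois: int
    alpha: float = ALPHA
    percentile_cutoffs: Optional[Tuple[float, float]] = None  # (lower, upper) diff thresholds
    selected_positive: List[Tuple[int, int]] = field(default_factory=list)
    selected_negative: List[Tuple[int, int]] = field(default_factory=list)


def _edge_matrix(connectomes: Sequence[Connectome]) -> np.ndarray:
    n = connectomes[0].n_rois
    if any(c.n_rois != n for c in connectomes):
        raise ValueError("cohort connectomes must share one dimension")
    iu = np.triu_indices(n, k=1)
    return np.stack([c.weights[iu] for c in connectomes])


def edge_anova(run1: Sequence[Connectome], run2: Sequence[Connectome]) -> EdgeDifferenceReport:
    """One-way ANOVA of edge weight on the run factor, vectorised over edges.

    Requires >= 2 subjects per run and a common atlas/dimension.  Edges with
    zero variance everywhere get F = 0 and p = 1 with a degeneracy flag.
    The Tukey HSD p-value for the run-1 vs run-2 contrast is computed from
    the studentized range distribution.
    """
    if len(run1) < 2 or len(run2) < 2:
        raise ValueError("need >= 2 subjects per run")
    a = _edge_matrix(run1)  # (s1, m)
    b = _edge_matrix(run2)  # (s2, m)
    n1, n2 = a.shape[0], b.shape[0]
    n = connectome_dim = run1[0].n_rois
    grand = (a.sum(axis=0) + b.sum(axis=0)) / (n1 + n2)
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    ss_between = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ss_within = ((a - m1) ** 2).sum(axis=0) + ((b - m2) ** 2).sum(axis=0)
    df_between, df_within = 1, n1 + n2 - 2
    msb = ss_between / df_between
    msw = ss_within / df_within
    degenerate = (ss_within == 0) & (ss_between == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(msw > 0, msb / np.where(msw > 0, msw, 1.0), np.inf)
    F = np.where(degenerate, 0.0, F)
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 1.0, F), df_between, df_within))
    p = np.where(degenerate, 1.0, p)
    # Tukey HSD for the (only) run pair: studentized range statistic
    se = np.sqrt(msw / 2.0 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(se > 0, np.abs(m2 - m1) / np.where(se > 0, se, 1.0), np.inf)
    tukey_p = np.where(np.isinf(q), 0.0,
                       stats.studentized_range.sf(np.where(np.isinf(q), 1.0, q), 2, df_within))
    tukey_p = np.where(degenerate, 1.0, tukey_p)
    iu = np.triu_indices(connectome_dim, k=1)
    table = pd.DataFrame(
        {
            "roi_i": iu[0] + 1,
            "roi_j": iu[1] + 1,
            "diff": m2 - m1,
            "F": F,
            "p": p,
            "tukey_p": tukey_p,
            "degenerate": degenerate,
        }
    )
    return EdgeDifferenceReport(table=table, n_rois=connectome_dim)


def percentile_filter(
    report: EdgeDifferenceReport,
    lower_percentile: float = 5.0,
    upper_percentile: float = 95.0,
    scope: str = "all",
) -> EdgeDifferenceReport:
    """Select significant, extreme-magnitude edges.

    Among edges with Tukey p < alpha, keep those whose mean difference lies
    above the ``upper_percentile`` (strengthened) or below the
    ``lower_percentile`` (weakened) of the difference distribution.  By
    default percentiles are taken over *all* edges (``scope="all"``);
    ``scope="significant"`` restricts the reference distribution to the
    significant subset.  When every difference is identical, the strict
    inequality lets nothing through.
    """
    df = report.table
    sig = df["tukey_p"] < report.alpha
    ref = df["diff"] if scope == "all" else df.loc[sig, "diff"]
    if scope not in ("all", "significant"):
        raise ValueError(f"unknown scope {scope!r}")
    if len(ref) == 0:
        report.percentile_cutoffs = (np.nan, np.nan)
        report.selected_positive, report.selected_negative = [], []
        return report
    lo = float(np.percentile(ref, lower_percentile))
    hi = float(np.percentile(ref, upper_percentile))
    pos = df[sig & (df["diff"] > hi)]
    neg = df[sig & (df["diff"] < lo)]
    report.percentile_cutoffs = (lo, hi)
    report.selected_positive = [(int(r.roi_i) - 1, int(r.roi_j) - 1) for r in pos.itertuples()]
    report.selected_negative = [(int(r.roi_i) - 1, int(r.roi_j) - 1) for r in neg.itertuples()]
    return report


def report_frame(report: EdgeDifferenceReport, atlas: Optional[AtlasTable] = None) -> pd.DataFrame:
    """Exportable per-edge table; adds ROI names when an atlas is supplied."""
    df = report.table.copy()
    pos = {(i + 1, j + 1) for i, j in report.selected_positive}
    neg = {(i + 1, j + 1) for i, j in report.selected_negative}
    df["selected"] = [
        "+" if (r.roi_i, r.roi_j) in pos else ("-" if (r.roi_i, r.roi_j) in neg else "none")
        for r in df.itertuples()
    ]
    if atlas is not None:
        df["name_i"] = [atlas.lookup(int(i)).name for i in df["roi_i"]]
        df["name_j"] = [atlas.lookup(int(j)).name for j in df["roi_j"]]
    return df
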