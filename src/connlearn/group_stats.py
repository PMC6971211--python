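"""Non-parametric group contrasts for cohort-level network measures.

Pairwise (run 1 vs run 2) contrasts use the two-sided Wilcoxon signed-rank
test with Bonferroni correction across the measure family (corrected
p = min(1, p * n_hypotheses)); multi-group contrasts use Kruskal-Wallis with
Benjamini-Hochberg FDR across the family.  Significance is assessed at
alpha = 0.05 throughout.  The exact signed-rank null distribution is used
for n <= 25 pairs (no ties); larger samples fall back to the normal
approximation with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContrastReport",
    "wilcoxon_paired",
    "kruskal_wallis_groups",
    "run_contrast_suite",
    "ALPHA",
]

ALPHA = 0.05


@dataclass
class ContrastReport:
    measure: str
    test: str  # "wilcoxon_signed_rank" | "kruskal_wallis"
    correction: str  # "bonferroni" | "fdr"
    p_raw: float
    p_corrected: float
    statistic: float
    direction: int  # sign of median(run2 - run1); 0 for multi-group tests
    n: int
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_corrected < ALPHA


def wilcoxon_paired(
    x: Sequence[float],
    y: Sequence[float],
    n_hypotheses: int = 1,
    measure: str = "",
) -> ContrastReport:
    """Two-sided Wilcoxon signed-rank test on paired samples x (run 1) and y (run 2).

    Bonferroni correction multiplies the raw p by ``n_hypotheses`` (capped at
    1).  All-zero differences yield p = 1 with a degeneracy flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equally long 1-d paired samples")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    diffs = y - x
    if np.all(diffs == 0):
        return ContrastReport(
            measure=measure, test="wilcoxon_signed_rank", correction="bonferroni",
            p_raw=1.0, p_corrected=1.0, statistic=0.0, direction=0, n=len(x), degenerate=True,
        )
    nonzero = diffs[diffs != 0]
    exact_ok = len(nonzero) <= 25 and len(np.unique(np.abs(nonzero))) == len(nonzero)
    method = "exact" if exact_ok else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", correction=(method == "approx"), method=method)
    p_raw = float(res.pvalue)
    return ContrastReport(
        measure=measure, test="wilcoxon_signed_rank", correction="bonferroni",
        p_raw=p_raw, p_corrected=min(1.0, p_raw * n_hypotheses),
        statistic=float(res.statistic), direction=int(np.sign(np.median(diffs))), n=len(x),
    )


def kruskal_wallis_groups(
    families: Sequence[Sequence[Sequence[float]]],
    measures: Optional[Sequence[str]] = None,
) -> List[ContrastReport]:
    """Kruskal-Wallis tests over a family of group comparisons, BH-corrected.

    ``families`` is a sequence of comparisons, each a sequence of >= 2 groups
    with >= 3 values.  Identical constant groups yield p = 1 (degenerate).
    """
    measures = list(measures) if measures is not None else [""] * len(families)
    raw, stats_h, degenerate = [], [], []
    for groups in families:
        groups = [np.asarray(g, dtype=float) for g in groups]
        if len(groups) < 2 or any(len(g) < 3 for g in groups):
            raise ValueError("need >= 2 groups with >= 3 values each")
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            raw.append(1.0)
            stats_h.append(0.0)
            degenerate.append(True)
            continue
        h, p = stats.kruskal(*groups)
        raw.append(float(p))
        stats_h.append(float(h))
        degenerate.append(False)
    _, corrected, _, _ = multipletests(raw, alpha=ALPHA, method="fdr_bh")
    return [
        ContrastReport(
            measure=m, test="kruskal_wallis", correction="fdr",
            p_raw=p, p_corrected=float(pc), statistic=h, direction=0,
            n=sum(len(g) for g in fam), degenerate=d,
        )
        for m, p, pc, h, d, fam in zip(measures, raw, corrected, stats_h, degenerate, families)
    ]


def run_contrast_suite(
    table: pd.DataFrame,
    n_hypotheses: Optional[int] = None,
) -> pd.DataFrame:
    """Paired run-1 vs run-2 Wilcoxon contrasts for every measure in a long table.

    ``table`` needs columns subject_id, run, measure, value.  Bonferroni uses
    the family size (number of measures) unless ``n_hypotheses`` overrides
    it.  Subjects lacking either run are listed and excluded.
    """
    required = {"subject_id", "run", "measure", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    measures = sorted(table["measure"].unique())
    family = n_hypotheses if n_hypotheses is not None else len(measures)
    rows = []
    for measure in measures:
        sub = table[table["measure"] == measure].pivot_table(
            index="subject_id", columns="run", values="value"
        )
        if 1 not in sub.columns or 2 not in sub.columns:
            raise ValueError(f"measure {measure!r} lacks both runs")
        complete = sub.dropna()
        excluded = sorted(set(sub.index) - set(complete.index))
        report = wilcoxon_paired(
            complete[1].to_numpy(), complete[2].to_numpy(), n_hypotheses=family, measure=measure
        )
        rows.append(
            {
                "measure": measure,
                "n_pairs": report.n,
                "statistic": report.statistic,
                "p_raw": report.p_raw,
                "p_corrected": report.p_corrected,
                "direction": report.direction,
                "significant": report.significant,
                "excluded_subjects": ";".join(map(str, excluded)),
            }
        )
    return pd.DataFrame(rows)
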