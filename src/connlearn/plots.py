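"""Minimal plotting: box-whisker panels with scatter overlay.

Boxes span the 25th-50th percentiles with whiskers at the 1st and 99th,
the convention used for cohort network-statistic panels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["box_whisker"]


def box_whisker(groups: Sequence[Sequence[float]], labels: Sequence[str], path, title: str = ""):
    """One panel of per-group box-whisker summaries with jittered points."""
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 1.5, 3.2))
    rng = np.random.default_rng(0)
    for pos, (values, label) in enumerate(zip(groups, labels), start=1):
        values = np.asarray(values, dtype=float)
        p1, p25, p50, p99 = np.percentile(values, [1, 25, 50, 99])
        ax.bxp(
            [{"med": p50, "q1": p25, "q3": p50, "whislo": p1, "whishi": p99, "fliers": []}],
            positions=[pos],
            showfliers=False,
        )
        jitter = rng.uniform(-0.12, 0.12, size=len(values))
        ax.plot(pos + jitter, values, "o", ms=3, alpha=0.5)
    ax.set_xticks(range(1, len(groups) + 1))
    ax.set_xticklabels(labels)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
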