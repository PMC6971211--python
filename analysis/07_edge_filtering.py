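#!/usr/bin/env python
"""Detect strengthened/weakened connections between runs.

Per-edge one-way ANOVA on the run factor with Tukey post-hoc, then
percentile filtering (difference above the 95th / below the 5th percentile).
Writes results/edge_report_<condition>.csv with FSL ROI names.
"""

import json
from pathlib import Path

from connlearn.atlas import load_atlas
from connlearn.connectome import read_connectome
from connlearn.edge_filtering import edge_anova, percentile_filter, report_frame

atlas = load_atlas("FSL")

for condition in ("deterministic", "null"):
    conn_dir = Path("results/connectomes") / condition
    index = json.loads((conn_dir / "index.json").read_text())
    conns = [read_connectome(conn_dir / rec["file"], meta=rec) for rec in index]
    run1 = [c for c in conns if c.meta["run"] == 1]
    run2 = [c for c in conns if c.meta["run"] == 2]
    report = percentile_filter(edge_anova(run1, run2))
    frame = report_frame(report, atlas=atlas)
    frame.to_csv(f"results/edge_report_{condition}.csv", index=False)
    print(f"{condition}: {len(report.selected_positive)} strengthened, "
          f"{len(report.selected_negative)} weakened "
          f"(of {len(report.table)} edges)")
    for _, row in frame[frame["selected"] != "none"].head(8).iterrows():
        print(f"  [{row.selected}] {row.name_i} -- {row.name_j}  diff={row['diff']:+.3f}")
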