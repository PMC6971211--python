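#!/usr/bin/env python
"""Estimate FDR-masked Fisher-z connectomes for each cohort.

Reads results/cohorts/<condition>/, writes one weight matrix per
subject/run to results/connectomes/<condition>/ plus an index, and reports
the mean retained-edge count per run.
"""

import json
from pathlib import Path

import numpy as np

from connlearn.connectome import build_connectome, write_connectome
from connlearn.synthetic import read_cohort

for condition in ("deterministic", "null"):
    cohort = read_cohort(Path("results/cohorts") / condition)
    out = Path("results/connectomes") / condition
    out.mkdir(parents=True, exist_ok=True)
    index, edges = [], {1: [], 2: []}
    for ts in cohort:
        conn = build_connectome(ts, q=0.05)
        fname = f"{ts.subject_id}_run-{ts.run}_connectome.tsv"
        write_connectome(conn, out / fname)
        index.append({"subject_id": ts.subject_id, "run": ts.run,
                      "condition": ts.condition, "file": fname})
        edges[ts.run].append(conn.n_edges())
    (out / "index.json").write_text(json.dumps(index, indent=2))
    print(
        f"{condition}: mean retained edges run 1 = {np.mean(edges[1]):.0f}, "
        f"run 2 = {np.mean(edges[2]):.0f}"
    )
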