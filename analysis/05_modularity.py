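#!/usr/bin/env python
"""Module counts per subject/run and on the grand-average network.

Writes results/modules_<condition>.csv and prints the run-wise mean +/- sd
module counts (fewer modules in run 2 read as functional integration).
"""

import json
from pathlib import Path

from connlearn.connectome import read_connectome
from connlearn.modularity import cohort_module_counts, detect_modules, grand_average

for condition in ("deterministic", "null"):
    conn_dir = Path("results/connectomes") / condition
    index = json.loads((conn_dir / "index.json").read_text())
    conns = [read_connectome(conn_dir / rec["file"], meta=rec) for rec in index]
    counts = cohort_module_counts(conns)
    counts.to_csv(f"results/modules_{condition}.csv", index=False)
    summary = counts.groupby("run")["n_modules"].agg(["mean", "std"]).round(2)
    print(f"{condition} module counts:\n{summary}")
    for run in (1, 2):
        avg = grand_average([c for c in conns if c.meta["run"] == run])
        res = detect_modules(avg)
        print(f"  grand-average run {run}: {res.n_modules} modules")
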