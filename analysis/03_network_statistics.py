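#!/usr/bin/env python
"""Compute the five complex-network statistics per connectome.

Writes the long-format table results/statistics_<condition>.csv and prints
the run-wise means.
"""

import json
from pathlib import Path

from connlearn.connectome import read_connectome
from connlearn.metrics import compute_statistics, statistics_table

for condition in ("deterministic", "null"):
    conn_dir = Path("results/connectomes") / condition
    index = json.loads((conn_dir / "index.json").read_text())
    records = [
        compute_statistics(read_connectome(conn_dir / rec["file"], meta=rec))
        for rec in index
    ]
    table = statistics_table(records)
    out = Path(f"results/statistics_{condition}.csv")
    table.to_csv(out, index=False)
    print(f"{condition} run-wise means -> {out}")
    print(table.groupby(["measure", "run"])["value"].mean().unstack().round(4))
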