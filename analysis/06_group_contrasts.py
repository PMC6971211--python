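#!/usr/bin/env python
"""Run-1 vs run-2 non-parametric contrasts of all cohort-level measures.

Wilcoxon signed-rank with Bonferroni correction over the five-statistic
family, plus contrasts of Compression Flow and module counts.  Writes
results/contrasts_<condition>.csv and box-whisker panels under
results/plots/.
"""

import pandas as pd

from connlearn.group_stats import run_contrast_suite, wilcoxon_paired
from connlearn.metrics import MEASURES
from connlearn.plots import box_whisker

for condition in ("deterministic", "null"):
    stats = pd.read_csv(f"results/statistics_{condition}.csv")
    suite = run_contrast_suite(stats)
    extra = []
    for name, path, col in (("compression_flow", f"results/cf_{condition}.csv", "cf"),
                            ("n_modules", f"results/modules_{condition}.csv", "n_modules")):
        df = pd.read_csv(path)
        wide = df.pivot_table(index="subject_id", columns="run", values=col).dropna()
        rep = wilcoxon_paired(wide[1].to_numpy(), wide[2].to_numpy(), measure=name)
        extra.append({"measure": name, "n_pairs": rep.n, "statistic": rep.statistic,
                      "p_raw": rep.p_raw, "p_corrected": rep.p_corrected,
                      "direction": rep.direction, "significant": rep.significant,
                      "excluded_subjects": ""})
    suite = pd.concat([suite, pd.DataFrame(extra)], ignore_index=True)
    suite.to_csv(f"results/contrasts_{condition}.csv", index=False)
    print(f"{condition}:")
    print(suite[["measure", "p_corrected", "direction", "significant"]].to_string(index=False))
    for measure in MEASURES:
        sub = stats[stats["measure"] == measure]
        box_whisker([sub[sub["run"] == r]["value"].to_numpy() for r in (1, 2)],
                    ["run 1", "run 2"],
                    f"results/plots/{condition}_{measure}.png", title=measure)
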