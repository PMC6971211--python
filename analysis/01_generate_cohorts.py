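#!/usr/bin/env python
"""Generate the synthetic study cohorts.

Writes a deterministic-condition (learning) cohort and a null-condition
cohort of band-limited, block-correlated ROI time series to
results/cohorts/<condition>/ (one TSV per subject/run plus a manifest).
"""

from pathlib import Path

from connlearn.synthetic import CohortSpec, generate_cohort, write_cohort

OUT = Path("results/cohorts")
SEED = 0

for condition in ("deterministic", "null"):
    spec = CohortSpec(condition=condition, seed=SEED)
    cohort = generate_cohort(spec)
    write_cohort(cohort, OUT / condition, spec=spec)
    print(
        f"{condition}: {spec.n_subjects} subjects x 2 runs, "
        f"{spec.n_rois} ROIs, T={spec.n_scans} -> {OUT / condition}"
    )
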