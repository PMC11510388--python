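"""Stratify a small clinical cohort into neuropsychological subgroups.

Builds an in-memory clinical table, applies the severity / behaviour /
cognitive-level thresholds, and prints counts with integer percentages
over the scored subjects.
"""

import numpy as np
import pandas as pd

from asdgm.cohort import ClinicalTable, StratConfig, cohort_summary, stratify

rng = np.random.default_rng(0)
n = 30
clinical = ClinicalTable(
    pd.DataFrame(
        {
            "age": rng.uniform(3, 17, n).round(1),
            "gender": rng.choice(["male", "female"], n, p=[0.8, 0.2]),
            "css": np.clip(np.round(rng.normal(7, 1.5, n)), 1, 10),
            "cbcl_int": rng.normal(65, 9, n).round(1),
            "cbcl_ext": rng.normal(60, 9, n).round(1),
            "cbcl_tot": rng.normal(64, 10, n).round(1),
            "iq_dq": rng.normal(63, 20, n).round(0),
        },
        index=pd.Index([f"ASD{i:03d}" for i in range(n)], name="subject_id"),
    )
)

cfg = StratConfig()  # CBCL bands <60 / 60-63 / >=64; CSS severe at >=8; CI/DD below 70
for variable in ("CSS", "CBCL_EXT", "IQ_DQ"):
    labels = stratify(clinical, variable, cfg)
    print(f"\n{variable} subgroups:")
    print(cohort_summary(labels))

# Each row: how many scored subjects fall in the band and what integer share
# of the scored cohort they represent (missing scores are excluded from the
# denominator, never assigned a default class).
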