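"""Quality control for a raw clinical table.

Winsorizes continuous columns at the 1st/99th percentiles, drops columns
with more than 30% missing values, imputes (chained equations for
continuous, mode for categorical), standardizes continuous columns, and
reference-codes categoricals into dummies — the order the pipeline always
applies.
"""

import numpy as np
import pandas as pd

from knockoffml.preprocessing import run_pipeline

rng = np.random.default_rng(0)
n = 300
raw = pd.DataFrame(
    {
        "age": rng.normal(65, 12, n).clip(18, None),
        "creatinine": np.exp(rng.normal(0, 0.6, n)),  # heavy right tail
        "lactate": np.where(rng.random(n) < 0.15, np.nan, np.exp(rng.normal(0.3, 0.5, n))),
        "rare_lab": np.where(rng.random(n) < 0.55, np.nan, rng.normal(size=n)),
        "admission": rng.choice(["medical", "surgical", "trauma"], n),
    }
)
clean, report = run_pipeline(raw)
print(f"dropped (>30% missing): {report.dropped_columns}")
print(f"imputed: {report.imputed_columns}")
print(f"columns out: {list(clean.columns)}")
print(clean.describe().loc[["mean", "std"]].round(3).to_string())
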