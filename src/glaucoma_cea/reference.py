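"""Published reference outcomes used for model validation.

The packaged table holds the per-person discounted life-years, QALYs,
lifetime costs and incremental cost-utility ratios reported for the Indian
screening-programme evaluation this package re-implements: one row per
strategy within each comparison group (annual 40-75, annual 50-75,
quinquennial 40-75), each group headed by its usual-care comparator.
Validation tests recompute the printed between-strategy arithmetic
(life-year gains, annual-vs-quinquennial cost ratios) from these rows.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["reference_lifetime_outcomes"]


def reference_lifetime_outcomes() -> pd.DataFrame:
    path = resources.files("glaucoma_cea").joinpath("data/reference_lifetime_outcomes.csv")
    return pd.read_csv(str(path))
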