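"""Bundled reference tables.

The quartile-wise demographic summary of the developmental MEG cohort the
synthetic generator emulates (82 children, ages 4 to <19): per-quartile
sample sizes, mean/SD age, and sex/handedness counts.  The pooling helper
recovers the overall column from the quartile columns, a self-consistency
check reused by the acceptance script.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_cohort_demographics", "pool_quartile_demographics"]


def reference_cohort_demographics() -> pd.DataFrame:
    """Quartile-wise demographics of the reference developmental cohort."""
    return pd.DataFrame(
        {
            "quartile": [1, 2, 3, 4],
            "n": [21, 20, 20, 21],
            "age_mean": [5.46, 8.41, 13.1, 17.0],
            "age_sd": [0.69, 1.77, 1.07, 0.80],
            "male": [6, 11, 11, 9],
            "female": [15, 9, 9, 12],
            "hand_left": [1, 1, 1, 0],
            "hand_no_preference": [3, 3, 1, 0],
            "hand_right": [17, 16, 18, 21],
        }
    )


def pool_quartile_demographics(df: pd.DataFrame | None = None) -> dict:
    """Overall counts and means pooled from the quartile columns."""
    if df is None:
        df = reference_cohort_demographics()
    n = int(df["n"].sum())
    male = int(df["male"].sum())
    female = int(df["female"].sum())
    right = int(df["hand_right"].sum())
    mean_age = float((df["n"] * df["age_mean"]).sum() / n)
    return {
        "n": n,
        "male": male,
        "female": female,
        "female_pct": 100.0 * female / n,
        "hand_left": int(df["hand_left"].sum()),
        "hand_no_preference": int(df["hand_no_preference"].sum()),
        "hand_right": right,
        "mean_age": mean_age,
    }
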