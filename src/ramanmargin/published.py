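"""Published per-specimen statistics of the ex-vivo breast study.

The eight-specimen summary table of the line-scanning Raman study this
package models (per-image % of pixels excluded at QF < 0.5, % of
retained pixels classified fat, % of non-fat pixels classified cancer,
and mean ± sd of the cancer posterior probability over non-fat pixels),
together with the study-level spectrum counts.  These printed values are
inputs for consistency checks — the raw hypercubes were never deposited.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["specimen_table", "STUDY_COUNTS"]

_ROWS = [
    # specimen, pathology, cancer?, pct_excluded, pct_fat, pct_cancer, p_mean, p_std
    ("P4 S1", "Invasive mucinous carcinoma", True, 97, 0, 100, 0.98, 0.07),
    ("P2", "Invasive ductal carcinoma", True, 45, 41, 74, 0.64, 0.28),
    ("P1 S1", "Invasive ductal carcinoma", True, 46, 39, 62, 0.56, 0.32),
    ("P5", "Invasive ductal carcinoma", True, 0, 91, 22, 0.31, 0.18),
    ("P4 S2", "Fibrous tissue", False, 13, 79, 4, 0.15, 0.12),
    ("P6", "Fibrous tissue", False, 1, 81, 0, 0.12, 0.07),
    ("P3", "Adipose tissue", False, 32, 86, 1, 0.06, 0.09),
    ("P1 S2", "Adipose tissue", False, 17, 96, 2, 0.06, 0.10),
]

STUDY_COUNTS = {
    "n_rows": 40,
    "n_cols": 42,
    "n_images": 8,
    "n_retained": 8020,
    "n_fat": 6008,
    "n_normal": 1137,
    "n_cancer": 875,
    "mean_pct_excluded_printed": 31,
}


def specimen_table() -> pd.DataFrame:
    """The per-specimen summary table as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["specimen", "pathology", "contains_cancer", "pct_excluded",
                 "pct_fat", "pct_cancer", "p_mean", "p_std"],
    )
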