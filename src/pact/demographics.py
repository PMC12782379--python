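"""Reference cohort demographics.

The 19-participant transradial cohort that motivates this package: per-
participant sex, age, residual-limb length and the clinician-assessed
qualitative descriptors (length class per the Long/Short/Very Short
convention; shape class per the ISO 8548-3 Conical/Cylindrical/Bulbous
vocabulary).  These rows parameterize the synthetic population generator
and give exact summary-statistic checks.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

__all__ = ["REFERENCE_DEMOGRAPHICS", "summarize_demographics"]

_CSV = """\
id,sex,age,limb_length,length_class,shape_class
P01,F,15,66.6,short,conical
P02,M,10,78.6,very_short,cylindrical
P03,F,13,35.4,short,cylindrical
P04,F,22,45.8,very_short,cylindrical
P05,M,17,46.4,very_short,cylindrical
P06,F,16,75.6,very_short,conical
P07,M,61,59.2,very_short,conical
P08,M,47,78.4,short,conical
P09,M,55,87.9,short,conical
P10,F,29,88.1,short,conical
P11,M,37,104.0,short,conical
P12,M,58,104.3,short,conical
P13,M,17,88.9,very_short,conical
P14,F,10,51.8,short,cylindrical
P15,F,67,77.6,short,conical
P16,M,12,107.0,short,conical
P17,F,9,64.5,very_short,conical
P18,F,26,67.0,short,conical
P19,M,52,123.1,short,conical
"""

#: ages in years, lengths in mm
REFERENCE_DEMOGRAPHICS: pd.DataFrame = pd.read_csv(io.StringIO(_CSV))


def summarize_demographics(df: pd.DataFrame | None = None) -> dict:
    """Sample mean and (n-1) SD of age and limb length for a cohort table."""
    if df is None:
        df = REFERENCE_DEMOGRAPHICS
    out = {}
    for col, key in (("age", "age"), ("limb_length", "length")):
        vals = np.asarray(df[col], dtype=float)
        out[f"{key}_mean"] = float(vals.mean())
        out[f"{key}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    out["n"] = int(len(df))
    return out
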