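"""Compartment relevance: which compartment doses track the blood dose.

Across a cohort, the DVH D_X of each compartment (minimum dose to its
hottest X% of voxels, conventionally X = 90) is correlated with the
dynamic blood-dose estimate D_X% via the Pearson coefficient.  Strongly
correlated compartments are the ones whose sparing during treatment
planning would most directly reduce the estimated circulating-blood dose.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["compartment_relevance"]


def compartment_relevance(
    table: pd.DataFrame,
    compartment_col: str = "compartment",
    compartment_dose_col: str = "d90_compartment",
    blood_dose_col: str = "d90_blood",
) -> pd.DataFrame:
    """Pearson correlation of compartment dose with blood dose, per compartment.

    ``table`` is long-format with one row per (patient, compartment); rows
    with a missing value on either side are dropped per compartment, so a
    compartment present in only a subset of patients is correlated over
    its available subset (its ``n`` is reported; no imputation).  Returns a
    frame with columns ``compartment, n, r, p`` sorted by descending ``r``;
    ``r`` is NaN when a compartment has fewer than 3 complete pairs or
    zero variance on either axis.
    """
    rows = []
    for name, group in table.groupby(compartment_col, sort=False):
        pair = group[[compartment_dose_col, blood_dose_col]].dropna()
        n = len(pair)
        r = p = np.nan
        if n >= 3:
            x = pair[compartment_dose_col].to_numpy(dtype=float)
            y = pair[blood_dose_col].to_numpy(dtype=float)
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                r, p = stats.pearsonr(x, y)
        rows.append({"compartment": name, "n": n, "r": float(r), "p": float(p)})
    result = pd.DataFrame(rows, columns=["compartment", "n", "r", "p"])
    return result.sort_values("r", ascending=False, na_position="last").reset_index(drop=True)
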