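"""Cohort demographics checks.

Group comparisons of categorical covariates (e.g. gender) use the
Pearson chi-square test on the 2x2 contingency table, without continuity
correction, matching the convention of the demographic table.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import chi2_contingency


def gender_contingency_test(chd_counts, control_counts) -> tuple:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2
    group-by-gender table.

    ``chd_counts`` and ``control_counts`` are (female, male) pairs.
    Returns (chi2 statistic, p-value).
    """
    table = np.asarray([list(chd_counts), list(control_counts)], dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected two (female, male) count pairs")
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
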