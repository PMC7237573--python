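"""Demographic summary of the 15-subject MGCE-classified study cohort.

The printed per-category counts of the cohort the method was developed on
(five subjects per clinical group, classified by magnetically guided capsule
endoscopy). Proportions are always recomputed from the counts rather than
stored, so they stay consistent with the arithmetic.
"""

from __future__ import annotations

import pandas as pd

N_SUBJECTS = 15

# characteristic -> count out of N_SUBJECTS
COHORT_COUNTS: dict[str, int] = {
    "male": 6,
    "female": 9,
    "healthy": 5,
    "gastritis": 5,
    "duodenum_erosion": 1,
    "jejunum_erosion": 1,
    "ileum_erosion": 3,
    "fob_weakly_positive": 1,  # fecal occult blood
    "fob_negative": 14,
}


def proportion(characteristic: str, decimals: int = 1) -> float:
    """Percentage of the cohort with the characteristic, e.g. 33.3 for 5/15."""
    count = COHORT_COUNTS[characteristic]
    return round(100.0 * count / N_SUBJECTS, decimals)


def cohort_summary() -> pd.DataFrame:
    """Counts and recomputed percentages for every recorded characteristic."""
    rows = [
        {"characteristic": k, "count": v, "percent": proportion(k)}
        for k, v in COHORT_COUNTS.items()
    ]
    return pd.DataFrame(rows)
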