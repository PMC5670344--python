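"""Reference summary tables from a published military mTBI case–control
study (15 cases, 22 controls; diffusion imaging on 12 cases / 17 controls).

These printed group summaries serve three purposes: worked examples for
the statistics module (recomputing pooled t-statistics and the
Holm–Bonferroni adjustment from published means/SDs), the default ROI
vocabulary for fractional-anisotropy tables, and realistic per-ROI FA
baselines for the synthetic cohort generator.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "cohort_summary",
    "categorical_counts",
    "fa_reference",
    "DEFAULT_ROI_VOCABULARY",
]

# variable, case mean, case sd, case n, control mean, control sd, control n,
# printed df / t / p from the source table
_COHORT_ROWS = [
    ("Age", 27.1, 6.2, 15, 27.9, 6.1, 22, 35, 0.38, 0.71),
    ("CAPS total", 25.0, 13.6, 15, 15.7, 10.8, 22, 35, -2.32, 0.027),
    ("CAPS Criterion B", 6.9, 5.1, 15, 2.6, 3.1, 22, 35, -3.17, 0.0031),
    ("CAPS Criterion C", 5.1, 4.1, 15, 3.8, 5.6, 22, 35, -0.80, 0.43),
    ("CAPS Criterion D", 13.0, 6.8, 15, 9.3, 4.2, 22, 35, -2.07, 0.046),
    ("PSQI score", 6.9, 3.1, 15, 6.3, 2.5, 20, 33, -0.66, 0.52),
    ("PHQ-9 score", 3.1, 1.9, 15, 1.9, 2.1, 21, 34, -1.83, 0.076),
    ("PCL-M score", 32.1, 7.8, 15, 23.9, 6.9, 21, 34, -3.37, 0.0019),
]

# 2x2 counts (case yes/no, control yes/no) with the printed Fisher p
_CATEGORICAL_ROWS = [
    ("gender_male", 12, 3, 21, 1, 0.15),
    ("handedness_right", 13, 2, 19, 3, 0.37),
]

# roi, side, case mean, case sd, control mean, control sd, printed raw p
# (case n = 12, control n = 17 for all FA rows)
_FA_ROWS = [
    ("corpus callosum", "front", 0.377, 0.009, 0.361, 0.011, 0.31),
    ("corpus callosum", "posterior", 0.422, 0.005, 0.415, 0.008, 0.49),
    ("corpus callosum", "superior", 0.420, 0.006, 0.412, 0.008, 0.44),
    ("cingulum", "left", 0.345, 0.009, 0.337, 0.007, 0.46),
    ("cingulum", "right", 0.349, 0.006, 0.345, 0.006, 0.71),
    ("corticopontine tract", "left", 0.419, 0.007, 0.412, 0.009, 0.58),
    ("corticopontine tract", "right", 0.417, 0.006, 0.417, 0.008, 0.96),
    ("corticospinal tract", "left", 0.432, 0.012, 0.422, 0.011, 0.53),
    ("corticospinal tract", "right", 0.408, 0.009, 0.408, 0.009, 0.96),
    ("fornix", "left", 0.294, 0.004, 0.296, 0.007, 0.86),
    ("fornix", "right", 0.297, 0.006, 0.300, 0.006, 0.92),
    ("inferior cerebellar peduncle", "left", 0.273, 0.004, 0.289, 0.005, 0.026),
    ("inferior cerebellar peduncle", "right", 0.265, 0.003, 0.285, 0.004, 0.0015),
    ("inferior fronto-occipital fasciculus", "left", 0.341, 0.005, 0.339, 0.008, 0.77),
    ("inferior fronto-occipital fasciculus", "right", 0.344, 0.006, 0.341, 0.007, 0.76),
    ("inferior longitudinal fasciculus", "left", 0.361, 0.007, 0.358, 0.009, 0.85),
    ("inferior longitudinal fasciculus", "right", 0.353, 0.006, 0.349, 0.009, 0.76),
    ("middle cerebellar peduncle", "none", 0.334, 0.005, 0.332, 0.004, 0.78),
    ("optic radiation", "left", 0.399, 0.007, 0.392, 0.010, 0.60),
    ("optic radiation", "right", 0.378, 0.007, 0.377, 0.011, 0.96),
    ("superior cerebellar peduncle", "left", 0.322, 0.007, 0.331, 0.008, 0.42),
    ("superior cerebellar peduncle", "right", 0.289, 0.005, 0.303, 0.007, 0.17),
    ("superior fronto-occipital fasciculus", "left", 0.357, 0.006, 0.351, 0.008, 0.59),
    ("superior fronto-occipital fasciculus", "right", 0.344, 0.007, 0.343, 0.007, 0.94),
    ("superior longitudinal fasciculus", "left", 0.375, 0.004, 0.368, 0.009, 0.53),
    ("superior longitudinal fasciculus", "right", 0.360, 0.005, 0.355, 0.008, 0.65),
    ("uncinate fasciculus", "left", 0.279, 0.011, 0.281, 0.009, 0.89),
    ("uncinate fasciculus", "right", 0.291, 0.007, 0.301, 0.009, 0.43),
]


def cohort_summary() -> pd.DataFrame:
    """Published demographic / questionnaire summaries per group."""
    return pd.DataFrame(
        _COHORT_ROWS,
        columns=[
            "variable",
            "case_mean",
            "case_sd",
            "case_n",
            "control_mean",
            "control_sd",
            "control_n",
            "printed_df",
            "printed_t",
            "printed_p",
        ],
    )


def categorical_counts() -> pd.DataFrame:
    """Published 2x2 categorical counts with the printed Fisher p-values."""
    return pd.DataFrame(
        _CATEGORICAL_ROWS,
        columns=["variable", "case_yes", "case_no", "control_yes", "control_no", "printed_p"],
    )


def fa_reference() -> pd.DataFrame:
    """Published per-ROI fractional-anisotropy group summaries (28 rows)."""
    return pd.DataFrame(
        _FA_ROWS,
        columns=["roi", "side", "case_mean", "case_sd", "control_mean", "control_sd", "printed_p"],
    )


#: The 28 (roi, side) labels of the default white-matter ROI vocabulary.
DEFAULT_ROI_VOCABULARY: tuple[tuple[str, str], ...] = tuple(
    (roi, side) for roi, side, *_ in _FA_ROWS
)
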