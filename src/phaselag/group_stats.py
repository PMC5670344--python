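"""Group-level statistics: band→pair hierarchical synchrony contrasts,
demographic tests, ROI screening with Holm–Bonferroni, and the
structure–function correlation.

Conventions
-----------
* Pooled two-sample t-statistics are oriented (control mean − case mean)/SE
  so a deficit in the case group yields a negative t when cases score
  higher, matching the published table signs.
* The band→pair procedure is hierarchical: Wilcoxon rank-sum on the
  across-pairs band mean for every band first (uncorrected), then
  per-pair tests only within bands significant at α.
* Pearson correlation significance defaults to the Student-t form
  t = r·√((n−2)/(1−r²)); a Fisher-z variant is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsReport",
    "wilcoxon_rank_sum",
    "two_sample_t_pooled",
    "two_sample_t_from_data",
    "fisher_exact_2x2",
    "pearson_corr_test",
    "holm_bonferroni",
    "compare_groups",
    "fa_group_screen",
    "structure_function_correlation",
]

logger = logging.getLogger("phaselag")

GROUPS = ("case", "control")


@dataclass
class StatsReport:
    """Container for the full statistical workflow's outputs."""

    band_tests: pd.DataFrame | None = None
    pair_tests: pd.DataFrame | None = None
    fa_tests: pd.DataFrame | None = None
    correlation: dict | None = None
    alpha: float = 0.05

    def to_dict(self) -> dict:
        out: dict = {"alpha": self.alpha}
        for name in ("band_tests", "pair_tests", "fa_tests"):
            df = getattr(self, name)
            out[name] = None if df is None else df.to_dict(orient="records")
        out["correlation"] = self.correlation
        return out


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact null enumeration when the combined sample is small (≤ 12) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.  Returns (W, p) where W is the rank sum of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([x, y])
    w_stat = float(stats.rankdata(pooled)[: x.size].sum())
    if np.ptp(pooled) == 0:
        return w_stat, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return w_stat, float(min(1.0, res.pvalue))


def two_sample_t_pooled(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance t from group summaries; group 1 = case, group 2 = control.

    Returns (t, df, p) with t = (mean2 − mean1)/SE and df = n1 + n2 − 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("invalid standard deviations (both zero or negative)")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean2 - mean1) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, float(p)


def two_sample_t_from_data(case: Sequence[float], control: Sequence[float]) -> tuple[float, int, float]:
    """Pooled t from raw vectors (case first), same orientation as above."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    return two_sample_t_pooled(
        case.mean(), case.std(ddof=1), case.size,
        control.mean(), control.std(ddof=1), control.size,
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Fisher's exact test on a 2×2 table.

    Returns ``(p_two_sided, point_probability)``: the standard two-sided
    p (sum of hypergeometric probabilities of tables at least as extreme
    as observed) and the hypergeometric point probability of the observed
    table itself.  Published tables sometimes print the latter, so both
    are reported.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return 1.0, 1.0
    n = int(t.sum())
    point = float(stats.hypergeom.pmf(t[0, 0], n, row[0], col[0]))
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(min(1.0, p)), point


def pearson_corr_test(
    x: Sequence[float], y: Sequence[float], method: str = "t"
) -> tuple[float, float, float, int]:
    """Pearson correlation with significance test.

    ``method='t'`` (default) uses t = r·√((n−2)/(1−r²)) against Student
    df = n−2; ``method='fisher-z'`` uses z = atanh(r)·√(n−3) against the
    standard normal.  Pairs with any missing value are dropped.
    Returns (r, statistic, p, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 complete pairs (have {n})")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r = float(np.corrcoef(x, y)[0, 1])
    if method == "t":
        if 1.0 - r * r < 1e-15:
            return r, math.inf if r > 0 else -math.inf, 0.0, n
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
        return r, float(t), float(p), n
    if method == "fisher-z":
        if abs(r) >= 1.0:
            return r, math.inf if r > 0 else -math.inf, 0.0, n
        z = math.atanh(r) * math.sqrt(n - 3)
        p = 2.0 * stats.norm.sf(abs(z))
        return r, float(z), float(p), n
    raise ValueError(f"unknown method {method!r}")


def holm_bonferroni(pvals: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, in the input order."""
    pvals = list(pvals)
    if not pvals:
        return []
    arr = np.asarray(pvals, dtype=float)
    if ((arr <= 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return list(multipletests(arr, method="holm")[1])


def _group_values(
    df: pd.DataFrame, cohort: pd.DataFrame, value_col: str = "value"
) -> tuple[np.ndarray, np.ndarray]:
    merged = df.merge(cohort[["subject_id", "group"]], on="subject_id", how="inner")
    case = merged.loc[merged["group"] == "case", value_col].to_numpy()
    control = merged.loc[merged["group"] == "control", value_col].to_numpy()
    return case, control


def compare_groups(
    connectivity: pd.DataFrame,
    cohort: pd.DataFrame,
    bands: Sequence[str] | None = None,
    alpha: float = 0.05,
    correct_pairs: bool = False,
) -> StatsReport:
    """Hierarchical band→pair group contrast on a tidy connectivity table.

    ``connectivity`` needs columns subject_id, channel_a, channel_b, band,
    value.  Stage 1: Wilcoxon rank-sum (case vs control) on the
    across-pairs mean per band, uncorrected.  Stage 2: per-pair Wilcoxon
    within each stage-1-significant band; per-pair p-values are reported
    uncorrected unless ``correct_pairs``.
    """
    required = {"subject_id", "channel_a", "channel_b", "band", "value"}
    if not required <= set(connectivity.columns):
        raise ValueError(f"connectivity table missing columns {required - set(connectivity.columns)}")
    known = set(connectivity["subject_id"])
    missing = [s for s in cohort["subject_id"] if s not in known]
    if missing:
        logger.warning("no connectivity rows for %d subject(s): %s — excluded", len(missing), missing)
        cohort = cohort[~cohort["subject_id"].isin(missing)]
    for g in GROUPS:
        if (cohort["group"] == g).sum() < 2:
            raise ValueError(f"need at least 2 subjects in group {g!r}")

    if bands is None:
        bands = list(dict.fromkeys(connectivity["band"]))

    global_means = (
        connectivity.groupby(["subject_id", "band"], sort=False)["value"].mean().reset_index()
    )
    band_rows = []
    for band in bands:
        sub = global_means[global_means["band"] == band]
        case, control = _group_values(sub, cohort)
        w, p = wilcoxon_rank_sum(case, control)
        band_rows.append(
            {
                "band": band,
                "n_case": case.size,
                "n_control": control.size,
                "case_mean": float(case.mean()),
                "control_mean": float(control.mean()),
                "W": w,
                "p": p,
                "significant": bool(p < alpha),
            }
        )
    band_tests = pd.DataFrame(band_rows)

    pair_rows = []
    for band in band_tests.loc[band_tests["significant"], "band"]:
        sub = connectivity[connectivity["band"] == band]
        for (a, b), pair_df in sub.groupby(["channel_a", "channel_b"], sort=False):
            case, control = _group_values(pair_df, cohort)
            w, p = wilcoxon_rank_sum(case, control)
            pair_rows.append(
                {
                    "band": band,
                    "channel_a": a,
                    "channel_b": b,
                    "case_mean": float(case.mean()),
                    "control_mean": float(control.mean()),
                    "W": w,
                    "p": p,
                }
            )
    pair_tests = pd.DataFrame(
        pair_rows, columns=["band", "channel_a", "channel_b", "case_mean", "control_mean", "W", "p"]
    )
    if not pair_tests.empty:
        if correct_pairs:
            pair_tests["p_adjusted"] = np.concatenate(
                [
                    holm_bonferroni(g["p"].tolist())
                    for _, g in pair_tests.groupby("band", sort=False)
                ]
            )
            pair_tests["significant"] = pair_tests["p_adjusted"] < alpha
        else:
            pair_tests["significant"] = pair_tests["p"] < alpha

    return StatsReport(band_tests=band_tests, pair_tests=pair_tests, alpha=alpha)


def fa_group_screen(
    roi_table: pd.DataFrame, cohort: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-(roi, side) pooled t-tests with Holm adjustment across all rows.

    ROIs with FA for fewer than half of the cohort's subjects are dropped
    with a warning.  Returns a frame with raw and Holm-adjusted p-values.
    """
    merged = roi_table.merge(cohort[["subject_id", "group"]], on="subject_id", how="inner")
    n_subjects = cohort["subject_id"].nunique()
    rows = []
    for (roi, side), sub in merged.groupby(["roi", "side"], sort=False):
        if sub["subject_id"].nunique() < n_subjects / 2:
            logger.warning("ROI (%s, %s) present for <50%% of subjects — excluded", roi, side)
            continue
        case = sub.loc[sub["group"] == "case", "fa"].to_numpy()
        control = sub.loc[sub["group"] == "control", "fa"].to_numpy()
        if case.size < 2 or control.size < 2:
            raise ValueError(f"need >= 2 subjects per group with FA for ({roi}, {side})")
        if np.ptp(np.concatenate([case, control])) == 0:
            t, df, p = 0.0, case.size + control.size - 2, 1.0
        else:
            t, df, p = two_sample_t_from_data(case, control)
        rows.append(
            {
                "roi": roi,
                "side": side,
                "case_mean": float(case.mean()),
                "control_mean": float(control.mean()),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adjusted"] = holm_bonferroni(out["p"].tolist())
        out["significant"] = out["p_adjusted"] < alpha
    return out


def structure_function_correlation(
    normalized_sync: pd.DataFrame,
    roi_table: pd.DataFrame,
    roi: str,
    side: str,
    group: str,
    cohort: pd.DataFrame,
    method: str = "t",
) -> dict:
    """Pearson test: null-normalized synchrony vs one ROI's FA, within a group.

    ``normalized_sync`` needs columns subject_id, z (the surrogate-null
    z-score of the global band synchrony).  Returns a dict with r, the
    test statistic, p, n and identifying metadata.
    """
    fa = roi_table[(roi_table["roi"] == roi) & (roi_table["side"] == side)]
    subjects = cohort.loc[cohort["group"] == group, "subject_id"]
    merged = (
        normalized_sync.merge(fa[["subject_id", "fa"]], on="subject_id")
        .merge(subjects.to_frame(), on="subject_id")
    )
    r, stat, p, n = pearson_corr_test(merged["z"], merged["fa"], method=method)
    return {
        "roi": roi,
        "side": side,
        "group": group,
        "method": method,
        "r": r,
        "statistic": stat,
        "p": p,
        "n": n,
    }
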