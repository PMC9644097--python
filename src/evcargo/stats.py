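"""Cohort-level hypothesis tests.

Thin, opinionated wrappers over scipy: Pearson chi-square (no continuity
correction) for clinical contingency tables, two-sided Mann-Whitney /
Wilcoxon rank-sum for particle concentrations (exact for small samples
without ties, tie-corrected normal approximation otherwise), and
tie-corrected Kruskal-Wallis for biotype proportions across timepoints.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as sps


class DegenerateTableError(ValueError):
    """Contingency table with a zero row or column margin."""


def chisq_test(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c table, without Yates correction.

    Returns (X^2, df, p).  The uncorrected statistic is what reproduces
    standard clinical-characteristics tables for modest 2x2 counts.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any() or t.sum() == 0:
        raise ValueError("cells must be nonnegative with a positive total")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero row or column margin")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def wilcoxon_rank_sum(x, y, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U, p).

    Exact enumeration when the combined sample size is <= ``exact_max_n``
    and the data are tie-free; otherwise the tie-corrected normal
    approximation (with continuity correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = ("exact"
              if (x.size + y.size) <= exact_max_n and not has_ties
              else "asymptotic")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H test; returns (H, df, p).

    When every pooled value ties (all observations identical) the statistic
    is defined as H = 0 with p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate(arrays)
    df = len(arrays) - 1
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    H, p = sps.kruskal(*arrays)
    return float(H), df, float(p)


# Dichotomizations applied before testing multi-level covariates.
_DICHOTOMIES = {
    "grade": ("2", lambda v: v == "2"),
    "ER": ("pos", lambda v: v == "pos"),
    "PR": ("pos", lambda v: v == "pos"),
    "HER2": ("0-1", lambda v: v in ("0", "1")),
    "TNBC": ("yes", lambda v: v == "yes"),
    "Ecadherin": ("pos", lambda v: v == "pos"),
    "Ki67": ("<=14%", lambda v: v == "<=14%"),
    "Tstage": ("T1-2", lambda v: v in ("T1", "T2")),
    "progression_18m": ("yes", lambda v: v == "yes"),
}


def characteristics_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Clinical-characteristics report: responder vs non-responder 2x2 tests.

    One row per covariate with the dichotomized counts and the Pearson
    chi-square p-value.  T-stage is split T1-2 vs T3-4 and HER2 score 0-1 vs
    2-3 before testing.  Covariates degenerate in the cohort (an empty level)
    get p = NaN.
    """
    subj = samples.drop_duplicates("subject_id")
    subj = subj[subj["group"].isin(["R", "NR"])]
    rows = []
    for cov, (level, pred) in _DICHOTOMIES.items():
        if cov not in subj.columns:
            continue
        is_level = subj[cov].map(pred)
        table = [
            [int((is_level & (subj["group"] == g)).sum()),
             int((~is_level & (subj["group"] == g)).sum())]
            for g in ("R", "NR")
        ]
        try:
            _, _, p = chisq_test(table)
        except DegenerateTableError:
            p = float("nan")
        rows.append({
            "covariate": cov, "level": level,
            "R_yes": table[0][0], "R_no": table[0][1],
            "NR_yes": table[1][0], "NR_no": table[1][1],
            "p_value": p,
        })
    return pd.DataFrame(rows)
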