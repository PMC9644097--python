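"""Longitudinal biomarker-candidate selection and evaluation.

Selection logic for response-predictive EV RNAs: a candidate must be
significantly higher in non-responders than responders both at diagnosis and
at the end of chemotherapy (a marker of a resistant tumor should persist
through treatment), and must additionally be specific to patients relative
to healthy controls -- either by a direct DE contrast against controls or by
a detection-fraction cap.  Candidates are scored with a ROC curve on
normalized counts (non-responders as the positive class) and a Youden-index
cutoff yielding sensitivity and specificity.

A second selection identifies chemotherapy-induced RNAs by intersecting
three contrasts: end-of-NAC vs diagnosis (induction), end-of-NAC vs healthy
controls (cancer specificity), and non-responders vs responders (resistance
association) or progressors vs non-progressors (progression association).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

from .de import Contrast, DEResult, run_de
from .matrix import CountMatrix
from .stats import wilcoxon_rank_sum


@dataclass
class ROCResult:
    """ROC points from (0,0) to (1,1) plus trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def select_candidates(de_dg: DEResult, de_nac: DEResult) -> pd.DataFrame:
    """Features up in group a (non-responders) at *both* timepoints.

    Returns a frame indexed by feature_id with biotype and the per-timepoint
    log2FC / adjusted p columns (Dg and NAC suffixes).
    """
    both = de_dg.up_in_a().intersection(de_nac.up_in_a())
    out = pd.DataFrame({
        "biotype": de_dg.table.loc[both, "biotype"],
        "log2fc_dg": de_dg.table.loc[both, "log2fc"],
        "adj_p_dg": de_dg.table.loc[both, "adj_p"],
        "log2fc_nac": de_nac.table.loc[both, "log2fc"],
        "adj_p_nac": de_nac.table.loc[both, "adj_p"],
    }, index=both)
    out.index.name = "feature_id"
    return out.sort_index()


def hc_specificity_filter(candidates: pd.DataFrame, cm: CountMatrix,
                          hc_samples, bc_samples, mode: str = "de",
                          tau: float = 1.0, max_hc_fraction: float = 0.0,
                          lfc_threshold: float = 1.0, alpha: float = 0.05
                          ) -> pd.DataFrame:
    """Keep candidates specific to patients versus healthy controls.

    Always annotates ``hc_detection_fraction`` (fraction of HC samples with
    CPM > ``tau``).  mode "de": retain candidates significantly higher in the
    BC samples than in HC (same thresholds as the main DE).  mode "detect":
    retain candidates detected in at most ``max_hc_fraction`` of HC samples.
    """
    if candidates.empty:
        out = candidates.copy()
        out["hc_detection_fraction"] = pd.Series(dtype=float)
        return out
    hc_samples, bc_samples = list(hc_samples), list(bc_samples)
    cpm_hc = cm.subset_samples(hc_samples).cpm()
    frac = (cpm_hc.loc[candidates.index] > tau).mean(axis=1)
    out = candidates.copy()
    out["hc_detection_fraction"] = frac

    if mode == "detect":
        return out[out["hc_detection_fraction"] <= max_hc_fraction + 1e-12]
    if mode == "de":
        de = run_de(cm,
                    Contrast(bc_samples, hc_samples, label="BCvsHC"),
                    lfc_threshold=lfc_threshold, alpha=alpha)
        keep = out.index.intersection(de.up_in_a())
        return out.loc[keep]
    raise ValueError(f"unknown HC filter mode {mode!r}")


def roc_curve(scores_pos, scores_neg) -> ROCResult:
    """ROC for separating positives (non-responders) from negatives.

    Threshold sweep over the observed scores; a sample is called positive
    when its score is >= the cutoff, so tied scores step the curve
    diagonally.  AUC is the trapezoidal area.
    """
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("both score sets must be nonempty")
    y = np.concatenate([np.ones_like(scores_pos), np.zeros_like(scores_neg)])
    s = np.concatenate([scores_pos, scores_neg])
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def youden_cutoff(roc: ROCResult) -> tuple[float, float, float]:
    """(cutoff, sensitivity, specificity) maximizing J = Sn + Sp - 1.

    Ties in J resolve to the lowest cutoff, favoring sensitivity.  The
    sentinel point above the maximum score is never returned unless it is
    the strict maximizer.
    """
    J = roc.tpr - roc.fpr
    best = np.flatnonzero(J >= J.max() - 1e-12)[-1]   # thresholds descend
    cutoff = roc.thresholds[best]
    if np.isinf(cutoff):
        cutoff = float(roc.thresholds[min(best + 1, len(roc.thresholds) - 1)])
    return float(cutoff), float(roc.tpr[best]), float(1.0 - roc.fpr[best])


def evaluate_candidates(candidates: pd.DataFrame, cm: CountMatrix,
                        nr_samples, r_samples,
                        factors: pd.Series | None = None) -> pd.DataFrame:
    """Attach AUC, Youden cutoff, sensitivity and specificity per candidate.

    Scores are normalized counts (CPM) at the diagnosis timepoint with
    non-responders as the positive class.
    """
    out = candidates.copy()
    for col in ("auc", "youden_cutoff", "sensitivity", "specificity"):
        out[col] = np.nan
    if out.empty:
        return out
    cpm = cm.subset_samples(list(nr_samples) + list(r_samples)).cpm(factors)
    for fid in out.index:
        roc = roc_curve(cpm.loc[fid, list(nr_samples)],
                        cpm.loc[fid, list(r_samples)])
        cut, sn, sp = youden_cutoff(roc)
        out.loc[fid, ["auc", "youden_cutoff", "sensitivity", "specificity"]] \
            = [roc.auc, cut, sn, sp]
    return out


def longitudinal_profile(feature_id: str, cm: CountMatrix,
                         samples: pd.DataFrame, tau: float = 1.0,
                         alpha: float = 0.05,
                         pre_timepoints=("Dg", "NAC"),
                         post_timepoints=("PostOp7d", "PostOp6m", "PostOp12m")
                         ) -> dict:
    """Per-timepoint levels of one feature plus post-surgery trend flags.

    Returns group x timepoint mean CPM and detection fractions, and flags
    ``drops_after_surgery`` / ``rises_after_surgery`` from a two-sided
    rank-sum comparison of patients' pre-operative vs post-operative levels.
    """
    cpm = cm.cpm().loc[feature_id]
    samples = samples.set_index("sample_id") \
        if "sample_id" in samples.columns and samples.index.name != "sample_id" \
        else samples
    prof = []
    for (grp, tp), ids in samples.groupby(["group", "timepoint"]).groups.items():
        vals = cpm.loc[list(ids)]
        prof.append({"group": grp, "timepoint": tp,
                     "mean_cpm": float(vals.mean()),
                     "detection_fraction": float((vals > tau).mean())})
    bc = samples[samples["group"] != "HC"]
    pre = cpm.loc[bc.index[bc["timepoint"].isin(pre_timepoints)]]
    post = cpm.loc[bc.index[bc["timepoint"].isin(post_timepoints)]]
    drops = rises = False
    if len(pre) and len(post):
        _, p = wilcoxon_rank_sum(pre, post)
        if p < alpha:
            drops = post.mean() < pre.mean()
            rises = post.mean() > pre.mean()
    return {"feature_id": feature_id, "profile": pd.DataFrame(prof),
            "drops_after_surgery": bool(drops),
            "rises_after_surgery": bool(rises)}


def nac_induced_select(de_nac_vs_dg: DEResult, de_nac_vs_hc: DEResult,
                       de_nr_vs_r_at_nac: DEResult,
                       de_p_vs_np_at_nac: DEResult) -> dict:
    """Chemotherapy-induced RNA sets via the triple intersection.

    resistance set = up in (NAC vs Dg) & (NAC vs HC) & (NR vs R at NAC);
    progression set swaps the third contrast for progressors vs
    non-progressors.  The report also lists features common to both sets.
    """
    induced = de_nac_vs_dg.up_in_a().intersection(de_nac_vs_hc.up_in_a())
    resistance = induced.intersection(de_nr_vs_r_at_nac.up_in_a())
    progression = induced.intersection(de_p_vs_np_at_nac.up_in_a())
    common = resistance.intersection(progression)
    return {
        "resistance": sorted(resistance),
        "progression": sorted(progression),
        "common": sorted(common),
        "n_induced": int(len(induced)),
    }
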