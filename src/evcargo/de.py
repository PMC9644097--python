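"""Differential-expression core for overdispersed count data.

From-scratch implementations of the classic count-based DE stack:

* TMM (trimmed mean of M-values) between-sample normalization factors;
* common negative-binomial dispersion by conditional maximum likelihood on
  library-size-equalized pseudo-counts;
* the two-group NB exact test, conditioning each feature on its total --
  under a common mean and dispersion phi, the group-A sum given the total
  ``t`` is BetaBinomial(t, n_a/phi, n_b/phi), and the two-sided p-value sums
  all outcomes no more probable than the observed one (minimum-likelihood
  convention);
* log2 fold changes on prior-damped CPM;
* Benjamini-Hochberg step-up adjustment.

The NB model is mean mu, variance mu + phi*mu^2; phi = 0 is the Poisson
limit, in which the exact test reduces to the exact binomial test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .matrix import CountMatrix


@dataclass
class Contrast:
    """Two disjoint, nonempty sample groups; p-values test a vs b."""

    group_a: list
    group_b: list
    label: str = ""

    def __post_init__(self):
        self.group_a = list(self.group_a)
        self.group_b = list(self.group_b)
        if not self.group_a or not self.group_b:
            raise ValueError(f"contrast {self.label!r}: empty group")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.label!r}: groups overlap")


@dataclass
class DEResult:
    """Per-feature DE table for one contrast.

    ``table`` columns: biotype, log2fc (a over b), p_value, adj_p,
    mean_cpm_a, mean_cpm_b, significant, up_in_a, up_in_b.
    """

    table: pd.DataFrame
    label: str
    factors: pd.Series
    dispersion: float
    thresholds: dict = field(default_factory=dict)

    def up_in_a(self) -> pd.Index:
        return self.table.index[self.table["up_in_a"]]

    def up_in_b(self) -> pd.Index:
        return self.table.index[self.table["up_in_b"]]


def tmm_factors(cm: CountMatrix, ref_sample: str | None = None,
                trim_m: float = 0.3, trim_a: float = 0.05) -> pd.Series:
    """TMM normalization factors, geometric-mean-rescaled to 1.

    For each sample against the reference, M (log2 CPM ratio) and A (mean
    log2 CPM) are computed over features expressed in both; the top/bottom
    ``trim_m`` of M-values and ``trim_a`` of A-values are trimmed and the
    factor is 2**(precision-weighted mean of the surviving M-values),
    weighting by inverse delta-method variances computed on relative
    frequencies (scale-free: rescaling a sample cannot perturb any factor).
    The
    reference defaults to the sample whose upper-quartile CPM is closest to
    the mean upper quartile.  A sample sharing no expressed feature with the
    reference gets factor 1 with a warning.
    """
    Y = cm.counts.to_numpy(dtype=float)
    lib = cm.library_size.to_numpy(dtype=float)
    if Y.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")

    if ref_sample is None:
        cpm = Y / lib * 1e6
        uq = np.quantile(cpm, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = list(cm.sample_ids).index(ref_sample)

    yr, lr = Y[:, ref_idx], lib[ref_idx]
    log_f = np.zeros(Y.shape[1])
    for j in range(Y.shape[1]):
        if j == ref_idx:
            continue
        yj, lj = Y[:, j], lib[j]
        ok = (yj > 0) & (yr > 0)
        if not ok.any():
            warnings.warn(
                f"sample {cm.sample_ids[j]} shares no expressed feature "
                "with the reference; factor set to 1", stacklevel=2)
            continue
        pj, pr = yj[ok] / lj, yr[ok] / lr
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        # binomial delta-method variance of M on relative frequencies;
        # scale-free so per-sample rescaling cannot perturb the factors
        w = 1.0 / pj + 1.0 / pr

        n = len(M)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rank_m = pd.Series(M).rank().to_numpy()
        rank_a = pd.Series(A).rank().to_numpy()
        keep = ((rank_m >= lo_m) & (rank_m <= hi_m)
                & (rank_a >= lo_a) & (rank_a <= hi_a))
        if not keep.any() or w[keep].sum() == 0:
            continue
        log_f[j] = np.sum(w[keep] ** -1 * M[keep]) / np.sum(w[keep] ** -1)

    log_f -= log_f.mean()   # geometric mean of 2**log_f becomes 1
    return pd.Series(2.0 ** log_f, index=cm.sample_ids, name="tmm_factor")


def _equalized_pseudocounts(cm: CountMatrix, factors: pd.Series | None
                            ) -> tuple[np.ndarray, float]:
    """Scale counts to a common (geometric-mean) effective library size."""
    eff = cm.library_size.to_numpy(dtype=float)
    if factors is not None:
        eff = eff * factors.reindex(cm.sample_ids).to_numpy(dtype=float)
    common = np.exp(np.mean(np.log(eff)))
    pseudo = cm.counts.to_numpy(dtype=float) * (common / eff)
    return pseudo, common


def _cond_loglik(phi: float, group_mats: list) -> float:
    """Pooled NB conditional log-likelihood of rounded pseudo-counts.

    For n iid NB(r=1/phi, p) samples the count vector given its sum z is
    Dirichlet-multinomial-like:
    P = prod_i C(y_i + r - 1, y_i) / C(n r + z - 1, z).
    """
    r = 1.0 / phi
    ll = 0.0
    for Y in group_mats:
        n = Y.shape[1]
        z = Y.sum(axis=1)
        ll += float(
            np.sum(gammaln(Y + r)) - Y.size * gammaln(r)
            - np.sum(gammaln(n * r + z) - gammaln(n * r) - gammaln(z + 1))
            - np.sum(gammaln(Y + 1))
        )
    return ll


def estimate_common_dispersion(cm: CountMatrix, groups: dict,
                               factors: pd.Series | None = None,
                               bounds: tuple = (1e-4, 10.0),
                               fallback: float = 0.3) -> float:
    """Common NB dispersion by conditional ML over all replicated groups.

    ``groups`` maps label -> sample ids.  Counts are equalized to a common
    library size and rounded; the pooled conditional log-likelihood is
    maximized by bounded search on log10(phi) in ``bounds``.  Without any
    replicated group the ``fallback`` is returned with a warning.
    """
    mats = []
    for label, ids in groups.items():
        ids = list(ids)
        if len(ids) < 2:
            continue
        sub = cm.subset_samples(ids)
        pseudo, _ = _equalized_pseudocounts(
            sub, factors.loc[ids] if factors is not None else None)
        mats.append(np.round(pseudo))
    if not mats:
        warnings.warn("no replicated group; returning fallback dispersion",
                      stacklevel=2)
        return fallback

    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    res = minimize_scalar(lambda x: -_cond_loglik(10.0 ** x, mats),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    return float(10.0 ** res.x)


def _betabinom_logpmf(a: np.ndarray, t: int, alpha: float, beta: float
                      ) -> np.ndarray:
    return (gammaln(t + 1) - gammaln(a + 1) - gammaln(t - a + 1)
            + gammaln(a + alpha) + gammaln(t - a + beta)
            - gammaln(t + alpha + beta)
            + gammaln(alpha + beta) - gammaln(alpha) - gammaln(beta))


def nb_exact_test(count_sum_a: int, count_sum_b: int, n_a: int, n_b: int,
                  phi: float) -> float:
    """Two-sided NB exact test p-value for equalized group sums.

    Conditional on t = a + b, the group-A sum under the null common mean is
    BetaBinomial(t, n_a/phi, n_b/phi) (binomial with p = n_a/(n_a+n_b) at
    phi = 0).  p is the total probability of outcomes whose pmf does not
    exceed the observed pmf.  Always in (0, 1]; equals 1 exactly for a
    symmetric observed split.
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    a_obs = int(round(count_sum_a))
    b_obs = int(round(count_sum_b))
    if a_obs < 0 or b_obs < 0:
        raise ValueError("group sums must be nonnegative")
    t = a_obs + b_obs
    if t == 0:
        return 1.0

    support = np.arange(t + 1)
    # Below this dispersion the beta-binomial is numerically indistinguishable
    # from its binomial limit, and differencing huge gammaln values would lose
    # the precision needed for tie detection.
    if phi > 0 and (n_a + n_b) / phi > 1e7:
        phi = 0.0
    if phi == 0:
        p_a = n_a / (n_a + n_b)
        logpmf = (gammaln(t + 1) - gammaln(support + 1)
                  - gammaln(t - support + 1)
                  + support * np.log(p_a) + (t - support) * np.log1p(-p_a))
    else:
        logpmf = _betabinom_logpmf(support, t, n_a / phi, n_b / phi)

    # normalize in probability space for a well-conditioned sum; near-ties
    # count as "as likely" under the conventional 1 + 1e-7 relative slack
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    mask = logpmf <= logpmf[a_obs] + np.log1p(1e-7)
    if mask.all():
        return 1.0
    return float(min(1.0, max(pmf[mask].sum(), np.finfo(float).tiny)))


def log2_fold_change(cm: CountMatrix, contrast: Contrast,
                     factors: pd.Series | None = None,
                     prior: float = 0.5) -> pd.Series:
    """log2((mean CPM_a + prior) / (mean CPM_b + prior)); always finite.

    The prior pseudo-count (CPM units, default 0.5) keeps fold changes of
    features absent from one group large but finite.
    """
    cpm = cm.cpm(factors)
    ma = cpm[contrast.group_a].mean(axis=1)
    mb = cpm[contrast.group_b].mean(axis=1)
    return np.log2((ma + prior) / (mb + prior)).rename("log2fc")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_p(i) = min over j >= i (rank order) of p(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def run_de(cm: CountMatrix, contrast: Contrast,
           dispersion: float | None = None,
           lfc_threshold: float = 1.0, alpha: float = 0.05,
           prior: float = 0.5,
           factors: pd.Series | None = None) -> DEResult:
    """TMM-normalized NB exact-test DE for one two-group contrast.

    Features pass when adj_p <= ``alpha`` (BH) and |log2FC| > ``lfc_threshold``,
    split by sign into up_in_a / up_in_b.  ``dispersion=None`` estimates the
    common dispersion from the two groups.
    """
    ids = contrast.group_a + contrast.group_b
    sub = cm.subset_samples(ids)
    if factors is None:
        factors = tmm_factors(sub)
    else:
        factors = factors.reindex(ids)
    if dispersion is None:
        dispersion = estimate_common_dispersion(
            sub, {"a": contrast.group_a, "b": contrast.group_b}, factors)

    pseudo, _ = _equalized_pseudocounts(sub, factors)
    idx_a = [ids.index(s) for s in contrast.group_a]
    idx_b = [ids.index(s) for s in contrast.group_b]
    sums_a = np.round(pseudo[:, idx_a].sum(axis=1)).astype(np.int64)
    sums_b = np.round(pseudo[:, idx_b].sum(axis=1)).astype(np.int64)
    n_a, n_b = len(idx_a), len(idx_b)

    pvals = np.array([
        nb_exact_test(sa, sb, n_a, n_b, dispersion)
        for sa, sb in zip(sums_a, sums_b)
    ])
    adj = bh_adjust(pvals)
    lfc = log2_fold_change(sub, contrast, factors, prior)

    cpm = sub.cpm(factors)
    table = pd.DataFrame({
        "biotype": sub.biotype,
        "log2fc": lfc,
        "p_value": pvals,
        "adj_p": adj,
        "mean_cpm_a": cpm[contrast.group_a].mean(axis=1),
        "mean_cpm_b": cpm[contrast.group_b].mean(axis=1),
    }, index=sub.feature_ids)
    sig = (table["adj_p"] <= alpha) & (table["log2fc"].abs() > lfc_threshold)
    table["significant"] = sig
    table["up_in_a"] = sig & (table["log2fc"] > lfc_threshold)
    table["up_in_b"] = sig & (table["log2fc"] < -lfc_threshold)
    return DEResult(table=table, label=contrast.label, factors=factors,
                    dispersion=float(dispersion),
                    thresholds={"lfc": lfc_threshold, "alpha": alpha,
                                "prior": prior})
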