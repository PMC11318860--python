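"""Inference machinery: correlation tests, minimal-n, permutation nulls,
FDR, bootstrap model comparison, trend tests, and paired edge tests.

Correlation p-values use the exact null distribution of the Pearson r
(the beta distribution of r^2, equivalently the t transform with n-2
degrees of freedom), so the minimal significant sample size for an
observed correlation can be computed by inverting the critical value.

Permutation tests re-run the *entire* cross-validation on permuted
targets — penalty selection included — and use the add-one convention
p = (1 + #{null >= observed}) / (1 + n_perm), which never returns zero.

The pre-task vs intrinsic connectivity comparison is a per-edge paired t
test on participant-level condition means with Benjamini-Hochberg
correction across edges (a deliberate simplification of a trial-level
mixed model; the trial-level data remain exportable for external
refits).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .exceptions import BoundedSearchError


@dataclass(frozen=True)
class StatResult:
    """A statistic with its p-value and optional resampling metadata."""

    statistic: float
    p: float
    method: str
    ci: tuple | None = None
    n: int | None = None
    n_resamples: int | None = None
    seed: int | None = None
    degenerate: bool = False
    null_mean: float | None = None


def pearson_r_p(x, y, sided: str = "two") -> StatResult:
    """Pearson correlation with its exact-null p-value.

    ``sided="one"`` tests for positive correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        return StatResult(statistic=float("nan"), p=1.0,
                          method="pearson", n=x.size, degenerate=True)
    alternative = {"two": "two-sided", "one": "greater"}[sided]
    res = spstats.pearsonr(x, y, alternative=alternative)
    return StatResult(statistic=float(res.statistic),
                      p=float(max(res.pvalue, np.finfo(float).tiny)),
                      method="pearson", n=x.size)


def _r_pvalue(r: float, n: int, sided: str) -> float:
    df = n - 2
    denom = max(1.0 - r * r, 1e-300)
    t = r * np.sqrt(df / denom)
    p_one = spstats.t.sf(t, df)
    return float(p_one if sided == "one" else 2 * min(p_one, 1 - p_one))


def critical_r(n: int, alpha: float = 0.05, sided: str = "one") -> float:
    """Smallest correlation reaching significance at sample size ``n``."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    lo, hi = 1e-12, 1.0 - 1e-12
    if _r_pvalue(lo, n, sided) <= alpha:
        return 0.0
    return float(brentq(lambda r: _r_pvalue(r, n, sided) - alpha, lo, hi,
                        xtol=1e-9))


def min_n_for_r(r: float, alpha: float = 0.05, sided: str = "one",
                n_max: int = 100000) -> int:
    """Smallest sample size at which a correlation of ``r`` is significant."""
    if not 0 < r < 1:
        raise ValueError("r must lie in (0, 1)")
    for n in range(3, n_max + 1):
        if critical_r(n, alpha, sided) <= r + 1e-12:
            return n
    raise BoundedSearchError(
        f"r = {r} not significant for any n <= {n_max}")


def permutation_test(
    statistic_fn: Callable[[np.ndarray, np.ndarray], float],
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    observed: float | None = None,
) -> StatResult:
    """Permutation null of a cross-validated accuracy.

    ``statistic_fn(X, y)`` must re-run the full procedure (e.g. nested
    leave-one-out CV) and return its accuracy; each permutation shuffles
    the targets without replacement and re-runs it.  Add-one p-value.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if observed is None:
        observed = statistic_fn(X, y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = statistic_fn(X, rng.permutation(y))
    exceed = int(np.sum(null[~np.isnan(null)] >= observed))
    p = (1.0 + exceed) / (1.0 + n_perm)
    return StatResult(statistic=float(observed), p=float(p),
                      method="permutation", n=y.size, n_resamples=n_perm,
                      seed=seed, null_mean=float(np.nanmean(null)))


def bh_fdr(pvals: Sequence[float], alpha: float = 0.05):
    """Benjamini-Hochberg step-up FDR.

    Returns (reject_mask, adjusted_p).
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1 or pvals.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def bootstrap_corr_diff(y, yhat_a, yhat_b, n_boot: int = 2000,
                        seed: int = 0) -> StatResult:
    """Bootstrap comparison of two predictors of the same outcome.

    Resamples units with replacement, computes
    r(y, yhat_a) - r(y, yhat_b) per resample, and reports the percentile
    95% CI and the two-sided CI-inversion p-value.  Degenerate resamples
    (zero variance) are skipped and counted.
    """
    y = np.asarray(y, float)
    a = np.asarray(yhat_a, float)
    b = np.asarray(yhat_b, float)
    n = y.size
    if a.size != n or b.size != n or n < 3:
        raise ValueError("need >= 3 aligned observations")
    rng = np.random.default_rng(seed)
    diffs = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ys, as_, bs = y[idx], a[idx], b[idx]
        if ys.std() == 0 or as_.std() == 0 or bs.std() == 0:
            skipped += 1
            continue
        diffs.append(np.corrcoef(ys, as_)[0, 1] - np.corrcoef(ys, bs)[0, 1])
    diffs = np.asarray(diffs)
    if diffs.size == 0:
        return StatResult(statistic=float("nan"), p=1.0,
                          method="bootstrap_corr_diff", n=n,
                          n_resamples=n_boot, seed=seed, degenerate=True)
    ci = (float(np.percentile(diffs, 2.5)), float(np.percentile(diffs, 97.5)))
    m = diffs.size
    p_lo = (1 + np.sum(diffs <= 0)) / (1 + m)
    p_hi = (1 + np.sum(diffs >= 0)) / (1 + m)
    p = float(min(1.0, 2 * min(p_lo, p_hi)))
    point = float(np.corrcoef(y, a)[0, 1] - np.corrcoef(y, b)[0, 1])
    return StatResult(statistic=point, p=p, ci=ci,
                      method="bootstrap_corr_diff", n=n, n_resamples=n_boot,
                      seed=seed, null_mean=float(diffs.mean()))


def linear_trend_r2(x, y) -> StatResult:
    """r^2 and p of the simple linear regression of y on x."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 points")
    if y.std() == 0:
        return StatResult(statistic=0.0, p=1.0, method="linear_trend",
                          n=x.size, degenerate=True)
    res = spstats.linregress(x, y)
    return StatResult(statistic=float(res.rvalue ** 2),
                      p=float(res.pvalue), method="linear_trend", n=x.size)


def paired_edge_test(fc_a: np.ndarray, fc_b: np.ndarray,
                     edges: Sequence[tuple] | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-edge paired t test between two conditions with BH-FDR.

    ``fc_a`` and ``fc_b`` are (participants, edges) arrays of matched
    participant-level connectivity (e.g. pre-task vs intrinsic rest).
    Returns a DataFrame with t, p, p_fdr, significant per edge.
    """
    A = np.asarray(fc_a, float)
    B = np.asarray(fc_b, float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("conditions must be matched (participants, edges)")
    if A.shape[0] < 3:
        raise ValueError("need >= 3 participants")
    t, p = spstats.ttest_rel(A, B, axis=0)
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(np.isnan(t), 0.0, t)
    reject, p_adj = bh_fdr(p, alpha=alpha)
    labels = ([f"{a}--{b}" for a, b in edges] if edges is not None
              else [f"edge{i}" for i in range(A.shape[1])])
    return pd.DataFrame({
        "edge": labels,
        "mean_diff": (A - B).mean(axis=0),
        "t": t,
        "p": p,
        "p_fdr": p_adj,
        "significant": reject,
    })
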