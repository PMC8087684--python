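"""Two-group differential abundance testing.

Implements the empirical-Bayes moderated t-statistic (variance shrinkage
toward a prior estimated across features, Smyth-style), Benjamini-Hochberg
FDR adjustment, Mann-Whitney U testing and robust group-median differences.
Missing values are handled complete-case per feature; no imputation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import CohortDesign, ExpressionMatrix

logger = logging.getLogger(__name__)


class DifferentialError(ValueError):
    pass


@dataclass
class DifferentialResult:
    """Per-feature two-group statistics plus the shared shrinkage prior.

    ``table`` columns: log2FC (A - B), mean, s2, df, t, p, q, median_A,
    median_B, median_diff, mwu_U, mwu_p, n_A, n_B.  ``d0`` and ``s0_sq`` are
    the prior degrees of freedom and prior variance shared by all features
    (``d0`` may be ``inf`` when the residual variances show no excess spread).
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    cohort_a: str
    cohort_b: str


def log_transform_tpm(tpm: pd.DataFrame | ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform of a nonnegative transcript abundance matrix."""
    df = tpm.data if isinstance(tpm, ExpressionMatrix) else tpm
    values = df.to_numpy(dtype=float)
    if np.nanmin(values) < 0:
        raise DifferentialError("TPM values must be nonnegative")
    return ExpressionMatrix(pd.DataFrame(np.log2(values + 1.0), index=df.index, columns=df.columns), "transcript")


def _group_arrays(matrix: ExpressionMatrix, design: CohortDesign, cohorts=None):
    a, b = cohorts if cohorts is not None else design.cohort_pair()
    cols_a = [s for s in design.samples_in(a) if s in matrix.data.columns]
    cols_b = [s for s in design.samples_in(b) if s in matrix.data.columns]
    if len(cols_a) < 1 or len(cols_b) < 1:
        raise DifferentialError(f"cohorts {a!r}/{b!r} have no samples in the matrix")
    return a, b, matrix.data[cols_a].to_numpy(float), matrix.data[cols_b].to_numpy(float)


def fit_two_group(matrix: ExpressionMatrix, design: CohortDesign, cohorts=None) -> pd.DataFrame:
    """Per-feature log2FC, pooled residual variance and residual df.

    Complete-case per feature: means/variances use the available values in
    each group; features with fewer than 2 non-missing values in either
    group are dropped (logged).  Residual df = nA + nB - 2.
    """
    a, b, xa, xb = _group_arrays(matrix, design, cohorts)
    if np.isnan(xa).all() or np.isnan(xb).all():
        raise DifferentialError("one group is entirely missing for all features")
    na = np.sum(~np.isnan(xa), axis=1)
    nb = np.sum(~np.isnan(xb), axis=1)
    keep = (na >= 2) & (nb >= 2)
    if (~keep).any():
        logger.info("dropping %d features with < 2 observed values in a group", int((~keep).sum()))
    xa, xb, na, nb = xa[keep], xb[keep], na[keep], nb[keep]
    mean_a = np.nanmean(xa, axis=1)
    mean_b = np.nanmean(xb, axis=1)
    ss_a = np.nansum((xa - mean_a[:, None]) ** 2, axis=1)
    ss_b = np.nansum((xb - mean_b[:, None]) ** 2, axis=1)
    df = na + nb - 2
    s2 = (ss_a + ss_b) / df
    return pd.DataFrame(
        {
            "log2FC": mean_a - mean_b,
            "mean": (np.nansum(xa, axis=1) + np.nansum(xb, axis=1)) / (na + nb),
            "s2": s2,
            "df": df.astype(float),
            "n_A": na,
            "n_B": nb,
            "stdev_unscaled": np.sqrt(1.0 / na + 1.0 / nb),
        },
        index=matrix.data.index[keep],
    )


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif / y) < 1e-10:
            break
    return y


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior on residual variances.

    Matches digamma/trigamma moments of log s2 given per-feature residual df,
    returning (d0, s0_sq).  d0 = inf when the observed spread of log s2 does
    not exceed what the chi-square sampling noise alone explains.
    """
    ok = (df > 0) & np.isfinite(s2) & (s2 > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        raise DifferentialError("need >= 2 positive residual variances to estimate the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0_sq = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return d0, s0_sq


def ebayes_moderate(fits: pd.DataFrame, d0: float | None = None, s0_sq: float | None = None) -> pd.DataFrame:
    """Moderated t-statistics from per-feature fits.

    Shrinks each residual variance toward the prior:
    posterior s2 = (d0 * s0_sq + d * s2) / (d0 + d); t = log2FC /
    (sqrt(posterior s2) * stdev_unscaled); two-sided p on d0 + d df.
    Hyperparameters are estimated unless supplied (``d0 = 0`` recovers the
    ordinary per-feature t-test).
    """
    s2 = fits["s2"].to_numpy(float)
    df = fits["df"].to_numpy(float)
    if len(fits) >= 1 and np.all(s2 == 0):
        raise DifferentialError("degenerate variance ensemble: all residual variances are zero")
    if d0 is None or s0_sq is None:
        if int(np.sum(s2 > 0)) < 10:
            raise DifferentialError("need >= 10 features with positive residual variance to estimate the prior")
        d0, s0_sq = estimate_variance_prior(s2, df)
    if math.isinf(d0):
        post_var = np.full_like(s2, s0_sq)
        total_df = np.full_like(df, np.inf)
    else:
        post_var = (d0 * s0_sq + df * s2) / (d0 + df)
        total_df = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits["log2FC"].to_numpy(float) / (np.sqrt(post_var) * fits["stdev_unscaled"].to_numpy(float))
    p = 2.0 * stats.t.sf(np.abs(t), total_df)
    out = fits.copy()
    out["posterior_s2"] = post_var
    out["t"] = t
    out["p"] = p
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise DifferentialError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def mwu_test(x, y) -> tuple[float, float]:
    """Mann-Whitney U with exact p for small untied samples.

    Exact (permutation) two-sided p when nA + nB <= 12 and the pooled sample
    has no ties; otherwise the normal approximation with tie and continuity
    corrections.  Returns (U for x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DifferentialError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size + y.size <= 12 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def group_median_difference(matrix: ExpressionMatrix, design: CohortDesign, cohorts=None) -> pd.Series:
    """Per-feature median(A) - median(B) on the log2 scale (complete-case)."""
    a, b, xa, xb = _group_arrays(matrix, design, cohorts)
    na = np.sum(~np.isnan(xa), axis=1)
    nb = np.sum(~np.isnan(xb), axis=1)
    keep = (na >= 1) & (nb >= 1)
    if (~keep).any():
        logger.info("dropping %d features with an empty group", int((~keep).sum()))
    with np.errstate(all="ignore"):
        diff = np.nanmedian(xa[keep], axis=1) - np.nanmedian(xb[keep], axis=1)
    return pd.Series(diff, index=matrix.data.index[keep], name="median_diff")


def differential_analysis(matrix: ExpressionMatrix, design: CohortDesign, cohorts=None) -> DifferentialResult:
    """Full two-group analysis: moderated t + BH q + medians + Mann-Whitney U."""
    a, b = cohorts if cohorts is not None else design.cohort_pair()
    fits = fit_two_group(matrix, design, (a, b))
    mod = ebayes_moderate(fits)
    mod["q"] = bh_adjust(mod["p"].to_numpy())

    data = matrix.data.loc[mod.index]
    cols_a = [s for s in design.samples_in(a) if s in data.columns]
    cols_b = [s for s in design.samples_in(b) if s in data.columns]
    med_a = data[cols_a].median(axis=1)
    med_b = data[cols_b].median(axis=1)
    mod["median_A"] = med_a
    mod["median_B"] = med_b
    mod["median_diff"] = med_a - med_b
    u_stats, u_pvals = [], []
    for feature in mod.index:
        va = data.loc[feature, cols_a].dropna().to_numpy()
        vb = data.loc[feature, cols_b].dropna().to_numpy()
        u, p = mwu_test(va, vb)
        u_stats.append(u)
        u_pvals.append(p)
    mod["mwu_U"] = u_stats
    mod["mwu_p"] = u_pvals
    return DifferentialResult(table=mod, d0=mod.attrs["d0"], s0_sq=mod.attrs["s0_sq"], cohort_a=a, cohort_b=b)
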