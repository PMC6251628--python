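"""Differential methylation statistics.

Regions are compared between two conditions with a coverage-weighted Welch
t-test: within each condition the CpGs of the region (at >=5x) are the
sample, each weighted by its coverage.  The default variance estimate is
the weighted-least-squares one — s^2 = sum w_i (x_i - m)^2 / (n - 1) with
var(m) = s^2 / sum w — which treats the weights as inverse variances; for
binomial methylation fractions weighted by coverage this estimates the
variance of the weighted mean without bias, so the test stays calibrated
under varying coverage.  An effective-sample-size variant (Kish
n_eff = (sum w)^2 / sum w^2 in place of n) and a plain unweighted Welch
test are available for sensitivity analysis.  All variants reduce to the
ordinary Welch test when weights are equal.  Multiple testing is
controlled with Storey q-values (smoother pi0 estimate,
Benjamini-Hochberg fallback).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from statsmodels.stats.multitest import multipletests

from . import methylation as mc


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: float
    p_value: float
    status: str  # "ok" | "insufficient_data" | "degenerate"


def _group_moments(values: np.ndarray, weights: np.ndarray, variance: str):
    """Weighted mean, variance of that mean, and residual df of one group."""
    n = values.size
    if variance == "unweighted":
        weights = np.ones_like(values)
    wsum = weights.sum()
    mean = float(np.dot(weights, values) / wsum)
    resid2 = float(np.dot(weights, (values - mean) ** 2))
    if variance == "effective":
        n_eff = float(wsum**2 / np.dot(weights, weights))
        if n_eff <= 1.0:
            return mean, np.nan, 0.0
        var_mean = (resid2 / wsum) * n_eff / (n_eff - 1.0) / n_eff
        return mean, var_mean, n_eff - 1.0
    # WLS / unweighted: s^2 = sum w (x-m)^2 / (n-1), var(mean) = s^2 / sum w
    var_mean = resid2 / (n - 1.0) / wsum
    return mean, var_mean, n - 1.0


def weighted_t_test(values_a, weights_a, values_b, weights_b,
                    variance: str = "wls") -> TTestResult:
    """Two-sided coverage-weighted Welch t-test between two CpG samples.

    Each sample is the set of per-CpG methylation fractions of a region in
    one condition, weighted by read coverage.  ``variance`` selects the
    estimator: ``'wls'`` (default, inverse-variance reading of the
    weights), ``'effective'`` (Kish effective-sample-size formulation) or
    ``'unweighted'`` (plain Welch, ignoring weights).  With equal weights
    all three coincide exactly with the standard Welch test.
    """
    if variance not in ("wls", "effective", "unweighted"):
        raise ValueError("variance must be 'wls', 'effective' or "
                         "'unweighted'")
    va = np.asarray(values_a, float)
    wa = np.asarray(weights_a, float)
    vb = np.asarray(values_b, float)
    wb = np.asarray(weights_b, float)
    if va.size < 2 or vb.size < 2:
        return TTestResult(np.nan, np.nan, np.nan, "insufficient_data")
    if np.any(wa <= 0) or np.any(wb <= 0):
        raise ValueError("weights must be positive")
    ma, va_mean, dfa = _group_moments(va, wa, variance)
    mb, vb_mean, dfb = _group_moments(vb, wb, variance)
    if dfa <= 0.0 or dfb <= 0.0 or not np.isfinite(va_mean + vb_mean):
        return TTestResult(np.nan, np.nan, np.nan, "insufficient_data")
    se2 = va_mean + vb_mean
    if se2 == 0.0:
        # no within-group variability at all
        if ma == mb:
            return TTestResult(0.0, np.nan, 1.0, "ok")
        return TTestResult(np.inf if ma > mb else -np.inf, np.nan, 0.0,
                           "degenerate")
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / (va_mean**2 / dfa + vb_mean**2 / dfb)
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p), "ok")


# -- Storey q-values ---------------------------------------------------------

_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


def estimate_pi0(p_values: np.ndarray,
                 lambdas: np.ndarray = _LAMBDA_GRID) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is evaluated on the
    lambda grid and smoothed with a cubic spline; the estimate is the
    smoothed value at the largest lambda, clipped to (0, 1].  Falls back to
    pi0 = 1 (plain Benjamini-Hochberg) when m < 100 or the estimate is
    unstable.
    """
    p = np.asarray(p_values, float)
    m = p.size
    if m < 100:
        return 1.0
    pi0_lambda = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    if np.all(pi0_lambda == 0):
        return 1.0
    try:
        spline = interpolate.UnivariateSpline(lambdas, pi0_lambda, k=3)
        pi0 = float(spline(lambdas[-1]))
    except Exception:
        pi0 = float(pi0_lambda[-1])
    if not np.isfinite(pi0) or pi0 > 1.0 or pi0 <= 0.0:
        return 1.0
    return pi0


def q_values(p_values, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: pi0 times the Benjamini-Hochberg adjusted p-values.

    ``pi0=None`` estimates the null proportion with :func:`estimate_pi0`;
    ``pi0=1`` gives plain BH.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")
    bh = multipletests(p, method="fdr_bh")[1]
    return np.minimum(pi0 * bh, 1.0)


# -- region-level DMR calling ------------------------------------------------

def call_dmrs(
    cpgs_a: pd.DataFrame,
    cpgs_b: pd.DataFrame,
    regions: pd.DataFrame,
    min_cov: int = mc.MIN_COVERAGE,
    min_cpgs: int = mc.MIN_CPGS,
    q_thresh: float = 0.05,
    diff_thresh: float = 0.2,
    direction: str = "two-sided",
    variance: str = "wls",
) -> pd.DataFrame:
    """Test every region for differential methylation between conditions.

    Per region the CpGs at >= ``min_cov`` in each condition feed the
    weighted t-test; regions with fewer than ``min_cpgs`` qualifying CpGs in
    either condition are reported with status ``insufficient_data`` and are
    excluded from the multiple-testing correction.  A region is a DMR when
    q < ``q_thresh`` and the methylation difference (condition B minus A)
    passes ``diff_thresh`` — absolute difference for ``direction=
    'two-sided'``, signed gain for ``direction='gain'``.
    """
    if direction not in ("two-sided", "gain"):
        raise ValueError("direction must be 'two-sided' or 'gain'")
    records = []
    for r in regions.itertuples(index=False):
        sel_a = mc._select_cpgs(cpgs_a, r.chrom, int(r.start), int(r.end),
                                min_cov)
        sel_b = mc._select_cpgs(cpgs_b, r.chrom, int(r.start), int(r.end),
                                min_cov)
        rec = {"chrom": r.chrom, "start": int(r.start), "end": int(r.end),
               "n_a": len(sel_a), "n_b": len(sel_b)}
        if len(sel_a) < min_cpgs or len(sel_b) < min_cpgs:
            rec.update(mean_a=np.nan, mean_b=np.nan, diff=np.nan,
                       t_stat=np.nan, df=np.nan, p_value=np.nan,
                       status="insufficient_data")
        else:
            res = weighted_t_test(
                sel_a["methylation"].to_numpy(),
                sel_a["total_count"].to_numpy(),
                sel_b["methylation"].to_numpy(),
                sel_b["total_count"].to_numpy(),
                variance=variance,
            )
            mean_a = float(np.average(sel_a["methylation"],
                                      weights=sel_a["total_count"]))
            mean_b = float(np.average(sel_b["methylation"],
                                      weights=sel_b["total_count"]))
            rec.update(mean_a=mean_a, mean_b=mean_b, diff=mean_b - mean_a,
                       t_stat=res.t_stat, df=res.df, p_value=res.p_value,
                       status=res.status)
        records.append(rec)
    out = pd.DataFrame(records)
    testable = out["status"].isin(("ok", "degenerate"))
    out["q_value"] = np.nan
    if testable.any():
        out.loc[testable, "q_value"] = q_values(
            out.loc[testable, "p_value"].to_numpy())
    else:
        warnings.warn("no testable regions", stacklevel=2)
    if direction == "two-sided":
        passes_diff = out["diff"].abs() >= diff_thresh
    else:
        passes_diff = out["diff"] >= diff_thresh
    out["is_dmr"] = testable & (out["q_value"] < q_thresh) & passes_diff
    return out


def hypergeometric_overlap(universe: int, set_a: int, set_b: int,
                           overlap: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= overlap) for a set overlap.

    X counts the intersection of a random ``set_a``-subset with a fixed
    ``set_b``-subset of a ``universe``-element universe.
    """
    if not 0 <= overlap <= min(set_a, set_b):
        raise ValueError("overlap must lie in [0, min(set_a, set_b)]")
    if max(set_a, set_b) > universe:
        raise ValueError("set sizes cannot exceed the universe")
    return float(stats.hypergeom.sf(overlap - 1, universe, set_a, set_b))


def stratify_by_expression(
    dmr_genes,
    expression: pd.Series,
    bins=5,
) -> pd.DataFrame:
    """Count DMR promoters per expression class.

    ``dmr_genes`` is the set of gene ids whose promoter is a DMR;
    ``expression`` maps gene id -> normalized expression.  ``bins`` is an
    integer (quantile bins) or explicit bin edges.  Genes without an
    expression value are excluded (their count is returned in the
    ``n_missing`` attribute of the result).
    """
    dmr_genes = set(dmr_genes)
    expr = pd.Series(expression).dropna()
    n_missing = len(dmr_genes - set(expr.index))
    if isinstance(bins, int):
        binned = pd.qcut(expr, q=bins, duplicates="drop")
    else:
        binned = pd.cut(expr, bins=bins, include_lowest=True)
    df = pd.DataFrame({"bin": binned,
                       "is_dmr": expr.index.isin(dmr_genes)})
    out = (
        df.groupby("bin", observed=False)["is_dmr"]
        .agg(n_genes="size", n_dmr="sum")
        .reset_index()
    )
    out["fraction_dmr"] = np.where(out["n_genes"] > 0,
                                   out["n_dmr"] / out["n_genes"], np.nan)
    out.attrs["n_missing"] = n_missing
    return out
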