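"""Per-CpG methylation calls and coverage-aware feature/tile quantification.

The atomic observation is a CpG with a methylated-read count and a total
read count; its methylation level is the ratio of the two and its weight in
every downstream statistic is its coverage.  Feature-level methylation is
the coverage-weighted *median* over the CpGs inside the feature; fixed-size
genomic tiles use the coverage-weighted *mean*.  Both require at least
``min_cpgs`` CpGs covered at ``min_cov`` or better, otherwise the feature
is reported as ``insufficient_data`` rather than given a value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: column order of the on-disk CpG coverage table (bedGraph-coverage dialect)
CPG_COLUMNS = ["chrom", "start", "end", "meth_count", "unmeth_count"]

#: defaults of the coverage rule: >=2 CpGs covered at >=5x per feature
MIN_COVERAGE = 5
MIN_CPGS = 2


@dataclass(frozen=True)
class FeatureMethylation:
    """Methylation summary of one genomic feature."""

    chrom: str
    start: int
    end: int
    n_cpgs_used: int
    value: float  # NaN when status != "called"
    total_weight: float
    status: str  # "called" | "insufficient_data"


def read_cpg_table(path) -> pd.DataFrame:
    """Load a per-CpG coverage table (chrom, start, end, meth, unmeth).

    Returns a DataFrame with the five input columns plus derived
    ``total_count`` and ``methylation``.  Rows with zero total coverage are
    dropped with a warning; malformed rows raise ``ValueError`` naming the
    offending line.
    """
    raw = pd.read_csv(
        path, sep="\t", header=None, names=CPG_COLUMNS, dtype=str, comment="#"
    )
    if raw.empty:
        warnings.warn(f"empty CpG table: {path}", stacklevel=2)
        return _with_derived(pd.DataFrame(columns=CPG_COLUMNS))
    df = raw.copy()
    for col in ("start", "end", "meth_count", "unmeth_count"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(
                f"malformed value in column '{col}' at line {line} of {path}"
            )
        df[col] = converted.astype(np.int64)
    if ((df["meth_count"] < 0) | (df["unmeth_count"] < 0)).any():
        bad = ((df["meth_count"] < 0) | (df["unmeth_count"] < 0)).idxmax()
        raise ValueError(f"negative count at line {int(bad) + 1} of {path}")
    total = df["meth_count"] + df["unmeth_count"]
    if (total == 0).any():
        n_zero = int((total == 0).sum())
        warnings.warn(
            f"dropped {n_zero} CpG(s) with zero coverage from {path}",
            stacklevel=2,
        )
        df = df.loc[total > 0].reset_index(drop=True)
    return _with_derived(df)


def _with_derived(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    total = (
        df["meth_count"].astype(float) + df["unmeth_count"].astype(float)
        if len(df)
        else pd.Series(dtype=float)
    )
    df["total_count"] = total.astype(np.int64) if len(df) else total
    df["methylation"] = (
        df["meth_count"] / total if len(df) else pd.Series(dtype=float)
    )
    return df


def write_cpg_table(df: pd.DataFrame, path) -> None:
    df[CPG_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def weighted_median(values, weights) -> float:
    """Coverage-weighted median under the lower-median convention.

    Returns the smallest value whose cumulative weight (after sorting by
    value) reaches half the total weight.  For integer weights this equals
    the ordinary lower median of the weight-expanded sample.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("weighted_median of empty input")
    if values.shape != weights.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
        raise ValueError("weights must be positive and finite")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, 0.5 * cum[-1], side="left"))
    return float(values[order][idx])


def _select_cpgs(cpgs: pd.DataFrame, chrom: str, start: int, end: int,
                 min_cov: int) -> pd.DataFrame:
    mask = (
        (cpgs["chrom"] == chrom)
        & (cpgs["start"] >= start)
        & (cpgs["start"] < end)
        & (cpgs["total_count"] >= min_cov)
    )
    return cpgs.loc[mask]


def feature_methylation(
    cpgs: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    min_cov: int = MIN_COVERAGE,
    min_cpgs: int = MIN_CPGS,
) -> FeatureMethylation:
    """Weighted-median methylation of one interval under the coverage rule."""
    sel = _select_cpgs(cpgs, chrom, start, end, min_cov)
    if len(sel) < min_cpgs:
        return FeatureMethylation(chrom, start, end, len(sel), float("nan"),
                                  float(sel["total_count"].sum()),
                                  "insufficient_data")
    value = weighted_median(sel["methylation"].to_numpy(),
                            sel["total_count"].to_numpy())
    return FeatureMethylation(chrom, start, end, len(sel), value,
                              float(sel["total_count"].sum()), "called")


def features_methylation(
    cpgs: pd.DataFrame,
    features: pd.DataFrame,
    min_cov: int = MIN_COVERAGE,
    min_cpgs: int = MIN_CPGS,
) -> pd.DataFrame:
    """Vector version of :func:`feature_methylation` over a feature table.

    ``features`` needs columns chrom/start/end; the result carries one row
    per feature with n_cpgs_used, value, total_weight and status.
    """
    rows = [
        feature_methylation(cpgs, r.chrom, int(r.start), int(r.end),
                            min_cov, min_cpgs)
        for r in features.itertuples(index=False)
    ]
    return pd.DataFrame([vars(r) for r in rows])


def tile_methylation(
    cpgs: pd.DataFrame,
    tile_size: int = 100,
    min_cov: int = MIN_COVERAGE,
    min_cpgs: int = MIN_CPGS,
) -> pd.DataFrame:
    """Coverage-weighted *mean* methylation of fixed tiles from position 0.

    Tiles are non-overlapping ``tile_size``-bp bins anchored at coordinate 0
    of each chromosome; only CpGs at >= ``min_cov`` contribute and tiles with
    fewer than ``min_cpgs`` such CpGs are not called.
    """
    ok = cpgs.loc[cpgs["total_count"] >= min_cov].copy()
    if ok.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_cpgs", "value"])
    ok["tile"] = (ok["start"] // tile_size).astype(np.int64)
    grouped = ok.groupby(["chrom", "tile"], sort=True)
    agg = grouped.apply(
        lambda g: pd.Series({
            "n_cpgs": len(g),
            "value": float(np.average(g["methylation"],
                                      weights=g["total_count"])),
        }),
        include_groups=False,
    ).reset_index()
    agg = agg.loc[agg["n_cpgs"] >= min_cpgs].copy()
    agg["start"] = agg["tile"] * tile_size
    agg["end"] = agg["start"] + tile_size
    agg["n_cpgs"] = agg["n_cpgs"].astype(int)
    return agg[["chrom", "start", "end", "n_cpgs", "value"]].reset_index(
        drop=True)


def tile_methylation_delta(
    cpgs_control: pd.DataFrame,
    cpgs_treated: pd.DataFrame,
    tile_size: int = 100,
    min_cov: int = MIN_COVERAGE,
    min_cpgs: int = MIN_CPGS,
) -> pd.DataFrame:
    """Per-tile mean methylation in two conditions plus their difference.

    Only tiles callable in both conditions are reported;
    ``delta = treated - control``.
    """
    a = tile_methylation(cpgs_control, tile_size, min_cov, min_cpgs)
    b = tile_methylation(cpgs_treated, tile_size, min_cov, min_cpgs)
    merged = a.merge(b, on=["chrom", "start", "end"],
                     suffixes=("_control", "_treated"))
    merged["delta"] = merged["value_treated"] - merged["value_control"]
    return merged
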