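"""ChIP window counting, Poisson enrichment and chromatin-state classes.

Read counts are taken in fixed windows centred on each anchor (1 kb for
H3K4me3, 5 kb for H3K27me3 around CGI midpoints), normalised to RPKM, and
tested for enrichment against a Poisson fit to the global count
distribution: lambda is the mean window count (the MLE) and the p-value of
a window with k reads is P(X >= k).  CGIs are then classified four ways
from the H3K4me3/H3K27me3 enriched flags (q < 0.05): active-only,
Polycomb-only, bivalent, or neither.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import q_values

K4_WINDOW = 1000
K27_WINDOW = 5000

STATES = ("H3K4me3_only", "H3K27me3_only", "bivalent", "neither")


def count_reads_in_windows(
    read_positions: pd.DataFrame,
    anchors: pd.DataFrame,
    width: int,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Count read 5' positions falling in a window centred on each anchor.

    ``read_positions`` needs columns chrom and pos (the 5' coordinate);
    ``anchors`` needs chrom, start, end.  The window is ``width`` bp centred
    on the anchor midpoint, half-open, clipped at chromosome edges when
    lengths are given.
    """
    pos_by_chrom = {
        c: np.sort(g["pos"].to_numpy(dtype=np.int64))
        for c, g in read_positions.groupby("chrom")
    }
    records = []
    for r in anchors.itertuples(index=False):
        mid = (int(r.start) + int(r.end)) // 2
        ws = mid - width // 2
        we = ws + width
        if chrom_lengths is not None:
            clen = int(chrom_lengths[r.chrom])
            ws, we = max(0, ws), min(clen, we)
        pos = pos_by_chrom.get(r.chrom)
        if pos is None:
            count = 0
        else:
            count = int(np.searchsorted(pos, we, side="left")
                        - np.searchsorted(pos, ws, side="left"))
        records.append({"chrom": r.chrom, "anchor_start": int(r.start),
                        "anchor_end": int(r.end), "window_start": ws,
                        "window_end": we, "count": count})
    return pd.DataFrame(records)


def rpkm(count, region_length_bp, total_mapped_reads):
    """Reads per kilobase of region per million mapped reads."""
    length = np.asarray(region_length_bp, float)
    total = float(total_mapped_reads)
    if np.any(length <= 0) or total <= 0:
        raise ValueError("region length and total mapped reads must be > 0")
    return np.asarray(count, float) / (length / 1e3) / (total / 1e6)


@dataclass(frozen=True)
class PoissonEnrichment:
    lambda_hat: float
    p_values: np.ndarray
    q_values: np.ndarray
    enriched: np.ndarray


def poisson_enrichment(
    counts,
    q_thresh: float = 0.05,
    lambda_method: str = "mean",
    trim: float = 0.05,
    randomized: bool = False,
    rng: np.random.Generator | None = None,
) -> PoissonEnrichment:
    """Fit a Poisson to the window counts and flag enriched windows.

    ``lambda_method='mean'`` is the plain Poisson MLE over all windows (the
    default); ``'trimmed'`` uses a two-sided trimmed mean, robust to the
    enriched subpopulation inflating the background rate.  p(k) = P(X >= k)
    under Poisson(lambda_hat); q-values via the Storey procedure; enriched
    iff q < ``q_thresh``.

    ``randomized=True`` replaces the (conservative, discrete) survival
    p-values with randomized p-values P(X > k) + U*P(X = k), which are
    exactly Uniform(0,1) under the fitted model — useful for calibration
    audits, not for calling enrichment.
    """
    k = np.asarray(counts, dtype=np.int64)
    if k.size == 0:
        return PoissonEnrichment(0.0, np.array([]), np.array([]),
                                 np.array([], dtype=bool))
    if np.any(k < 0):
        raise ValueError("counts must be non-negative")
    if k.size < 2:
        raise ValueError("need at least two windows to fit the background")
    if lambda_method == "mean":
        lam = float(k.mean())
    elif lambda_method == "trimmed":
        lam = float(stats.trim_mean(k, trim))
    else:
        raise ValueError("lambda_method must be 'mean' or 'trimmed'")
    if lam == 0.0:
        p = np.where(k == 0, 1.0, 0.0)
    else:
        p = stats.poisson.sf(k - 1, lam)  # P(X >= k)
    if randomized:
        if rng is None:
            rng = np.random.default_rng()
        p = stats.poisson.sf(k, lam) + rng.random(k.size) * \
            stats.poisson.pmf(k, lam)
    q = q_values(p)
    return PoissonEnrichment(lam, p, q, q < q_thresh)


def classify_cgi_states(k4_enriched, k27_enriched) -> np.ndarray:
    """Four-way chromatin state from the two marks' enriched flags."""
    k4 = np.asarray(k4_enriched, dtype=bool)
    k27 = np.asarray(k27_enriched, dtype=bool)
    if k4.shape != k27.shape:
        raise ValueError("anchor sets of the two marks do not match")
    out = np.where(
        k4 & k27, "bivalent",
        np.where(k4, "H3K4me3_only",
                 np.where(k27, "H3K27me3_only", "neither")))
    return out.astype(object)


def composite_profile(
    positions: pd.DataFrame,
    anchors: pd.DataFrame,
    flank: int = 5000,
    bin_size: int = 100,
    weights: str | None = None,
) -> pd.DataFrame:
    """Strand-oriented mean signal around a set of anchors (TSS metaplot).

    ``positions`` has columns chrom and pos, optionally a signal column
    named by ``weights`` (e.g. per-CpG methylation; omitted -> read
    density).  ``anchors`` has chrom, pos (the TSS) and strand; minus-strand
    anchors are reflected so that negative bins are upstream.  Returns one
    row per bin with the mean per-anchor signal: mean read count per bin for
    densities, or the weighted mean of the signal column.
    """
    anchors = anchors.copy()
    if "strand" not in anchors.columns:
        anchors["strand"] = "+"
    if (anchors["strand"] == ".").any():
        warnings.warn("anchors without strand treated as '+'", stacklevel=2)
        anchors.loc[anchors["strand"] == ".", "strand"] = "+"
    n_bins = 2 * flank // bin_size
    edges = np.arange(-flank, flank + bin_size, bin_size)
    sums = np.zeros(n_bins)
    wsums = np.zeros(n_bins)
    n_anchors = 0
    pos_by_chrom = {c: g for c, g in positions.groupby("chrom")}
    for a in anchors.itertuples(index=False):
        g = pos_by_chrom.get(a.chrom)
        n_anchors += 1
        if g is None:
            continue
        rel = g["pos"].to_numpy(dtype=np.int64) - int(a.pos)
        if a.strand == "-":
            rel = -rel - 1  # reflect; keep half-open orientation
        inside = (rel >= -flank) & (rel < flank)
        rel = rel[inside]
        which = (rel + flank) // bin_size
        if weights is None:
            np.add.at(sums, which, 1.0)
        else:
            w = g[weights].to_numpy(dtype=float)[inside]
            np.add.at(sums, which, w)
            np.add.at(wsums, which, 1.0)
    if n_anchors == 0:
        raise ValueError("no anchors")
    if weights is None:
        value = sums / n_anchors
    else:
        with np.errstate(invalid="ignore"):
            value = np.where(wsums > 0, sums / wsums, np.nan)
    return pd.DataFrame({
        "bin_start": edges[:-1],
        "bin_end": edges[1:],
        "value": value,
    })
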