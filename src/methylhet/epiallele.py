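"""Read-level methylation heterogeneity at deep amplicon loci.

Each sequenced molecule contributes a pattern of methylated (M) /
unmethylated (U) states over the ordered CpGs of the locus.  Epialleles
are the distinct complete patterns observed in the population; they are
counted overall and stratified by the number of methylated CpGs per
molecule.  Two complementary statistics quantify within-molecule
heterogeneity: the proportion of discordant reads (reads mixing M and U
states) and the pairwise in-phase correlation of CpG states across reads
as a function of genomic distance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_CHAR = "."
_STATE_CODE = {"U": 0, "M": 1, MISSING_CHAR: 2}


@dataclass(frozen=True)
class AmpliconLocus:
    """An amplicon target: an interval plus the positions of its CpGs."""

    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]

    def __post_init__(self):
        pos = np.asarray(self.cpg_positions)
        if pos.size == 0 or np.any(np.diff(pos) <= 0):
            raise ValueError("cpg_positions must be strictly increasing")
        if pos[0] < self.start or pos[-1] >= self.end:
            raise ValueError("cpg_positions must lie inside the interval")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


@dataclass
class EpialleleSummary:
    total_epialleles: int
    per_k_epialleles: dict = field(default_factory=dict)
    per_read_meth: np.ndarray = field(default_factory=lambda: np.array([]))
    per_site_meth: np.ndarray = field(default_factory=lambda: np.array([]))
    n_reads: int = 0


def patterns_to_matrix(patterns) -> np.ndarray:
    """Encode M/U/missing pattern strings as a uint8 matrix (1/0/2)."""
    if len(patterns) == 0:
        return np.zeros((0, 0), dtype=np.uint8)
    lengths = {len(p) for p in patterns}
    if len(lengths) != 1:
        raise ValueError("patterns have unequal lengths")
    table = np.full(256, 255, dtype=np.uint8)
    for ch, code in _STATE_CODE.items():
        table[ord(ch)] = code
    mat = table[
        np.frombuffer("".join(patterns).encode("ascii"), dtype=np.uint8)
    ].reshape(len(patterns), lengths.pop())
    if np.any(mat == 255):
        raise ValueError(f"patterns may only contain M, U or '{MISSING_CHAR}'")
    return mat


def extract_patterns(
    reads: pd.DataFrame,
    locus: AmpliconLocus | None = None,
    require_complete: bool = True,
) -> tuple[pd.DataFrame, int]:
    """Validate read patterns against a locus and apply the complete-read rule.

    ``reads`` has columns read_id and pattern (strings over M/U/'.').
    Returns the retained reads plus the number dropped for missing CpGs.
    Reads covering no locus CpG at all are rejected outright.
    """
    reads = reads.copy()
    if locus is not None:
        bad_len = reads["pattern"].str.len() != locus.n_cpgs
        if bad_len.any():
            raise ValueError(
                f"{int(bad_len.sum())} read(s) do not map onto the "
                f"{locus.n_cpgs} locus CpGs")
    covered = reads["pattern"].str.count("[MU]")
    n_uncovered = int((covered == 0).sum())
    if n_uncovered:
        raise ValueError(f"{n_uncovered} read(s) cover no locus CpG")
    n_dropped = 0
    if require_complete:
        complete = ~reads["pattern"].str.contains(MISSING_CHAR, regex=False)
        n_dropped = int((~complete).sum())
        reads = reads.loc[complete]
    return reads.reset_index(drop=True), n_dropped


def count_epialleles(patterns) -> EpialleleSummary:
    """Distinct-pattern counts, overall and per methylated-CpG count.

    ``patterns`` is a sequence of complete M/U strings (or a DataFrame with
    a ``pattern`` column).  ``per_k_epialleles[k]`` is the number of
    distinct patterns with exactly k methylated CpGs; the per-read
    methylation fractions and the per-site methylated fraction are
    returned alongside.
    """
    if isinstance(patterns, pd.DataFrame):
        patterns = patterns["pattern"].tolist()
    patterns = list(patterns)
    if not patterns:
        return EpialleleSummary(0)
    mat = patterns_to_matrix(patterns)
    if np.any(mat == 2):
        raise ValueError("epiallele counting requires complete patterns")
    distinct = set(patterns)
    per_k = Counter(p.count("M") for p in distinct)
    n_meth = mat.sum(axis=1)
    return EpialleleSummary(
        total_epialleles=len(distinct),
        per_k_epialleles=dict(sorted(per_k.items())),
        per_read_meth=n_meth / mat.shape[1],
        per_site_meth=mat.mean(axis=0),
        n_reads=mat.shape[0],
    )


def per_read_discordance(patterns, min_covered: int = 4):
    """Proportion of reads whose covered CpGs mix M and U states.

    A read is concordant when every covered CpG has the same state; only
    reads with at least ``min_covered`` covered CpGs are eligible.  Returns
    ``(proportion, n_eligible)``; the proportion is NaN when no read is
    eligible.
    """
    if isinstance(patterns, pd.DataFrame):
        patterns = patterns["pattern"].tolist()
    mat = patterns_to_matrix(list(patterns))
    if mat.size == 0:
        return float("nan"), 0
    covered = mat != 2
    n_cov = covered.sum(axis=1)
    eligible = n_cov >= min_covered
    if not eligible.any():
        return float("nan"), 0
    n_meth = ((mat == 1) & covered).sum(axis=1)
    discordant = (n_meth[eligible] > 0) & (n_meth[eligible] < n_cov[eligible])
    return float(discordant.mean()), int(eligible.sum())


def phase_correlation(
    patterns,
    cpg_positions,
    bin_edges=None,
    bin_width: int = 25,
) -> pd.DataFrame:
    """Pairwise CpG-state correlation across reads, binned by distance.

    For every CpG pair the Pearson correlation (phi coefficient) of their
    binary states is computed over the reads covering both; pairs involving
    a zero-variance site are excluded and counted in the result's
    ``attrs['n_excluded_pairs']``.  Correlations are averaged within
    genomic-distance bins (default ``bin_width``-bp edges spanning the
    locus).
    """
    if isinstance(patterns, pd.DataFrame):
        patterns = patterns["pattern"].tolist()
    mat = patterns_to_matrix(list(patterns)).astype(float)
    mat[mat == 2] = np.nan
    pos = np.asarray(cpg_positions, dtype=np.int64)
    if mat.shape[1] != pos.size:
        raise ValueError("pattern length does not match cpg_positions")
    m = pos.size
    dists, rs = [], []
    n_excluded = 0
    if mat.shape[0] >= 2 and not np.isnan(mat).any():
        # complete patterns: one correlation matrix covers all pairs
        sd = mat.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(mat.T) if m > 1 else np.ones((1, 1))
        for i in range(m):
            for j in range(i + 1, m):
                if sd[i] == 0 or sd[j] == 0:
                    n_excluded += 1
                    continue
                dists.append(pos[j] - pos[i])
                rs.append(corr[i, j])
    else:
        for i in range(m):
            for j in range(i + 1, m):
                both = ~np.isnan(mat[:, i]) & ~np.isnan(mat[:, j])
                if both.sum() < 2:
                    n_excluded += 1
                    continue
                xi, xj = mat[both, i], mat[both, j]
                if xi.std() == 0 or xj.std() == 0:
                    n_excluded += 1
                    continue
                r = np.corrcoef(xi, xj)[0, 1]
                dists.append(pos[j] - pos[i])
                rs.append(r)
    if not dists:
        out = pd.DataFrame(columns=["bin_start", "bin_end", "mean_r",
                                    "n_pairs"])
        out.attrs["n_excluded_pairs"] = n_excluded
        return out
    dists = np.asarray(dists)
    rs = np.asarray(rs)
    if bin_edges is None:
        top = int(np.ceil(dists.max() / bin_width)) * bin_width
        bin_edges = np.arange(0, top + bin_width, bin_width)
    bin_edges = np.asarray(bin_edges)
    which = np.clip(np.digitize(dists, bin_edges) - 1, 0,
                    len(bin_edges) - 2)
    records = []
    for b in range(len(bin_edges) - 1):
        sel = which == b
        if not sel.any():
            continue
        records.append({"bin_start": int(bin_edges[b]),
                        "bin_end": int(bin_edges[b + 1]),
                        "mean_r": float(rs[sel].mean()),
                        "n_pairs": int(sel.sum())})
    out = pd.DataFrame(records)
    out.attrs["n_excluded_pairs"] = n_excluded
    return out
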