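"""CpG-island detection and CGI-relative annotation.

A CpG island (CGI) is a region with GC fraction > 0.5, length > 200 bp and
an observed/expected CpG ratio > 0.6, where obs/exp = n_CpG * L / (n_C *
n_G).  Detection slides a 200-bp window with 1-bp step, merges qualifying
windows and trims merged spans until the reported region itself satisfies
all three thresholds (boundary resolution is therefore one window size).
Shores are the 2-kb flanks of each island minus any neighbouring island;
promoters are TSS +/- 500 bp and are high-CpG (HCP) when they overlap a
CGI by at least one base, low-CpG (LCP) otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

GC_MIN = 0.5
OBS_EXP_MIN = 0.6
LENGTH_MIN = 200  # strict: islands must be longer than this
WINDOW = 200
PROMOTER_FLANK = 500
SHORE_WIDTH = 2000


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


def compute_obs_exp(sequence: str) -> tuple[float, float, int]:
    """GC fraction, observed/expected CpG ratio and CpG count of a sequence.

    obs/exp = n_CpG * L / (n_C * n_G); zero when the sequence lacks C or G.
    Ambiguity codes are permitted and count toward length only.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    L = len(seq)
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cpg = seq.count("CG")
    gc = (n_c + n_g) / L
    obs_exp = 0.0 if n_c == 0 or n_g == 0 else n_cpg * L / (n_c * n_g)
    return gc, obs_exp, n_cpg


def _base_arrays(seq: str):
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_cg = np.zeros(arr.size, dtype=bool)
    if arr.size > 1:
        is_cg[:-1] = is_c[:-1] & is_g[1:]
    return is_c, is_g, is_cg


def _window_stats(is_c, is_g, is_cg, window):
    """Per-start C, G and CpG counts of all length-`window` windows."""
    cs = np.concatenate([[0], np.cumsum(is_c)])
    gs = np.concatenate([[0], np.cumsum(is_g)])
    cgs = np.concatenate([[0], np.cumsum(is_cg)])
    n = is_c.size - window + 1
    nc = cs[window:window + n] - cs[:n]
    ng = gs[window:window + n] - gs[:n]
    # CpG fully inside the window: the C must sit before the last base
    ncg = cgs[window - 1:window - 1 + n] - cgs[:n]
    return nc, ng, ncg


def _passes(seq: str) -> bool:
    gc, oe, _ = compute_obs_exp(seq)
    return gc > GC_MIN and oe > OBS_EXP_MIN and len(seq) > LENGTH_MIN


def _trim(seq: str, start: int):
    """Greedy 1-bp end-trimming until the region passes all thresholds."""
    lo, hi = 0, len(seq)
    while hi - lo > LENGTH_MIN:
        sub = seq[lo:hi]
        if _passes(sub):
            return start + lo, start + hi
        # drop the end whose removal scores better on the failing criteria
        gc_l, oe_l, _ = compute_obs_exp(seq[lo + 1:hi])
        gc_r, oe_r, _ = compute_obs_exp(seq[lo:hi - 1])
        score_l = min(gc_l - GC_MIN, oe_l - OBS_EXP_MIN)
        score_r = min(gc_r - GC_MIN, oe_r - OBS_EXP_MIN)
        if score_l >= score_r:
            lo += 1
        else:
            hi -= 1
    return None


def detect_cgis_in_sequence(seq: str, chrom: str = "chr",
                            window: int = WINDOW) -> pd.DataFrame:
    """CGIs of one chromosome sequence via the sliding-window scan."""
    cols = ["chrom", "start", "end", "gc_fraction", "obs_exp", "n_cpg"]
    if len(seq) <= window:
        return pd.DataFrame(columns=cols)
    is_c, is_g, is_cg = _base_arrays(seq)
    nc, ng, ncg = _window_stats(is_c, is_g, is_cg, window)
    gc_ok = (nc + ng) / window > GC_MIN
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((nc > 0) & (ng > 0), ncg * window / (nc * ng), 0.0)
    qual = gc_ok & (oe > OBS_EXP_MIN)
    if not qual.any():
        return pd.DataFrame(columns=cols)
    # merge overlapping qualifying windows [i, i+window)
    idx = np.flatnonzero(qual)
    breaks = np.flatnonzero(np.diff(idx) > window)
    starts = idx[np.concatenate([[0], breaks + 1])]
    ends = idx[np.concatenate([breaks, [idx.size - 1]])] + window
    records = []
    for s, e in zip(starts, ends):
        trimmed = _trim(seq[s:e], int(s))
        if trimmed is None:
            continue
        ts, te = trimmed
        gc, obs_exp, n_cpg = compute_obs_exp(seq[ts:te])
        records.append({"chrom": chrom, "start": ts, "end": te,
                        "gc_fraction": gc, "obs_exp": obs_exp,
                        "n_cpg": n_cpg})
    return pd.DataFrame(records, columns=cols)


def detect_cgis(genome, window: int = WINDOW) -> pd.DataFrame:
    """Detect CGIs across a genome.

    ``genome`` is a mapping of chromosome name to sequence (a plain dict or
    a ``pyfaidx.Fasta``).  Returns a BED-like frame with gc_fraction,
    obs_exp and n_cpg columns; every reported island satisfies all three
    defining thresholds when recomputed from sequence.
    """
    frames = []
    for chrom in genome.keys():
        seq = str(genome[chrom][:]) if hasattr(genome[chrom], "__getitem__") \
            else str(genome[chrom])
        frames.append(detect_cgis_in_sequence(seq, chrom=str(chrom),
                                              window=window))
    if not frames:
        return detect_cgis_in_sequence("", "chr")
    return pd.concat(frames, ignore_index=True)


def _subtract(start: int, end: int, blockers) -> list[tuple[int, int]]:
    """Interval minus a list of (start, end) blockers."""
    pieces = [(start, end)]
    for bs, be in blockers:
        nxt = []
        for s, e in pieces:
            if be <= s or bs >= e:
                nxt.append((s, e))
                continue
            if s < bs:
                nxt.append((s, bs))
            if be < e:
                nxt.append((be, e))
        pieces = nxt
    return [(s, e) for s, e in pieces if e > s]


def define_shores(cgis: pd.DataFrame, chrom_lengths: dict,
                  width: int = SHORE_WIDTH) -> pd.DataFrame:
    """2-kb CGI flanks, clipped at chromosome edges, minus any CGI."""
    records = []
    for chrom, group in cgis.groupby("chrom", sort=True):
        islands = sorted(zip(group["start"].astype(int),
                             group["end"].astype(int)))
        clen = int(chrom_lengths[chrom])
        for s, e in islands:
            for fs, fe in ((max(0, s - width), s),
                           (e, min(clen, e + width))):
                for ps, pe in _subtract(fs, fe, islands):
                    records.append({"chrom": chrom, "start": ps, "end": pe})
    out = pd.DataFrame(records, columns=["chrom", "start", "end"])
    return out.drop_duplicates().sort_values(
        ["chrom", "start"]).reset_index(drop=True)


def classify_promoters(
    tss: pd.DataFrame,
    cgis: pd.DataFrame,
    chrom_lengths: dict,
    flank: int = PROMOTER_FLANK,
) -> pd.DataFrame:
    """TSS +/- flank promoters labelled HCP/LCP by CGI overlap.

    ``tss`` needs columns chrom, pos, strand and gene_id (a BED6 frame with
    the TSS as the start coordinate also works via ``pos = start``).
    Records outside chromosome bounds are dropped with a warning.
    """
    tss = tss.copy()
    if "pos" not in tss.columns:
        tss["pos"] = tss["start"]
    records = []
    n_bad = 0
    cgi_by_chrom = {
        c: np.array(sorted(zip(g["start"], g["end"])), dtype=np.int64)
        for c, g in cgis.groupby("chrom")
    }
    for r in tss.itertuples(index=False):
        clen = chrom_lengths.get(r.chrom)
        if clen is None or not 0 <= r.pos < clen:
            n_bad += 1
            continue
        start = max(0, int(r.pos) - flank)
        end = min(int(clen), int(r.pos) + flank)
        islands = cgi_by_chrom.get(r.chrom)
        hcp = False
        if islands is not None and islands.size:
            hcp = bool(np.any((islands[:, 0] < end) & (islands[:, 1] > start)))
        records.append({"chrom": r.chrom, "start": start, "end": end,
                        "strand": getattr(r, "strand", "+"),
                        "gene_id": getattr(r, "gene_id", ""),
                        "cpg_class": "HCP" if hcp else "LCP"})
    if n_bad:
        warnings.warn(f"dropped {n_bad} TSS outside chromosome bounds",
                      stacklevel=2)
    return pd.DataFrame(records, columns=["chrom", "start", "end", "strand",
                                          "gene_id", "cpg_class"])
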