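"""Synthetic data with the statistical structure the pipeline assumes.

Four generators cover the pipeline's inputs: (1) two-condition per-CpG
binomial methylation counts over regions, with a planted fraction of
regions gaining methylation in condition B; (2) per-molecule amplicon
methylation patterns under distributive (independent per-site) or
processive (run-based) accrual; (3) ChIP window read counts as a Poisson
mixture of background and an enriched subpopulation; (4) CGI feature
tables in which a latent chromatin-openness variable induces the observed
correlation structure (H3K4me3 with DNase, both against H3K27me3 and
starting methylation) and hypermethylation susceptibility follows a
logistic in the features.

Ground truth (planted labels, generating parameters) is returned beside
the data and never written into the data tables themselves.  Every
generator is a pure function of a ``SimulationConfig`` whose seed makes
re-runs bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """Raised for non-finite or out-of-range simulation parameters."""


def _default_susceptibility() -> tuple:
    # 50 CpGs spanning the per-site methylated fractions seen at a deeply
    # sequenced CGI amplicon (~2% to ~54%)
    return tuple(np.round(np.linspace(0.02, 0.54, 50), 4))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of all four generators (only the relevant ones are used).

    Coverage is negative-binomial with the given mean and dispersion
    (``dispersion`` is the NB shape r, variance = mu + mu^2/r), truncated
    at one read.  Region baseline methylation is Beta(alpha, beta); DMR
    regions add ``dmr_effect`` to condition B, clipped to [0, 1].
    """

    seed: int = 0
    n_regions: int = 2000
    cpgs_per_region: int = 10
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    baseline_beta_params: tuple[float, float] = (0.6, 4.0)
    dmr_fraction: float = 0.1
    dmr_effect: float = 0.3
    site_jitter_sd: float = 0.02
    amplicon_model: str = "distributive"
    site_susceptibility: tuple = field(
        default_factory=_default_susceptibility)
    processive_run_mean: float = 5.0
    mixed_weight: float = 0.5
    chip_lambda_background: float = 10.0
    chip_enrichment_factor: float = 6.0
    chip_enriched_fraction: float = 0.05
    cpg_spacing: int = 20
    region_gap: int = 1000

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        def _finite(*xs):
            return all(np.isfinite(x) for x in xs)

        if self.n_regions < 0 or self.cpgs_per_region < 2:
            raise ConfigError("need n_regions >= 0 and >= 2 CpGs per region")
        if not _finite(self.coverage_mean, self.coverage_dispersion) or \
                self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ConfigError("coverage mean and dispersion must be positive")
        a, b = self.baseline_beta_params
        if not _finite(a, b) or a <= 0 or b <= 0:
            raise ConfigError("Beta parameters must be positive")
        for name in ("dmr_fraction", "dmr_effect", "mixed_weight",
                     "chip_enriched_fraction"):
            v = getattr(self, name)
            if not _finite(v) or not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.site_jitter_sd < 0 or not _finite(self.site_jitter_sd):
            raise ConfigError("site_jitter_sd must be >= 0")
        if self.amplicon_model not in ("distributive", "processive", "mixed"):
            raise ConfigError("unknown amplicon_model")
        p = np.asarray(self.site_susceptibility, float)
        if p.size == 0 or np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
            raise ConfigError("site_susceptibility must lie in [0, 1]")
        if self.processive_run_mean < 1:
            raise ConfigError("processive_run_mean must be >= 1")
        if not _finite(self.chip_lambda_background) or \
                self.chip_lambda_background < 0:
            raise ConfigError("chip_lambda_background must be >= 0")
        if self.chip_enrichment_factor <= 1:
            raise ConfigError("chip_enrichment_factor must be > 1")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["site_susceptibility"] = list(d["site_susceptibility"])
        d["baseline_beta_params"] = list(d["baseline_beta_params"])
        return json.dumps(d, indent=1)


@dataclass
class SyntheticTruth:
    """Planted labels and parameters, kept separate from the data files."""

    config: SimulationConfig
    region_truth: pd.DataFrame | None = None
    window_is_enriched: np.ndarray | None = None
    per_site_probability: np.ndarray | None = None


def _nb_coverage(rng, mean, r, size):
    cov = rng.negative_binomial(r, r / (r + mean), size=size)
    return np.maximum(cov, 1)


def simulate_rrbs_pair(config: SimulationConfig):
    """Two-condition per-CpG methylation count tables with planted DMRs.

    Per region a true methylation fraction m ~ Beta(alpha, beta) is drawn;
    per CpG and condition an independent site offset (Gaussian, sd
    ``site_jitter_sd``) perturbs m, and counts are Binomial(coverage, m)
    with negative-binomial coverage.  Jitter independent between
    conditions keeps the two samples of a region independent, which is the
    structure the downstream two-sample test assumes.  A ``dmr_fraction``
    of regions gains ``dmr_effect`` in condition B only (clipped to
    [0, 1]).  Returns (table_a, table_b, truth); tables are in the CpG
    coverage dialect (chrom, start, end, meth_count, unmeth_count).
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_regions, config.cpgs_per_region
    a, b = config.baseline_beta_params
    m0 = rng.beta(a, b, size=n)
    is_dmr = rng.random(n) < config.dmr_fraction
    jit_a = rng.normal(0.0, config.site_jitter_sd, size=(n, k))
    jit_b = rng.normal(0.0, config.site_jitter_sd, size=(n, k))
    p_a = np.clip(m0[:, None] + jit_a, 0.0, 1.0)
    p_b = np.clip(m0[:, None] + is_dmr[:, None] * config.dmr_effect + jit_b,
                  0.0, 1.0)
    span = k * config.cpg_spacing
    region_start = np.arange(n) * (span + config.region_gap)
    pos = (region_start[:, None]
           + np.arange(k)[None, :] * config.cpg_spacing).ravel()

    from .methylation import _with_derived

    tables = []
    for p in (p_a, p_b):
        cov = _nb_coverage(rng, config.coverage_mean,
                           config.coverage_dispersion, (n, k))
        meth = rng.binomial(cov, p)
        tables.append(_with_derived(pd.DataFrame({
            "chrom": "chrS",
            "start": pos,
            "end": pos + 1,
            "meth_count": meth.ravel(),
            "unmeth_count": (cov - meth).ravel(),
        })))
    region_truth = pd.DataFrame({
        "region_id": np.arange(n),
        "chrom": "chrS",
        "start": region_start,
        "end": region_start + span,
        "is_dmr": is_dmr,
        "m_baseline": m0,
        "m_condition_b": np.clip(m0 + is_dmr * config.dmr_effect, 0, 1),
    })
    truth = SyntheticTruth(config=config, region_truth=region_truth)
    return tables[0], tables[1], truth


def _processive_reads(rng, p, n_reads, run_mean):
    """Run-based accrual: per molecule a Poisson number of engagement
    events each methylates a geometric-length run of consecutive CpGs
    (uniform start, truncated at the amplicon edge).  The event rate
    m * mean(p) / run_mean targets the requested mean methylation; the
    per-site marginals are approximate (edge truncation and run overlap
    pull them slightly below p)."""
    m = p.size
    nu = m * float(p.mean()) / run_mean
    mat = np.zeros((n_reads, m), dtype=np.uint8)
    n_runs = rng.poisson(nu, size=n_reads)
    rows = np.repeat(np.arange(n_reads), n_runs)
    starts = rng.integers(m, size=rows.size)
    lengths = rng.geometric(1.0 / run_mean, size=rows.size)
    for i, s, length in zip(rows, starts, lengths):
        mat[i, s:s + length] = 1
    return mat


def simulate_amplicon_reads(config: SimulationConfig, n_reads: int):
    """Per-molecule M/U patterns over the amplicon CpGs.

    Distributive accrual methylates each CpG of each molecule independently
    with its site susceptibility; processive accrual places a Poisson
    number of runs of consecutive methylated CpGs per molecule (geometric
    run length with mean ``processive_run_mean``, uniform start, truncated
    at edges), with the event rate set to match the mean susceptibility;
    the mixed model draws each molecule from the processive model with
    probability ``mixed_weight``, else distributive.
    """
    if n_reads <= 0:
        raise ConfigError("n_reads must be positive")
    rng = np.random.default_rng(config.seed)
    p = np.asarray(config.site_susceptibility, float)
    if config.amplicon_model == "distributive":
        mat = (rng.random((n_reads, p.size)) < p).astype(np.uint8)
    elif config.amplicon_model == "processive":
        mat = _processive_reads(rng, p, n_reads, config.processive_run_mean)
    else:
        take_proc = rng.random(n_reads) < config.mixed_weight
        mat = (rng.random((n_reads, p.size)) < p).astype(np.uint8)
        n_proc = int(take_proc.sum())
        if n_proc:
            mat[take_proc] = _processive_reads(
                rng, p, n_proc, config.processive_run_mean)
    lut = np.array(["U", "M"])
    patterns = ["".join(lut[row]) for row in mat]
    reads = pd.DataFrame({
        "read_id": [f"read_{i}" for i in range(n_reads)],
        "pattern": patterns,
    })
    truth = SyntheticTruth(config=config, per_site_probability=p)
    return reads, truth


def simulate_chip_windows(config: SimulationConfig, n_windows: int):
    """Poisson window counts with an enriched subpopulation.

    Background windows draw Poisson(lambda); an ``enriched_fraction`` draws
    Poisson(lambda * enrichment_factor).  Returns (table, truth) where the
    table is a window-count TSV frame and truth carries the planted flags.
    """
    if n_windows < 0:
        raise ConfigError("n_windows must be >= 0")
    rng = np.random.default_rng(config.seed)
    enriched = rng.random(n_windows) < config.chip_enriched_fraction
    lam = np.where(enriched,
                   config.chip_lambda_background *
                   config.chip_enrichment_factor,
                   config.chip_lambda_background)
    counts = rng.poisson(lam)
    width = 1000
    starts = np.arange(n_windows, dtype=np.int64) * width
    table = pd.DataFrame({
        "window_id": [f"win_{i}" for i in range(n_windows)],
        "chrom": "chrS",
        "start": starts,
        "end": starts + width,
        "count": counts.astype(np.int64),
    })
    truth = SyntheticTruth(config=config, window_is_enriched=enriched)
    return table, truth


FEATURE_NAMES = ("h3k4me3", "h3k27me3", "h3k36me3", "dnase", "cpg_density",
                 "normalized_cpg_density", "gc_fraction",
                 "control_methylation")

#: default logistic weights of hypermethylation susceptibility: CGIs that
#: are H3K4me3-marked, DNase-open and start unmethylated resist methylation
#: gain; H3K27me3-marked CGIs are susceptible.
DEFAULT_LABEL_WEIGHTS = {
    "h3k4me3": -1.4,
    "dnase": -1.4,
    "h3k27me3": 1.0,
    "control_methylation": 8.0,  # on the [0, 0.2) starting-methylation scale
}


def simulate_feature_table(
    config: SimulationConfig,
    n_cgis: int,
    label_weights: dict | None = None,
    intercept: float = -2.0,
) -> pd.DataFrame:
    """CGI feature table with openness-driven correlation and DMR labels.

    A latent openness z per CGI drives H3K4me3 and DNase positively,
    H3K27me3 and starting (control) methylation negatively; CpG density,
    normalized CpG density, GC fraction and H3K36me3 depend on z only
    weakly.  The DMR label is Bernoulli with logistic probability
    ``sigmoid(intercept + sum_w w_f x_f)``; ``label_weights`` overrides the
    default weight map (features absent from the map get weight 0).
    """
    if n_cgis <= 0:
        raise ConfigError("n_cgis must be positive")
    rng = np.random.default_rng(config.seed)
    z = rng.normal(size=n_cgis)

    def noisy(load, scale=1.0):
        return load * z + np.sqrt(max(scale**2 - load**2, 0.0)) * \
            rng.normal(size=n_cgis)

    df = pd.DataFrame({
        "cgi_id": [f"cgi_{i}" for i in range(n_cgis)],
        "h3k4me3": noisy(0.8),
        "dnase": noisy(0.8),
        "h3k27me3": noisy(-0.6),
        "h3k36me3": noisy(0.2),
        "cpg_density": np.clip(0.08 + 0.01 * noisy(0.2), 0.01, None),
        "normalized_cpg_density": np.clip(0.75 + 0.1 * noisy(0.2),
                                          0.05, None),
        "gc_fraction": np.clip(0.55 + 0.03 * noisy(0.2), 0.3, 0.9),
        "control_methylation": 0.2 / (1.0 + np.exp(-(
            -0.8 * z + 0.6 * rng.normal(size=n_cgis)))),
    })
    weights = DEFAULT_LABEL_WEIGHTS if label_weights is None else label_weights
    logit = np.full(n_cgis, float(intercept))
    for name, w in weights.items():
        if name not in FEATURE_NAMES:
            raise ConfigError(f"unknown feature '{name}' in label_weights")
        logit = logit + w * df[name].to_numpy()
    prob = 1.0 / (1.0 + np.exp(-logit))
    df["label"] = (rng.random(n_cgis) < prob).astype(int)
    return df
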