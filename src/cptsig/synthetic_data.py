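"""Synthetic datasets with the statistical structure the analysis assumes.

A single latent driver factor (one value per sample, standard normal by
default) generates:

* a driver gene whose expression IS the latent factor, expanded to
  several probesets (one optionally decorrelated, to exercise the
  coherent-probe selection);
* a planted module of genes ``g = beta * latent + sigma * noise`` whose
  population correlation with the latent factor is the closed form
  ``beta / sqrt(beta^2 + sigma^2)`` (beta = 1, sigma = 0.75 gives 0.8);
* independent standard-normal background genes.

Probe-level replication adds independent N(0, probe_noise_sd) per probe,
giving within-gene coherence.  A negative-binomial count analog and a
monotone platform-distortion operator support the gene-level and
cross-platform stages.  Every generator is bit-reproducible from the
config seed; per-stage sub-streams are spawned deterministically.

Default configuration mirrors the study conditions the pipeline is
verified under: 40 samples (the human tumour cohort size), 120 module
genes at population r = 0.8, 2000 background genes, 4 probes per gene,
a 6-probe driver with one decorrelated probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .matrix_io import ExpressionMatrix, ProbeAnnotation

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_exon_dataset",
    "simulate_count_dataset",
    "apply_platform_distortion",
    "expected_population_correlation",
]

DRIVER_GENE = "MYC"


def expected_population_correlation(beta: float, sigma: float) -> float:
    """Population correlation of a module gene with the latent driver factor."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return beta / math.sqrt(beta * beta + sigma * sigma)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the verification conditions.

    ``probes_per_gene`` may be an int or an inclusive (lo, hi) range.
    ``group_means`` replaces the standard-normal latent factor with
    per-group levels (samples split into near-equal groups round-robin)
    plus N(0, group_latent_sd) within-group spread — used for clustered
    cohort fixtures, where adjacent group means spaced ``3 * sigma / beta``
    apart separate each module gene's group distributions by three
    gene-level noise SDs.  ``driver_beta`` is the driver gene's own
    loading on the latent factor (1 by default; set 0 together with
    ``beta=0`` for fully null calibration datasets).
    """

    n_samples: int = 40
    n_module_genes: int = 120
    n_background_genes: int = 2000
    probes_per_gene: int | tuple[int, int] = 4
    beta: float = 1.0
    sigma: float = 0.75
    probe_noise_sd: float = 0.25
    driver_probe_count: int = 6
    driver_beta: float = 1.0
    decorrelated_driver_probe: bool = True
    group_means: tuple[float, ...] | None = None
    group_latent_sd: float = 0.0
    nb_dispersion: float = 0.1
    baseline_log_mean: float = math.log(200.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_module_genes + self.n_background_genes) <= 0:
            raise ValueError("sample and gene counts must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.probe_noise_sd < 0:
            raise ValueError("probe_noise_sd must be non-negative")
        if self.driver_probe_count < 1:
            raise ValueError("driver_probe_count must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        lo, hi = self._probe_range()
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid probes_per_gene range ({lo}, {hi})")

    def _probe_range(self) -> tuple[int, int]:
        if isinstance(self.probes_per_gene, tuple):
            return self.probes_per_gene
        return (self.probes_per_gene, self.probes_per_gene)


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    latent: np.ndarray
    module_genes: set[str]
    betas: dict[str, float]
    expected_population_r: float
    group_labels: np.ndarray | None = None
    driver_gene: str = DRIVER_GENE


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def _latent(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray | None]:
    noise = rng.standard_normal(cfg.n_samples)
    if cfg.group_means is None:
        return noise, None
    k = len(cfg.group_means)
    groups = np.arange(cfg.n_samples) % k
    means = np.asarray(cfg.group_means, dtype=float)[groups]
    return means + cfg.group_latent_sd * noise, groups


def _gene_names(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    width = max(4, len(str(cfg.n_module_genes)), len(str(cfg.n_background_genes)))
    module = [f"MOD{i:0{width}d}" for i in range(1, cfg.n_module_genes + 1)]
    background = [f"BG{i:0{width}d}" for i in range(1, cfg.n_background_genes + 1)]
    return module, background


def _gene_level_values(
    cfg: SyntheticConfig, latent: np.ndarray, rng: np.random.Generator
) -> tuple[list[str], np.ndarray, dict[str, float]]:
    module, background = _gene_names(cfg)
    genes = [DRIVER_GENE] + module + background
    betas = {DRIVER_GENE: cfg.driver_beta}
    if cfg.driver_beta == 0.0:
        rows = [rng.standard_normal(cfg.n_samples)]  # fully null driver
    else:
        # the driver gene's profile is the (scaled) latent factor itself
        rows = [cfg.driver_beta * latent]
    for g in module:
        betas[g] = cfg.beta
        rows.append(cfg.beta * latent + cfg.sigma * rng.standard_normal(cfg.n_samples))
    for g in background:
        betas[g] = 0.0
        rows.append(rng.standard_normal(cfg.n_samples))
    return genes, np.vstack(rows), betas


def simulate_exon_dataset(
    cfg: SyntheticConfig,
) -> tuple[ExpressionMatrix, ProbeAnnotation, SyntheticTruth]:
    """Probe-level dataset emulating a multi-probeset exon array.

    Each gene's probes are its gene-level value plus independent
    N(0, probe_noise_sd).  The driver gene receives
    ``driver_probe_count`` probes; when ``decorrelated_driver_probe`` is
    set, its LAST probe is replaced by independent noise, so coherent
    probe selection should retain the other ``driver_probe_count - 1``.
    """
    rng_latent, rng_genes, rng_probes = _streams(cfg.seed, 3)
    latent, groups = _latent(cfg, rng_latent)
    genes, gene_values, betas = _gene_level_values(cfg, latent, rng_genes)

    lo, hi = cfg._probe_range()
    probe_ids: list[str] = []
    probe_rows: list[np.ndarray] = []
    mapping: dict[str, str] = {}
    for gi, g in enumerate(genes):
        if g == DRIVER_GENE:
            n_probes = cfg.driver_probe_count
        elif lo == hi:
            n_probes = lo
        else:
            n_probes = int(rng_probes.integers(lo, hi + 1))
        for pi in range(1, n_probes + 1):
            pid = f"{g}_p{pi}"
            if (
                g == DRIVER_GENE
                and cfg.decorrelated_driver_probe
                and pi == n_probes
                and n_probes > 1
            ):
                row = rng_probes.standard_normal(cfg.n_samples)
            else:
                row = gene_values[gi] + cfg.probe_noise_sd * rng_probes.standard_normal(
                    cfg.n_samples
                )
            probe_ids.append(pid)
            probe_rows.append(row)
            mapping[pid] = g

    matrix = ExpressionMatrix.from_arrays(
        probe_ids,
        [f"S{j:03d}" for j in range(1, cfg.n_samples + 1)],
        np.vstack(probe_rows),
        scale_tag="log",
        platform_tag="synthetic_exon_array",
    )
    truth = SyntheticTruth(
        latent=latent,
        module_genes=set(_gene_names(cfg)[0]),
        betas=betas,
        expected_population_r=expected_population_correlation(cfg.beta, cfg.sigma),
        group_labels=groups,
    )
    return matrix, ProbeAnnotation(mapping), truth


def simulate_count_dataset(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Gene-level negative-binomial count dataset converted to CPM.

    Gene counts are NB with log-mean ``baseline + beta * latent`` for
    module genes (dispersion ``nb_dispersion``, so variance
    mu + phi * mu^2) and ``baseline`` for background genes; the driver
    gene loads on the latent factor with coefficient 1.  Counts are
    converted to counts-per-million with per-sample totals.
    """
    rng_latent, rng_counts = _streams(cfg.seed, 2)
    latent, groups = _latent(cfg, rng_latent)
    module, background = _gene_names(cfg)
    genes = [DRIVER_GENE] + module + background
    betas = {DRIVER_GENE: cfg.driver_beta, **{g: cfg.beta for g in module},
             **{g: 0.0 for g in background}}

    log_mu = np.empty((len(genes), cfg.n_samples))
    for i, g in enumerate(genes):
        log_mu[i] = cfg.baseline_log_mean + betas[g] * latent
    mu = np.exp(log_mu)
    phi = cfg.nb_dispersion
    # NB(r, p) with r = 1/phi, p = r / (r + mu) has mean mu, var mu + phi mu^2
    r_shape = 1.0 / phi
    counts = rng_counts.negative_binomial(r_shape, r_shape / (r_shape + mu))
    totals = counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise RuntimeError("degenerate simulation: a sample drew zero total counts")
    cpm = counts / totals * 1e6

    matrix = ExpressionMatrix.from_arrays(
        genes,
        [f"S{j:03d}" for j in range(1, cfg.n_samples + 1)],
        cpm,
        scale_tag="linear",
        platform_tag="synthetic_rnaseq_cpm",
    )
    truth = SyntheticTruth(
        latent=latent,
        module_genes=set(module),
        betas=betas,
        expected_population_r=expected_population_correlation(cfg.beta, cfg.sigma),
        group_labels=groups,
    )
    return matrix, truth


def apply_platform_distortion(
    m: ExpressionMatrix, gamma: float = 1.5, jitter_sd: float = 0.0, seed: int = 0
) -> ExpressionMatrix:
    """Monotone per-sample distortion emulating a platform change.

    Each value maps to ``value ** gamma`` times a random per-sample
    scale factor, with optional multiplicative log-normal jitter
    (``exp(N(0, jitter_sd))`` per cell).  With ``jitter_sd == 0`` the
    map is strictly monotone within each sample, so rank structure — and
    hence the cumulative-proportion transform up to value magnitudes —
    is preserved; with ``gamma == 1`` and no jitter the transform is
    exactly invariant.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    values = m.values
    if values.min() < 0:
        raise ValueError("platform distortion requires non-negative values")
    rng = np.random.default_rng(seed)
    scales = rng.uniform(0.5, 2.0, size=m.n_samples)
    out = np.power(values, gamma) * scales[None, :]
    if jitter_sd > 0:
        out = out * np.exp(jitter_sd * rng.standard_normal(values.shape))
    return ExpressionMatrix.from_arrays(
        m.feature_ids, m.sample_ids, out, scale_tag="linear",
        platform_tag=f"{m.platform_tag}_distorted",
    )
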