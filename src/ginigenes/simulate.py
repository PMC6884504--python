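"""Synthetic expression matrices and Cq tables with known ground truth.

Bulk expression is emulated with a per-gene log-normal model:

    value(g, s) = exp(mu_g + sigma_g * z_gs),   z_gs ~ N(0, 1)

chosen because the log-normal admits a closed-form Gini coefficient,

    G = 2 * Phi(sigma / sqrt(2)) - 1,

which gives every estimator in the package an analytic target.  A planted
subset of genes receives a low log-scale SD (the "stable" genes a
selection procedure should recover); an optional outlier process
multiplies a random sparse subset of cells by a large factor, mimicking
the isolated extreme samples that inflate the Gini coefficient.

Cq tables are generated gene-by-gene: a per-line true mean Cq drawn
around a gene-specific baseline, then technical replicates with small
Gaussian noise; a configurable fraction of (gene, line) pairs is pushed
above the expression cutoff to exercise censoring.

Reproducibility: a single integer seed drives a splittable
``numpy.random.SeedSequence`` stream with one child per gene, so a gene's
draws do not depend on how many genes precede it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix
from .qpcr import CqTable

__all__ = [
    "SimulationConfig",
    "CqSimulationConfig",
    "lognormal_gini",
    "cv_to_sigma",
    "simulate_expression_matrix",
    "simulate_cq_table",
]


def lognormal_gini(sigma: float) -> float:
    """Closed-form Gini coefficient of a log-normal distribution with
    log-scale SD *sigma*: ``2*Phi(sigma/sqrt(2)) - 1``."""
    return float(2.0 * sps.norm.cdf(sigma / np.sqrt(2.0)) - 1.0)


def cv_to_sigma(cv: float) -> float:
    """Log-scale SD giving a log-normal coefficient of variation *cv*
    (sigma^2 = ln(1 + cv^2))."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    return float(np.sqrt(np.log1p(cv * cv)))


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic expression matrix.

    Defaults describe the benchmark condition used throughout the test
    suite: 500 genes x 100 samples with 50 planted stable genes.  The
    planted genes draw their log-scale SD from ``stable_sigma_range``
    (0.05-0.25, i.e. CV roughly 5-25%, the regime of genuinely stable
    transcripts); background genes from ``sigma_range`` (0.5-1.5, the
    broad variability typical of unselected genes across heterogeneous
    samples).  ``log_mean_range`` spans baseline abundances from ~1 to
    ~1100 on the natural-exponential scale.  Outliers are off by default;
    when ``outlier_rate`` > 0, each cell is independently multiplied by
    ``outlier_multiplier`` with that probability.
    """

    n_genes: int = 500
    n_samples: int = 100
    n_planted: int = 50
    sigma_range: tuple[float, float] = (0.5, 1.5)
    stable_sigma_range: tuple[float, float] = (0.05, 0.25)
    log_mean_range: tuple[float, float] = (0.0, 7.0)
    outlier_rate: float = 0.0
    outlier_multiplier: float = 100.0
    seed: int = 0
    #: When set, sample noise (and outlier placement) draws from this
    #: separate stream while mu/sigma still come from ``seed`` — two
    #: configs differing only in noise_seed emulate two independent
    #: datasets measuring the same gene population.
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted cannot exceed n_genes")
        if not (0.0 <= self.outlier_rate <= 1.0):
            raise ValueError("outlier_rate must lie in [0, 1]")
        for lo, hi in (self.sigma_range, self.stable_sigma_range):
            if lo < 0 or hi < lo:
                raise ValueError("sigma ranges must satisfy 0 <= lo <= hi")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(gene_index,)))


def simulate_expression_matrix(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a synthetic matrix plus its ground-truth table.

    The first ``n_planted`` gene indices are the planted stable genes.
    Ground truth has columns ``gene``, ``mu``, ``sigma``, ``planted``,
    ``true_gini`` (the closed-form log-normal Gini, before outliers).
    """
    n_g, n_s = config.n_genes, config.n_samples
    values = np.empty((n_g, n_s))
    truth_rows = []
    genes = [f"G{i:04d}" for i in range(n_g)]
    for i in range(n_g):
        rng = _gene_rng(config.seed, i)
        noise_rng = (
            _gene_rng(config.noise_seed, i) if config.noise_seed is not None else rng
        )
        planted = i < config.n_planted
        lo, hi = config.stable_sigma_range if planted else config.sigma_range
        sigma = rng.uniform(lo, hi)
        mu = rng.uniform(*config.log_mean_range)
        row = np.exp(mu + sigma * noise_rng.standard_normal(n_s))
        if config.outlier_rate > 0:
            mask = noise_rng.random(n_s) < config.outlier_rate
            row[mask] *= config.outlier_multiplier
        values[i] = row
        truth_rows.append(
            {"gene": genes[i], "mu": mu, "sigma": sigma, "planted": planted,
             "true_gini": lognormal_gini(sigma)}
        )
    samples = [f"S{j:03d}" for j in range(n_s)]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="Gene ID"), columns=samples),
        dataset_id=f"synthetic-seed{config.seed}",
        unit="TPM",
    )
    return matrix, pd.DataFrame(truth_rows)


@dataclass
class CqSimulationConfig:
    """Generative parameters for a synthetic replicate-level Cq table.

    Defaults mirror a typical validation experiment: 40 candidate genes
    across a panel of 10 cell lines in technical triplicate.  Planted
    stable genes vary across lines with SD ``stable_line_sd`` cycles;
    background genes with ``line_sd`` cycles.  Technical replicate noise
    is 0.15 cycles SD.  ``censored_rate`` pushes that fraction of
    (gene, line) pairs above the cutoff (cutoff + 1..5 cycles) so the
    censoring path is exercised.
    """

    n_genes: int = 40
    n_lines: int = 10
    n_replicates: int = 3
    n_planted: int = 3
    base_cq_range: tuple[float, float] = (18.0, 28.0)
    line_sd: float = 1.5
    stable_line_sd: float = 0.1
    technical_sd: float = 0.15
    censored_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted cannot exceed n_genes")
        if not (0.0 <= self.censored_rate <= 1.0):
            raise ValueError("censored_rate must lie in [0, 1]")


def simulate_cq_table(
    config: CqSimulationConfig, cutoff: float = 32.0
) -> tuple[CqTable, pd.DataFrame]:
    """Generate a synthetic Cq table plus ground truth.

    The first ``n_planted`` genes are the planted stable genes (low
    across-line variance).  Ground truth columns: ``gene``, ``base_cq``,
    ``line_sd``, ``planted``.
    """
    rows = []
    truth_rows = []
    genes = [f"Q{i:03d}" for i in range(config.n_genes)]
    lines = [f"L{j:02d}" for j in range(config.n_lines)]
    for i, gene in enumerate(genes):
        rng = _gene_rng(config.seed, i)
        planted = i < config.n_planted
        line_sd = config.stable_line_sd if planted else config.line_sd
        base = rng.uniform(*config.base_cq_range)
        true_line_cq = base + line_sd * rng.standard_normal(config.n_lines)
        if config.censored_rate > 0:
            mask = rng.random(config.n_lines) < config.censored_rate
            true_line_cq[mask] = cutoff + rng.uniform(1.0, 5.0, size=mask.sum())[: mask.sum()]
        for j, line in enumerate(lines):
            reps = true_line_cq[j] + config.technical_sd * rng.standard_normal(
                config.n_replicates
            )
            reps = np.maximum(reps, 1e-6)  # Cq must stay positive
            for r, cq in enumerate(reps, start=1):
                rows.append(
                    {"gene": gene, "cell_line": line, "replicate": r, "cq": float(cq)}
                )
        truth_rows.append(
            {"gene": gene, "base_cq": base, "line_sd": line_sd, "planted": planted}
        )
    table = CqTable(data=pd.DataFrame(rows), cutoff=cutoff)
    return table, pd.DataFrame(truth_rows)
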