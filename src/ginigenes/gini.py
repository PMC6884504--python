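"""Gini coefficient, Lorenz curve and companion expression-stability metrics.

The Gini coefficient (GC) measures the inequality of a gene's abundance
across samples.  A gene expressed identically in every sample has GC = 0;
a gene expressed in a single sample out of n approaches GC = 1 (exactly
(n-1)/n).  Low GC therefore means stable expression, which is what makes a
transcript a good normalisation reference.

The estimator used here is the classical mean-absolute-difference form
with no small-sample correction,

    G = sum_i sum_j |x_i - x_j| / (2 n^2 xbar)
      = (2 * sum_i i * x_(i)) / (n * sum x) - (n + 1) / n

on ascending-sorted values, identical to the default of the R ``ineq``
package.  It equals twice the area between the Lorenz curve and the
diagonal of equality.

Alongside the GC the module computes the outlier-resistant companion
statistics used to check its robustness: the interquartile ratio q3/q1,
the percentage relative standard deviation (100*SD/mean, sample SD),
the max:min fold range and the max:median ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedStatisticError
from .io import ExpressionMatrix

__all__ = [
    "LorenzCurve",
    "GeneStabilityRecord",
    "gini_coefficient",
    "lorenz_curve",
    "stability_metrics",
    "per_gene_stability",
    "write_stability_tsv",
    "STABILITY_COLUMNS",
]

#: Fixed column order of the per-gene stability table.
STABILITY_COLUMNS = [
    "gene",
    "n_samples",
    "n_missing",
    "gini",
    "median",
    "q1",
    "q3",
    "iqr_ratio",
    "rsd_percent",
    "max_min_ratio",
    "max_median_ratio",
    "mean",
    "low_confidence",
]


def _checked_vector(values, allow_all_zero: bool = False) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 values, got {x.size}")
    if np.isnan(x).any():
        raise UndefinedStatisticError(
            "missing values must be removed before computing statistics"
        )
    if (x < 0).any():
        raise UndefinedStatisticError("negative values are outside the domain")
    if not allow_all_zero and not (x > 0).any():
        raise UndefinedStatisticError(
            "statistic undefined for an all-zero vector"
        )
    return x


def gini_coefficient(values) -> float:
    """Gini coefficient of a non-negative vector (n >= 2).

    Scale- and permutation-invariant; bounded by 0 <= G <= 1 - 1/n.  Raises
    :class:`~ginigenes.errors.UndefinedStatisticError` on negative entries
    or an all-zero vector (where the statistic has no value — it is not 0).
    """
    x = _checked_vector(values)
    xs = np.sort(x)
    n = xs.size
    ranks = np.arange(1, n + 1, dtype=float)
    g = 2.0 * (ranks * xs).sum() / (n * xs.sum()) - (n + 1.0) / n
    # the estimator is >= 0 analytically; guard against -1e-16 rounding
    return float(max(g, 0.0))


@dataclass
class LorenzCurve:
    """Piecewise-linear Lorenz curve: cumulative share of expression versus
    cumulative share of samples, on ascending-sorted values.

    ``points`` has shape (n+1, 2); the first point is (0, 0) and the last
    (1, 1), and the curve never rises above the diagonal.
    """

    points: np.ndarray

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def gini(self) -> float:
        """GC as twice the area between the diagonal and the curve.

        Exact (trapezoid rule is exact on piecewise-linear curves) and
        agrees with :func:`gini_coefficient` to ~1e-12.
        """
        area_under = float(np.trapezoid(self.y, self.x))
        return 1.0 - 2.0 * area_under


def lorenz_curve(values) -> LorenzCurve:
    """Lorenz curve of a non-negative vector: (k/n, sum of the k smallest
    values / total) for k = 0..n."""
    x = _checked_vector(values)
    xs = np.sort(x)
    n = xs.size
    cum = np.concatenate([[0.0], np.cumsum(xs)]) / xs.sum()
    frac = np.arange(n + 1) / n
    return LorenzCurve(points=np.column_stack([frac, cum]))


@dataclass
class GeneStabilityRecord:
    """Per-gene stability statistics across samples.

    ``iqr_ratio`` is q3/q1 (>= 1); ``rsd_percent`` is 100*SD/mean with the
    n-1 sample SD; ``max_min_ratio`` is NaN when the minimum is zero;
    ``low_confidence`` flags records built from only 2 samples.
    """

    gene: str
    n_samples: int
    n_missing: int
    gini: float
    median: float
    q1: float
    q3: float
    iqr_ratio: float
    rsd_percent: float
    max_min_ratio: float
    max_median_ratio: float
    mean: float
    low_confidence: bool


def stability_metrics(values, gene: str = "", n_missing: int = 0) -> GeneStabilityRecord:
    """Compute the full stability record for one gene's non-missing values.

    Quartiles use linear interpolation between order statistics with
    plotting position (i-1)/(n-1) (numpy's default ``linear`` method), so
    the interquartile ratio is reproducible bit-for-bit.
    """
    x = _checked_vector(values, allow_all_zero=True)
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    q1, med, q3 = (float(q) for q in np.quantile(x, [0.25, 0.5, 0.75], method="linear"))
    xmin, xmax = float(x.min()), float(x.max())
    return GeneStabilityRecord(
        gene=gene,
        n_samples=n,
        n_missing=int(n_missing),
        gini=gini_coefficient(x) if (x > 0).any() else math.nan,
        median=med,
        q1=q1,
        q3=q3,
        iqr_ratio=q3 / q1 if q1 > 0 else math.nan,
        rsd_percent=100.0 * sd / mean if mean > 0 else math.nan,
        max_min_ratio=xmax / xmin if xmin > 0 else math.nan,
        max_median_ratio=xmax / med if med > 0 else math.nan,
        mean=mean,
        low_confidence=n < 3,
    )


def per_gene_stability(
    matrix: ExpressionMatrix, min_samples: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stability statistics for every gene of *matrix*.

    Returns ``(records, excluded)``: *records* has one row per gene with at
    least *min_samples* non-missing values (columns
    :data:`STABILITY_COLUMNS`), *excluded* lists every gene that could not
    be scored together with the reason — genes are never silently dropped.
    The GC and every companion statistic are computed on the same
    non-missing vector.
    """
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    rows: list[dict] = []
    excluded: list[dict] = []
    arr = matrix.values.to_numpy(dtype=float)
    for i, gene in enumerate(matrix.gene_ids):
        row = arr[i]
        keep = ~np.isnan(row)
        vec = row[keep]
        n_missing = int((~keep).sum())
        if vec.size < min_samples:
            excluded.append(
                {"gene": gene, "n_samples": int(vec.size), "reason": "too-few-values"}
            )
            continue
        if not (vec > 0).any():
            excluded.append(
                {"gene": gene, "n_samples": int(vec.size), "reason": "all-zero"}
            )
            continue
        rows.append(asdict(stability_metrics(vec, gene=str(gene), n_missing=n_missing)))
    records = pd.DataFrame(rows, columns=STABILITY_COLUMNS)
    excluded_df = pd.DataFrame(excluded, columns=["gene", "n_samples", "reason"])
    return records, excluded_df


def write_stability_tsv(records: pd.DataFrame, path: str | Path) -> None:
    """Write a per-gene stability table with the documented fixed column
    order and '.' decimal separator."""
    records.loc[:, STABILITY_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_stability_tsv(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_stability_tsv`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "gini", "median") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not a stability table, missing columns {missing}")
    return df
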