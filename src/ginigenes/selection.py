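"""Turning stability tables into candidate reference-gene lists.

Genes whose Gini coefficient falls at or below a threshold (default 0.2)
are "Gini genes" — data-driven candidate references.  Across several
datasets the candidates of interest are those passing the filter in every
dataset, summarised here as a membership grid plus per-pattern counts (the
table underlying an UpSet plot).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import PanelAnnotation

__all__ = [
    "SelectionConfig",
    "IntersectionTable",
    "filter_by_gini",
    "intersect_datasets",
    "rank_candidates",
    "top_expressed",
]


@dataclass
class SelectionConfig:
    """Parameters of the candidate-gene filter and ranking.

    gini_threshold
        Maximum GC to accept, inclusive by default (0.2: the working point
        at which the shared gene lists are neither empty nor unmanageable).
        Set ``strict=True`` for a strict ``<`` comparison.
    min_median
        Optional median-expression floor; 0 disables it.  The GC filter is
        primary — expression level is inspected afterwards — but very low
        expressed candidates can be excluded up front with this knob.
    top_n
        Length of the ranked candidate list.
    """

    gini_threshold: float = 0.2
    strict: bool = False
    min_median: float = 0.0
    top_n: int = 32

    def __post_init__(self) -> None:
        if not (0.0 < self.gini_threshold < 1.0):
            raise ValueError("gini_threshold must lie in (0, 1)")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.min_median < 0:
            raise ValueError("min_median must be >= 0")


@dataclass
class IntersectionTable:
    """Cross-dataset membership of filtered gene sets.

    membership
        Boolean grid, genes (union, sorted) x datasets.
    pattern_counts
        One row per distinct membership pattern: the dataset indicator
        columns, ``count`` and ``degree`` (number of datasets in the
        pattern); rows sorted by degree then count descending.  This is
        exactly the input an UpSet-style plot consumes.
    shared_all
        Genes present in every dataset's set.
    """

    membership: pd.DataFrame
    pattern_counts: pd.DataFrame
    shared_all: set[str]


def filter_by_gini(records: pd.DataFrame, config: SelectionConfig | None = None) -> set[str]:
    """Genes whose GC passes the threshold (and optional median floor).

    Non-finite GC values never pass.  Deterministic: the result depends
    only on the table contents.
    """
    config = config or SelectionConfig()
    if records.empty:
        return set()
    gini = records["gini"].to_numpy(dtype=float)
    ok = np.isfinite(gini)
    if config.strict:
        ok &= gini < config.gini_threshold
    else:
        ok &= gini <= config.gini_threshold
    if config.min_median > 0:
        ok &= records["median"].to_numpy(dtype=float) >= config.min_median
    return set(records.loc[ok, "gene"].astype(str))


def intersect_datasets(
    filtered_sets: Mapping[str, set] | Sequence[tuple[str, set]],
) -> IntersectionTable:
    """Membership grid and pattern counts over two or more named gene sets."""
    if not isinstance(filtered_sets, Mapping):
        names = [name for name, _ in filtered_sets]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate dataset names in {names}")
        filtered_sets = dict(filtered_sets)
    if len(filtered_sets) < 2:
        raise ValueError("need at least 2 datasets to intersect")

    datasets = list(filtered_sets)
    union = sorted({str(g) for s in filtered_sets.values() for g in s})
    grid = pd.DataFrame(
        {d: [g in filtered_sets[d] for g in union] for d in datasets},
        index=pd.Index(union, name="gene"),
    )
    patterns = (
        grid.groupby(datasets, sort=False)
        .size()
        .rename("count")
        .reset_index()
    )
    patterns["degree"] = patterns[datasets].sum(axis=1)
    patterns = patterns.sort_values(
        ["degree", "count"], ascending=[False, False], kind="stable"
    ).reset_index(drop=True)
    shared_all = {g for g in union if grid.loc[g].all()}
    return IntersectionTable(membership=grid, pattern_counts=patterns, shared_all=shared_all)


def rank_candidates(
    records: pd.DataFrame,
    config: SelectionConfig | None = None,
    panels: PanelAnnotation | None = None,
) -> pd.DataFrame:
    """Ranked candidate list: ascending GC, ties broken by descending
    median expression then lexicographic gene id, truncated to ``top_n``.

    When *panels* is given, each row is annotated with the gene's panel
    memberships.
    """
    config = config or SelectionConfig()
    if records.empty:
        raise ValueError("cannot rank an empty stability table")
    out = records.copy()
    out["gene"] = out["gene"].astype(str)
    out = out.sort_values(
        ["gini", "median", "gene"], ascending=[True, False, True], kind="stable"
    ).head(config.top_n)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    if panels is not None:
        out["panels"] = [panels.label(g) for g in out["gene"]]
    return out.reset_index(drop=True)


def top_expressed(records: pd.DataFrame, n: int) -> set[str]:
    """The *n* genes with the highest median expression (ties broken by
    gene id).  Composes with :func:`intersect_datasets` to find the
    top-expressing genes shared across datasets."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if records.empty:
        raise ValueError("cannot select from an empty stability table")
    if n > len(records):
        warnings.warn(
            f"requested top {n} genes but table has only {len(records)}; returning all",
            stacklevel=2,
        )
        n = len(records)
    ordered = records.assign(gene=records["gene"].astype(str)).sort_values(
        ["median", "gene"], ascending=[False, True], kind="stable"
    )
    return set(ordered["gene"].head(n))


def write_intersection(table: IntersectionTable, out_dir: str | Path, prefix: str = "intersection") -> None:
    """Write membership and pattern-count TSVs (UpSet-compatible)."""
    out_dir = Path(out_dir)
    table.membership.to_csv(out_dir / f"{prefix}_membership.tsv", sep="\t")
    table.pattern_counts.to_csv(out_dir / f"{prefix}_patterns.tsv", sep="\t", index=False)
    with open(out_dir / f"{prefix}_shared_all.txt", "w") as handle:
        for gene in sorted(table.shared_all):
            handle.write(gene + "\n")
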