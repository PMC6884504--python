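"""RT-qPCR expression-stability analysis.

Pipeline (each stage feeds the next, no hidden state):

1. average technical replicates per (gene, cell line) to a mean Cq;
2. censor pairs whose mean Cq exceeds the expression cutoff (default 32
   cycles — beyond it no expression is considered observed; exactly 32
   still counts as expressed);
3. convert expressed mean Cq to a relative expression level
   ``cutoff / Cq`` (so higher expression — lower Cq — gives a larger
   value, and the cutoff itself maps to 1);
4. per-gene descriptive statistics across cell lines, including the Gini
   coefficient over the per-line expression values.

Two comparators are provided on top of the same censored Cq values:

* the ΔCq transform ``R = 2^-(Cq - min Cq in panel)``, mapping each gene's
  best-expressing line to R = 1 under the perfect-doubling assumption
  (amplification efficiency 2.0 per cycle);
* a geNorm-style stability ranking: pairwise variation V_jk = SD over
  samples of log2(a_j / a_k), M_j = mean of V_jk over partners, and
  stepwise exclusion of the least stable gene until two remain.

Note that ``cutoff/Cq`` and ``2^-dCq`` are different transforms of the
same data; both are emitted, labelled, and never mixed within a statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, MalformedDataError, UndefinedStatisticError
from .gini import stability_metrics

__all__ = [
    "CqTable",
    "GeNormResult",
    "read_cq_tsv",
    "aggregate_replicates",
    "apply_cq_cutoff",
    "relative_expression_from_cq",
    "qpcr_gene_stability",
    "delta_cq_relative",
    "genorm_m_values",
    "genorm_stepwise",
]

DEFAULT_CUTOFF = 32.0
#: Replicate range (cycles) beyond which a (gene, line) pair is flagged as
#: discordant.  Flag only — replicates are never auto-dropped.
DEFAULT_CONCORDANCE_LIMIT = 0.5


@dataclass
class CqTable:
    """Replicate-level quantification cycles.

    ``data`` is a long-format frame with columns ``gene``, ``cell_line``,
    ``replicate``, ``cq``; every Cq must be positive.
    """

    data: pd.DataFrame
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        required = {"gene", "cell_line", "replicate", "cq"}
        missing = required - set(self.data.columns)
        if missing:
            raise MalformedDataError(f"Cq table missing columns {sorted(missing)}")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        bad = self.data[self.data["cq"] <= 0]
        if len(bad):
            row = bad.iloc[0]
            raise MalformedDataError(
                f"non-positive Cq {row['cq']} for gene {row['gene']!r}, "
                f"cell line {row['cell_line']!r}"
            )

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].astype(str).unique())

    @property
    def cell_lines(self) -> list[str]:
        return sorted(self.data["cell_line"].astype(str).unique())


@dataclass
class GeNormResult:
    """geNorm stability analysis output.

    ``pairwise_variation`` is the symmetric gene x gene matrix of SDs of
    log2 expression ratios (zero diagonal); ``m_values`` the initial M of
    every gene.  After stepwise exclusion, ``exclusion_order`` lists genes
    from least to most stable (the final two are tied at rank 1) and
    ``normalization_factor`` is the per-sample geometric mean of the final
    pair.
    """

    pairwise_variation: pd.DataFrame
    m_values: pd.Series
    exclusion_order: list[str] = field(default_factory=list)
    final_pair: tuple[str, str] | None = None
    normalization_factor: pd.Series | None = None

    def ranking(self) -> pd.DataFrame:
        """Stability ranking table, most stable first; final pair tied."""
        if not self.exclusion_order:
            raise ValueError("run genorm_stepwise for a ranking")
        rows = []
        n = len(self.exclusion_order)
        for i, gene in enumerate(reversed(self.exclusion_order)):
            rank = 1 if i < 2 else i  # final two share rank 1
            rows.append({"gene": gene, "rank": rank})
        assert len(rows) == n
        return pd.DataFrame(rows)


def read_cq_tsv(path: str | Path, cutoff: float = DEFAULT_CUTOFF) -> CqTable:
    """Read a long-format replicate-level Cq TSV
    (``gene<TAB>cell_line<TAB>replicate<TAB>cq``)."""
    df = pd.read_csv(path, sep="\t")
    return CqTable(data=df, cutoff=cutoff)


def write_cq_tsv(table: CqTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def aggregate_replicates(
    table: CqTable, concordance_limit: float = DEFAULT_CONCORDANCE_LIMIT
) -> pd.DataFrame:
    """Arithmetic mean Cq per (gene, cell line) over technical replicates.

    Returns one row per pair with ``mean_cq``, ``sd_cq`` (NaN for a single
    replicate), ``n_replicates`` and a ``discordant`` flag set when the
    replicate range exceeds *concordance_limit* cycles.
    """
    grouped = table.data.groupby(["gene", "cell_line"], sort=True)["cq"]
    out = grouped.agg(
        mean_cq="mean",
        sd_cq=lambda v: v.std(ddof=1),
        n_replicates="count",
        cq_range=lambda v: v.max() - v.min(),
    ).reset_index()
    out["discordant"] = out["cq_range"] > concordance_limit
    return out.drop(columns="cq_range")


def apply_cq_cutoff(mean_cq: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Censor pairs with mean Cq above the cutoff.

    Adds an ``expressed`` column and sets ``mean_cq`` of censored pairs to
    missing (never clamped to the cutoff).  A mean Cq exactly at the
    cutoff is retained.  The number of censored pairs is recorded in the
    frame's ``attrs['n_censored']``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    out = mean_cq.copy()
    expressed = out["mean_cq"] <= cutoff
    out["expressed"] = expressed
    out.loc[~expressed, "mean_cq"] = np.nan
    out.attrs["n_censored"] = int((~expressed).sum())
    return out


def relative_expression_from_cq(mean_cq, cutoff: float = DEFAULT_CUTOFF):
    """Relative expression level ``cutoff / Cq``.

    Accepts a scalar or array; values above the cutoff (not expressed)
    come back as NaN rather than a number.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    arr = np.asarray(mean_cq, dtype=float)
    flat = np.atleast_1d(arr)
    if (flat[~np.isnan(flat)] <= 0).any():
        raise MalformedDataError("Cq values must be positive")
    with np.errstate(divide="ignore"):
        rel = np.where(arr <= cutoff, cutoff / arr, np.nan)
    if arr.ndim == 0:
        return float(rel)
    return rel


def _relative_matrix(table: CqTable, concordance_limit: float = DEFAULT_CONCORDANCE_LIMIT) -> pd.DataFrame:
    """genes x cell-lines relative-expression matrix (cutoff/Cq), censored
    pairs missing."""
    agg = aggregate_replicates(table, concordance_limit)
    cut = apply_cq_cutoff(agg, table.cutoff)
    cut["relative"] = relative_expression_from_cq(cut["mean_cq"].to_numpy(), table.cutoff)
    return cut.pivot(index="gene", columns="cell_line", values="relative")


def qpcr_gene_stability(
    relative: pd.DataFrame,
    min_lines: int = 2,
    min_expressed_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-line stability statistics per gene from a genes x cell-lines
    relative-expression matrix (missing = not expressed).

    Returns ``(summary, excluded)``.  Genes expressed in fewer than
    *min_lines* lines are excluded with a reason; genes expressed in less
    than *min_expressed_fraction* of the panel are kept but flagged
    ``low_coverage`` (stably detected in only part of the panel is itself
    evidence against a reference gene).
    """
    rows: list[dict] = []
    excluded: list[dict] = []
    n_panel = relative.shape[1]
    for gene, row in relative.iterrows():
        vals = row.to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size < min_lines:
            excluded.append(
                {"gene": gene, "n_lines_expressed": int(vals.size),
                 "reason": "expressed-in-too-few-lines"}
            )
            continue
        rec = stability_metrics(vals, gene=str(gene))
        rows.append(
            {
                "gene": str(gene),
                "n_lines_expressed": int(vals.size),
                "median_relative": rec.median,
                "gini": rec.gini,
                "rsd_percent": rec.rsd_percent,
                "iqr_ratio": rec.iqr_ratio,
                "low_coverage": vals.size < min_expressed_fraction * n_panel,
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=["gene", "n_lines_expressed", "median_relative", "gini",
                 "rsd_percent", "iqr_ratio", "low_coverage"],
    )
    excluded_df = pd.DataFrame(
        excluded, columns=["gene", "n_lines_expressed", "reason"]
    )
    return summary, excluded_df


def delta_cq_relative(mean_cq: pd.DataFrame) -> pd.DataFrame:
    """ΔCq transform per gene across a panel of cell lines.

    *mean_cq* is a genes x cell-lines matrix of expressed mean Cq values
    (missing = not expressed).  For each gene, ΔCq = Cq - min Cq over the
    panel and R = 2^-ΔCq, so ΔCq >= 0, R in (0, 1] and the line at the
    panel minimum has R exactly 1.  Not-expressed entries stay missing.
    """
    out_rows = []
    for gene, row in mean_cq.iterrows():
        vals = row.to_numpy(dtype=float)
        finite = ~np.isnan(vals)
        if finite.sum() < 2:
            raise InsufficientDataError(
                f"gene {gene!r}: need >= 2 expressed lines for the ΔCq transform"
            )
        dcq = vals - np.nanmin(vals)
        r = np.power(2.0, -dcq)
        for line, d, rr in zip(mean_cq.columns, dcq, r):
            if not np.isnan(d):
                out_rows.append(
                    {"gene": str(gene), "cell_line": str(line),
                     "delta_cq": float(d), "relative_value": float(rr)}
                )
    return pd.DataFrame(out_rows, columns=["gene", "cell_line", "delta_cq", "relative_value"])


def _check_genorm_input(relative: pd.DataFrame) -> np.ndarray:
    arr = relative.to_numpy(dtype=float)
    if relative.shape[0] < 3:
        raise InsufficientDataError("geNorm needs at least 3 genes")
    if relative.shape[1] < 2:
        raise InsufficientDataError("geNorm needs at least 2 samples")
    if np.isnan(arr).any() or (arr <= 0).any():
        raise UndefinedStatisticError(
            "geNorm requires strictly positive expression for every gene in "
            "every sample (log ratios are undefined otherwise)"
        )
    return arr


def genorm_m_values(relative: pd.DataFrame) -> GeNormResult:
    """Pairwise variation matrix V and gene stability measure M.

    V_jk is the sample SD (over samples) of log2(a_j / a_k); M_j is the
    arithmetic mean of V_jk over all partners k != j.  Lower M = more
    stable.  M is invariant to rescaling any gene by a positive constant.
    """
    arr = _check_genorm_input(relative)
    logx = np.log2(arr)
    n_genes = arr.shape[0]
    v = np.zeros((n_genes, n_genes))
    for j in range(n_genes):
        for k in range(j + 1, n_genes):
            sd = np.std(logx[j] - logx[k], ddof=1)
            v[j, k] = v[k, j] = sd
    m = v.sum(axis=1) / (n_genes - 1)
    genes = relative.index.astype(str)
    return GeNormResult(
        pairwise_variation=pd.DataFrame(v, index=genes, columns=genes),
        m_values=pd.Series(m, index=genes, name="M"),
    )


def genorm_stepwise(relative: pd.DataFrame) -> GeNormResult:
    """Full geNorm ranking by stepwise exclusion.

    Repeatedly removes the gene with the highest M (ties broken by gene
    id) and recomputes M on the remainder until two genes are left; those
    two are reported as the tied most-stable pair, and the per-sample
    geometric mean of their values is the normalisation factor.
    """
    _check_genorm_input(relative)
    base = genorm_m_values(relative)
    current = relative.copy()
    current.index = current.index.astype(str)
    exclusion: list[str] = []
    while current.shape[0] > 2:
        m = genorm_m_values(current).m_values
        # highest M leaves; ties resolved lexicographically for determinism
        worst = m.loc[m == m.max()].index.min()
        exclusion.append(worst)
        current = current.drop(index=worst)
    pair = tuple(sorted(current.index))
    exclusion.extend(pair)
    nf = pd.Series(
        np.exp(np.mean(np.log(current.to_numpy(dtype=float)), axis=0)),
        index=relative.columns,
        name="normalization_factor",
    )
    return GeNormResult(
        pairwise_variation=base.pairwise_variation,
        m_values=base.m_values,
        exclusion_order=exclusion,
        final_pair=pair,  # type: ignore[arg-type]
        normalization_factor=nf,
    )


def run_qpcr_pipeline(
    table: CqTable,
    min_lines: int = 2,
    min_expressed_fraction: float = 0.5,
    concordance_limit: float = DEFAULT_CONCORDANCE_LIMIT,
    genorm: bool = False,
) -> dict:
    """End-to-end qPCR workflow: replicate mean -> cutoff -> relative
    expression -> per-gene cross-line statistics (+ ΔCq, optionally geNorm
    on the fully expressed gene subset).

    Returns a dict with keys ``aggregated``, ``relative``, ``summary``,
    ``excluded``, ``delta_cq`` and (if requested) ``genorm``.
    """
    agg = aggregate_replicates(table, concordance_limit)
    censored = apply_cq_cutoff(agg, table.cutoff)
    cq_matrix = censored.pivot(index="gene", columns="cell_line", values="mean_cq")
    rel = pd.DataFrame(
        relative_expression_from_cq(cq_matrix.to_numpy(), table.cutoff),
        index=cq_matrix.index,
        columns=cq_matrix.columns,
    )
    summary, excluded = qpcr_gene_stability(rel, min_lines, min_expressed_fraction)
    expressed_enough = cq_matrix.dropna(axis=0, how="any")
    dcq = delta_cq_relative(cq_matrix.loc[cq_matrix.notna().sum(axis=1) >= 2])
    result = {
        "aggregated": censored,
        "relative": rel,
        "summary": summary,
        "excluded": excluded,
        "delta_cq": dcq,
    }
    if genorm:
        rel_full = rel.loc[expressed_enough.index]
        result["genorm"] = genorm_stepwise(rel_full)
    return result
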