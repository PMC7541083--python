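"""RNA-seq screen for genes expressed most (or least) in one focal cell type.

TPM values are summed across splice variants per gene, log10-transformed
with zeros floored at log10 = -2 (TPM 0.01, below the dataset minimum of
0.1), and averaged across biological replicates per cell type — i.e. the
geometric mean of TPM.  A gene passes the screen when the focal type's mean
strictly exceeds (or undercuts) every other cell type's.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "aggregate_gene_expression",
    "screen_focal_extremes",
    "filter_low_expression",
    "LOG10_ZERO_FLOOR",
]

#: log10 assigned to TPM = 0 (corresponds to TPM 0.01)
LOG10_ZERO_FLOOR = -2.0


def _check_table(table):
    if not isinstance(table.columns, pd.MultiIndex) or table.columns.nlevels != 2:
        raise ValueError(
            "expression table needs MultiIndex columns (cell type, replicate)"
        )
    if (table.to_numpy() < 0).any():
        raise ValueError("negative TPM values")


def aggregate_gene_expression(table: pd.DataFrame, gene_of=None, zero_floor=LOG10_ZERO_FLOOR):
    """Gene x cell-type matrix of mean log10(TPM).

    ``table`` is transcripts x (cell type, replicate) TPM with a two-level
    column MultiIndex; ``gene_of`` maps transcript index -> gene id (omit if
    rows are already genes).  Splice variants are summed on the TPM scale,
    zeros floored at ``zero_floor`` after log10, and replicate log10 values
    averaged per cell type (the geometric mean of TPM).
    """
    _check_table(table)
    if gene_of is not None:
        genes = table.index.map(dict(gene_of) if not callable(gene_of) else gene_of)
        table = table.groupby(genes.values).sum()
    vals = table.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.where(vals > 0, np.log10(np.where(vals > 0, vals, 1.0)), zero_floor)
    logged = pd.DataFrame(logs, index=table.index, columns=table.columns)
    return logged.T.groupby(level=0).mean().T


def screen_focal_extremes(matrix: pd.DataFrame, focal="APL", direction="higher"):
    """Genes where the focal type's mean log10(TPM) strictly beats all others.

    ``direction="higher"`` keeps genes with focal > every other type;
    ``"lower"`` keeps focal < every other.  Ties fail the strict comparison.
    Returns the gene index (and its length is the screen count).
    """
    if focal not in matrix.columns:
        raise KeyError(f"focal cell type {focal!r} not in matrix")
    if matrix.shape[1] < 2:
        raise ValueError("need at least two cell types")
    focal_col = matrix[focal]
    others = matrix.drop(columns=[focal])
    if direction == "higher":
        keep = focal_col > others.max(axis=1)
    elif direction == "lower":
        keep = focal_col < others.min(axis=1)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return matrix.index[keep]


def filter_low_expression(table: pd.DataFrame, genes, focal="APL", threshold_tpm=1.0,
                          gene_of=None):
    """Drop genes weakly expressed outside the focal type.

    Keeps genes whose mean TPM (TPM scale, not log) across all non-focal
    cell types is >= ``threshold_tpm``.  ``table`` is the raw transcript (or
    gene) x (cell type, replicate) TPM table.
    """
    _check_table(table)
    if threshold_tpm < 0:
        raise ValueError("threshold must be non-negative")
    if gene_of is not None:
        g = table.index.map(dict(gene_of) if not callable(gene_of) else gene_of)
        table = table.groupby(g.values).sum()
    per_type = table.T.groupby(level=0).mean().T  # mean TPM per cell type
    non_focal_mean = per_type.drop(columns=[focal]).mean(axis=1)
    keep = [g for g in genes if non_focal_mean.loc[g] >= threshold_tpm]
    return pd.Index(keep)
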