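"""Expression preprocessing: cell filtering, normalization, relative
expression (fold change) and per-sample gene ranking.

Without control samples, the expected expression of a gene is taken to be its
median logged expression across all samples/cells in the run; the analysis
then works on the relative expression ``fc[g, s] = log_expr[g, s] -
median_s(log_expr[g, ·])``.  The median is a surrogate for the unrepressed
state: genes that are off in most cells do not rank extreme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._io import PathLike, open_text

log = logging.getLogger(__name__)

LAYER_COUNTS = "counts"
LAYER_LOG = "log_expression"


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values plus a layer tag.

    ``layer`` is ``"counts"`` (non-negative raw counts) or
    ``"log_expression"`` (already normalised and logged, e.g. bulk input).
    """

    values: pd.DataFrame  # index: gene ids, columns: sample/cell ids
    layer: str = LAYER_COUNTS

    def __post_init__(self) -> None:
        if self.layer not in (LAYER_COUNTS, LAYER_LOG):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.layer == LAYER_COUNTS and (self.values.to_numpy() < 0).any():
            raise ValueError("counts layer contains negative values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class RankedGeneList:
    """One sample's genes ordered ascending by fold change (most repressed first).

    ``gene_ids`` is the stable full ordering (fold-change ascending, ties
    broken by gene id) used by walk-based statistics; ``midranks`` are the
    tie-averaged ranks of the same genes, aligned to ``gene_ids``, used by
    rank-sum statistics.
    """

    sample_id: str
    gene_ids: np.ndarray  # ordered gene identifiers
    fold_change: np.ndarray  # fold-change values in that order
    midranks: np.ndarray  # midranks aligned with gene_ids


def filter_cells(matrix: ExpressionMatrix, min_total: int = 1000) -> ExpressionMatrix:
    """Drop cells with total mapped reads below ``min_total`` (>= kept)."""
    if matrix.layer != LAYER_COUNTS:
        raise ValueError("filter_cells expects a counts layer")
    totals = matrix.values.sum(axis=0)
    keep = totals >= min_total
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("filter_cells: removed %d of %d cells with < %d reads",
                 n_dropped, len(keep), min_total)
    if not keep.any():
        raise ValueError(f"all {len(keep)} cells fall below min_total={min_total}")
    return ExpressionMatrix(matrix.values.loc[:, keep], layer=LAYER_COUNTS)


def normalize_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Depth-normalise and log: v -> log2(v / total_cell * max_total + 1).

    Each cell is scaled to the sequencing depth of the deepest cell, a
    pseudocount of one is added, and values are logged base 2.
    """
    if matrix.layer != LAYER_COUNTS:
        raise ValueError("normalize_counts expects a counts layer")
    totals = matrix.values.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero-total cells reached normalization: {bad[:5]}")
    max_total = float(totals.max())
    scaled = matrix.values * (max_total / totals)
    logged = np.log2(scaled + 1.0)
    return ExpressionMatrix(logged, layer=LAYER_LOG)


def fold_changes(
    matrix: ExpressionMatrix, min_samples: int = 3, allow_few: bool = False
) -> pd.DataFrame:
    """Relative expression: logged expression minus per-gene median across samples."""
    if matrix.layer != LAYER_LOG:
        raise ValueError("fold_changes expects a log_expression layer")
    n = matrix.values.shape[1]
    if n < min_samples and not allow_few:
        raise ValueError(
            f"only {n} samples; a cross-sample median needs >= {min_samples} "
            "(pass allow_few=True to override)"
        )
    medians = matrix.values.median(axis=1)
    return matrix.values.sub(medians, axis=0)


def rank_genes(fold_change_column: pd.Series, sample_id: str | None = None) -> RankedGeneList:
    """Rank one sample's genes ascending by fold change (rank 1 = most repressed).

    Ordering ties are broken lexicographically by gene id (stable across input
    order); midranks average over fold-change ties.
    """
    genes = fold_change_column.index.to_numpy(dtype=object)
    values = fold_change_column.to_numpy(dtype=float)
    order = np.lexsort((genes, values))
    midranks_all = rankdata(values, method="average")
    return RankedGeneList(
        sample_id=sample_id if sample_id is not None else str(fold_change_column.name),
        gene_ids=genes[order],
        fold_change=values[order],
        midranks=midranks_all[order],
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_tsv(path: PathLike, layer: str = LAYER_COUNTS) -> ExpressionMatrix:
    """Read a genes × samples TSV (header row; first column gene ids)."""
    df = pd.read_csv(open_text(path), sep="\t", index_col=0)
    return ExpressionMatrix(df, layer=layer)


def read_expression_mtx(
    matrix_path: PathLike,
    genes_path: PathLike,
    barcodes_path: PathLike,
    layer: str = LAYER_COUNTS,
) -> ExpressionMatrix:
    """Read an MTX triplet (MatrixMarket matrix + gene list + barcode list).

    The gene and barcode files are one identifier per line (first tab field
    used, so CellRanger-style two-column files also work).
    """
    from scipy.io import mmread

    mat = mmread(open_text(matrix_path)).toarray()
    with open_text(genes_path) as fh:
        genes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    with open_text(barcodes_path) as fh:
        barcodes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"MTX shape {mat.shape} does not match {len(genes)} genes x {len(barcodes)} barcodes"
        )
    return ExpressionMatrix(pd.DataFrame(mat, index=genes, columns=barcodes), layer=layer)


def write_expression_tsv(df: pd.DataFrame, path: PathLike) -> None:
    with open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index_label="gene_id")
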