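"""Per-cell gene-set module scores with expression-binned control genes.

The score of a cell for a gene set is the mean log-normalized expression of
the set genes minus the mean expression of control genes sampled from the
same average-expression bins — the classic module-scoring scheme used by
single-cell toolkits.  Binned controls remove the component of the set mean
that is explained by overall expression level, so the score reads as
enrichment relative to transcriptionally comparable genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io_formats import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = ["qc_filter", "log_normalize", "module_score", "QCReport"]


@dataclass
class QCReport:
    n_input: int
    n_removed_counts: int
    n_removed_genes: int
    n_removed_mito: int
    n_kept: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def qc_filter(
    matrix: ExpressionMatrix,
    min_counts: float = 0,
    min_genes: int = 0,
    max_pct_mito: float = 100.0,
    mito_prefix: str = "mt-",
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove low-quality cells from a raw count matrix.

    A cell is kept when its total counts are >= ``min_counts``, its number of
    detected genes is >= ``min_genes``, and the percentage of counts in
    mitochondrial genes (symbols starting with ``mito_prefix``) is
    <= ``max_pct_mito``.  Removal counts are reported per criterion (a cell
    failing several criteria is counted under each).
    """
    if matrix.layer != "raw":
        raise ValueError("qc_filter expects the raw count layer")
    X = matrix.counts
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    mito_idx = [i for i, g in enumerate(matrix.genes) if g.startswith(mito_prefix)]
    if mito_idx:
        mito_counts = np.asarray(X[:, mito_idx].sum(axis=1)).ravel()
    else:
        mito_counts = np.zeros(matrix.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(totals > 0, 100.0 * mito_counts / np.maximum(totals, 1), 0.0)

    pass_counts = totals >= min_counts
    pass_genes = n_genes >= min_genes
    pass_mito = pct_mito <= max_pct_mito
    keep = pass_counts & pass_genes & pass_mito
    report = QCReport(
        n_input=matrix.n_cells,
        n_removed_counts=int((~pass_counts).sum()),
        n_removed_genes=int((~pass_genes).sum()),
        n_removed_mito=int((~pass_mito).sum()),
        n_kept=int(keep.sum()),
    )
    if report.n_kept == 0:
        raise ValueError(
            "qc_filter removed every cell; review thresholds "
            f"(min_counts={min_counts}, min_genes={min_genes}, max_pct_mito={max_pct_mito})"
        )
    return matrix.subset_cells(keep), report


def log_normalize(matrix: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then log(1 + x).

    All-zero cells are left all-zero (with a warning).  Within a cell the
    transform is monotone, so gene ordering is preserved.
    """
    if matrix.layer != "raw":
        raise ValueError("log_normalize expects the raw count layer")
    X = sp.csr_matrix(matrix.counts, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("log_normalize: %d all-zero cells left all-zero", n_zero)
    scale = np.where(totals > 0, target_sum / np.maximum(totals, 1e-300), 0.0)
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    return ExpressionMatrix(
        genes=list(matrix.genes), cells=list(matrix.cells), counts=X, layer="lognorm"
    )


def module_score(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Module score of every cell for one gene set.

    Genes are ranked by mean expression across all cells (ties broken by
    gene-list order) and cut into ``n_bins`` equal-size bins.  For every set
    gene, ``n_ctrl`` control genes are sampled without replacement from its
    bin, excluding all set genes; the score of a cell is the mean expression
    of the set genes minus the mean over all sampled controls (pooled, with
    multiplicity).  One seeded stream per call makes the sampling
    reproducible.

    A bin holding fewer than ``n_ctrl`` eligible genes is sampled with
    replacement (warned).  Raises if no set gene is present in the matrix.
    """
    if matrix.layer != "lognorm":
        raise ValueError("module_score expects log-normalized expression")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    gene_pos = {g: i for i, g in enumerate(matrix.genes)}
    present = [g for g in gene_set.genes if g in gene_pos]
    if not present:
        raise ValueError(
            f"no genes of set {gene_set.name!r} present in matrix; "
            f"missing: {', '.join(gene_set.genes)}"
        )
    missing = [g for g in gene_set.genes if g not in gene_pos]
    if missing:
        logger.warning(
            "module_score(%s): %d set genes absent from matrix", gene_set.name, len(missing)
        )

    X = matrix.counts
    means = np.asarray(X.mean(axis=0)).ravel()
    order = np.argsort(means, kind="stable")  # stable sort = ties by gene-list order
    rank = np.empty(matrix.n_genes, dtype=np.int64)
    rank[order] = np.arange(matrix.n_genes)
    bins = rank * n_bins // matrix.n_genes

    set_idx = np.array([gene_pos[g] for g in present])
    set_mask = np.zeros(matrix.n_genes, dtype=bool)
    set_mask[set_idx] = True

    rng = np.random.default_rng(seed)
    ctrl_parts = []
    n_short_bins = 0
    for gi in set_idx:
        candidates = np.flatnonzero((bins == bins[gi]) & ~set_mask)
        if len(candidates) == 0:
            raise ValueError(
                f"no eligible control genes in expression bin of gene {matrix.genes[gi]!r}"
            )
        if len(candidates) < n_ctrl:
            n_short_bins += 1
            ctrl_parts.append(rng.choice(candidates, size=n_ctrl, replace=True))
        else:
            ctrl_parts.append(rng.choice(candidates, size=n_ctrl, replace=False))
    if n_short_bins:
        logger.warning(
            "module_score(%s): %d of %d set genes sit in bins with fewer than "
            "%d eligible controls; sampled those with replacement",
            gene_set.name, n_short_bins, len(set_idx), n_ctrl,
        )
    ctrl_idx = np.concatenate(ctrl_parts)

    set_mean = np.asarray(X[:, set_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(X[:, ctrl_idx].mean(axis=1)).ravel()
    return set_mean - ctrl_mean
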