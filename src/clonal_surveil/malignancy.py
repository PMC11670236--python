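"""Malignant / nonmalignant classification of gated plasma cells.

Plasma cells are gated by marker expression (any of Sdc1/Xbp1/Prdm1, and not
Cd19), scored for two gene signatures, and classified by a dual-percentile
rule: a cell is called malignant when its malignant-signature score is in the
top 20% and its nonmalignant score in the bottom 20%; the mirror condition
defines nonmalignant; everything else stays unclassified.  The compound
score (malignant minus nonmalignant) summarizes each cell on one axis, and
its distribution shift between treated and untreated groups is the treatment
readout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sps

from .io_formats import ExpressionMatrix
from .stats_core import TestReport, bh_fdr, mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "GateRule",
    "ClassificationParams",
    "gate_plasma_cells",
    "classify_cells",
    "compound_distribution",
    "compare_groups",
    "differential_expression",
]


@dataclass
class GateRule:
    """Marker-expression gate: keep cells expressing at least one required
    gene above ``min_expression`` and none of the excluded genes above it."""

    required_any: list[str] = field(default_factory=lambda: ["Sdc1", "Xbp1", "Prdm1"])
    excluded: list[str] = field(default_factory=lambda: ["Cd19"])
    min_expression: float = 0.0

    def __post_init__(self) -> None:
        if not self.required_any:
            raise ValueError("gate rule needs at least one required gene")


@dataclass
class ClassificationParams:
    upper_quantile: float = 0.80
    lower_quantile: float = 0.20
    hist_bin_width: float = 0.2
    compound_sign: int = 1  # +1: malignant - nonmalignant; -1 flips

    def __post_init__(self) -> None:
        if not (0.0 < self.lower_quantile < self.upper_quantile < 1.0):
            raise ValueError("need 0 < lower_quantile < upper_quantile < 1")
        if self.hist_bin_width <= 0:
            raise ValueError("hist_bin_width must be positive")
        if self.compound_sign not in (1, -1):
            raise ValueError("compound_sign must be +1 or -1")


def gate_plasma_cells(matrix: ExpressionMatrix, rule: GateRule | None = None) -> np.ndarray:
    """Boolean mask over cells passing the plasma-cell gate.

    Rule genes absent from the matrix are skipped with a warning.  An empty
    gate result warns (downstream steps should skip the sample).
    """
    rule = rule or GateRule()
    if matrix.layer != "lognorm":
        raise ValueError("gate_plasma_cells expects log-normalized expression")
    gene_pos = {g: i for i, g in enumerate(matrix.genes)}
    req = [gene_pos[g] for g in rule.required_any if g in gene_pos]
    for g in rule.required_any:
        if g not in gene_pos:
            logger.warning("gate: required gene %s absent, skipped", g)
    exc = [gene_pos[g] for g in rule.excluded if g in gene_pos]
    for g in rule.excluded:
        if g not in gene_pos:
            logger.warning("gate: excluded gene %s absent, skipped", g)
    if not req:
        raise ValueError("none of the required gate genes are present in the matrix")
    X = matrix.counts
    dense_req = np.asarray(X[:, req].todense())
    mask = (dense_req > rule.min_expression).any(axis=1)
    if exc:
        dense_exc = np.asarray(X[:, exc].todense())
        mask &= ~(dense_exc > rule.min_expression).any(axis=1)
    mask = np.asarray(mask).ravel()
    if not mask.any():
        logger.warning("gate selected no cells")
    return mask


def classify_cells(scores: pd.DataFrame, params: ClassificationParams | None = None) -> pd.DataFrame:
    """Apply the dual-percentile malignant / nonmalignant classification.

    ``scores`` needs columns ``malignant_score`` and ``nonmalignant_score``.
    Returns a copy with ``compound_score`` and ``label`` columns added.
    Quantiles are linear-interpolation quantiles over the cells in the table
    (pooled across samples); comparisons at the quantile boundaries are
    inclusive.
    """
    params = params or ClassificationParams()
    if len(scores) < 5:
        raise ValueError("need at least 5 cells to classify (quantiles meaningless below)")
    m = scores["malignant_score"].to_numpy(dtype=float)
    n = scores["nonmalignant_score"].to_numpy(dtype=float)
    m_hi = np.quantile(m, params.upper_quantile)
    m_lo = np.quantile(m, params.lower_quantile)
    n_hi = np.quantile(n, params.upper_quantile)
    n_lo = np.quantile(n, params.lower_quantile)
    label = np.full(len(scores), "unclassified", dtype=object)
    label[(m >= m_hi) & (n <= n_lo)] = "malignant"
    label[(m <= m_lo) & (n >= n_hi)] = "nonmalignant"
    out = scores.copy()
    out["compound_score"] = params.compound_sign * (m - n)
    out["label"] = label
    return out


def compound_distribution(
    scores: pd.DataFrame,
    params: ClassificationParams | None = None,
    group_col: str | None = "group",
) -> pd.DataFrame:
    """Histogram of compound scores in half-open bins anchored at zero.

    Bins are ``[k*w, (k+1)*w)``.  With a group column, per-group frequencies
    are expressed as percent of that group's cells (each group sums to 100).
    """
    params = params or ClassificationParams()
    df = scores.copy()
    if "compound_score" not in df.columns:
        df = classify_cells(df, params)
    w = params.hist_bin_width
    k = np.floor(df["compound_score"].to_numpy(dtype=float) / w).astype(int)
    df["_bin"] = k
    groups = [None] if group_col is None or group_col not in df.columns else sorted(
        df[group_col].unique()
    )
    lo, hi = k.min(), k.max()
    rows = []
    for kk in range(lo, hi + 1):
        row = {"bin_left": kk * w, "bin_right": (kk + 1) * w}
        for g in groups:
            sub = df if g is None else df[df[group_col] == g]
            cnt = int((sub["_bin"] == kk).sum())
            name = "count" if g is None else f"count_{g}"
            pname = "percent" if g is None else f"percent_{g}"
            row[name] = cnt
            row[pname] = 100.0 * cnt / len(sub) if len(sub) else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    scores: pd.DataFrame,
    group_col: str = "group",
    sample_col: str = "sample_id",
) -> dict:
    """Treated-vs-untreated comparison of compound scores.

    Returns a dict with the two-tailed Mann-Whitney report on the per-cell
    compound scores and, when labels and sample ids are available, the
    per-sample malignant-cell frequency table (malignant / gated cells).
    """
    groups = sorted(scores[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected two groups, found {groups}")
    a = scores.loc[scores[group_col] == groups[0], "compound_score"].to_numpy()
    b = scores.loc[scores[group_col] == groups[1], "compound_score"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    report = mann_whitney(a, b)
    out = {"groups": groups, "mann_whitney": report}
    if "label" in scores.columns and sample_col in scores.columns:
        freq = (
            scores.assign(_mal=scores["label"] == "malignant")
            .groupby([sample_col, group_col], observed=True)["_mal"]
            .agg(n_malignant="sum", n_gated="count")
            .reset_index()
        )
        freq["malignant_frequency"] = freq["n_malignant"] / freq["n_gated"]
        out["per_sample_malignant_frequency"] = freq
    return out


def differential_expression(
    matrix: ExpressionMatrix,
    groups,
    alpha_levels=(0.001, 0.05),
    chunk_size: int = 400,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene two-group differential expression on log-normalized values.

    Rank-sum (Mann-Whitney, tie-corrected normal approximation) per gene with
    Benjamini-Hochberg adjustment and log2 fold change of group means.
    Constant genes get p = 1 by convention and are flagged.  Returns the
    per-gene table and the counts of genes passing each alpha on adjusted p.
    """
    if matrix.layer != "lognorm":
        raise ValueError("differential_expression expects log-normalized expression")
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"expected two groups, found {levels}")
    ia = np.flatnonzero(groups == levels[0])
    ib = np.flatnonzero(groups == levels[1])
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError("each group needs at least 3 cells")

    n_genes = matrix.n_genes
    pvals = np.ones(n_genes)
    constant = np.zeros(n_genes, dtype=bool)
    mean_a = np.zeros(n_genes)
    mean_b = np.zeros(n_genes)
    Xa_all = matrix.counts[ia]
    Xb_all = matrix.counts[ib]
    for start in range(0, n_genes, chunk_size):
        sl = slice(start, min(start + chunk_size, n_genes))
        Xa = np.asarray(Xa_all[:, sl].todense())
        Xb = np.asarray(Xb_all[:, sl].todense())
        mean_a[sl] = Xa.mean(axis=0)
        mean_b[sl] = Xb.mean(axis=0)
        pooled_min = np.minimum(Xa.min(axis=0), Xb.min(axis=0))
        pooled_max = np.maximum(Xa.max(axis=0), Xb.max(axis=0))
        const = pooled_min == pooled_max
        constant[sl] = const
        if (~const).any():
            res = sps.mannwhitneyu(
                Xa[:, ~const], Xb[:, ~const], axis=0, method="asymptotic"
            )
            block = np.ones(const.size)
            block[~const] = res.pvalue
            pvals[sl] = block
    eps = 1e-9
    log2fc = np.log2((mean_a + eps) / (mean_b + eps))
    padj = bh_fdr(pvals)
    table = pd.DataFrame(
        {
            "gene": matrix.genes,
            f"mean_{levels[0]}": mean_a,
            f"mean_{levels[1]}": mean_b,
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "p_adjusted": padj,
            "constant": constant,
        }
    )
    counts = {alpha: int((padj < alpha).sum()) for alpha in alpha_levels}
    return table, counts
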