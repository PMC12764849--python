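"""Per-cell single-sample gene-set enrichment (ssGSEA) scoring.

For one cell, genes are ranked by decreasing expression; the rank statistic
assigns r = N to the top gene and r = 1 to the bottom. Walking down the
ordered gene list, the score accumulates the difference between a weighted
in-set ECDF and the uniform out-of-set ECDF:

    ES(S) = sum_i [ P_in(i) - P_out(i) ]
    P_in(i)  = sum_{g in S, pos(g) <= i} r_g^alpha / sum_{g in S} r_g^alpha
    P_out(i) = |{g not in S : pos(g) <= i}| / (N - |S|)

Summing the walk analytically (each gene's term is counted once per position
at or below it, i.e. r_g times) gives the closed form used here:

    ES(S) = sum_{g in S} r_g^(alpha+1) / sum_{g in S} r_g^alpha
            - sum_{g not in S} r_g / (N - |S|)

which is exactly the running sum for untied data and its expectation over
tie-consistent orderings when ties are present (ties, including the many
zeros of sparse data, receive average ranks). This makes scores invariant to
the input gene order, and lets the whole cell x set matrix be computed with
two matrix products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._exceptions import ConfigError, ValidationError
from .containers import ExpressionMatrix, GeneSetCollection, PathwayScoreMatrix

logger = logging.getLogger(__name__)


@dataclass
class SsgseaConfig:
    """Scoring options.

    alpha is the rank-weight exponent (0.25 is the conventional default;
    alpha = 0 weights all in-set genes equally). With ``normalize`` the whole
    score matrix is divided by its global max - min, mapping the observed
    range to width 1 while preserving ordering. Sets whose overlap with the
    expression panel falls outside [min_set_size, max_set_size] are dropped.
    """

    alpha: float = 0.25
    normalize: bool = True
    min_set_size: int = 2
    max_set_size: int = 1000

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigError("alpha must be >= 0")
        if self.min_set_size > self.max_set_size:
            raise ConfigError("min_set_size must be <= max_set_size")


def rank_statistic(values: np.ndarray) -> np.ndarray:
    """Descending average ranks for one cell: top gene N, bottom gene 1.

    Ties — including the zeros that dominate sparse single-nuclei data —
    receive the average of the ranks they span, so the statistic does not
    depend on the order genes happen to be listed in.
    """
    values = np.asarray(values, dtype=float)
    return rankdata(values, method="average")  # ascending avg rank == descending statistic


def ssgsea_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    cfg: SsgseaConfig | None = None,
) -> PathwayScoreMatrix:
    """Score every cell against every gene set.

    Sets with no overlap with the expression panel, or equal to the entire
    panel (the out-of-set ECDF is then undefined), are dropped with a
    warning; an empty surviving set list is an error.
    """
    cfg = cfg or SsgseaConfig()
    n_genes = expr.n_genes
    if n_genes < 2:
        raise ValidationError("ssGSEA needs at least 2 genes")
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}

    kept_names: list[str] = []
    columns: list[np.ndarray] = []
    sizes: list[int] = []
    for name, genes in sets:
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if not idx:
            logger.warning("gene set %r has no genes in the matrix; dropped", name)
            continue
        if len(idx) == n_genes:
            logger.warning("gene set %r covers all genes; dropped", name)
            continue
        if not (cfg.min_set_size <= len(idx) <= cfg.max_set_size):
            logger.warning(
                "gene set %r overlap size %d outside [%d, %d]; dropped",
                name, len(idx), cfg.min_set_size, cfg.max_set_size,
            )
            continue
        col = np.zeros(n_genes)
        col[idx] = 1.0
        kept_names.append(name)
        columns.append(col)
        sizes.append(len(idx))
    if not kept_names:
        raise ValidationError("no gene set survived filtering against the matrix")

    membership = np.column_stack(columns)  # genes x sets
    set_sizes = np.asarray(sizes, dtype=float)

    dense = expr.to_dense()
    ranks = np.vstack([rank_statistic(row) for row in dense])  # cells x genes
    w = ranks**cfg.alpha
    num_in = (w * ranks) @ membership          # sum_{g in S} r^(alpha+1)
    den_in = w @ membership                    # sum_{g in S} r^alpha
    total_r = ranks.sum(axis=1, keepdims=True)
    sum_out = total_r - ranks @ membership     # sum_{g not in S} r
    es = num_in / den_in - sum_out / (n_genes - set_sizes)

    if cfg.normalize:
        rng = es.max() - es.min()
        if rng > 0:
            es = es / rng
    scores = pd.DataFrame(es, index=expr.cell_ids, columns=kept_names)
    snapshot = {
        "alpha": cfg.alpha,
        "normalize": cfg.normalize,
        "min_set_size": cfg.min_set_size,
        "max_set_size": cfg.max_set_size,
        "statistic": "tie-symmetrized descending-rank running sum",
        "n_sets_scored": len(kept_names),
    }
    return PathwayScoreMatrix(scores, config=snapshot, scored_sets=kept_names)


def pathway_mean_expression(
    expr: ExpressionMatrix, sets: GeneSetCollection
) -> pd.DataFrame:
    """Per-cell mean log-normalized expression over each set's genes.

    A simple pathway summary on the expression scale; used when a response
    must stay in (log) expression units, e.g. when comparing fitted temporal
    slopes against slopes planted on gene log-means.
    """
    if expr.layer != "lognorm":
        raise ValidationError("pathway_mean_expression expects lognorm layer")
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    out = {}
    for name, genes in sets:
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if not idx:
            logger.warning("gene set %r has no genes in the matrix; dropped", name)
            continue
        out[name] = np.asarray(expr.values[:, idx].mean(axis=1)).ravel()
    return pd.DataFrame(out, index=expr.cell_ids)
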