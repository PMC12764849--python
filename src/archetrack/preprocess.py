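"""Cell-level QC filtering and library-size normalization."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._exceptions import ValidationError
from .containers import ExpressionMatrix, QcConfig, validate_metadata

logger = logging.getLogger(__name__)


def qc_filter(
    expr: ExpressionMatrix, meta: pd.DataFrame, cfg: QcConfig | None = None
):
    """Drop low-quality cells by detected-feature count and mitochondrial load.

    A cell is retained only if ``min_features < n_features < max_features``
    and ``pct_mt < max_pct_mt`` — all inequalities strict, so a cell sitting
    exactly on a threshold is removed. Returns the filtered matrix, the
    filtered metadata, and a report dict counting cells failing each
    criterion (a cell can fail several).
    """
    if expr.layer != "counts":
        raise ValidationError("qc_filter expects the counts layer")
    cfg = cfg or QcConfig()
    meta = validate_metadata(meta, expr.cell_ids)
    meta = meta.set_index("cell_id").loc[expr.cell_ids].reset_index()

    nf = meta["n_features"].to_numpy(dtype=float)
    mt = meta["pct_mt"].to_numpy(dtype=float)
    low = nf <= cfg.min_features
    high = nf >= cfg.max_features
    mito = mt >= cfg.max_pct_mt
    keep = ~(low | high | mito)

    report = {
        "n_input": expr.n_cells,
        "removed_low_features": int(low.sum()),
        "removed_high_features": int(high.sum()),
        "removed_high_mt": int(mito.sum()),
        "n_removed": int((~keep).sum()),
        "n_retained": int(keep.sum()),
        "config": {
            "min_features": cfg.min_features,
            "max_features": cfg.max_features,
            "max_pct_mt": cfg.max_pct_mt,
            "assumed_doublet_rate": cfg.assumed_doublet_rate,
        },
    }
    if report["n_retained"] == 0:
        logger.warning("QC filtering removed every cell; output is empty")
    filtered = expr.subset_cells(keep)
    return filtered, meta.loc[keep].reset_index(drop=True), report


def lognormalize(expr: ExpressionMatrix, scale_total: float = 1e4) -> ExpressionMatrix:
    """Scale each cell to ``scale_total`` counts and apply log1p.

    This log-CPM style transform is the pre-scoring normalization; because
    downstream ssGSEA depends only on within-cell gene ranks, any strictly
    monotone per-cell transform yields identical pathway scores.
    """
    if expr.layer != "counts":
        raise ValidationError("lognormalize expects the counts layer")
    totals = np.asarray(expr.values.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = [expr.cell_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValidationError(f"cell(s) with zero total counts: {bad}")
    scaled = sp.csr_matrix(expr.values, dtype=float)
    scaled = sp.diags(scale_total / totals) @ scaled
    scaled.data = np.log1p(scaled.data)
    return ExpressionMatrix(scaled, expr.gene_ids, expr.cell_ids, layer="lognorm")
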