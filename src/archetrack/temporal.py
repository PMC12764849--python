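"""Linear modeling of pathway scores and gene expression across treatment cycles.

Each feature (pathway score or gene) is regressed on the integer cycle number
by ordinary least squares, with cells as observations, separately per patient.
The slope per cycle, its standard error, t statistic and two-sided p-value
are reported, with Benjamini-Hochberg adjustment across features within each
(patient, feature family) batch.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ValidationError

logger = logging.getLogger(__name__)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, preserving input order.

    Missing values (NaN) are passed through unadjusted and do not count
    toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]  # step-up monotonicity
        fdr = np.empty(m)
        fdr[order] = np.minimum(adj, 1.0)
        out[mask] = fdr
    return out


def fit_temporal_linear(
    values,
    meta: pd.DataFrame,
    group_by_patient: bool = True,
    feature_family: str = "pathway",
    cancer_cells_only: bool = True,
) -> pd.DataFrame:
    """OLS of each feature on the numeric treatment cycle, per patient.

    ``values`` is a cells x features DataFrame (pathway scores or log-
    normalized gene expression) or a PathwayScoreMatrix. By default only
    cells labeled aneuploid (the malignant proxy) enter the fit; pass
    ``cancer_cells_only=False`` to use every cell. Cells are treated as
    independent observations and biopsy sites within a cycle are pooled —
    the model has a single explanatory term.

    A group with fewer than two distinct cycles is skipped with a warning.
    A zero-variance feature gets estimate 0 with p and fdr missing. BH
    adjustment runs across features within each patient batch.
    """
    if hasattr(values, "scores"):
        values = values.scores
    values = pd.DataFrame(values)
    meta = meta.set_index("cell_id").loc[values.index]
    if cancer_cells_only and "ploidy" in meta.columns:
        keep = meta["ploidy"].eq("aneuploid").to_numpy()
        if keep.any():
            values = values.loc[keep]
            meta = meta.loc[keep]
        else:
            logger.warning("no aneuploid cells; fitting on all cells")

    groups = meta.groupby("patient").groups if group_by_patient else {"all": meta.index}
    rows = []
    for patient, idx in groups.items():
        y_all = values.loc[idx].to_numpy(dtype=float)
        x = meta.loc[idx, "cycle"].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            logger.warning(
                "patient %s has a single cycle; %s family skipped", patient, feature_family
            )
            continue
        n = x.size
        xc = x - x.mean()
        sxx = float(xc @ xc)
        yc = y_all - y_all.mean(axis=0)
        slope = (xc @ yc) / sxx
        resid = yc - np.outer(xc, slope)
        dof = n - 2
        s2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(s2 / sxx)
        zero_var = y_all.std(axis=0) == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(zero_var, np.nan, slope / se)  # exact fits give t = inf, p = 0
        p = 2 * stats.t.sf(np.abs(t), dof)
        slope = np.where(zero_var, 0.0, slope)
        fdr = bh_adjust(p)
        for j, feat in enumerate(values.columns):
            rows.append(
                {
                    "patient": patient,
                    "feature": feat,
                    "family": feature_family,
                    "estimate": slope[j],
                    "se": se[j] if not zero_var[j] else np.nan,
                    "t": t[j],
                    "p": p[j],
                    "fdr": fdr[j],
                    "n_cells": n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient", "feature", "family", "estimate", "se", "t", "p", "fdr", "n_cells"],
    )


def volcano_table(
    results: pd.DataFrame, estimate_cutoff: float = 0.0, fdr_cutoff: float = 0.05
) -> pd.DataFrame:
    """Classify fitted features as up / down / ns at the given cutoffs.

    'up' requires fdr strictly below ``fdr_cutoff`` and estimate strictly
    above ``estimate_cutoff`` (symmetrically for 'down'); a feature with fdr
    exactly at the cutoff is 'ns'. Output is sorted by fdr (missing last).
    """
    out = results.copy()
    est = out["estimate"].to_numpy(dtype=float)
    fdr = out["fdr"].to_numpy(dtype=float)
    sig = fdr < fdr_cutoff  # NaN compares False
    cls = np.where(sig & (est > estimate_cutoff), "up",
                   np.where(sig & (est < -estimate_cutoff), "down", "ns"))
    out["class"] = cls
    return out.sort_values("fdr", na_position="last", kind="stable").reset_index(drop=True)
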