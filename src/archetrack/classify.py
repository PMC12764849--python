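"""AUC-gated rescue of ambiguous ploidy calls.

Copy-number callers leave a `not.defined` population that can often be
rescued: a reference classifier is trained on cells confidently labeled
diploid or aneuploid, scored by cross-validated one-vs-rest AUC, and its
predictions are accepted only when that AUC exceeds 0.7 (strictly). The
classifier is the rank-correlation core of reference-profile annotation:
per-label mean expression profiles over a dispersion-selected variable-gene
panel, with each cell assigned the label whose profile its expression
correlates with best (Spearman). The AUC score for a label is the
correlation margin (that label's correlation minus the best competing one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._exceptions import ValidationError
from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

CONFIDENT_LABELS = ("diploid", "aneuploid")


@dataclass
class ClassifierModel:
    profiles: pd.DataFrame  # panel genes x labels, mean lognorm expression
    panel: list[str]
    cv_auc: float
    gate_threshold: float = 0.7
    labels: tuple[str, ...] = CONFIDENT_LABELS
    cv_margins: pd.DataFrame | None = None  # held-out margin scores, cells x labels
    cv_truth: pd.Series | None = None  # true labels aligned to cv_margins

    @property
    def accepted(self) -> bool:
        return self.cv_auc > self.gate_threshold


def _variable_genes(X: np.ndarray, gene_ids: list[str], n: int) -> np.ndarray:
    """Indices of the top-n genes by dispersion (variance / mean)."""
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(-disp, kind="stable")
    return np.sort(order[: min(n, X.shape[1])])


def _rank_correlations(X: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Spearman correlation of each cell (rows of X) with each profile column."""
    rx = np.apply_along_axis(rankdata, 1, X)
    rp = np.apply_along_axis(rankdata, 0, profiles)
    rx = rx - rx.mean(axis=1, keepdims=True)
    rp = rp - rp.mean(axis=0, keepdims=True)
    num = rx @ rp
    den = np.sqrt((rx**2).sum(axis=1))[:, None] * np.sqrt((rp**2).sum(axis=0))[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(den > 0, num / den, 0.0)
    return corr


def _margin_scores(corr: np.ndarray) -> np.ndarray:
    """Per-label margin: own correlation minus the best competing label's."""
    margins = np.empty_like(corr)
    for j in range(corr.shape[1]):
        others = np.delete(corr, j, axis=1)
        margins[:, j] = corr[:, j] - others.max(axis=1)
    return margins


def train_reference_classifier(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    n_variable_genes: int = 2000,
    cv_folds: int = 5,
    seed: int = 0,
    gate_threshold: float = 0.7,
) -> ClassifierModel:
    """Train the reference classifier on confidently labeled cells.

    Variable genes are chosen by dispersion on the training cells; cv_auc is
    the unweighted mean of one-vs-rest AUCs of the margin score over
    stratified held-out folds. A label with fewer cells than ``cv_folds``
    reduces the fold count with a warning; a single label is an error.
    """
    if expr.layer != "lognorm":
        raise ValidationError("classifier expects log-normalized expression")
    meta = meta.set_index("cell_id").loc[expr.cell_ids]
    conf_mask = meta["ploidy"].isin(CONFIDENT_LABELS).to_numpy()
    y = meta["ploidy"].to_numpy()[conf_mask]
    labels = tuple(sorted(set(y)))
    if len(labels) < 2:
        raise ValidationError("need both diploid and aneuploid training cells")
    X_all = expr.to_dense()
    X = X_all[conf_mask]

    counts = pd.Series(y).value_counts()
    folds = min(cv_folds, int(counts.min()))
    if folds < cv_folds:
        logger.warning(
            "smallest class has %d cells; reducing folds %d -> %d",
            counts.min(), cv_folds, folds,
        )
    if folds < 2:
        raise ValidationError("need at least 2 cells per label for cross-validation")

    panel_idx = _variable_genes(X, expr.gene_ids, n_variable_genes)
    Xp = X[:, panel_idx]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    margins = np.zeros((len(y), len(labels)))
    for train, test in skf.split(Xp, y):
        profiles = np.column_stack(
            [Xp[train][y[train] == lab].mean(axis=0) for lab in labels]
        )
        margins[test] = _margin_scores(_rank_correlations(Xp[test], profiles))
    aucs = [
        roc_auc_score((y == lab).astype(int), margins[:, j])
        for j, lab in enumerate(labels)
    ]
    cv_auc = float(np.mean(aucs))

    full_profiles = np.column_stack(
        [Xp[y == lab].mean(axis=0) for lab in labels]
    )
    panel = [expr.gene_ids[i] for i in panel_idx]
    conf_ids = [c for c, m in zip(expr.cell_ids, conf_mask) if m]
    model = ClassifierModel(
        profiles=pd.DataFrame(full_profiles, index=panel, columns=list(labels)),
        panel=panel,
        cv_auc=cv_auc,
        gate_threshold=gate_threshold,
        labels=labels,
        cv_margins=pd.DataFrame(margins, index=conf_ids, columns=list(labels)),
        cv_truth=pd.Series(y, index=conf_ids),
    )
    logger.info(
        "reference classifier cv_auc=%.3f (%d folds); %s",
        cv_auc, folds, "accepted" if model.accepted else "rejected by gate",
    )
    return model


def reclassify_undefined(
    model: ClassifierModel, expr: ExpressionMatrix, meta: pd.DataFrame
) -> pd.DataFrame:
    """Assign a ploidy label to `not.defined` cells if the model passed the gate.

    Confident diploid/aneuploid labels are never altered. Adds a
    ``ploidy_rescued`` provenance column; with a rejected model the metadata
    is returned unchanged apart from that (all-False) column.
    """
    if expr.layer != "lognorm":
        raise ValidationError("classifier expects log-normalized expression")
    out = meta.copy()
    out["ploidy_rescued"] = False
    if not model.accepted:
        logger.info(
            "model cv_auc %.3f <= gate %.2f: no cells reclassified",
            model.cv_auc, model.gate_threshold,
        )
        return out
    undef = out["ploidy"].eq("not.defined").to_numpy()
    if not undef.any():
        return out
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    panel_idx = np.array([gene_pos[g] for g in model.panel])
    cell_pos = {c: i for i, c in enumerate(expr.cell_ids)}
    rows = np.array([cell_pos[c] for c in out.loc[undef, "cell_id"]])
    X = expr.to_dense()[np.ix_(rows, panel_idx)]
    corr = _rank_correlations(X, model.profiles.to_numpy())
    assigned = [model.labels[j] for j in corr.argmax(axis=1)]
    out.loc[undef, "ploidy"] = assigned
    out.loc[undef, "ploidy_rescued"] = True
    logger.info("rescued %d of %d not.defined cells", undef.sum(), len(out))
    return out
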