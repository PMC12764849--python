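"""Core data containers for the longitudinal single-nuclei analysis.

The pipeline operates on three in-memory objects: a sparse cell x gene
expression matrix, a per-cell metadata table (patient, treatment cycle,
biopsy site, cell type, ploidy call, QC statistics) and a named collection
of gene sets. All downstream stages (QC, ssGSEA scoring, temporal modeling,
archetype discovery, malignancy reclassification) consume these and nothing
else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._exceptions import ConfigError, ValidationError

PLOIDY_LEVELS = ("diploid", "aneuploid", "not.defined", "unassigned")

#: Columns required in a cell metadata table, in canonical order.
METADATA_COLUMNS = (
    "cell_id",
    "patient",
    "cycle",
    "biopsy_site",
    "cell_type",
    "ploidy",
    "n_features",
    "pct_mt",
)


@dataclass
class ExpressionMatrix:
    """Sparse cell x gene matrix with named rows (cells) and columns (genes).

    ``layer`` records whether ``values`` holds raw counts (nonnegative
    integers) or log-normalized expression (``log1p`` of counts-per-
    ``scale_total``).
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.layer not in ("counts", "lognorm"):
            raise ValidationError(f"unknown layer {self.layer!r}")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids):
            raise ValidationError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValidationError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell ids are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene ids are not unique")
        if self.layer == "counts":
            data = self.values.data
            if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
                raise ValidationError("counts layer must hold nonnegative integers")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given cells.

        Accepts a boolean mask aligned to ``cell_ids`` or an explicit list of
        cell identifiers (kept in the given order).
        """
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {c: i for i, c in enumerate(self.cell_ids)}
            idx = np.array([pos[c] for c in mask_or_ids], dtype=int)
        return ExpressionMatrix(
            self.values[idx],
            self.gene_ids,
            [self.cell_ids[i] for i in idx],
            layer=self.layer,
        )

    def to_frame(self) -> pd.DataFrame:
        """Dense DataFrame view (cells x genes); for small matrices only."""
        return pd.DataFrame(self.to_dense(), index=self.cell_ids, columns=self.gene_ids)


def validate_metadata(meta: pd.DataFrame, cell_ids: list[str] | None = None) -> pd.DataFrame:
    """Check a metadata table against the container invariants.

    One row per cell, required columns present, cycle >= 1, pct_mt within
    [0, 100], ploidy from the known vocabulary. Returns the table with
    canonical column order (extra columns preserved at the end).
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    if meta["cell_id"].duplicated().any():
        raise ValidationError("metadata has duplicated cell_id rows")
    if (meta["cycle"] < 1).any():
        raise ValidationError("cycle must be >= 1")
    pct = meta["pct_mt"].to_numpy(dtype=float)
    if np.any((pct < 0) | (pct > 100)):
        raise ValidationError("pct_mt must lie in [0, 100]")
    bad = set(meta["ploidy"].unique()) - set(PLOIDY_LEVELS)
    if bad:
        raise ValidationError(f"unknown ploidy labels: {sorted(bad)}")
    if cell_ids is not None:
        if set(cell_ids) - set(meta["cell_id"]):
            raise ValidationError("metadata does not cover all matrix cells")
    extra = [c for c in meta.columns if c not in METADATA_COLUMNS]
    return meta[list(METADATA_COLUMNS) + extra]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. Hallmark / C2 pathway collections)."""

    sets: dict[str, list[str]]
    source: str = "custom"

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            seen: dict[str, None] = dict.fromkeys(genes)
            if not seen:
                raise ValidationError(f"gene set {name!r} is empty")
            cleaned[name] = list(seen)
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names}, source=self.source)


@dataclass
class QcConfig:
    """Cell-level quality thresholds.

    Cells are retained when ``min_features < n_features < max_features`` and
    ``pct_mt < max_pct_mt`` (all strict). ``assumed_doublet_rate`` is recorded
    for provenance only; doublet removal happens upstream of this package.
    """

    min_features: int = 300
    max_features: int = 8000
    max_pct_mt: float = 5.0
    assumed_doublet_rate: float = 0.04

    def __post_init__(self) -> None:
        if self.min_features >= self.max_features:
            raise ConfigError("min_features must be < max_features")
        if not (0 < self.max_pct_mt <= 100):
            raise ConfigError("max_pct_mt must lie in (0, 100]")


@dataclass
class PathwayScoreMatrix:
    """Cell x gene-set enrichment score matrix with its scoring config."""

    scores: pd.DataFrame  # cells x sets
    config: dict = field(default_factory=dict)
    scored_sets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValidationError("pathway scores must be finite")
        if not self.scored_sets:
            self.scored_sets = list(self.scores.columns)
        if list(self.scores.columns) != list(self.scored_sets):
            raise ValidationError("score columns do not match scored set list")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.scores.index)
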