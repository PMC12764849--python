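"""Reading and writing the on-disk formats.

Counts travel as matrix-market coordinate files (genes x cells, 1-based, the
droplet-pipeline convention) with row-aligned gene and cell annotation TSVs;
gene sets as GMT; metadata and all result tables as TSV. Everything is plain
text so runs are diffable and portable.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from ._exceptions import FormatError, ValidationError
from .containers import ExpressionMatrix, GeneSetCollection, validate_metadata

logger = logging.getLogger(__name__)


def read_counts(matrix_path, genes_path, cells_path) -> ExpressionMatrix:
    """Load a counts matrix from matrix-market + annotation TSVs.

    The matrix file stores genes as rows and cells as columns; the gene and
    cell files hold one identifier per line aligned to those dimensions.
    Duplicate gene symbols are collapsed by summing their rows (logged).
    """
    try:
        mat = spio.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on malformed files
        raise FormatError(f"cannot parse matrix-market file {matrix_path}: {exc}") from exc
    genes = _read_id_column(genes_path)
    cells = _read_id_column(cells_path)
    mat = sp.coo_matrix(mat)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix is {mat.shape[0]} x {mat.shape[1]} but annotations declare "
            f"{len(genes)} genes x {len(cells)} cells"
        )
    data = mat.data
    if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
        raise ValidationError("counts file contains negative or non-integer entries")
    counts = sp.csr_matrix(mat.T)  # cells x genes

    if len(set(genes)) != len(genes):
        counts, genes = _collapse_duplicate_genes(counts, genes)
    return ExpressionMatrix(counts, genes, cells, layer="counts")


def _read_id_column(path) -> list[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def _collapse_duplicate_genes(counts: sp.csr_matrix, genes: list[str]):
    order: dict[str, int] = {}
    for g in genes:
        order.setdefault(g, len(order))
    n_dupes = len(genes) - len(order)
    logger.warning("collapsing %d duplicated gene symbol(s) by summation", n_dupes)
    cols = np.array([order[g] for g in genes])
    indicator = sp.csr_matrix(
        (np.ones(len(genes)), (np.arange(len(genes)), cols)),
        shape=(len(genes), len(order)),
    )
    return sp.csr_matrix(counts @ indicator), list(order)


def write_counts(expr: ExpressionMatrix, matrix_path, genes_path, cells_path) -> None:
    """Write counts back out in the same genes x cells layout.

    The matrix-market body is written with integer formatting and rows sorted
    by (gene, cell) so identical matrices produce byte-identical files.
    """
    coo = sp.coo_matrix(expr.values.T)
    order = np.lexsort((coo.col, coo.row))
    buf = _io.StringIO()
    buf.write("%%MatrixMarket matrix coordinate integer general\n")
    buf.write(f"{coo.shape[0]} {coo.shape[1]} {coo.nnz}\n")
    for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
        buf.write(f"{i + 1} {j + 1} {int(v)}\n")
    Path(matrix_path).write_text(buf.getvalue())
    Path(genes_path).write_text("".join(f"{g}\n" for g in expr.gene_ids))
    Path(cells_path).write_text("".join(f"{c}\n" for c in expr.cell_ids))


def read_gmt(path) -> GeneSetCollection:
    """Parse a tab-separated GMT file (set name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno} has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}: duplicate gene set name {name!r} at line {lineno}")
            genes = [g for g in fields[2:] if g]
            sets[name] = genes
    return GeneSetCollection(sets, source=Path(path).stem)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, collection.source] + list(genes)) + "\n")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "patient": str})
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, header_lines: list[str] | None = None,
                index: bool = False) -> None:
    """Write a result TSV with optional '#'-prefixed provenance header."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
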