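"""Reading, writing and preprocessing of expression matrices, labels and L-R pairs.

The preprocessing pipeline mirrors the standard scRNA-seq path for CCI
analysis: raw counts -> CPMED library-size normalization -> log10(x+1)
variance stabilization -> per-cell-type averaging.  CPMED rescales every
cell so its library size (column sum) equals the median library size of
the dataset; unlike CPM this keeps the normalized values on the scale of
the original counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


@dataclass
class ExpressionMatrix:
    """Gene x cell matrix of non-negative values with identifiers.

    ``values`` has shape (I, H) where I = len(gene_ids), H = len(cell_ids).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D gene x cell matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class CellTypeLabels:
    """Assignment of every cell to one cell type.

    ``celltype_names`` fixes the ordering of all downstream cell-type axes
    (lexicographic by default, see :func:`read_labels`).
    """

    assignment: dict[str, str]
    celltype_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.celltype_names is None:
            self.celltype_names = sorted(set(self.assignment.values()))
        self.celltype_names = list(self.celltype_names)
        if len(set(self.celltype_names)) != len(self.celltype_names):
            raise ValueError("duplicate cell type names")
        unknown = set(self.assignment.values()) - set(self.celltype_names)
        if unknown:
            raise ValueError(f"labels reference unknown cell types: {sorted(unknown)}")

    @property
    def n_celltypes(self) -> int:
        return len(self.celltype_names)

    def counts(self) -> np.ndarray:
        """Number of cells per cell type, in celltype_names order."""
        c = pd.Series(list(self.assignment.values())).value_counts()
        return np.array([int(c.get(name, 0)) for name in self.celltype_names])

    def indicator(self, cell_ids: list[str]) -> np.ndarray:
        """H x J averaging matrix A with A[h, j] = 1/n_j for cell h of type j."""
        missing = [c for c in cell_ids if c not in self.assignment]
        if missing:
            raise ValueError(f"label table is missing cells: {missing[:5]}")
        extra = set(self.assignment) - set(cell_ids)
        if extra:
            raise ValueError(
                f"label table references unknown cells: {sorted(extra)[:5]}"
            )
        j_index = {name: j for j, name in enumerate(self.celltype_names)}
        A = np.zeros((len(cell_ids), self.n_celltypes))
        for h, cid in enumerate(cell_ids):
            A[h, j_index[self.assignment[cid]]] = 1.0
        n_j = A.sum(axis=0)
        if np.any(n_j == 0):
            empty = [self.celltype_names[j] for j in np.flatnonzero(n_j == 0)]
            raise ValueError(f"cell types with no cells: {empty}")
        return A / n_j


@dataclass
class CellTypeMatrix:
    """Gene x cell-type averaged matrix (I x J)."""

    values: np.ndarray
    gene_ids: list[str]
    celltype_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.celltype_names)):
            raise ValueError("CellTypeMatrix shape mismatch")

    def row(self, gene: str) -> np.ndarray:
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not found") from None
        return self.values[i]


@dataclass
class LRPairTable:
    """Ordered list of (ligand, receptor) gene-ID pairs."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = [(str(l), str(r)) for l, r in self.pairs]

    @property
    def K(self) -> int:
        return len(self.pairs)

    def ligands(self) -> list[str]:
        return [l for l, _ in self.pairs]

    def receptors(self) -> list[str]:
        return [r for _, r in self.pairs]


# ---------------------------------------------------------------------------
# preprocessing


def normalize_cpmed(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Count-per-median library-size normalization.

    Each cell's column is rescaled so its sum equals the median library
    size of the input; cells with zero counts are rejected by name.
    """
    libsize = expr.values.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero library size: {[expr.cell_ids[h] for h in zero[:5]]}"
        )
    med = float(np.median(libsize))
    return ExpressionMatrix(expr.values / libsize * med, expr.gene_ids, expr.cell_ids)


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Entrywise log10(x + 1)."""
    if np.any(expr.values < 0):
        raise ValueError("log transform requires non-negative input")
    return ExpressionMatrix(np.log10(expr.values + 1.0), expr.gene_ids, expr.cell_ids)


def average_by_celltype(expr: ExpressionMatrix, labels: CellTypeLabels) -> CellTypeMatrix:
    """Cell-type-wise average matrix X = Y A (A the 1/n_j indicator)."""
    A = labels.indicator(expr.cell_ids)
    return CellTypeMatrix(expr.values @ A, expr.gene_ids, labels.celltype_names)


def match_lr_pairs(table: LRPairTable, gene_ids) -> LRPairTable:
    """Retain deduplicated pairs whose ligand AND receptor occur in gene_ids."""
    present = set(gene_ids)
    seen: set[tuple[str, str]] = set()
    kept: list[tuple[str, str]] = []
    for pair in table.pairs:
        if pair in seen:
            continue
        seen.add(pair)
        if pair[0] in present and pair[1] in present:
            kept.append(pair)
    if not kept:
        raise ValueError("no L-R pair has both genes present in the expression matrix")
    return LRPairTable(kept)


def filter_hvg(expr: ExpressionMatrix, n_top: int) -> ExpressionMatrix:
    """Optional convenience: keep the n_top genes by variance/mean ratio.

    OFF by default in the pipeline; real-data HVG selection is usually done
    upstream by the user with their tool of choice.
    """
    mean = expr.values.mean(axis=1)
    var = expr.values.var(axis=1, ddof=1) if expr.n_cells > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(-disp, kind="stable")[: int(n_top)]
    order = np.sort(order)  # preserve gene order
    return ExpressionMatrix(
        expr.values[order], [expr.gene_ids[i] for i in order], expr.cell_ids
    )


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path: str) -> ExpressionMatrix:
    """Auto-detect by extension: .mtx (+genes.tsv/barcodes.tsv), .tsv/.csv, .h5/.hdf5."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".mtx":
        return read_expression_mtx(path)
    if ext in (".tsv", ".txt", ".csv"):
        sep = "," if ext == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return ExpressionMatrix(df.to_numpy(float), list(map(str, df.index)), list(map(str, df.columns)))
    if ext in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return ExpressionMatrix(
                f["values"][...],
                [g.decode() for g in f["gene_ids"][...]],
                [c.decode() for c in f["cell_ids"][...]],
            )
    raise ValueError(f"unrecognized expression matrix format: {path}")


def read_expression_mtx(mtx_path: str, genes_path: str | None = None, barcodes_path: str | None = None) -> ExpressionMatrix:
    base = os.path.dirname(mtx_path)
    genes_path = genes_path or os.path.join(base, "genes.tsv")
    barcodes_path = barcodes_path or os.path.join(base, "barcodes.tsv")
    m = scipy.io.mmread(mtx_path)
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    return ExpressionMatrix(np.asarray(scipy.sparse.coo_matrix(m).todense(), dtype=float), genes, cells)


def write_expression_mtx(expr: ExpressionMatrix, mtx_path: str) -> None:
    base = os.path.dirname(mtx_path)
    os.makedirs(base or ".", exist_ok=True)
    scipy.io.mmwrite(mtx_path, scipy.sparse.coo_matrix(expr.values))
    pd.Series(expr.gene_ids).to_csv(os.path.join(base, "genes.tsv"), sep="\t", header=False, index=False)
    pd.Series(expr.cell_ids).to_csv(os.path.join(base, "barcodes.tsv"), sep="\t", header=False, index=False)


def write_expression_tsv(expr: ExpressionMatrix, path: str) -> None:
    pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.cell_ids).to_csv(path, sep="\t")


def write_expression_h5(expr: ExpressionMatrix, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=expr.values)
        f.create_dataset("gene_ids", data=np.array(expr.gene_ids, dtype="S"))
        f.create_dataset("cell_ids", data=np.array(expr.cell_ids, dtype="S"))


def read_labels(path: str, order_path: str | None = None) -> CellTypeLabels:
    """TSV with header ``cell_id<TAB>cell_type``; optional explicit order file."""
    df = pd.read_csv(path, sep="\t")
    if not {"cell_id", "cell_type"} <= set(df.columns):
        raise ValueError("label table must have columns cell_id and cell_type")
    assignment = dict(zip(df["cell_id"].astype(str), df["cell_type"].astype(str)))
    if len(assignment) != len(df):
        raise ValueError("duplicate cell_id rows in label table")
    order = None
    if order_path is not None:
        order = pd.read_csv(order_path, sep="\t", header=None)[0].astype(str).tolist()
    return CellTypeLabels(assignment, order)


def write_labels(labels: CellTypeLabels, path: str) -> None:
    pd.DataFrame(
        {"cell_id": list(labels.assignment), "cell_type": list(labels.assignment.values())}
    ).to_csv(path, sep="\t", index=False)


def read_lr_pairs(path: str) -> LRPairTable:
    """TSV with header ``ligand<TAB>receptor``."""
    df = pd.read_csv(path, sep="\t")
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError("pair table must have columns ligand and receptor")
    return LRPairTable(list(zip(df["ligand"].astype(str), df["receptor"].astype(str))))


def write_lr_pairs(table: LRPairTable, path: str) -> None:
    pd.DataFrame(table.pairs, columns=["ligand", "receptor"]).to_csv(path, sep="\t", index=False)


def preprocess(
    expr: ExpressionMatrix,
    labels: CellTypeLabels,
    normalize: bool = True,
    hvg_top: int | None = None,
) -> CellTypeMatrix:
    """counts -> [HVG filter] -> CPMED -> log10(x+1) -> cell-type averaging.

    Library sizes are computed on the matrix as given, i.e. after any
    optional HVG filter.  Set ``normalize=False`` for pre-normalized input.
    """
    if hvg_top is not None:
        expr = filter_hvg(expr, hvg_top)
    if normalize:
        expr = log_transform(normalize_cpmed(expr))
    return average_by_celltype(expr, labels)
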