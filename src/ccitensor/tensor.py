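"""Construction of the J x J x K CCI-tensor.

Frontal slice k is the outer product of pair k's ligand and receptor
cell-type-average row vectors: values[s, t, k] = X[L(k), s] * X[R(k), t].
Mode 1 indexes the ligand-expressing cell type, mode 2 the
receptor-expressing cell type, mode 3 the L-R pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .io import CellTypeMatrix, LRPairTable


@dataclass
class CCITensor:
    values: np.ndarray  # (J, J, K), non-negative
    celltype_names: list[str]  # shared by modes 1 and 2
    pair_ids: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        J = len(self.celltype_names)
        if self.values.shape != (J, J, len(self.pair_ids)):
            raise ValueError("CCITensor shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("CCITensor must be non-negative")

    @property
    def J(self) -> int:
        return len(self.celltype_names)

    @property
    def K(self) -> int:
        return len(self.pair_ids)


def build_cci_tensor(X: CellTypeMatrix, pairs: LRPairTable) -> CCITensor:
    """Stack outer products x_L(k) o x_R(k) as frontal slices."""
    gene_index = {g: i for i, g in enumerate(X.gene_ids)}
    missing = [g for p in pairs.pairs for g in p if g not in gene_index]
    if missing:
        raise ValueError(f"pair genes absent from the matrix: {sorted(set(missing))[:5]}")
    L = np.array([gene_index[l] for l, _ in pairs.pairs])
    R = np.array([gene_index[r] for _, r in pairs.pairs])
    XL = X.values[L]  # (K, J)
    XR = X.values[R]
    # values[s, t, k] = XL[k, s] * XR[k, t]
    values = np.einsum("ks,kt->stk", XL, XR)
    dead = np.flatnonzero(values.sum(axis=(0, 1)) == 0)
    if dead.size:
        warnings.warn(
            f"{dead.size} L-R pair(s) have an all-zero tensor slice (kept to preserve indexing)"
        )
    return CCITensor(values, X.celltype_names, pairs.pairs)


def write_cci_tensor_h5(chi: CCITensor, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=chi.values)
        f.create_dataset("celltype_names", data=np.array(chi.celltype_names, dtype="S"))
        f.create_dataset("ligands", data=np.array([l for l, _ in chi.pair_ids], dtype="S"))
        f.create_dataset("receptors", data=np.array([r for _, r in chi.pair_ids], dtype="S"))


def read_cci_tensor_h5(path: str) -> CCITensor:
    with h5py.File(path, "r") as f:
        return CCITensor(
            f["values"][...],
            [c.decode() for c in f["celltype_names"][...]],
            list(zip((l.decode() for l in f["ligands"][...]),
                     (r.decode() for r in f["receptors"][...]))),
        )


def tensor_to_long_tsv(chi: CCITensor, path: str) -> None:
    """Long-format export: one row per (ligand_celltype, receptor_celltype, pair)."""
    J, K = chi.J, chi.K
    s, t, k = np.meshgrid(np.arange(J), np.arange(J), np.arange(K), indexing="ij")
    df = pd.DataFrame(
        {
            "ligand_celltype": [chi.celltype_names[i] for i in s.ravel()],
            "receptor_celltype": [chi.celltype_names[i] for i in t.ravel()],
            "ligand": [chi.pair_ids[i][0] for i in k.ravel()],
            "receptor": [chi.pair_ids[i][1] for i in k.ravel()],
            "value": chi.values.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)
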