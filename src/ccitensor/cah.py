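"""Extraction and binarization of CCI-as-hypergraph (CaH) triads.

Each CaH(r1, r2) is the outer product of three non-negative vectors: a
ligand cell-type pattern (column r1 of A1), a receptor cell-type pattern
(column r2 of A2) and a pair-loading fiber (G[r1, r2, :]).  CaHs are
ranked by the L1 mass of their core fiber and binarized by one-sided MAD
thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decomposition import NTDResult


@dataclass
class CaH:
    r1: int
    r2: int
    ligand_vector: np.ndarray  # J
    receptor_vector: np.ndarray  # J
    pair_vector: np.ndarray  # K
    core_weight: float


@dataclass
class BinarizedCaH:
    ligand_mask: np.ndarray
    receptor_mask: np.ndarray
    pair_mask: np.ndarray
    thr_bin: float

    def predicted_tensor(self) -> np.ndarray:
        """Binary J x J x K prediction: outer product of the three masks."""
        return np.einsum(
            "s,t,k->stk", self.ligand_mask, self.receptor_mask, self.pair_mask
        )


def mad_binarize(x: np.ndarray, thr_bin: float = 1.0) -> np.ndarray:
    """One-sided outlier mask: 1 iff x_i >= median(x) + thr_bin * MAD(x).

    MAD is the raw median absolute deviation (no consistency constant).
    When MAD = 0 (e.g. a mostly-constant vector) the comparison becomes
    strict (x_i > median), so constant vectors yield an all-zero mask.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot binarize an empty vector")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return (x > med).astype(int)
    return (x >= med + thr_bin * mad).astype(int)


def rank_cahs(res: NTDResult, top_n: int = 20) -> list[CaH]:
    """All (r1, r2) combinations sorted by descending core-fiber L1 mass.

    Returns the first ``min(top_n, R1*R2)``; ties break lexicographically
    on (r1, r2).
    """
    R1, R2 = res.core.shape[0], res.core.shape[1]
    weights = res.core.sum(axis=2)  # (R1, R2)
    order = sorted(
        ((r1, r2) for r1 in range(R1) for r2 in range(R2)),
        key=lambda p: (-weights[p], p),
    )
    cahs = []
    for r1, r2 in order[: min(top_n, R1 * R2)]:
        pair_vector = res.core[r1, r2, :]
        if res.A3 is not None:  # NTD-3: project the core fiber to pair space
            pair_vector = res.A3 @ pair_vector
        cahs.append(
            CaH(r1, r2, res.A1[:, r1], res.A2[:, r2], pair_vector, float(weights[r1, r2]))
        )
    return cahs


def reconstruct_cah(cah: CaH) -> np.ndarray:
    """Continuous J x J x K score tensor of one CaH (triple outer product)."""
    return np.einsum(
        "s,t,k->stk", cah.ligand_vector, cah.receptor_vector, cah.pair_vector
    )


def binarize_cah(cah: CaH, thr_bin: float = 1.0, pair_rule: str = "mad") -> BinarizedCaH:
    """MAD-binarize the ligand/receptor vectors (and the pair fiber).

    ``pair_rule='mad'`` applies the same MAD rule to the pair fiber;
    ``pair_rule='positive'`` instead flags every pair with loading above
    the positivity floor (useful when all pairs of a CaH should count).
    """
    lig = mad_binarize(cah.ligand_vector, thr_bin)
    rec = mad_binarize(cah.receptor_vector, thr_bin)
    if pair_rule == "mad":
        pair = mad_binarize(cah.pair_vector, thr_bin)
    elif pair_rule == "positive":
        pair = (cah.pair_vector > 1e-8).astype(int)
    else:
        raise ValueError(f"unknown pair_rule {pair_rule!r}")
    return BinarizedCaH(lig, rec, pair, thr_bin)


def cahs_to_tsv(cahs: list[CaH], path: str) -> None:
    pd.DataFrame(
        {
            "rank": np.arange(1, len(cahs) + 1),
            "r1": [c.r1 for c in cahs],
            "r2": [c.r2 for c in cahs],
            "core_weight": [c.core_weight for c in cahs],
        }
    ).to_csv(path, sep="\t", index=False)
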