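"""End-to-end orchestration: detection runs and the simulation benchmark.

``run_detect`` chains read -> normalize -> average -> tensor ->
(decompose + extract | score + permute) -> export, writing every artifact
with a manifest that records the resolved configuration and seeds.
``run_benchmark`` drives the simulation study across the factorial design
and scores all six methods (four L-R scores and the two tensor variants)
with the nine evaluation measures.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cah import binarize_cah, cahs_to_tsv, rank_cahs
from .decomposition import estimate_tensor_ranks, ntd2, ntd3
from .evaluation import (
    aucpr,
    aucroc,
    binary_report,
    evaluate_cahs,
    evaluate_permutation_method,
)
from .io import (
    ExpressionMatrix,
    CellTypeLabels,
    LRPairTable,
    log_transform,
    match_lr_pairs,
    normalize_cpmed,
    preprocess,
    read_expression,
    read_labels,
    read_lr_pairs,
)
from .scoring import binarize_by_pvalue, permutation_test, score_all_pairs
from .simulate import SimulatedDataset, SimulationConfig, enumerate_paper_configs, simulate_dataset
from .tensor import build_cci_tensor, tensor_to_long_tsv, write_cci_tensor_h5

logger = logging.getLogger("ccitensor")

TENSOR_METHODS = ("sctensor-ntd2", "sctensor-ntd3")
SCORE_METHODS = ("sum", "product", "halpern", "cabello-aguilar")
ALL_METHODS = TENSOR_METHODS + SCORE_METHODS


@dataclass
class RunConfig:
    """Resolved parameters of one detection run (defaults mirror the method's)."""

    expression_path: str | None = None
    labels_path: str | None = None
    pairs_path: str | None = None
    method: str = "sctensor-ntd2"
    normalize: bool = True
    hvg_top: int | None = None
    rank: str = "auto"  # "auto" or "R1,R2[,R3]"
    thr_rank: float = 0.8
    thr_bin: float = 1.0
    top_n: int = 20
    n_iter: int = 100
    n_restarts: int = 3
    P: int = 1000
    alpha: float = 0.05
    eps: float = 1e-10
    seed: int = 0
    permute: bool = False
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ALL_METHODS:
            raise ValueError(f"method must be one of {ALL_METHODS}")


def _normalized(expr: ExpressionMatrix, normalize: bool) -> ExpressionMatrix:
    return log_transform(normalize_cpmed(expr)) if normalize else expr


def detect(
    expr: ExpressionMatrix,
    labels: CellTypeLabels,
    pairs: LRPairTable,
    config: RunConfig,
) -> dict:
    """In-memory detection; returns a bundle of intermediate and final results."""
    pairs = match_lr_pairs(pairs, expr.gene_ids)
    norm = _normalized(expr, config.normalize)
    X = preprocess(expr, labels, normalize=config.normalize, hvg_top=config.hvg_top)
    bundle: dict = {"config": config, "pairs": pairs, "celltype_matrix": X}
    if config.method in TENSOR_METHODS:
        chi = build_cci_tensor(X, pairs)
        bundle["tensor"] = chi
        if config.rank == "auto":
            R1, R2 = estimate_tensor_ranks(
                chi.values, thr_rank=config.thr_rank, seed=config.seed
            )
            R3 = max(R1, R2)
        else:
            parts = [int(x) for x in config.rank.split(",")]
            R1, R2 = parts[0], parts[1]
            R3 = parts[2] if len(parts) > 2 else max(R1, R2)
        logger.info("NTD ranks: R1=%d R2=%d", R1, R2)
        if config.method == "sctensor-ntd2":
            res = ntd2(chi, R1, R2, n_iter=config.n_iter, seed=config.seed,
                       eps=config.eps, n_restarts=config.n_restarts)
        else:
            res = ntd3(chi, R1, R2, R3, n_iter=config.n_iter, seed=config.seed,
                       eps=config.eps, n_restarts=config.n_restarts)
        cahs = rank_cahs(res, top_n=config.top_n)
        bundle["ntd"] = res
        bundle["ranks"] = (R1, R2)
        bundle["cahs"] = cahs
        bundle["binarized"] = [binarize_cah(c, config.thr_bin) for c in cahs]
    else:
        method = config.method.replace("-", "_")
        st = score_all_pairs(norm, labels, pairs, method)
        bundle["scores"] = st
        if config.permute:
            pr = permutation_test(
                norm, labels, pairs, method, P=config.P, seed=config.seed
            )
            bundle["permutation"] = pr
            bundle["significant"] = binarize_by_pvalue(pr, config.alpha)
    return bundle


def run_detect(config: RunConfig) -> dict:
    """File-based detection run: read inputs, run, export with a manifest."""
    stage = "read"
    try:
        expr = read_expression(config.expression_path)
        labels = read_labels(config.labels_path)
        pairs = read_lr_pairs(config.pairs_path)
        stage = "detect"
        bundle = detect(expr, labels, pairs, config)
        stage = "export"
        if config.outdir:
            _export(bundle, Path(config.outdir), config)
        return bundle
    except Exception as err:
        raise RuntimeError(f"stage '{stage}' failed: {err}") from err


def _export(bundle: dict, outdir: Path, config: RunConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    if "tensor" in bundle:
        write_cci_tensor_h5(bundle["tensor"], str(outdir / "cci_tensor.h5"))
        cahs_to_tsv(bundle["cahs"], str(outdir / "cahs.tsv"))
        manifest["ranks"] = list(bundle["ranks"])
        chi = bundle["tensor"]
        rows = []
        for rank, (cah, bc) in enumerate(zip(bundle["cahs"], bundle["binarized"]), 1):
            for s in np.flatnonzero(bc.ligand_mask):
                for t in np.flatnonzero(bc.receptor_mask):
                    for k in np.flatnonzero(bc.pair_mask):
                        rows.append(
                            (rank, chi.celltype_names[s], chi.celltype_names[t],
                             chi.pair_ids[k][0], chi.pair_ids[k][1])
                        )
        pd.DataFrame(
            rows, columns=["cah_rank", "ligand_celltype", "receptor_celltype",
                           "ligand", "receptor"]
        ).to_csv(outdir / "predicted_ccis.tsv", sep="\t", index=False)
    if "scores" in bundle:
        from .tensor import CCITensor

        st = bundle["scores"]
        tensor_to_long_tsv(
            CCITensor(np.maximum(st.values, 0), st.celltype_names, st.pair_ids),
            str(outdir / "scores.tsv"),
        )
    if "permutation" in bundle:
        np.savetxt(
            outdir / "pvalues_flat.tsv",
            bundle["permutation"].pvalues.reshape(bundle["permutation"].pvalues.shape[0], -1),
            delimiter="\t",
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# benchmark driver


def _evaluate_tensor_method(ds: SimulatedDataset, variant: str, config: RunConfig) -> dict:
    bundle = detect(ds.counts, ds.labels, ds.pairs, config)
    truths = ds.truth_per_type()
    cahs, binarized = bundle["cahs"], bundle["binarized"]
    row = {
        "aucroc_score": evaluate_cahs(cahs, truths, "aucroc")["mean_best"],
        "aucpr_score": evaluate_cahs(cahs, truths, "aucpr")["mean_best"],
    }
    row["aucroc_binarized"] = evaluate_cahs(binarized, truths, "aucroc")["mean_best"]
    row["aucpr_binarized"] = evaluate_cahs(binarized, truths, "aucpr")["mean_best"]
    for metric in ("f_measure", "mcc", "pr", "fpr", "fnr"):
        row[metric] = evaluate_cahs(binarized, truths, metric)["mean_best"]
    return row


def _evaluate_score_method(ds: SimulatedDataset, method: str, config: RunConfig) -> dict:
    norm = _normalized(ds.counts, True)
    key = method.replace("-", "_")
    st = score_all_pairs(norm, ds.labels, ds.pairs, key)
    pr = permutation_test(norm, ds.labels, ds.pairs, key, P=config.P, seed=config.seed)
    rep = evaluate_permutation_method(pr, ds.truth, config.alpha)
    pred = binarize_by_pvalue(pr, config.alpha)
    bin_rep = binary_report(pred, ds.truth)
    row = {
        "aucroc_score": aucroc(st.values, ds.truth),
        "aucpr_score": aucpr(st.values, ds.truth),
        "aucroc_binarized": rep.aucroc,
        "aucpr_binarized": rep.aucpr,
        "f_measure": bin_rep.f_measure,
        "mcc": bin_rep.mcc,
        "pr": bin_rep.pr,
        "fpr": bin_rep.fpr,
        "fnr": bin_rep.fnr,
    }
    return row


def small_scale_configs(seed: int = 0) -> list[SimulationConfig]:
    """A 12-config subset (J in {3,5} x both styles x 1/3/5 CCI types, E10)
    at desk scale, for quick end-to-end runs."""
    configs = []
    for c in enumerate_paper_configs(seed, n_genes=500, n_cells_per_type=20, n_lr_pairs=50):
        if c.n_celltypes in (3, 5) and c.threshold_name == "E10":
            configs.append(c)
    return configs


def run_benchmark(
    scale: str = "small",
    seed: int = 0,
    P: int = 100,
    methods: tuple[str, ...] = ALL_METHODS,
    outpath: str | None = None,
) -> pd.DataFrame:
    """Simulate every design cell, run the chosen methods, score all measures.

    ``scale='paper'`` runs all 90 configurations at full default sizes;
    ``scale='small'`` runs the 12-config desk-scale subset.
    """
    if scale == "paper":
        configs = enumerate_paper_configs(seed)
    elif scale == "small":
        configs = small_scale_configs(seed)
    else:
        raise ValueError("scale must be 'paper' or 'small'")
    rows = []
    for cfg in configs:
        ds = simulate_dataset(cfg)
        for method in methods:
            rc = RunConfig(method=method, P=P, seed=seed,
                           n_iter=100, n_restarts=2)
            if method in TENSOR_METHODS:
                row = _evaluate_tensor_method(ds, method, rc)
            else:
                row = _evaluate_score_method(ds, method, rc)
            row.update(
                method=method,
                n_celltypes=cfg.n_celltypes,
                cci_style=cfg.cci_style,
                n_cci_types=cfg.n_cci_types,
                threshold=cfg.threshold_name,
                seed=cfg.seed,
            )
            rows.append(row)
            logger.info("benchmark: %s J=%d %s done", method, cfg.n_celltypes, cfg.cci_style)
    df = pd.DataFrame(rows)
    front = ["method", "n_celltypes", "cci_style", "n_cci_types", "threshold", "seed"]
    df = df[front + [c for c in df.columns if c not in front]]
    if outpath:
        df.to_csv(outpath, sep="\t", index=False)
    return df
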