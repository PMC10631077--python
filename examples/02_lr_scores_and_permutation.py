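"""Classical ligand-receptor co-expression scores and the permutation test.

Computes the four co-expression scores (sum, product, Halpern,
Cabello-Aguilar) on a small simulated dataset and runs the
label-permutation significance test for the product score.
"""

import numpy as np

import ccitensor as ct

cfg = ct.SimulationConfig(
    n_celltypes=3, cci_style="one-to-one", n_cci_types=1, threshold_name="E10",
    n_genes=500, n_cells_per_type=30, n_lr_pairs=50, seed=3,
)
ds = ct.simulate_dataset(cfg)
pat = ds.patterns[0]
s, t = pat.ligand_celltypes[0], pat.receptor_celltypes[0]
k = pat.pair_indices[0]
print(f"planted one-to-one CCI: cell type {s} -> cell type {t}, "
      f"{len(pat.pair_indices)} pairs")

norm = ct.log_transform(ct.normalize_cpmed(ds.counts))
for method in ("sum", "product", "halpern", "cabello_aguilar"):
    st = ct.score_all_pairs(norm, ds.labels, ds.pairs, method)
    print(f"{method:16s} score at planted (s,t,k): {st.values[s, t, k]:.3f}  "
          f"(tensor max {st.values.max():.3f})")

pr = ct.permutation_test(norm, ds.labels, ds.pairs, "product", P=1000, seed=0)
print(f"permutation p-value at the planted triplet: {pr.pvalues[s, t, k]:.3f}")
sig = ct.binarize_by_pvalue(pr, alpha=0.05)
print(f"significant triplets at alpha=0.05: {int(sig.sum())} of {sig.size}")
rep = ct.evaluate_permutation_method(pr, ds.truth, alpha=0.05)
print(f"permutation test vs truth: AUCPR={rep.aucpr:.3f}, MCC={rep.mcc:.3f}, "
      f"FPR={rep.fpr:.3f}, FNR={rep.fnr:.3f}")
print("(p=0 at the planted triplet means no permuted labeling matched the "
      "observed co-expression; FNR=0 shows every planted CCI is called, while "
      "the nonzero FPR reflects the cross-shaped false positives that single-"
      "side-high cell-type combinations produce)")
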