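# ccitensor

Detection of **many-to-many cell–cell interactions (CCIs)** from single-cell
RNA-seq by non-negative Tucker decomposition of a ligand × receptor × pair
tensor, in the style of the scTensor method, together with the classical
ligand–receptor (L–R) co-expression scores, a label-permutation significance
test, a negative-binomial simulator with planted ground-truth CCIs, and a
quantitative benchmark harness.

## The problem

scRNA-seq CCI analyses score the co-expression of known ligand–receptor gene
pairs between annotated cell types. Most tools implicitly assume one-to-one
interactions: one ligand-expressing cell type talking to one
receptor-expressing cell type. Real tissues contain many-to-many patterns — a
ligand broadcast by several cell types and received by several others — and
the widely used label-permutation test is biased against exactly those
patterns, because broadly expressed ligands and receptors also produce high
scores under shuffled labels.

## The model

Let Y ∈ ℝ^{I×H} be the gene × cell expression matrix, normalized by count per
median library size (CPMED) and log₁₀(x+1)-transformed, and let X = Y·A ∈
ℝ^{I×J} be its cell-type average (A the 1/nⱼ membership matrix over J cell
types). For each of K matched L–R pairs with ligand row x_L(k) and receptor
row x_R(k), the **CCI-tensor** χ ∈ ℝ^{J×J×K} stacks the outer products

    χ_{::k} = x_{L(k)} ∘ x_{R(k)}.

Non-negative Tucker2 decomposition (NTD-2), fitted by seeded multiplicative
updates, factorizes χ ≈ G ×₁ A⁽¹⁾ ×₂ A⁽²⁾ with non-negative factors
A⁽¹⁾ ∈ ℝ^{J×R1} (ligand cell-type patterns), A⁽²⁾ ∈ ℝ^{J×R2} (receptor
patterns) and core G ∈ ℝ^{R1×R2×K}; the pair mode is left at the identity.
NTD-3 additionally learns a pair factor A⁽³⁾ ∈ ℝ^{K×R3}. Ranks are chosen per
unfolding as the smallest k whose explained-RSS ratio from multiplicative-
update NMF reaches thr_rank = 0.8. Each triad

    CaH(r1, r2) = A⁽¹⁾_{:r1} ∘ A⁽²⁾_{:r2} ∘ G_{r1,r2,:}

is a candidate "CCI as hypergraph": a set of ligand cell types, a set of
receptor cell types, and the L–R pairs that mediate them. The top 20 triads by
core mass are kept and binarized one-sidedly by median absolute deviation:
an element is called iff x ≥ median(x) + thr_bin · MAD(x), thr_bin = 1.

For comparison the package implements the four standard co-expression scores
(sum, product, Halpern's Z-norm score, Cabello-Aguilar's saturating product
score) and the one-tailed label-permutation test (P = 1000 global label
shuffles; p = proportion of permuted scores ≥ observed).

## Worked example

`python examples/01_detect_cci_hypergraphs.py` simulates a 5-cell-type
dataset (2000 genes, 50 cells/type, 200 L–R pairs) with one planted
many-to-many CCI type at the strictest DEG level and runs the full pipeline:

```
planted: ligand cell types [2, 4] -> receptor cell types [0, 1], 100 L-R pairs
estimated NTD-2 ranks: R1=2, R2=2
best-matching CaH(r1=1, r2=0), core weight 286.2
  ligand cell types  : [2, 4]
  receptor cell types: [0, 1]
  flagged L-R pairs  : 99
recovery vs truth: AUCPR=1.000, MCC=0.995
```

The decomposition finds the planted block exactly: the matched hypergraph
loads on ligand cell types {2, 4} and receptor cell types {0, 1}, flags 99 of
the 100 planted pairs, ranks every true (ligand type, receptor type, pair)
triplet above every false one (AUCPR = 1), and its MAD-binarized calls agree
with the truth almost perfectly (MCC = 0.995).

`examples/02_lr_scores_and_permutation.py` runs the four scores plus the
permutation test on a one-to-one dataset, and
`examples/03_benchmark_design.py` runs a slice of the 90-configuration
factorial benchmark across all six methods. The same benchmark is available
from the shell:

```bash
ccitensor simulate --n-celltypes 5 --seed 0 --outdir sim/
ccitensor detect --expression sim/counts.mtx --labels sim/labels.tsv \
    --pairs sim/pairs.tsv --method sctensor-ntd2 --outdir out/
ccitensor evaluate --pred out/predicted_ccis.tsv --truth sim/truth.tsv --out metrics.json
ccitensor benchmark --scale small --out benchmark.tsv
```

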