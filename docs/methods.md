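# Methods

## Preprocessing

Raw counts are normalized per cell by **CPMED** (each column rescaled so its
sum equals the median library size of the dataset), then variance-stabilized
by log₁₀(x+1), then averaged per cell type. Cells with zero library size are
rejected by name. Library sizes are computed on the matrix as given — i.e.
after the optional highly-variable-gene filter when one is requested; the HVG
filter (variance/mean ranking, keep top N) is a convenience and is off by
default. Gene identifiers are opaque, case-sensitive strings; L–R pairs are
deduplicated and kept only when both genes occur in the matrix. Cell types
are ordered lexicographically unless an explicit order file is supplied, and
every downstream axis uses that order.

## The CCI-tensor and its decomposition

The tensor χ ∈ ℝ^{J×J×K} stores, for pair k, the outer product of the ligand
gene's and receptor gene's cell-type-average vectors. Mode 1 is the
ligand-expressing cell type, mode 2 the receptor-expressing cell type, mode 3
the pair. Pairs whose slice is all zero are kept (with a warning) so that
pair indexing is stable. Storage is dense; at the intended scales (J ≤ ~50,
K ≤ ~5000) the tensor occupies at most tens of megabytes, and memory stays
O(J²K) throughout (no per-permutation tensors are retained).

**NTD-2 / NTD-3.** Both are fitted by Lee–Seung-style multiplicative updates
on the Frobenius loss. Factor updates work on the mode-n matricized problem
X₍ₙ₎ ≈ A⁽ⁿ⁾ G₍ₙ₎ (⊗ₘ≠ₙ A⁽ᵐ⁾)ᵀ; the core update divides the projection
χ ×ₙ A⁽ⁿ⁾ᵀ by G ×ₙ (A⁽ⁿ⁾ᵀA⁽ⁿ⁾) elementwise. Numerical choices:

- **Positivity floor** ε = 1e-10: denominators are floored at ε and factors
  and core are clamped at ε after every update, so no entry can reach zero or
  go negative.
- **Initialization**: factors and core are drawn i.i.d. uniform(0.1, 1) from
  a seeded generator and the core is rescaled so the initial reconstruction
  matches the data mean. Each fit runs `n_restarts` (default 3) seeded
  initializations and keeps the lowest-loss solution, recording its seed.
- **Stopping**: a fixed iteration budget (default 100) with early stop when
  the relative loss change stays below 1e-10 for 5 consecutive iterations.
- **Matricization convention**: `unfold(T, n) = moveaxis(T, n, 0).reshape`
  with the remaining modes in ascending order and the matching Kronecker
  ordering. Any self-consistent convention yields the same model.

Each sub-update is a standard multiplicative step, so the loss trace is
non-increasing up to the ε-clamping perturbation; the tests assert
monotonicity at 1e-8 relative tolerance. NTD-2 is implemented as NTD-3 with
the pair-mode factor frozen at the identity, which makes the two models
definitionally identical when R3 = K (asserted to 1e-6 relative in tests).

**Rank estimation.** For each of the mode-1 and mode-2 unfoldings,
multiplicative-update NMF is run at every candidate rank k = 1..J (best of 2
restarts) and the chosen rank is the smallest k with

    (RSS₁ − RSS_k) / (RSS₁ − RSS_J) ≥ thr_rank   (default 0.8),

i.e. an explained-residual ratio that is 0 at rank 1 and 1 at full rank. The
comparison is "≥" so that thr_rank = 1 is attainable; exactly rank-1 input
(flat RSS curve) degenerates to rank 1 with a warning. Candidates are
evaluated on the raw (unnormalized) unfolding.

**CaH extraction and binarization.** All (r1, r2) combinations are ranked by
the L1 mass Σₖ G[r1,r2,k] of their core fiber — for a non-negative 1-D fiber
any norm gives the same order — with lexicographic tie-break, and the top 20
kept by default. Vectors are binarized one-sidedly: element i is called iff
xᵢ ≥ median(x) + thr_bin · MAD(x), with MAD the raw median absolute deviation
(no 1.4826 consistency constant) and thr_bin = 1. When MAD = 0 the rule
becomes strict (xᵢ > median), so constant vectors produce empty masks rather
than flagging everything. The predicted binary tensor of a CaH is the outer
product of its ligand, receptor and pair masks; the pair mask comes from
MAD-binarizing the core fiber by default, with an alternative "all positively
loaded pairs" rule behind a flag, since factor-matrix binarization is the
only part of the rule fixed by the method's definition.

## L–R scores and the permutation test

All four scores consume cell-type means of the normalized matrix. Halpern's
score Z-scales each gene's J-vector using the sample standard deviation
(ddof = 1; a flag switches to the population convention) and returns
√(Z_l² + Z_r²) — note it is large when *either* side deviates, the source of
its characteristic cross-shaped false-positive pattern. Cabello-Aguilar's
score uses μ = the grand mean of the same normalized matrix that feeds the
cell-type means. Zero-variance vectors in Halpern's score degrade gracefully
(that side's Z set to zero, with a warning).

The permutation test applies one global shuffle of the cell labels per
permutation (group sizes preserved, the same shuffle reused across all
pairs — this preserves the cross-pair correlation of the null and is P-fold
cheaper than per-pair shuffling), recomputes the score tensor, and reports
the one-tailed p-value p = #(permuted ≥ observed)/P with P = 1000 by default.
No pseudo-count is added, so p = 0 is possible; a flag switches to
(b+1)/(P+1). Calls use p < α with α = 0.05, uncorrected by default, with
Benjamini–Hochberg behind a flag.

Because the observed labeling itself can be redrawn, p-values are uniform
under exchangeability only when the score distribution is continuous: tied
scores (e.g. genes zeroed everywhere by dropout) create a point mass at
p = 1, a generic property of discrete permutation tests. The calibration
test therefore uses exchangeable null data simulated without dropout.

## Simulator

Counts are drawn per gene and cell type from NB(f_gc·m_g, φ_g) with variance
μ + φμ², sampled as a gamma–Poisson mixture (shape 1/φ, scale φμ), which is
numerically safe down to the dispersion floor φ = 1e-6 used for
under-dispersed genes. Gene parameters can be estimated from a real matrix
(m = row mean, v = row variance, φ = (v−m)/m²) or drawn from the built-in
synthetic generator (log₁₀ m ~ Normal(0.5, 0.7), φ ~ Gamma(2, 0.25)), which
emulates the right-skewed mean distribution and over-dispersion of plate-
based scRNA-seq without requiring external data.

DEG fold changes follow log₁₀ f = a·exp(−b·log₁₀(m+1)) with
(a, b) = (0.701, 0.363), (1.907, 0.666), (4.429, 0.814) for the E2/E5/E10
stringency levels; only up-regulation is planted (f ≥ 1). Dropout zeroes each
entry independently with probability exp(−c·f·m²), c = 1 by default, applied
after NB sampling.

A CCI type is a ligand cell-type set S, receptor set T and a disjoint block
of L–R pairs; the truth tensor marks S × T × block. One-to-one types use
singletons; many-to-many types draw set sizes seeded with max(|S|,|T|) ≥ 2;
an explicit `pattern_spec` reproduces any fixed pattern (e.g. one-to-all).
Half of the L–R pairs carry signal, split evenly across CCI types, and the
rest are background — so the benchmark always contains unaffected pairs.
Ligand and receptor genes of different pairs are distinct, which keeps DEG
assignments conflict-free. Default sizes are 2000 genes, 50 cells per type
and 200 pairs — large enough that cell-type means are stable, small enough
for desk-scale runs. The factorial design crosses 5 cell-type levels ×
2 CCI styles × 3 CCI-type counts × 3 DEG thresholds = 90 configurations,
each with a distinct CRC32-derived seed.

What the simulator does **not** model: library-size variation between cells,
batch effects, gene–gene correlation beyond the planted blocks, multi-subunit
receptor complexes, and down-regulated DEGs. Passing benchmarks here shows
the methods recover block-structured mean shifts under NB noise and dropout;
it does not certify performance on data with strong batch structure or
compositional artifacts.

## Evaluation

Nine measures: AUCROC and AUCPR before and after binarization, F-measure,
MCC, and PR/FPR/FNR after binarization. AUCROC uses the rank (Mann–Whitney)
form with mid-rank ties; AUCPR uses the average-precision (step) convention,
which avoids the optimistic linear interpolation of trapezoidal PR areas.
"PR" is the predicted-positive fraction (TP+FP)/total — the reading that lets
it separate call volume from selectivity — and 0/0 cases in F-measure, MCC
and the rates return 0 so that benchmark tables aggregate cleanly.

Because the decomposition is unsupervised, extracted CaHs are matched to
ground-truth CCI types by the best-over-CaH rule: each truth pattern is
scored against every CaH (continuous metrics on the triple-outer-product
reconstruction, binary metrics on the mask tensor) and the best value is
kept — maximum for goodness measures, minimum for FPR/FNR, and PR reported
at the MCC-matched CaH, since a raw maximum is degenerate for error rates.
Dataset-level summaries report both the mean over truth patterns
("mean_best") and the single best combination ("global_best"), as it is not
knowable in advance which aggregation a given benchmark table uses.

## Problem sizes

The test suite and the acceptance script run the full pipeline at
2000 genes × 250 cells × 200 pairs for planted-recovery checks, 300 × 90 ×
40 for permutation calibration (P = 1000), and desk-scale tensors (~5×5×8)
for the decomposition property checks — sizes chosen so cell-type means and
empirical p-values are stable while whole-suite runs stay in seconds. The
`benchmark` driver exposes `scale="paper"` (all 90 configurations at default
sizes) and `scale="small"` (a 12-configuration subset at 500 genes ×
20 cells/type × 50 pairs).

## Known limitations

- Multiplicative updates converge to local optima; restarts mitigate but do
  not eliminate initialization dependence, and the RSS rank-selection curve
  inherits that variance (best-of-restarts per rank).
- The MAD rule assumes a CaH's loading vector has a majority of background
  entries; patterns covering more than half the cell types are systematically
  truncated (the all-to-all case is a known blind spot of every method here).
- The permutation test is valid but conservative for broadly expressed
  ligands/receptors — the very bias that motivates the tensor approach — so
  its benchmark numbers on many-to-many data should be read as a property of
  the test, not an implementation artifact.
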