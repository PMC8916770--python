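# Methods

This note documents the models and procedures `sigscore` implements, the
parameters that matter, the numerical choices taken where a definition was
open, and what the synthetic cohort does and does not emulate.

## Scoring backends

All four scorers consume a cells × genes non-negative matrix. They are
invariant to per-cell depth scaling (ranks and ratios only), so raw counts
and depth-normalized layers give identical scores; tie structure is the one
thing that matters, and count layers carry more ties than continuous
normalized layers.

### JASMINE

For one cell and one signature `S` (intersected with the matrix's gene
universe — this effective size is used everywhere downstream):

* `V_mean = Σ R_g / (m·N)` with ranks ascending over the `N` genes with
  value > 0 only (highest-expressed gene has rank `N`, ties averaged),
  `m` = expressed signature genes. The ascending direction makes `V_mean`
  grow with signature activity. `m = 0` (fully dropped-out signature) gives
  `V_mean = 0` rather than an error: a silent signature should score
  minimal.
* Enrichment: odds ratio `a·d/(b·c)` with `b := 1` when `b = 0`, or
  likelihood ratio `a(c+d)/(c(a+b))` (the ratio of expressed fractions,
  0 when `a = 0`). A cell with `c = 0` expresses nothing outside the
  signature and is refused as degenerate.
* Both components are min–max scaled to [0, 1] **per signature, across
  cells**, then averaged. A constant component has no range and maps to
  all zeros with a logged warning; single-cell matrices are refused because
  the scaling is undefined. The enrichment is scaled raw (no log
  transform).

### SCSE

`score = (Σ signature values / Σ all values) × 100`. The scale factor is
cosmetic (Cohen's d and all rankings are invariant to it); 100 makes the
score a percentage of transcriptional output.

### AUCell-style AUC

`k = ceil(0.05 × universe)` top-ranked genes per cell; the score is the
area under the recovery curve (cumulative signature-gene count at each of
the top `k` ranks), divided by the maximum achievable for the signature's
size. Rank ties — in practice the zero-expression block, and tied counts
generally — are broken by a random permutation drawn per cell from a seeded
generator (one `default_rng(seed)` stream, one permutation per cell in row
order), making runs exactly reproducible.

### ssGSEA

Per cell, all genes are ranked ascending with average ties (the dropout
block therefore shares one tie rank); genes are walked from highest to
lowest rank, ties broken by gene storage index. With weights
`w_g = rank_g^τ` (τ = 0.25), the score is
`Σ_i (P_in(i) − P_out(i))`, where `P_in` is the weighted CDF of signature
genes and `P_out` the uniform CDF of the rest. This running sum telescopes
into per-gene closed form

`score = Σ_{g∈S} w_g q_g / Σ_{g∈S} w_g − Σ_{g∉S} q_g / (N − |S|)`,

with `q_g = N − walk position + 1`. The package uses the closed form (it is
algebraically identical and O(|S|) per cell once rank/order caches exist);
the test suite checks it against a literal loop-based walk. When several
tied genes fall partly inside and partly outside a signature, the walk
order — hence the score — depends on storage order; this is inherited from
the walk definition and matches the reference implementations' behaviour.
With `normalize` on, scores are divided by the (max − min) range of the
whole score matrix of the run; this is a common positive scaling and does
not move Cohen's d.

## Contrasts and benchmark statistics

Cohen's d with the classic pooled SD compares a signature between two cell
groups; |d| ≥ 1 (inclusive) calls up/down. Hedges' small-sample correction
is deliberately omitted: at the group sizes used (hundreds of cells) it is
a per-mille effect on a ±1 threshold. Zero pooled SD with unequal means
returns a signed sentinel (10⁶) so summaries stay finite while the call is
preserved. Supporting statistics: recovery rate (fraction of gold-standard
sets called in their true direction), false-call rates under a null
contrast, per-signature coefficient of variation (sample SD/mean; NaN with
a warning at zero mean), Spearman correlation of d with effective signature
size (two-sided asymptotic p), and consensus accuracy — a signature's
consensus is a direction supported by ≥ 2 methods, and accuracy is computed
only over signatures with a non-neutral consensus, separately for up and
down consensus sets.

When comparing up:down call ratios between methods, the ratio is computed
with a +1 continuity correction on both counts, `(n_up+1)/(n_down+1)`, so a
method with zero down calls still yields a finite, ordered value.

## Simulation machinery

**Noisy gold-standard sets.** For each direction × size × noise level `q`,
`size − round(q·size)` genes are drawn without replacement from the true
DE pool and the rest from the universe minus that pool (the other
direction's pool is a legitimate noise source). Rounding is half away from
zero; the default grid (sizes 50–300, noise 0–80%, 200 replicates per
combination) only produces exact products, so the tie rule never fires
there. One seeded generator drives all draws in direction-major, then size,
noise, replicate order.

**Down-sampling.** Every count `k` becomes `Binomial(k, rate)` — the
standard read-thinning model: zeros never become positive, detected genes
decrease stochastically as the rate drops. With rescaling, each cell is
scaled back to its own original total, emulating equal-coverage
re-normalization; the result is a normalized layer. The specificity null
samples a seed-fixed subset of tumor cells (the same subset for every
method compared), thins at the chosen rate, scores original + twin cells as
one matrix, and contrasts the groups: every non-neutral call is false by
construction.

**Dummy-cell dropout probe.** The probe cell has strictly decreasing
values `n, n−1, …, 1`, so gene index equals expression rank at every
dropout rate and the curves are exactly reproducible; dropout zeroes the
lowest `floor(rate·n)` genes. The floating-gene sweep scores a
`(99 fixed + 1 floating)`-gene signature on the cell and its dropout twin
with a backend's **raw single-cell** score (no cross-cell normalization,
which would couple the two curves); JASMINE's full score needs cross-cell
scaling and is refused, while its rank-mean component is available as the
`jasmine_vmean` backend. The fixed genes are drawn seeded from the top
1,000 ranks; every top-1,000 gene survives all rates ≤ 0.8, and the tests
assert the divergence and crossing landmarks across five seeds. Landmarks
reported: `divergence_rank` (largest floating rank with equal scores —
equal to the expression boundary `n − floor(rate·n)` for ssGSEA),
`crossing_rank` (largest rank where the dropout cell scores at least the
reference), and the dropout tie rank (average high→low rank of the zeroed
genes, e.g. 7000.5 at 60% of 10,000; the crossing lands on its integer
part).

## Synthetic cohort

The generator emulates the structure that makes gene-count bias visible in
real tumor/normal scRNA-seq: log-normal per-gene means (lognormal(0, 1) by
default, so ranks are informative), gamma–Poisson (negative binomial)
counts with dispersion 0.3, a known set of true up-/down-regulated genes in
tumor cells, and a controlled detected-gene imbalance. The imbalance is
produced by binomially thinning normal cells at a rate solved (Brent's
method) from the closed-form expected detected-gene count of a thinned NB
gene, `E[detected](r) = Σ_g 1 − (1 + r·μ_g·φ)^(−1/φ)`, so that the expected
tumor:normal detected-gene ratio equals `detect_shift`. Thinning-to-depth
was chosen over zero-inflation because it is the same manipulation the
down-sampling experiments use.

Defaults: 200 + 200 cells × 2,000 genes; 150 up + 150 down DE genes at
2-fold; `detect_shift = 1.75`. The DE load (15% of genes) is kept modest on
purpose: much larger DE programs at high fold change dominate the
transcriptome compositionally and dilute every non-DE signature in tumor
cells, which buries the gene-count effect under a compositional one that
real cohorts do not show at this strength. `detect_shift` has no published
quantitative anchor; 1.75 is inside the range spanned by real malignant vs
stromal/immune detected-gene ratios and gives a clearly resolvable signal
at 400 cells. The desk-scale benchmark grid uses sizes 50/100/150 so that
noiseless sets fit inside the 150-gene truth pools.

What the cohort does **not** emulate: cell-type substructure within the
normal compartment, depth heterogeneity beyond NB sampling, batch effects,
gene–gene correlation within programs, or signatures biased toward
well-expressed genes (neutral sets are uniform draws). Passing directional
tests on this cohort therefore demonstrates the scorers' response to
gene-count imbalance under controlled conditions, not performance on any
particular real dataset.

### Observed directional behaviour

With these defaults, tumor cells detect ~1.75× more genes than normal
cells (t-test p ≈ 0), ssGSEA calls a substantial fraction of direction-free
signatures up in tumor while JASMINE/SCSE/AUCell stay balanced, and all
four scorers recover 100% of noiseless gold-standard sets. In the
down-sampling null at rate 0.5, ssGSEA's score distribution shifts
systematically (its median null d is positive) while JASMINE's stays
centered; the shift direction follows from the tie-rank analysis — for a
uniformly random signature the expected ssGSEA score is a decreasing
function of the cell's zero count alone, so the twin group with more
dropouts scores lower and spurious calls surface as *up* calls of the
original group. A regime where the same null produces predominantly *down*
calls was not observed on this generator at any tested configuration; see
the package's tests for exactly what is asserted.

## Numerical and degenerate-input conventions

* Min–max scaling of a constant vector → zeros + warning; ssGSEA range
  normalization with zero range → raw scores + warning.
* Cells with no expressed genes are errors for rank-based scorers; cells
  expressing only signature genes are errors for the enrichment table
  (`c = 0`).
* A cell that loses all counts during thinning cannot be rescaled; it
  stays zero with a warning.
* Score equality in the dropout probe is tested at rtol 1e−12/atol 1e−9;
  in the equal region the two computations share bitwise-identical inputs,
  so the tolerance only guards against platform-level reassociation.
* Seeds: every stochastic operation takes an explicit seed and derives any
  internal streams from it; derived seeds stay below 2³¹.
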