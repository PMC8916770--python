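# sigscore

Dropout-aware gene-signature scoring for single-cell RNA-seq, with the
benchmarking machinery to show *why* dropout-awareness matters.

## The problem

Gene-signature ("gene set") scoring assigns each cell a scalar activity for
a named gene program, independent of other cells. Methods designed for bulk
RNA-seq — notably ssGSEA — rank **every** gene in the universe, so the
thousands of zero-expression genes (dropouts) in an scRNA-seq profile all
collapse onto one shared tie rank. When two cell populations differ
systematically in how many genes they detect — cancer cells, for example,
consistently detect more genes than normal cells — this tie rank moves, and
signature scores shift with it even when the underlying biology is
identical. Scores then correlate with gene counts and with signature size,
producing spurious "up-regulated" programs in the high-gene-count
population.

`sigscore` is for computational biologists who score signatures on
single-cell data and want both dropout-robust scores and the tools to
quantify how a scorer reacts to dropout structure.

## Methods implemented

All four scorers map `(cell expression profile, gene set S)` to a scalar.

**JASMINE** (Jointly Assessing Signature Mean and Inferring Enrichment) —
the dropout-aware method. Per cell, with `N` expressed genes of which `m`
belong to `S`:

* mean rank of expressed signature genes,
  `V_mean = Σ_{g∈S, expressed} R_g / (m·N)`, where `R_g` is the ascending
  rank of gene `g` among the expressed genes only;
* enrichment of `S` in the expressed fraction via the odds ratio
  `OR = a·d / (b·c)` (with `b := 1` when `b = 0`) or the likelihood ratio
  `LR = (a/(a+b)) / (c/(c+d))`, over the 2×2 table *a* = signature genes
  expressed, *b* = signature dropouts, *c* = non-signature genes expressed,
  *d* = non-signature dropouts.

`V_mean` and the enrichment are each min–max scaled to [0, 1] across cells
and averaged. Dropouts never enter a rank, so the score cannot inherit a
tie-rank artifact.

**SCSE** — the signature's share of a cell's total expression, ×100.
**AUCell-style AUC** — the area under the recovery curve of signature genes
among the top 5% expressed genes of the cell, normalized to [0, 1].
**ssGSEA** — the Barbie-style weighted running sum over the full ranked
gene list (rank weight exponent τ = 0.25, average-rank ties), the bulk
method that the benchmark probes.

Around the scorers: Cohen's d contrasts with ±1 up/down calling, noisy
gold-standard gene-set simulation, binomial down-sampling nulls,
coefficient-of-variation stability, consensus accuracy, a dummy-cell
dropout probe, and a negative-binomial synthetic tumor/normal cohort
generator with a controlled detected-gene imbalance.

## Worked example

```python
import sigscore as ss

# synthetic 400-cell tumor/normal cohort with known DE truth
matrix, truth = ss.generate_cohort(ss.CohortConfig(seed=1))

# gold-standard signatures: size 100, at 0% and 40% noise
sets = ss.simulate_noisy_sets(truth.up_genes, truth.down_genes,
                              list(matrix.gene_ids), sizes=(100,),
                              noise_levels=(0.0, 0.4), n_per_combo=3, seed=7)
coll = ss.sets_to_collection(sets)

scores = ss.score_collection(matrix, coll, "jasmine_or", seed=0)
out = ss.contrast_collection(scores, truth.annotation, "Tumor", "Normal",
                             sizes=ss.effective_sizes(coll, matrix))
print(out.to_frame())
```

prints (abridged):

```
       signature  size  cohens_d call
   up_s100_q0_r0   100  5.432179   up
  up_s100_q40_r0   100  3.632055   up
 down_s100_q0_r0   100 -4.375557 down
down_s100_q40_r0   100 -2.350772 down
```

Every noiseless up/down program is recovered with |d| ≈ 4–5; adding 40%
noise genes attenuates the effect toward |d| ≈ 2–4, still called correctly.

The dummy-cell dropout probe — a 10,000-gene strictly decreasing profile, a
99-gene fixed signature from the top 1,000 genes, and one floating gene
swept down the list — isolates what dropout alone does to ssGSEA:

```python
curve = ss.floating_gene_sweep(ss.make_dummy_cell(10_000), rate=0.6, seed=1)
print(curve.summary())
```

```
{'scorer': 'ssgsea', 'dropout_rate': 0.6, 'n_genes': 10000, 'n_fixed': 99,
 'top_pool': 1000, 'divergence_rank': 4000, 'crossing_rank': 7000,
 'tie_rank': 7000.5}
```

With 60% dropout the two cells score identically while the floating gene is
expressed in both (ranks ≤ 4000); past that boundary the scores diverge and
the difference changes sign exactly at the dropout tie rank (average rank
7000.5 of the 6,000 zeroed genes).

## Command line

One executable, one subcommand per workflow:

```bash
sigscore make-cohort --out-dir cohort/
sigscore score --matrix cohort/matrix.mtx --genes cohort/genes.txt \
    --cells cohort/cells.txt --layer counts --gmt sets.gmt \
    --method jasmine_or --out scores.tsv
sigscore benchmark --cohort-dir cohort/ --out-dir bench/
sigscore dropout-probe --rate 0.6 --out-prefix probe
sigscore downsample --matrix cohort/matrix.mtx --genes cohort/genes.txt \
    --cells cohort/cells.txt --rate 0.5 --out-dir thinned/
```

All stochastic commands take `--seed` and are fully reproducible from it.

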