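# inco — integrative co-localization of SNV and CNV association signals

Genomic studies that analyze single-nucleotide variants (SNVs) and
copy-number variations (CNVs) on separate tracks can miss traits driven by
the *concurrent* presence of both in the same genomic neighborhood —
especially when each marker's marginal effect is weak or the variant is
rare.  `inco` implements a two-stage, region-based alternative for
statistical geneticists working with case-control or quantitative
phenotypes:

1. **Gene-level screen.** For each gene, the per-sample SNV dosage block
   (n × q₁, additive 0/1/2 coding) and the dichotomized CNV segment block
   (n × q₂, 1 = gain or loss) are concatenated into one matrix
   `G = [G_SNV | G_CNV]` and tested jointly under a GLM null
   `g(E[Y]) = Gβ + Zα` with an optimal weighted-kernel score test
   (the SKAT-O family): `Q_ρ = (y−μ̂)' G W R_ρ W G' (y−μ̂)` with
   `R_ρ = (1−ρ)I + ρ11'`, minimized over a ρ grid between the
   variance-component kernel (ρ = 0) and burden (ρ = 1) limits, with
   p-values from 1-df chi-square mixtures (characteristic-function
   inversion, exact-series and saddlepoint/moment fallbacks).
2. **Moving-window co-localization.** Screened genes are tiled with small
   windows (default 0.5 kb) and each marker-containing window is retested
   jointly, localizing the concurrent signal; per-window SNV-only and
   CNV-only p-values are emitted alongside so the three "skylines" can be
   compared.

The package also ships the traditional parallel baselines (union-union,
TUU, and intersection-union, TIU, per-marker analyses), and a simulation
harness — a synthetic 21-gene marker pool and a logistic disease model
with an SNV×CNV concurrent effect — that measures false-positive,
true-positive and true-negative rates of all three methods at gene and
window level.

## Worked example

Generate a small deterministic demo dataset (200 samples, 3 genes, one
planted concurrent SNV+CNV effect in gene `DEMO1`) and run the two-stage
analysis:

```bash
inco fixtures --out demo --seed 0
inco run \
  --snv demo/snv.tsv --cnv-segments demo/cnv_segments.bed \
  --cnv-status demo/cnv_status.tsv --genes demo/genes.bed \
  --pheno demo/pheno.tsv \
  --gene-alpha 0.05 --correction none --window-alpha 0.01 \
  --out demo/results
cat demo/results/genes.tsv
```

```
gene_id  chrom  start    end      q1  q2  rho  p_value       p_adjusted    selected
DEMO1    1      1000000  1003999  8   4   0.0  7.709298e-06  7.709298e-06  True
DEMO2    2      2000000  2003999  6   3   1.0  0.669628      0.669628      False
DEMO3    3      3000000  3003999  5   2   1.0  0.668963      0.668963      False
```

Only the gene carrying the planted effect passes the screen
(p ≈ 7.7 × 10⁻⁶; its optimal mixing weight sits at the
variance-component end, ρ = 0).  The skyline
(`demo/results/skyline_DEMO1.tsv`) then localizes the signal to the first
500 bp tile — exactly where the fixture plants the causal SNV/CNV pair —
and the joint p-value there is an order of magnitude below the SNV-only
test of the same window:

```
window  start    end      q1  q2  p_combined    p_snv         p_cnv         significant
0       1000000  1000499  3   2   3.766556e-06  3.652014e-05  4.100230e-06  True
1       1000500  1000999  0   2   0.917868                    0.917868      False
2       1001000  1001499  2   2   0.915849      0.145113      0.917868      False
...
```

The same data through the parallel baseline (`inco traditional --mode
tuu ...`) flags windows purely by single-marker significance, which is
the behavior the simulation study quantifies.

Operating characteristics on the synthetic 21-gene pool (here a quick
40-replicate illustration; the calibration study uses 1,000):

```bash
inco simulate --setting A1 --n 200 --reps 40 --seed 7 --out sim_a1
```

prints per-method gene-level and region-level false-positive rates; under
the all-null setting A1 the two-stage pipeline sits near the nominal 5%
at gene level while the union baseline's per-marker stage-1 rule is far
more liberal.

## Library surface

```python
from inco import (
    read_snv_panel, read_cnv_panel, read_gene_annotations,   # I/O
    qc_snv, impute_missing, build_gene_matrix,               # data prep
    fit_null, test_unit, skat_o,                             # region tests
    screen_genes, colocalize, run_inco,                      # pipeline
    run_traditional,                                         # baselines
    table1_pool_spec, generate_pool, evaluate_methods,       # simulation
)
```

See `docs/methods.md` for the model, the mixture-tail numerics, the
synthetic-data design, and known limitations.
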