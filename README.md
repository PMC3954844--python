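# threetc — 3' tag counting for RNA-seq of degraded samples

RNA is fragile. PolyA-selected RNA-seq libraries made from partially
degraded samples (low RIN) keep only the 3'-anchored piece of each broken
molecule, so coverage collapses toward the 3' end and — crucially — long
transcripts lose a larger share of their reads than short ones. Comparing
an intact group against a degraded group then produces thousands of
spurious, length-correlated "differentially expressed" genes even when
true expression is identical.

**3' tag counting (3TC)** suppresses these false positives by editing the
annotation used for counting, in two steps:

1. **Isoform filtering** — keep one representative isoform per gene
   (the most highly expressed one, or alternatively the isoform whose 3'
   end is the most downstream), so overlapping isoforms cannot
   contaminate gene-level counts.
2. **3' length restriction** — truncate each retained isoform to its
   3'-terminal *N* nucleotides (*N* = 1500 is a safe default; *N* = ∞
   disables truncation).

Both intact and degraded samples are then counted over the same 3' window,
where coverage is insensitive to degradation. The cost is *sensitivity*,
defined as expressed(N) / expressed(∞): the fraction of genes still
detectable as expressed after truncation.

The package is aimed at bioinformaticians analysing bulk RNA-seq where
sample quality differs between conditions (clinical, post-mortem, forensic
or archived material), and at anyone re-analysing published polyA datasets.

## What is inside

- `threetc.annotation` — GTF parsing/writing (Ensembl dialect),
  `filter_major_isoform`, `filter_threeprime_isoform`,
  `restrict_threeprime`.
- `threetc.counting` — htseq-style **intersection-strict** fragment
  counting (every aligned base must fall in exons of exactly one gene;
  partial overlap → `no_feature`, multi-gene containment → `ambiguous`),
  mate merging, fragment-level downsampling.
- `threetc.diffexpr` — two-group negative-binomial differential
  expression in the classic DESeq (2010) style: median-of-ratios size
  factors, method-of-moments dispersion (variance = μ + αμ²), a
  conditioned two-sided exact test on the group count sums, and
  Benjamini–Hochberg FDR; DEG ⇔ adjusted p < 0.05.
- `threetc.coverage` — 100-bin 5'→3' gene-body coverage and the
  3'-fraction bias statistic.
- `threetc.evaluation` — the sensitivity/%DEG sweep across an *N* grid,
  DEG transcript-length contrasts (Welch t-test), DEG-set overlaps.
- `threetc.simulate` — a degraded-RNA experiment generator (toy genome,
  exponential 3'-anchored retention `D = min(L, Exp(λ))`, NB count noise,
  planted fold changes, truth tables) so everything is testable offline.
- `three-tc` — a CLI over all of the above.

## Worked example

Simulate a *confounded null*: two groups with identical true expression,
group A intact (λ = 0), group B degraded (λ = 10⁻³ per nt), three
replicates each — then run the 3TC sweep:

```python
import math
from threetc import SimConfig, simulate_experiment, sweep_lengths

cfg = SimConfig(n_genes=400, library_size=200_000, de_fraction=0.0,
                group_lambda=(0.0, 1e-3), seed=42)
bundle = simulate_experiment(cfg)
report = sweep_lengths(bundle.fragments, bundle.annotation, bundle.sample_sheet,
                       abundance=bundle.abundance,
                       lengths=[math.inf, 1500, 1000, 500, 200])
print(report.to_string(index=False))
```

```
length_restriction  expressed  degs  pct_degs  sensitivity
               inf        400   277      69.2         1.00
              1500        400    44      11.0         1.00
              1000        400    27       6.8         1.00
               500        400    13       3.2         1.00
               200        394    10       2.5         0.98
```

Every one of the 277 DEGs at `inf` is a false positive (true expression is
identical by construction); they exist only because degradation removes
proportionally more reads from long genes in group B. Restricting counting
to the 3'-terminal 1500 nt removes 84% of them at no sensitivity cost
here; tightening *N* further keeps shrinking the false-positive count,
with sensitivity starting to drop at *N* = 200. On real data the same
table is produced by `three-tc sweep --gtf ann.gtf --samples samples.tsv
--abundance fpkm.tsv --out report.tsv`, and `three-tc coverage` reports
the 3'-fraction QC statistic that signals degradation in the first place.

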