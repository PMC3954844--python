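# Methods

## The problem being modelled

PolyA-selected RNA-seq recovers, from each mRNA molecule, only fragments
linked to the 3' polyadenylated end. If a molecule has broken, everything
5' of the most 3' break is lost. Two consequences follow for a comparison
between an intact and a degraded group: (i) coverage within each gene
shifts toward the 3' end in the degraded group, and (ii) the *total*
countable mass of a gene shrinks by a factor that grows with transcript
length, so long genes appear down-regulated in the degraded group. The
second effect is a composition artifact that a global size factor cannot
remove, and it manifests as length-correlated false-positive DEGs.

3' tag counting removes the artifact at the counting stage: if both groups
are counted only over the 3'-terminal N nucleotides of one representative
isoform per gene, the countable region is (approximately) equally affected
by degradation in both groups, and the length-dependent bias cancels.

## Annotation surgery

Internal coordinates are 0-based half-open; GTF I/O converts to and from
the 1-based inclusive convention. Only `exon` features are modelled —
counting is exon-based, CDS/UTR structure is irrelevant here.

*Isoform filtering.* Two modes. `expression`: keep the per-gene argmax of
a user-supplied isoform abundance table (FPKM-like, typically estimated
from the highest-quality group); absent transcripts count as abundance 0,
ties (including all-zero genes) break to the lexicographically smallest
transcript id so the output is deterministic, and silent genes are kept —
the downstream expression filter removes them. `threeprime`: keep the
isoform(s) whose 3' end is the most downstream genomic coordinate (max
end on `+`, min start on `-`), with all tied isoforms retained. This
annotation-only mode needs no expression estimate but can select
unexpressed isoforms, costing some sensitivity.

*3' restriction.* Each transcript keeps exactly its 3'-terminal
min(N, length) transcript-coordinate bases: whole exons outside the
window are dropped and the boundary exon is trimmed, strand-aware. N = ∞
is the identity and is a first-class mode. The operation satisfies
`restrict(restrict(t, N1), N2) = restrict(t, min(N1, N2))` and is verified
base-for-base against a 5'→3' base-walk oracle.

## Intersection-strict counting

A fragment is one read or a merged mate pair (union of aligned blocks;
overlapping mate bases count once). The gene set of a fragment is the
intersection over its aligned bases of the genes whose merged exons cover
that base: empty → `no_feature`, singleton → counted, larger →
`ambiguous`. Counting is unstranded (TruSeq-style libraries), uses primary
alignments only, retains duplicates, does not filter MAPQ, and counts
orphan mates as single-end fragments. Spliced blocks need not match
annotated introns — only exonic containment of aligned bases matters.

Implementation: each chromosome is partitioned into segments between exon
boundary coordinates, each segment labelled with its covering gene set;
a fragment's classification reduces to an intersection of segment labels,
which vectorizes over millions of fragments. Equivalence with a literal
per-base brute force is asserted on randomized layouts, including
overlapping genes.

Downsampling selects fragments (query names) uniformly without
replacement with a numpy PCG64 generator, so a seed fixes the selection
and mates stay together.

## Differential expression

The two-group NB test follows the 2010-era DESeq recipe, implemented here
rather than wrapped, with deliberately simple choices:

- *Expression filter*: a gene is "expressed" when the mean of its two
  group-mean raw counts is ≥ 5 (strictly below 5 is removed). The mean of
  group means (rather than the grand mean) keeps the rule balanced under
  unequal group sizes; a `grand` mode exists.
- *Size factors*: median over genes (with all-positive counts) of
  k_ij / geometric-mean_i, not rescaled further.
- *Dispersion*: per-gene method of moments on normalized counts.
  With q_ij = k_ij / s_j, Var(q) ≈ μ/s + αμ², so
  α̂ = max(0, (pooled within-group variance − μ·ξ)/μ²), ξ = mean of 1/s_j,
  floored at 10⁻⁸. No mean–dispersion regression is fitted; this is the
  simplest defensible variant and its calibration is validated by
  simulation, not by numeric parity with any package. When a group has a
  single replicate the estimate is *blind* (both groups pooled as one
  condition), which allows 1-vs-n comparisons at the price of
  conservatism under true differences.
- *Exact test*: conditional on the total k_S of a gene, each split
  (a, k_S − a) is weighted by P(K_A = a)·P(K_B = k_S − a) with the group
  sums NB-distributed around μ_g = s_g·q₀ (q₀ the pooled normalized mean,
  s_g the summed size factors). The variance of a group sum is taken as
  μ_g + α·q₀²·Σ_j s_j² — the sum of independent per-sample NB variances
  s_j q₀ + α (s_j q₀)². The two-sided p-value is the total mass of splits
  no more probable than the observed one (computed in log space with a
  10⁻¹⁰ relative tie tolerance); α = 0 reduces exactly to the
  binomial-split (Poisson) test. Totals are summed exhaustively, which is
  O(k_S) per gene and fast at bulk scales.
- *FDR*: Benjamini–Hochberg step-up (via statsmodels), DEG ⇔ padj < 0.05.
  Log2 fold change is oriented second-group-over-first with no
  pseudocount; ±inf appears when one group mean is zero.

## Evaluation

`sweep_lengths` runs filter → restrict(N) → count → DE for an N grid and
emits expressed genes, DEGs, %DEG (1 decimal) and sensitivity
(= expressed(N)/expressed(∞), 2 decimals; the baseline is the
isoform-filtered annotation at N = ∞). Expressed counts are non-increasing
as N shrinks (the countable region only shrinks); a violation warns rather
than errors. `deg_length_summary` splits DEGs by fold-change sign and
contrasts selected-isoform lengths with a Welch t-test; with fewer than
two genes in a direction the statistic is undefined and flagged, and two
identical constant length lists report t = 0, p = 1.

## The simulator

The generator's defaults are the study conditions used throughout the
tests: 2000 non-overlapping genes on one synthetic chromosome, mixed
strands, 1–10 exons, lengths log-uniform on 200–15000 nt, 1–3 isoforms
per gene (minor isoforms are 5'-truncations, occasionally lacking the
3'-terminal exon), lognormal baseline expression (meanlog 1.5, sdlog 1),
NB dispersion 0.05, three replicates per group, 10⁶ single-end 100-nt
fragments per library, 10% planted DE at 4-fold (random direction) when
DE is requested, and degradation λ = 0 (intact) versus 5·10⁻⁴ per nt.

Degradation is modelled as memoryless random breakage plus polyA capture:
a molecule of length L retains its 3'-terminal D = min(L, Exp(λ)) bases.
λ is an abstract degradation level standing in for (inverse) RNA
integrity; no quantitative mapping to RIN is claimed. Expected fragment
yield per gene is expression × E[D] = expression × (1 − e^(−λL))/λ,
renormalized to the library size — this is what reproduces the
length-correlated composition artifact. Since library preparation samples
fragments in proportion to retained mass, the parent molecule of a
sequenced fragment carries a *length-biased* draw of D (sampled by
rejection, accepting D with probability D/L); fragment starts are uniform
within the retained segment and reads are emitted pre-aligned with
correct spliced CIGARs. Without the length-biasing the expected yield
inside a small 3' window would retain a spurious dependence on the full
transcript length, which the physical sampling process does not have.

What the simulator does *not* emulate: sequence content and sequencing
error (qualities are cosmetic; nothing downstream reads them), rRNA
contamination, ribosomal-depletion protocols, positional/sequence-specific
priming bias, exonucleolytic (5'-protected) degradation, multi-mapping
reads, and expression of minor isoforms (all molecules come from the
major isoform). Passing tests therefore demonstrate the counting and
inference machinery and the degradation-confound mechanism, not
performance on every real-data pathology.

## Numerical and scale choices

Fragment classification, transcript-coordinate mapping and retention
sampling are vectorized numpy; a 6-sample, 10⁶-fragment experiment runs
the full five-point sweep in well under a minute. Test problem sizes
(hundreds of genes, 10⁵ fragments for unit tests; 2000 genes, 10⁶
fragments for the end-to-end property checks) were chosen as the smallest
scales at which the Monte-Carlo assertions are stable. Coverage bins are
floor(100·t/L) with the final base clamped to bin 99; per-transcript
profiles are depth-normalized before averaging so expression does not
weight the mean profile; the 3' half is bins 50–99. Seeds derive from a
single `numpy.random.SeedSequence` so every artifact is reproducible
byte-for-byte from one integer.

## Known limitations

- Gene-level only: unsuitable for alternative-splicing analysis, and a
  gene whose condition-specific signal lives in a non-major isoform can
  be missed.
- The dispersion scheme is cruder than shrinkage estimators; at n = 3 per
  group raw p-values are mildly anti-conservative, though BH-adjusted
  calls remain calibrated in the null simulations.
- The `threeprime` isoform mode can pick unexpressed isoforms when genes
  have alternative polyadenylation sites.
- Sensitivity of the sweep is defined against the isoform-filtered N = ∞
  baseline, not the raw multi-isoform annotation.
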