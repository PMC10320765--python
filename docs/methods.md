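# Methods

## The statistical model

### Allele-by-condition interaction (delta-ASE)

For one gene, let Y_acr be the TPM of allele a ∈ {A, B} in condition
c ∈ {control, senescent}, replicate r = 1..R. The design is balanced, so the
two-way fixed-effects ANOVA decomposes exactly over cell means:

    SS_int = R · Σ_ac (ȳ_ac − ȳ_a· − ȳ_·c + ȳ)²,   F = SS_int / (SS_res / 4(R−1))

with 1 and 4(R−1) degrees of freedom. The implementation vectorizes this
decomposition across all genes at once; tests cross-check it against an
independent regression route (residual-SS difference of nested linear
models, and statsmodels `anova_lm`) to 1e-9.

The analysis scale is raw TPM by default, with `scale="log2"`
(log2(TPM + 0.5)) as a documented alternative. Genes with zero residual
variance are flagged degenerate, excluded from the "genes tested"
denominator, and never called delta-ASE. The delta-ASE call takes the top
25% by interaction F — exactly ceil(0.25 · n_tested) genes, ties broken by
ascending gene id so reruns are deterministic. Ranking by F rather than p
is the procedure's definition; in a balanced design with common degrees of
freedom the two orders coincide.

### The TF screen

A TF's targets are the genes whose strand-aware 5-kb upstream window a
binding site overlaps by ≥ 1 bp (full containment is a config option; with
the generator's default 12-bp sites the two rules differ only for sites
straddling a window edge). Window coordinates for a 1-based TSS t:
`[t−1−window, t−1)` on '+', `[t, t+window)` on '−', 0-based half-open.
A gene has a variant for a TF if *any* of that TF's in-window sites
contains an SNV (`start ≤ pos−1 < end`); the per-gene variant count sums
over sites. The most inclusive ("any-site") aggregation is the default
because multi-site genes are otherwise ambiguous.

Per TF the 2x2 table (variant presence × delta-ASE) is tested with the
conventional two-sided Fisher's exact test (sum of hypergeometric point
probabilities ≤ the observed one; scipy's implementation, verified against
exhaustive fixed-margin enumeration to 1e-12). Eligibility requires ≥ 250
targets in every cell **at genome scale**; BH correction runs across
eligible TFs only, since ineligible TFs are eliminated before testing.

Variant-position profiles use a Gaussian kernel evaluated directly
(mean of N(x_i, h) densities on a fixed grid) so an absolute bandwidth in
bp is meaningful and zero-variance strata are well defined; densities
integrate to 1 within 1e-3 by the trapezoid rule on the default 512-point
grid spanning the data ± 4 bandwidths.

### Directional gene-set enrichment

For a log2-ratio profile r over profiled genes and a term with k profiled
members, s_true = Σ r over those members. The null draws sets of size k
without replacement from all profiled genes and recomputes |s|; the
default p is the add-one estimator (1 + #{|s_rand| ≥ |s_true|}) / (N + 1),
which is never zero and respects p ≥ 1/(N+1). Ties count against
significance, and an exact-tie tolerance of 1e-12 relative makes the
comparison robust to summation order (the term-equals-universe case is
exactly p = 1). The plain proportion and the as-printed reversed
inequality (proportion with |s_true| > |s_rand|, which is *large* under
strong enrichment) are available behind flags; the conventional direction
is the default because a small-p-is-significant convention is the only
self-consistent reading. BH correction runs across all tested terms.

## The synthetic-data generator

The generator emulates the study design, not the study's genome:

- **Annotation**: genes placed round-robin on chromosomes, TSS ≥ 10,001 so
  upstream windows never underflow, consecutive TSS ≥ 12 kb apart so 5-kb
  windows are disjoint; strands ~50/50; exonic lengths log-normal around
  1.5 kb.
- **Sites**: per (TF, gene), with probability `site_prob` (default 0.7,
  reflecting how broadly ChIP-compendium TFs cover promoters) one 12-bp
  site uniformly inside the gene's upstream window; decoys (default
  probability 0.1) rejection-sampled outside every window.
- **Variants**: per site, Bernoulli(p_causal or p_background); position
  round(center + N(0, offset_sd)) clipped into the site, emitted 1-based;
  duplicate positions collapsed.
- **Counts**: per gene, baseline μ ~ LogNormal(ln 100, 1.2); background
  main effects β, γ ~ N(0, 0.1) log2 units; interaction δ = +1.5 log2 on
  variant-bearing causal-TF targets with probability
  `planted_fraction` = 0.3 (a minority of binding-site variants are
  functional). Expected counts are scaled per sample to a common library
  size (default 1e6) before a Gamma–Poisson draw with dispersion 0.1
  (var = μ + 0.1 μ²), a typical biological CV for bulk RNA-seq of cell
  lines. No within-species variance estimate exists for this design, so
  dispersion is a declared free parameter, not an estimate.
- **Gene sets**: terms sample genes without replacement; planted terms
  take ~80% of members from the planted-gene pool.

Each generator draws from its own RNG stream keyed by (seed, operation),
so regenerating one stage never perturbs another, and all outputs are
byte-identical under a fixed seed.

What the generator does **not** emulate: sequence content (no FASTA,
motifs or reads), mapping bias, overdispersion heterogeneity across genes,
correlated replicates, GO-graph structure, or the compositional coupling
of real libraries beyond simple library-size scaling. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the declared model — not that the biological conclusions transfer to
any particular real dataset. One consequence worth knowing: because TPM is
compositional, a planted interaction on a large fraction of the library is
partially absorbed by normalization; the planted-minority regime
(planted_fraction · variant rate · site_prob ≪ 1) is both the realistic
and the identifiable one.

## Problem sizes and scaled thresholds

The default 250-per-cell eligibility filter presumes a genome-wide
universe (~17,600 expressed genes). The synthetic benchmarks run at
2,000–4,000 genes, where no TF can reach 250 targets per cell, so
end-to-end tests and `scripts/acceptance.py` scale the threshold with the
universe — 100 at 4,000 genes, 50 at 2,000 — while the library default
remains 250. Benchmark sizes: null calibration at 2,000 genes × 20 TFs
over 5–10 seeds; recovery at 4,000 genes × 20 TFs over 10–20 seeds;
resampling checks at N = 10,000 draws. These sizes give the quoted checks
comfortable statistical resolution (e.g. ≥ 100 eligible-TF null tests for
the FDR bound) while keeping a full run in minutes.

## Numerical and degenerate-input choices

- "Counts in more than half the samples" is read as a strict inequality on
  nonzero-count samples (a gene nonzero in exactly half is dropped);
  configurable by the caller filtering on the returned index.
- Pseudocount 0.5 TPM in ratio stages guards zeros; 0 is allowed when the
  caller guarantees positivity.
- All-zero sample columns are an error naming the sample (TPM undefined).
- The timecourse test is a per-gene one-way ANOVA across timepoint labels
  on log2(TPM+1); zero-variance genes return p = 1 with a degenerate flag.
  A true multivariate (across-gene) ANOVA would need many more replicates
  than the design provides.
- Odds ratios use the sample estimate ad/bc with ∞ when only bc = 0 and
  NaN when both products vanish.
- Sort orders everywhere are total (mergesort on explicit key columns), so
  equal statistics cannot reorder output between runs.

## Known limitations

- The interaction test on raw TPM relies on the F-test's robustness to the
  mild mean–variance coupling the NB model induces; calibration is
  verified empirically (KS < 0.05 at 2,000 genes) rather than guaranteed
  analytically. The log2 scale option is the conservative alternative.
- The resampling p-value loops over draws; at the default N = 10,000 and
  catalog sizes in the hundreds this is seconds-to-minutes, not optimized
  further.
- Spearman concordance treats genes as exchangeable; no gene-length or
  expression-level stratification is attempted.
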