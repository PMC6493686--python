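# Methods

This note documents the models and procedures `sescape` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Chromatin-element definitions

Elements are defined by two-mark co-occupancy (≥ 1 bp overlap):

| element | defining marks | anchor coordinates |
|---|---|---|
| active enhancer | H3K4me1 ∩ H3K27ac, promoter-distal | the H3K4me1 peak |
| poised enhancer | H3K4me1 ∩ H3K27me3, without H3K27ac | the H3K4me1 peak |
| active promoter | H3K4me3 ∩ H3K27ac | the H3K4me3 peak |

The anchor choice is open in principle (the H3K4me1 peak, the H3K27ac peak,
or their intersection could each serve); the enhancer-defining mark is used
because it is the element's identity, and `anchor="intersection"` is
available. An H3K4me1 peak carrying both H3K27ac and H3K27me3 counts as
active, not poised — the activating mark wins. Promoter exclusion uses the
same ±2 kb TSS window as the promoter/intragenic/intergenic classification
(`promoter_halfwidth`, default 2000 bp); the ±1 kb window used when
splitting shared vs unique binding sites between cell types is a separate
parameter (`tss_window`).

All coordinates are 0-based half-open throughout (BED convention); SNP
tables give 1-based positions converted to width-1 intervals `[p−1, p)` on
read. Abutting intervals share zero bases and do not overlap.

## Peak-to-gene assignment

Regions are assigned to the gene with the nearest TSS on the same
chromosome, measured from the region midpoint (configurable to
nearest-edge). The signed distance is `midpoint − TSS`, negated for
minus-strand genes. Ties break to the lexicographically smallest gene id so
runs are reproducible. A regulatory-domain (GREAT-style) assignment is not
implemented.

## Super-enhancer calling

1. **Promoter exclusion.** Active enhancers with midpoints within ±2 kb of
   a TSS are removed. (The ROSE convention of ±2.5 kb is available through
   `promoter_exclusion`; the internal ±2 kb promoter window is the default
   for consistency with the element definitions.)
2. **Stitching.** Remaining enhancers are concatenated whenever the
   intervening gap (`next.start − prev.end`) is at most 12.5 kb; overlapping
   or touching enhancers always merge; merging is transitive. Each stitched
   entity records its constituents.
3. **Quantification.** Signal is re-counted over the stitched span (not
   summed over constituents): reads are taken as uniform within their source
   regions, so a span receives `count × (shared bp / region width)` from
   each overlapping region. The ranking signal is
   `treatment_rpm/bp − input_rpm/bp`, floored at 0. rpm is reads per million
   mapped reads; per-bp division uses the full span width, so sparse
   stitched entities are diluted by their internal gaps, as in ranked
   hockey plots.
4. **Cutoff.** Entities are sorted by ascending signal; ranks and signals
   are rescaled to [0, 1]. The cutoff is the smallest rank from which the
   tangent slope of the curve exceeds 1 and stays above. The slope is
   measured on the **lower convex envelope** of the scaled curve rather
   than on raw finite differences: envelope slopes are nondecreasing, so
   the "stays above" condition is well-posed under counting noise, and on
   convex curves the crossing point provably coincides with the point of
   maximum vertical distance below the diagonal (the classic geometric
   knee). Raw central differences wiggle around 1 throughout the
   super-enhancer range of a noisy curve and make the sustained-crossing
   rule cut essentially arbitrarily; the envelope form is the same
   tangent-slope-1 geometry made robust. Entities strictly above the
   cutoff are super-enhancers; a constant or never-steep (e.g. linear)
   curve yields zero super-enhancers with a warning.
5. **Gene assignment** by nearest TSS of the span.

Any count matrix can rank the entities — the activating histone mark by
default, a TF or cofactor alternatively — with identical stitching
parameters in every mode.

Library-size invariance: multiplying all library sizes by a constant
rescales every signal by the same factor and leaves ranks, the cutoff, and
the SE set unchanged.

## Statistics

* **Fisher exact** (binding fractions): two-sided by the probability-mass
  rule — the sum over fixed-margin tables no more probable than the
  observed one (the most common convention; scipy's).
* **Hypergeometric** (gene-set overlap): upper tail `P(X ≥ k)` inclusive.
* **Binomial** (SNP enrichment): upper tail `P(X ≥ k)`, computed in log
  space.
* **Wilcoxon rank-sum**: exact permutation null when the combined sample
  size is ≤ 20 (a tie-aware subset-sum dynamic program over midranks,
  written here because scipy's exact method refuses ties), otherwise the
  normal approximation with tie and continuity corrections. Two-sided
  exact p doubles the smaller tail, capped at 1.
* **Kruskal–Wallis**: H with tie correction, chi-square tail on k−1 df;
  identical values across groups return H = 0, p = 1 with a warning.
* **Pearson** on log2-transformed mean SE signal (pseudocount 1 rpm/bp).
* `−log(P)` always means `−log10(P)`.
* Benjamini–Hochberg q-values are provided for the trait scan.

## Differential enrichment

No replicate structure is assumed (knockdown vs control, pooled counts).
The statistic is the exact conditional binomial rate-ratio test: given a
region's total `t = a + b` pooled reads across conditions, under no change
`a ~ Binomial(t, L_kd/(L_kd + L_ctl))`; the two-sided p doubles the smaller
tail (capped at 1) and is computed in log space so extreme regions keep
finite `−log10 p`. This engine was chosen deliberately over a moderated
(dispersion-shrinking) model: it is self-contained, enumerable, and exactly
testable against a summation oracle. It is anti-conservative if biological
replicates with overdispersion were pooled — a documented limitation, not
an issue for the pooled-count design it serves.

Effect size: `log2((kd_rpm + ψ)/(ctl_rpm + ψ))` with pseudocount ψ = 1 rpm.
Classes: *loss* iff `log2FC ≤ −1` and `−log10 p ≥ 4`; *gain* symmetric;
otherwise *unchanged*. Super-enhancer spans use the milder `|log2FC| ≥
0.58` (fold change 1.5) with the same p threshold and classes
decreased/increased/constant. Swapping the condition labels negates every
log2FC and exchanges loss↔gain exactly (the two tails of the conditional
binomial are mirror images).

Power at these thresholds: an effect exactly equal to the fold-change
threshold is detected ~50% of the time at any depth, because the estimate
is centered on the threshold; the calibration suite therefore measures
power at the generator's planted effect (|log2FC| = 1.5) and mean depth
≥ 50 reads, where the correct class is assigned in ≳80% of regions.

## SNP enrichment and the matched null

Trait SNPs are counted per SNP (a region holding several SNPs contributes
each; per-region indicator counting is available). The null hit
probability `p0` comes either from a background SNP catalog (fraction of
background SNPs inside the regions) or from matched permutations (mean
fraction of the trait's own SNPs hitting shuffled regions); significance is
the upper-tail binomial, and permutation mode adds the empirical
`(1 + #{perm ≥ obs}) / (1 + n_perm)`. A zero `p0` is floored at half the
reciprocal background size and flagged.

The shuffle keeps each region's chromosome and exact width and places it
uniformly over every start position whose full interval fits inside one
permissive segment (one draw over the concatenated valid starts, so
placement is exactly uniform). Within one permutation regions may not
overlap each other (toggleable); placement is rejection-sampled
widest-first, and a jammed chromosome discards its placements and restarts
rather than biasing toward the jam. No linkage-disequilibrium expansion of
SNP catalogs is performed — enrichment statements are per catalog SNP, a
documented limitation.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
real genomes. Default study conditions: 3 chromosomes × 10 Mb; ~30%
repressed territory in 100 kb blocks; 300 genes; 25 planted enhancer
clusters of 3–6 constituents (widths 0.8–2 kb, intra-cluster gaps 0.2–2 kb)
among 250 singleton enhancers and 40 poised enhancers, all placed in
permissive territory with ≥ 13 kb between entities so distinct entities
never stitch together.

**Counts** are Gamma–Poisson: each region draws a latent strength
`s ~ Gamma(5, 1/5)` (mean 1; the standard negative-binomial account of
ChIP-seq overdispersion) shared across marks and conditions, and counts are
Poisson around `0.05 reads/bp × width × multiplier × s`. Singleton
enhancers therefore average ~70 reads. Planted cluster constituents carry a
multiplier of 5× times a per-cluster boost drawn log-uniform over [1, 10]:
the 5× floor keeps every cluster above typical enhancers, and the
long-tailed boost reproduces the orders-of-magnitude dynamic range real
ranked curves show. That range is what makes the knee unambiguous: with a
strictly uniform 5× multiplier the slope-1 cutoff falls where the upper
tail of ~250 Gamma-dispersed typical enhancers is still dense (the knee
sits where the order-statistic spacing reaches `ymax/n`), letting ~15
typical enhancers through and capping precision near 0.6 regardless of
cutoff estimator. `se_multiplier_log10_spread=0` restores the strict
uniform multiplier for stress tests.

**TF binding** is Bernoulli per entity — per cluster (p = 0.9) or per
singleton (p = 0.3) — and a bound cluster places a TF peak on every
constituent; TF counts scale with the shared strength where bound, so
entity-level bound fractions and TF-ranked calling are both recoverable.
MED1 counts are half the activating-mark rate with mild extra per-mark
noise (Gamma, shape 10), and co-change with the planted differential
factors. Input counts are flat at 4% of the base rate.

**Differential planting**: 25% of clusters (whole clusters) plus enough
singletons to reach 15% of regions lose signal in the knockdown
(× 2^−1.5); 5% of regions (singletons) gain (× 2^+1.5).

**Expression** couples to the landscape by the package's own nearest-TSS
assignment: genes nearest planted clusters draw higher absolute expression
than genes nearest singletons; genes nearest loss/gain regions draw
negative/positive expression log2FC (±1.2 ± 0.4), others ~N(0, 0.25).

**SNPs**: background SNPs are Poisson (100/Mb of permissive territory)
placed uniformly on permissive chromatin. One trait ("CVD") is planted with
relative risk 5: a SNP falls in planted SE spans with probability
`RR·f/(RR·f + 1 − f)` where f is the SE fraction of permissive territory,
uniformly within the chosen stratum — the strata are exclusive (SE vs
permissive-minus-SE), so relative risk 1 reduces exactly to the uniform
null. Nine additional traits are uniform null traits. No SNP falls in
repressed chromatin, matching the null the enrichment stage assumes.

What the generator does **not** emulate: read-level data (mappability, GC
bias, fragment-length effects), realistic gene annotation (isoforms,
overlapping genes), peak-width/signal correlation structure beyond the
shared latent strength, linkage disequilibrium between SNPs, or replicate
structure. Passing tests therefore demonstrate the correctness and
calibration of the pipeline's logic under its own model assumptions — not
robustness to alignment or peak-calling artifacts in real data.

A fully deterministic worked example (one 200 kb chromosome, 12 enhancers,
two planted clusters, hand-checkable counts and SNPs) is generated by
`sescape.simulate.worked_example()`; every number it produces downstream —
the two SE calls, the decreased cluster, the binomial SNP p — is enumerable
by hand and frozen in the tests.

## Numerical and degenerate-case choices

* Tie-breaks are deterministic everywhere (stable sorts, lexicographic
  gene ids), so identical inputs give byte-identical outputs; output
  headers record the tool version, a hash of the analysis parameters, and
  the seed — never a timestamp.
* Constant ranking signal, a linear ranked curve, empty peak sets, empty
  differential classes, and geneless chromosomes all degrade to defined
  results with warnings rather than errors; infeasible synthetic
  placement and infeasible shuffles raise before emitting anything.
* `recount` rounds redistributed counts to the nearest integer; spans that
  fully contain their source regions (the stitched-entity case) recover
  exact sums.
* Problem sizes in the test and acceptance suites (10⁴-region null
  calibrations, 10-seed recovery runs, 1000-replicate empirical-p
  calibration at 79 permutations, 100-seed negative controls) were chosen
  as the smallest sizes at which the asserted bounds are stable.

## Known limitations

* The conditional binomial differential test ignores biological replicate
  dispersion (pooled design only).
* Nearest-TSS assignment misattributes enhancers that skip their nearest
  gene; no 3D-contact information is used.
* SNP enrichment treats catalog SNPs as independent (no LD).
* bigWig input is not supported; coverage comes from per-region counts or
  text bedGraph.
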