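# Methods

## Scope and data model

The package analyses per-cytosine bisulfite methylation reports
(chromosome, position, strand, trinucleotide context CG/CHG/CHH,
methylated and total read counts). All genomic intervals are 0-based
half-open internally; GFF3 and 1-based reports are converted on read, BED
is native. The atomic container is a columnar `Methylome` (a sorted
DataFrame with per-chromosome range queries); per-record streaming is
available where a consumer wants row-level validation.

## Weighted methylation and the island test

The weighted level of a region/context is Σ methylated reads / Σ total
reads — the read-weighted estimator, bounded in [0, 1] and undefined (NaN,
never 0/0) for uncovered regions. A genome-wide weighted level per context
forms the background p₀, the null rate of the island test.

Island calling tiles each chromosome into nonoverlapping windows
(default 100 bp; a short terminal window is kept and flagged). Windows
with more than five covered CHH cytosines are tested with the exact
one-sided binomial tail P[X ≥ k | Bin(n, p₀)] on their pooled CHH read
counts. Adjustment is Benjamini–Yekutieli, pooled across all tested
windows genome-wide, because window counts along a chromosome are
spatially dependent and BY remains valid under arbitrary dependence.
A window becomes an island when q < α (default 0.01) *and* any of its
bases overlaps the strand-aware 2 kb 5′ or 3′ flank of a gene
(containment would silently drop boundary windows, since windows and
flanks sit on different lattices).

Deliberate readings of underspecified rules, each switchable:

- "More than five mCHH cytosines" counts **covered** CHH sites, not
  methylated ones — a minimum-information filter should not precondition
  on the alternative hypothesis (`site_metric="methylated"` gives the
  other reading).
- Testing precedes the proximity rule; BY spans all tested windows, not
  only near-gene ones, and pools across chromosomes.
- The empirical alternative calls a window at weighted mCHH ≥ 0.25, a
  closed lower bound.
- Genes qualify for island association only if they pass the near-gene
  coverage rule: ≥ 50% of CHH sites in the 5′ 2 kb flank with depth > 2.

A per-site caller (binomial against a user-supplied bisulfite
non-conversion rate, no hidden default, BH across sites, no-call below
two reads) supports the site-fraction variant of the analysis.
`method_agreement` reports the fraction of genes designated identically
by two calling modes.

## Profiles and enrichment

Metaprofiles use 10 × 200 bp flanking bins on each side and 20
proportional gene-body bins, strand-mirrored so bin 0 is always 5′-most;
a bin with no covered sites in a gene is skipped for that gene's average
rather than zero-filled. Near-gene enrichment divides the mean 1 kb
upstream weighted mCHH by the mean over an equal number of 1 kb windows
sampled uniformly without replacement from the genome tiling, restricted
to windows with at least one covered CHH site (unassembled or uncovered
stretches would otherwise deflate the denominator); the RNG seed is part
of the result. Genes whose flanks run off the chromosome are excluded
from profiles and enrichment. Island-centered profiles take, per gene,
the significant window nearest the TSS and average 100 bp bins ±2 kb
around its midpoint.

## Genic predictors

- **TE distance**: min over same-chromosome repeats of
  min(|TSS − start|, |TSS − end|), 0 on gene overlap, missing when the
  scaffold has no repeat (such genes drop out of TE analyses). With
  half-open intervals the mirrored-coordinate distance can differ by 1 bp;
  this is the documented edge convention, not an error.
- **Gene length**: annotated span (introns included); exon-sum length of
  the longest transcript is carried as a secondary measure. When a gene
  has several transcripts, the longest (by summed exon length, ties by
  smallest transcript id) defines the exons.
- **Expression quartiles**: 25/50/75% linear-interpolation quantiles of
  log₂ RPKM over expressed genes; genes absent from the table — and, by
  default, genes with RPKM = 0, whose log is undefined — sit in
  quartile 0. A value equal to a breakpoint falls into the lower
  quartile, so a fully tied expressed set lands in quartile 1.
- **gbM**: exonic weighted CG level over the longest transcript's exons;
  the binary trait is a one-sided binomial CG-hypermethylation test
  against the genome CG background with BH FDR 0.05 across genes, under
  the classic definition additionally requiring no CHG/CHH
  hypermethylation (`definition="cg_only"` relaxes this).
- **Standardisation**: (x − min)/(max − min) to [0, 1]; the divisor is
  the shifted maximum so the output actually spans [0, 1]; missing values
  propagate; constant vectors are an error.

## Model fits

Logistic regression is a maximum-likelihood logit fit (statsmodels;
convergence 1e-8, 100 iterations) with listwise deletion of rows missing
any predictor (the dropped count is reported). Complete separation and
rank-deficient designs are flagged on the fit object rather than silently
returned; variable importance (|z| per coefficient, with signed z for
directional display) refuses unconverged or collinear fits. gbM may enter
as the binary trait (default) or as quantitative exonic mCG.

PGLS assumes Brownian motion with no λ estimation: the tip covariance is
the shared root-to-tip path length, computed from patristic distances as
(d(root,i) + d(root,j) − d(i,j))/2, and the fit is GLS with that sigma.
On a star tree with equal branch lengths this reduces to OLS exactly
(machine tolerance), which the tests verify. The OLS helper reports
signed r² (sign of the slope times r²) for display parity with
negative-association conventions.

## Conservation

The ortholog panel is an ortholog × species boolean matrix; an ortholog
failing the coverage filter in a species is missing (NaN) in that column,
and each pairwise comparison uses only doubly-scored orthologs — the
proportions entering the expectation N·pᵢ·pⱼ are recomputed on that
subset rather than taken from the full panel. The permutation test
shuffles one species' labels (shuffling both is equivalent in
distribution) with p = (1 + #{perm ≥ observed})/(n_perm + 1). The random
model for per-ortholog species counts is independent Bernoulli per
species; its analytic mean is Σ pₛ, and a seeded Monte-Carlo variant
returns a p-value for an observed mean, two-sided by default (the
question is "indistinguishable from random", with a one-sided option).

## TE analyses

Per-superfamily enrichment tests each superfamily's island count k of n
(genes whose nearest upstream-within-2-kb TE belongs to it) with an exact
binomial test against the pooled proportion, two-sided by default with
direction labels (Enriched/Under/NS) at BH FDR 0.05; a one-sided
alternative is available. The count-weighted mean of per-superfamily
proportions equals the pooled proportion by construction — an identity
the tests use to check published tables for internal consistency.

The Feltz–Miller asymptotic test compares coefficients of variation:
with cᵢ = sᵢ/x̄ᵢ and pooled c = Σ(nᵢ−1)cᵢ/Σ(nᵢ−1), the statistic
Σ(nᵢ−1)(cᵢ−c)²/(c²(0.5+c²)) is χ²(k−1). Distances for the island/TE CV
comparison anchor at the island window midpoint (edge-order invariant for
a 100 bp window), for islands whose midpoint lies inside an annotated TE;
when several TEs contain the midpoint the shortest is used.

Coincidence analysis restricts an ortholog panel to one species pair,
discards orthologs with islands in both or neither species, and classes
single-island orthologs by where the lineage-specific TE sits: same
species → coincident, other species → dissonant; TE in both or neither
is unclassifiable. The headline test is a 1-df goodness-of-fit of
(coincident, dissonant) against 50:50; per-superfamily over/under-
representation uses 2×2 contingency χ² with BH FDR, as the construction
is otherwise unspecified.

BLAST summaries reduce tabular (-outfmt 6) hits to the best e-value per
query window, assign 1.0 to hitless queries, and report fractions below
1e-5 and 1e-40 plus a log₁₀ histogram; control mode is the same summary
over an equal number of sampled non-island windows.

## Synthetic data

The generator emulates the study conditions, not any particular genome:
random uniform-composition chromosomes with cytosine contexts derived
from the sequence on both strands (so CG/CHG/CHH site densities and
strand handling are realistic); backgrounds CG 0.60, CHG 0.40, CHH 0.05
(grass-like; CHH backgrounds in grasses are ≤ ~12%); islands as
100–300 bp tracts ending 0–1500 bp upstream of the TSS at CHH 0.40 with
CG/CHG raised 0.2 over background (islands are elevated in all three
contexts); gbM genes at exonic CG 0.85; TEs with an edge within 2 kb of
a configurable fraction of genes plus intergenic background elements;
log-normal RPKM for ~85% of genes. Depth is Poisson (mean 10×) and
methylated counts are beta-binomial with concentration 50 to emulate
biological overdispersion; an exact-binomial mode exists for
distribution-theory tests. Genes are packed in fixed slots so every gene
keeps full 2 kb flanks; overfull configurations raise an infeasible-
packing error. Panels draw island indicators from an equicorrelated
Gaussian copula (marginals pₛ, latent correlation ρ; ρ = 0 is the random
regime) and impose them on per-species generators sharing ortholog ids;
the species tree is a random coalescent. All randomness flows from one
mandatory seed and reruns are bit-identical.

What the generator does *not* emulate: realistic sequence composition or
TE sequence evolution, read-level artefacts (mapping bias, conversion
failure beyond a scalar), chromosome-scale methylation domains, or
correlated placement of islands with expression. Passing recovery tests
therefore demonstrates the statistical machinery is correct under the
stated generative model, not that real-data results are reproduced.

## Problem sizes and numerical choices

The test suite exercises FDR control on twenty 5 Mb single-chromosome
null genomes and island recovery on three 1.5 Mb planted genomes;
conservation null/power use 100 replicate panels of 500 orthologs × 8
species; calibration suites use 200–1000 replicates. These sizes give
stable Monte-Carlo estimates while keeping the default run fast.
Binomial tails use exact scipy survival functions (no normal
approximation); BY/BH adjustments go through statsmodels and are checked
against direct step-up implementations; logistic and GLS fits go through
statsmodels. Zero-coverage regions are NaN, never zero; degenerate
backgrounds (p₀ ∈ {0, 1}) are errors, not silent saturation.

## Known limitations

- Published full-genome results that require the original WGBS data
  (per-species island percentages, importances, BLAST fractions) are not
  reproducible at desk scale; the package validates internal arithmetic
  of the published tables and the machinery's statistical properties.
- The binomial window test assumes read-level independence within a
  window; overdispersion makes it anti-conservative in principle, though
  at the simulated overdispersion (concentration 50) the BY-controlled
  genome-wide calls remain well below the nominal rate.
- Context is taken from the report, never recomputed from a reference
  sequence (the sequence-based deriver exists only inside the
  generator).
- PGLS fixes Brownian covariance; no Pagel's λ or OU alternatives.
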