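# Methods

This note documents the models and conventions behind `speqtl`, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Coordinates and formats

All in-memory coordinates are 0-based half-open. VCF and GFF3 files are
read and written 1-based per their standards; BED/BEDPE are 0-based
half-open; the SNP and GWAS TSV dialects carry an explicit `pos_1based`
column. Round-trip identity of every record type is property-tested.
Unknown chromosomes in any input are skipped with a logged tally rather
than aborting the run.

## Restriction digestion and spatial pairing

The genome is cut at `match start + cut_offset` for every exact
forward-strand occurrence of the enzyme motif (default `GATC`, offset 0 —
MboI-style). Overlapping occurrences all count. Forward-strand matching is
lossless for the palindromic motifs the common Hi-C enzymes use. Fragments
tile each chromosome exactly; the tiling invariant is asserted after every
digestion.

BEDPE contact intervals are reduced to fragments by their **midpoint** — an
unambiguous rule for intervals straddling cut sites; heterogeneous
published Hi-C libraries do not come with a canonical reduction, so this is
our convention. Contacts are unordered fragment pairs, canonicalized with
the smaller id first; self-pairs are dropped at read time.

Genes are anchored by **TSS** for fragment assignment, because eQTL
distance conventions are TSS-based; `gene_anchor="any-overlap"` assigns a
gene to every fragment its body intersects, for sensitivity analyses. A
SNP–gene pair is *spatial* when any library shows a contact between their
fragments; contacts are binary evidence (count ≥ 1, no frequency
threshold), libraries are pooled, and provenance is retained per pair.
SNP–gene pairs sharing one fragment are emitted too, flagged
`same_fragment`, since within-fragment proximity is unobservable by Hi-C —
these are the only pairs allowed to carry an empty library set.

## eQTL model

Association is ordinary least squares of log2 expression on additive
dosage (0/1/2) with a two-sided t-test on the slope and pairwise deletion
of missing values; no covariates are fitted by default (a covariates hook
exists but expression-factor inference is out of scope). The slope on the
log2 scale is the allelic fold change (aFC) per alternative allele;
downstream analyses use only its sign (direction of effect), which this
definition preserves. Degenerate inputs are skipped with reason codes
(`zero_dosage_variance`, `zero_expr_variance`, `too_few_samples`; default
minimum 10 complete pairs); a perfect fit gets the smallest positive
normal float as p with a `degenerate` flag.

BH adjustment is applied **once across all SNP–gene–tissue tests jointly**
(the singular correction over a combined test set; conservative as the
test set grows). `fdr_scope="per-tissue"` is available since the
alternative scope is defensible. Significance is FDR < 0.05.

Distance classes: *cis* ≤ 1 Mb on one chromosome (boundary inclusive — the
published definition says "within 1 Mb" without a boundary rule, so the
inclusive reading was fixed once), *trans*-intrachromosomal > 1 Mb,
*trans*-interchromosomal across chromosomes (distance undefined).

## Overlap and bootstrap null

Identity is by rsID (and gene id) string. The observed overlap is compared
to `n_boot = 10,000` draws of |A| identifiers without replacement from a
universe; the draw-overlap counts *are* samples from
Hypergeometric(N, |B|, |A|), which gives the closed-form oracle used in
tests. Both the fitted-normal upper-tail p and the add-one empirical p
`(1 + #{null ≥ obs})/(n_boot + 1)` are reported; the empirical p is
primary.

The **universe is the single most consequential choice** and is exposed:
for SNP overlaps the default is the union of the two trait lists (plus any
user-supplied background); for eGene overlaps, all genes tested in the
eQTL stage rather than all annotated genes. Note that under the pure-union
SNP universe an overlap equal to the identical-SNP count is typically
*below* its hypergeometric expectation — a genome-scale background list is
needed for that test to be informative, which is why `--universe` exists.
Resampling is uniform; per-chromosome density or MAF matching is not
attempted. Gene-family exclusion lists (e.g. HLA) are applied before any
counting. A shared gene is `identical_snp_driven` only when every
supporting eQTL in both traits carries one and the same rsID.

## Colocalization

Per SNP, the Wakefield log approximate Bayes factor is
`½(log(1−r) + r z²)` with `z = β/se`, `r = w/(w + se²)`. Prior effect
variances default to `w = 0.15²` for quantitative and `0.2²` for
case-control tracks (the standard defaults of the ABF framework; each
track's `trait_type` column selects its w, diseases defaulting to
case-control). Per-SNP hypothesis priors default to p1 = p2 = 1e-4,
p12 = 5e-5.

Locus posteriors use `S3 = p1·p2·(L1·L2 − L12)` and `S4 = p12·L12` with
all sums in log space (log-sum-exp); S3 is floored at zero against
rounding, and a single-SNP locus yields PP3 = 0 exactly. The decision rule
is PP3 + PP4 ≥ 0.99 together with PP4 ≥ 5·PP3, the ratio treated as
infinite when PP3 is exactly zero. Tracks are inner-joined on rsID;
when allele columns are present, swapped ref/alt flips the second β and
strand-ambiguous (A/T, C/G) SNPs are dropped with a warning. The model
assumes a single causal variant per trait in the locus; multi-causal
(SuSiE-style) colocalization is out of scope. A helper reproduces the
"lowest p-value per SNP" pre-selection of eQTL pairs ahead of
colocalization.

## Downstream reports

Tissues are ranked by the count of significant SNP–gene–tissue triads,
ties broken lexicographically for determinism. Direction concordance is
evaluated per (shared gene, tissue) cell requiring at least one
significant eQTL from each trait: `concordant` when both traits' aFC signs
agree on one direction, `discordant` when each side is internally
consistent but opposite, `mixed` otherwise (the three-way split is our
operationalization of "mixed effects"). Enrichment is the hypergeometric
upper tail against a stated background (default: genes tested in the eQTL
stage), BH-corrected across terms; service-specific corrections such as
g:SCS are deliberately not reimplemented, and output headers say BH.

## Synthetic data

The generator's defaults are the study conditions of the test-suite:
2 chromosomes × 1.2 Mb, `GATC` digestion, 60 genes, 80 SNPs per trait with
12 identical, 3 tissues × 200 samples, MAF ~ U(0.1, 0.45), LD blocks of 5
SNPs, aFC ±1.0, residual SD 0.2 on the log2 scale. Problem sizes were
chosen so the full suite and the acceptance script each run in well under
a minute on one CPU while leaving every statistical check non-trivial.

* **Genotypes.** Per haplotype, alleles within an LD block share a latent
  Gaussian factor (correlation 0.8) thresholded at the per-SNP allele
  frequency; the two haplotypes are independent, so each SNP is exactly in
  HWE (χ²-tested over 1,000 SNPs) while neighbours are correlated.
  Blocks are consecutive runs of `ld_block_size` SNPs per chromosome — a
  deliberate caricature of population LD (no recombination maps, no
  structure, no imputation error).
* **Planting by construction.** Planted SNPs are positioned relative to
  their target gene so cis/trans geometry is guaranteed, and a contact
  between SNP and gene fragments is always added (same-fragment cases ride
  the `same_fragment` route) — hence spatial-pair sensitivity to planted
  effects is 1 by construction, and the suite asserts it. Expression is
  simulated directly on the log2 scale, `baseline + aFC × dosage + noise`,
  so the planted effect *is* the estimand of the eQTL stage. Each planted
  shared eGene consumes one cis triple from each trait's SNP pool, both in
  the same tissue so concordance cells exist; the two co-causal SNPs are
  kept in different LD blocks, because correlated co-causal dosages would
  bias each other's marginal OLS slope — a multi-causal-gene property, not
  an effect-size miscalibration. Background contacts are sampled at
  `contact_background_rate` × (SNP-fragment × gene-fragment) pairs to
  create true-null spatial pairs for FDR checks.
* **GWAS loci.** Summary tracks follow the single-causal-variant regime
  the colocalization model assumes: non-causal z-scores are independent
  standard normal (redrawn above |z| = 6 so a planted causal variant, with
  z ~ N(8, 0.5) truncated above 6.5, always carries the locus minimum p by
  construction); `se = 1/√n`. Scenarios: shared causal, distinct causal,
  trait-1 only, null.
* **Determinism.** Everything derives from one `numpy` Generator seeded by
  `SimConfig.seed`; identical seeds give byte-identical output files
  (SHA-256-tested).

What passing tests show — and do not. Parameter recovery on this
generator demonstrates that the pipeline's statistics behave as designed
(FDR control, sign recovery, bootstrap/hypergeometric equivalence,
coloc discrimination). It does not demonstrate robustness to realistic
human LD, cell-type mixtures, expression covariates, or cross-library
Hi-C heterogeneity, none of which the generator emulates.

## Numerical choices and edge cases

* BH runs through `statsmodels.multipletests(fdr_bh)` behind `bh_adjust`,
  verified against a brute-force step-up oracle; BH is tie-invariant, so
  p-value ties need no special handling.
* Posterior arithmetic is entirely in log space; PP normalization is
  asserted to 1e-9, trait-swap symmetry to 1e-9.
* Bootstrap `p_empirical` uses the add-one rule and can never be 0; its
  floor at n_boot = 10,000 is 1/(n_boot+1) ≈ 1.0e-4.
* `shared_fraction` rounds half-even to one decimal.
* Fragment lookup is binary search on fragment starts, cross-checked
  against a linear scan.
* Empty inputs return empty outputs everywhere except where the operation
  is undefined (a coloc locus with no common SNPs, an empty enrichment
  background), which raise.

## Known limitations

No covariate adjustment or permutation-based per-gene p-values in the
eQTL stage; contacts are binary with no significance calling (no Fit-Hi-C,
TADs, loops); one alternative allele per site (no multi-allelic splitting,
no phasing); colocalization is single-causal-variant; the bootstrap
universe must be supplied by the user for genome-scale SNP-overlap claims.
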