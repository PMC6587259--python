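# Methods

This note documents the models and procedures implemented in `neoprior`,
the defaults and why they were chosen, what the synthetic data does and
does not emulate, and the numerical conventions that matter for
reproducing results.

## Somatic variant post-call filters (`neoprior.variants`)

Variant calling itself (alignment, pileups, caller internals) is out of
scope; calls arrive as tables carrying site-level read evidence. Four
screens remove common false-call modes, each re-cast as an explicit test
on that evidence:

1. **Normal contamination** — fails when the normal sample carries any
   alt reads *and* a one-sided Fisher exact test (tumor enriched for the
   alt allele) is not significant at α = 0.05. The one-sided orientation
   is a design choice: the question is whether the tumor is genuinely
   enriched relative to the normal.
2. **Strand bias** — fails when alt reads sit entirely on one strand and
   the exact two-sided binomial test against a 0.5 strand split has
   p < 0.05.
3. **Base-quality drop** — fails when mean base quality at the site is
   more than δq = 10 below the flanking mean.
4. **Mapping quality** — fails when mean mapping quality of alt-carrying
   reads is below 30.

All thresholds are configurable; the defaults are stated here because the
original screens are caller-internal and do not specify test identities.
Germline-database subtraction is represented by an optional gene
exclusion list rather than bundled population databases.

## Peptide enumeration (`neoprior.epitopes`)

For a missense substitution at protein position *p*, every window of
length L ∈ [8, 15] fully inside the protein and covering *p* is emitted
as a mutant/wild-type pair; the count per length is
min(p, n−L+1) − max(1, p−L+1) + 1 clipped at zero. Downstream affinity
scoring uses the 8–11-mer subset for class I and 13–15-mers for class II,
matching the conventional length preferences of the two MHC classes; both
subsets are configurable since only the global 8–15 range is prescribed.
Windows containing ambiguous residues (U, X, B, Z, J, O) are skipped with
a warning.

## Neoepitope criteria (`neoprior.binding`)

Affinity is predicted IC50 in nM — lower is stronger. The three criteria
are applied with the stated strictness: mut < 150 (strict), mut/wt < 0.9
(strict), wt − mut ≥ 100 (inclusive), with the CGC exemption attached to
the difference criterion only. The ratio and difference criteria select
*specific* binders, on the rationale that T-cell precursors recognizing
peptides presented similarly in mutant and wild-type form are depleted by
central tolerance. Ties among passing calls collapse to the minimal
mutant nM, breaking further ties by peptide length then allele name (an
arbitrary but deterministic convention).

## Mutant-allele expression (`neoprior.expression`)

RNA evidence is judged at the mutated site: ≥2 supporting reads; VAF ≥ 4%
when ≥3 reads or ≥ 20% when exactly 2 (inclusive boundaries, "minimum
of"); strand bias tested by the same exact two-sided binomial as the DNA
filter, chosen because the criterion names only a p-threshold. Site-level
RNA depth defines the VAF denominator. RPKM = 10⁹·count/(length·total);
genes below 1 RPKM are "weakly expressed".

## Ranking and panel selection (`neoprior.prioritize`)

The six prioritization criteria are combined lexicographically (CGC,
mutant affinity, affinity difference, VAF, expression, class type), with
the final tie broken by mutation id so output is a deterministic total
order. The published procedure does not specify how its criteria combine
— the ranking there ended at a human selection board — so the lexicographic
order plus an explicit non-expressed quota in `select_panel` replaces
that judgment with a reproducible mechanism. The CLP color strata are
likewise under-specified in the source material; the implementation uses
four strata from {specific vs nonspecific binder} × {expressed vs not},
where "specific" means mut/wt IC50 below 0.5. Every plot writes a TSV
sidecar of plotted values so rendering is testable without image
comparison.

## ELISpot calling (`neoprior.elispot`)

Counts are rescaled linearly to 5×10⁴ plated cells; positivity requires
scaled mutant spots ≥ 25 and ≥ 2× the scaled wild-type count (wild-type
zero gives fold = ∞). No background subtraction is applied by default
because the rule compares mutant to wild-type directly; a no-peptide well
may be supplied to subtract. A *response* is one positive
(patient, target, subset, compartment) combination; an *immunogenic
target* is a distinct (patient, target). The validation rate divides
immunogenic individual peptides plus immunogenic pools by the number of
screened individual peptides — the denominator convention that reproduces
the published 19% from 14 immunogenic targets over 75 screened peptides;
an all-targets denominator is selectable.

## Statistical kernel (`neoprior.stats`)

- 2×2 chi-square defaults to **no continuity correction**
  (N(ad−bc)²/∏margins, 1 df); this is required to reproduce p = 0.038
  from the 3/5-vs-0/5 responder table (Yates gives ≈ 0.167). Both modes
  are exposed.
- Welch's t with Satterthwaite df is the default t-test (the source
  flavor is unstated); a pooled-variance option exists.
- Log-rank pools tied event times and uses the standard
  (O−E)²/V statistic on 1 df.
- The univariate Cox fit maximizes the Breslow partial likelihood by
  Newton–Raphson (centered covariate, tolerance 1e−9, 50-iteration
  budget, convergence error with diagnostics otherwise); Breslow ties
  were chosen as the simplest well-defined convention, and the fit is
  cross-checked against lifelines on tie-free data where Breslow and
  Efron coincide.

## Signature analyses (`neoprior.signatures`)

**Moderated differential expression** shrinks per-gene pooled variances
toward a scaled-inverse-χ² prior whose (d₀, s₀²) are moment-matched on
log s² (mean and variance, via digamma/trigamma inversion); the posterior
variance is the d-weighted mix and the t reference gains d₀ df. This is
an empirical-Bayes scheme in the limma tradition; exact numerical
equivalence with that package is not claimed, and oracle tests target the
Welch mode. DEG significance uses unadjusted p < 0.05 (the convention the
signature derivation prescribes); Benjamini–Hochberg q-values are
available but off by default.

**APPM signature** = significant DEGs ∩ union of APPM gene-set members,
sorted. The identity of the APPM pathway sets is consumed as a GMT input
rather than hard-coded, since the specific sets are not enumerated in the
source. Per-sample score = median expression over signature genes.

**Tertiles** are rank-based with sizes differing by ≤1; the largest
remainder goes to the top tertile (307 samples → 103/102/102) and score
ties break by sample id. Survival contrasts use high vs low only.

**ssGSEA** ranks genes per sample descending (rank values N…1); in-set
steps add rank^0.25 normalized over the set, out-of-set steps subtract
1/(N−|S|); ES is the sum of the running difference. Normalized scores
divide all ES by the largest |ES| across sets and samples, which bounds
NES in [−1, 1]; raw ES are available via `normalize=False`.

## Synthetic cohorts (`neoprior.synthetic`)

Defaults encode the study conditions: 20 patients; per-patient mutation
counts negative-binomial with mean 62 and dispersion 8, truncated to the
observed 9–183 range; ~80% missense; DNA depth 80×, RNA depth 40×; tumor
VAF ~ Beta(2,4); ELISpot background 2 and effect 60 spots per 5×10⁴
cells; expression cohort of 300 samples with a 31-gene planted signature
shifted 2 SD in the responder-like group and an exponential survival
model whose log-hazard is −log(2.5) × standardized signature score
(median survival 31 months, administrative censoring at 120 months). The
per-patient ELISpot background is a chosen default — no empirical
distribution is available to fit.

The toy affinity model is a pure function: SHA-256 of (peptide, allele)
mapped log-uniformly onto 500–50,000 nM for unplanted pairs, so unplanted
peptides essentially never reach 150 nM; planted binders are placed near
50 nM (±~12% in log10), which satisfies all three binding criteria
against any unplanted wild-type partner by construction. One global seed
expands into per-component child seeds via `numpy.random.SeedSequence`,
making each stage and the serialized cohort byte-reproducible.

What the generator does **not** emulate: read-level artifacts (mapping
error, duplicates), linkage between DNA and RNA sampling noise beyond a
shared true VAF, indel/fusion neoantigens, clonal evolution, correlated
gene-gene expression structure, and real peptide–MHC binding chemistry.
Passing recovery tests therefore certify the *decision logic* of each
stage under its stated statistical assumptions, not predictive accuracy
on real sequencing data.

## Problem sizes and tolerances in the test suite

Power-style checks use sizes where the expected operating
characteristics are comfortably separated from their thresholds:
differential-expression recovery at n = 5 vs 5 with a 2 SD effect
(expected power ≈ 0.88 for the moderated test); survival recovery at
n = 300, hazard ratio 2.5, 100 seeds (expected rejection ≫ 90%); ELISpot
recovery over 500 wells at background 2 / effect 60 (Poisson tails put
sensitivity and FPR beyond 0.95/0.05 by large margins). Null
calibrations use 200–500 replicates with a KS threshold of 0.01.
Deterministic oracles (closed forms, brute-force enumerations,
step-by-step running sums) are compared at 1e−10 relative or better.

## Known limitations

- The moderated-t prior fit assumes a common residual df across genes
  (balanced two-group design).
- `cox_univariate` is univariate only; no proportionality diagnostics.
- ssGSEA normalization is cohort-dependent (global scale factor), so NES
  values are comparable within one matrix, not across runs.
- The MAF-like TSV dialect requires full read-evidence columns; the
  minimal-VCF reader fills neutral defaults for absent quality fields,
  which disables the corresponding filters rather than failing them.
- Percentile-rank binding thresholds, proteasomal processing and TAP
  transport are deliberately not modeled.
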