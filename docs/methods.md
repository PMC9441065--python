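# Methods

`bovarray` evaluates how well SNP genotyping arrays capture and impute the
variation of genetically diverged and admixed cattle populations. Because
the real whole-genome-sequence and array cohorts such an evaluation needs
are large and access-restricted, the package pairs the analysis machinery
(LD tagging, QC, harmonization, Li–Stephens imputation, accuracy metrics)
with a synthetic-cohort generator that reproduces the statistical structure
the analysis depends on: deep divergence between two ancestral lineages,
admixed cohorts, population-specific LD decay, arrays ascertained in one
discovery population, and rare-skewed functional annotation.

## The synthetic cohort generator

### Population differentiation (Balding–Nichols)

Each site has an ancestral allele frequency `p` drawn from a configurable
distribution (default Uniform(0.02, 0.98)). Population `k`'s frequency is
drawn from

    Beta( p (1 - F_k) / F_k ,  (1 - p)(1 - F_k) / F_k )

so that `E[q] = p` and `Var[q] = F_k p (1 - p)` — the Balding–Nichols model
with per-population differentiation `F_k` relative to the shared ancestral
pool. `F = 0` is implemented as an exact pass-through and `F = 1` is
rejected (degenerate Beta). Fixed sites (`p` in {0, 1}) stay fixed. The
default scenario uses `F = 0.2` for both populations, an
order-of-magnitude choice for deeply diverged lineages; it is configurable,
not inferred from data.

### Haplotypes (founder-mosaic copying model)

Within a population, a founder set of `K0` haplotypes (default 10% of the
pool, minimum 2) is drawn site-wise Bernoulli from the population
frequencies. Every further haplotype copies the founders as a mosaic:
template switches occur between adjacent sites with probability
`1 - exp(-rho * d)` for a gap of `d` bp, the new template is uniform over
founders, and each copied allele flips with probability `mut_eps`
(default 1e-3). This is the standard haplotype-copying (HAPGEN-style)
construction: it preserves the Balding–Nichols marginal frequencies while
producing linkage disequilibrium that decays with distance at a rate set by
`rho`. The default scenario gives the "taurine" population `rho = 5e-7`/bp
and the "indicine" population `rho = 2e-6`/bp, so the former holds LD over
longer ranges — the qualitative contrast reported between taurine and
indicine breeds.

Two consequences of the founder construction are worth knowing:

* **Realized differentiation exceeds the nominal F.** Founder sampling adds
  coancestry `~1/K0` within each population, so a Hudson-type FST estimate
  between two pure cohorts is approximately `F + (1 - F)/K0` rather than
  `F` (about 0.30 for `F = 0.2`, `K0 = 8`). The unit tests assert against
  this derived value.
* **LD strength is bounded by founder diversity.** Short-range mean r² is
  of order `1/K_eff`; with small founder sets, a useful fraction of close
  pairs reaches r² > 0.8, which is what the tagging analysis needs.

### Cohorts, admixture and private variation

A cohort is defined by a sample count and an ancestry vector `alpha` over
the populations. Each haplotype of an admixed sample is an ancestry mosaic:
segment breakpoints follow the same exponential switch process (at the mean
of the population `rho` values) and each segment's ancestry is drawn from
`alpha`, then copied from a uniformly chosen haplotype of that population's
pool. The per-site copy flip (`mut_eps`) is applied to cohort haplotypes as
well, creating *private* young variants that no pool haplotype carries.
This matters for realism of the accuracy metrics: private rare variants are
the class of variation a reference panel genuinely lacks, and they are what
drives imputation accuracy down at low minor allele frequency.

Observed genotypes are the site-wise sums of the two truth haplotypes, with
optional symmetric allele-flip error and missingness injected per call
(both default 0, and exercised by the QC tests).

### Array ascertainment and impact annotation

`design_array` emulates three designs. `uniform-common` selects sites with
MAF above a threshold (default 0.05) *in a named discovery population*,
spaced toward uniform bp coverage — the commodity-array design whose
content is biased toward variants common in the discovery breeds.
`functional-enriched` selects impact-annotated sites (rare ones included)
plus a common backbone — the design of functional arrays. `random` is the
neutral control. `subset_array` derives a nested lower-density design from
an existing one, the way 50k content sits inside HD content. Manifests
carry both FORWARD (ref/alt as simulated) and Illumina-style TOP codings so
the harmonization logic is exercisable.

Impact labels (`LOW`/`MODERATE`/`HIGH`, remainder `NONE`) are assigned only
to segregating sites; `HIGH` is sampled with probability proportional to
`min(1/max(MAF, 0.01), 50)`, skewing it toward rare sites, as observed for
stop-gain/splice variants. Class counts are binomial in the configured
proportions.

## Harmonization

`reconcile_alleles` classifies each query record against a reference
dataset keyed by (chrom, pos): `OK`, `SWAPPED` (genotypes recoded
`g -> 2 - g`), `STRAND_FLIP` (alleles complemented, genotypes untouched),
`SWAPPED_AND_FLIP` (both), or a discard category (`AMBIGUOUS_DISCARDED` for
A/T and C/G pairs, `ABSENT_DISCARDED`, `NONBIALLELIC_DISCARDED`).
Strand-ambiguous pairs are always discarded, even on an exact match,
because a strand error there is indistinguishable from a swap; we do not
attempt frequency-based rescue. The classifier is verified against an
independently coded brute-force oracle over the exhaustive cross of ordered
allele pairs. Liftover is table-driven (a coordinate map with optional
strand flags) rather than chain-file based; unmapped sites and target-key
collisions are dropped and counted.

## QC

Three preset regimes mirror common practice for (i) array cohorts (site
call rate >= 0.90, MAF >= 0.01, sample missingness <= 10%, duplicate removal
at kinship > 0.40), (ii) WGS panels (QUAL > 100, per-call GQ >= 25 masked
before call-rate computation, call rate >= 0.75, site missingness <= 25%,
relatedness pruning at kinship > 0.0625), and (iii) HD cohorts (as array).
Site removals are attributed to the first failing rule in a fixed order
(MAF, call rate, missingness, QUAL, WGS call rate). Kinship is the
KING-robust between-family estimator

    phi(i, j) = (N_het,het - 2 N_opp,hom) / (N_het(i) + N_het(j))

over sites non-missing in both samples (0.5 for duplicates and self, ~0 for
unrelated pairs, invariant to allele relabeling). Relatedness pruning is
greedy by over-threshold degree, ties broken by higher mean kinship then
input order; the choice of which member of a pair to drop is a convention,
so the tests only assert set-level properties.

## LD and tagging

r² between two sites is computed on phased haplotypes by direct counting:
`D = pAB - pA pB`, `r² = D² / (pA(1-pA) pB(1-pB))`, which equals the squared
Pearson correlation of the allele vectors; monomorphic sites are flagged
undefined. A genotype-dosage (composite) mode exists for unphased data. A
variant is *tagged* by an array if any array site within ±window (default
500 kb — a pair window, not disjoint tiles) has r² strictly above the
threshold (default 0.8). Array sites count as tagged (r² = 1 with self),
and because that convention affects proportions, the complementary
statistic excluding array sites from numerator and denominator is always
reported alongside. Sites monomorphic in the evaluated haplotype set are
excluded from the evaluation set — this, plus the frequency mismatch of
ascertained content, is what depresses tagging in a diverged population.
The windowed engine is checked exactly (1e-12) against an all-pairs
brute-force oracle.

## Imputation (Li–Stephens HMM)

Each target haplotype is modelled as an imperfect mosaic of the K reference
haplotypes over the full reference site grid. Transitions between adjacent
sites switch template with probability `1 - exp(-rho_scale * d / K)`
(uniform new template, including the current one; floor `min_switch`,
default 1e-8); emissions apply only at the target's typed sites with
mismatch probability `eps` (default 1e-3, valid range (0, 0.5)).
`rho_scale` defaults to `4e-8 * Ne` with `Ne = 100`. Posteriors come from a
scaled forward–backward pass, O(K·M) per haplotype, vectorized across
target haplotypes in memory-bounded chunks; per-site template posteriors
normalize to 1 within 1e-9 and the engine is verified exactly against path
enumeration on small instances.

The posterior alternate-allele probability is the template-posterior
weighted panel allele; diploid dosage is the sum over the two haplotypes
(bounded in [0, 2]). The **leave-one-out (LOO) dosage** at a typed site is
the dosage recomputed with that site's own emission hidden. Because hiding
one emission leaves the forward messages before the site and the backward
messages after it unchanged, the LOO posterior is read off the shared
forward/backward arrays in O(K) per typed site; a naive re-run per site is
retained and the two are asserted equal to float precision.

**Two-step imputation** (sparse array -> dense array -> sequence) imputes
the targets to the dense grid against an intermediate panel, hardens
per-haplotype alleles at posterior > 0.5 (ties to the allele with higher
panel frequency; dosage passing available as a flag), then imputes the
hardened dense haplotypes to the full grid against the final panel. Any
intermediate-panel sample that also appears among the targets is removed
first. The gain over direct sparse-to-sequence imputation comes from the
intermediate panel being larger than the sequence panel, which is the
economic rationale for the design.

Targets are taken as phased (truth phase comes from the simulator);
statistical phasing is out of scope.

## Accuracy metrics

* **ER²** per typed site: squared Pearson correlation across samples
  between true genotypes (0/1/2) and LOO dosages. The squared form keeps
  ER² and dosage R² on a single scale.
* **Dosage R²** per untyped site: squared correlation between true
  genotypes and imputed dosages (masked evaluation).

Sites with zero variance in truth or dosage are flagged undefined and
excluded from aggregates (never zero-filled); aggregates are reported per
MAF bin ((0.01, 0.05], then 0.05-wide bins to 0.5), impact class, and
sample group. Stratification MAF is computed in the reference panel by
default — the target-set MAF is an alternative convention; both are easy to
pass explicitly since `accuracy` takes the frequency vector as an argument.
Under the null (dosages independent of truth) per-site ER² has expectation
`1/(n-1)`, which the tests verify.

## Experiment designs

`evalpipe.run_experiment` executes five arms from one seeded configuration:
per-array, per-population **tagging**; **masked imputation** (restrict the
cohort to an array's sites, impute to sequence level against the combined
panel, stratify ER²/dosage R²); **leave-one-out CV** (each selected panel
sample removed and imputed from the remainder; default n = 20, configurable
— a desk-scale stand-in for larger CV designs); and **one-step / two-step**
arms against the combined ("global") panel and each single-population
subset. Arrays whose post-QC variant count falls below
`min_post_qc_variants` (default 10,000, scaled in shipped configs to the
synthetic array sizes) are skipped and recorded with a reason. Reports are
long-format CSV (one metric value per row) with full provenance;
`summarize` produces n_sites-weighted means. Binned means are reported raw,
without smoothing.

## Default scenario and problem sizes

The shipped scenario (`simdata.default_scenario`) is one 10-Mb chromosome
with 20,000 sites, two ancestral populations at `F = 0.2` with contrasting
`rho`, pools of 120 haplotypes, and three cohorts of 50 samples (two pure,
one 50/50 admixed); `ExperimentConfig.example()` adds a 60-sample
HD-genotyped cohort (the intermediate panel) and three arrays: an HD-like
2,000-site design ascertained in the taurine population, a nested 200-site
sparse design, and a 1,000-site functional-enriched design. The test suite
uses the same generator at reduced sizes (800–3,000 sites, pools of 40–80)
so that multi-seed directional checks run in seconds; these sizes were
chosen once as the smallest at which the directional effects are
well-resolved, and the acceptance script runs the full example scenario.

## What the synthetic data does and does not show

The generator reproduces the *structure* the analysis depends on —
divergence, admixture, LD-decay contrast, ascertainment bias, rare-skewed
functional annotation, private rare variation — so passing tests show the
machinery measures those effects with the right signs and orderings. It
does not reproduce real cattle allele-frequency spectra, recombination
hotspots, gene conversion, indels/multiallelics, sex chromosomes,
selection, or real array content; numeric values (tagging percentages, ER²
levels) on synthetic cohorts are therefore not comparable to values
measured on real cohorts, only their qualitative relationships are.

## Numerical and design choices

* 1-based, fully closed coordinates throughout; VCF 4.2 with `|`-separated
  GT for phased panels; imputation output carries DS and, at typed sites,
  an LDS (LOO dosage) field.
* Tagging threshold is strict (`> 0.8`); ties at the hardening threshold
  (posterior exactly 0.5) go to the allele with higher panel frequency.
* Undefined r²/accuracy values are NaN-flagged, never zero-filled.
* Greedy relatedness pruning and first-failing-rule attribution are
  conventions chosen for determinism and reported as such.
* All randomness flows from a single `numpy.random.Generator` seeded at the
  configuration level; seeded runs are byte-identical end to end.
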