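# bovarray

Genotyping-array evaluation and genotype imputation for diverged and
admixed cattle populations.

## The problem

Commercial bovine SNP arrays were ascertained largely in European taurine
breeds. African cattle are admixtures of two deeply diverged lineages —
taurine (*Bos taurus*) and indicine (*Bos indicus*) — whose variation those
arrays capture poorly: a variant chosen for being common in the discovery
population is often rare or absent in a diverged one, and LD-based tagging
degrades further because r² between two sites is maximised only when their
allele frequencies match. Imputation from array genotypes up to sequence
level can recover much of the missing variation, but its accuracy depends
on the reference panel's composition, the array's density, and the
frequency and annotation class of each variant.

`bovarray` packages the full evaluation loop for these questions:

* **simdata** — synthetic cohorts with the relevant structure: two
  ancestral populations differentiated by the Balding–Nichols model
  (population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral
  frequency p), haplotypes from a founder-mosaic copying process whose
  switch rate sets the LD decay, admixed cohorts, ascertained array
  designs, and rare-skewed impact annotation.
* **vcfio** — the variant/genotype data model plus VCF 4.2, manifest-CSV,
  coordinate-map and report I/O.
* **harmonize** — table-driven liftover and allele reconciliation (swap /
  strand-flip / both; A/T and C/G ambiguity always discarded).
* **qc** — site, sample and relatedness filters with preset regimes;
  KING-robust kinship and greedy pruning.
* **ldtag** — haplotype r² (D²/(pA(1−pA)pB(1−pB))), windowed best-tag
  statistics (tagged ⇔ some array site within ±500 kb has r² > 0.8), LD
  decay curves.
* **impute** — a Li–Stephens forward–backward imputation engine over the
  reference site grid with leave-one-out dosages; ER² (squared correlation
  of truth with LOO dosage at typed sites) and dosage R² (at untyped
  sites), stratified by MAF bin and impact class.
* **evalpipe** — seeded end-to-end experiments: tagging, masked imputation,
  leave-one-out cross-validation, and one-step vs two-step (sparse → dense
  → sequence) imputation with global vs single-population panels.

See `docs/methods.md` for models, parameters and design choices.

## Worked example

```python
import numpy as np
from bovarray import simdata, ldtag, impute
from bovarray.evalpipe import build_target_set

# two diverged populations (F = 0.2), pure + admixed cohorts
scenario = simdata.default_scenario()
scenario["model"]["n_sites"] = 3000
scenario["model"]["chrom_length_bp"] = 2_000_000
scenario["pool_size"] = 80
cohort = simdata.simulate_scenario(scenario, seed=0)
groups = np.asarray(cohort.sample_groups)
rng = np.random.default_rng(0)

# an HD-like array ascertained in the taurine population
array = simdata.design_array(cohort, "uniform-common", 300, rng,
                             discovery_population="taurine")

# tagging per population
for g in ("taurine", "indicine"):
    sub = cohort.truth_haplotypes.subset_samples(np.flatnonzero(groups == g))
    s = ldtag.tagging_summary(sub, cohort.site_table, array)
    print(g, round(s.proportion_tagged, 3))

# masked imputation of the admixed cohort against the combined panel
truth = cohort.truth_haplotypes
panel = truth.subset_samples(np.flatnonzero(np.isin(groups, ["taurine", "indicine"])))
targets = truth.subset_samples(np.flatnonzero(groups == "admixed"))
tp, ts, _ = build_target_set(targets, cohort.site_table, array)
result = impute.impute_cohort(tp, ts, panel, cohort.site_table)
acc = impute.accuracy(result, targets.to_genotypes(), panel.maf())
print("mean ER2", round(acc["er2"].mean(), 3),
      "| mean dosage R2", round(acc["dosage_r2"].mean(), 3))
```

Output:

```
taurine 0.348
indicine 0.24
mean ER2 0.96 | mean dosage R2 0.951
```

The array tags far more of the variation segregating in its discovery
population (35%) than in the diverged population (24%) — the ascertainment
bias the evaluation is designed to expose — while imputation against the
combined two-population panel recovers the admixed cohort's untyped
variants with high accuracy (dosage R² 0.95), and the array's own sites are
recovered almost perfectly when each is hidden in turn (ER² 0.96).

A command-line interface mirrors the library:
`bovarray simulate|harmonize|qc|tag|impute|evaluate --help`.

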