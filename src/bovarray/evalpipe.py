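"""End-to-end experiment designs and stratified accuracy reports.

This module wires the simulator, the LD/tagging statistics, the QC filters
and the imputation engine into the study designs the package exists to
reproduce on synthetic cohorts:

* **tagging** — per-array, per-population proportion of variants tagged at
  r² > threshold within a window;
* **masked_imputation** — build a target set by restricting the cohort to an
  array's sites, impute to full density against the reference panel, and
  stratify ER²/dosage R² by MAF bin and impact class;
* **loo_cv** — leave-one-out cross-validation: each of n panel samples is
  removed from the panel and imputed from array sites using the remainder;
* **one_step / two_step** — impute a sparse array directly to sequence
  density, or via a denser intermediate panel first, against the combined
  ("global") panel and each single-population subset.

Arrays whose post-QC variant count falls below ``min_post_qc_variants`` are
excluded from imputation arms and recorded with a reason. Reports are
long-format tables (one metric value per row) carrying full provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simdata
from .impute import (
    LiStephensParams,
    accuracy,
    aggregate_accuracy,
    impute_cohort,
    two_step_impute,
)
from .ldtag import tagging_summary
from .qc import QCThresholds, filter_sites
from .simdata import SimulatedCohort, default_scenario
from .vcfio import ArrayManifest, HaplotypePanel, VariantTable, intersect_sites

ARMS = {"tagging", "masked_imputation", "loo_cv", "one_step", "two_step"}


@dataclass
class ExperimentConfig:
    """Everything a seeded end-to-end run needs."""

    scenario: dict = field(default_factory=default_scenario)
    arrays: dict = field(default_factory=dict)  # name -> design_array kwargs
    arms: list[str] = field(default_factory=lambda: ["tagging", "masked_imputation"])
    reference_groups: list[str] = field(default_factory=lambda: ["taurine", "indicine"])
    target_group: str = "admixed"
    hd_reference_group: str | None = None  # intermediate-panel samples for two_step
    sparse_array: str | None = None  # array names used by one_step/two_step
    dense_array: str | None = None
    loo_cv_n: int = 20
    loo_cv_array: str | None = None
    window_bp: int = 500_000
    r2_threshold: float = 0.8
    min_post_qc_variants: int = 10_000
    qc: QCThresholds = field(
        default_factory=lambda: QCThresholds(
            site_maf_min=0.01, site_call_rate_min=0.90, qual_min=None,
            gq_min=None, site_missing_max=None, wgs_call_rate_min=None,
        )
    )
    ls_params: LiStephensParams = field(default_factory=LiStephensParams)
    seed: int = 0

    def __post_init__(self):
        if not self.arms:
            raise ValueError("at least one analysis arm required")
        unknown = set(self.arms) - ARMS
        if unknown:
            raise ValueError(f"unknown arms: {sorted(unknown)}")

    @classmethod
    def example(cls, seed: int = 0) -> "ExperimentConfig":
        """A coherent desk-scale configuration exercising every arm.

        Extends the default scenario with an HD-genotyped cohort (the
        intermediate panel of the two-step design) and nested dense/sparse
        arrays ascertained in the 'taurine' discovery population. The
        post-QC variant floor is scaled to the synthetic array sizes.
        """
        scenario = default_scenario()
        scenario["cohorts"].append(
            {"name": "hdpool", "n_samples": 60,
             "admixture": {"taurine": 0.5, "indicine": 0.5}}
        )
        return cls(
            scenario=scenario,
            arrays={
                "hd_like": {"scheme": "uniform-common", "size": 2000,
                            "discovery_population": "taurine"},
                "sparse_50k_like": {"scheme": "subset", "parent": "hd_like",
                                    "size": 200},
                "functional": {"scheme": "functional-enriched", "size": 1000},
            },
            arms=["tagging", "masked_imputation", "loo_cv", "one_step", "two_step"],
            hd_reference_group="hdpool",
            sparse_array="sparse_50k_like",
            dense_array="hd_like",
            loo_cv_array="hd_like",
            loo_cv_n=10,
            min_post_qc_variants=100,
            seed=seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "qc" in raw:
            raw["qc"] = QCThresholds(**raw["qc"])
        if "ls_params" in raw:
            raw["ls_params"] = LiStephensParams(**raw["ls_params"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Panel plumbing


def build_target_set(
    wgs: HaplotypePanel, sites: VariantTable, manifest: ArrayManifest
) -> tuple[HaplotypePanel, VariantTable, int]:
    """Restrict a sequence panel to an array's sites.

    Returns (target panel, target site table, count of manifest sites absent
    from the panel). An empty overlap is fatal.
    """
    ia, _ = intersect_sites(sites, manifest)
    if len(ia) == 0:
        raise ValueError("array manifest shares no sites with the panel")
    n_absent = len(manifest) - len(ia)
    return wgs.subset_sites(ia), sites.subset(ia), n_absent


def subset_panel(panel: HaplotypePanel, groups: list[str]) -> HaplotypePanel:
    """Samples whose group label is in ``groups`` (haplotype pairs intact)."""
    if panel.groups is None:
        raise ValueError("panel carries no group labels")
    garr = np.asarray(panel.groups)
    unknown = set(groups) - set(garr)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    idx = np.flatnonzero(np.isin(garr, list(groups)))
    if len(idx) == 0:
        raise ValueError("empty panel subset")
    return panel.subset_samples(idx)


# ---------------------------------------------------------------------------
# Experiment runner


def _record(**kw) -> dict:
    base = {
        "arm": None, "array": None, "panel": None, "target_group": None,
        "maf_bin": None, "impact": None, "metric": None, "value": np.nan,
        "n_sites": 0, "n_samples": 0,
    }
    base.update(kw)
    return base


@dataclass
class ExperimentReport:
    records: pd.DataFrame
    skipped_arrays: pd.DataFrame
    provenance: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "report.csv", index=False, float_format="%.6g")
        self.skipped_arrays.to_csv(outdir / "skipped_arrays.csv", index=False)
        (outdir / "provenance.json").write_text(json.dumps(self.provenance, indent=1, default=str))


def _design_arrays(cohort: SimulatedCohort, config: ExperimentConfig,
                   rng: np.random.Generator) -> dict[str, ArrayManifest]:
    manifests = {}
    subsets = {k: v for k, v in config.arrays.items() if v.get("scheme") == "subset"}
    for name, spec in config.arrays.items():
        if name in subsets:
            continue
        manifests[name] = simdata.design_array(cohort, rng=rng, id_prefix=name, **spec)
    for name, spec in subsets.items():
        parent = manifests[spec["parent"]]
        manifests[name] = simdata.subset_array(
            parent, spec["size"], rng, spaced=spec.get("spaced", True), id_prefix=name
        )
    return manifests


def _post_qc_site_count(target_panel, target_sites, config) -> tuple[np.ndarray, int]:
    geno = target_panel.to_genotypes()
    mask, _ = filter_sites(target_sites, geno, config.qc)
    return mask, int(mask.sum())


def _accuracy_records(acc: pd.DataFrame, arm, array, panel_name, target_group):
    """Aggregate a per-site accuracy table into long-format report records."""
    recs = []
    scoped = acc[acc["group"] == "all"]
    for metric in ("er2", "dosage_r2"):
        overall = aggregate_accuracy(scoped, metric)
        recs.append(_record(arm=arm, array=array, panel=panel_name,
                            target_group=target_group, metric=f"mean_{metric}",
                            value=overall["value"].iloc[0],
                            n_sites=int(overall["n_sites"].iloc[0]),
                            n_samples=int(scoped["n_samples"].iloc[0])))
        per_bin = aggregate_accuracy(scoped, metric, by=["maf_bin"])
        for _, row in per_bin.iterrows():
            if row["n_sites"] == 0:
                continue
            recs.append(_record(arm=arm, array=array, panel=panel_name,
                                target_group=target_group, maf_bin=str(row["maf_bin"]),
                                metric=f"mean_{metric}", value=row["value"],
                                n_sites=int(row["n_sites"]),
                                n_samples=int(scoped["n_samples"].iloc[0])))
        if "impact" in scoped.columns:
            per_imp = aggregate_accuracy(scoped, metric, by=["impact"])
            for _, row in per_imp.iterrows():
                if row["n_sites"] == 0:
                    continue
                recs.append(_record(arm=arm, array=array, panel=panel_name,
                                    target_group=target_group, impact=row["impact"],
                                    metric=f"mean_{metric}", value=row["value"],
                                    n_sites=int(row["n_sites"]),
                                    n_samples=int(scoped["n_samples"].iloc[0])))
    return recs


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the configured arms; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    cohort = simdata.simulate_scenario(config.scenario, config.seed)
    manifests = _design_arrays(cohort, config, rng)
    truth = cohort.truth_haplotypes
    sites = cohort.site_table
    groups = np.asarray(cohort.sample_groups)

    ref_idx = np.flatnonzero(np.isin(groups, config.reference_groups))
    tgt_idx = np.flatnonzero(groups == config.target_group)
    reference = truth.subset_samples(ref_idx)
    targets_full = truth.subset_samples(tgt_idx)
    ref_maf = reference.maf()

    records: list[dict] = []
    skipped: list[dict] = []

    try:
        if "tagging" in config.arms:
            records += _run_tagging(cohort, manifests, config)
        imputation_arms = {"masked_imputation", "loo_cv", "one_step", "two_step"}
        active = imputation_arms & set(config.arms)
        if active:
            usable = {}
            for name, manifest in manifests.items():
                tp, ts, n_absent = build_target_set(truth, sites, manifest)
                mask, n_qc = _post_qc_site_count(tp, ts, config)
                if n_qc < config.min_post_qc_variants:
                    skipped.append({"array": name, "post_qc_variants": n_qc,
                                    "reason": "below min_post_qc_variants"})
                    continue
                usable[name] = (mask, n_absent)
            if "masked_imputation" in config.arms:
                records += _run_masked(cohort, manifests, usable, reference,
                                       targets_full, ref_maf, config)
            if "loo_cv" in config.arms:
                records += _run_loo_cv(cohort, manifests, usable, reference,
                                       ref_maf, config, rng)
            if {"one_step", "two_step"} & set(config.arms):
                needed = {config.sparse_array, config.dense_array}
                if needed <= set(usable):
                    records += _run_step_arms(cohort, manifests, usable, config)
    except Exception as err:  # pragma: no cover - defensive re-raise with arm context
        raise RuntimeError(f"experiment arm failed: {err}") from err

    report = pd.DataFrame(records)
    prov = {"seed": config.seed, "arms": config.arms,
            "arrays": {k: len(v) for k, v in manifests.items()},
            "reference_groups": config.reference_groups,
            "target_group": config.target_group}
    return ExperimentReport(
        report,
        pd.DataFrame(skipped, columns=["array", "post_qc_variants", "reason"]),
        prov,
    )


def _run_tagging(cohort, manifests, config):
    truth = cohort.truth_haplotypes
    groups = np.asarray(cohort.sample_groups)
    records = []
    for name, manifest in manifests.items():
        for g in pd.unique(groups):
            sub = truth.subset_samples(np.flatnonzero(groups == g))
            summ = tagging_summary(sub, cohort.site_table, manifest,
                                   window_bp=config.window_bp,
                                   r2_threshold=config.r2_threshold)
            records.append(_record(arm="tagging", array=name, target_group=g,
                                   metric="proportion_tagged",
                                   value=summ.proportion_tagged,
                                   n_sites=len(summ.per_site),
                                   n_samples=sub.n_samples))
            records.append(_record(arm="tagging", array=name, target_group=g,
                                   metric="proportion_tagged_excl_array",
                                   value=summ.proportion_tagged_excl_array,
                                   n_sites=int((~summ.per_site["is_array"]).sum()),
                                   n_samples=sub.n_samples))
    return records


def _run_masked(cohort, manifests, usable, reference, targets, ref_maf, config):
    sites = cohort.site_table
    records = []
    for name in usable:
        tp, ts, _ = build_target_set(targets, sites, manifests[name])
        result = impute_cohort(tp, ts, reference, sites, config.ls_params)
        acc = accuracy(result, targets.to_genotypes(), ref_maf,
                       impact=cohort.impact_labels)
        records += _accuracy_records(acc, "masked_imputation", name, "global",
                                     config.target_group)
    return records


def _run_loo_cv(cohort, manifests, usable, reference, ref_maf, config, rng):
    sites = cohort.site_table
    name = config.loo_cv_array or next(iter(usable), None)
    if name is None or name not in usable:
        return []
    manifest = manifests[name]
    n = min(config.loo_cv_n, reference.n_samples)
    chosen = np.sort(rng.choice(reference.n_samples, size=n, replace=False))
    dosages, loos = [], []
    tp_all, ts, _ = build_target_set(reference, sites, manifest)
    for i in chosen:
        panel = reference.subset_samples(np.setdiff1d(np.arange(reference.n_samples), [i]))
        target = tp_all.subset_samples(np.asarray([i]))
        res = impute_cohort(target, ts, panel, sites, config.ls_params)
        dosages.append(res.dosages[:, 0])
        loos.append(res.loo_dosages[:, 0])
    from .impute import ImputationResult
    combined = ImputationResult(
        np.column_stack(dosages), np.column_stack(loos),
        res.typed_mask, [reference.samples[i] for i in chosen], config.ls_params,
    )
    truth = reference.subset_samples(chosen).to_genotypes()
    acc = accuracy(combined, truth, ref_maf, impact=cohort.impact_labels)
    return _accuracy_records(acc, "loo_cv", name, "global", "reference")


def _run_step_arms(cohort, manifests, usable, config):
    if not (config.sparse_array and config.dense_array):
        raise ValueError("one_step/two_step require sparse_array and dense_array names")
    sites = cohort.site_table
    truth = cohort.truth_haplotypes
    groups = np.asarray(cohort.sample_groups)
    tgt_idx = np.flatnonzero(groups == config.target_group)
    targets = truth.subset_samples(tgt_idx)
    truth_geno = targets.to_genotypes()

    sparse_tp, sparse_ts, _ = build_target_set(targets, sites, manifests[config.sparse_array])
    dense_manifest = manifests[config.dense_array]

    hd_group = config.hd_reference_group
    panels = {"global": config.reference_groups}
    panels.update({g: [g] for g in config.reference_groups})

    records = []
    for pname, pgroups in panels.items():
        panel = subset_panel(truth, pgroups)
        panel = panel.subset_samples(
            np.flatnonzero(~np.isin(panel.samples, targets.samples))
        )
        ref_maf = panel.maf()
        if "one_step" in config.arms:
            res = impute_cohort(sparse_tp, sparse_ts, panel, sites, config.ls_params)
            acc = accuracy(res, truth_geno, ref_maf, impact=cohort.impact_labels)
            records += _accuracy_records(acc, "one_step", config.sparse_array,
                                         pname, config.target_group)
        if "two_step" in config.arms:
            if hd_group is None:
                raise ValueError("two_step requires hd_reference_group")
            hd_panel_full = subset_panel(truth, [hd_group])
            dense_hp, dense_ts, _ = build_target_set(hd_panel_full, sites, dense_manifest)
            res = two_step_impute(sparse_tp, sparse_ts, dense_hp, dense_ts,
                                  panel, sites, config.ls_params)
            sparse_mask = res.provenance["sparse_mask"]
            acc = accuracy(res, truth_geno, ref_maf, impact=cohort.impact_labels,
                           typed_subset=sparse_mask)
            records += _accuracy_records(acc, "two_step", config.sparse_array,
                                         pname, config.target_group)
    return records


def summarize(report: pd.DataFrame, grouping: list[str]) -> pd.DataFrame:
    """n_sites-weighted mean metric value per grouping; NaNs excluded."""
    if report.empty:
        raise ValueError("empty report")
    df = report.dropna(subset=["value"]).copy()
    excluded = len(report) - len(df)

    def agg(g):
        w = g["n_sites"].to_numpy(float)
        v = g["value"].to_numpy(float)
        return pd.Series({
            "value": np.average(v, weights=w) if w.sum() > 0 else np.nan,
            "n_sites": int(w.sum()),
        })

    out = df.groupby(grouping + ["metric"], observed=True, dropna=False).apply(
        agg, include_groups=False
    ).reset_index()
    out.attrs["excluded_undefined"] = excluded
    return out
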