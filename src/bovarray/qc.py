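"""Site, sample and relatedness quality control.

Three preset threshold regimes mirror the usual handling of (i) array
cohorts (call rate >= 0.90, MAF >= 0.01, sample missingness <= 10%,
duplicate removal at kinship > 0.40), (ii) WGS reference panels (QUAL > 100,
per-call GQ >= 25, call rate >= 75%, site missingness <= 25%, relatedness
pruning at kinship > 0.0625) and (iii) HD cohorts used as intermediate
imputation panels.

Pairwise kinship uses the KING-robust between-family estimator

    phi(i, j) = (N_het,het - 2 N_opp_hom) / (N_het(i) + N_het(j))

with all counts over sites non-missing in both samples: ~0.5 for duplicates,
~0.25 for parent-offspring, ~0 for unrelated pairs, and robust to population
structure. Related samples are pruned greedily by over-threshold degree.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np

from .vcfio import GenotypeMatrix, MISSING, VariantTable, minor_allele_frequency


@dataclass
class QCThresholds:
    """Filter thresholds; ``None`` disables the corresponding rule."""

    site_maf_min: float | None = 0.01
    site_call_rate_min: float | None = 0.90
    sample_missing_max: float | None = 0.10
    site_missing_max: float | None = 0.25
    qual_min: float | None = 100.0
    gq_min: float | None = 25.0
    wgs_call_rate_min: float | None = 0.75
    kinship_unrelated_max: float = 0.0625
    kinship_duplicate_max: float = 0.40

    def __post_init__(self):
        for name in ("site_maf_min", "site_call_rate_min", "sample_missing_max",
                     "site_missing_max", "wgs_call_rate_min"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


PROFILES: dict[str, QCThresholds] = {
    # array-cohort QC: call-rate/MAF site rules + sample missingness,
    # duplicates removed at kinship > 0.40
    "array": QCThresholds(
        site_maf_min=0.01, site_call_rate_min=0.90, sample_missing_max=0.10,
        site_missing_max=None, qual_min=None, gq_min=None, wgs_call_rate_min=None,
    ),
    # WGS panel QC: QUAL/GQ/call-rate rules, relatedness pruning at 0.0625
    "wgs-panel": QCThresholds(
        site_maf_min=None, site_call_rate_min=None, sample_missing_max=None,
        site_missing_max=0.25, qual_min=100.0, gq_min=25.0, wgs_call_rate_min=0.75,
    ),
    # HD cohort used as an intermediate reference panel
    "hd-cohort": QCThresholds(
        site_maf_min=0.01, site_call_rate_min=0.90, sample_missing_max=0.10,
        site_missing_max=None, qual_min=None, gq_min=None, wgs_call_rate_min=None,
    ),
}


# ---------------------------------------------------------------------------
# Site and sample filters


def filter_sites(
    table: VariantTable,
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds,
    groups: list[str] | None = None,
) -> tuple[np.ndarray, OrderedDict]:
    """Boolean kept mask over sites plus per-rule removal counts.

    A site is removed if it fails any enabled rule; attribution is to the
    first failing rule in the order MAF, call rate, site missingness, QUAL,
    WGS call rate (after GQ masking). If ``gq_min`` is enabled, calls below
    it are treated as missing for the call-rate/missingness computations.
    ``groups`` applies the missingness rule within each group (a site fails
    if it fails in any group), mirroring per-breed missingness filters.
    """
    d = genotypes.dosages
    n_sites, n_samples = d.shape
    valid = d != MISSING
    if thresholds.gq_min is not None and genotypes.gq is not None:
        valid = valid & ~(np.nan_to_num(genotypes.gq, nan=np.inf) < thresholds.gq_min)

    with np.errstate(invalid="ignore"):
        call_rate = valid.mean(axis=1)
    masked = np.where(valid, d, MISSING)
    maf = minor_allele_frequency(masked)
    maf = np.where(np.isnan(maf), 0.0, maf)

    def group_missing(max_missing: float) -> np.ndarray:
        if groups is None:
            return (1.0 - call_rate) > max_missing
        fails = np.zeros(n_sites, dtype=bool)
        garr = np.asarray(groups)
        for g in np.unique(garr):
            cols = garr == g
            fails |= (1.0 - valid[:, cols].mean(axis=1)) > max_missing
        return fails

    rules: list[tuple[str, np.ndarray]] = []
    if thresholds.site_maf_min is not None:
        rules.append(("maf", maf < thresholds.site_maf_min))
    if thresholds.site_call_rate_min is not None:
        rules.append(("call_rate", call_rate < thresholds.site_call_rate_min))
    if thresholds.site_missing_max is not None:
        rules.append(("missingness", group_missing(thresholds.site_missing_max)))
    if thresholds.qual_min is not None and "qual" in table.df.columns:
        qual = table.df["qual"].to_numpy(float)
        rules.append(("qual", ~(qual > thresholds.qual_min)))
    if thresholds.wgs_call_rate_min is not None:
        rules.append(("wgs_call_rate", call_rate < thresholds.wgs_call_rate_min))

    kept = np.ones(n_sites, dtype=bool)
    counts: OrderedDict[str, int] = OrderedDict()
    unattributed = np.ones(n_sites, dtype=bool)
    for name, fails in rules:
        newly = fails & unattributed
        counts[name] = int(newly.sum())
        kept &= ~fails
        unattributed &= ~fails
    return kept, counts


def filter_samples(genotypes: GenotypeMatrix, thresholds: QCThresholds) -> np.ndarray:
    """Boolean kept mask over samples (missing fraction <= sample_missing_max)."""
    if genotypes.n_samples == 0:
        return np.zeros(0, dtype=bool)
    if thresholds.sample_missing_max is None:
        return np.ones(genotypes.n_samples, dtype=bool)
    missing_frac = (genotypes.dosages == MISSING).mean(axis=0)
    return missing_frac <= thresholds.sample_missing_max


# ---------------------------------------------------------------------------
# Kinship


def kinship_matrix(genotypes: GenotypeMatrix) -> np.ndarray:
    """KING-robust pairwise kinship (symmetric, NaN diagonal-free).

    phi(i,j) = (N_het,het - 2 N_opp_hom) / (N_het(i) + N_het(j)), counting
    only sites non-missing in both samples; pairs with a zero denominator or
    zero usable sites get NaN. The diagonal equals 0.5 by the same algebra.
    """
    d = genotypes.dosages
    if d.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    valid = (d != MISSING).astype(np.float64)
    het = (d == 1).astype(np.float64)
    hom_ref = (d == 0).astype(np.float64)
    hom_alt = (d == 2).astype(np.float64)

    n_hethet = het.T @ het
    n_opp = hom_ref.T @ hom_alt + hom_alt.T @ hom_ref
    het_i = het.T @ valid  # het in i over sites valid in both (het implies valid)
    het_j = het_i.T
    n_usable = valid.T @ valid
    denom = het_i + het_j
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where((denom > 0) & (n_usable > 0), (n_hethet - 2.0 * n_opp) / denom, np.nan)
    return phi


def prune_related(kinship: np.ndarray, threshold: float) -> np.ndarray:
    """Greedy pruning: boolean kept mask with no remaining pair > threshold.

    Iteratively drops the sample with the most over-threshold partners
    (ties broken by higher mean kinship over those partners, then by input
    order), until no pair exceeds the threshold.
    """
    k = np.array(kinship, dtype=float)
    n = k.shape[0]
    np.fill_diagonal(k, np.nan)
    over = np.nan_to_num(k, nan=-np.inf) > threshold
    kept = np.ones(n, dtype=bool)
    while True:
        active = over & kept[:, None] & kept[None, :]
        degree = active.sum(axis=1)
        if degree.max(initial=0) == 0:
            return kept
        cand = np.flatnonzero(degree == degree.max())
        if len(cand) > 1:
            with np.errstate(invalid="ignore"):
                means = np.array(
                    [np.nanmean(np.where(active[c], k[c], np.nan)) for c in cand]
                )
            cand = cand[means == means.max()]
        kept[cand[0]] = False


def apply_qc(
    table: VariantTable,
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds,
    prune_kinship_at: float | None = None,
    groups: list[str] | None = None,
):
    """Full QC pass: sample filter, site filter, optional relatedness pruning.

    Returns (table, genotypes, report dict). Idempotent: a second pass over
    the output removes nothing.
    """
    sample_mask = filter_samples(genotypes, thresholds)
    g = genotypes.subset_samples(np.flatnonzero(sample_mask))
    if groups is not None:
        groups = [gr for gr, keep in zip(groups, sample_mask) if keep]
    report = {"samples_removed_missingness": int((~sample_mask).sum())}
    if prune_kinship_at is not None and g.n_samples >= 2:
        phi = kinship_matrix(g)
        kept = prune_related(phi, prune_kinship_at)
        report["samples_removed_relatedness"] = int((~kept).sum())
        g = g.subset_samples(np.flatnonzero(kept))
        if groups is not None:
            groups = [gr for gr, keep in zip(groups, kept) if keep]
    site_mask, counts = filter_sites(table, g, thresholds, groups=groups)
    report["site_removals"] = dict(counts)
    table_out = table.subset(np.flatnonzero(site_mask))
    g = g.subset_sites(np.flatnonzero(site_mask))
    return table_out, g, report
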