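"""Synthetic cohorts with the population structure of diverged/admixed cattle.

The generator composes two classic models:

* **Balding–Nichols differentiation**: each population's allele frequency at a
  site is drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral
  frequency p, so that the expected differentiation of the population from
  the ancestral pool equals F.
* **Haplotype-copying mosaics** (HAPGEN-style): a small founder set per
  population is drawn site-wise Bernoulli from the population frequencies;
  every further haplotype is a mosaic of founders, switching template with
  probability 1 - exp(-rho * d) across a gap of d bp and flipping the copied
  allele with a small mutation probability. This produces linkage
  disequilibrium that decays with distance at a rate set by rho, so a
  low-rho ("taurine-like") population holds LD over longer ranges than a
  high-rho ("indicine-like") one.

Admixed cohorts draw the ancestry of each haplotype segment from a per-cohort
ancestry vector alpha and then copy from that population's haplotype pool,
giving mosaic ancestry tracts.

Array designs are ascertained on the simulated data: the ``uniform-common``
scheme emulates the common-variant, discovery-population-biased content of
commodity SNP arrays, and ``functional-enriched`` emulates arrays that target
putatively functional (often rare) variation plus a common backbone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .vcfio import (
    ArrayManifest,
    GenotypeMatrix,
    HaplotypePanel,
    MANIFEST_COLUMNS,
    MISSING,
    VariantTable,
    complement,
    write_vcf,
)

IMPACT_LEVELS = ["NONE", "LOW", "MODERATE", "HIGH"]

_UNAMBIGUOUS_TOP = {("A", "C"), ("A", "G"), ("C", "A"), ("G", "A")}


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Model specification


@dataclass
class PopulationModel:
    """Parameters of the two-layer (differentiation + copying) simulator.

    ``fst`` holds each population's Balding–Nichols F relative to the shared
    ancestral pool; the expected pairwise differentiation between two
    populations with equal F is of the same order. ``copy_rho`` is the
    per-bp template switch rate of the copying process (smaller rho, longer
    shared haplotypes, stronger LD); ``mut_eps`` the per-site copy error.
    """

    populations: list[str]
    fst: list[float]
    admixture_profiles: dict[str, list[float]] = field(default_factory=dict)
    ancestral_freq_dist: dict = field(
        default_factory=lambda: {"dist": "uniform", "low": 0.02, "high": 0.98}
    )
    copy_rho: list[float] | float = 1e-6
    mut_eps: float = 1e-3
    chrom_length_bp: int = 10_000_000
    n_sites: int = 20_000
    chrom: str = "1"
    founder_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if len(self.fst) != len(self.populations):
            raise SimulationError("one F value per population required")
        for f in self.fst:
            if not (0.0 <= f < 1.0):
                raise SimulationError(f"F must be in [0, 1); got {f}")
        if np.isscalar(self.copy_rho):
            self.copy_rho = [float(self.copy_rho)] * len(self.populations)
        if any(r <= 0 for r in self.copy_rho):
            raise SimulationError("copy_rho must be > 0")
        if self.n_sites < 2:
            raise SimulationError("n_sites must be >= 2")
        for name, alpha in self.admixture_profiles.items():
            if len(alpha) != len(self.populations):
                raise SimulationError(f"admixture vector for {name} has wrong length")
            if abs(sum(alpha) - 1.0) > 1e-9:
                raise SimulationError(f"admixture vector for {name} must sum to 1")
            if any(a < 0 for a in alpha):
                raise SimulationError("admixture proportions must be non-negative")

    def rho_of(self, population: str) -> float:
        return self.copy_rho[self.populations.index(population)]

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        return cls(**d)


@dataclass
class CohortSpec:
    """One simulated cohort: a name, a size and an ancestry profile."""

    name: str
    n_samples: int
    admixture: dict[str, float]
    missing_rate: float = 0.0
    error_rate: float = 0.0


@dataclass
class SimulatedCohort:
    """Truth haplotypes plus the derived (possibly degraded) genotypes."""

    truth_haplotypes: HaplotypePanel
    genotypes: GenotypeMatrix
    sample_groups: list[str]
    site_table: VariantTable
    impact_labels: np.ndarray

    def __post_init__(self):
        truth = self.truth_haplotypes.to_genotypes().dosages
        obs = self.genotypes.dosages
        if truth.shape != obs.shape:
            raise SimulationError("genotype/haplotype dimensions disagree")


# ---------------------------------------------------------------------------
# Frequencies and positions


def draw_ancestral_frequencies(model: PopulationModel, rng: np.random.Generator) -> np.ndarray:
    spec = model.ancestral_freq_dist
    if spec["dist"] == "uniform":
        return rng.uniform(spec.get("low", 0.02), spec.get("high", 0.98), model.n_sites)
    if spec["dist"] == "beta":
        return rng.beta(spec["a"], spec["b"], model.n_sites)
    raise SimulationError(f"unknown ancestral frequency distribution {spec['dist']!r}")


def draw_population_frequencies(
    model: PopulationModel,
    rng: np.random.Generator,
    ancestral: np.ndarray | None = None,
) -> pd.DataFrame:
    """Balding–Nichols population frequencies around an ancestral draw.

    Returns a DataFrame with one column per population plus ``ancestral``.
    F = 0 returns the ancestral frequency exactly; fixed ancestral sites
    (p in {0, 1}) stay fixed in every population.
    """
    if ancestral is None:
        ancestral = draw_ancestral_frequencies(model, rng)
    p = np.asarray(ancestral, dtype=float)
    out = {"ancestral": p}
    for name, f in zip(model.populations, model.fst):
        if f == 0.0:
            out[name] = p.copy()
            continue
        ratio = (1.0 - f) / f
        q = np.empty_like(p)
        seg = (p > 0.0) & (p < 1.0)
        q[~seg] = p[~seg]
        q[seg] = rng.beta(p[seg] * ratio, (1.0 - p[seg]) * ratio)
        out[name] = q
    return pd.DataFrame(out)


def draw_site_positions(model: PopulationModel, rng: np.random.Generator) -> np.ndarray:
    """Sorted 1-based site positions, uniform without replacement."""
    if model.n_sites > model.chrom_length_bp:
        raise SimulationError("more sites than base pairs")
    pos = rng.choice(model.chrom_length_bp, size=model.n_sites, replace=False) + 1
    return np.sort(pos)


def _random_alleles(n_sites: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, n_sites)
    alt_off = rng.integers(1, 4, n_sites)
    alt_idx = (ref_idx + alt_off) % 4
    return bases[ref_idx], bases[alt_idx]


# ---------------------------------------------------------------------------
# Haplotype simulation


def _switch_probabilities(positions: np.ndarray, rho: float) -> np.ndarray:
    gaps = np.diff(positions).astype(float)
    return 1.0 - np.exp(-rho * gaps)


def simulate_haplotypes(
    freqs: np.ndarray,
    positions: np.ndarray,
    n_haps: int,
    rho: float,
    mut_eps: float,
    rng: np.random.Generator,
    n_founders: int | None = None,
) -> np.ndarray:
    """Founder-mosaic haplotypes with distance-decaying LD.

    The first ``n_founders`` haplotypes are drawn site-wise Bernoulli(freq);
    each later haplotype copies a founder, re-drawing the template with
    probability 1 - exp(-rho * d) at each inter-site gap of d bp, and flips
    the copied allele with probability ``mut_eps``. Deterministic given the
    generator state. Returns a (n_sites, n_haps) uint8 array.
    """
    if n_haps < 2:
        raise SimulationError("n_haps must be >= 2")
    freqs = np.asarray(freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise SimulationError("frequencies must lie in [0, 1]")
    n_sites = len(freqs)
    if n_founders is None:
        n_founders = max(2, int(round(0.1 * n_haps)))
    n_founders = min(n_founders, n_haps)

    founders = (rng.random((n_sites, n_founders)) < freqs[:, None]).astype(np.uint8)
    out = np.empty((n_sites, n_haps), dtype=np.uint8)
    out[:, :n_founders] = founders

    n_copies = n_haps - n_founders
    if n_copies > 0:
        s = _switch_probabilities(positions, rho)
        switch = np.empty((n_sites, n_copies), dtype=bool)
        switch[0] = True
        switch[1:] = rng.random((n_sites - 1, n_copies)) < s[:, None]
        segment = np.cumsum(switch, axis=0) - 1
        n_segments = int(segment.max()) + 1
        template = rng.integers(0, n_founders, size=(n_segments, n_copies))
        tmpl_per_site = np.take_along_axis(template, segment, axis=0)
        copied = np.take_along_axis(founders, tmpl_per_site, axis=1)
        if mut_eps > 0:
            flips = rng.random((n_sites, n_copies)) < mut_eps
            copied = copied ^ flips
        out[:, n_founders:] = copied
    return out


def simulate_population_pools(
    model: PopulationModel,
    pool_size: int,
    rng: np.random.Generator,
    freqs: pd.DataFrame | None = None,
    positions: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame, np.ndarray]:
    """One haplotype pool per population (pool_size haplotypes each)."""
    if positions is None:
        positions = draw_site_positions(model, rng)
    if freqs is None:
        freqs = draw_population_frequencies(model, rng)
    pools = {}
    for name, rho in zip(model.populations, model.copy_rho):
        n_founders = max(2, int(round(model.founder_fraction * pool_size)))
        pools[name] = simulate_haplotypes(
            freqs[name].to_numpy(), positions, pool_size, rho, model.mut_eps, rng,
            n_founders=n_founders,
        )
    return pools, freqs, positions


def _mosaic_from_pools(
    pools: list[np.ndarray],
    alpha: np.ndarray,
    positions: np.ndarray,
    rho: float,
    n_haps: int,
    rng: np.random.Generator,
    mut_eps: float = 0.0,
) -> np.ndarray:
    """Haplotypes as ancestry mosaics over population pools.

    ``mut_eps`` applies the copying process's per-site flip, creating young
    *private* variants that no pool haplotype carries — the class of rare
    variation that reference panels genuinely lack.
    """
    n_sites = len(positions)
    s = _switch_probabilities(positions, rho)
    switch = np.empty((n_sites, n_haps), dtype=bool)
    switch[0] = True
    switch[1:] = rng.random((n_sites - 1, n_haps)) < s[:, None]
    segment = np.cumsum(switch, axis=0) - 1
    n_segments = int(segment.max()) + 1
    anc = rng.choice(len(pools), size=(n_segments, n_haps), p=alpha)
    tmpl = np.empty((n_segments, n_haps), dtype=np.int64)
    for k, pool in enumerate(pools):
        mask = anc == k
        tmpl[mask] = rng.integers(0, pool.shape[1], size=int(mask.sum()))
    anc_site = np.take_along_axis(anc, segment, axis=0)
    tmpl_site = np.take_along_axis(tmpl, segment, axis=0)
    out = np.empty((n_sites, n_haps), dtype=np.uint8)
    for k, pool in enumerate(pools):
        mask = anc_site == k
        cols = np.where(mask, tmpl_site, 0)
        vals = np.take_along_axis(pool, cols, axis=1)
        out[mask] = vals[mask]
    if mut_eps > 0:
        flips = rng.random((n_sites, n_haps)) < mut_eps
        out ^= flips.astype(np.uint8)
    return out


def simulate_cohort(
    model: PopulationModel,
    panel_per_pop: dict[str, np.ndarray],
    cohort_specs: list[CohortSpec],
    positions: np.ndarray,
    rng: np.random.Generator,
    impact_spec: dict[str, float] | None = None,
    site_table: VariantTable | None = None,
) -> SimulatedCohort:
    """Assemble admixed/pure cohorts from population haplotype pools.

    Each haplotype of an admixed sample is an ancestry mosaic: segment
    breakpoints follow the exponential switch process (at the mean of the
    populations' rho values) and each segment's ancestry is drawn from the
    cohort's alpha, then copied from a uniformly chosen pool haplotype.
    Optional genotype missingness and symmetric allele-flip error are
    injected at the stated per-call rates.
    """
    pools = []
    for name in model.populations:
        if name not in panel_per_pop:
            raise SimulationError(f"no haplotype pool for population {name!r}")
        pools.append(np.asarray(panel_per_pop[name], dtype=np.uint8))
    n_sites = len(positions)
    for pool in pools:
        if pool.shape[0] != n_sites:
            raise SimulationError("pools must share one site list")

    mean_rho = float(np.mean(model.copy_rho))
    hap_blocks, samples, groups = [], [], []
    for spec in cohort_specs:
        alpha = np.array([spec.admixture.get(p, 0.0) for p in model.populations], float)
        if abs(alpha.sum() - 1.0) > 1e-9:
            raise SimulationError(f"admixture for cohort {spec.name!r} must sum to 1")
        haps = _mosaic_from_pools(pools, alpha, positions, mean_rho,
                                  2 * spec.n_samples, rng, mut_eps=model.mut_eps)
        hap_blocks.append(haps)
        samples += [f"{spec.name}_{i:03d}" for i in range(spec.n_samples)]
        groups += [spec.name] * spec.n_samples
    alleles = np.concatenate(hap_blocks, axis=1)
    truth = HaplotypePanel(alleles, samples, groups)

    # observed genotypes: truth, then per-haplotype-call error, then missingness
    obs_alleles = alleles.copy()
    col = 0
    for spec in cohort_specs:
        ncols = 2 * spec.n_samples
        if spec.error_rate > 0:
            flips = rng.random((n_sites, ncols)) < spec.error_rate
            obs_alleles[:, col:col + ncols] ^= flips.astype(np.uint8)
        col += ncols
    dosages = (obs_alleles[:, 0::2].astype(np.int8) + obs_alleles[:, 1::2])
    col = 0
    for spec in cohort_specs:
        if spec.missing_rate > 0:
            miss = rng.random((n_sites, spec.n_samples)) < spec.missing_rate
            block = dosages[:, col:col + spec.n_samples]
            block[miss] = MISSING
        col += spec.n_samples
    genotypes = GenotypeMatrix(dosages, samples, groups)

    if site_table is None:
        ref, alt = _random_alleles(n_sites, rng)
        site_table = VariantTable.from_arrays(
            model.chrom, positions, ref=ref, alt=alt,
            qual=np.round(rng.uniform(150.0, 2000.0, n_sites), 2),
        )
    maf = truth.maf()
    impacts = annotate_impacts(maf, impact_spec or {}, rng)
    return SimulatedCohort(truth, genotypes, groups, site_table, impacts)


# ---------------------------------------------------------------------------
# Impact annotation


def annotate_impacts(
    maf: np.ndarray,
    mixture_spec: dict[str, float],
    rng: np.random.Generator,
    rare_weight_cap: float = 50.0,
) -> np.ndarray:
    """Assign impact labels; HIGH is skewed toward rare sites (weight ~ 1/MAF).

    ``mixture_spec`` gives the expected proportion of each non-NONE class;
    remaining mass is NONE. Only segregating sites (MAF > 0) are labelled —
    functional annotation applies to observed variants. HIGH labels are
    sampled without replacement with probability proportional to
    min(1/max(MAF, 0.01), cap); the other classes are uniform over the
    remaining polymorphic sites.
    """
    props = {k: mixture_spec.get(k, 0.0) for k in ("LOW", "MODERATE", "HIGH")}
    if any(v < 0 for v in props.values()):
        raise SimulationError("impact proportions must be non-negative")
    if sum(props.values()) > 1.0 + 1e-12:
        raise SimulationError("impact proportions must sum to <= 1")
    maf = np.asarray(maf, dtype=float)
    n = len(maf)
    labels = np.full(n, "NONE", dtype=object)
    available = maf > 0

    n_high = min(rng.binomial(n, props["HIGH"]), int(available.sum()))
    if n_high > 0:
        w = np.minimum(1.0 / np.maximum(maf, 0.01), rare_weight_cap)
        w = w * available
        idx = rng.choice(n, size=n_high, replace=False, p=w / w.sum())
        labels[idx] = "HIGH"
        available[idx] = False
    for cls in ("MODERATE", "LOW"):
        n_cls = rng.binomial(n, props[cls])
        pool = np.flatnonzero(available)
        n_cls = min(n_cls, len(pool))
        if n_cls > 0:
            idx = rng.choice(pool, size=n_cls, replace=False)
            labels[idx] = cls
            available[idx] = False
    return labels


# ---------------------------------------------------------------------------
# Array design


def _top_coding(ref: str, alt: str) -> tuple[str, str]:
    """Illumina-style TOP coding: unambiguous pairs are oriented so the pair
    contains an A on the TOP strand; ambiguous pairs are designated as-is."""
    if (ref, alt) in _UNAMBIGUOUS_TOP or {ref, alt} in ({"A", "T"}, {"C", "G"}):
        return ref, alt
    return complement(ref), complement(alt)


def design_array(
    cohort: SimulatedCohort,
    scheme: str,
    size: int,
    rng: np.random.Generator,
    discovery_population: str | None = None,
    maf_threshold: float = 0.05,
    functional_fraction: float = 0.8,
    id_prefix: str = "array",
) -> ArrayManifest:
    """Ascertain an array design on a simulated cohort.

    Schemes: ``random`` (uniform over polymorphic sites), ``uniform-common``
    (MAF >= threshold in the discovery population, spaced toward uniform bp
    coverage) and ``functional-enriched`` (impact-labelled sites, rare ones
    included, plus a common-variant backbone).
    """
    table = cohort.site_table
    truth = cohort.truth_haplotypes
    groups = np.asarray(cohort.sample_groups)
    freq = truth.alt_frequency()
    poly = (freq > 0) & (freq < 1)

    if scheme == "random":
        eligible = np.flatnonzero(poly)
        if size > len(eligible):
            raise SimulationError("requested array size exceeds eligible sites")
        chosen = np.sort(rng.choice(eligible, size=size, replace=False))
    elif scheme == "uniform-common":
        if discovery_population is None:
            raise SimulationError("uniform-common requires a discovery population")
        mask = groups == discovery_population
        if not mask.any():
            raise SimulationError(f"no samples in group {discovery_population!r}")
        sub = truth.subset_samples(np.flatnonzero(mask))
        maf = sub.maf()
        eligible = np.flatnonzero(maf >= maf_threshold)
        if size > len(eligible):
            raise SimulationError("requested array size exceeds eligible sites")
        chosen = _spaced_selection(table.pos, eligible, size, rng)
    elif scheme == "functional-enriched":
        labelled = np.flatnonzero((cohort.impact_labels != "NONE") & poly)
        n_func = min(int(round(functional_fraction * size)), len(labelled))
        func = rng.choice(labelled, size=n_func, replace=False) if n_func else np.array([], int)
        backbone_pool = np.flatnonzero((truth.maf() >= maf_threshold) & poly)
        backbone_pool = np.setdiff1d(backbone_pool, func)
        n_back = size - n_func
        if n_back > len(backbone_pool):
            raise SimulationError("requested array size exceeds eligible sites")
        back = rng.choice(backbone_pool, size=n_back, replace=False) if n_back else np.array([], int)
        chosen = np.sort(np.concatenate([func, back]))
    else:
        raise SimulationError(f"unknown ascertainment scheme {scheme!r}")

    sub = table.df.iloc[chosen]
    rows = []
    for k, (_, r) in enumerate(sub.iterrows()):
        a_top, b_top = _top_coding(r["ref"], r["alt"])
        rows.append(
            (f"{id_prefix}_{k:06d}", r["chrom"], r["pos"], a_top, b_top, r["ref"], r["alt"])
        )
    return ArrayManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


def subset_array(
    manifest: ArrayManifest, size: int, rng: np.random.Generator, spaced: bool = True,
    id_prefix: str | None = None,
) -> ArrayManifest:
    """A lower-density array nested in an existing design (e.g. 50k within HD).

    ``spaced`` picks rows approximating uniform bp coverage; otherwise
    uniformly at random. Site content is always a subset of the parent.
    """
    if size > len(manifest):
        raise SimulationError("requested subset exceeds parent array size")
    if spaced:
        idx = np.unique(np.round(np.linspace(0, len(manifest) - 1, size)).astype(int))
        while len(idx) < size:  # fill rounding collisions
            pool = np.setdiff1d(np.arange(len(manifest)), idx)
            idx = np.union1d(idx, rng.choice(pool, size - len(idx), replace=False))
    else:
        idx = np.sort(rng.choice(len(manifest), size=size, replace=False))
    df = manifest.df.iloc[idx].reset_index(drop=True)
    if id_prefix is not None:
        df = df.copy()
        df["id"] = [f"{id_prefix}_{k:06d}" for k in range(len(df))]
    return ArrayManifest(df)


def _spaced_selection(pos, eligible, size, rng) -> np.ndarray:
    """Pick `size` eligible sites approximating uniform bp coverage."""
    epos = pos[eligible]
    targets = np.linspace(epos[0], epos[-1], size)
    chosen = set()
    for t in targets:
        j = int(np.searchsorted(epos, t))
        for cand in (j, j - 1, j + 1):
            if 0 <= cand < len(eligible) and eligible[cand] not in chosen:
                chosen.add(int(eligible[cand]))
                break
    remaining = [int(e) for e in eligible if e not in chosen]
    if len(chosen) < size:
        extra = rng.choice(remaining, size=size - len(chosen), replace=False)
        chosen.update(int(e) for e in extra)
    return np.sort(np.fromiter(chosen, dtype=np.int64))


# ---------------------------------------------------------------------------
# Scenario configuration and disk output


def default_scenario() -> dict:
    """The shipped two-population scenario: diverged 'taurine' and 'indicine'
    pools at F = 0.2 each, three cohorts (two pure, one 50/50 admixed)."""
    return {
        "model": {
            "populations": ["taurine", "indicine"],
            "fst": [0.2, 0.2],
            "copy_rho": [5e-7, 2e-6],
            "mut_eps": 1e-3,
            "chrom_length_bp": 10_000_000,
            "n_sites": 20_000,
        },
        "pool_size": 120,
        "cohorts": [
            {"name": "taurine", "n_samples": 50, "admixture": {"taurine": 1.0}},
            {"name": "indicine", "n_samples": 50, "admixture": {"indicine": 1.0}},
            {"name": "admixed", "n_samples": 50,
             "admixture": {"taurine": 0.5, "indicine": 0.5}},
        ],
        "impact_spec": {"LOW": 0.05, "MODERATE": 0.03, "HIGH": 0.01},
    }


def load_scenario(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def simulate_scenario(scenario: dict, seed: int) -> SimulatedCohort:
    """Run a full scenario dict (see :func:`default_scenario`)."""
    rng = np.random.default_rng(seed)
    model = PopulationModel.from_dict({**scenario["model"], "seed": seed})
    pools, freqs, positions = simulate_population_pools(model, scenario["pool_size"], rng)
    specs = [CohortSpec(**c) for c in scenario["cohorts"]]
    return simulate_cohort(
        model, pools, specs, positions, rng, impact_spec=scenario.get("impact_spec")
    )


def write_cohort(cohort: SimulatedCohort, outdir, seed: int, model: PopulationModel | None = None) -> None:
    """Write truth VCF, genotype VCF, impact CSV and JSON metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(outdir / "truth.vcf", cohort.site_table, cohort.truth_haplotypes)
    write_vcf(outdir / "genotypes.vcf", cohort.site_table, cohort.genotypes)
    pd.DataFrame(
        {
            "chrom": cohort.site_table.chrom,
            "pos": cohort.site_table.pos,
            "id": cohort.site_table.ids,
            "impact": cohort.impact_labels,
        }
    ).to_csv(outdir / "impacts.csv", index=False)
    meta = {"seed": seed, "n_sites": cohort.site_table.__len__(),
            "samples": cohort.truth_haplotypes.samples,
            "groups": cohort.sample_groups}
    if model is not None:
        meta["model"] = {
            "populations": model.populations, "fst": model.fst,
            "copy_rho": model.copy_rho, "mut_eps": model.mut_eps,
            "chrom_length_bp": model.chrom_length_bp, "n_sites": model.n_sites,
        }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
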