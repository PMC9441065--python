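"""Shared fixtures: small simulated cohorts and toy panels."""

import numpy as np
import pytest

from bovarray import simdata
from bovarray.vcfio import HaplotypePanel, VariantTable


def make_model(**overrides):
    """Two diverged populations with contrasting LD decay, desk scale."""
    kw = dict(
        populations=["taurine", "indicine"],
        fst=[0.2, 0.2],
        copy_rho=[5e-7, 2e-6],
        mut_eps=1e-3,
        chrom_length_bp=2_000_000,
        n_sites=2500,
    )
    kw.update(overrides)
    return simdata.PopulationModel(**kw)


def make_cohort(seed, model=None, pool_size=80, cohorts=None,
                impact_spec=None):
    """Simulate a small three-cohort (+ optional extras) study."""
    rng = np.random.default_rng(seed)
    model = model or make_model()
    pools, freqs, pos = simdata.simulate_population_pools(model, pool_size, rng)
    specs = cohorts or [
        simdata.CohortSpec("taurine", 25, {"taurine": 1.0}),
        simdata.CohortSpec("indicine", 25, {"indicine": 1.0}),
        simdata.CohortSpec("admixed", 15, {"taurine": 0.5, "indicine": 0.5}),
    ]
    cohort = simdata.simulate_cohort(
        model, pools, specs, pos, rng,
        impact_spec=impact_spec if impact_spec is not None else {"HIGH": 0.02, "LOW": 0.05},
    )
    return cohort, rng


@pytest.fixture(scope="session")
def small_cohort():
    cohort, _ = make_cohort(seed=11)
    return cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def toy_panel(alleles, positions=None, chrom="1", samples=None):
    """HaplotypePanel + VariantTable from a literal allele matrix."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_sites, n_haps = alleles.shape
    assert n_haps % 2 == 0
    samples = samples or [f"s{i}" for i in range(n_haps // 2)]
    positions = positions if positions is not None else np.arange(1, n_sites + 1) * 1000
    refs = ["A"] * n_sites
    alts = ["G"] * n_sites
    table = VariantTable.from_arrays(chrom, np.asarray(positions), ref=refs, alt=alts)
    return HaplotypePanel(alleles, samples), table


def hudson_fst(h1: np.ndarray, h2: np.ndarray) -> float:
    """Independent Hudson/Bhatia FST estimator (ratio of sums)."""
    p1, p2 = h1.mean(1), h2.mean(1)
    n1, n2 = h1.shape[1], h2.shape[1]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    return float(num[ok].sum() / den[ok].sum())
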