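"""Li–Stephens engine: enumeration oracle, LOO identity, accuracy metrics."""

import itertools

import numpy as np
import pytest

from bovarray import impute
from bovarray.impute import (
    ImputationResult,
    LiStephensParams,
    accuracy,
    impute_cohort,
    impute_haplotype,
    maf_bin,
    template_posteriors,
    two_step_impute,
)
from bovarray.vcfio import GenotypeMatrix, HaplotypePanel, VariantTable

from conftest import make_cohort


def enumeration_posteriors(ref, typed_idx, obs, positions, params):
    """Independent oracle: exhaustive sum over all K^M template paths."""
    M, K = ref.shape
    s = params.switch_probabilities(positions, K)
    eps = params.eps
    typed = dict(zip(typed_idx, obs))
    post = np.zeros((M, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=M):
        p = 1.0 / K
        for m in range(1, M):
            trans = s[m - 1] / K + (1.0 - s[m - 1]) * (path[m] == path[m - 1])
            p *= trans
        for t, o in typed.items():
            p *= (1 - eps) if ref[t, path[t]] == o else eps
        for m in range(M):
            post[m, path[m]] += p
        total += p
    return post / total


def random_instance(rng, K=None, M=None):
    K = K or int(rng.integers(1, 4))
    M = M or int(rng.integers(2, 7))
    ref = rng.integers(0, 2, size=(M, K)).astype(np.uint8)
    pos = np.sort(rng.choice(10_000, M, replace=False)) + 1
    n_typed = int(rng.integers(1, M + 1))
    typed_idx = np.sort(rng.choice(M, n_typed, replace=False))
    obs = rng.integers(0, 2, size=n_typed).astype(np.uint8)
    params = LiStephensParams(
        eps=float(rng.uniform(1e-4, 0.3)),
        rho_scale=float(10 ** rng.uniform(-6, -2)),
    )
    return ref, typed_idx, obs, pos, params


class TestEnumerationOracle:
    def test_posteriors_match_path_enumeration(self):
        """Forward–backward equals exhaustive path enumeration, K<=3, M<=6."""
        max_err = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ref, typed_idx, obs, pos, params = random_instance(rng)
            gamma = template_posteriors(obs, typed_idx, ref, pos, params)
            oracle = enumeration_posteriors(ref, typed_idx, obs, pos, params)
            max_err = max(max_err, np.max(np.abs(gamma - oracle)))
            np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)
        assert max_err <= 1e-12

    def test_allele_posterior_consistent_with_gamma(self, rng):
        ref, typed_idx, obs, pos, params = random_instance(rng, K=3, M=6)
        gamma = template_posteriors(obs, typed_idx, ref, pos, params)
        expected = (gamma * ref).sum(axis=1)
        got = impute_haplotype(obs, typed_idx, ref, pos, params)
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestDegenerateCases:
    def test_single_template_copies_reference(self, rng):
        ref = rng.integers(0, 2, size=(30, 1)).astype(np.uint8)
        pos = np.arange(1, 31) * 100
        typed = np.array([0, 10, 20])
        obs = 1 - ref[typed, 0]  # even contradictory observations
        post = impute_haplotype(obs, typed, ref, pos, LiStephensParams(eps=0.4))
        np.testing.assert_allclose(post, ref[:, 0].astype(float), atol=1e-12)

    def test_target_matching_one_template(self):
        """Target identical to one reference haplotype at all typed sites:
        untyped-site posterior follows that haplotype with prob > 0.99."""
        rng = np.random.default_rng(5)
        K, M = 10, 60
        ref = rng.integers(0, 2, size=(M, K)).astype(np.uint8)
        pos = np.arange(1, M + 1) * 1000
        typed = np.arange(0, M, 2)
        obs = ref[typed, 3]
        params = LiStephensParams(eps=1e-6)
        post = impute_haplotype(obs, typed, ref, pos, params)
        untyped = np.setdiff1d(np.arange(M), typed)
        agree = np.abs(post[untyped] - ref[untyped, 3])
        assert (agree < 0.01).mean() > 0.99 or (agree < 0.01).all()

    def test_zero_typed_sites_returns_panel_frequency(self, rng):
        ref = rng.integers(0, 2, size=(10, 6)).astype(np.uint8)
        pos = np.arange(1, 11) * 50
        post = impute_haplotype(np.array([], dtype=np.uint8),
                                np.array([], dtype=np.int64), ref, pos,
                                LiStephensParams())
        np.testing.assert_allclose(post, ref.mean(axis=1))

    def test_posterior_normalization_invariant(self):
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            ref, typed_idx, obs, pos, params = random_instance(rng, K=3, M=6)
            gamma = template_posteriors(obs, typed_idx, ref, pos, params)
            np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-9)


class TestLeaveOneOut:
    def test_shared_pass_loo_equals_naive_masking(self):
        """The shared forward/backward LOO equals an explicit re-run with the
        site's emission removed, to float precision."""
        rng = np.random.default_rng(17)
        K, M = 8, 40
        ref = rng.integers(0, 2, size=(M, K)).astype(np.uint8)
        pos = np.sort(rng.choice(100_000, M, replace=False)) + 1
        typed = np.sort(rng.choice(M, 12, replace=False))
        table = VariantTable.from_arrays("1", pos, ref=["A"] * M, alt=["G"] * M)
        t_table = table.subset(typed)
        params = LiStephensParams(eps=0.01)

        tgt_alleles = rng.integers(0, 2, size=(12, 2)).astype(np.uint8)
        targets = HaplotypePanel(tgt_alleles, ["t0"])
        panel = HaplotypePanel(ref, [f"r{i}" for i in range(K // 2)])
        res = impute_cohort(targets, t_table, panel, table, params)
        for row, site in enumerate(typed):
            naive = sum(
                impute_haplotype(tgt_alleles[:, h], typed, ref, pos, params,
                                 mask_emission_at=site)[site]
                for h in range(2)
            )
            assert res.loo_dosages[site, 0] == pytest.approx(naive, abs=1e-10)

    def test_loo_nan_at_untyped_sites(self, rng):
        ref = rng.integers(0, 2, size=(10, 4)).astype(np.uint8)
        pos = np.arange(1, 11) * 10
        table = VariantTable.from_arrays("1", pos, ref=["A"] * 10, alt=["G"] * 10)
        typed = np.array([2, 7])
        targets = HaplotypePanel(ref[typed][:, :2], ["t0"])
        res = impute_cohort(targets, table.subset(typed),
                            HaplotypePanel(ref, ["a", "b"]), table)
        untyped = np.setdiff1d(np.arange(10), typed)
        assert np.isnan(res.loo_dosages[untyped]).all()
        assert np.isfinite(res.loo_dosages[typed]).all()


class TestImputeCohort:
    def test_self_imputation_recovers_truth(self):
        """Panel containing the target's truth haplotypes, small eps:
        dosages equal truth genotypes within 0.01."""
        rng = np.random.default_rng(23)
        M = 100
        alleles = rng.integers(0, 2, size=(M, 12)).astype(np.uint8)
        pos = np.sort(rng.choice(1_000_000, M, replace=False)) + 1
        table = VariantTable.from_arrays("1", pos, ref=["A"] * M, alt=["G"] * M)
        panel = HaplotypePanel(alleles, [f"s{i}" for i in range(6)])
        typed = np.sort(rng.choice(M, 30, replace=False))
        targets = HaplotypePanel(alleles[typed][:, :4], ["s0", "s1"])
        res = impute_cohort(targets, table.subset(typed), panel, table,
                            LiStephensParams(eps=1e-6, rho_scale=1e-7))
        truth = alleles[:, :4:2] + alleles[:, 1:4:2]
        assert np.max(np.abs(res.dosages - truth)) < 0.01

    def test_dosages_bounded(self, rng):
        ref = rng.integers(0, 2, size=(50, 10)).astype(np.uint8)
        pos = np.arange(1, 51) * 100
        table = VariantTable.from_arrays("1", pos, ref=["A"] * 50, alt=["G"] * 50)
        typed = np.arange(0, 50, 5)
        targets = HaplotypePanel(rng.integers(0, 2, (10, 4)).astype(np.uint8),
                                 ["a", "b"])
        res = impute_cohort(targets, table.subset(typed), ref_panel(ref), table)
        assert (res.dosages >= 0).all() and (res.dosages <= 2).all()

    def test_site_mismatch_raises_with_diff(self, rng):
        table = VariantTable.from_arrays("1", [10, 20, 30],
                                         ref=["A"] * 3, alt=["G"] * 3)
        bad = VariantTable.from_arrays("1", [10, 25], ref=["A", "A"], alt=["G", "G"])
        targets = HaplotypePanel(np.zeros((2, 2), dtype=np.uint8), ["t"])
        panel = HaplotypePanel(rng.integers(0, 2, (3, 4)).astype(np.uint8), ["a", "b"])
        with pytest.raises(impute.SiteMismatchError) as err:
            impute_cohort(targets, bad, panel, table)
        assert 25 in err.value.missing["pos"].tolist()

    def test_empty_target_site_set_rejected(self, rng):
        table = VariantTable.from_arrays("1", [10], ref=["A"], alt=["G"])
        empty = VariantTable(table.df.iloc[:0])
        targets = HaplotypePanel(np.zeros((0, 2), dtype=np.uint8), ["t"])
        panel = HaplotypePanel(np.zeros((1, 4), dtype=np.uint8), ["a", "b"])
        with pytest.raises(ValueError, match="empty target site set"):
            impute_cohort(targets, empty, panel, table)

    def test_eps_toward_half_shrinks_to_panel_frequency(self, rng):
        """Monotone response: raising eps drives dosages toward the panel
        frequency expectation (emissions become uninformative)."""
        ref = rng.integers(0, 2, size=(40, 20)).astype(np.uint8)
        pos = np.arange(1, 41) * 500
        table = VariantTable.from_arrays("1", pos, ref=["A"] * 40, alt=["G"] * 40)
        typed = np.arange(0, 40, 2)
        targets = HaplotypePanel(ref[typed][:, :2], ["t"])
        panel = HaplotypePanel(ref, [f"s{i}" for i in range(10)])
        freq_dosage = 2 * ref.mean(axis=1)
        dev = {}
        for eps in (1e-3, 0.2, 0.49):
            res = impute_cohort(targets, table.subset(typed), panel, table,
                                LiStephensParams(eps=eps))
            dev[eps] = np.abs(res.dosages[:, 0] - freq_dosage).mean()
        assert dev[0.49] < dev[0.2] < dev[1e-3]


def ref_panel(ref):
    return HaplotypePanel(ref, [f"s{i}" for i in range(ref.shape[1] // 2)])


class TestAccuracy:
    def _result(self, dosages, loo, typed):
        d = np.asarray(dosages, float)
        return ImputationResult(d, np.asarray(loo, float), np.asarray(typed),
                                [f"s{i}" for i in range(d.shape[1])],
                                LiStephensParams())

    def test_perfect_loo_gives_er2_one(self):
        truth = GenotypeMatrix(np.array([[0, 1, 2, 1]], dtype=np.int8),
                               list("abcd"))
        res = self._result([[0.0, 1, 2, 1]], [[0.0, 1, 2, 1]], [True])
        acc = accuracy(res, truth, maf=np.array([0.3]))
        assert acc["er2"].iloc[0] == pytest.approx(1.0)

    def test_monomorphic_truth_undefined(self):
        truth = GenotypeMatrix(np.zeros((1, 4), dtype=np.int8), list("abcd"))
        res = self._result([[0.1, 0.2, 0.1, 0.3]], [[0.1, 0.2, 0.1, 0.3]], [True])
        acc = accuracy(res, truth, maf=np.array([0.0]))
        assert np.isnan(acc["er2"].iloc[0])

    def test_null_er2_matches_one_over_n_minus_one(self):
        """Dosages independent of truth: E[r²] = 1/(n-1) under the null."""
        rng = np.random.default_rng(31)
        n, sites = 50, 1000
        truth = GenotypeMatrix(rng.integers(0, 3, size=(sites, n)).astype(np.int8),
                               [f"s{i}" for i in range(n)])
        noise = rng.random((sites, n)) * 2
        res = self._result(noise, noise, np.ones(sites, dtype=bool))
        acc = accuracy(res, truth, maf=np.full(sites, 0.3))
        mean_er2 = acc["er2"].mean()
        se = np.sqrt(2) / (n - 1) / np.sqrt(sites)  # ~Var(r²) ≈ 2/(n-1)²
        assert mean_er2 == pytest.approx(1 / (n - 1), abs=5 * se)

    def test_fewer_than_two_samples_rejected(self):
        truth = GenotypeMatrix(np.array([[1]], dtype=np.int8), ["a"])
        res = self._result([[1.0]], [[1.0]], [True])
        with pytest.raises(ValueError, match=">= 2 samples"):
            accuracy(res, truth, maf=np.array([0.5]))

    def test_maf_bins_half_open(self):
        bins = maf_bin(np.array([0.01, 0.03, 0.05, 0.051, 0.5, 0.0]))
        assert str(bins[1]) == "(0.01,0.05]"
        assert str(bins[2]) == "(0.01,0.05]"
        assert str(bins[3]) == "(0.05,0.10]"
        assert str(bins[4]) == "(0.45,0.50]"
        assert bins[0] is np.nan or str(bins[0]) == "nan"


class TestPanelSizeMonotonicity:
    def test_accuracy_increases_with_panel_size(self):
        """Mean dosage R² rises with reference panel size (K in {10,50,200}
        haplotypes), averaged over seeds."""
        means = {10: [], 50: [], 200: []}
        for seed in range(3):
            cohort, rng2 = make_cohort(seed=300 + seed, impact_spec={})
            groups = np.asarray(cohort.sample_groups)
            truth = cohort.truth_haplotypes
            ref_idx = np.flatnonzero(np.isin(groups, ["taurine", "indicine"]))
            tgt_idx = np.flatnonzero(groups == "admixed")
            tgt = truth.subset_samples(tgt_idx)
            man = np.flatnonzero(truth.maf() >= 0.05)[::10]
            table = cohort.site_table
            tp = tgt.subset_sites(man)
            ts = table.subset(man)
            for K in means:
                panel = truth.subset_samples(ref_idx[: K // 2])
                res = impute_cohort(tp, ts, panel, table)
                acc = accuracy(res, tgt.to_genotypes(), panel.maf())
                means[K].append(acc["dosage_r2"].mean())
        m = {k: np.mean(v) for k, v in means.items()}
        assert m[10] < m[50] < m[200]


class TestTwoStep:
    def test_degenerate_two_step_equals_one_step(self):
        """Intermediate = final panel restricted to the typed set and sparse
        = dense: hardening from its own emissions with small eps makes step 1
        the identity, so both routes agree."""
        rng = np.random.default_rng(41)
        M = 80
        alleles = rng.integers(0, 2, size=(M, 16)).astype(np.uint8)
        pos = np.sort(rng.choice(500_000, M, replace=False)) + 1
        table = VariantTable.from_arrays("1", pos, ref=["A"] * M, alt=["G"] * M)
        panel = HaplotypePanel(alleles, [f"p{i}" for i in range(8)])
        typed = np.sort(rng.choice(M, 25, replace=False))
        t_table = table.subset(typed)
        targets = HaplotypePanel(rng.integers(0, 2, (25, 4)).astype(np.uint8),
                                 ["t0", "t1"])
        params = LiStephensParams(eps=1e-5)
        one = impute_cohort(targets, t_table, panel, table, params)
        two = two_step_impute(targets, t_table, panel.subset_sites(typed),
                              t_table, panel, table, params)
        np.testing.assert_allclose(two.dosages, one.dosages, atol=1e-6)

    def test_overlap_sample_dropped_from_intermediate(self, caplog, rng):
        M = 30
        alleles = rng.integers(0, 2, size=(M, 12)).astype(np.uint8)
        pos = np.arange(1, M + 1) * 100
        table = VariantTable.from_arrays("1", pos, ref=["A"] * M, alt=["G"] * M)
        typed = np.arange(0, M, 3)
        inter = HaplotypePanel(alleles[:, :8], ["t0", "x1", "x2", "x3"])
        final = HaplotypePanel(alleles, [f"f{i}" for i in range(6)])
        targets = HaplotypePanel(alleles[typed][:, :2], ["t0"])
        import logging
        with caplog.at_level(logging.INFO, logger="bovarray.impute"):
            res = two_step_impute(targets, table.subset(typed), inter, table,
                                  final, table)
        assert res.provenance["overlap_removed"] == 1

    def test_two_step_beats_one_step_from_sparse(self):
        """With a larger intermediate panel at dense-array sites, two-step
        imputation outperforms direct sparse-to-sequence in >= 8/10 seeds."""
        from bovarray.evalpipe import build_target_set
        from bovarray.simdata import CohortSpec, design_array, subset_array
        from conftest import make_model
        from bovarray import simdata as sd

        wins = 0
        n_seeds = 6
        for seed in range(n_seeds):
            rng = np.random.default_rng(700 + seed)
            model = make_model(n_sites=1500, chrom_length_bp=1_500_000)
            pools, _, pos = sd.simulate_population_pools(model, 60, rng)
            specs = [CohortSpec("taurine", 20, {"taurine": 1.0}),
                     CohortSpec("indicine", 20, {"indicine": 1.0}),
                     CohortSpec("hdpool", 40, {"taurine": 0.5, "indicine": 0.5}),
                     CohortSpec("admixed", 10, {"taurine": 0.5, "indicine": 0.5})]
            cohort = sd.simulate_cohort(model, pools, specs, pos, rng, impact_spec={})
            groups = np.asarray(cohort.sample_groups)
            truth, sites = cohort.truth_haplotypes, cohort.site_table
            tgt = truth.subset_samples(np.flatnonzero(groups == "admixed"))
            wgs = truth.subset_samples(
                np.flatnonzero(np.isin(groups, ["taurine", "indicine"])))
            hdp = truth.subset_samples(np.flatnonzero(groups == "hdpool"))
            dense = design_array(cohort, "uniform-common", 300, rng,
                                 discovery_population="taurine", id_prefix="dn")
            sparse = subset_array(dense, 30, rng, id_prefix="sp")
            tp, ts, _ = build_target_set(tgt, sites, sparse)
            hd_tp, hd_ts, _ = build_target_set(hdp, sites, dense)
            truthg = tgt.to_genotypes()
            maf = wgs.maf()
            one = impute_cohort(tp, ts, wgs, sites)
            er2_one = accuracy(one, truthg, maf)["er2"].mean()
            two = two_step_impute(tp, ts, hd_tp, hd_ts, wgs, sites)
            er2_two = accuracy(two, truthg, maf,
                               typed_subset=two.provenance["sparse_mask"])["er2"].mean()
            wins += er2_two > er2_one
        assert wins >= n_seeds - 1
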