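"""Soft-threshold network, signed TOM (against a brute-force oracle), module
detection, connectivity statistics, cores/periphery, scale-free fit and the
gene-label permutation machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from coexqtl.network import (
    build_network,
    define_cores_and_periphery,
    detect_modules,
    label_permutation_test,
    node_statistics,
    scale_free_fit,
    signed_tom,
)
from coexqtl.quantgen import genotype_means


def brute_force_signed_tom(adjacency, r):
    """Triple-loop oracle for the signed TOM formula."""
    n = adjacency.shape[0]
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    sa = np.sign(r) * a
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(sa[i, u] * sa[u, j] for u in range(n)
                         if u != i and u != j)
            tom[i, j] = abs(sa[i, j] + shared) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def _random_network(n, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 30))
    means = pd.DataFrame(x, index=[f"g{i}" for i in range(n)])
    return build_network(means)


class TestBuildNetwork:
    def test_power_rule(self):
        assert 0.5 ** 5 == pytest.approx(0.03125)
        net = _random_network(5, 0)
        assert np.allclose(net.adjacency - np.eye(5),
                           np.abs(net.r) ** 5 - np.eye(5))

    def test_two_gene_tom_equals_adjacency(self):
        r = np.array([[1.0, 0.6], [0.6, 1.0]])
        a = np.abs(r) ** 5
        tom = signed_tom(a, r)
        assert tom[0, 1] == pytest.approx(a[0, 1])

    @pytest.mark.parametrize("n,seed", [(20, 1), (50, 2)])
    def test_tom_matches_brute_force(self, n, seed):
        net = _random_network(n, seed)
        oracle = brute_force_signed_tom(net.adjacency, net.r)
        assert np.max(np.abs(net.tom - oracle)) < 1e-10

    def test_constant_gene_named_in_error(self):
        means = pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.1, 0.5, 0.9], [2.0, 1.0, 3.0]],
            index=["flat", "a", "b"],
        )
        with pytest.raises(ValueError, match="flat"):
            build_network(means)

    def test_adjacency_and_tom_ranges(self):
        net = _random_network(25, 3)
        assert np.all((net.adjacency >= 0) & (net.adjacency <= 1))
        assert np.all((net.tom >= -1e-12) & (net.tom <= 1 + 1e-12))
        assert np.allclose(net.tom, net.tom.T)
        assert np.allclose(np.diag(net.adjacency), 1.0)


class TestDetectModules:
    def test_planted_modules_recovered(self, module_cohort):
        _, genotypes, _, expression, truth = module_cohort
        means = genotype_means(expression, genotypes.samples)
        net = build_network(means.sub(means.mean(axis=1), axis=0))
        labels = detect_modules(net.dissimilarity, min_module_size=20)
        # same partition up to label names; hubs all co-clustered
        mm = truth.module_membership.to_numpy()
        for mod in (1, 2, 3):
            hub_labels = labels[(mm == mod) & truth.hub_flags.to_numpy()]
            assert hub_labels.min() == hub_labels.max() != 0
        assert adjusted_rand_score(mm, labels) > 0.6

    def test_pure_noise_goes_to_junk(self):
        rng = np.random.default_rng(4)
        means = pd.DataFrame(rng.standard_normal((120, 86)),
                             index=[f"g{i}" for i in range(120)])
        net = build_network(means)
        labels = detect_modules(net.dissimilarity)
        assert (labels == 0).mean() > 0.8

    def test_min_module_size_above_all_clusters_gives_all_junk(self):
        net = _random_network(40, 5)
        labels = detect_modules(net.dissimilarity, min_module_size=1000)
        assert (labels == 0).all()


class TestNodeStatistics:
    def test_clique_statistics(self):
        r = np.ones((4, 4))
        means = None
        from coexqtl.network import NetworkModel

        a = np.ones((4, 4))
        net = NetworkModel(gene_ids=list("abcd"), r=r, beta=5.0,
                           adjacency=a, tom=np.ones((4, 4)))
        stats = node_statistics(net, np.ones(4, dtype=int))
        assert np.allclose(stats["kTotal"], 3.0)
        assert np.allclose(stats["kWithin"], 3.0)
        assert np.allclose(stats["kOut"], 0.0)

    def test_ktotal_split_and_brute_force_rowsums(self):
        net = _random_network(30, 6)
        labels = np.random.default_rng(7).integers(1, 4, size=30)
        stats = node_statistics(net, labels)
        a = net.adjacency.copy()
        np.fill_diagonal(a, 0.0)
        assert np.allclose(stats["kTotal"], a.sum(axis=1), atol=1e-12)
        assert np.allclose(stats["kTotal"],
                           stats["kWithin"] + stats["kOut"], atol=1e-12)

    def test_all_within_module_kdiff(self):
        from coexqtl.network import NetworkModel

        r = np.eye(6)
        r[:3, :3] = 0.9
        np.fill_diagonal(r, 1.0)
        a = np.abs(r) ** 5
        np.fill_diagonal(a, 1.0)
        net = NetworkModel(gene_ids=[f"g{i}" for i in range(6)], r=r,
                           beta=5.0, adjacency=a, tom=signed_tom(a, r))
        labels = np.array([1, 1, 1, 2, 2, 2])
        stats = node_statistics(net, labels)
        g0 = stats.iloc[0]
        assert g0["kOut"] == pytest.approx(0.0)
        assert g0["kDiff_norm"] == pytest.approx(g0["kWithin"] / 2)


class TestCoresAndPeriphery:
    def test_exact_core_decile(self, module_cohort):
        _, genotypes, _, expression, truth = module_cohort
        means = genotype_means(expression, genotypes.samples)
        net = build_network(means.sub(means.mean(axis=1), axis=0))
        labels = truth.module_membership.to_numpy()
        stats = node_statistics(net, labels)
        flags = define_cores_and_periphery(net, labels, stats)
        for mod, size in ((1, 50), (2, 40), (3, 30)):
            n_core = flags.loc[labels == mod, "core"].sum()
            cand = (stats.loc[labels == mod, "kWithin"] > 1).sum()
            assert n_core == min(int(np.ceil(0.10 * size)), cand)

    def test_degree_one_is_peripheral(self):
        from coexqtl.network import NetworkModel

        # gene 3 correlates only with gene 0 above threshold
        r = np.eye(4)
        r[0, 1] = r[1, 0] = 0.9
        r[0, 2] = r[2, 0] = 0.9
        r[1, 2] = r[2, 1] = 0.9
        r[0, 3] = r[3, 0] = 0.5
        a = np.abs(r) ** 5
        np.fill_diagonal(a, 1.0)
        net = NetworkModel(gene_ids=list("wxyz"), r=r, beta=5.0,
                           adjacency=a, tom=signed_tom(a, r))
        labels = np.array([1, 1, 1, 0])
        stats = node_statistics(net, labels)
        flags = define_cores_and_periphery(net, labels, stats)
        assert bool(flags.loc["z", "peripheral"])
        assert not flags.loc["w", "peripheral"]

    def test_planted_hubs_flagged_core(self, module_cohort):
        _, genotypes, _, expression, truth = module_cohort
        means = genotype_means(expression, genotypes.samples)
        net = build_network(means.sub(means.mean(axis=1), axis=0))
        labels = detect_modules(net.dissimilarity, min_module_size=20)
        stats = node_statistics(net, labels)
        flags = define_cores_and_periphery(net, labels, stats)
        hub_core = flags.loc[truth.hub_flags.to_numpy(), "core"]
        assert hub_core.mean() >= 0.8


class TestScaleFreeFit:
    def test_power_law_degrees(self):
        rng = np.random.default_rng(8)
        # p(k) ~ k^-2 on a grid of degrees
        ks = np.arange(1, 40, dtype=float)
        weights = ks ** -2.0
        counts = np.round(weights / weights.sum() * 50_000).astype(int)
        k_total = np.repeat(ks, counts) + rng.uniform(0, 1e-6, counts.sum())
        r2, slope = scale_free_fit(k_total)
        assert r2 >= 0.95
        assert slope == pytest.approx(-2.0, abs=0.3)

    def test_uniform_degrees_fit_poorly(self):
        rng = np.random.default_rng(9)
        k_total = rng.uniform(1, 50, size=5000)
        r2, _ = scale_free_fit(k_total)
        assert r2 < 0.5

    def test_constant_connectivity_rejected(self):
        with pytest.raises(ValueError):
            scale_free_fit(np.full(100, 3.0))


class TestLabelPermutationTest:
    def test_exhaustive_enumeration_oracle(self):
        # 6 nodes, 2 fixed cores, a single flagged node; statistic = flagged
        # cores. Exact null: P(count >= 1) = 2/6.
        core = np.array([True, True, False, False, False, False])
        attribute = np.array([1, 0, 0, 0, 0, 0])

        def statistic(attr):
            return int(attr[core].sum())

        exact = np.mean([
            statistic(np.array(perm)) >= 1
            for perm in set(itertools.permutations(attribute))
        ])
        assert exact == pytest.approx(2.0 / 6.0)
        res = label_permutation_test(attribute, statistic, n_perm=5000,
                                     rng=0, alternative="greater")
        assert res.p == pytest.approx(exact, abs=0.02)

    def test_statistic_invariant_to_attribute_gives_p_one(self):
        attribute = np.arange(10)
        res = label_permutation_test(attribute, lambda a: 1.0, n_perm=50,
                                     rng=1, alternative="greater")
        assert res.p == 1.0

    def test_constant_attribute_rejected(self):
        with pytest.raises(ValueError):
            label_permutation_test(np.ones(5), lambda a: a.sum(), n_perm=10)

    def test_null_calibration_uniform(self):
        # continuous attribute independent of topology -> p ~ uniform
        rng = np.random.default_rng(2)
        core = np.zeros(30, dtype=bool)
        core[:5] = True
        ps = []
        for _ in range(200):
            attr = rng.standard_normal(30)
            res = label_permutation_test(
                attr, lambda a: float(a[core].mean()), n_perm=199,
                rng=rng, alternative="greater",
            )
            ps.append(res.p)
        from scipy import stats as sps

        assert sps.kstest(ps, "uniform").pvalue > 0.01
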