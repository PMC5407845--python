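"""Variant filtering, structure covariate, association scan, permutation FDR,
classification, eSNP collapsing, hotspot scan and MAF-fixing subsampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexqtl.data import GenotypeData
from coexqtl.eqtl import (
    benjamini_hochberg,
    classify_local_distant,
    collapse_unique_esnps,
    empirical_fdr,
    filter_variants,
    hotspot_scan,
    map_associations,
    structure_covariate,
    subsample_fix_maf,
    variant_stats,
)
from coexqtl.quantgen import genotype_means
from coexqtl.simulate import SimConfig, simulate_genotypes


def _genotypes(matrix, positions=None, chrom="chr1"):
    matrix = np.asarray(matrix, dtype=np.int8)
    n_gt, n_snp = matrix.shape
    if positions is None:
        positions = list(range(100, 100 + 100 * n_snp, 100))
    variants = pd.DataFrame(
        {"id": [f"s{j}" for j in range(n_snp)],
         "chrom": [chrom] * n_snp, "pos": positions,
         "ref": ["A"] * n_snp, "alt": ["G"] * n_snp}
    )
    ids = [f"G{i}" for i in range(n_gt)]
    samples = pd.DataFrame({"sample": ids, "genotype": ids,
                            "population": ["P1"] * n_gt})
    return GenotypeData(variants=variants, matrix=matrix,
                        genotype_ids=ids, samples=samples)


class TestFilterVariants:
    def test_single_homozygote_mgf_exclusion(self):
        # 49 heterozygotes + 1 hom-ref: MAF 0.49 passes, MGF 0.98 fails
        col = np.ones((50, 1), dtype=np.int8)
        col[0, 0] = 0
        gt = _genotypes(col)
        vstats, filtered = filter_variants(gt)
        assert vstats.loc[0, "maf"] == pytest.approx(0.49)
        assert vstats.loc[0, "mgf"] == pytest.approx(0.98)
        assert filtered.n_variants == 0

    def test_monomorphic_excluded(self):
        gt = _genotypes(np.zeros((10, 1)))
        _, filtered = filter_variants(gt)
        assert filtered.n_variants == 0

    def test_balanced_homozygotes_kept(self):
        gt = _genotypes(np.array([[0]] * 5 + [[2]] * 5))
        vstats, filtered = filter_variants(gt)
        assert vstats.loc[0, "maf"] == pytest.approx(0.5)
        assert vstats.loc[0, "mgf"] == pytest.approx(0.5)
        assert filtered.n_variants == 1

    def test_all_missing_snp_dropped(self):
        gt = _genotypes(np.full((10, 1), -1))
        _, filtered = filter_variants(gt)
        assert filtered.n_variants == 0


class TestStructureCovariate:
    def test_identical_columns_pruned_then_pc1(self):
        rng = np.random.default_rng(0)
        a = rng.choice([0, 1, 2], size=(40, 1))
        b = rng.choice([0, 1, 2], size=(40, 3))
        gt = _genotypes(np.hstack([a, a, b]))
        cov = structure_covariate(gt, block_size=50)
        assert cov.shape == (40,)

    def test_independent_snps_not_pruned(self):
        rng = np.random.default_rng(1)
        m = rng.choice([0, 1, 2], size=(200, 5), p=[0.25, 0.5, 0.25])
        gt = _genotypes(m)
        from coexqtl.eqtl import _prune_block

        kept = _prune_block(m.astype(float), r2_max=0.2)
        assert kept == [0, 1, 2, 3, 4]

    def test_two_subpopulations_separated(self):
        rng = np.random.default_rng(2)
        n, n_snp = 60, 120
        pops = np.repeat([0, 1], n // 2)
        freqs = np.where(pops[:, None] == 0, 0.15, 0.85)
        m = rng.binomial(2, np.broadcast_to(freqs, (n, n_snp)))
        gt = _genotypes(m.astype(np.int8))
        cov = structure_covariate(gt)
        r = np.corrcoef(cov, pops)[0, 1]
        assert abs(r) > 0.9


class TestMapAssociations:
    def test_perfect_fit(self):
        rng = np.random.default_rng(3)
        dose = rng.choice([0, 1, 2], size=(30, 1), p=[0.25, 0.5, 0.25])
        gt = _genotypes(dose)
        cov = rng.standard_normal(30)
        cov -= cov.mean()
        dose_c = dose[:, 0] - dose[:, 0].mean()
        cov -= (cov @ dose_c) / (dose_c @ dose_c) * dose_c  # orthogonalise
        means = pd.DataFrame([dose[:, 0].astype(float)], index=["g0"],
                             columns=gt.genotype_ids)
        scan = map_associations(means, gt, cov)
        assert scan.beta[0, 0] == pytest.approx(1.0)
        assert scan.r2[0, 0] == pytest.approx(1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        dose = rng.choice([0, 1, 2], size=(50, 4))
        gt = _genotypes(dose)
        cov = rng.standard_normal(50)
        y = rng.standard_normal((3, 50))
        means = pd.DataFrame(y, index=["a", "b", "c"], columns=gt.genotype_ids)
        s1 = map_associations(means, gt, cov)
        s2 = map_associations(2.0 * means, gt, cov)
        assert np.allclose(s2.beta, 2.0 * s1.beta, equal_nan=True)
        assert np.allclose(s2.t, s1.t, equal_nan=True)
        assert np.allclose(s2.p, s1.p, equal_nan=True)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(5)
        dose = rng.choice([0, 1, 2], size=(80, 50), p=[0.25, 0.5, 0.25])
        gt = _genotypes(dose)
        cov = rng.standard_normal(80)
        y = rng.standard_normal((40, 80))
        means = pd.DataFrame(y, index=[f"g{i}" for i in range(40)],
                             columns=gt.genotype_ids)
        scan = map_associations(means, gt, cov)
        p = scan.p[np.isfinite(scan.p)]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_zero_variance_pair_skipped(self):
        rng = np.random.default_rng(0)
        gt = _genotypes(np.ones((20, 1)))
        means = pd.DataFrame([rng.standard_normal(20)],
                             index=["g"], columns=gt.genotype_ids)
        scan = map_associations(means, gt, rng.standard_normal(20))
        assert np.isnan(scan.t[0, 0])


class TestEmpiricalFdr:
    def test_planted_signal_beats_all_null_maxima(self):
        rng = np.random.default_rng(6)
        cfg = SimConfig(n_snps=100, n_genes=1, n_genotypes=86, seed=1)
        gt = simulate_genotypes(cfg)
        _, filt = filter_variants(gt)
        dose = filt.matrix[:, 0].astype(float)
        y = dose / dose.std() * np.sqrt(0.5) + rng.standard_normal(86) * np.sqrt(0.5)
        means = pd.DataFrame([y], index=["g0"], columns=filt.genotype_ids)
        cov = rng.standard_normal(86) * 0.01
        scan = map_associations(means, filt, cov)
        records = empirical_fdr(scan, means, filt, cov, n_perm=200,
                                rng=np.random.default_rng(7))
        top = records.loc[records["t"].abs().idxmax()]
        assert top["emp_p"] == pytest.approx(1.0 / 201.0)
        assert top["significant"]

    def test_low_permutation_count_rejected(self):
        with pytest.raises(ValueError):
            empirical_fdr(None, None, None, None, n_perm=5)


class TestClassification:
    @pytest.fixture()
    def annotation(self):
        from coexqtl.data import Gene, GeneAnnotation, SubFeature

        gene = Gene(id="g1", chrom="chr1", strand="+", start=500_000,
                    end=510_000,
                    subfeatures=[SubFeature("exon", 500_000, 510_000)])
        return GeneAnnotation({"g1": gene})

    def _records(self, snp_pos, chrom="chr1"):
        records = pd.DataFrame({"gene": ["g1"], "snp": ["s"], "t": [5.0],
                                "p": [1e-9]})
        variants = pd.DataFrame({"id": ["s"], "chrom": [chrom],
                                 "pos": [snp_pos]})
        return records, variants

    def test_exactly_100kb_is_local(self, annotation):
        records, variants = self._records(610_000)
        out = classify_local_distant(records, annotation, variants)
        assert out.loc[0, "class"] == "local"
        assert out.loc[0, "distance"] == 100_000

    def test_one_bp_beyond_is_distant(self, annotation):
        records, variants = self._records(610_001)
        out = classify_local_distant(records, annotation, variants)
        assert out.loc[0, "class"] == "distant"

    def test_other_chromosome_is_distant(self, annotation):
        records, variants = self._records(500_001, chrom="chr2")
        out = classify_local_distant(records, annotation, variants)
        assert out.loc[0, "class"] == "distant"
        assert out.loc[0, "distance"] == 0

    def test_missing_egene_rejected(self, annotation):
        records, variants = self._records(1)
        records["gene"] = "unknown"
        with pytest.raises(KeyError):
            classify_local_distant(records, annotation, variants)


class TestCollapseUniqueEsnps:
    def test_identical_columns_masked(self):
        rng = np.random.default_rng(8)
        d = rng.choice([0.0, 1, 2], size=40)
        y = d + rng.standard_normal(40) * 0.5
        model = collapse_unique_esnps("g", ["a", "b"],
                                      np.column_stack([d, d]), y)
        assert model.unique_esnps == ["a"]
        single = collapse_unique_esnps("g", ["a"], d[:, None], y)
        assert model.adjusted_ve == pytest.approx(single.adjusted_ve)

    def test_orthogonal_effects_are_additive(self):
        rng = np.random.default_rng(9)
        n = 4000
        d1 = rng.choice([0.0, 1, 2], size=n)
        d2 = rng.choice([0.0, 1, 2], size=n)
        d1s = (d1 - d1.mean()) / d1.std()
        d2s = (d2 - d2.mean()) / d2.std()
        y = np.sqrt(0.25) * d1s + np.sqrt(0.25) * d2s \
            + np.sqrt(0.5) * rng.standard_normal(n)
        model = collapse_unique_esnps("g", ["a", "b"],
                                      np.column_stack([d1, d2]), y)
        assert model.unique_esnps == ["a", "b"]
        assert model.adjusted_ve == pytest.approx(50.0, abs=3.0)

    def test_masking_is_order_dependent_but_ve_is_not(self):
        rng = np.random.default_rng(10)
        d = rng.choice([0.0, 1, 2], size=60)
        y = d + rng.standard_normal(60)
        fwd = collapse_unique_esnps("g", ["a", "b"], np.column_stack([d, d]), y)
        rev = collapse_unique_esnps("g", ["b", "a"], np.column_stack([d, d]), y)
        assert fwd.unique_esnps == ["a"] and rev.unique_esnps == ["b"]
        assert fwd.adjusted_ve == pytest.approx(rev.adjusted_ve)

    def test_single_esnp_returned_as_is(self):
        d = np.array([0.0, 1, 2, 1, 0, 2])
        y = np.array([0.1, 1.2, 2.1, 0.9, 0.0, 2.2])
        model = collapse_unique_esnps("g", ["only"], d[:, None], y)
        assert model.unique_esnps == ["only"]


class TestHotspotScan:
    def test_constructed_window_counts(self):
        variants = pd.DataFrame({
            "id": [f"s{i}" for i in range(6)],
            "chrom": ["chr1"] * 6,
            "pos": [10_000, 20_000, 30_000, 40_000, 50_000, 150_000],
        })
        records = pd.DataFrame({
            "gene": ["gA", "gA", "gB", "gB", "gC", "gD"],
            "snp": ["s0", "s1", "s2", "s3", "s4", "s5"],
            "p": [1e-9] * 6,
        })
        table = hotspot_scan(records, variants)
        first = table[(table["chrom"] == "chr1") & (table["start"] == 1)]
        assert first["n_esnps"].iloc[0] == 5
        assert first["n_genes"].iloc[0] == 3

    def test_empty_window_zero_counts(self):
        variants = pd.DataFrame({"id": ["s0"], "chrom": ["chr1"],
                                 "pos": [250_000]})
        records = pd.DataFrame({"gene": ["g"], "snp": ["s0"], "p": [1e-9]})
        table = hotspot_scan(records, variants)
        empty = table[table["start"] == 1]
        assert empty["n_esnps"].iloc[0] == 0
        assert empty["n_genes"].iloc[0] == 0


class TestSubsampleFixMaf:
    def test_all_heterozygote_vector_fails(self):
        dosage = np.ones(86, dtype=int)
        kept, ok = subsample_fix_maf(dosage, seed=0)
        assert not ok and kept is None

    def test_maf_quarter_already(self):
        rng = np.random.default_rng(11)
        d = rng.binomial(2, 0.25, size=86)
        kept, ok = subsample_fix_maf(d, seed=1)
        assert ok and kept.size == 40
        maf = min(d[kept].mean() / 2, 1 - d[kept].mean() / 2)
        assert 0.23 <= maf <= 0.27

    def test_maf_040_panel_steered_into_window(self):
        rng = np.random.default_rng(12)
        d = rng.binomial(2, 0.40, size=86)
        kept, ok = subsample_fix_maf(d, seed=2)
        assert ok and kept.size == 40
        maf = min(d[kept].mean() / 2, 1 - d[kept].mean() / 2)
        assert 0.23 <= maf <= 0.27

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(13)
        d = rng.binomial(2, 0.35, size=90)
        k1, _ = subsample_fix_maf(d, seed=5)
        k2, _ = subsample_fix_maf(d, seed=5)
        assert np.array_equal(k1, k2)


def test_benjamini_hochberg_matches_statsmodels_convention():
    rng = np.random.default_rng(14)
    p = np.concatenate([rng.uniform(size=50), rng.uniform(0, 1e-4, size=5)])
    adj = benjamini_hochberg(p)
    # step-up property: adjusted values monotone in p after sorting
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0)
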