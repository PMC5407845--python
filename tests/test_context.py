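"""Genomic-context priority, discard and double-count rules, densities and
positional profiles."""

import numpy as np
import pandas as pd
import pytest

from coexqtl.context import (
    classify_genomic_context,
    context_density_profile,
    feature_lengths,
)
from coexqtl.data import Gene, GeneAnnotation, SubFeature


def _plus_gene(gid="g1", chrom="chr1", start=10_000):
    # 5'UTR 10000-10149, exon 10150-10599, intron 10600-10719,
    # exon 10720-11169, 3'UTR 11170-11369
    subs = [
        SubFeature("five_prime_UTR", start, start + 149),
        SubFeature("exon", start + 150, start + 599),
        SubFeature("intron", start + 600, start + 719),
        SubFeature("exon", start + 720, start + 1169),
        SubFeature("three_prime_UTR", start + 1170, start + 1369),
    ]
    return Gene(id=gid, chrom=chrom, strand="+", start=start,
                end=start + 1369, subfeatures=subs)


class TestPriorityRules:
    def test_utr_beats_exon(self):
        # a transcript whose annotated exon span covers the 3'UTR as well
        start = 10_000
        subs = [
            SubFeature("exon", start, start + 500),
            SubFeature("three_prime_UTR", start + 400, start + 500),
        ]
        gene = Gene(id="g1", chrom="chr1", strand="+", start=start,
                    end=start + 500, subfeatures=subs)
        ann = GeneAnnotation({"g1": gene})
        out = classify_genomic_context("s", "chr1", start + 450, ann)
        assert out.labels == ["three_prime_utr"]

    def test_exon_and_intron_assignment(self):
        ann = GeneAnnotation({"g1": _plus_gene()})
        assert classify_genomic_context("s", "chr1", 10_200, ann).labels == ["exon"]
        assert classify_genomic_context("s", "chr1", 10_650, ann).labels == ["intron"]

    def test_minus_strand_upstream_flank(self):
        subs = [SubFeature("exon", 50_000, 51_000)]
        gene = Gene(id="g1", chrom="chr1", strand="-", start=50_000,
                    end=51_000, subfeatures=subs)
        ann = GeneAnnotation({"g1": gene})
        # 1,500 bp 5' of a minus-strand gene = beyond its end coordinate
        out = classify_genomic_context("s", "chr1", 52_500, ann)
        assert out.labels == ["upstream"]
        out2 = classify_genomic_context("s", "chr1", 49_000, ann)
        assert out2.labels == ["downstream"]

    def test_intergenic_far_from_genes(self):
        ann = GeneAnnotation({"g1": _plus_gene()})
        out = classify_genomic_context("s", "chr1", 500_000, ann)
        assert out.labels == ["intergenic"]


class TestDiscardRules:
    def test_same_strand_intron_exon_overlap_discarded(self):
        host = _plus_gene()
        intron = host.features_of("intron")[0]
        nested = Gene(id="g2", chrom="chr1", strand="+",
                      start=intron.start, end=intron.end,
                      subfeatures=[SubFeature("exon", intron.start, intron.end)])
        ann = GeneAnnotation({"g1": host, "g2": nested})
        out = classify_genomic_context("s", "chr1", intron.start + 10, ann)
        assert out.discarded
        assert out.discard_reason == "intron_exon_same_strand_overlap"

    def test_gene_without_subfeature_discarded(self):
        gene = Gene(id="g1", chrom="chr1", strand="+", start=1000, end=2000,
                    subfeatures=[SubFeature("exon", 1000, 1400)])
        ann = GeneAnnotation({"g1": gene})
        out = classify_genomic_context("s", "chr1", 1700, ann)
        assert out.discarded
        assert out.discard_reason == "gene_without_subfeature"

    def test_opposite_strand_overlap_counts_both(self):
        plus = _plus_gene()
        minus = Gene(id="g2", chrom="chr1", strand="-", start=10_100,
                     end=10_900,
                     subfeatures=[SubFeature("exon", 10_100, 10_900)])
        ann = GeneAnnotation({"g1": plus, "g2": minus})
        out = classify_genomic_context("s", "chr1", 10_200, ann)
        assert len(out.labels) == 2
        assert set(out.host_genes) == {"g1", "g2"}


class TestRelationAndAccounting:
    def test_relation_to_egene(self):
        ann = GeneAnnotation({"g1": _plus_gene(), "g2": _plus_gene("g2", start=40_000)})
        within = classify_genomic_context("s", "chr1", 10_200, ann, egene="g1")
        other = classify_genomic_context("s", "chr1", 40_200, ann, egene="g1")
        assert within.relation == "within_egene"
        assert other.relation == "within_other_gene"

    def test_counts_partition_snps(self):
        ann = GeneAnnotation({"g1": _plus_gene()})
        positions = list(range(9_000, 13_000, 37))
        outs = [classify_genomic_context(f"s{p}", "chr1", p, ann)
                for p in positions]
        n_discarded = sum(o.discarded for o in outs)
        n_labelled = sum(len(o.labels) > 0 for o in outs if not o.discarded)
        assert n_discarded + n_labelled == len(positions)

    def test_idempotent(self):
        ann = GeneAnnotation({"g1": _plus_gene()})
        a = classify_genomic_context("s", "chr1", 10_650, ann)
        b = classify_genomic_context("s", "chr1", 10_650, ann)
        assert a.labels == b.labels and a.discarded == b.discarded


class TestDensityProfile:
    def test_density_ratio(self):
        # 10 eSNPs inside a 10-kbp single-exon "UTR-free" gene body: density
        # over the exon class = count / kbp
        gene = Gene(id="g1", chrom="chr1", strand="+", start=10_001,
                    end=20_000,
                    subfeatures=[SubFeature("exon", 10_001, 20_000)])
        ann = GeneAnnotation({"g1": gene})
        positions = {f"s{i}": ("chr1", 10_001 + i * 999) for i in range(10)}
        outs = [classify_genomic_context(s, c, p, ann)
                for s, (c, p) in positions.items()]
        density, _ = context_density_profile(outs, ann, positions)
        exon_row = density[density["context"] == "exon"].iloc[0]
        assert exon_row["count"] == 10
        assert exon_row["per_kbp"] == pytest.approx(1.0)

    def test_uniform_body_placement_gives_flat_profile(self):
        gene = Gene(id="g1", chrom="chr1", strand="+", start=10_001,
                    end=30_000,
                    subfeatures=[SubFeature("exon", 10_001, 30_000)])
        ann = GeneAnnotation({"g1": gene})
        rng = np.random.default_rng(0)
        positions = {f"s{i}": ("chr1", int(rng.integers(10_001, 30_001)))
                     for i in range(2000)}
        outs = [classify_genomic_context(s, c, p, ann)
                for s, (c, p) in positions.items()]
        _, profile = context_density_profile(outs, ann, positions)
        body = profile[profile["region"] == "body"]
        counts = body.set_index("bin")["count"].reindex(range(20), fill_value=0)
        expected = 2000 / 20
        assert np.all(np.abs(counts - expected) < 5 * np.sqrt(expected))

    def test_tss_proximal_placement_peaks_in_first_bin(self):
        gene = Gene(id="g1", chrom="chr1", strand="+", start=10_001,
                    end=30_000,
                    subfeatures=[SubFeature("exon", 10_001, 30_000)])
        ann = GeneAnnotation({"g1": gene})
        rng = np.random.default_rng(1)
        positions = {}
        for i in range(200):  # first kbp of the gene body
            positions[f"b{i}"] = ("chr1", int(rng.integers(10_001, 11_001)))
        for i in range(200):  # first kbp upstream
            positions[f"u{i}"] = ("chr1", int(rng.integers(9_001, 10_001)))
        outs = [classify_genomic_context(s, c, p, ann)
                for s, (c, p) in positions.items()]
        _, profile = context_density_profile(outs, ann, positions)
        body = profile[profile["region"] == "body"].set_index("bin")["count"]
        up = profile[profile["region"] == "upstream"].set_index("bin")["count"]
        assert body.idxmax() == 0
        assert up.idxmax() == -1

    def test_zero_length_class_missing_density(self):
        gene = Gene(id="g1", chrom="chr1", strand="+", start=1000, end=2000,
                    subfeatures=[SubFeature("exon", 1000, 2000)])
        ann = GeneAnnotation({"g1": gene})
        density, _ = context_density_profile([], ann, {})
        intron = density[density["context"] == "intron"].iloc[0]
        assert np.isnan(intron["per_kbp"])
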