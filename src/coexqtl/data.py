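"""In-memory containers for genotype, annotation and expression data.

Conventions: coordinates are 1-based inclusive (VCF/GFF3 native), distances in
base pairs, genotypes coded as alternate-allele dosage {0, 1, 2} with -1 for
missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: sub-feature types recognised in gene models, in 5'->3' order on the mRNA
SUBFEATURE_TYPES = ("five_prime_UTR", "exon", "intron", "three_prime_UTR")


@dataclass
class GenotypeData:
    """Biallelic SNP genotypes for a clonally replicated cohort.

    ``matrix`` is genotypes x variants (one row per *genotype*, not per
    sample); ``samples`` maps each assayed sample to its genotype and
    population of origin.
    """

    variants: pd.DataFrame  # columns: id, chrom, pos, ref, alt
    matrix: np.ndarray      # shape (n_genotypes, n_variants), int8 dosage
    genotype_ids: list[str]
    samples: pd.DataFrame   # columns: sample, genotype, population

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.genotype_ids), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {self.matrix.shape} does not match "
                f"{len(self.genotype_ids)} genotypes x {len(self.variants)} variants"
            )
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"variant positions not sorted on {chrom}")
        known = set(self.genotype_ids)
        unknown = set(self.samples["genotype"]) - known
        if unknown:
            raise ValueError(f"samples reference unknown genotypes: {sorted(unknown)[:5]}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    def dosage(self, snp_index: int) -> np.ndarray:
        return self.matrix[:, snp_index]


@dataclass
class SubFeature:
    type: str      # one of SUBFEATURE_TYPES
    start: int     # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.type not in SUBFEATURE_TYPES:
            raise ValueError(f"unknown sub-feature type {self.type!r}")
        if self.end < self.start:
            raise ValueError(f"{self.type}: end {self.end} < start {self.start}")


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str    # '+' or '-'
    start: int
    end: int
    subfeatures: list[SubFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be '+' or '-'")
        for sf in self.subfeatures:
            if sf.start < self.start or sf.end > self.end:
                raise ValueError(
                    f"{self.id}: sub-feature {sf.type} [{sf.start},{sf.end}] "
                    f"outside gene span [{self.start},{self.end}]"
                )

    def flank(self, which: str, length: int) -> tuple[int, int]:
        """Strand-aware flanking interval ('upstream' or 'downstream')."""
        five_prime = (which == "upstream") == (self.strand == "+")
        if five_prime:
            return (self.start - length, self.start - 1)
        return (self.end + 1, self.end + length)

    def features_of(self, ftype: str) -> list[SubFeature]:
        return [sf for sf in self.subfeatures if sf.type == ftype]


@dataclass
class GeneAnnotation:
    genes: dict[str, Gene]

    def __iter__(self):
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def by_chromosome(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes.values():
            out.setdefault(g.chrom, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: (g.start, g.id))
        return out


@dataclass
class ExpressionData:
    """Genes x samples matrix of normalised (log-like scale) expression."""

    matrix: np.ndarray   # shape (n_genes, n_samples), float
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression matrix shape mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicated gene ids in expression matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample ids in expression matrix")
        if np.isnan(self.matrix).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionData":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionData(self.matrix[rows], list(gene_ids), list(self.sample_ids))
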