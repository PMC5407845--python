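"""Readers and writers for the standard formats: VCF v4.2 (GT only), GFF3,
TSV expression/metadata tables, FASTA haplotype panels and the JSON truth
table, plus the run configuration."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .data import (
    MISSING,
    ExpressionData,
    Gene,
    GeneAnnotation,
    GenotypeData,
    SubFeature,
)

__all__ = [
    "RunConfig",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_annotation_gff3",
    "write_annotation_gff3",
    "read_expression_table",
    "write_expression_table",
    "read_sample_table",
    "write_sample_table",
    "read_sequence_panels",
    "write_sequence_panels",
]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters, defaulting to the study's published values."""

    maf_min: float = 0.1
    mgf_max: float = 0.9
    max_missing: float = 0.1
    local_window: int = 100_000
    context_flank: int = 2000
    popgen_flank: int = 1000
    soft_power: float = 5.0
    periphery_r: float = 0.4
    core_fraction: float = 0.10
    kwithin_min: float = 1.0
    min_module_size: int = 30
    eqtl_permutations: int = 1000
    network_permutations: int = 10_000
    quantgen_permutations: int = 1000
    confounder_grid_max: int = 20
    fdr: float = 0.05
    bh_alpha: float = 0.05
    hotspot_window: int = 100_000
    hotspot_p: float = 1e-6
    subsample_maf: float = 0.25
    subsample_tol: float = 0.02
    subsample_n: int = 40
    min_covered_sites: int = 50
    expr_var_threshold: float = 0.05
    expr_median_threshold: float = 2.0
    seed: int = 0
    log_level: str = "INFO"

    _RANGES = {
        "maf_min": (0.0, 0.5),
        "mgf_max": (1.0 / 3.0, 1.0),
        "max_missing": (0.0, 1.0),
        "fdr": (0.0, 1.0),
        "bh_alpha": (0.0, 1.0),
        "core_fraction": (0.0, 1.0),
        "periphery_r": (0.0, 1.0),
        "subsample_maf": (0.0, 0.5),
        "subsample_tol": (0.0, 0.5),
        "hotspot_p": (0.0, 1.0),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        for name in ("local_window", "context_flank", "popgen_flank",
                     "eqtl_permutations", "network_permutations",
                     "subsample_n", "min_covered_sites", "min_module_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.quantgen_permutations < 0:
            raise ValueError("quantgen_permutations must be >= 0")
        if self.soft_power <= 0:
            raise ValueError("soft_power must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# VCF

def read_genotypes_vcf(
    path: str | Path, samples: pd.DataFrame | None = None
) -> GenotypeData:
    """Load biallelic SNPs from a VCF (v4.2, GT field).

    Multi-allelic and indel records are skipped (count logged). Phased and
    unphased genotypes are treated identically; ``./.`` becomes missing. The
    VCF sample columns are the genotype ids; an optional sample table links
    them to replicated samples and populations (defaults to one sample per
    genotype in a single population).
    """
    path = str(path)
    vcf = VCF(path)
    genotype_ids = list(vcf.samples)
    rows, columns = [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        rows.append(
            {"id": rec.ID or f"{rec.CHROM}:{rec.POS}", "chrom": rec.CHROM,
             "pos": rec.POS, "ref": rec.REF, "alt": rec.ALT[0]}
        )
        gts = rec.genotype.array()[:, :2]
        code = gts.sum(axis=1).astype(np.int8)
        code[(gts < 0).any(axis=1)] = MISSING
        columns.append(code)
    if skipped:
        log.info("skipped %d non-biallelic-SNP records in %s", skipped, path)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    matrix = np.column_stack(columns).astype(np.int8)
    if samples is None:
        samples = pd.DataFrame(
            {"sample": genotype_ids, "genotype": genotype_ids,
             "population": "pop1"}
        )
    return GenotypeData(
        variants=pd.DataFrame(rows), matrix=matrix,
        genotype_ids=genotype_ids, samples=samples,
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes_vcf(genotypes: GenotypeData, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only FORMAT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(genotypes.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                  "INFO", "FORMAT", *genotypes.genotype_ids]
        fh.write("\t".join(header) + "\n")
        for j, row in enumerate(genotypes.variants.itertuples(index=False)):
            gts = "\t".join(_GT_STRINGS[int(c)] for c in genotypes.matrix[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# GFF3

_GFF_TYPES = {"five_prime_UTR", "three_prime_UTR", "exon"}


def write_annotation_gff3(annotation: GeneAnnotation, path: str | Path) -> None:
    """GFF3 with gene -> mRNA -> exon/UTR features (introns are implicit, as
    gaps between exons, and re-derived on read)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in annotation:
            fh.write(
                f"{gene.chrom}\tsim\tgene\t{gene.start}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.id}\n"
            )
            mrna = f"{gene.id}.1"
            fh.write(
                f"{gene.chrom}\tsim\tmRNA\t{gene.start}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={mrna};Parent={gene.id}\n"
            )
            for sf in gene.subfeatures:
                if sf.type == "intron":
                    continue
                fh.write(
                    f"{gene.chrom}\tsim\t{sf.type}\t{sf.start}\t{sf.end}\t.\t"
                    f"{gene.strand}\t.\tParent={mrna}\n"
                )


def _derive_introns(exons: list[SubFeature]) -> list[SubFeature]:
    exons = sorted(exons, key=lambda e: e.start)
    introns = []
    for a, b in zip(exons, exons[1:]):
        if b.start > a.end + 1:
            introns.append(SubFeature("intron", a.end + 1, b.start - 1))
    return introns


def read_annotation_gff3(path: str | Path) -> GeneAnnotation:
    """Parse gene models from GFF3.

    Introns are derived from exon gaps. When a gene has several transcripts,
    the one with the greatest total exonic (protein-coding proxy) length is
    used. Raises on features outside their gene span.
    """
    genes_raw: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    mrna_feats: dict[str, list[SubFeature]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            start, end = int(start), int(end)
            if ftype == "gene":
                genes_raw[attr["ID"]] = {
                    "chrom": chrom, "strand": strand, "start": start, "end": end,
                }
            elif ftype == "mRNA":
                mrna_parent[attr["ID"]] = attr["Parent"]
                mrna_feats.setdefault(attr["ID"], [])
            elif ftype in _GFF_TYPES or ftype == "CDS":
                parent = attr["Parent"]
                sftype = "exon" if ftype == "CDS" else ftype
                mrna_feats.setdefault(parent, []).append(
                    SubFeature(sftype, start, end)
                )
    genes: dict[str, Gene] = {}
    by_gene: dict[str, list[str]] = {}
    for mrna, parent in mrna_parent.items():
        by_gene.setdefault(parent, []).append(mrna)
    for gene_id, info in genes_raw.items():
        transcripts = by_gene.get(gene_id, [])
        if not transcripts:
            genes[gene_id] = Gene(id=gene_id, subfeatures=[], **info)
            continue
        # transcript with the greatest coding content wins
        def coding_length(mrna: str) -> int:
            return sum(
                sf.end - sf.start + 1
                for sf in mrna_feats.get(mrna, [])
                if sf.type == "exon"
            )
        best = max(sorted(transcripts), key=coding_length)
        feats = sorted(mrna_feats.get(best, []), key=lambda sf: (sf.start, sf.type))
        exons = [sf for sf in feats if sf.type == "exon"]
        feats = feats + _derive_introns(exons)
        for sf in feats:
            if sf.start < info["start"] or sf.end > info["end"]:
                raise ValueError(
                    f"{gene_id}: {sf.type} [{sf.start},{sf.end}] outside gene span"
                )
        genes[gene_id] = Gene(
            id=gene_id, subfeatures=sorted(feats, key=lambda s: s.start), **info
        )
    return GeneAnnotation(genes=genes)


# ---------------------------------------------------------------------------
# TSV tables

def write_expression_table(expr: ExpressionData, path: str | Path) -> None:
    expr.to_frame().rename_axis("gene").to_csv(path, sep="\t")


def read_expression_table(path: str | Path) -> ExpressionData:
    """TSV with gene ids in the first column and sample ids as the header.

    Strict numeric coercion: any non-numeric or empty cell raises with its
    row/column position.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene id(s): {dupes[:5]}")
    values = np.empty(df.shape)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna().to_numpy()
        if bad.any():
            gene = df.index[int(np.argmax(bad))]
            raise ValueError(
                f"non-numeric or missing value at gene {gene!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    return ExpressionData(
        matrix=values, gene_ids=list(df.index), sample_ids=list(df.columns)
    )


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "genotype", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# FASTA sequence panels

def write_sequence_panels(
    panels: dict[str, dict], directory: str | Path
) -> None:
    """One FASTA per gene (outgroup record suffixed ``_outgroup``) plus a
    JSON sidecar with the site-category masks."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    masks_out = {}
    for gene, panel in panels.items():
        records = [
            SeqRecord(Seq("".join(map(str, row))), id=f"{gene}_hap{i + 1}",
                      description="")
            for i, row in enumerate(np.asarray(panel["haplotypes"]))
        ]
        if panel.get("outgroup") is not None:
            records.append(
                SeqRecord(Seq(panel["outgroup"]), id=f"{gene}_outgroup",
                          description="")
            )
        SeqIO.write(records, directory / f"{gene}.fasta", "fasta")
        masks_out[gene] = {
            "cds_mask": np.flatnonzero(panel["cds_mask"]).tolist(),
            "masks": {
                k: np.flatnonzero(v).tolist()
                for k, v in panel["masks"].items()
            },
        }
    with open(directory / "site_masks.json", "w") as fh:
        json.dump(masks_out, fh)


def read_sequence_panels(directory: str | Path) -> dict[str, dict]:
    directory = Path(directory)
    with open(directory / "site_masks.json") as fh:
        masks_in = json.load(fh)
    panels = {}
    for fasta in sorted(directory.glob("*.fasta")):
        gene = fasta.stem
        haps, outgroup = [], None
        length = None
        for rec in SeqIO.parse(str(fasta), "fasta"):
            seq = str(rec.seq)
            length = len(seq) if length is None else length
            if rec.id.endswith("_outgroup"):
                outgroup = seq
            else:
                haps.append(list(seq))
        info = masks_in[gene]
        cds_mask = np.zeros(length, dtype=bool)
        cds_mask[info["cds_mask"]] = True
        masks = {}
        for k, idx in info["masks"].items():
            m = np.zeros(length, dtype=bool)
            m[idx] = True
            masks[k] = m
        panels[gene] = {
            "haplotypes": np.array(haps),
            "outgroup": outgroup,
            "masks": masks,
            "cds_mask": cds_mask,
        }
    return panels
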