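"""Genomic-context assignment for SNPs with priority, discard, double-count
and length-normalisation rules, plus positional eSNP profiles.

Per strand, the highest-priority feature overlapping a SNP wins:
UTR > exon/intron > upstream/downstream flank > intergenic. A SNP inside
same-strand overlapping gene models where one gene's intron overlaps
another's exon is discarded (ambiguous), as is a SNP inside a gene span but
in none of its sub-features (incomplete model). Genes on opposite strands
both contribute a label (double-counting across strands is intended).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Gene, GeneAnnotation

__all__ = [
    "classify_genomic_context",
    "context_density_profile",
    "ContextAssignment",
    "feature_lengths",
]

#: label priority, best first
PRIORITY = ("utr", "exon_intron", "flank", "intergenic")

UTR_TYPES = {"five_prime_UTR": "five_prime_utr", "three_prime_UTR": "three_prime_utr"}


@dataclass
class ContextAssignment:
    snp: str
    labels: list[str] = field(default_factory=list)
    host_genes: list[str] = field(default_factory=list)
    discarded: bool = False
    discard_reason: str | None = None
    relation: str = "intergenic"  # within_egene / within_other_gene / intergenic


def _gene_context(pos: int, gene: Gene, flank: int) -> tuple[str, str] | None:
    """(priority class, label) of ``pos`` relative to one gene, or None if
    out of range. Raises a sentinel for the in-span/no-sub-feature case."""
    if gene.start <= pos <= gene.end:
        for sf in gene.subfeatures:
            if sf.start <= pos <= sf.end and sf.type in UTR_TYPES:
                return ("utr", UTR_TYPES[sf.type])
        for sf in gene.subfeatures:
            if sf.start <= pos <= sf.end and sf.type == "exon":
                return ("exon_intron", "exon")
        for sf in gene.subfeatures:
            if sf.start <= pos <= sf.end and sf.type == "intron":
                return ("exon_intron", "intron")
        return ("in_gene_no_subfeature", "")
    up = gene.flank("upstream", flank)
    if up[0] <= pos <= up[1]:
        return ("flank", "upstream")
    down = gene.flank("downstream", flank)
    if down[0] <= pos <= down[1]:
        return ("flank", "downstream")
    return None


def classify_genomic_context(
    snp_id: str,
    chrom: str,
    pos: int,
    annotation: GeneAnnotation,
    flank: int = 2000,
    egene: str | None = None,
) -> ContextAssignment:
    """Assign per-strand context labels to one SNP.

    ``egene`` (optional) sets the relation field: within_egene when the SNP
    hits the associated gene itself, within_other_gene when it hits a
    different gene, else intergenic.
    """
    out = ContextAssignment(snp=snp_id)
    by_chrom = annotation.by_chromosome().get(chrom, [])
    per_strand: dict[str, list[tuple[str, str, Gene]]] = {"+": [], "-": []}
    in_span: dict[str, list[tuple[str, Gene]]] = {"+": [], "-": []}
    for gene in by_chrom:
        hit = _gene_context(pos, gene, flank)
        if hit is None:
            continue
        cls, label = hit
        if gene.start <= pos <= gene.end:
            # remember the body-level class for the same-strand overlap rule
            body = "exon" if label in ("exon", "five_prime_utr", "three_prime_utr") else (
                "intron" if label == "intron" else "none")
            in_span[gene.strand].append((body, gene))
        if cls == "in_gene_no_subfeature":
            continue  # handled below once overlaps are known
        per_strand[gene.strand].append((cls, label, gene))

    # same-strand overlap: one gene's intron over another's exon -> discard
    for strand, hits in in_span.items():
        if len(hits) >= 2:
            bodies = {b for b, _ in hits}
            if "exon" in bodies and "intron" in bodies:
                out.discarded = True
                out.discard_reason = "intron_exon_same_strand_overlap"
                return out

    # gene span hit but no sub-feature on any gene of that strand -> discard
    for strand, hits in in_span.items():
        if hits and all(b == "none" for b, _ in hits):
            out.discarded = True
            out.discard_reason = "gene_without_subfeature"
            return out

    for strand in "+-":
        hits = per_strand[strand]
        if not hits:
            continue
        best_rank = min(PRIORITY.index(cls) for cls, _, _ in hits)
        # among equal-priority hits prefer the closest gene, ties to lower id
        best = sorted(
            (h for h in hits if PRIORITY.index(h[0]) == best_rank),
            key=lambda h: (_boundary_distance(pos, h[2]), h[2].id),
        )[0]
        out.labels.append(best[1])
        out.host_genes.append(best[2].id)
    if not out.labels:
        out.labels = ["intergenic"]
    if egene is not None:
        if egene in out.host_genes:
            out.relation = "within_egene"
        elif out.host_genes:
            out.relation = "within_other_gene"
    return out


def _boundary_distance(pos: int, gene: Gene) -> int:
    if gene.start <= pos <= gene.end:
        return 0
    return min(abs(pos - gene.start), abs(pos - gene.end))


def feature_lengths(annotation: GeneAnnotation, flank: int = 2000) -> dict[str, int]:
    """Total bp per context class across the annotation (flanks counted per
    gene; intergenic = span not covered by genes or flanks, per chromosome
    up to the last annotated coordinate)."""
    totals = {k: 0 for k in
              ("five_prime_utr", "three_prime_utr", "exon", "intron",
               "upstream", "downstream", "intergenic")}
    for chrom, genes in annotation.by_chromosome().items():
        covered = 0
        last = max(g.end + flank for g in genes)
        for g in genes:
            for sf in g.subfeatures:
                key = UTR_TYPES.get(sf.type, sf.type)
                if key in totals:
                    totals[key] += sf.end - sf.start + 1
            totals["upstream"] += flank
            totals["downstream"] += flank
            covered += (g.end - g.start + 1) + 2 * flank
        totals["intergenic"] += max(last - covered, 0)
    return totals


def context_density_profile(
    assignments: list[ContextAssignment],
    annotation: GeneAnnotation,
    snp_positions: dict[str, tuple[str, int]],
    flank: int = 2000,
    n_body_bins: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class eSNP density (per kbp of that class) and a positional
    profile: flanks in 1-kbp bins, gene body rescaled to ``n_body_bins``
    relative bins, split by the SNP's relation to its eGene.

    Returns (density table, profile table). Classes of zero total length get
    a missing density.
    """
    lengths = feature_lengths(annotation, flank)
    counts: dict[str, int] = {k: 0 for k in lengths}
    for a in assignments:
        if a.discarded:
            continue
        for label in a.labels:
            if label in counts:
                counts[label] += 1
    density = pd.DataFrame(
        {
            "context": list(lengths),
            "count": [counts[k] for k in lengths],
            "length_bp": [lengths[k] for k in lengths],
        }
    )
    density["per_kbp"] = np.where(
        density["length_bp"] > 0,
        density["count"] / (density["length_bp"] / 1000.0),
        np.nan,
    )

    n_flank_bins = int(np.ceil(flank / 1000))
    profile_rows = []
    for a in assignments:
        if a.discarded or not a.host_genes:
            continue
        chrom, pos = snp_positions[a.snp]
        for gene_id in a.host_genes:
            gene = annotation[gene_id]
            if gene.chrom != chrom:
                continue
            # orientation: measure 5'->3' along the gene's strand
            if gene.start <= pos <= gene.end:
                frac = (pos - gene.start) / max(gene.end - gene.start, 1)
                if gene.strand == "-":
                    frac = 1.0 - frac
                bin_id = min(int(frac * n_body_bins), n_body_bins - 1)
                region, bin_lab = "body", bin_id
            else:
                up = gene.flank("upstream", flank)
                if up[0] <= pos <= up[1]:
                    dist = abs(pos - (gene.start if gene.strand == "+" else gene.end))
                    region, bin_lab = "upstream", -1 - (dist - 1) // 1000
                else:
                    dist = abs(pos - (gene.end if gene.strand == "+" else gene.start))
                    region, bin_lab = "downstream", n_body_bins + (dist - 1) // 1000
            profile_rows.append(
                {"snp": a.snp, "gene": gene_id, "relation": a.relation,
                 "region": region, "bin": bin_lab}
            )
    profile = (
        pd.DataFrame(profile_rows)
        .groupby(["relation", "region", "bin"])
        .size()
        .rename("count")
        .reset_index()
        if profile_rows
        else pd.DataFrame(columns=["relation", "region", "bin", "count"])
    )
    return density, profile
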