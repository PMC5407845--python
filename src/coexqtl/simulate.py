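"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a clonally replicated common-garden cohort: by
default 12 populations, 86 genotypes and replicate counts drawn from {2, 3}
(~215 samples), dense biallelic SNPs with block LD, planted local/distant
eQTLs with controlled variance shares, latent co-expression modules with
hub cores, sample-level hidden confounders, and per-gene coding haplotype
panels under neutral or constrained (purifying-selection-like) sequence
regimes. Every dataset is paired with a machine-readable truth table so
downstream stages are testable by parameter recovery.

Generative model for expression (sample s of genotype g, population q):

    y = mu + Σ_e beta_e·dose_e(g) + Σ_m lambda_m·f_m(g)
        + sqrt(popdiff)·u(q) + resid(g) + Σ_c Lambda_c·c(s) + eps(s)

with the genotype-level terms scaled to unit total variance, so planted
variance fractions are directly interpretable, and eps chosen to hit the
per-gene repeatability target H²: Var(eps) = (1 − H²)/H².
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    ExpressionData,
    Gene,
    GeneAnnotation,
    GenotypeData,
    SubFeature,
)
from .popgen import GENETIC_CODE, degeneracy_masks

__all__ = [
    "SimConfig",
    "SimTruth",
    "EqtlSpec",
    "ModuleSpec",
    "ConfounderSpec",
    "simulate_genotypes",
    "simulate_annotation",
    "simulate_expression",
    "simulate_sequences",
    "simulate_cohort",
]

BASES = np.array(list("ACGT"))


@dataclass
class EqtlSpec:
    gene: str | None = None       # auto-assigned when None
    placement: str = "local"      # local / distant
    ve: float = 0.4               # target fraction of genotype-mean variance


@dataclass
class ModuleSpec:
    size: int
    n_core_hubs: int
    core_loading: float = 0.9
    peripheral_loading: float = 0.3


@dataclass
class ConfounderSpec:
    strength: float = 1.0  # sd of per-gene loadings on the sample factor


@dataclass
class SimConfig:
    n_populations: int = 12
    n_genotypes: int = 86
    replicate_choices: tuple[int, ...] = (2, 3)
    replicates_per_genotype: list[int] | None = None  # overrides the draw
    n_chromosomes: int = 5
    n_snps: int = 2000
    n_genes: int = 200
    allele_freq_beta: tuple[float, float] = (0.8, 0.8)
    ld_copy_prob: float = 0.2
    eqtl_plan: list[EqtlSpec] = field(default_factory=list)
    module_plan: list[ModuleSpec] = field(default_factory=list)
    confounder_plan: list[ConfounderSpec] = field(default_factory=list)
    h2_target: float | dict[str, float] = 0.5
    popdiff_target: float | dict[str, float] = 0.02
    baseline_range: tuple[float, float] = (2.0, 8.0)
    # annotation geometry (bp)
    utr5_len: int = 150
    utr3_len: int = 200
    exon_len: int = 450
    intron_len: int = 120
    n_exons: int = 2
    gene_gap_range: tuple[int, int] = (4000, 16000)
    overlap_same_strand_pairs: int = 0
    overlap_opposite_strand_pairs: int = 0
    # sequence panel parameters
    n_haplotypes: int = 24
    theta_sim: float = 0.005          # per-site, Watterson scale
    outgroup_divergence: float = 0.03  # per-site substitution probability
    zero_fold_suppression: float = 0.1  # mutation-rate factor at 0-fold sites
    constrained_theta_factor: float = 0.7   # overall theta factor, constrained
    constrained_sfs_alpha: float = 1.5      # SFS tilt 1/i^alpha, constrained
    flank_len: int = 1000
    paralog_plan: list[tuple[float, int]] = field(default_factory=list)
    tf_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.allele_freq_beta
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")
        if not 0.0 <= self.ld_copy_prob <= 1.0:
            raise ValueError("ld_copy_prob must be a probability")
        if self.n_genotypes < 2 or self.n_snps < 1:
            raise ValueError("need >= 2 genotypes and >= 1 SNP")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream so each generator stage is individually
        reproducible from the master seed (stable across processes)."""
        key = zlib.crc32(stream.encode()) % 2**31
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,))
        )

    def h2_for(self, gene: str) -> float:
        if isinstance(self.h2_target, dict):
            return self.h2_target[gene]
        return self.h2_target

    def popdiff_for(self, gene: str) -> float:
        if isinstance(self.popdiff_target, dict):
            return self.popdiff_target[gene]
        return self.popdiff_target


@dataclass
class SimTruth:
    planted_eqtls: pd.DataFrame           # gene, snp, beta, class, target_ve
    module_membership: pd.Series          # gene -> module id (0 = none)
    hub_flags: pd.Series
    confounder_loadings: pd.DataFrame     # genes x factors
    true_h2: pd.Series
    true_qst: pd.Series
    selection_regime: pd.Series           # gene -> neutral / constrained
    paralog_pairs: pd.DataFrame           # gene_a, gene_b, planted_correlation
    tf_flags: pd.Series
    conserved_flags: pd.Series

    def to_json_dict(self) -> dict:
        return {
            "planted_eqtls": self.planted_eqtls.to_dict(orient="records"),
            "module_membership": self.module_membership.to_dict(),
            "hub_flags": self.hub_flags.astype(bool).to_dict(),
            "confounder_loadings": self.confounder_loadings.to_dict(),
            "true_h2": self.true_h2.to_dict(),
            "true_qst": self.true_qst.to_dict(),
            "selection_regime": self.selection_regime.to_dict(),
            "paralog_pairs": self.paralog_pairs.to_dict(orient="records"),
            "tf_flags": self.tf_flags.astype(bool).to_dict(),
            "conserved_flags": self.conserved_flags.astype(bool).to_dict(),
        }


def _gene_ids(config: SimConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"gene{str(i + 1).zfill(width)}" for i in range(config.n_genes)]


def simulate_genotypes(config: SimConfig) -> GenotypeData:
    """Biallelic SNP genotypes under Hardy-Weinberg with neighbour-copy LD.

    Allele frequencies are Beta draws; each SNP is, with probability
    ``ld_copy_prob``, an exact copy of its left neighbour's genotype column
    (a deliberately crude LD model, sufficient to exercise LD pruning and
    redundant-eSNP collapsing). Positions are strictly increasing within
    chromosomes.
    """
    rng = config.rng("genotypes")
    a, b = config.allele_freq_beta
    n_gt, n_snp = config.n_genotypes, config.n_snps
    per_chrom = np.array_split(np.arange(n_snp), config.n_chromosomes)
    chroms, positions = [], []
    for c, idx in enumerate(per_chrom, start=1):
        gaps = rng.integers(200, 3000, size=len(idx))
        pos = np.cumsum(gaps) + 1
        chroms.extend([f"chr{c}"] * len(idx))
        positions.extend(pos.tolist())
    matrix = np.empty((n_gt, n_snp), dtype=np.int8)
    freqs = rng.beta(a, b, size=n_snp)
    prev_chrom = None
    for j in range(n_snp):
        copy = (
            chroms[j] == prev_chrom
            and rng.random() < config.ld_copy_prob
        )
        if copy:
            matrix[:, j] = matrix[:, j - 1]
        else:
            p = freqs[j]
            matrix[:, j] = rng.choice(
                [0, 1, 2],
                size=n_gt,
                p=[(1 - p) ** 2, 2 * p * (1 - p), p ** 2],
            )
        prev_chrom = chroms[j]
    ref = rng.choice(BASES, size=n_snp)
    alt = np.array(
        [rng.choice([x for x in "ACGT" if x != r]) for r in ref]
    )
    variants = pd.DataFrame(
        {
            "id": [f"snp{i + 1}" for i in range(n_snp)],
            "chrom": chroms,
            "pos": positions,
            "ref": ref,
            "alt": alt,
        }
    )
    genotype_ids = [f"G{str(i + 1).zfill(3)}" for i in range(n_gt)]
    pops = [f"P{str(i % config.n_populations + 1).zfill(2)}" for i in range(n_gt)]
    if config.replicates_per_genotype is not None:
        reps = list(config.replicates_per_genotype)
    else:
        reps = rng.choice(config.replicate_choices, size=n_gt).tolist()
    rows = []
    s = 0
    for g, pop, r in zip(genotype_ids, pops, reps):
        for _ in range(int(r)):
            s += 1
            rows.append({"sample": f"S{str(s).zfill(4)}", "genotype": g,
                         "population": pop})
    samples = pd.DataFrame(rows)
    return GenotypeData(
        variants=variants, matrix=matrix, genotype_ids=genotype_ids,
        samples=samples,
    )


def _gene_model(gene_id: str, chrom: str, strand: str, start: int,
                config: SimConfig) -> Gene:
    """One gene model laid out 5'->3' in genomic coordinates for '+' strand
    (mirrored feature roles for '-')."""
    blocks: list[tuple[str, int]] = [("five_prime_UTR", config.utr5_len)]
    for e in range(config.n_exons):
        blocks.append(("exon", config.exon_len))
        if e < config.n_exons - 1:
            blocks.append(("intron", config.intron_len))
    blocks.append(("three_prime_UTR", config.utr3_len))
    if strand == "-":
        blocks = blocks[::-1]
    subs, cursor = [], start
    for ftype, length in blocks:
        subs.append(SubFeature(ftype, cursor, cursor + length - 1))
        cursor += length
    return Gene(id=gene_id, chrom=chrom, strand=strand, start=start,
                end=cursor - 1, subfeatures=subs)


def simulate_annotation(config: SimConfig) -> GeneAnnotation:
    """Non-overlapping gene models with UTR/exon/intron sub-features, plus
    optional planted same-strand and opposite-strand overlaps to exercise the
    context discard and double-count rules."""
    rng = config.rng("annotation")
    ids = _gene_ids(config)
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chromosomes)
    genes: dict[str, Gene] = {}
    lo, hi = config.gene_gap_range
    gene_span = (
        config.utr5_len + config.utr3_len
        + config.n_exons * config.exon_len
        + (config.n_exons - 1) * config.intron_len
    )
    min_gap = 2 * 2000 + 1  # keep default 2-kbp flanks of neighbours disjoint
    if lo < min_gap:
        lo, hi = min_gap, max(hi, min_gap + 1)
    for c, idx in enumerate(per_chrom, start=1):
        cursor = 3000
        for i in idx:
            cursor += int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            g = _gene_model(ids[i], f"chr{c}", strand, cursor, config)
            genes[g.id] = g
            cursor = g.end + 1

    counter = 0
    plain = [g for g in genes.values() if g.strand == "+"]
    for _ in range(config.overlap_opposite_strand_pairs):
        host = plain[counter % len(plain)]
        counter += 1
        gid = f"ovl_opp{counter}"
        g = _gene_model(gid, host.chrom, "-", host.start + 50, config)
        genes[gid] = g
    for _ in range(config.overlap_same_strand_pairs):
        host = plain[counter % len(plain)]
        counter += 1
        introns = host.features_of("intron")
        if not introns:
            continue
        gid = f"ovl_same{counter}"
        # a single-exon gene model sitting inside the host's intron: its exon
        # overlaps the host's intron, triggering the same-strand discard rule
        intron = introns[0]
        g = Gene(
            id=gid, chrom=host.chrom, strand=host.strand,
            start=intron.start, end=intron.end,
            subfeatures=[SubFeature("exon", intron.start, intron.end)],
        )
        genes[gid] = g
    return GeneAnnotation(genes=genes)


def _assign_genes(config: SimConfig, ids: list[str]):
    """Deterministic gene bookkeeping: modules take genes from the front,
    auto-assigned eQTL genes follow, paralog pairs take the tail."""
    membership = pd.Series(0, index=ids, dtype=int)
    hubs = pd.Series(False, index=ids)
    cursor = 0
    for m, spec in enumerate(config.module_plan, start=1):
        block = ids[cursor : cursor + spec.size]
        if len(block) < spec.size:
            raise ValueError("module_plan exceeds the number of genes")
        membership[block] = m
        hubs[block[: spec.n_core_hubs]] = True
        cursor += spec.size
    auto_eqtl = []
    for spec in config.eqtl_plan:
        if spec.gene is None:
            if cursor >= len(ids):
                raise ValueError("eqtl_plan exceeds the number of genes")
            auto_eqtl.append(ids[cursor])
            cursor += 1
        else:
            auto_eqtl.append(spec.gene)
    pairs = []
    tail = len(ids)
    for rho, count in config.paralog_plan:
        for _ in range(count):
            if tail - 2 < cursor:
                raise ValueError("paralog_plan exceeds the number of genes")
            pairs.append((ids[tail - 2], ids[tail - 1], rho))
            tail -= 2
    return membership, hubs, auto_eqtl, pairs


def _pick_eqtl_snp(
    spec: EqtlSpec,
    gene: Gene,
    genotypes: GenotypeData,
    used: set[int],
    rng: np.random.Generator,
    local_window: int = 100_000,
    maf_min: float = 0.1,
    mgf_max: float = 0.9,
) -> int:
    """Index of an unused SNP satisfying the placement rule and passing the
    default MAF/MGF filters at its realised genotype frequencies."""
    v = genotypes.variants
    m = genotypes.matrix
    p = m.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    mgf = np.max(
        np.stack([(m == c).mean(axis=0) for c in (0, 1, 2)]), axis=0
    )
    discoverable = (maf >= maf_min + 0.02) & (mgf <= mgf_max - 0.02)
    same = (v["chrom"] == gene.chrom).to_numpy()
    dist = np.minimum(
        np.abs(v["pos"].to_numpy() - gene.start),
        np.abs(v["pos"].to_numpy() - gene.end),
    )
    inside = (v["pos"].to_numpy() >= gene.start) & (v["pos"].to_numpy() <= gene.end)
    dist = np.where(inside, 0, dist)
    if spec.placement == "local":
        eligible = discoverable & same & (dist <= local_window)
    elif spec.placement == "distant":
        eligible = discoverable & (~same | (dist > local_window))
    else:
        raise ValueError(f"unknown placement {spec.placement!r}")
    candidates = [j for j in np.flatnonzero(eligible) if j not in used]
    if not candidates:
        raise ValueError(
            f"no eligible {spec.placement} SNP for gene {gene.id}"
        )
    return int(rng.choice(candidates))


def simulate_expression(
    genotypes: GenotypeData,
    annotation: GeneAnnotation,
    config: SimConfig,
) -> tuple[ExpressionData, SimTruth]:
    """Sample-level expression realising the planted eQTL, module, population
    and confounder structure; see the module docstring for the model."""
    rng = config.rng("expression")
    ids = _gene_ids(config)
    membership, hubs, eqtl_genes, paralog_triples = _assign_genes(config, ids)
    n_gt = genotypes.n_genotypes
    samples = genotypes.samples
    n_samples = len(samples)
    gt_index = {g: i for i, g in enumerate(genotypes.genotype_ids)}
    sample_gt = samples["genotype"].map(gt_index).to_numpy()
    pop_codes, pop_uniq = pd.factorize(
        samples.drop_duplicates("genotype").set_index("genotype")
        .loc[genotypes.genotype_ids, "population"]
    )

    module_factors = rng.standard_normal((len(config.module_plan), n_gt))
    pop_effects = rng.standard_normal((config.n_genes, len(pop_uniq)))
    paralog_factors = {
        pair[:2]: rng.standard_normal(n_gt) for pair in paralog_triples
    }

    # plant eQTL SNPs
    used: set[int] = set()
    eqtl_rows = []
    gene_eqtls: dict[str, list[tuple[int, float]]] = {g: [] for g in ids}
    for spec, gene_id in zip(config.eqtl_plan, eqtl_genes):
        j = _pick_eqtl_snp(spec, annotation[gene_id], genotypes, used, rng)
        used.add(j)
        dose = genotypes.matrix[:, j].astype(float)
        sd = dose.std(ddof=0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        beta = sign * np.sqrt(spec.ve) / sd
        gene_eqtls[gene_id].append((j, beta))
        eqtl_rows.append(
            {"gene": gene_id, "snp": genotypes.variants["id"].iloc[j],
             "beta": beta, "class": spec.placement, "target_ve": spec.ve}
        )

    loadings = np.zeros((config.n_genes, len(config.confounder_plan)))
    for c, cspec in enumerate(config.confounder_plan):
        loadings[:, c] = rng.normal(0.0, cspec.strength, size=config.n_genes)
    factors = rng.standard_normal((len(config.confounder_plan), n_samples))

    baselines = rng.uniform(*config.baseline_range, size=config.n_genes)
    paralog_load = {}
    for g1, g2, rho in paralog_triples:
        lam = np.sqrt(rho)
        paralog_load[g1] = (paralog_factors[(g1, g2)], lam)
        paralog_load[g2] = (paralog_factors[(g1, g2)], lam)

    # replicate-noise dilution on genotype means: Var(mean eps) = V_E * m_harm
    rep_counts = samples.groupby("genotype").size().loc[genotypes.genotype_ids]
    m_harm = float((1.0 / rep_counts).mean())

    expr = np.empty((config.n_genes, n_samples))
    true_h2 = pd.Series(index=ids, dtype=float)
    true_qst = pd.Series(index=ids, dtype=float)
    for i, gene_id in enumerate(ids):
        # all planted shares are fractions of the *genotype-mean* variance,
        # normalised to 1; the genetic part of that variance is
        # s = 1/(1 + m_harm (1-H2)/H2), the rest is averaged replicate noise
        h2 = config.h2_for(gene_id)
        if not 0.0 < h2 <= 1.0:
            raise ValueError(f"{gene_id}: H2 target must be in (0, 1]")
        eps_rel = (1.0 - h2) / h2          # V_E relative to V_G
        s = 1.0 / (1.0 + eps_rel * m_harm)  # genetic share of mean variance
        budget = 0.0
        z = np.zeros(n_gt)
        for j, beta in gene_eqtls[gene_id]:
            dose = genotypes.matrix[:, j].astype(float)
            z += beta * (dose - dose.mean())
            budget += beta ** 2 * dose.var(ddof=0)
        mod = membership[gene_id]
        if mod > 0:
            spec = config.module_plan[mod - 1]
            lam = (
                spec.core_loading
                if hubs[gene_id]
                else spec.peripheral_loading * (1 if rng.random() < 0.5 else -1)
            )
            z += lam * module_factors[mod - 1]
            budget += lam ** 2
        if gene_id in paralog_load:
            f, lam = paralog_load[gene_id]
            z += lam * f
            budget += lam ** 2
        q = config.popdiff_for(gene_id)
        z += np.sqrt(q) * pop_effects[i, pop_codes]
        budget += q
        if budget > s + 1e-9:
            raise ValueError(
                f"{gene_id}: planted variance shares ({budget:.3f}) exceed the "
                f"genetic share {s:.3f} of the genotype-mean variance at "
                f"H2={h2}; raise the H2 target or lower the shares"
            )
        resid_sd = np.sqrt(max(s - budget, 0.0))
        z += resid_sd * rng.standard_normal(n_gt)

        eps_sd = np.sqrt(s * eps_rel)
        y = baselines[i] + z[sample_gt] + eps_sd * rng.standard_normal(n_samples)
        if loadings.size:
            y = y + loadings[i] @ factors
        expr[i] = y
        true_h2[gene_id] = h2
        true_qst[gene_id] = q / (q + 2.0 * (1.0 - q)) if q > 0 else 0.0

    regime = pd.Series(
        np.where(hubs.to_numpy(), "constrained", "neutral"), index=ids
    )
    tf = pd.Series(False, index=ids)
    n_tf = int(round(config.tf_fraction * config.n_genes))
    if n_tf:
        # transcription factors sit preferentially among hubs, as in real
        # regulatory networks
        hub_ids = list(hubs[hubs].index)
        rest = [g for g in ids if g not in set(hub_ids)]
        chosen = (hub_ids + rest)[:n_tf]
        tf[chosen] = True
    conserved = hubs.copy()

    truth = SimTruth(
        planted_eqtls=pd.DataFrame(
            eqtl_rows,
            columns=["gene", "snp", "beta", "class", "target_ve"],
        ),
        module_membership=membership,
        hub_flags=hubs,
        confounder_loadings=pd.DataFrame(
            loadings, index=ids,
            columns=[f"factor{c + 1}" for c in range(loadings.shape[1])],
        ),
        true_h2=true_h2,
        true_qst=true_qst,
        selection_regime=regime,
        paralog_pairs=pd.DataFrame(
            [{"gene_a": a, "gene_b": b, "planted_correlation": r}
             for a, b, r in paralog_triples],
            columns=["gene_a", "gene_b", "planted_correlation"],
        ),
        tf_flags=tf,
        conserved_flags=conserved,
    )
    data = ExpressionData(
        matrix=expr, gene_ids=ids, sample_ids=list(samples["sample"])
    )
    return data, truth


# ---------------------------------------------------------------------------
# sequence panels

STOP_CODONS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    codons = []
    sense = sorted(set(GENETIC_CODE) - STOP_CODONS)
    idx = rng.integers(0, len(sense), size=n_codons)
    for i in idx:
        codons.append(sense[i])
    return "".join(codons)


def _gene_layout(config: SimConfig) -> dict[str, np.ndarray]:
    """Category masks over the concatenated per-gene sequence:
    upstream | utr5 | exon1 | intron | ... | utr3 | downstream."""
    sizes = [("upstream_1kb", config.flank_len), ("utr5", config.utr5_len)]
    for e in range(config.n_exons):
        sizes.append(("cds", config.exon_len))
        if e < config.n_exons - 1:
            sizes.append(("intron", config.intron_len))
    sizes.append(("utr3", config.utr3_len))
    sizes.append(("downstream_1kb", config.flank_len))
    total = sum(s for _, s in sizes)
    masks = {k: np.zeros(total, dtype=bool)
             for k in ("upstream_1kb", "downstream_1kb", "utr5", "utr3",
                       "intron", "cds")}
    cursor = 0
    for name, size in sizes:
        masks[name][cursor : cursor + size] = True
        cursor += size
    return masks


def _sfs_probabilities(n: int, alpha: float) -> np.ndarray:
    i = np.arange(1, n)
    w = 1.0 / i ** alpha
    return w / w.sum()


def simulate_sequences(
    config: SimConfig,
    regimes: pd.Series | None = None,
) -> dict[str, dict]:
    """Per-gene haplotype panels with outgroup, under neutral or constrained
    regimes.

    Neutral genes: segregating sites placed at per-site probability
    theta_sim·a1(n) with derived-allele counts from the standard neutral SFS
    (∝ 1/i), giving E[θW] = E[θπ] = theta_sim and Tajima's D ≈ 0.
    Constrained genes: overall mutation rate scaled by
    ``constrained_theta_factor``; nonsynonymous changes (classified against
    the reference codon) are accepted with probability
    ``zero_fold_suppression`` — at a 0-fold site this scales the whole site
    rate, at 2-/3-fold sites only the nonsynonymous fraction — applied to
    both polymorphism and outgroup divergence; and the SFS is tilted toward
    rare variants (∝ 1/i^alpha). Together these emulate the diversity loss,
    dN/dS reduction and negative Tajima's D skew of purifying selection.

    Returns {gene: {"haplotypes", "outgroup", "masks", "cds_mask"}} in the
    form ``popgen.gene_category_stats`` consumes.
    """
    rng = config.rng("sequences")
    ids = _gene_ids(config)
    if regimes is None:
        regimes = pd.Series("neutral", index=ids)
    layout = _gene_layout(config)
    cds_mask = layout["cds"]
    masks = {k: v for k, v in layout.items() if k != "cds"}
    n = config.n_haplotypes
    if n < 2:
        raise ValueError("need at least two haplotypes")
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    total_len = cds_mask.size
    panels: dict[str, dict] = {}
    for gene_id in ids:
        constrained = regimes.get(gene_id, "neutral") == "constrained"
        for _ in range(20):
            cds = _random_cds(
                (config.n_exons * config.exon_len) // 3, rng
            )
            if not any(
                cds[i : i + 3] in STOP_CODONS for i in range(0, len(cds) - 3, 3)
            ):
                break
        else:
            raise RuntimeError(f"{gene_id}: could not build a stop-free CDS")
        ref = rng.choice(BASES, size=total_len)
        ref[cds_mask] = list(cds)

        cds_positions = np.flatnonzero(cds_mask)
        cds_index = np.full(total_len, -1)
        cds_index[cds_positions] = np.arange(cds_positions.size)
        suppression = config.zero_fold_suppression if constrained else 1.0

        def change_weights(site: int) -> tuple[list[str], np.ndarray]:
            """Stop-free substitutions at a site with selection weights:
            synonymous changes weight 1, nonsynonymous changes the regime's
            acceptance probability (all weight 1 outside the CDS)."""
            ci = cds_index[site]
            others = [b for b in "ACGT" if b != ref[site]]
            if ci < 0:
                return others, np.ones(3)
            codon_sites = cds_positions[ci - ci % 3 : ci - ci % 3 + 3]
            codon = [str(ref[s]) for s in codon_sites]
            aa = GENETIC_CODE["".join(codon)]
            bases, weights = [], []
            for b in others:
                codon[ci % 3] = b
                alt_aa = GENETIC_CODE["".join(codon)]
                codon[ci % 3] = str(ref[site])
                if alt_aa == "*":
                    continue
                bases.append(b)
                weights.append(1.0 if alt_aa == aa else suppression)
            return bases, np.asarray(weights)

        theta = config.theta_sim * (
            config.constrained_theta_factor if constrained else 1.0
        )
        base_rate = min(theta * a1, 1.0)
        div_rate = config.outgroup_divergence
        alpha = config.constrained_sfs_alpha if constrained else 1.0
        probs = _sfs_probabilities(n, alpha)

        # per-site effective rate factor: mean selection weight over the
        # three possible changes (stop-creating changes count as weight 0)
        factors = np.ones(total_len)
        weight_cache: dict[int, tuple[list[str], np.ndarray]] = {}
        if suppression != 1.0 or cds_positions.size:
            for site in cds_positions:
                bases, weights = change_weights(site)
                weight_cache[site] = (bases, weights)
                factors[site] = weights.sum() / 3.0 if len(bases) else 0.0

        def draw_base(site: int) -> str | None:
            if cds_index[site] < 0:
                return rng.choice([b for b in "ACGT" if b != ref[site]])
            bases, weights = weight_cache[site]
            if not bases or weights.sum() == 0:
                return None
            return rng.choice(bases, p=weights / weights.sum())

        # haplotype 0 stays identical to the reference so that degeneracy
        # classified from the first haplotype matches the generating masks;
        # SFS statistics depend only on derived-allele counts, not placement
        seg = rng.random(total_len) < base_rate * factors
        hap = np.tile(ref, (n, 1))
        for site in np.flatnonzero(seg):
            derived = draw_base(site)
            if derived is None:
                continue
            count = int(rng.choice(np.arange(1, n), p=probs))
            carriers = 1 + rng.choice(n - 1, size=min(count, n - 1), replace=False)
            hap[carriers, site] = derived

        mut = rng.random(total_len) < div_rate * factors
        outgroup = ref.copy()
        for site in np.flatnonzero(mut):
            sub = draw_base(site)
            if sub is not None:
                outgroup[site] = sub

        panels[gene_id] = {
            "haplotypes": hap,
            "outgroup": "".join(outgroup),
            "masks": {k: v.copy() for k, v in masks.items()},
            "cds_mask": cds_mask.copy(),
        }
    return panels


def simulate_cohort(config: SimConfig):
    """Convenience wrapper: genotypes, annotation, expression + truth, and
    sequence panels keyed off the same master seed."""
    genotypes = simulate_genotypes(config)
    annotation = simulate_annotation(config)
    expression, truth = simulate_expression(genotypes, annotation, config)
    panels = simulate_sequences(config, truth.selection_regime)
    return genotypes, annotation, expression, truth, panels
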