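"""eQTL mapping: variant filtering, population-structure covariate, per-pair
additive linear models, gene-wise max-|t| permutation null with empirical
FDR, local/distant classification, redundant-eSNP collapsing, hotspot scan
and MAF-fixing subsampling.

The association model for each gene x SNP pair is

    expression ~ intercept + dosage + covariate

fitted by OLS on genotype means, with the t statistic of the dosage term
tested against a null built by permuting genotype labels and recording, per
gene, the maximum |t| across all SNPs (one global permutation per iteration,
preserving gene-gene correlation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import MISSING, GeneAnnotation, GenotypeData
from .quantgen import empirical_pvalue

__all__ = [
    "filter_variants",
    "structure_covariate",
    "map_associations",
    "empirical_fdr",
    "classify_local_distant",
    "collapse_unique_esnps",
    "hotspot_scan",
    "subsample_fix_maf",
    "benjamini_hochberg",
    "storey_qvalues",
    "AssociationScan",
    "UniqueEsnpModel",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# variant statistics and filtering

def _fold(p: np.ndarray | float) -> np.ndarray | float:
    return np.minimum(p, 1.0 - p)


def variant_stats(genotypes: GenotypeData) -> pd.DataFrame:
    """Per-SNP MAF, MGF and missing fraction from genotype codes."""
    m = genotypes.matrix
    obs = m != MISSING
    n_obs = obs.sum(axis=0).astype(float)
    alt = np.where(obs, m, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = alt / (2.0 * n_obs)
        maf = _fold(alt_freq)
        class_counts = np.stack(
            [np.where(obs, m == c, False).sum(axis=0) for c in (0, 1, 2)]
        )
        mgf = class_counts.max(axis=0) / n_obs
    missing_frac = 1.0 - n_obs / m.shape[0]
    return pd.DataFrame(
        {
            "id": genotypes.variants["id"].to_numpy(),
            "maf": maf,
            "mgf": mgf,
            "missing_frac": missing_frac,
        }
    )


def filter_variants(
    genotypes: GenotypeData,
    maf_min: float = 0.1,
    mgf_max: float = 0.9,
    max_missing: float = 0.1,
) -> tuple[pd.DataFrame, GenotypeData]:
    """Drop SNPs with MAF below ``maf_min`` or MGF above ``mgf_max``.

    The MGF filter removes SNPs where an association would rest on a single
    deviating genotype class (e.g. one homozygote among heterozygotes, which
    passes a MAF filter with MAF near 0.5). SNPs with every call missing, or
    with more than ``max_missing`` missing calls, are dropped and logged.
    """
    vstats = variant_stats(genotypes)
    all_missing = vstats["missing_frac"] >= 1.0
    if all_missing.any():
        log.info("dropping %d SNPs with all genotypes missing", all_missing.sum())
    keep = (
        ~all_missing
        & (vstats["missing_frac"] <= max_missing)
        & (vstats["maf"] >= maf_min)
        & (vstats["mgf"] <= mgf_max)
    )
    vstats["pass"] = keep
    idx = np.flatnonzero(keep.to_numpy())
    filtered = GenotypeData(
        variants=genotypes.variants.iloc[idx].reset_index(drop=True),
        matrix=genotypes.matrix[:, idx],
        genotype_ids=genotypes.genotype_ids,
        samples=genotypes.samples,
    )
    return vstats, filtered


# ---------------------------------------------------------------------------
# population-structure covariate

def _prune_block(block: np.ndarray, r2_max: float) -> list[int]:
    """Greedy LD pruning inside one block; keeps the earlier-position SNP of
    any pair with dosage r^2 above the threshold."""
    kept: list[int] = []
    centred = block - block.mean(axis=0)
    norms = np.sqrt((centred ** 2).sum(axis=0))
    for j in range(block.shape[1]):
        if norms[j] == 0:
            continue
        ok = True
        for i in kept:
            r = centred[:, i] @ centred[:, j] / (norms[i] * norms[j])
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return kept


def structure_covariate(
    genotypes: GenotypeData, r2_max: float = 0.2, block_size: int = 50
) -> np.ndarray:
    """First principal component of the LD-pruned dosage matrix.

    Pruning runs in non-overlapping blocks of ``block_size`` SNPs in genome
    order, dropping the later SNP of any pair with r^2 above ``r2_max``. The
    returned vector has one score per genotype, sign-fixed so the largest
    absolute score is positive.
    """
    m = genotypes.matrix.astype(float)
    m[genotypes.matrix == MISSING] = np.nan
    col_mean = np.nanmean(m, axis=0)
    inds = np.where(np.isnan(m))
    m[inds] = np.take(col_mean, inds[1])
    if m.shape[1] < 2:
        raise ValueError("need at least two SNPs for the structure covariate")
    kept_cols: list[int] = []
    for start in range(0, m.shape[1], block_size):
        block = m[:, start : start + block_size]
        kept_cols.extend(start + j for j in _prune_block(block, r2_max))
    if not kept_cols:
        raise ValueError("LD pruning removed all SNPs")
    pruned = m[:, kept_cols]
    centred = pruned - pruned.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    return pc1


# ---------------------------------------------------------------------------
# per-pair association scan

@dataclass
class AssociationScan:
    """Dense results of the gene x SNP linear-model scan.

    Matrices are genes x SNPs; pairs skipped for zero dosage variance hold
    NaN. ``df`` is the residual degrees of freedom (n - 3).
    """

    gene_ids: list[str]
    snp_ids: list[str]
    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    r2: np.ndarray
    df: int

    def to_records(self, p_max: float | None = None) -> pd.DataFrame:
        gi, si = np.nonzero(~np.isnan(self.t))
        if p_max is not None:
            sel = self.p[gi, si] <= p_max
            gi, si = gi[sel], si[sel]
        return pd.DataFrame(
            {
                "gene": np.asarray(self.gene_ids)[gi],
                "snp": np.asarray(self.snp_ids)[si],
                "beta": self.beta[gi, si],
                "t": self.t[gi, si],
                "p": self.p[gi, si],
                "r2": self.r2[gi, si],
                "_gi": gi,
                "_si": si,
            }
        )


def _residualise(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of the rows of ``y`` on the columns of ``design`` (with
    intercept included by the caller)."""
    q, _ = np.linalg.qr(design)
    return y - (y @ q) @ q.T


def _scan_matrices(
    expr: np.ndarray, dosage: np.ndarray, covariate: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised partial-correlation scan.

    expr: genes x n; dosage: n x snps; covariate: n. Returns (beta, r) of the
    dosage term given the covariate, plus dosage residual variance flag via r
    = NaN for zero-variance columns.
    """
    n = dosage.shape[0]
    design = np.column_stack([np.ones(n), covariate])
    e = _residualise(expr, design)
    g = _residualise(dosage.T, design).T
    gss = (g ** 2).sum(axis=0)
    # zero residual dosage variance up to numerical noise -> pair skipped
    scale = (dosage ** 2).sum(axis=0)
    gss[gss <= 1e-12 * np.maximum(scale, 1.0)] = 0.0
    ess = (e ** 2).sum(axis=1)
    cross = e @ g
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = cross / gss
        denom = np.sqrt(np.outer(ess, gss))
        r = np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), np.nan)
    beta[:, gss == 0] = np.nan
    r[:, gss == 0] = np.nan
    return beta, r, gss


def _t_from_r(r: np.ndarray, df: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return r * np.sqrt(df / np.maximum(1.0 - r ** 2, 1e-300))


def map_associations(
    means: pd.DataFrame,
    genotypes: GenotypeData,
    covariate: np.ndarray,
) -> AssociationScan:
    """OLS scan of every gene x SNP pair with the structure covariate.

    ``means`` is genes x genotypes (residualised genotype means), aligned on
    ``genotypes.genotype_ids``. Missing genotype calls are excluded pairwise
    (the affected SNPs are refitted on their non-missing genotypes). Nominal
    p-values are two-sided on t with n - 3 degrees of freedom.
    """
    if list(means.columns) != list(genotypes.genotype_ids):
        means = means.loc[:, genotypes.genotype_ids]
    expr = means.to_numpy()
    dosage = genotypes.matrix.astype(float)  # genotypes x snps
    n = dosage.shape[0]
    df = n - 3
    missing = genotypes.matrix == MISSING
    incomplete = np.flatnonzero(missing.any(axis=0))
    # fast path on the complete columns
    complete_cols = np.setdiff1d(np.arange(dosage.shape[1]), incomplete)
    beta = np.full((expr.shape[0], dosage.shape[1]), np.nan)
    r = np.full_like(beta, np.nan)
    if complete_cols.size:
        b, rr, _ = _scan_matrices(expr, dosage[:, complete_cols], covariate)
        beta[:, complete_cols] = b
        r[:, complete_cols] = rr
    # pairwise-exclusion path for columns with missing calls
    for j in incomplete:
        ok = ~missing[:, j]
        if ok.sum() < 4:
            continue
        b, rr, _ = _scan_matrices(expr[:, ok], dosage[ok, j : j + 1], covariate[ok])
        beta[:, j] = b[:, 0]
        r[:, j] = rr[:, 0]
    t = _t_from_r(r, df)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return AssociationScan(
        gene_ids=list(means.index),
        snp_ids=list(genotypes.variants["id"]),
        beta=beta,
        t=t,
        p=p,
        r2=r ** 2,
        df=df,
    )


# ---------------------------------------------------------------------------
# multiple testing

def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH adjusted p-values (step-up)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's pi0 from the smoothed lambda profile, capped at 1."""
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    pi0_lambda = np.array(
        [(p > lam).mean() / (1.0 - lam) for lam in lambdas]
    )
    if np.allclose(pi0_lambda, pi0_lambda[0]):
        pi0 = pi0_lambda[-1]
    else:
        coeffs = np.polyfit(lambdas, pi0_lambda, 3)
        pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return float(min(max(pi0, 1.0 / p.size), 1.0))


def storey_qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; ``pi0=1`` reproduces BH adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if pi0 is None:
        pi0 = storey_pi0(p)
    return np.minimum(benjamini_hochberg(p) * pi0, 1.0)


# ---------------------------------------------------------------------------
# permutation empirical FDR

def empirical_fdr(
    scan: AssociationScan,
    means: pd.DataFrame,
    genotypes: GenotypeData,
    covariate: np.ndarray,
    n_perm: int = 1000,
    fdr: float = 0.05,
    rng: np.random.Generator | None = None,
    pi0: float | None = None,
    nominal_p_max: float = 1e-6,
) -> pd.DataFrame:
    """Gene-wise max-|t| permutation null and association-level q-values.

    For each permutation the genotype labels of the dosage matrix (and the
    genotype-derived covariate, which travels with them) are shuffled once
    globally, the full scan recomputed, and per gene the maximum |t| over all
    SNPs recorded, yielding an n_perm-sized null per gene. Candidate
    associations are the pairs below the nominal output threshold
    ``nominal_p_max`` (the scan's reporting cut; the same threshold the
    hotspot scan uses); for those, empirical p-values use add-one smoothing
    and q-values are Storey's, computed across the candidate set. Records
    with q <= ``fdr`` are the reported eQTLs.

    Returns the candidate association table with ``emp_p``, ``q`` and
    ``significant`` columns.
    """
    if n_perm < 10:
        raise ValueError("fewer than 10 permutations is not interpretable")
    if n_perm < 100:
        log.warning("n_perm=%d is low; empirical p-values will be coarse", n_perm)
    rng = np.random.default_rng() if rng is None else rng
    if list(means.columns) != list(genotypes.genotype_ids):
        means = means.loc[:, genotypes.genotype_ids]
    expr = means.to_numpy()
    dosage = genotypes.matrix.astype(float)
    has_missing = (genotypes.matrix == MISSING).any()
    if has_missing:
        # permutation scan imputes column means for missing calls
        d = dosage.copy()
        d[genotypes.matrix == MISSING] = np.nan
        mu = np.nanmean(d, axis=0)
        inds = np.where(np.isnan(d))
        d[inds] = np.take(mu, inds[1])
        dosage = d
    n = dosage.shape[0]
    n_genes = expr.shape[0]
    null_max = np.empty((n_genes, n_perm))
    identity = np.arange(n)
    for b in range(n_perm):
        perm = rng.permutation(n)
        while np.array_equal(perm, identity):
            perm = rng.permutation(n)
        _, r, _ = _scan_matrices(expr, dosage[perm], covariate[perm])
        t = np.abs(_t_from_r(r, scan.df))
        null_max[:, b] = np.nanmax(t, axis=1)
    null_sorted = np.sort(null_max, axis=1)

    records = scan.to_records(p_max=nominal_p_max)
    if records.empty:
        return records.assign(
            emp_p=np.array([], dtype=float),
            q=np.array([], dtype=float),
            significant=np.array([], dtype=bool),
        )
    records = records.reset_index(drop=True)
    gi = records["_gi"].to_numpy()
    abs_t = np.abs(records["t"].to_numpy())
    # emp_p = (1 + #{null >= |t|}) / (1 + n_perm), via searchsorted per gene
    ge_counts = np.empty(len(records), dtype=float)
    for g in np.unique(gi):
        sel = gi == g
        ge_counts[sel] = n_perm - np.searchsorted(
            null_sorted[g], abs_t[sel], side="left"
        )
    records["emp_p"] = (1.0 + ge_counts) / (1.0 + n_perm)
    records["q"] = storey_qvalues(records["emp_p"].to_numpy(), pi0=pi0)
    records["significant"] = records["q"] <= fdr
    return records


# ---------------------------------------------------------------------------
# classification and downstream summaries

def classify_local_distant(
    records: pd.DataFrame,
    annotation: GeneAnnotation,
    variants: pd.DataFrame,
    window: int = 100_000,
) -> pd.DataFrame:
    """Label each association local (same chromosome, within ``window`` bp of
    the gene span) or distant; distance is 0 for SNPs inside the gene."""
    snp_pos = variants.set_index("id")[["chrom", "pos"]]
    out = records.copy()
    chroms = snp_pos.loc[out["snp"], "chrom"].to_numpy()
    pos = snp_pos.loc[out["snp"], "pos"].to_numpy()
    dist = np.empty(len(out))
    local = np.empty(len(out), dtype=bool)
    for i, (gene_id, c, x) in enumerate(zip(out["gene"], chroms, pos)):
        if gene_id not in annotation:
            raise KeyError(f"eGene {gene_id} absent from annotation")
        g = annotation[gene_id]
        if g.start <= x <= g.end:
            d = 0
        else:
            d = min(abs(x - g.start), abs(x - g.end))
        dist[i] = d
        local[i] = (c == g.chrom) and d <= window
    out["distance"] = dist
    out["class"] = np.where(local, "local", "distant")
    return out


@dataclass
class UniqueEsnpModel:
    gene: str
    input_esnps: list[str]
    unique_esnps: list[str] = field(default_factory=list)
    adjusted_ve: float = np.nan  # adjusted R^2 x 100 of the joint model


def collapse_unique_esnps(
    gene: str,
    esnp_ids: list[str],
    dosages: np.ndarray,
    expression: np.ndarray,
    tol: float = 1e-8,
) -> UniqueEsnpModel:
    """Joint linear model over a gene's significant eSNPs, masking redundant
    (linearly dependent) dosage columns.

    eSNPs enter in the order given (ascending genomic position upstream);
    a column aliased by earlier entries, at pivot tolerance ``tol``, is
    masked. The retained columns are the gene's "unique eSNPs" and the
    adjusted R^2 of the joint fit (x100) is the joint percentage of variance
    explained. Which of a collinear pair survives depends on entry order; the
    fitted %VE does not.
    """
    n = len(expression)
    basis = [np.ones(n) / np.sqrt(n)]
    kept: list[int] = []
    for j in range(dosages.shape[1]):
        v = dosages[:, j].astype(float)
        scale = float(v @ v)
        for q in basis:
            v = v - (q @ v) * q
        if scale == 0 or (v @ v) / scale < tol:
            continue
        basis.append(v / np.sqrt(v @ v))
        kept.append(j)
    if not kept:
        return UniqueEsnpModel(gene, list(esnp_ids), [], np.nan)
    x = np.column_stack([np.ones(n), dosages[:, kept]])
    coef, _, _, _ = np.linalg.lstsq(x, expression, rcond=None)
    fitted = x @ coef
    ss_res = float(((expression - fitted) ** 2).sum())
    ss_tot = float(((expression - expression.mean()) ** 2).sum())
    k = len(kept)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n - k - 1 > 0 else np.nan
    return UniqueEsnpModel(
        gene, list(esnp_ids), [esnp_ids[j] for j in kept], 100.0 * adj
    )


def hotspot_scan(
    records: pd.DataFrame,
    variants: pd.DataFrame,
    window: int = 100_000,
    nominal_p_max: float = 1e-6,
) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping windows and count, among
    associations with nominal p below threshold, the distinct eSNPs and the
    distinct associated genes per window."""
    snp_pos = variants.set_index("id")[["chrom", "pos"]]
    hits = records.loc[records["p"] < nominal_p_max, ["gene", "snp"]].copy()
    hits["chrom"] = snp_pos.loc[hits["snp"], "chrom"].to_numpy()
    hits["pos"] = snp_pos.loc[hits["snp"], "pos"].to_numpy()
    rows = []
    for chrom, sub in variants.groupby("chrom", sort=False):
        chrom_len = int(sub["pos"].max())
        chits = hits[hits["chrom"] == chrom]
        for start in range(1, chrom_len + 1, window):
            end = start + window - 1
            inw = chits[(chits["pos"] >= start) & (chits["pos"] <= end)]
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_esnps": inw["snp"].nunique(),
                    "n_genes": inw["gene"].nunique(),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MAF-fixing subsampling

def _maf_of(dosage: np.ndarray) -> float:
    p = dosage.sum() / (2.0 * dosage.size)
    return float(min(p, 1.0 - p))


def subsample_fix_maf(
    dosage: np.ndarray,
    target: float = 0.25,
    tol: float = 0.02,
    n_out: int = 40,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray | None, bool]:
    """Greedily drop samples until ``n_out`` remain, steering the minor allele
    frequency toward ``target``.

    At each step the sample whose removal minimises |MAF - target| is
    dropped (ties broken by seeded RNG). Succeeds iff the final MAF lies in
    [target - tol, target + tol]. Returns (kept sample indices, success);
    on failure the indices are None and the SNP should be excluded from the
    full-vs-subsampled effect-size comparison.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dosage = np.asarray(dosage)
    keep = np.flatnonzero(dosage != MISSING)
    if keep.size <= n_out:
        raise ValueError(f"need more than {n_out} non-missing samples")
    values = dosage[keep].astype(float)
    while keep.size > n_out:
        total = values.sum()
        n = values.size
        # resulting folded MAF after dropping one sample of each dosage class
        best_dist = np.inf
        best_class: list[int] = []
        for c in (0, 1, 2):
            if not np.any(values == c):
                continue
            p = (total - c) / (2.0 * (n - 1))
            dist = abs(min(p, 1.0 - p) - target)
            if dist < best_dist - 1e-12:
                best_dist = dist
                best_class = [c]
            elif abs(dist - best_dist) <= 1e-12:
                best_class.append(c)
        c = best_class[0] if len(best_class) == 1 else int(rng.choice(best_class))
        candidates = np.flatnonzero(values == c)
        drop = int(rng.choice(candidates))
        keep = np.delete(keep, drop)
        values = np.delete(values, drop)
    success = abs(_maf_of(values) - target) <= tol + 1e-12
    return (keep if success else None), success
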