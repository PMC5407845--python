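"""Genotype means, expression filtering, and per-gene repeatability (H²) and
Q_ST with permutation significance.

H² is computed as repeatability across clonal replicates, an upper bound on
broad-sense heritability:

    H² = V_G / (V_G + V_E)

with V_G the variance among genotype means and V_E the mean within-genotype
(replicate) variance. Q_ST contrasts among-population to within-population
genetic variance on genotype means:

    Q_ST = V_between / (V_between + 2 V_within)

with the components estimated by Henderson-III (method-of-moments) ANOVA on
the one-observation-per-genotype design, negative estimates truncated to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionData

__all__ = [
    "genotype_means",
    "filter_expression",
    "estimate_h2",
    "estimate_qst",
    "empirical_pvalue",
    "FilterReport",
]


def empirical_pvalue(stat: float, null: np.ndarray) -> float:
    """Permutation p-value with add-one smoothing.

    p = (1 + #{null >= stat}) / (1 + len(null)); strictly positive so that
    downstream -log10 and q-value machinery never sees p = 0.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty permutation null")
    return (1.0 + np.count_nonzero(null >= stat)) / (1.0 + null.size)


def genotype_means(expr: ExpressionData, samples: pd.DataFrame) -> pd.DataFrame:
    """Average replicate samples within each genotype.

    Returns a genes x genotypes DataFrame; column order follows first
    appearance of each genotype in the sample table.
    """
    sample_index = {s: i for i, s in enumerate(expr.sample_ids)}
    missing = [s for s in samples["sample"] if s not in sample_index]
    if missing:
        raise ValueError(f"samples absent from expression matrix: {missing[:5]}")
    genotypes = list(dict.fromkeys(samples["genotype"]))
    cols = np.empty((expr.n_genes, len(genotypes)))
    for j, g in enumerate(genotypes):
        idx = [sample_index[s] for s in samples.loc[samples["genotype"] == g, "sample"]]
        if not idx:
            raise ValueError(f"genotype {g} has no samples")
        cols[:, j] = expr.matrix[:, idx].mean(axis=1)
    return pd.DataFrame(cols, index=expr.gene_ids, columns=genotypes)


@dataclass
class FilterReport:
    classes: pd.Series  # per gene: unexpressed / weak / stable / retained
    counts: dict[str, int]


def filter_expression(
    means: pd.DataFrame,
    var_threshold: float = 0.05,
    median_threshold: float = 2.0,
) -> tuple[FilterReport, pd.DataFrame]:
    """Partition genes into unexpressed / weak / stable / retained.

    Unexpressed: median genotype-mean expression of zero. Weak: variance below
    the threshold and median below the expression threshold. Stable: variance
    below the threshold with median at or above it (candidate canalised
    expression). Everything else is retained for mapping and networks.
    Variance is the n-1 sample variance across genotype means.
    """
    if means.empty:
        raise ValueError("empty genotype-mean matrix")
    med = means.median(axis=1)
    var = means.var(axis=1, ddof=1)
    classes = pd.Series("retained", index=means.index, dtype=object)
    classes[(var < var_threshold) & (med >= median_threshold)] = "stable"
    classes[(var < var_threshold) & (med < median_threshold)] = "weak"
    classes[med == 0] = "unexpressed"
    counts = {c: int((classes == c).sum())
              for c in ("unexpressed", "weak", "stable", "retained")}
    report = FilterReport(classes=classes, counts=counts)
    return report, means.loc[classes == "retained"]


def _h2_components(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(V_G, V_E) for one gene by one-way ANOVA on clonal replicates.

    V_E is the pooled within-genotype mean square; V_G is the
    replicate-noise-corrected between-genotype component
    (MS_between − MS_within)/n0 with Henderson's n0 for unbalanced designs,
    truncated at zero. Without the correction the between-genotype mean
    square absorbs Var(eps)/r and repeatability cannot drop below
    ~1/(1 + r̄) however noisy the trait."""
    uniq, codes = np.unique(groups, return_inverse=True)
    counts = np.bincount(codes).astype(float)
    if not np.any(counts >= 2):
        raise ValueError("all genotypes have a single replicate; V_E undefined")
    a = uniq.size
    n_total = float(values.size)
    sums = np.bincount(codes, weights=values)
    gmeans = sums / counts
    grand = values.mean()
    ss_between = float(np.sum(counts * (gmeans - grand) ** 2))
    ss_within = float(np.sum((values - gmeans[codes]) ** 2))
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (n_total - a)
    n0 = (n_total - np.sum(counts ** 2) / n_total) / (a - 1)
    v_g = max((ms_between - ms_within) / n0, 0.0)
    return v_g, ms_within


def estimate_h2(
    expr: ExpressionData,
    samples: pd.DataFrame,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-gene repeatability with a label-permutation null.

    Returns a DataFrame with V_G, V_E, V_P, H2, zero_vp flag and, when
    ``n_perm`` > 0, a permutation p-value obtained by reassigning samples to
    genotype labels.
    """
    groups = samples.set_index("sample").loc[expr.sample_ids, "genotype"].to_numpy()
    if np.unique(groups).size < 2:
        raise ValueError("need at least two genotypes")
    codes = pd.factorize(groups)[0]
    n_gt = codes.max() + 1
    counts = np.bincount(codes, minlength=n_gt).astype(float)
    if not np.any(counts >= 2):
        raise ValueError("all genotypes have a single replicate; V_E undefined")

    def components_matrix(col_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised ANOVA components (V_G, V_E) over all genes for one
        sample->genotype assignment; mirrors ``_h2_components``."""
        cnt = np.bincount(col_codes, minlength=n_gt).astype(float)
        n_total = float(expr.matrix.shape[1])
        sums = np.zeros((expr.n_genes, n_gt))
        sq = np.zeros((expr.n_genes, n_gt))
        np.add.at(sums.T, col_codes, expr.matrix.T)
        np.add.at(sq.T, col_codes, (expr.matrix ** 2).T)
        gmeans = sums / cnt
        grand = expr.matrix.mean(axis=1)
        ss_between = ((gmeans - grand[:, None]) ** 2 * cnt).sum(axis=1)
        ss_within = (sq - cnt * gmeans ** 2).sum(axis=1)
        a = n_gt
        ms_between = ss_between / (a - 1)
        ms_within = ss_within / (n_total - a)
        n0 = (n_total - np.sum(cnt ** 2) / n_total) / (a - 1)
        v_g_raw = (ms_between - ms_within) / n0
        return v_g_raw, ms_within

    v_g_raw, v_e = components_matrix(codes)
    v_g = np.maximum(v_g_raw, 0.0)
    v_p = v_g + v_e
    zero_vp = v_p <= 0
    h2 = np.where(zero_vp, 0.0, v_g / np.where(zero_vp, 1.0, v_p))

    out = pd.DataFrame(
        {"V_G": v_g, "V_E": v_e, "V_P": v_p, "H2": h2, "zero_vp": zero_vp},
        index=expr.gene_ids,
    )
    if n_perm > 0:
        # permutation on the untruncated between/within ratio: truncating
        # negative components first would put an atom of ties at zero and
        # make null p-values non-uniform
        tiny = 1e-300
        stat = v_g_raw / np.maximum(v_e, tiny)
        rng = np.random.default_rng() if rng is None else rng
        exceed = np.zeros(expr.n_genes)
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            pv_g_raw, pv_e = components_matrix(perm)
            exceed += pv_g_raw / np.maximum(pv_e, tiny) >= stat
        out["p_H2"] = (1.0 + exceed) / (1.0 + n_perm)
    return out


def _qst_components(
    gmeans: np.ndarray, pop_codes: np.ndarray, n_pops: int
) -> tuple[np.ndarray, np.ndarray]:
    """Henderson-III variance components on genotype means, vectorised over
    genes. Returns (V_between, V_within), untruncated.

    Unbalanced one-way ANOVA: MS_within estimates V_within; V_between =
    (MS_between - MS_within)/n0 with n0 = (N - sum(n_i^2)/N)/(a-1).
    """
    counts = np.bincount(pop_codes, minlength=n_pops).astype(float)
    n_total = counts.sum()
    pop_sums = np.zeros((gmeans.shape[0], n_pops))
    np.add.at(pop_sums.T, pop_codes, gmeans.T)
    pop_means = pop_sums / counts
    grand = gmeans.mean(axis=1, keepdims=True)
    ss_between = ((pop_means - grand) ** 2 * counts).sum(axis=1)
    ss_total = ((gmeans - grand) ** 2).sum(axis=1)
    ss_within = ss_total - ss_between
    df_between = n_pops - 1
    df_within = n_total - n_pops
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    n0 = (n_total - (counts ** 2).sum() / n_total) / df_between
    v_between = (ms_between - ms_within) / n0
    return v_between, ms_within


def estimate_qst(
    gmeans: pd.DataFrame,
    genotype_pops: pd.Series,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-gene Q_ST from genotype means, with a population-shuffle null.

    ``genotype_pops`` maps genotype id -> population id. Negative component
    estimates are truncated to zero before forming the ratio; genes with a
    zero denominator are flagged ``undefined_qst``. Permutation replicates
    with undefined Q_ST are dropped from the null and the effective null size
    is recorded per gene (``n_null``).
    """
    pops = genotype_pops.loc[gmeans.columns].to_numpy()
    pop_codes, pop_uniq = pd.factorize(pops)
    n_pops = len(pop_uniq)
    if n_pops < 2:
        raise ValueError("need at least two populations")
    pop_sizes = np.bincount(pop_codes)
    if np.any(pop_sizes < 2):
        raise ValueError("every population needs at least two genotypes")

    x = gmeans.to_numpy()

    def qst_from(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vb, vw = _qst_components(x, codes, n_pops)
        vb = np.maximum(vb, 0.0)
        vw = np.maximum(vw, 0.0)
        denom = vb + 2.0 * vw
        undef = denom <= 0
        q = np.where(undef, np.nan, vb / np.where(undef, 1.0, denom))
        return q, undef

    qst, undef = qst_from(pop_codes)
    vb, vw = _qst_components(x, pop_codes, n_pops)
    out = pd.DataFrame(
        {
            "V_between": np.maximum(vb, 0.0),
            "V_within": np.maximum(vw, 0.0),
            "QST": qst,
            "undefined_qst": undef,
        },
        index=gmeans.index,
    )
    if n_perm > 0:
        rng = np.random.default_rng() if rng is None else rng
        exceed = np.zeros(len(gmeans))
        n_null = np.zeros(len(gmeans))
        for _ in range(n_perm):
            perm = rng.permutation(pop_codes)
            pq, pundef = qst_from(perm)
            valid = ~pundef
            exceed[valid] += pq[valid] >= qst[valid]
            n_null += valid
        out["p_QST"] = (1.0 + exceed) / (1.0 + n_null)
        out.loc[undef, "p_QST"] = np.nan
        out["n_null"] = n_null.astype(int)
    return out
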