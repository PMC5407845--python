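"""Synthesis layer: group comparisons, PCA over the five expression-related
gene measures, partial Spearman correlations against sequence-evolution
metrics, and the paralog analysis.

The five expression measures integrated per gene are network connectivity
(kTotal), module-core membership, expression level and variance (both taken
before confounder removal) and eGene status. Their relationships to θπ,
Tajima's D, θ0-fold/θ4-fold and dN/dS are summarised by Mann-Whitney group
contrasts, a scaled PCA, and rank-based partial correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "group_compare",
    "expression_measure_pca",
    "partial_spearman",
    "paralog_analysis",
    "GroupComparison",
    "PcaResult",
    "ParalogResult",
]

EXPRESSION_MEASURES = (
    "kTotal",
    "core",
    "expr_level",
    "expr_variance",
    "egene",
)


@dataclass
class GroupComparison:
    n_a: int
    n_b: int
    u: float
    p: float
    shift: float        # Hodges-Lehmann location shift (a relative to b)
    ci_low: float
    ci_high: float


def _hodges_lehmann(a: np.ndarray, b: np.ndarray, conf: float = 0.95):
    """Median of pairwise differences and the Moses distribution-free CI."""
    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    shift = float(np.median(diffs))
    m, n = len(a), len(b)
    # normal approximation to the rank of the CI endpoints
    z = stats.norm.ppf(0.5 + conf / 2.0)
    sigma = np.sqrt(m * n * (m + n + 1) / 12.0)
    k = int(np.floor(m * n / 2.0 - z * sigma))
    k = max(k, 0)
    lo = diffs[k] if k < diffs.size else diffs[0]
    hi = diffs[diffs.size - 1 - k] if k < diffs.size else diffs[-1]
    return shift, float(lo), float(hi)


def group_compare(values_a: np.ndarray, values_b: np.ndarray) -> GroupComparison:
    """Mann-Whitney U with Hodges-Lehmann shift and 95% CI.

    Exact p-value by complete enumeration when both groups have at most 8
    observations; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (a.size <= 8 and b.size <= 8) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    shift, lo, hi = _hodges_lehmann(a, b)
    return GroupComparison(
        n_a=a.size, n_b=b.size, u=float(res.statistic), p=float(res.pvalue),
        shift=shift, ci_low=lo, ci_high=hi,
    )


@dataclass
class PcaResult:
    loadings: pd.DataFrame        # variables x PCs
    contributions: pd.DataFrame   # squared loadings, columns sum to 1
    variance_explained: pd.Series  # percent per PC, sums to 100
    scores: pd.DataFrame


def expression_measure_pca(summary: pd.DataFrame,
                           measures: tuple[str, ...] = EXPRESSION_MEASURES) -> PcaResult:
    """Scaled PCA of the expression-related gene measures.

    Boolean flags are treated as 0/1 and all variables standardised, so this
    is an eigendecomposition of their correlation matrix. Each PC is oriented
    so that its largest-|loading| variable loads positively. Rows with any
    missing measure are dropped.
    """
    x = summary.loc[:, list(measures)].astype(float).dropna()
    sd = x.std(ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise ValueError(f"constant variable(s): {list(constant.index)}")
    z = (x - x.mean()) / sd
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    for j in range(eigvec.shape[1]):
        lead = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[lead, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    pcs = [f"PC{i + 1}" for i in range(len(measures))]
    loadings = pd.DataFrame(eigvec, index=list(measures), columns=pcs)
    contributions = loadings ** 2
    contributions = contributions / contributions.sum(axis=0)
    variance = pd.Series(100.0 * eigval / eigval.sum(), index=pcs)
    scores = pd.DataFrame(z.to_numpy() @ eigvec, index=x.index, columns=pcs)
    return PcaResult(loadings, contributions, variance, scores)


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    controls: np.ndarray | None = None,
) -> tuple[float, float]:
    """Rank-based partial correlation of x and y given control variables.

    All variables are converted to average ranks; the partial correlation is
    read off the inverse of the rank correlation matrix; the p-value uses the
    t approximation with n − 2 − #controls degrees of freedom. With no
    controls this is plain Spearman's rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cols = [x, y]
    if controls is not None:
        c = np.asarray(controls, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        cols.extend(c[:, j] for j in range(c.shape[1]))
    data = np.column_stack(cols)
    ok = np.all(np.isfinite(data), axis=1)
    data = data[ok]
    n, k = data.shape
    n_controls = k - 2
    if n < 5 + n_controls:
        raise ValueError("too few complete cases")
    ranks = np.apply_along_axis(stats.rankdata, 0, data)
    corr = np.corrcoef(ranks, rowvar=False)
    if abs(corr[0, 1]) >= 1.0 - 1e-12:
        # x and y carry identical rank information; controls cannot change it
        return float(np.sign(corr[0, 1])), 0.0
    if n_controls == 0:
        rho = corr[0, 1]
    else:
        try:
            prec = np.linalg.inv(corr)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular rank correlation matrix") from err
        rho = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - n_controls
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


@dataclass
class ParalogResult:
    pair_table: pd.DataFrame      # pair, correlation, n_egenes
    class_means: pd.Series        # mean correlation by eGene count 0/1/2
    slope: float                  # OLS slope of correlation on eGene count
    slope_p: float
    perm_p: float                 # planted-vs-random-pair permutation p
    hypergeom_p: float            # eGene under-representation among paralogs


def paralog_analysis(
    pairs: list[tuple[str, str]],
    means: pd.DataFrame,
    egene_flags: pd.Series,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> ParalogResult:
    """Expression correlation of paralog pairs vs eGene content.

    Per pair: Pearson correlation of genotype means and the pair's eGene
    count (0/1/2). Reports the OLS slope of correlation on eGene count, a
    permutation test of the observed mean pair correlation against
    size-matched random gene pairs, and a hypergeometric test of eGene
    under-representation among paralog genes relative to all genes in
    ``means``.
    """
    if not pairs:
        raise ValueError("no paralog pairs supplied")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x = means.to_numpy()
    index = {g: i for i, g in enumerate(means.index)}
    rows = []
    for g1, g2 in pairs:
        i, j = index[g1], index[g2]
        r = np.corrcoef(x[i], x[j])[0, 1]
        n_eg = int(egene_flags.get(g1, False)) + int(egene_flags.get(g2, False))
        rows.append({"gene_a": g1, "gene_b": g2, "correlation": r, "n_egenes": n_eg})
    table = pd.DataFrame(rows)
    class_means = table.groupby("n_egenes")["correlation"].mean()
    if table["n_egenes"].nunique() > 1:
        slope, _, _, slope_p, _ = stats.linregress(
            table["n_egenes"], table["correlation"]
        )
    else:
        slope, slope_p = float("nan"), float("nan")

    observed = table["correlation"].mean()
    n_genes = len(means)
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.integers(0, n_genes, size=(len(pairs), 2))
        clash = idx[:, 0] == idx[:, 1]
        while clash.any():
            idx[clash, 1] = rng.integers(0, n_genes, size=clash.sum())
            clash = idx[:, 0] == idx[:, 1]
        rs = np.array([np.corrcoef(x[i], x[j])[0, 1] for i, j in idx])
        null[b] = rs.mean()
    perm_p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_perm)

    paralog_genes = sorted({g for p in pairs for g in p})
    k_egenes = int(sum(bool(egene_flags.get(g, False)) for g in paralog_genes))
    total_egenes = int(egene_flags.reindex(means.index).fillna(False).sum())
    # under-representation: P(X <= k) under the hypergeometric null
    hyper_p = float(
        stats.hypergeom.cdf(k_egenes, n_genes, total_egenes, len(paralog_genes))
    )
    return ParalogResult(
        pair_table=table,
        class_means=class_means,
        slope=float(slope),
        slope_p=float(slope_p),
        perm_p=float(perm_p),
        hypergeom_p=hyper_p,
    )
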