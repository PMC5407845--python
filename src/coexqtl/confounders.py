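"""Hidden-confounder removal by principal-component regression.

Latent technical or environmental factors inflate global correlation in the
expression matrix and mask genotype-expression associations. The leading PCs
of the genotype-mean expression matrix are taken as confounder estimates and
regressed out gene by gene; the number of PCs removed is chosen to maximise
the number of associations passing a Benjamini-Hochberg cut on the nominal
scan p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeData
from .eqtl import benjamini_hochberg, map_associations

__all__ = ["remove_expression_pcs", "select_confounder_count", "ConfounderResult"]


def _pc_scores(means: pd.DataFrame, k: int) -> np.ndarray:
    """Scores (genotypes x k) of the first k PCs of the genotype x gene
    matrix with genes centred."""
    x = means.to_numpy().T  # genotypes x genes
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :k] * s[:k]


def remove_expression_pcs(means: pd.DataFrame, k: int) -> pd.DataFrame:
    """Residualise each gene's genotype means on the first ``k`` expression
    PCs; ``k = 0`` returns the centred input."""
    n_gt = means.shape[1]
    if k >= n_gt:
        raise ValueError(f"k={k} >= number of genotypes ({n_gt})")
    centred = means.sub(means.mean(axis=1), axis=0)
    if k == 0:
        return centred
    scores = _pc_scores(means, k)
    q, _ = np.linalg.qr(scores)
    resid = centred.to_numpy() - (centred.to_numpy() @ q) @ q.T
    return pd.DataFrame(resid, index=means.index, columns=means.columns)


@dataclass
class ConfounderResult:
    k_selected: int
    eqtl_counts_by_k: pd.Series  # k -> significant association count
    residuals: pd.DataFrame      # genotype means after removal at k_selected
    pc_scores: np.ndarray        # scores of the PCs actually removed


def select_confounder_count(
    means: pd.DataFrame,
    genotypes: GenotypeData,
    covariate: np.ndarray,
    grid: range | list[int] = range(0, 21),
    alpha: float = 0.05,
    snp_fraction: float = 1.0,
    rng: np.random.Generator | None = None,
) -> ConfounderResult:
    """Choose how many expression PCs to remove.

    For each k in ``grid`` the association scan is run on the residual matrix
    and associations with BH-adjusted nominal p below ``alpha`` are counted;
    the k with the largest count wins, ties going to the smaller k (minimal
    data surgery). ``snp_fraction`` < 1 subsamples SNPs for the selection loop
    only (the chosen residual matrix is returned at full resolution).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty confounder grid")
    scan_genotypes = genotypes
    if snp_fraction < 1.0:
        rng = np.random.default_rng() if rng is None else rng
        n_keep = max(2, int(round(snp_fraction * genotypes.n_variants)))
        idx = np.sort(rng.choice(genotypes.n_variants, size=n_keep, replace=False))
        scan_genotypes = GenotypeData(
            variants=genotypes.variants.iloc[idx].reset_index(drop=True),
            matrix=genotypes.matrix[:, idx],
            genotype_ids=genotypes.genotype_ids,
            samples=genotypes.samples,
        )
    counts = {}
    for k in grid:
        resid = remove_expression_pcs(means, k)
        scan = map_associations(resid, scan_genotypes, covariate)
        # regressing out k PCs consumes k residual degrees of freedom; the
        # nominal p must be recomputed at n - 3 - k or the count rises with k
        # purely mechanically
        df_adj = scan.df - k
        if df_adj < 1:
            raise ValueError(f"k={k} leaves no residual degrees of freedom")
        r2 = scan.r2[~np.isnan(scan.r2)]
        r2 = np.minimum(r2, 1.0 - 1e-15)
        t_adj = np.sqrt(r2 * df_adj / (1.0 - r2))
        p = 2.0 * stats.t.sf(t_adj, df_adj)
        counts[k] = int((benjamini_hochberg(p) <= alpha).sum())
    series = pd.Series(counts).sort_index()
    best = int(series.index[np.argmax(series.to_numpy())])  # argmax -> first = smallest k
    return ConfounderResult(
        k_selected=best,
        eqtl_counts_by_k=series,
        residuals=remove_expression_pcs(means, best),
        pc_scores=_pc_scores(means, best),
    )
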