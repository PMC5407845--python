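"""Unsigned soft-threshold co-expression network with signed topological
overlap, module detection, connectivity statistics, core/periphery calls,
scale-free fit and gene-label permutation tests.

The network is built from Pearson correlations r across genotype means
(after confounder removal). Adjacency is unsigned, a_ij = |r_ij|^beta, so
strongly negatively correlated genes share modules; the topological overlap
measure (TOM) is the *signed* variant, whose shared-neighbour sum uses
sign(r)*a and therefore cancels when a third gene connects two genes with
inconsistent signs:

    TOM_ij = |ã_ij + Σ_{u≠i,j} ã_iu ã_uj| / (min(k_i, k_j) + 1 − |ã_ij|),

with ã = sign(r)·a and k_i the unsigned connectivity Σ_{u≠i} a_iu. Modules
are average-linkage clusters of the 1−TOM dissimilarity under a static tree
cut; module cores are the top decile of normalised intra/inter connectivity
difference (k_diff) with intra-modular connectivity above 1; the periphery
holds genes with exactly one partner in the hard-thresholded |r| graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .quantgen import empirical_pvalue

__all__ = [
    "build_network",
    "detect_modules",
    "node_statistics",
    "define_cores_and_periphery",
    "scale_free_fit",
    "label_permutation_test",
    "NetworkModel",
]

log = logging.getLogger(__name__)


@dataclass
class NetworkModel:
    gene_ids: list[str]
    r: np.ndarray          # Pearson correlation, genes x genes
    beta: float            # soft-threshold power
    adjacency: np.ndarray  # |r|^beta, unit diagonal
    tom: np.ndarray        # signed TOM
    labels: np.ndarray | None = None   # module labels, 0 = unassigned
    stats: pd.DataFrame | None = None  # per-gene NodeStats

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.tom


def signed_tom(adjacency: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Signed topological overlap of an unsigned adjacency matrix.

    Matrix form of the pairwise definition: with ã = sign(r)·a (diagonal
    zeroed for the neighbour sum), numerator |ã_ij + (Ã²)_ij| and denominator
    min(k_i,k_j) + 1 − a_ij.
    """
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    sa = np.sign(r) * a
    k = a.sum(axis=1)
    shared = sa @ sa  # (Ã²)_ij = Σ_u ã_iu ã_uj, u ranging over all; diag already 0
    numer = np.abs(sa + shared)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def build_network(means: pd.DataFrame, beta: float = 5.0) -> NetworkModel:
    """Correlation, soft-threshold adjacency and signed TOM from a genes x
    genotypes matrix of (residualised) genotype means."""
    if means.shape[0] < 3:
        raise ValueError("need at least three genes to build a network")
    sd = means.std(axis=1, ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise ValueError(f"constant gene(s): {list(constant.index)[:5]}")
    r = np.corrcoef(means.to_numpy())
    adjacency = np.abs(r) ** beta
    np.fill_diagonal(adjacency, 1.0)
    tom = signed_tom(adjacency, r)
    return NetworkModel(
        gene_ids=list(means.index), r=r, beta=beta, adjacency=adjacency, tom=tom
    )


def detect_modules(
    dissimilarity: np.ndarray,
    min_module_size: int = 30,
    cut_height: float | None = None,
    seed_size: int = 5,
    n_representatives: int = 10,
    junk_ratio: float = 100.0,
) -> np.ndarray:
    """Module labels from average-linkage clustering of 1−TOM.

    Two stages. (1) Seeding: the tree is cut statically — at ``cut_height``
    when given, otherwise at the height maximising the number of clusters
    of at least ``seed_size`` genes (ties to the lower, purer cut); those
    clusters are the module seeds. (2) Assignment: each seed is represented
    by its ``n_representatives`` most intra-connected genes (in practice the
    hubs) and every gene joins the seed with the highest mean TOM to its
    representatives, provided that exceeds ``junk_ratio`` times the gene's
    median TOM to the whole network — otherwise it stays unassigned. The
    representative step is needed because average linkage dilutes the
    hub signal as clusters absorb weakly attached members, stranding module
    peripheries near the cut; anchoring on the seed cores keeps assignment
    power at the pairwise-correlation limit. ``junk_ratio`` acts on the TOM
    scale, where the soft-threshold power compresses correlation ratios
    (a ratio of 100 in TOM is roughly a ratio of 2.5 in correlation at
    power 5). Modules ending below
    ``min_module_size`` are dissolved into the unassigned label 0; the rest
    are renumbered 1, 2, ... by decreasing size.
    """
    n = dissimilarity.shape[0]
    z = linkage(squareform(dissimilarity, checks=False), method="average")
    heights = z[:, 2]
    if cut_height is None:
        best_n = 0
        cut_height = float(heights[-1])
        for cut in np.unique(np.quantile(heights, np.linspace(0.05, 0.999, 80))):
            raw = fcluster(z, t=cut, criterion="distance")
            sizes = pd.Series(raw).value_counts()
            n_seeds = int((sizes >= seed_size).sum())
            if n_seeds > best_n:
                best_n, cut_height = n_seeds, float(cut)
        if best_n == 0:
            log.warning("no seed cluster of >= %d genes; all genes unassigned",
                        seed_size)
            return np.zeros(n, dtype=int)
    raw = fcluster(z, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    seeds = [c for c in sizes.index if sizes[c] >= seed_size]
    if not seeds:
        log.warning("no seed cluster at cut height %.4f", cut_height)
        return np.zeros(n, dtype=int)
    if len(seeds) == 1 and sizes[seeds[0]] == n:
        log.warning("all genes fall in a single cluster at cut height %.4f",
                    cut_height)
    tom = 1.0 - dissimilarity
    t = tom.copy()
    np.fill_diagonal(t, 0.0)
    rep_sets = []
    for c in seeds:
        members = np.flatnonzero(raw == c)
        within = t[np.ix_(members, members)].sum(axis=1)
        rep_sets.append(members[np.argsort(within)[::-1][:n_representatives]])
    scores = np.stack([t[:, reps].mean(axis=1) for reps in rep_sets], axis=1)
    best = scores.argmax(axis=1)
    best_score = scores.max(axis=1)
    # background affinity per seed: the lower quartile of that seed's score
    # column (non-members dominate it); genes must clear it by junk_ratio
    background = np.quantile(scores, 0.25, axis=0)
    labels = np.where(
        best_score > junk_ratio * np.maximum(background[best], 1e-12), best + 1, 0
    )
    for m in range(1, len(seeds) + 1):
        if (labels == m).sum() < min_module_size:
            labels[labels == m] = 0
    out = np.zeros_like(labels)
    mods = sorted(
        (m for m in np.unique(labels) if m > 0),
        key=lambda m: -(labels == m).sum(),
    )
    for new, m in enumerate(mods, start=1):
        out[labels == m] = new
    return out


def node_statistics(
    network: NetworkModel,
    labels: np.ndarray,
    peri_r: float = 0.4,
) -> pd.DataFrame:
    """Per-gene connectivity statistics.

    kTotal is the adjacency sum excluding self; kWithin/kOut split it by
    module co-membership. kDiff_norm = kWithin/(m−1) − kOut/(N−m) puts the
    intra and inter parts on a per-partner scale so modules of different
    sizes are comparable (guarded to 0 for singleton or all-gene modules).
    Hard-threshold degree and betweenness are computed on the unweighted
    |r| > ``peri_r`` graph.
    """
    a = network.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k_total = a.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    k_within = np.where(same, a, 0.0).sum(axis=1)
    k_out = k_total - k_within
    m = np.array([np.count_nonzero(labels == lab) for lab in labels])
    with np.errstate(invalid="ignore", divide="ignore"):
        within_norm = np.where(m > 1, k_within / np.maximum(m - 1, 1), 0.0)
        out_norm = np.where(n - m > 0, k_out / np.maximum(n - m, 1), 0.0)
    k_diff_norm = within_norm - out_norm

    hard = np.abs(network.r) > peri_r
    np.fill_diagonal(hard, False)
    degree = hard.sum(axis=1)
    g = nx.from_numpy_array(hard)
    betweenness = np.array(
        [nx.betweenness_centrality(g, normalized=True)[i] for i in range(n)]
    )
    return pd.DataFrame(
        {
            "module": labels,
            "kTotal": k_total,
            "kWithin": k_within,
            "kOut": k_out,
            "kDiff_norm": k_diff_norm,
            "degree": degree,
            "betweenness": betweenness,
        },
        index=network.gene_ids,
    )


def define_cores_and_periphery(
    network: NetworkModel,
    labels: np.ndarray,
    stats: pd.DataFrame,
    core_frac: float = 0.10,
    kwithin_min: float = 1.0,
    peri_r: float = 0.4,
    peri_quantile: float | None = None,
) -> pd.DataFrame:
    """Flag module cores and the network periphery.

    Core: per module, candidates with kWithin > ``kwithin_min`` ranked by
    kDiff_norm (ties to higher kWithin, then gene id); the top
    ceil(core_frac x module size) are cores. A module may legitimately have
    no cores. Periphery: genes of degree exactly 1 in the hard-threshold
    graph, built either at |r| > ``peri_r`` or, when ``peri_quantile`` is
    given, at the threshold keeping that top fraction of pairs (e.g. 0.001
    for the top 0.1% most correlated pairs).
    """
    out = stats.copy()
    out["core"] = False
    for lab in np.unique(labels):
        if lab == 0:
            continue
        members = np.flatnonzero(labels == lab)
        sub = out.iloc[members]
        cand = sub[sub["kWithin"] > kwithin_min]
        if cand.empty:
            continue
        n_core = int(np.ceil(core_frac * len(members)))
        ranked = cand.sort_values(
            by=["kDiff_norm", "kWithin"], ascending=False, kind="mergesort"
        )
        # stable sort + index order makes boundary ties deterministic by gene id
        out.loc[ranked.index[:n_core], "core"] = True

    if peri_quantile is not None:
        absr = np.abs(network.r[np.triu_indices_from(network.r, k=1)])
        thr = float(np.quantile(absr, 1.0 - peri_quantile))
    else:
        thr = peri_r
    hard = np.abs(network.r) > thr
    np.fill_diagonal(hard, False)
    degree = hard.sum(axis=1)
    out["peripheral"] = degree == 1
    return out


def scale_free_fit(k_total: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology index: R² and slope of log10 p(k) on log10 k.

    Connectivities are binned into ``n_bins`` equal-width bins; each
    non-empty bin contributes its mean connectivity and its empirical
    frequency. A high R² with negative slope indicates an approximate
    power-law degree distribution.
    """
    k = np.asarray(k_total, dtype=float)
    if np.unique(k).size < n_bins:
        raise ValueError(f"need at least {n_bins} distinct connectivity values")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        mean_k = k[sel].mean()
        freq = sel.mean()
        if mean_k > 0 and freq > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 3:
        raise ValueError("fewer than 3 usable bins for the scale-free fit")
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = np.polyval([slope, intercept], xs)
    ss_res = float(((np.array(ys) - fitted) ** 2).sum())
    ss_tot = float(((np.array(ys) - np.mean(ys)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return r2, float(slope)


@dataclass
class PermutationTestResult:
    observed: float
    p: float
    n_perm: int
    null: np.ndarray = field(repr=False)


def label_permutation_test(
    attribute: np.ndarray,
    statistic: Callable[[np.ndarray], float],
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
    alternative: str = "greater",
) -> PermutationTestResult:
    """Shuffle a per-gene attribute across nodes of a fixed network and
    recompute ``statistic``; empirical p with add-one smoothing.

    ``alternative``: 'greater' tests enrichment of the observed statistic,
    'less' depletion, 'two-sided' either. Used for eGene depletion in cores,
    periphery enrichment, TF/conserved-gene core enrichment and group
    differences in connectivity, betweenness or H².
    """
    attribute = np.asarray(attribute)
    if np.all(attribute == attribute[0]):
        raise ValueError("constant attribute: nothing to permute")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    observed = float(statistic(attribute))
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = statistic(rng.permutation(attribute))
    if alternative == "greater":
        p = empirical_pvalue(observed, null)
    elif alternative == "less":
        p = empirical_pvalue(-observed, -null)
    elif alternative == "two-sided":
        centre = float(np.median(null))
        p = empirical_pvalue(abs(observed - centre), np.abs(null - centre))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return PermutationTestResult(observed=observed, p=p, n_perm=n_perm, null=null)
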