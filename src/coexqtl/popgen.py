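"""Per-gene diversity and divergence statistics: segregating sites, θπ,
Watterson's θ, Tajima's D, θ0-fold/θ4-fold and NG86 dN/dS.

All statistics are computed from aligned intra-specific haplotype panels
(one FASTA panel per gene, outgroup sequence excluded from diversity), with
site-category masks over positions: 1 kbp upstream/downstream flanks, 5'/3'
UTR, intron, and 0-fold / 4-fold degenerate coding positions classified
against the standard genetic code using the reference haplotype's codons.
Divergence uses the Nei–Gojobori (1986) counting method with equal-weight
pathway averaging for multi-hit codons and the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "sfs_statistics",
    "codon_degeneracy",
    "degeneracy_masks",
    "degeneracy_ratio",
    "ng86_dnds",
    "gene_category_stats",
    "SfsResult",
]

SITE_CATEGORIES = (
    "upstream_1kb",
    "downstream_1kb",
    "utr5",
    "utr3",
    "intron",
    "zero_fold",
    "four_fold",
)

GENETIC_CODE = {
    "".join(codon): aa
    for codon, aa in zip(
        itertools.product("TCAG", repeat=3),
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG",
    )
}
BASES = "ACGT"


@dataclass
class SfsResult:
    n: int            # haplotypes
    length: int       # masked sites surveyed
    s: int            # segregating sites
    theta_pi: float   # per site
    theta_w: float    # per site
    tajima_d: float   # NaN when S = 0 (undefined, not zero)


def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def sfs_statistics(
    haplotypes: np.ndarray, mask: np.ndarray | None = None
) -> SfsResult:
    """Site-frequency-spectrum summaries over the masked sites.

    ``haplotypes`` is an (n, L) array of single characters or small ints;
    sites with more than two states contribute to S and to θπ via the full
    heterozygosity formula θπ_site = (1 − Σ p_a²)·n/(n−1). Tajima's D uses
    the 1989 variance constants and is NaN (undefined) when S = 0.
    """
    h = np.asarray(haplotypes)
    n, total_l = h.shape
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        h = h[:, mask]
    length = h.shape[1]
    if length == 0:
        raise ValueError("mask selects no sites")
    segregating = np.any(h != h[0], axis=0)
    s = int(segregating.sum())
    pi_sum = 0.0
    for col in np.nonzero(segregating)[0]:
        _, counts = np.unique(h[:, col], return_counts=True)
        p = counts / n
        pi_sum += (1.0 - np.sum(p ** 2)) * n / (n - 1)
    theta_pi = pi_sum / length
    c = _tajima_constants(n)
    theta_w = s / (c["a1"] * length)
    if s == 0:
        d = float("nan")
    else:
        var = c["e1"] * s + c["e2"] * s * (s - 1)
        numer = pi_sum - s / c["a1"]
        if var <= 0:
            # n = 2: theta_pi and theta_W coincide identically, D = 0
            d = 0.0 if abs(numer) < 1e-12 else float("nan")
        else:
            d = numer / np.sqrt(var)
    return SfsResult(n=n, length=length, s=s, theta_pi=theta_pi,
                     theta_w=theta_w, tajima_d=float(d))


def codon_degeneracy(codon: str) -> tuple[int, int, int]:
    """Fold degeneracy (count of synonymous substitutions possible: 0, 2, 3
    as 'neither', or 4) of each position of a codon.

    Returned per position: 0 if every change is nonsynonymous (0-fold), 4 if
    every change at that position is synonymous (4-fold), else the number of
    synonymous alternatives + 1 (2- or 3-fold; excluded from both masks)."""
    codon = codon.upper()
    aa = GENETIC_CODE[codon]
    folds = []
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[alt] == aa:
                syn += 1
        folds.append(0 if syn == 0 else (4 if syn == 3 else syn + 1))
    return tuple(folds)


def degeneracy_masks(reference_cds: str) -> tuple[np.ndarray, np.ndarray]:
    """(0-fold mask, 4-fold mask) over CDS positions, classified from the
    reference haplotype's codons; 2-/3-fold sites belong to neither."""
    cds = reference_cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    zero = np.zeros(len(cds), dtype=bool)
    four = np.zeros(len(cds), dtype=bool)
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if GENETIC_CODE.get(codon) in (None, "*"):
            continue
        for pos, fold in enumerate(codon_degeneracy(codon)):
            if fold == 0:
                zero[i + pos] = True
            elif fold == 4:
                four[i + pos] = True
    return zero, four


def degeneracy_ratio(
    cds_haplotypes: np.ndarray,
) -> tuple[SfsResult | None, SfsResult | None, float]:
    """θ at 0-fold and 4-fold degenerate sites of an aligned CDS panel, and
    their ratio (NaN when θ4-fold is 0 or a mask is empty).

    Degeneracy is assigned from the first (reference) haplotype; polymorphic
    codons keep the reference classification.
    """
    h = np.asarray(cds_haplotypes)
    ref = "".join(h[0].astype(str)) if h.dtype.kind in "SU" else "".join(h[0])
    zero_mask, four_mask = degeneracy_masks(ref)
    res0 = sfs_statistics(h, zero_mask) if zero_mask.any() else None
    res4 = sfs_statistics(h, four_mask) if four_mask.any() else None
    if res0 is None or res4 is None or res4.theta_pi == 0:
        ratio = float("nan")
    else:
        ratio = res0.theta_pi / res4.theta_pi
    return res0, res4, ratio


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """NG86 (synonymous, nonsynonymous) site counts of one codon."""
    syn = 0.0
    aa = GENETIC_CODE[codon]
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[alt] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Observed (synonymous, nonsynonymous) differences between two codons,
    averaging over all orderings of the differing positions; pathways through
    stop codons are skipped (all-stop pathway sets fall back to counting every
    change as nonsynonymous)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    syn_tot, nsyn_tot, n_paths = 0.0, 0.0, 0
    for order in itertools.permutations(diff):
        cur = c1
        syn, nsyn, valid = 0.0, 0.0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                valid = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        if valid:
            syn_tot += syn
            nsyn_tot += nsyn
            n_paths += 1
    if n_paths == 0:
        return 0.0, float(len(diff))
    return syn_tot / n_paths, nsyn_tot / n_paths


def jukes_cantor(p: float) -> float:
    """JC69 distance; NaN when p >= 3/4 (correction undefined)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(
    cds_ingroup: str, cds_outgroup: str, on_stop: str = "raise"
) -> tuple[float, float, float]:
    """Nei–Gojobori dN, dS and their ratio for one aligned CDS pair.

    Site counts are averaged between the two sequences; observed differences
    use equal-weight pathway averaging; both proportions are Jukes–Cantor
    corrected. dN/dS is NaN when dS is 0 or a correction is undefined.
    Raises on length mismatch; internal stop codons raise by default or, with
    ``on_stop='skip'``, drop the affected codon from the counting (the usual
    treatment when consensus/outgroup construction can create stops).
    """
    s1, s2 = cds_ingroup.upper(), cds_outgroup.upper()
    if len(s1) != len(s2):
        raise ValueError("aligned CDS pair has unequal lengths")
    if len(s1) % 3:
        raise ValueError("CDS length not divisible by 3")
    syn_sites = nsyn_sites = 0.0
    syn_diff = nsyn_diff = 0.0
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        if GENETIC_CODE[c1] == "*" or GENETIC_CODE[c2] == "*":
            if i + 3 >= len(s1):
                continue  # terminal stop excluded from counting
            if on_stop == "skip":
                continue
            raise ValueError(f"internal stop codon at position {i + 1}")
        sa, na = _codon_site_counts(c1)
        sb, nb = _codon_site_counts(c2)
        syn_sites += (sa + sb) / 2.0
        nsyn_sites += (na + nb) / 2.0
        sd, nd = _pathway_differences(c1, c2)
        syn_diff += sd
        nsyn_diff += nd
    ps = syn_diff / syn_sites if syn_sites > 0 else float("nan")
    pn = nsyn_diff / nsyn_sites if nsyn_sites > 0 else float("nan")
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    ratio = dn / ds if ds and ds > 0 and np.isfinite(ds) and np.isfinite(dn) else float("nan")
    return dn, ds, ratio


def consensus_sequence(haplotypes: np.ndarray) -> str:
    """Majority-rule consensus of an aligned panel (ties to the first
    haplotype's base, keeping the consensus a real observed state)."""
    h = np.asarray(haplotypes)
    out = []
    for j in range(h.shape[1]):
        vals, counts = np.unique(h[:, j], return_counts=True)
        best = counts.max()
        winners = set(vals[counts == best])
        out.append(h[0, j] if h[0, j] in winners else vals[np.argmax(counts)])
    return "".join(str(b) for b in out)


def gene_category_stats(
    panels: dict[str, dict],
    min_sites: int = 50,
) -> pd.DataFrame:
    """Diversity table per gene x site category, plus gene-level aggregates
    and NG86 divergence.

    ``panels`` maps gene id -> {"haplotypes": (n, L) array, "outgroup": str,
    "masks": {category: bool array}, "cds_mask": bool array}. Categories (or
    whole genes) with fewer than ``min_sites`` covered sites are flagged
    excluded; empty categories are emitted with missing values.
    """
    rows = []
    for gene, panel in panels.items():
        h = np.asarray(panel["haplotypes"])
        masks = panel["masks"]
        cds_mask = np.asarray(panel["cds_mask"], dtype=bool)
        cds = h[:, cds_mask]
        ref_cds = "".join(str(b) for b in cds[0])
        zero_mask, four_mask = degeneracy_masks(ref_cds)
        cat_masks = dict(masks)
        full0 = np.zeros(h.shape[1], dtype=bool)
        full0[np.flatnonzero(cds_mask)[zero_mask]] = True
        full4 = np.zeros(h.shape[1], dtype=bool)
        full4[np.flatnonzero(cds_mask)[four_mask]] = True
        cat_masks["zero_fold"] = full0
        cat_masks["four_fold"] = full4

        outgroup = panel.get("outgroup")
        if outgroup is not None:
            out_cds = "".join(
                np.asarray(list(outgroup))[cds_mask].tolist()
            )
            dn, ds, dnds = ng86_dnds(
                consensus_sequence(cds), out_cds, on_stop="skip"
            )
        else:
            dn = ds = dnds = float("nan")

        theta0 = theta4 = float("nan")
        for category in SITE_CATEGORIES:
            m = cat_masks.get(category)
            n_sites = int(m.sum()) if m is not None else 0
            if n_sites == 0:
                rows.append({"gene": gene, "category": category, "L": 0,
                             "S": np.nan, "theta_pi": np.nan, "theta_w": np.nan,
                             "tajima_d": np.nan, "excluded": True})
                continue
            res = sfs_statistics(h, m)
            if category == "zero_fold":
                theta0 = res.theta_pi
            elif category == "four_fold":
                theta4 = res.theta_pi
            rows.append({"gene": gene, "category": category, "L": res.length,
                         "S": res.s, "theta_pi": res.theta_pi,
                         "theta_w": res.theta_w, "tajima_d": res.tajima_d,
                         "excluded": res.length < min_sites})
        covered = np.zeros(h.shape[1], dtype=bool)
        for m in cat_masks.values():
            covered |= np.asarray(m, dtype=bool)
        res = sfs_statistics(h, covered) if covered.any() else None
        ratio = theta0 / theta4 if theta4 and np.isfinite(theta4) and theta4 > 0 else float("nan")
        rows.append({
            "gene": gene, "category": "gene", "L": res.length if res else 0,
            "S": res.s if res else np.nan,
            "theta_pi": res.theta_pi if res else np.nan,
            "theta_w": res.theta_w if res else np.nan,
            "tajima_d": res.tajima_d if res else np.nan,
            "theta0_theta4": ratio, "dN": dn, "dS": ds, "dNdS": dnds,
            "excluded": (res.length if res else 0) < min_sites,
        })
    return pd.DataFrame(rows)
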