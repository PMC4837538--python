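"""Genotype quality control, kinship and linkage-disequilibrium summaries.

Covers the standard SNP-chip QC trio (MAF, call rate, exact Hardy-Weinberg
test), the pedigree numerator relationship matrix A with Meuwissen-Luo
inbreeding coefficients, and chromosome-averaged r^2 decay curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .popsim import MISSING, GenotypePanel, Pedigree

# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the
    observed count (the standard exact-test construction used by PLINK).
    Monomorphic input returns 1.0 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa < 1:
        raise ValueError("genotype counts must be non-negative with positive total")
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_AA + n_Aa  # count of the A allele
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(n_het | n, n_rare) up to a constant
    homr = (n_rare - hets) // 2
    homc = n - hets - homr
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[np.where(hets == n_Aa)[0][0]]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    snp_stats: pd.DataFrame  # snp_id, maf, call_rate, hwe_p, kept
    animal_stats: pd.DataFrame  # animal_id, call_rate, kept
    thresholds: dict


def qc_filter(
    panel: GenotypePanel,
    maf_min: float = 0.01,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 0.001,
    animal_call_rate_min: float = 0.95,
) -> tuple[GenotypePanel, QCReport]:
    """Drop low-call-rate animals, then SNPs failing MAF/call-rate/HWE.

    Every per-SNP statistic is computed on non-missing calls of the animals
    that survived the animal-level filter. Raises if nothing survives.
    """
    if panel.n_animals == 0 or panel.n_snps == 0:
        raise ValueError("empty panel")
    obs = panel.dosage != MISSING
    a_cr = obs.mean(axis=1)
    a_keep = a_cr >= animal_call_rate_min
    animal_stats = pd.DataFrame(
        {"animal_id": panel.animal_ids, "call_rate": a_cr, "kept": a_keep}
    )
    sub = panel.subset(animal_idx=np.where(a_keep)[0])
    obs = sub.dosage != MISSING
    n_obs = obs.sum(axis=0)
    call_rate = obs.mean(axis=0)
    p = sub.allele_freq()
    maf = np.minimum(p, 1 - p)
    n_aa = ((sub.dosage == 0) & obs).sum(axis=0)
    n_het = (sub.dosage == 1).sum(axis=0)
    n_AA = (sub.dosage == 2).sum(axis=0)
    hwe_p = np.array(
        [
            hwe_exact_test(int(n_AA[j]), int(n_het[j]), int(n_aa[j]))
            if n_obs[j] > 0
            else 1.0
            for j in range(sub.n_snps)
        ]
    )
    with np.errstate(invalid="ignore"):
        s_keep = (
            (np.nan_to_num(maf) >= maf_min)
            & (call_rate >= call_rate_min)
            & (hwe_p >= hwe_p_min)
        )
    snp_stats = pd.DataFrame(
        {
            "snp_id": sub.marker_map["snp_id"],
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "kept": s_keep,
        }
    )
    if not s_keep.any():
        raise ValueError("all SNPs removed by QC")
    out = sub.subset(snp_idx=np.where(s_keep)[0])
    report = QCReport(
        snp_stats=snp_stats,
        animal_stats=animal_stats,
        thresholds={
            "maf_min": maf_min,
            "call_rate_min": call_rate_min,
            "hwe_p_min": hwe_p_min,
            "animal_call_rate_min": animal_call_rate_min,
        },
    )
    return out, report


# ---------------------------------------------------------------------------
# Pedigree relationship matrix and inbreeding
# ---------------------------------------------------------------------------


def inbreeding_meuwissen_luo(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo L-and-D recursion.

    Computes each animal's diagonal of A = L D L' by tracing its ancestor
    list youngest-first, without ever forming the full A matrix.
    """
    import heapq

    sire, dam = pedigree.parent_indices()
    n = pedigree.n
    F = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == -1 and d == -1:
            F[i] = 0.0
            continue
        # accumulate A_ii = sum_j L_ij^2 D_jj over the ancestor set of i,
        # visiting ancestors youngest-first so each L coefficient is final
        # when its owner is popped (topological order = index order here)
        a_ii = 0.0
        heap = [-i]
        Lcoef = {i: 1.0}
        while heap:
            j = -heapq.heappop(heap)
            if j not in Lcoef:
                continue  # stale heap entry
            lj = Lcoef.pop(j)
            sj, dj = sire[j], dam[j]
            d_jj = 1.0 if sj == -1 else 0.5 - 0.25 * (F[sj] + F[dj])
            a_ii += lj * lj * d_jj
            for p in (sj, dj):
                if p == -1:
                    continue
                if p in Lcoef:
                    Lcoef[p] += 0.5 * lj
                else:
                    Lcoef[p] = 0.5 * lj
                    heapq.heappush(heap, -p)
        F[i] = a_ii - 1.0
    return F


def relationship_matrix(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix A by the tabular method (O(n^2))."""
    sire, dam = pedigree.parent_indices()
    n = pedigree.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == -1:
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        if i == 0:
            continue
        j = np.arange(i)
        if s == -1:
            aij = np.zeros(i)
        else:
            aij = 0.5 * (A[s, j] + A[d, j])
        A[i, j] = aij
        A[j, i] = aij
    return A


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix with per-animal inbreeding F = diag - 1."""

    animal_ids: list[str]
    A: np.ndarray
    F: np.ndarray


def relationship_and_inbreeding(
    pedigree: Pedigree, build_a: bool = True
) -> RelationshipMatrix:
    """Meuwissen-Luo F, plus the full tabular A when ``build_a``."""
    F = inbreeding_meuwissen_luo(pedigree)
    A = relationship_matrix(pedigree) if build_a else None
    return RelationshipMatrix(animal_ids=pedigree.ids, A=A, F=F)


# ---------------------------------------------------------------------------
# Linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (pairwise complete).

    Returns ``nan`` when fewer than two complete pairs remain or either SNP
    is monomorphic among them.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x, y = g1[ok], g2[ok]
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    c = np.cov(x, y, bias=True)[0, 1]
    return float(min(1.0, c * c / (vx * vy)))


def _pairwise_r2(dosage: np.ndarray) -> np.ndarray:
    """All-pairs r^2 with pairwise-complete handling, via masked matmuls."""
    M = (dosage != MISSING).astype(float)
    D = np.where(dosage != MISSING, dosage, 0).astype(float)
    N = M.T @ M
    Sx = D.T @ M
    Sxy = D.T @ D
    Sxx = (D * D).T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Sxy - Sx * Sx.T / N
        varx = Sxx - Sx * Sx / N
        r2 = cov * cov / (varx * varx.T)
        r2[N < 2] = np.nan
    return np.clip(r2, 0.0, 1.0)


@dataclass
class LDDecayCurve:
    """Chromosome-averaged mean r^2 per 1 kb distance bin."""

    bin_bp: int
    table: pd.DataFrame  # bin_lo, bin_hi, mean_r2 (nan if empty), n_pairs
    per_chrom: pd.DataFrame  # chrom, bin_lo, mean_r2, n_pairs


def ld_decay_curve(
    panel: GenotypePanel, max_dist_bp: int = 10_000_000, bin_bp: int = 1000
) -> LDDecayCurve:
    """r^2 of all intra-chromosome pairs within ``max_dist_bp``, binned.

    Means are taken per chromosome first, then averaged across chromosomes
    without pair-count weighting; empty bins are reported as ``nan``.
    """
    chrom = panel.marker_map["chrom"].to_numpy()
    pos = panel.marker_map["pos_bp"].to_numpy()
    rows = []
    for c in np.unique(chrom):
        sel = np.where(chrom == c)[0]
        if len(sel) < 2:
            continue
        r2 = _pairwise_r2(panel.dosage[:, sel])
        p = pos[sel]
        iu, ju = np.triu_indices(len(sel), k=1)
        d = p[ju] - p[iu]
        keep = (d <= max_dist_bp) & np.isfinite(r2[iu, ju])
        b = (d[keep] // bin_bp).astype(np.int64)
        v = r2[iu, ju][keep]
        df = pd.DataFrame({"bin": b, "r2": v})
        agg = df.groupby("bin")["r2"].agg(["mean", "size"]).reset_index()
        agg["chrom"] = c
        rows.append(agg)
    if not rows:
        raise ValueError("need at least two SNPs on some chromosome")
    per = pd.concat(rows, ignore_index=True)
    per = per.rename(columns={"mean": "mean_r2", "size": "n_pairs"})
    per["bin_lo"] = per["bin"] * bin_bp
    avg = (
        per.groupby("bin")
        .agg(mean_r2=("mean_r2", "mean"), n_pairs=("n_pairs", "sum"))
        .reset_index()
    )
    avg["bin_lo"] = avg["bin"] * bin_bp
    avg["bin_hi"] = avg["bin_lo"] + bin_bp
    table = avg[["bin_lo", "bin_hi", "mean_r2", "n_pairs"]]
    return LDDecayCurve(
        bin_bp=bin_bp,
        table=table,
        per_chrom=per[["chrom", "bin_lo", "mean_r2", "n_pairs"]],
    )


def mean_r2_near(
    curve: LDDecayCurve, dist_bp: int, half_window_bp: int = 100_000
) -> float:
    """Pair-weighted mean r^2 of bins within +/- ``half_window_bp`` of a distance."""
    t = curve.table
    sel = t[(t["bin_lo"] >= dist_bp - half_window_bp) & (t["bin_lo"] < dist_bp + half_window_bp)]
    if sel.empty or sel["n_pairs"].sum() == 0:
        return float("nan")
    return float(np.average(sel["mean_r2"], weights=sel["n_pairs"]))
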