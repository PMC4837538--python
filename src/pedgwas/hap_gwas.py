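"""Haplotype-cluster HMM and the two-step score test for haplotype effects.

The genotype model is a haplotype-cluster hidden Markov model: each gamete
is a mosaic of K ancestral haplotype states; states emit allele 1 with a
locus-specific probability, switch between loci with a homogeneous jump
probability, and jump targets follow the state weight vector. A diploid
genotype is the sum of two independent gamete chains; the exact K x K
pair-state forward-backward is run with a rank-1 transition factorisation
(the jump move makes every transition matrix (1-j)I + j 1 a'), so the cost
per locus is O(K^2) rather than O(K^4). Emission, weight and jump
parameters are fitted by EM.

The per-position output is the ancestral dosage H_i: the posterior expected
number of copies (0..2) of each state carried by each animal. Association
is the two-step construction: residuals r = y_adj - 1 mu - u from an
intercept-only animal model, then per position the score statistic
T = 0.5 ||H_i' r||^2 whose null is approximated by a gamma distribution --
by default moment-matched to the exact mean and variance of the quadratic
form under the fitted null mixed model, optionally to permutations of r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import gamma as gamma_dist

from .popsim import MISSING, GenotypePanel
from .reml import eigendecompose, reml_fit

_P_FLOOR = 5e-324


@njit(cache=True, fastmath=True)
def _em_pass(geno, theta, alpha, jump, want_post, dosage, imputed):  # pragma: no cover
    """One exact E-step over all animals; returns sufficient statistics.

    geno: (n, m) int8 with -1 missing; theta: (m, K); alpha: (K,); jump: float.
    When ``want_post`` also fills ``dosage`` (m, n, K) and imputes missing
    genotypes into ``imputed`` (n, m) by the posterior-mode allele count.
    """
    n, m = geno.shape
    K = theta.shape[1]
    c1 = np.zeros((m, K))
    c0 = np.zeros((m, K))
    acount = np.zeros(K)
    jumps = 0.0
    loglik = 0.0

    F = np.empty((m, K, K))
    EMs = np.empty((m, K, K))
    cs = np.empty(m)
    B = np.empty((K, K))
    D = np.empty((K, K))
    Mx = np.empty((K, K))
    G = np.empty((K, K))
    P = np.empty((K, K))
    colsum = np.empty(K)
    rowsum = np.empty(K)
    marg1 = np.empty(K)
    marg2 = np.empty(K)
    u = np.empty(K)
    v = np.empty(K)
    w1p = np.empty(K)
    w2p = np.empty(K)

    omj = 1.0 - jump
    for a in range(n):
        # ---------------- forward ----------------
        for l in range(m):
            g = geno[a, l]
            for k1 in range(K):
                t1 = theta[l, k1]
                for k2 in range(K):
                    t2 = theta[l, k2]
                    if g == 0:
                        e = (1.0 - t1) * (1.0 - t2)
                    elif g == 2:
                        e = t1 * t2
                    elif g == 1:
                        e = t1 * (1.0 - t2) + (1.0 - t1) * t2
                    else:
                        e = 1.0
                    EMs[l, k1, k2] = e
            tot = 0.0
            if l == 0:
                for k1 in range(K):
                    for k2 in range(K):
                        val = alpha[k1] * alpha[k2] * EMs[0, k1, k2]
                        F[0, k1, k2] = val
                        tot += val
            else:
                for k2 in range(K):
                    ssum = 0.0
                    for k1 in range(K):
                        ssum += F[l - 1, k1, k2]
                    colsum[k2] = ssum
                # gamete-1 move
                for k1 in range(K):
                    ja = jump * alpha[k1]
                    for k2 in range(K):
                        G[k1, k2] = omj * F[l - 1, k1, k2] + ja * colsum[k2]
                for k1 in range(K):
                    ssum = 0.0
                    for k2 in range(K):
                        ssum += G[k1, k2]
                    rowsum[k1] = ssum
                # gamete-2 move, emission, accumulate
                for k1 in range(K):
                    for k2 in range(K):
                        val = (omj * G[k1, k2] + jump * rowsum[k1] * alpha[k2]) * EMs[
                            l, k1, k2
                        ]
                        F[l, k1, k2] = val
                        tot += val
            cs[l] = tot
            inv = 1.0 / tot
            for k1 in range(K):
                for k2 in range(K):
                    F[l, k1, k2] *= inv
            loglik += np.log(tot)

        # ---------------- backward, posteriors, expectations ----------------
        for k1 in range(K):
            for k2 in range(K):
                B[k1, k2] = 1.0
        for l in range(m - 1, -1, -1):
            # posterior at locus l (B currently holds B_l)
            ptot = 0.0
            for k1 in range(K):
                for k2 in range(K):
                    val = F[l, k1, k2] * B[k1, k2]
                    P[k1, k2] = val
                    ptot += val
            pinv = 1.0 / ptot
            for k1 in range(K):
                m1 = 0.0
                for k2 in range(K):
                    P[k1, k2] *= pinv
                    m1 += P[k1, k2]
                marg1[k1] = m1
            for k2 in range(K):
                m2 = 0.0
                for k1 in range(K):
                    m2 += P[k1, k2]
                marg2[k2] = m2

            g = geno[a, l]
            if g == 0:
                for k in range(K):
                    c0[l, k] += marg1[k] + marg2[k]
            elif g == 2:
                for k in range(K):
                    c1[l, k] += marg1[k] + marg2[k]
            elif g == 1:
                for k1 in range(K):
                    t1 = theta[l, k1]
                    for k2 in range(K):
                        t2 = theta[l, k2]
                        wa = t1 * (1.0 - t2)
                        wb = (1.0 - t1) * t2
                        tot2 = wa + wb
                        if tot2 > 0.0:
                            fa = P[k1, k2] * wa / tot2
                            fb = P[k1, k2] * wb / tot2
                            c1[l, k1] += fa
                            c0[l, k2] += fa
                            c0[l, k1] += fb
                            c1[l, k2] += fb
            else:
                for k in range(K):
                    mk = marg1[k] + marg2[k]
                    c1[l, k] += mk * theta[l, k]
                    c0[l, k] += mk * (1.0 - theta[l, k])

            if l == 0:
                for k in range(K):
                    acount[k] += marg1[k] + marg2[k]

            if want_post:
                for k in range(K):
                    dosage[l, a, k] = marg1[k] + marg2[k]
                if g == MISSING:
                    p0 = 0.0
                    p2 = 0.0
                    for k1 in range(K):
                        t1 = theta[l, k1]
                        for k2 in range(K):
                            t2 = theta[l, k2]
                            p0 += P[k1, k2] * (1.0 - t1) * (1.0 - t2)
                            p2 += P[k1, k2] * t1 * t2
                    p1 = 1.0 - p0 - p2
                    best = 0
                    pb = p0
                    if p1 > pb:
                        best = 1
                        pb = p1
                    if p2 > pb:
                        best = 2
                    imputed[a, l] = best

            if l > 0:
                # jump expectations in interval (l-1, l) and B_{l-1}
                ci = 1.0 / cs[l]
                for k1 in range(K):
                    for k2 in range(K):
                        Mx[k1, k2] = EMs[l, k1, k2] * B[k1, k2] * ci
                for k2 in range(K):
                    ssum = 0.0
                    for k1 in range(K):
                        ssum += F[l - 1, k1, k2]
                    u[k2] = ssum
                for k1 in range(K):
                    ssum = 0.0
                    for k2 in range(K):
                        ssum += F[l - 1, k1, k2]
                    v[k1] = ssum
                for k in range(K):
                    w2p[k] = omj * u[k] + jump * alpha[k]
                    w1p[k] = omj * v[k] + jump * alpha[k]
                for k1 in range(K):
                    s1 = 0.0
                    for k2 in range(K):
                        s1 += w2p[k2] * Mx[k1, k2]
                    j1 = jump * alpha[k1] * s1
                    acount[k1] += j1
                    jumps += j1
                for k2 in range(K):
                    s2 = 0.0
                    for k1 in range(K):
                        s2 += w1p[k1] * Mx[k1, k2]
                    j2 = jump * alpha[k2] * s2
                    acount[k2] += j2
                    jumps += j2
                # B_{l-1}: reverse transition applied to Mx
                for k1 in range(K):
                    ssum = 0.0
                    for k2 in range(K):
                        ssum += Mx[k1, k2] * alpha[k2]
                    rowsum[k1] = ssum
                for k1 in range(K):
                    for k2 in range(K):
                        D[k1, k2] = omj * Mx[k1, k2] + jump * rowsum[k1]
                for k2 in range(K):
                    ssum = 0.0
                    for k1 in range(K):
                        ssum += alpha[k1] * D[k1, k2]
                    colsum[k2] = ssum
                for k1 in range(K):
                    for k2 in range(K):
                        B[k1, k2] = omj * D[k1, k2] + jump * colsum[k2]
    return loglik, c1, c0, acount, jumps


@dataclass
class AncestralHaplotypeModel:
    """Fitted haplotype-cluster HMM, one parameter block per chromosome."""

    K: int
    chroms: list[int]
    theta: dict  # chrom -> (m_c, K) emission allele-1 probabilities
    alpha: dict  # chrom -> (K,) state weights
    jump: dict  # chrom -> per-interval switch probability
    loglik_trace: dict  # chrom -> list of per-EM-pass log-likelihoods


@dataclass
class DosagePanel:
    """Per-position ancestral dosages H: (positions, animals, K), rows sum to 2."""

    animal_ids: list[str]
    marker_map: pd.DataFrame
    H: np.ndarray  # (m, n, K) float32


def fit_haplotype_hmm(
    panel: GenotypePanel,
    K: int = 20,
    n_em_iter: int = 25,
    seed: int = 0,
    jump_init: float = 0.02,
    fit_jump: bool = True,
    theta_prior: float = 1e-8,
) -> tuple[AncestralHaplotypeModel, DosagePanel, GenotypePanel]:
    """Fit the cluster HMM per chromosome and return model, dosages, imputation.

    EM runs ``n_em_iter`` parameter updates (0 returns the seeded
    initialisation); the recorded log-likelihood trace is non-decreasing.
    Missing genotypes in the returned panel are replaced by their
    posterior-mode count under the fitted model.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > 2 * panel.n_animals:
        raise ValueError("K exceeds the number of gametes in the panel")
    rng = np.random.default_rng(seed)
    chroms = list(np.unique(panel.marker_map["chrom"]))
    theta_d, alpha_d, jump_d, trace_d = {}, {}, {}, {}
    H_blocks = []
    imputed = panel.copy()
    chrom_arr = panel.marker_map["chrom"].to_numpy()
    for c in chroms:
        sel = np.where(chrom_arr == c)[0]
        geno = np.ascontiguousarray(panel.dosage[:, sel])
        n, m = geno.shape
        obs = geno != MISSING
        with np.errstate(invalid="ignore"):
            p_obs = np.where(obs, geno, 0).sum(0) / np.maximum(1, 2 * obs.sum(0))
        theta = np.clip(
            p_obs[:, None] + rng.normal(0.0, 0.1, size=(m, K)), 1e-3, 1 - 1e-3
        )
        alpha = rng.dirichlet(np.full(K, 5.0))
        jump = jump_init
        trace = []
        dummy_dos = np.zeros((1, 1, 1), dtype=np.float32)
        dummy_imp = np.zeros((1, 1), dtype=np.int8)
        for _ in range(n_em_iter):
            ll, c1, c0, acount, jumps = _em_pass(
                geno, theta, alpha, jump, False, dummy_dos, dummy_imp
            )
            trace.append(ll)
            theta = (c1 + theta_prior) / (c1 + c0 + 2 * theta_prior)
            theta = np.clip(theta, 1e-6, 1 - 1e-6)
            alpha = (acount + 1e-12) / (acount.sum() + K * 1e-12)
            if fit_jump and m > 1:
                jump = float(np.clip(jumps / (2.0 * (m - 1) * n), 1e-6, 0.5))
        dosage = np.zeros((m, n, K), dtype=np.float32)
        imp = geno.copy()
        ll, *_ = _em_pass(geno, theta, alpha, jump, True, dosage, imp)
        trace.append(ll)
        imputed.dosage[:, sel] = imp
        theta_d[c], alpha_d[c], jump_d[c], trace_d[c] = theta, alpha, jump, trace
        H_blocks.append(dosage)
    model = AncestralHaplotypeModel(
        K=K, chroms=chroms, theta=theta_d, alpha=alpha_d, jump=jump_d,
        loglik_trace=trace_d,
    )
    dosage_panel = DosagePanel(
        animal_ids=list(panel.animal_ids),
        marker_map=panel.marker_map.reset_index(drop=True),
        H=np.concatenate(H_blocks, axis=0),
    )
    return model, dosage_panel, imputed


# ---------------------------------------------------------------------------
# Two-step score test
# ---------------------------------------------------------------------------


def glascow_residuals(
    y_adj: np.ndarray,
    A: np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    return_fit: bool = False,
):
    """Residuals r = y_adj - 1 mu - u from an intercept-only animal model."""
    y_adj = np.asarray(y_adj, dtype=float)
    fit = reml_fit(y_adj, np.ones((len(y_adj), 1)), A=A, eig=eig)
    r = y_adj - fit.b_hat[0] - fit.u_hat
    if return_fit:
        return r, fit
    return r


def score_statistic(r: np.ndarray, H: np.ndarray) -> float:
    """T = 0.5 || H' r ||^2, the haplotype-variance score statistic."""
    q = np.asarray(H, dtype=float).T @ np.asarray(r, dtype=float)
    return float(0.5 * (q @ q))


def gamma_from_moments(mean: float, var: float) -> tuple[float, float]:
    """Moment-matched gamma (shape, scale) = (m^2/v, v/m)."""
    if mean <= 0 or var <= 0:
        raise ValueError("moments must be positive")
    return mean * mean / var, var / mean


@dataclass
class ScoreTestResult:
    T: float
    gamma_shape: float
    gamma_scale: float
    p: float
    degenerate: bool = False


def _null_scores(r: np.ndarray, H: np.ndarray, perm_T: np.ndarray) -> np.ndarray:
    q = H.T.astype(float) @ perm_T  # (K, n_perm)
    return 0.5 * (q * q).sum(axis=0)


def _permutation_matrix(r: np.ndarray, n_perm: int, rng: np.random.Generator):
    n = len(r)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    return np.asarray(r, dtype=float)[idx].T  # (n, n_perm)


def gamma_null_pvalue(
    T_obs: float,
    r: np.ndarray,
    H: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> ScoreTestResult:
    """Gamma-approximated upper-tail p of T under permutation of residuals."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    perm_T = _permutation_matrix(r, n_perm, rng)
    null_T = _null_scores(np.asarray(r, dtype=float), np.asarray(H, float), perm_T)
    m = float(null_T.mean())
    v = float(null_T.var(ddof=1))
    if v <= 0 or m <= 0:
        return ScoreTestResult(T=T_obs, gamma_shape=np.nan, gamma_scale=np.nan,
                               p=1.0, degenerate=True)
    shape, scale = gamma_from_moments(m, v)
    p = float(gamma_dist.sf(T_obs, a=shape, scale=scale))
    return ScoreTestResult(T=T_obs, gamma_shape=shape, gamma_scale=scale,
                           p=max(p, _P_FLOOR))


def rotate_dosages(
    dosages: DosagePanel, eig: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Precompute U' H_i for every position (reused by the analytic null).

    The rotation depends only on the relationship matrix, so one pass
    serves every phenotype replicate scanned against the same pedigree.
    """
    _, U = eig
    m, n, K = dosages.H.shape
    out = np.empty((m, n, K), dtype=np.float32)
    Ut = U.T
    for i in range(m):
        out[i] = Ut @ dosages.H[i].astype(float)
    return out


def _analytic_null_pieces(fit, eig):
    """Diagonal + rank-1 representation of Cov(r) in the eigenbasis of A.

    Under sigma_h^2 = 0, r = sigma_e^2 V^{-1} Q y_adj with Q the GLS
    mean-centering projector, giving
    Cov(r) = sigma_e^4 (V^{-1} - V^{-1} 1 c 1' V^{-1}).
    Returns (d, z) with U' Cov(r) U = diag(d) - z z'.
    """
    s, U = eig
    sigma2 = fit.sigma2_u + fit.sigma2_e
    w = fit.h2 * s + (1.0 - fit.h2)
    ones_t = U.T @ np.ones(len(s))
    vinv_diag = 1.0 / (sigma2 * w)
    c = 1.0 / float(ones_t * ones_t @ vinv_diag)
    d = fit.sigma2_e**2 * vinv_diag
    z = fit.sigma2_e * vinv_diag * ones_t * np.sqrt(c)
    return d, z


def hap_scan(
    y_adj: np.ndarray,
    dosages: DosagePanel,
    A: np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    position_idx: np.ndarray | None = None,
    null: str = "analytic",
    n_perm: int = 1000,
    seed: int = 0,
    rotated: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score test at each tested position with a gamma-approximated null.

    ``null='analytic'`` (default) moment-matches the gamma to the exact
    mean/variance of the quadratic form T under the fitted null mixed model;
    ``null='permutation'`` moment-matches to ``n_perm`` permutations of the
    residuals instead. ``position_idx`` restricts the scan;
    ``rotated`` (from :func:`rotate_dosages`) skips the per-position
    rotation in replicate loops.
    """
    y_adj = np.asarray(y_adj, dtype=float)
    if eig is None:
        if A is None:
            raise ValueError("need A or its eigendecomposition")
        eig = eigendecompose(A)
    r, fit = glascow_residuals(y_adj, eig=eig, return_fit=True)
    idx = np.arange(dosages.H.shape[0]) if position_idx is None else np.asarray(position_idx)
    rows = []
    if null == "analytic":
        d, z = _analytic_null_pieces(fit, eig)
        _, U = eig
        for i in idx:
            if rotated is not None:
                G = rotated[i].astype(float)
            else:
                G = U.T @ dosages.H[i].astype(float)
            T = score_statistic(r, dosages.H[i].astype(float))
            S = G.T @ (d[:, None] * G)
            gz = G.T @ z
            S -= np.outer(gz, gz)
            m = 0.5 * float(np.trace(S))
            v = 0.5 * float((S * S).sum())
            if v <= 0 or m <= 0:
                rows.append((T, np.nan, np.nan, 1.0, True))
                continue
            shape, scale = gamma_from_moments(m, v)
            p = max(float(gamma_dist.sf(T, a=shape, scale=scale)), _P_FLOOR)
            rows.append((T, shape, scale, p, False))
    elif null == "permutation":
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        rng = np.random.default_rng(seed)
        perm_T = _permutation_matrix(r, n_perm, rng)
        for i in idx:
            H = dosages.H[i].astype(float)
            T = score_statistic(r, H)
            null_T = _null_scores(r, H, perm_T)
            m = float(null_T.mean())
            v = float(null_T.var(ddof=1))
            if v <= 0 or m <= 0:
                rows.append((T, np.nan, np.nan, 1.0, True))
                continue
            shape, scale = gamma_from_moments(m, v)
            p = max(float(gamma_dist.sf(T, a=shape, scale=scale)), _P_FLOOR)
            rows.append((T, shape, scale, p, False))
    else:
        raise ValueError(f"unknown null mode {null!r}")
    out = pd.DataFrame(
        rows, columns=["T", "gamma_shape", "gamma_scale", "p", "degenerate"]
    )
    mm = dosages.marker_map.iloc[idx]
    out.insert(0, "snp_id", mm["snp_id"].to_numpy())
    out.insert(1, "chrom", mm["chrom"].to_numpy())
    out.insert(2, "pos_bp", mm["pos_bp"].to_numpy())
    return out
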