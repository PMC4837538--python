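"""Per-SNP linear mixed-model association on adjusted phenotypes.

Each SNP is tested in y_adj = beta_i w_i + u + e'_i with u ~ N(0, A s_u^2),
e' ~ N(0, I s_e^2). A single eigendecomposition of A is shared across SNPs;
by default the polygenic/residual variance ratio is re-optimised per SNP on
the profiled restricted likelihood (the exact-LMM construction popularised
by GEMMA), with a fast mode that freezes the null-model ratio. The Wald
statistic (beta/se)^2 is referred to chi-square with 1 df.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .popsim import MISSING, GenotypePanel
from .reml import _restricted_ll, eigendecompose, _H2_EPS


def proportion_variance(p: float, beta: float, V_P: float) -> float:
    """Phenotypic-variance fraction 2 p (1-p) beta^2 / V_P of one SNP."""
    if V_P <= 0:
        raise ValueError("V_P must be positive")
    if not 0 < p < 1:
        raise ValueError("allele frequency must be in (0, 1)")
    prop = 2.0 * p * (1.0 - p) * beta * beta / V_P
    if prop > 1.0:
        warnings.warn("proportion of variance exceeds 1; capped", stacklevel=2)
        prop = 1.0
    return prop


def _wald_at(h2, yt, Xt, s):
    """GLS beta/se for the SNP column (last column of Xt) at a given ratio."""
    n, p = Xt.shape
    w = h2 * s + (1.0 - h2)
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    XtWXi = np.linalg.inv(XtWX)
    beta = XtWXi @ (Xw.T @ yt)
    resid = yt - Xt @ beta
    sigma2 = float(resid @ (resid / w)) / (n - p)
    se = np.sqrt(sigma2 * XtWXi[-1, -1])
    return float(beta[-1]), float(se)


def lmm_scan(
    y_adj: np.ndarray,
    panel: GenotypePanel,
    A: np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    snp_idx: np.ndarray | None = None,
    per_snp_ratio: bool = True,
    null_h2: float | None = None,
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Mixed-model Wald scan; returns one row per tested SNP.

    Missing dosages are mean-imputed per SNP before testing. SNPs
    monomorphic after missing-handling are flagged (``tested = False``) and
    carry NaN statistics. ``snp_idx`` restricts the scan (e.g. to a window
    around a simulated QTL); statistics are unaffected by the restriction.
    """
    y_adj = np.asarray(y_adj, dtype=float)
    if eig is None:
        if A is None:
            eig = (np.ones(len(y_adj)), np.eye(len(y_adj)))
        else:
            eig = eigendecompose(A)
    s, U = eig
    yt = U.T @ y_adj
    ones_t = U.T @ np.ones(len(y_adj))
    idx = np.arange(panel.n_snps) if snp_idx is None else np.asarray(snp_idx)

    if null_h2 is None and not per_snp_ratio:
        Xt0 = ones_t[:, None]  # intercept-only null model
        res = minimize_scalar(
            lambda h: -_restricted_ll(h, yt, Xt0, s)[0],
            bounds=(_H2_EPS, 1 - _H2_EPS),
            method="bounded",
        )
        null_h2 = float(res.x)

    V_P = float(np.var(y_adj))
    rows = []
    for j in idx:
        g = panel.dosage[:, j].astype(float)
        obs = g != MISSING
        if obs.sum() == 0:
            rows.append((panel.marker_map["snp_id"].iloc[j], np.nan) + (np.nan,) * 4 + (False,))
            continue
        mean_g = g[obs].mean()
        g[~obs] = mean_g
        eaf = mean_g / 2.0
        if g.var() == 0 or not 0 < eaf < 1:
            rows.append((panel.marker_map["snp_id"].iloc[j], eaf) + (np.nan,) * 4 + (False,))
            continue
        gt = U.T @ g
        Xt = np.column_stack([ones_t, gt]) if add_intercept else gt[:, None]
        if per_snp_ratio:
            res = minimize_scalar(
                lambda h: -_restricted_ll(h, yt, Xt, s)[0],
                bounds=(_H2_EPS, 1 - _H2_EPS),
                method="bounded",
                options={"xatol": 1e-6},
            )
            h2_j = float(res.x)
        else:
            h2_j = null_h2
        beta, se = _wald_at(h2_j, yt, Xt, s)
        wald = (beta / se) ** 2
        p_val = float(chi2.sf(wald, df=1))
        prop = proportion_variance(eaf, beta, V_P) if V_P > 0 else np.nan
        rows.append(
            (panel.marker_map["snp_id"].iloc[j], eaf, beta, se, max(p_val, 5e-324), prop, True)
        )
    out = pd.DataFrame(
        rows, columns=["snp_id", "eaf", "beta", "se", "wald_p", "proportion", "tested"]
    )
    out.insert(1, "chrom", panel.marker_map["chrom"].iloc[idx].to_numpy())
    out.insert(2, "pos_bp", panel.marker_map["pos_bp"].iloc[idx].to_numpy())
    return out
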