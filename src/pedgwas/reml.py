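"""Animal-model REML: y = Xb + Zu + e with u ~ N(0, A sigma_u^2).

Variance components are estimated by maximising the restricted likelihood
profiled over the heritability ratio on the eigendecomposition of A (one
decomposition serves any number of fits on the same pedigree, which the
replicate-heavy power study exploits). For the two-component animal model
this profile is one-dimensional, so a coarse-grid bracket followed by
bounded Brent refinement finds the REML optimum directly; the fit records
the likelihood evaluations it made.

Records are assumed single-per-animal (Z = I after alignment with the
pedigree ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

_H2_EPS = 1e-6


def design_matrix(
    sex: np.ndarray | pd.Series, generation: np.ndarray | pd.Series
) -> np.ndarray:
    """Intercept + treatment-coded sex and generation effects."""
    df = pd.DataFrame({"sex": pd.Categorical(sex), "gen": pd.Categorical(generation)})
    X = [np.ones((len(df), 1))]
    for col in ("sex", "gen"):
        d = pd.get_dummies(df[col], drop_first=True).to_numpy(dtype=float)
        if d.shape[1]:
            X.append(d)
    return np.hstack(X)


def eigendecompose(A: np.ndarray, jitter: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition of A with a tiny diagonal ridge.

    Returns ``(s, U)`` with ``A + jitter*I = U diag(s) U'``; reuse across
    fits on the same relationship matrix.
    """
    s, U = np.linalg.eigh(A + jitter * np.eye(A.shape[0]))
    return np.maximum(s, 0.0), U


@dataclass
class AnimalModelFit:
    sigma2_u: float
    sigma2_e: float
    h2: float
    b_hat: np.ndarray
    u_hat: np.ndarray
    y_adj: np.ndarray
    loglik: float
    trace: pd.DataFrame = field(repr=False)
    converged: bool = True

    @property
    def boundary(self) -> bool:
        return self.h2 <= 2 * _H2_EPS or self.h2 >= 1 - 2 * _H2_EPS


def _restricted_ll(h2: float, yt: np.ndarray, Xt: np.ndarray, s: np.ndarray):
    """Profiled restricted log-likelihood at heritability ``h2`` (+ GLS pieces)."""
    n, p = Xt.shape
    w = h2 * s + (1.0 - h2)
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    cho = np.linalg.cholesky(XtWX)
    beta = np.linalg.solve(XtWX, XtWy)
    resid = yt - Xt @ beta
    rss = float(resid @ (resid / w))
    sigma2 = rss / (n - p)
    ll = -0.5 * (
        (n - p) * np.log(sigma2)
        + np.log(w).sum()
        + 2.0 * np.log(np.diag(cho)).sum()
        + (n - p)
    )
    return ll, beta, sigma2, w, resid


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    A: np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    n_grid: int = 21,
    tol: float = 1e-8,
) -> AnimalModelFit:
    """REML fit of the animal model; pass ``eig`` to reuse a decomposition.

    The heritability profile is evaluated on a coarse grid, then refined by
    bounded Brent search in the bracketing interval; boundary estimates
    (h2 -> 0 or 1) are reported, not raised.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X row counts disagree")
    if eig is None:
        if A is None:
            raise ValueError("need A or its eigendecomposition")
        eig = eigendecompose(A)
    s, U = eig
    yt = U.T @ y
    Xt = U.T @ X

    grid = np.linspace(_H2_EPS, 1.0 - _H2_EPS, n_grid)
    evals = []

    def nll(h2: float) -> float:
        ll = _restricted_ll(h2, yt, Xt, s)[0]
        evals.append((h2, ll))
        return -ll

    vals = np.array([nll(h) for h in grid])
    k = int(vals.argmin())
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded", options={"xatol": tol})
    h2_hat = float(res.x) if res.fun <= vals[k] else float(grid[k])

    ll, beta, sigma2, w, resid = _restricted_ll(h2_hat, yt, Xt, s)
    sigma2_u = h2_hat * sigma2
    sigma2_e = (1.0 - h2_hat) * sigma2
    # BLUP: u = sigma2_u A V^{-1} (y - Xb) = h2 U diag(s/w) U' resid_rot
    u_hat = U @ (h2_hat * s / w * resid)
    y_adj = y - X @ beta
    trace = pd.DataFrame(sorted(evals), columns=["h2", "restricted_ll"])
    return AnimalModelFit(
        sigma2_u=sigma2_u,
        sigma2_e=sigma2_e,
        h2=h2_hat,
        b_hat=beta,
        u_hat=u_hat,
        y_adj=y_adj,
        loglik=ll,
        trace=trace,
    )


def adjust_phenotypes(y: np.ndarray, X: np.ndarray, b_hat: np.ndarray) -> np.ndarray:
    """y_adj = y - X b_hat (exact affine residual, no rescaling)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    b = np.asarray(b_hat, dtype=float)
    if X.shape != (y.shape[0], b.shape[0]):
        raise ValueError("shape mismatch between y, X and b_hat")
    return y - X @ b
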