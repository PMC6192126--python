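"""Quasi-Poisson (overdispersion-adjusted Poisson) log-link GLM.

Point estimates are the Poisson maximum-likelihood estimates obtained by
iteratively reweighted least squares; overdispersion enters only through the
Pearson scale phi = X^2 / (n - p), which multiplies the inverse Fisher
information to give the quasi-likelihood covariance.  Fisher scoring with the
canonical log link is exact Newton-Raphson here, so convergence is quadratic;
the implementation is kept lean because the bootstrap refits it thousands of
times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

_MAX_ETA = 30.0  # exp(30) ~ 1e13; guards overflow in degenerate iterations


class FitError(RuntimeError):
    """Raised on non-convergence or a rank-deficient design."""


@dataclass
class QuasiPoissonFit:
    """Fitted quasi-Poisson GLM.

    ``params``/``cov`` are indexed by design-column name; ``scale`` is the
    Pearson dispersion estimate; ``dropped`` lists design columns removed
    for zero support before fitting.
    """

    params: pd.Series
    cov: pd.DataFrame
    scale: float
    n_obs: int
    df_resid: int
    converged: bool
    n_iter: int
    pearson_chi2: float
    dropped: list[str] = field(default_factory=list)
    # retained for influence-function computations (delta-method contrasts)
    X: np.ndarray | None = None
    y: np.ndarray | None = None
    mu: np.ndarray | None = None
    columns: list[str] = field(default_factory=list)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def wald_table(self) -> pd.DataFrame:
        se = self.bse
        z = self.params / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({"coef": self.params, "se": se, "z": z, "p": p})


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # QR with column pivoting: columns beyond the numerical rank are the
        # ones expressible from earlier pivots.
        _, r, piv = sla.qr(X, mode="economic", pivoting=True)
        tol = np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = [columns[j] for j in piv[np.sum(np.abs(np.diag(r)) > tol):]]
        raise FitError(f"design is rank deficient; collinear columns: {bad}")


def irls_poisson(
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Poisson ML via IRLS.  Returns (beta, fitted mu, iterations, converged)."""
    n, p = X.shape
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    if start is None:
        ybar = y.mean()
        beta[0] = np.log(ybar) if ybar > 0 else -1.0
    dev_old = np.inf
    mu = None
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -_MAX_ETA, _MAX_ETA)
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        Xw = X * mu[:, None]
        try:
            beta = np.linalg.solve(Xw.T @ X, Xw.T @ z)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular weighted design at iteration {it}") from exc
        eta = np.clip(X @ beta, -_MAX_ETA, _MAX_ETA)
        mu = np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 2.0 * np.sum(np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu))
        if abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            return beta, mu, it, True
        dev_old = dev
    return beta, mu, max_iter, False


def fit_quasi_poisson(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    drop_zero_support: bool = True,
    start: pd.Series | None = None,
    keep_data: bool = True,
) -> QuasiPoissonFit:
    """Fit the overdispersion-adjusted Poisson GLM on a named design matrix.

    Columns with zero support (identically zero) are dropped and recorded.
    The covariance is phi * (X' W X)^-1 with W = diag(mu) and phi the Pearson
    dispersion; point estimates coincide with the unadjusted Poisson MLE.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError("response must be finite and nonnegative")
    dropped: list[str] = []
    if drop_zero_support:
        support = (X != 0).any(axis=0)
        dropped = [c for c in X.columns if not support[c]]
        if dropped:
            X = X.loc[:, support]
    columns = list(X.columns)
    Xv = np.ascontiguousarray(X.to_numpy(dtype=float))
    n, p = Xv.shape
    if n <= p:
        raise FitError(f"need more rows ({n}) than parameters ({p})")
    _check_rank(Xv, columns)

    start_v = None
    if start is not None:
        start_v = start.reindex(columns).fillna(0.0).to_numpy()
    beta, mu, n_iter, converged = irls_poisson(Xv, y, start=start_v)
    if not converged:
        raise FitError(f"IRLS did not converge in {n_iter} iterations")

    pearson = float(np.sum((y - mu) ** 2 / mu))
    df_resid = n - p
    scale = pearson / df_resid
    info = (Xv * mu[:, None]).T @ Xv
    cov = scale * np.linalg.inv(info)
    return QuasiPoissonFit(
        params=pd.Series(beta, index=columns),
        cov=pd.DataFrame(cov, index=columns, columns=columns),
        scale=scale,
        n_obs=n,
        df_resid=df_resid,
        converged=converged,
        n_iter=n_iter,
        pearson_chi2=pearson,
        dropped=dropped,
        X=Xv if keep_data else None,
        y=y if keep_data else None,
        mu=mu if keep_data else None,
        columns=columns,
    )
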