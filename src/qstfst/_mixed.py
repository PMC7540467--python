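"""Gaussian mixed-model engine used by the variance-component estimators.

Model: y = X beta + sum_k Z_k u_k + e with u_k ~ N(0, sigma_k^2 I) and
e ~ N(0, sigma^2 I), all independent.  The likelihood is profiled over
sigma^2 by working with the variance ratios gamma_k = sigma_k^2 / sigma^2:

    V = sigma^2 H,  H = I + sum_k gamma_k Z_k Z_k'

All solves go through the q x q matrix M = I_q + D Z'Z D with
D = diag(sqrt(gamma)) expanded over the random-effect columns, so one
likelihood evaluation costs a Cholesky of size q (total number of
random-effect levels), never n.  Ratios are optimised by L-BFGS-B under a
zero lower bound, which lets estimates sit exactly on the boundary.

This engine serves both REML fits (variance components, heritability,
bootstrap refits) and ML fits (fixed-effect likelihood-ratio tests), so it
is deliberately free of any study-specific vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

_LOG2PI = float(np.log(2.0 * np.pi))


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class DesignError(ValueError):
    """Design too degenerate to identify the requested components."""


def indicator_matrix(codes: np.ndarray) -> np.ndarray:
    """Dense 0/1 incidence matrix from integer level codes."""
    codes = np.asarray(codes)
    q = codes.max() + 1
    Z = np.zeros((codes.size, q))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


@dataclass
class MixedFit:
    beta: np.ndarray
    beta_cov: np.ndarray
    sigma2: float  # residual variance
    gamma: np.ndarray  # variance ratios per random term
    variances: np.ndarray  # sigma_k^2 = gamma_k * sigma2
    loglik: float
    method: str  # "reml" | "ml"
    converged: bool
    n_obs: int


class MixedModel:
    """One design: fixed matrix X and named random-effect indicator blocks."""

    def __init__(self, y: np.ndarray, X: np.ndarray, random_terms: dict[str, np.ndarray]):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.n, self.p = self.X.shape
        if self.y.shape != (self.n,):
            raise ValueError("y and X have incompatible shapes")
        self.term_names = list(random_terms)
        Zs = []
        self.block_slices = []
        start = 0
        for name in self.term_names:
            Z = np.asarray(random_terms[name], dtype=float)
            Zs.append(Z)
            self.block_slices.append(slice(start, start + Z.shape[1]))
            start += Z.shape[1]
        self.Z = np.concatenate(Zs, axis=1) if Zs else np.zeros((self.n, 0))
        self.q = self.Z.shape[1]
        # cross-products reused by every likelihood evaluation
        self.ZtZ = self.Z.T @ self.Z
        self.ZtX = self.Z.T @ self.X
        self.Zty = self.Z.T @ self.y
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    def with_y(self, y: np.ndarray) -> "MixedModel":
        """Same design, new response; reuses the expensive cross-products."""
        other = object.__new__(MixedModel)
        other.__dict__.update(self.__dict__)
        other.y = np.asarray(y, dtype=float)
        if other.y.shape != (self.n,):
            raise ValueError("response length does not match the design")
        other.Zty = self.Z.T @ other.y
        other.Xty = self.X.T @ other.y
        other.yty = float(other.y @ other.y)
        return other

    def _expand(self, gamma: np.ndarray) -> np.ndarray:
        d = np.empty(self.q)
        for g, sl in zip(gamma, self.block_slices):
            d[sl.start : sl.stop] = np.sqrt(max(g, 0.0))
        return d

    def _core(self, gamma: np.ndarray):
        """Factorise M and return GLS pieces for H = I + Z Gamma Z'."""
        d = self._expand(gamma)
        M = self.ZtZ * np.outer(d, d)
        M[np.diag_indices_from(M)] += 1.0
        cf = cho_factor(M, lower=True, check_finite=False)
        logdetH = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        DZtX = d[:, None] * self.ZtX
        DZty = d * self.Zty
        MiDZtX = cho_solve(cf, DZtX, check_finite=False)
        MiDZty = cho_solve(cf, DZty, check_finite=False)
        XtHiX = self.XtX - DZtX.T @ MiDZtX
        XtHiy = self.Xty - DZtX.T @ MiDZty
        ytHiy = self.yty - DZty @ MiDZty
        return logdetH, XtHiX, XtHiy, ytHiy

    def _profiled_negloglik(self, gamma: np.ndarray, method: str) -> float:
        try:
            logdetH, XtHiX, XtHiy, ytHiy = self._core(gamma)
            cfx = cho_factor(XtHiX, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return np.inf
        beta = cho_solve(cfx, XtHiy, check_finite=False)
        rss = max(ytHiy - XtHiy @ beta, 1e-300)
        if method == "reml":
            df = self.n - self.p
            logdetXtHiX = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
            ll = -0.5 * (df * (_LOG2PI + np.log(rss / df) + 1.0) + logdetH + logdetXtHiX)
        else:
            ll = -0.5 * (self.n * (_LOG2PI + np.log(rss / self.n) + 1.0) + logdetH)
        return -ll

    def _negloglik_and_grad(self, gamma: np.ndarray, method: str):
        """Profiled criterion and its analytic gradient in the ratios.

        Uses tr(H^-1 Z_k Z_k') (ML) or tr(P Z_k Z_k') (REML) together with
        the envelope identity d(y'Py)/dgamma_k = -|Z_k' P y|^2; everything
        is assembled from the q x q factorisation, never an n x n matrix.
        """
        d = self._expand(gamma)
        M = self.ZtZ * np.outer(d, d)
        M[np.diag_indices_from(M)] += 1.0
        try:
            cf = cho_factor(M, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(gamma)
        logdetH = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        W = d[:, None] * self.ZtZ  # D Z'Z
        DZtX = d[:, None] * self.ZtX
        DZty = d * self.Zty
        S = cho_solve(cf, np.concatenate([W, DZtX, DZty[:, None]], axis=1),
                      check_finite=False)
        MiW, MiDZtX, MiDZty = S[:, : self.q], S[:, self.q : self.q + self.p], S[:, -1]
        XtHiX = self.XtX - DZtX.T @ MiDZtX
        XtHiy = self.Xty - DZtX.T @ MiDZty
        ytHiy = self.yty - DZty @ MiDZty
        try:
            cfx = cho_factor(XtHiX, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros_like(gamma)
        beta = cho_solve(cfx, XtHiy, check_finite=False)
        rss = max(ytHiy - XtHiy @ beta, 1e-300)

        ZtHiZ_diag = np.diag(self.ZtZ) - np.einsum("ij,ij->j", W, MiW)
        ZtHiX = self.ZtX - W.T @ MiDZtX  # (q, p)
        ZtHiy = self.Zty - W.T @ MiDZty
        ZtPy = ZtHiy - ZtHiX @ beta
        if method == "reml":
            df = self.n - self.p
            logdetXtHiX = 2.0 * float(np.sum(np.log(np.diag(cfx[0]))))
            nll = 0.5 * (df * (_LOG2PI + np.log(rss / df) + 1.0) + logdetH + logdetXtHiX)
            C = cho_solve(cfx, ZtHiX.T, check_finite=False)  # (p, q)
            tr_diag = ZtHiZ_diag - np.einsum("qp,pq->q", ZtHiX, C)
            scale = df
        else:
            nll = 0.5 * (self.n * (_LOG2PI + np.log(rss / self.n) + 1.0) + logdetH)
            tr_diag = ZtHiZ_diag
            scale = self.n
        grad = np.empty(len(self.block_slices))
        for k, sl in enumerate(self.block_slices):
            t1 = float(np.sum(tr_diag[sl.start : sl.stop]))
            t2 = float(np.sum(ZtPy[sl.start : sl.stop] ** 2))
            grad[k] = 0.5 * (t1 - scale * t2 / rss)
        return nll, grad

    def fit(self, method: str = "reml", starts=None, tol: float = 1e-10) -> MixedFit:
        """Maximise the profiled (restricted) likelihood over the ratios.

        The response is standardised internally (the ratios are scale-free),
        so trait units never affect conditioning; estimates are mapped back
        to the original scale, including the likelihood value.
        """
        if method not in ("reml", "ml"):
            raise ValueError(method)
        scale = float(np.std(self.y))
        if scale > 0 and not (0.5 < scale < 2.0):
            return self.with_y(self.y / scale)._fit_unit(method, starts, tol, scale)
        return self._fit_unit(method, starts, tol, 1.0)

    def _fit_unit(self, method: str, starts, tol: float, scale: float) -> MixedFit:
        k = len(self.term_names)
        if self.n <= self.p and method == "reml":
            raise DesignError("no residual degrees of freedom")
        if starts is None:
            starts = [np.full(k, 0.5), np.full(k, 0.05)]
        best = None
        for x0 in starts:
            res = minimize(
                self._negloglik_and_grad,
                np.asarray(x0, dtype=float),
                args=(method,),
                jac=True,
                method="L-BFGS-B",
                bounds=[(0.0, 1e8)] * k,
                options={"ftol": tol, "gtol": 1e-8, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("likelihood optimisation failed", best)
        gamma = np.maximum(best.x, 0.0)
        gamma[gamma < 1e-10] = 0.0  # snap numerically-zero ratios onto the boundary

        logdetH, XtHiX, XtHiy, ytHiy = self._core(gamma)
        cfx = cho_factor(XtHiX, lower=True, check_finite=False)
        beta = cho_solve(cfx, XtHiy, check_finite=False)
        rss = max(ytHiy - XtHiy @ beta, 0.0)
        df = self.n - self.p if method == "reml" else self.n
        sigma2 = rss / df
        beta_cov = sigma2 * cho_solve(cfx, np.eye(self.p), check_finite=False)
        loglik = -self._profiled_negloglik(gamma, method) - df * np.log(scale)
        return MixedFit(
            beta=beta * scale,
            beta_cov=beta_cov * scale**2,
            sigma2=float(sigma2 * scale**2),
            gamma=gamma,
            variances=gamma * sigma2 * scale**2,
            loglik=float(loglik),
            method=method,
            converged=bool(best.success),
            n_obs=self.n,
        )
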