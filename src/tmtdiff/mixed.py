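"""Restricted-maximum-likelihood estimation for small variance-component
models of the form

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma_k^2 I),  e ~ N(0, sigma^2 I)

The problems solved here are tiny (n in the tens to low hundreds, at most a
handful of variance components), so the implementation works with dense
matrices and profiles beta and sigma^2 out of the REML criterion, leaving an
optimization (with analytic gradient) over the variance ratios
theta_k = sigma_k^2 / sigma^2 >= 0.

Satterthwaite degrees of freedom for a fixed-effect contrast are computed
from the observed information of the unprofiled REML log-likelihood via
finite differences, following the approach popularized by lmerTest.  The
information matrix is computed once per fit and shared by all contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

_SINGULAR_TOL = 1e-6  # variance ratio below which a component counts as zero
_MAX_DF = 1e6


def indicator_matrix(codes) -> np.ndarray:
    """0/1 design matrix from arbitrary (factorizable) level codes."""
    codes = np.asarray(codes)
    levels, inv = np.unique(codes, return_inverse=True)
    Z = np.zeros((codes.size, levels.size))
    Z[np.arange(codes.size), inv] = 1.0
    return Z


@dataclass
class MixedFitResult:
    beta: np.ndarray
    cov_beta_unit: np.ndarray  # (X' V(theta)^-1 X)^-1, to be scaled by sigma2
    sigma2: float
    varcomps: dict  # name -> sigma_k^2
    theta: np.ndarray
    converged: bool
    singular: bool
    residual_df: float
    n_obs: int
    _information: np.ndarray | None = field(default=None, repr=False)
    _active: np.ndarray | None = field(default=None, repr=False)


class VarCompModel:
    """One protein's mixed model: fixed design ``X`` plus iid random terms."""

    def __init__(self, y, X, random_terms: dict):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.names = list(random_terms)
        self.Z = {name: indicator_matrix(codes) for name, codes in random_terms.items()}
        self.G = [self.Z[name] @ self.Z[name].T for name in self.names]
        self.k = len(self.names)
        self._eye = np.eye(self.n)

    # -- profiled REML criterion over theta = sigma_k^2 / sigma^2 ----------

    def _decompose(self, theta):
        V = self._eye.copy()
        for t, G in zip(theta, self.G):
            V += t * G
        cho = linalg.cho_factor(V, lower=True, check_finite=False)
        logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))
        Vi_y = linalg.cho_solve(cho, self.y, check_finite=False)
        Vi_X = linalg.cho_solve(cho, self.X, check_finite=False)
        XtViX = self.X.T @ Vi_X
        return cho, logdetV, Vi_y, Vi_X, XtViX

    def _fun_and_grad(self, theta):
        theta = np.maximum(theta, 0.0)
        try:
            cho, logdetV, Vi_y, Vi_X, XtViX = self._decompose(theta)
            sign, logdetX = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return np.inf, np.zeros(self.k)
            B = np.linalg.inv(XtViX)
            beta = B @ (self.X.T @ Vi_y)
        except (linalg.LinAlgError, np.linalg.LinAlgError):
            return np.inf, np.zeros(self.k)
        rtil = Vi_y - Vi_X @ beta  # = V^-1 (y - X beta)
        r = self.y - self.X @ beta
        q = float(r @ rtil)
        q = max(q, 1e-300)
        f = logdetV + logdetX + (self.n - self.p) * np.log(q)
        grad = np.zeros(self.k)
        for k, name in enumerate(self.names):
            Zk = self.Z[name]
            Vi_Zk = linalg.cho_solve(cho, Zk, check_finite=False)
            tr1 = float(np.sum(Zk * Vi_Zk))
            WZ = Vi_X.T @ Zk  # p x q_k
            tr2 = float(np.sum((B @ WZ) * WZ))
            a = Zk.T @ rtil
            grad[k] = tr1 - tr2 - (self.n - self.p) * float(a @ a) / q
        return f, grad

    def neg2_reml(self, theta) -> float:
        return self._fun_and_grad(np.asarray(theta, dtype=float))[0]

    def fit(self) -> MixedFitResult:
        if self.n <= self.p:
            raise ValueError("not enough observations to estimate residual variance")
        if self.k == 0:
            theta = np.zeros(0)
            converged = True
        else:
            best = None
            for start in ([0.2] * self.k, [2.0] * self.k):
                res = optimize.minimize(
                    self._fun_and_grad,
                    np.asarray(start, dtype=float),
                    jac=True,
                    method="L-BFGS-B",
                    bounds=[(0.0, 1e8)] * self.k,
                )
                if best is None or res.fun < best.fun:
                    best = res
            theta = np.maximum(best.x, 0.0)
            converged = bool(best.success) and np.isfinite(best.fun)

        cho, _, Vi_y, Vi_X, XtViX = self._decompose(theta)
        beta = np.linalg.solve(XtViX, self.X.T @ Vi_y)
        r = self.y - self.X @ beta
        q = float(r @ linalg.cho_solve(cho, r, check_finite=False))
        sigma2 = max(q, 0.0) / (self.n - self.p)
        cov_unit = np.linalg.inv(XtViX)
        singular = bool(np.any(theta < _SINGULAR_TOL)) if self.k else False
        varcomps = {name: float(t * sigma2) for name, t in zip(self.names, theta)}

        full = np.hstack([self.X] + [self.Z[name] for name in self.names])
        rank = np.linalg.matrix_rank(full)
        residual_df = float(self.n - rank)

        return MixedFitResult(
            beta=beta,
            cov_beta_unit=cov_unit,
            sigma2=float(sigma2),
            varcomps=varcomps,
            theta=theta,
            converged=converged,
            singular=singular,
            residual_df=residual_df,
            n_obs=self.n,
        )

    # -- contrast variance & Satterthwaite df in absolute variances --------

    def _phi(self, fit: MixedFitResult) -> np.ndarray:
        return np.concatenate([[fit.sigma2], [fit.varcomps[n] for n in self.names]])

    def _v_full(self, phi) -> np.ndarray:
        V = phi[0] * self._eye
        for s, G in zip(phi[1:], self.G):
            V += s * G
        return V

    def _cov_full(self, phi) -> np.ndarray:
        V = self._v_full(phi)
        Vi_X = np.linalg.solve(V, self.X)
        return np.linalg.inv(self.X.T @ Vi_X)

    def contrast_variance(self, c, fit: MixedFitResult, sigma2=None) -> float:
        """Variance of c'beta_hat; ``sigma2`` overrides the residual variance
        (used to plug in a moderated estimate)."""
        phi = self._phi(fit)
        if sigma2 is not None:
            phi = phi.copy()
            phi[0] = sigma2
        if np.all(phi <= 0):
            return 0.0
        return float(c @ self._cov_full(phi) @ c)

    def _neg2_reml_phi(self, phi) -> float:
        if phi[0] <= 0 or np.any(phi[1:] < 0):
            return np.inf
        try:
            V = self._v_full(phi)
            cho = linalg.cho_factor(V, lower=True, check_finite=False)
            logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))
            Vi_y = linalg.cho_solve(cho, self.y, check_finite=False)
            Vi_X = linalg.cho_solve(cho, self.X, check_finite=False)
            XtViX = self.X.T @ Vi_X
            sign, logdetX = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return np.inf
            beta = np.linalg.solve(XtViX, self.X.T @ Vi_y)
            r = self.y - self.X @ beta
            q = float(r @ linalg.cho_solve(cho, r, check_finite=False))
        except (linalg.LinAlgError, np.linalg.LinAlgError):
            return np.inf
        return logdetV + logdetX + q

    def _information_matrix(self, fit: MixedFitResult):
        """Observed REML information of the active variance parameters,
        cached on the fit result (shared by all contrasts)."""
        if fit._information is not None:
            return fit._information, fit._active
        phi = self._phi(fit)
        active = np.concatenate(
            [[True], phi[1:] > _SINGULAR_TOL * max(fit.sigma2, 1e-12)]
        )
        idx = np.nonzero(active)[0]
        x0 = phi[idx]
        h = np.maximum(1e-7, 1e-4 * np.abs(x0))
        m = x0.size

        def f_of(xa):
            full = phi.copy()
            full[idx] = xa
            return self._neg2_reml_phi(full)

        H = np.zeros((m, m))
        f0 = f_of(x0)
        for i in range(m):
            for j in range(i, m):
                if i == j:
                    xp = x0.copy(); xp[i] += h[i]
                    xm = x0.copy(); xm[i] = max(xm[i] - h[i], 1e-12)
                    H[i, i] = (f_of(xp) - 2 * f0 + f_of(xm)) / (
                        (xp[i] - x0[i]) * (x0[i] - xm[i])
                    )
                else:
                    xpp = x0.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                    xpm = x0.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                    xmp = x0.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                    xmm = x0.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                    if np.any(xpm[1:] < 0) or np.any(xmp[1:] < 0) or np.any(xmm[1:] < 0):
                        H[i, j] = H[j, i] = 0.0
                        continue
                    H[i, j] = H[j, i] = (
                        f_of(xpp) - f_of(xpm) - f_of(xmp) + f_of(xmm)
                    ) / (4 * h[i] * h[j])
        A = H / 2.0  # observed information of the REML log-likelihood
        fit._information = A
        fit._active = active
        return A, active

    def satterthwaite_df(self, c, fit: MixedFitResult) -> float:
        """Approximate degrees of freedom of var(c'beta_hat).

        df = 2 g^2 / (grad' A^{-1} grad) with g the contrast variance as a
        function of the variance parameters and A the observed REML
        information, both evaluated at the estimates.
        """
        if self.k == 0 or fit.sigma2 <= 0:
            return float(self.n - self.p)
        A, active = self._information_matrix(fit)
        if not np.all(np.isfinite(A)):
            return fit.residual_df
        phi = self._phi(fit)
        idx = np.nonzero(active)[0]
        x0 = phi[idx]
        h = np.maximum(1e-7, 1e-4 * np.abs(x0))
        m = x0.size

        def g_of(xa):
            full = phi.copy()
            full[idx] = xa
            return float(c @ self._cov_full(np.maximum(full, 0.0)) @ c)

        grad = np.zeros(m)
        for i in range(m):
            xp = x0.copy(); xp[i] += h[i]
            xm = x0.copy(); xm[i] = max(xm[i] - h[i], 0.0)
            grad[i] = (g_of(xp) - g_of(xm)) / (xp[i] - xm[i])
        try:
            denom = float(grad @ np.linalg.solve(A, grad))
        except np.linalg.LinAlgError:
            denom = float(grad @ np.linalg.pinv(A) @ grad)
        g0 = g_of(x0)
        if denom <= 0 or g0 <= 0:
            return fit.residual_df
        df = 2.0 * g0 * g0 / denom
        return float(np.clip(df, 1.0, _MAX_DF))
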