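"""Linear mixed-model machinery: BLUE/BLUP/PEV and AI-REML variance components.

The engine works with the phenotypic covariance form of the mixed model

    y = X beta + sum_t Z_t u_t + e,     V = sum_t Var(Z_t u_t) + R,

which is algebraically equivalent to Henderson's mixed-model equations:
beta_hat is the GLS estimate, u_hat = Cov(u, y) P y with
P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1, and PEV(u_i) = Var(u_i) -
[Cov(u,y) P Cov(u,y)']_ii.  Variance components maximise the restricted
log-likelihood

    lR = -0.5 * (log|V| + log|X'V^-1X| + y'Py)

by average-information (AI) updates on transformed parameters (log variances,
Fisher-z correlations) with step-halving, falling back to a derivative-free
simplex when AI steps fail.

Random terms cover the structures a multi-site progeny-trial evaluation
needs: a scalar variance times an arbitrary relationship matrix, and an
unstructured across-group (site) covariance Kronecker a relationship matrix.
Residuals may be iid, heterogeneous by site, or separable AR1(col) x AR1(row)
spatial plus nugget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

__all__ = [
    "ar1_matrix", "spatial_residual_cov", "RandomTerm", "IidResidual",
    "SitewiseResidual", "Ar1Residual", "MixedModel", "FitResult",
    "solve_mme", "reml_fit", "MixedModelError",
]


class MixedModelError(ValueError):
    pass


def ar1_matrix(rho: float, n: int) -> np.ndarray:
    """First-order autoregressive correlation matrix, entry (k,l) = rho^|k-l|."""
    if not abs(rho) < 1.0:
        raise MixedModelError(f"AR1 correlation must satisfy |rho| < 1, got {rho}")
    if n < 1:
        raise MixedModelError("AR1 dimension must be >= 1")
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :]).astype(float)


def spatial_residual_cov(sigma2_xi: float, sigma2_eta: float,
                         rho_col: float, rho_row: float,
                         layout: Sequence[tuple[int, int]]) -> np.ndarray:
    """Dense covariance of a separable AR1xAR1 field plus nugget on occupied cells.

    `layout` maps each observation to its (row, column) grid position; the
    covariance between observations i, j is
    sigma2_xi * rho_col^|c_i-c_j| * rho_row^|r_i-r_j| + sigma2_eta * 1(i=j).
    """
    rows = np.asarray([p[0] for p in layout], dtype=float)
    cols = np.asarray([p[1] for p in layout], dtype=float)
    if sigma2_xi < 0 or sigma2_eta < 0:
        raise MixedModelError("spatial variances must be >= 0")
    if len(set(map(tuple, layout))) != len(layout):
        raise MixedModelError("duplicate (row, column) occupancy in layout")
    for rho in (rho_col, rho_row):
        if not abs(rho) < 1.0:
            raise MixedModelError("AR1 correlations must satisfy |rho| < 1")
    dc = np.abs(cols[:, None] - cols[None, :])
    dr = np.abs(rows[:, None] - rows[None, :])
    cov = sigma2_xi * (rho_col ** dc) * (rho_row ** dr)
    cov[np.diag_indices_from(cov)] += sigma2_eta
    return cov


def _safe_pow(rho: float, d: np.ndarray) -> np.ndarray:
    if rho == 0.0:
        return (d == 0).astype(float)
    return rho ** d


# ---------------------------------------------------------------------------
# Random terms
# ---------------------------------------------------------------------------

class RandomTerm:
    """Random effect with covariance Sigma (k x k, unstructured) kron K.

    levels : int array (n_obs,), index of each observation's effect level in
        K (or in an identity if K is None); -1 excludes an observation from
        the term (e.g. non-bulk trees in a bulk-lot effect).
    groups : int array (n_obs,), group (site) of each observation; with
        n_groups == 1 the term is a plain scalar-variance term.
    """

    def __init__(self, name: str, levels: np.ndarray, K: Optional[np.ndarray],
                 n_levels: int, groups: Optional[np.ndarray] = None,
                 n_groups: int = 1, level_ids: Optional[list[str]] = None,
                 group_names: Optional[list[str]] = None):
        self.name = name
        self.levels = np.asarray(levels, dtype=int)
        self.K = None if K is None else np.asarray(K, dtype=float)
        self.n_levels = int(n_levels)
        n = len(self.levels)
        self.groups = np.zeros(n, dtype=int) if groups is None \
            else np.asarray(groups, dtype=int)
        self.k = int(n_groups)
        self.level_ids = level_ids
        self.group_names = group_names or [str(i) for i in range(self.k)]
        if self.levels.max(initial=-1) >= self.n_levels:
            raise MixedModelError(f"term {name}: level index out of range")
        # Precompute K restricted to observations (zero for excluded rows).
        lev = np.clip(self.levels, 0, None)
        if self.K is None:
            KL = (self.levels[:, None] == self.levels[None, :]).astype(float)
        else:
            KL = self.K[np.ix_(lev, lev)].copy()
        excl = self.levels < 0
        KL[excl, :] = 0.0
        KL[:, excl] = 0.0
        self._KL = KL
        self._pairs = [(i, j) for i in range(self.k) for j in range(i + 1, self.k)]

    # -- parameterisation: Cholesky factor of Sigma = L L', with
    # log-diagonal (k params) followed by free sub-diagonal entries, row by
    # row.  Unconstrained, positive semidefinite by construction, and the
    # singular boundary is reachable smoothly (no rejected steps).
    @property
    def n_params(self) -> int:
        return self.k + len(self._pairs)

    def param_names(self) -> list[str]:
        names = [f"{self.name}:var[{g}]" for g in self.group_names]
        names += [f"{self.name}:cov[{self.group_names[i]},{self.group_names[j]}]"
                  for i, j in self._pairs]
        return names

    def default_start(self, vary: float) -> np.ndarray:
        return np.concatenate([
            np.full(self.k, 0.5 * np.log(max(vary, 1e-12))),
            np.zeros(len(self._pairs)),
        ])

    def _chol(self, theta: np.ndarray) -> np.ndarray:
        L = np.zeros((self.k, self.k))
        L[np.diag_indices(self.k)] = np.exp(theta[: self.k])
        for idx, (i, j) in enumerate(self._pairs):
            L[j, i] = theta[self.k + idx]  # row j, column i (i < j)
        return L

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        L = self._chol(theta)
        return L @ L.T

    def valid(self, theta: np.ndarray) -> bool:
        return True

    def natural(self, theta: np.ndarray) -> dict:
        S = self.sigma(theta)
        out = {"Sigma": S, "variances": np.diag(S).copy()}
        if self._pairs:
            d = np.sqrt(np.maximum(np.diag(S), 1e-300))
            out["correlations"] = {
                (self.group_names[i], self.group_names[j]):
                    S[j, i] / (d[i] * d[j])
                for i, j in self._pairs
            }
        return out

    def transform(self, variances, correlations=None) -> np.ndarray:
        v = np.atleast_1d(np.asarray(variances, dtype=float))
        S = np.diag(v.astype(float))
        if correlations is not None:
            for (i, j) in self._pairs:
                r = correlations[i][j] if isinstance(correlations, np.ndarray) \
                    else correlations.get((i, j),
                                          correlations.get((self.group_names[i],
                                                            self.group_names[j]), 0.0))
                S[i, j] = S[j, i] = r * np.sqrt(v[i] * v[j])
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(S + 1e-10 * np.trace(S) * np.eye(self.k)
                                   + 1e-300 * np.eye(self.k))
        theta = list(np.log(np.maximum(np.diag(L), 1e-150)))
        theta += [L[j, i] for (i, j) in self._pairs]
        return np.asarray(theta)

    def clamp(self, theta: np.ndarray, floor_log: float,
              cap_log: float) -> np.ndarray:
        out = theta.copy()
        out[: self.k] = np.clip(out[: self.k], 0.5 * floor_log, 0.5 * cap_log)
        lim = np.exp(0.5 * cap_log)
        out[self.k:] = np.clip(out[self.k:], -lim, lim)
        return out

    def _group_matrix(self, M: np.ndarray) -> np.ndarray:
        """Expand a k x k matrix to n x n over observation group pairs."""
        return M[self.groups[:, None], self.groups[None, :]]

    def contribution(self, theta: np.ndarray) -> np.ndarray:
        return self._group_matrix(self.sigma(theta)) * self._KL

    def derivatives(self, theta: np.ndarray) -> list[np.ndarray]:
        L = self._chol(theta)
        derivs = []

        def push(dL):
            dS = dL @ L.T
            dS = dS + dS.T
            derivs.append(self._group_matrix(dS) * self._KL)

        for g in range(self.k):
            dL = np.zeros_like(L)
            dL[g, g] = L[g, g]  # d/d theta of exp(theta)
            push(dL)
        for (i, j) in self._pairs:
            dL = np.zeros_like(L)
            dL[j, i] = 1.0
            push(dL)
        return derivs

    # -- prediction ------------------------------------------------------
    def cross_cov(self, theta: np.ndarray, pred_levels: np.ndarray,
                  pred_groups: np.ndarray) -> np.ndarray:
        """Cov(u_pred, y_obs) / residual-free part: (n_pred x n_obs)."""
        S = self.sigma(theta)
        pl = np.asarray(pred_levels, dtype=int)
        pg = np.asarray(pred_groups, dtype=int)
        lev = np.clip(self.levels, 0, None)
        if self.K is None:
            KX = (pl[:, None] == self.levels[None, :]).astype(float)
        else:
            KX = self.K[np.ix_(pl, lev)].copy()
        KX[:, self.levels < 0] = 0.0
        return S[pg[:, None], self.groups[None, :]] * KX

    def var_diag(self, theta: np.ndarray, pred_levels: np.ndarray,
                 pred_groups: np.ndarray) -> np.ndarray:
        S = self.sigma(theta)
        pl = np.asarray(pred_levels, dtype=int)
        pg = np.asarray(pred_groups, dtype=int)
        kd = np.ones(len(pl)) if self.K is None else self.K[pl, pl]
        return S[pg, pg] * kd

    def boundary_names(self, theta: np.ndarray, floor_log: float) -> list[str]:
        names = self.param_names()
        return [names[g] for g in range(self.k)
                if theta[g] <= 0.5 * floor_log + 1e-9]

    def natural_se(self, theta: np.ndarray, cov: np.ndarray) -> dict:
        """Delta-method SEs of the per-group variances and correlations."""
        L = self._chol(theta)
        dS_list = []
        for g in range(self.k):
            dL = np.zeros_like(L)
            dL[g, g] = L[g, g]
            dS = dL @ L.T
            dS_list.append(dS + dS.T)
        for (i, j) in self._pairs:
            dL = np.zeros_like(L)
            dL[j, i] = 1.0
            dS = dL @ L.T
            dS_list.append(dS + dS.T)
        S = L @ L.T
        out = {}
        for g in range(self.k):
            J = np.array([dS[g, g] for dS in dS_list])
            out[f"{self.name}:var[{self.group_names[g]}]"] = \
                float(np.sqrt(max(J @ cov @ J, 0.0)))
        d = np.sqrt(np.maximum(np.diag(S), 1e-300))
        for (i, j) in self._pairs:
            r = S[j, i] / (d[i] * d[j])
            J = np.array([
                dS[j, i] / (d[i] * d[j])
                - 0.5 * r * (dS[i, i] / S[i, i] + dS[j, j] / S[j, j])
                if S[i, i] > 1e-200 and S[j, j] > 1e-200 else 0.0
                for dS in dS_list
            ])
            out[f"{self.name}:corr[{self.group_names[i]},{self.group_names[j]}]"] = \
                float(np.sqrt(max(J @ cov @ J, 0.0)))
        return out


# ---------------------------------------------------------------------------
# Residual structures
# ---------------------------------------------------------------------------

class IidResidual:
    name = "residual"

    def __init__(self, n_obs: int):
        self.n = int(n_obs)

    n_params = 1

    def param_names(self):
        return ["residual:var"]

    def default_start(self, vary):
        return np.array([np.log(max(vary, 1e-12))])

    def valid(self, theta):
        return True

    def natural(self, theta):
        return {"variances": np.array([np.exp(theta[0])])}

    def transform(self, variances):
        return np.log(np.atleast_1d(np.asarray(variances, dtype=float)))

    def contribution(self, theta):
        return np.exp(theta[0]) * np.eye(self.n)

    def derivatives(self, theta):
        return [np.exp(theta[0]) * np.eye(self.n)]

    def clamp(self, theta, floor_log, cap_log):
        return np.clip(theta, floor_log, cap_log)

    def boundary_names(self, theta, floor_log):
        return ["residual:var"] if theta[0] <= floor_log + 1e-9 else []

    def natural_se(self, theta, cov):
        return {"residual:var": float(np.exp(theta[0]) * np.sqrt(max(cov[0, 0], 0.0)))}


class SitewiseResidual:
    """Heterogeneous diagonal residual: one variance per site."""

    name = "residual"

    def __init__(self, site: np.ndarray, n_sites: int,
                 site_names: Optional[list[str]] = None):
        self.site = np.asarray(site, dtype=int)
        self.k = int(n_sites)
        self.site_names = site_names or [str(i) for i in range(self.k)]
        self._masks = [(self.site == s).astype(float) for s in range(self.k)]

    @property
    def n_params(self):
        return self.k

    def param_names(self):
        return [f"residual:var[{s}]" for s in self.site_names]

    def default_start(self, vary):
        return np.full(self.k, np.log(max(vary, 1e-12)))

    def valid(self, theta):
        return True

    def natural(self, theta):
        return {"variances": np.exp(theta[: self.k])}

    def transform(self, variances):
        return np.log(np.asarray(variances, dtype=float))

    def contribution(self, theta):
        v = np.exp(theta)
        return np.diag(v[self.site])

    def derivatives(self, theta):
        v = np.exp(theta)
        return [np.diag(v[s] * m) for s, m in enumerate(self._masks)]

    def clamp(self, theta, floor_log, cap_log):
        return np.clip(theta, floor_log, cap_log)

    def boundary_names(self, theta, floor_log):
        return [n for n, tv in zip(self.param_names(), theta)
                if tv <= floor_log + 1e-9]

    def natural_se(self, theta, cov):
        return {n: float(np.exp(tv) * np.sqrt(max(cov[j, j], 0.0)))
                for j, (n, tv) in enumerate(zip(self.param_names(), theta))}


class Ar1Residual:
    """Separable AR1(col) x AR1(row) spatial residual plus independent nugget.

    Parameters (natural scale): sigma2_xi, sigma2_eta, rho_col, rho_row.
    """

    name = "residual"

    def __init__(self, rows: np.ndarray, cols: np.ndarray):
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        cells = list(zip(rows.tolist(), cols.tolist()))
        if len(set(cells)) != len(cells):
            raise MixedModelError("duplicate (row, column) occupancy within site")
        self._dr = np.abs(rows[:, None] - rows[None, :])
        self._dc = np.abs(cols[:, None] - cols[None, :])
        self.n = len(rows)

    n_params = 4

    def param_names(self):
        return ["residual:var_xi", "residual:var_eta",
                "residual:rho_col", "residual:rho_row"]

    def default_start(self, vary):
        half = max(vary, 1e-12) / 2.0
        return np.array([np.log(half), np.log(half),
                         np.arctanh(0.5), np.arctanh(0.5)])

    def valid(self, theta):
        return True

    def natural(self, theta):
        return {
            "sigma2_xi": float(np.exp(theta[0])),
            "sigma2_eta": float(np.exp(theta[1])),
            "rho_col": float(np.tanh(theta[2])),
            "rho_row": float(np.tanh(theta[3])),
        }

    def transform(self, sigma2_xi, sigma2_eta, rho_col, rho_row):
        return np.array([
            np.log(max(sigma2_xi, 1e-300)), np.log(max(sigma2_eta, 1e-300)),
            np.arctanh(np.clip(rho_col, -0.999999, 0.999999)),
            np.arctanh(np.clip(rho_row, -0.999999, 0.999999)),
        ])

    def _corr(self, theta):
        rc, rr = np.tanh(theta[2]), np.tanh(theta[3])
        return _safe_pow(rc, self._dc) * _safe_pow(rr, self._dr)

    def contribution(self, theta):
        s2x, s2e = np.exp(theta[0]), np.exp(theta[1])
        R = s2x * self._corr(theta)
        R[np.diag_indices_from(R)] += s2e
        return R

    def derivatives(self, theta):
        s2x, s2e = np.exp(theta[0]), np.exp(theta[1])
        rc, rr = np.tanh(theta[2]), np.tanh(theta[3])
        pc, pr = _safe_pow(rc, self._dc), _safe_pow(rr, self._dr)
        d_xi = s2x * pc * pr
        d_eta = s2e * np.eye(self.n)
        # d/drho rho^d = d * rho^(d-1); zero where d == 0
        if rc == 0.0:
            dpc = (self._dc == 1).astype(float)
        else:
            dpc = self._dc * _safe_pow(rc, np.maximum(self._dc - 1, 0)) \
                * (self._dc > 0)
        if rr == 0.0:
            dpr = (self._dr == 1).astype(float)
        else:
            dpr = self._dr * _safe_pow(rr, np.maximum(self._dr - 1, 0)) \
                * (self._dr > 0)
        d_rc = s2x * (1.0 - rc ** 2) * dpc * pr
        d_rr = s2x * (1.0 - rr ** 2) * pc * dpr
        return [d_xi, d_eta, d_rc, d_rr]

    def clamp(self, theta, floor_log, cap_log):
        out = theta.copy()
        out[:2] = np.clip(out[:2], floor_log, cap_log)
        out[2:] = np.clip(out[2:], -7.0, 7.0)
        return out

    def boundary_names(self, theta, floor_log):
        return [n for n, tv in zip(self.param_names()[:2], theta[:2])
                if tv <= floor_log + 1e-9]

    def natural_se(self, theta, cov):
        names = self.param_names()
        scales = [np.exp(theta[0]), np.exp(theta[1]),
                  1.0 - np.tanh(theta[2]) ** 2, 1.0 - np.tanh(theta[3]) ** 2]
        return {n: float(s * np.sqrt(max(cov[j, j], 0.0)))
                for j, (n, s) in enumerate(zip(names, scales))}

    def spatial_blup(self, theta, Py):
        """BLUP of the spatially dependent residual xi at each observation."""
        s2x = np.exp(theta[0])
        return s2x * (self._corr(theta) @ Py)


# ---------------------------------------------------------------------------
# FitResult and the model itself
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    beta: np.ndarray
    beta_se: np.ndarray
    fixed_names: list[str]
    loglik: float
    converged: bool
    n_iter: int
    theta: np.ndarray
    varcomp: dict
    varcomp_se: dict
    boundary: list[str]
    trace: list = field(default_factory=list)
    model: "MixedModel" = None
    method: str = "ai-reml"
    meta: dict = field(default_factory=dict)

    def fixed_effects(self):
        import pandas as pd
        return pd.DataFrame({"estimate": self.beta, "se": self.beta_se},
                            index=self.fixed_names)

    def vc(self, term: str, key: str = "variances"):
        return self.varcomp[term][key]


class MixedModel:
    """Dense-V mixed model with REML variance-component estimation."""

    #: variance floor as a fraction of var(y)
    FLOOR_FRAC = 1e-10

    def __init__(self, y: np.ndarray, X: np.ndarray,
                 terms: dict[str, RandomTerm], residual,
                 fixed_names: Optional[list[str]] = None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != len(self.y):
            raise MixedModelError("X rows != length of y")
        self.n = len(self.y)
        self.terms = dict(terms)
        self.residual = residual
        self.fixed_names = fixed_names or [f"b{j}" for j in range(self.X.shape[1])]
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            # name aliased columns via pivoted QR
            from scipy.linalg import qr
            _, _, piv = qr(self.X, pivoting=True, mode="economic")
            aliased = [self.fixed_names[j] for j in piv[rank:]]
            raise MixedModelError(f"fixed-effect design is rank deficient; "
                                  f"aliased terms: {aliased}")
        self._blocks = [(name, t) for name, t in self.terms.items()]
        self._slices = {}
        ofs = 0
        for name, t in self._blocks:
            self._slices[name] = slice(ofs, ofs + t.n_params)
            ofs += t.n_params
        self._slices["residual"] = slice(ofs, ofs + self.residual.n_params)
        self.n_params = ofs + self.residual.n_params
        self._floor = np.log(max(self.y.var() * self.FLOOR_FRAC, 1e-300))

    # -- parameter plumbing ---------------------------------------------
    def param_names(self) -> list[str]:
        names = []
        for name, t in self._blocks:
            names += t.param_names()
        names += self.residual.param_names()
        return names

    def _pieces(self):
        return list(self._blocks) + [("residual", self.residual)]

    def default_start(self) -> np.ndarray:
        vary = float(np.var(self.y)) or 1.0
        n_var_terms = len(self._blocks) + 1
        share = vary / (n_var_terms + 1)
        parts = [t.default_start(share) for _, t in self._blocks]
        parts.append(self.residual.default_start(vary / 2.0))
        return np.concatenate(parts) if parts else np.array([])

    def pack(self, params: dict) -> np.ndarray:
        """Transformed vector from natural-scale parameters per term.

        `params[name]` is passed as kwargs to the term's `transform`.
        """
        out = np.zeros(self.n_params)
        for name, t in self._pieces():
            spec = params[name]
            vec = t.transform(**spec) if isinstance(spec, dict) else t.transform(spec)
            out[self._slices[name]] = vec
        return out

    def _clamp(self, theta: np.ndarray) -> np.ndarray:
        theta = theta.copy()
        cap = np.log(np.var(self.y) * 1e6 + 1e-300)
        for name, t in self._pieces():
            sl = self._slices[name]
            theta[sl] = t.clamp(theta[sl], self._floor, cap)
        return theta

    def _build_V(self, theta: np.ndarray) -> Optional[np.ndarray]:
        for name, t in self._pieces():
            if not t.valid(theta[self._slices[name]]):
                return None
        V = self.residual.contribution(theta[self._slices["residual"]])
        for name, t in self._blocks:
            V = V + t.contribution(theta[self._slices[name]])
        return V

    def _reml_pieces(self, theta: np.ndarray):
        """Cholesky-based REML quantities; None when V is not PD."""
        V = self._build_V(theta)
        if V is None:
            return None
        try:
            L = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        logdetV = 2.0 * float(np.sum(np.log(np.diag(L[0]))))
        ViX = cho_solve(L, self.X, check_finite=False)
        Viy = cho_solve(L, self.y, check_finite=False)
        C = self.X.T @ ViX
        sign, logdetC = np.linalg.slogdet(C)
        if sign <= 0:
            return None
        beta = np.linalg.solve(C, self.X.T @ Viy)
        Py = Viy - ViX @ beta
        yPy = float(self.y @ Py)
        ll = -0.5 * (logdetV + logdetC + yPy)
        return {"L": L, "ViX": ViX, "C": C, "beta": beta, "Py": Py,
                "ll": ll, "V": V}

    def loglik(self, theta: np.ndarray) -> float:
        pieces = self._reml_pieces(theta)
        return -np.inf if pieces is None else pieces["ll"]

    def _P(self, pieces) -> np.ndarray:
        Vinv = cho_solve(pieces["L"], np.eye(self.n), check_finite=False)
        ViX = pieces["ViX"]
        return Vinv - ViX @ np.linalg.solve(pieces["C"], ViX.T)

    def _derivative_list(self, theta):
        derivs = []
        for name, t in self._pieces():
            derivs.extend(t.derivatives(theta[self._slices[name]]))
        return derivs

    # -- solving at fixed variance components ----------------------------
    def solve(self, params: dict | np.ndarray) -> FitResult:
        """BLUE/BLUP solution at fixed variance components.

        `params` is either a transformed vector or a dict of natural-scale
        parameters (see `pack`).
        """
        theta = params if isinstance(params, np.ndarray) else self.pack(params)
        pieces = self._reml_pieces(theta)
        if pieces is None:
            raise MixedModelError("covariance matrix singular at the supplied "
                                  "variance components")
        beta_cov = np.linalg.inv(pieces["C"])
        fit = FitResult(
            beta=pieces["beta"],
            beta_se=np.sqrt(np.clip(np.diag(beta_cov), 0, None)),
            fixed_names=list(self.fixed_names),
            loglik=pieces["ll"], converged=True, n_iter=0, theta=theta,
            varcomp=self._natural_all(theta), varcomp_se={}, boundary=[],
            model=self, method="fixed-vc",
        )
        fit.meta["pieces"] = pieces
        return fit

    def _natural_all(self, theta):
        return {name: t.natural(theta[self._slices[name]])
                for name, t in self._pieces()}

    # -- REML -------------------------------------------------------------
    def reml(self, start: Optional[dict | np.ndarray] = None,
             max_iter: int = 60, ll_tol: float = 1e-8, par_tol: float = 1e-6,
             use_simplex_fallback: bool = True, simplex_max_n: int = 900,
             verbose: bool = False) -> FitResult:
        if start is None:
            theta = self.default_start()
        elif isinstance(start, np.ndarray):
            theta = start.copy()
        else:
            theta = self.pack(start)
        theta = self._clamp(theta)
        pieces = self._reml_pieces(theta)
        if pieces is None:
            raise MixedModelError("REML start gives a singular covariance")
        ll = pieces["ll"]
        trace = [(0, ll)]
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            P = self._P(pieces)
            Py = pieces["Py"]
            derivs = self._derivative_list(theta)
            m = len(derivs)
            grad = np.empty(m)
            W = np.empty((self.n, m))
            for k, dV in enumerate(derivs):
                w = dV @ Py
                W[:, k] = w
                grad[k] = -0.5 * (float(np.sum(P * dV)) - float(Py @ w))
            AI = 0.5 * (W.T @ (P @ W))
            dscale = np.trace(AI) / m + 1.0
            # Levenberg-Marquardt ridge escalation, each level with step halving
            improved = False
            cand = cand_pieces = None
            for lam in (0.0, 0.01, 0.1, 1.0, 10.0):
                A_lm = AI + (1e-8 + lam) * dscale * np.eye(m)
                try:
                    step = np.linalg.solve(A_lm, grad)
                except np.linalg.LinAlgError:
                    continue
                for _ in range(12):
                    cand = self._clamp(theta + step)
                    cand_pieces = self._reml_pieces(cand)
                    if cand_pieces is not None \
                            and np.isfinite(cand_pieces["ll"]) \
                            and cand_pieces["ll"] > ll - 1e-12:
                        improved = True
                        break
                    step = 0.5 * step
                if improved:
                    break
            if not improved:
                break
            d_ll = cand_pieces["ll"] - ll
            d_par = self._max_natural_change(theta, cand)
            theta, pieces, ll = cand, cand_pieces, cand_pieces["ll"]
            trace.append((it, ll))
            if verbose:  # pragma: no cover
                print(f"iter {it}: ll={ll:.8f} d_ll={d_ll:.2e} d_par={d_par:.2e}")
            if abs(d_ll) < ll_tol and d_par < par_tol:
                converged = True
                break

        method = "ai-reml"
        # Derivative-free refinement only where an O(n^3)-per-evaluation
        # simplex is affordable; large non-converged fits return the best AI
        # point, flagged.
        if not converged and use_simplex_fallback and self.n <= simplex_max_n:
            res = minimize(
                lambda t: -self.loglik(self._clamp(t)), theta,
                method="Nelder-Mead",
                options={"maxiter": 120 * self.n_params,
                         "maxfev": 120 * self.n_params,
                         "xatol": 1e-7, "fatol": 1e-9, "adaptive": True},
            )
            cand = self._clamp(res.x)
            cand_pieces = self._reml_pieces(cand)
            if cand_pieces is not None and cand_pieces["ll"] >= ll - 1e-9:
                theta, pieces, ll = cand, cand_pieces, cand_pieces["ll"]
                method = "ai-reml+simplex"
                converged = converged or res.success
                trace.append((it + 1, ll))

        vc_se, vc_cov = self._approx_se(theta, pieces)
        boundary = []
        for name, t in self._pieces():
            boundary += t.boundary_names(theta[self._slices[name]], self._floor)
        beta_cov = np.linalg.inv(pieces["C"])
        fit = FitResult(
            beta=pieces["beta"],
            beta_se=np.sqrt(np.clip(np.diag(beta_cov), 0, None)),
            fixed_names=list(self.fixed_names),
            loglik=ll, converged=converged, n_iter=it, theta=theta,
            varcomp=self._natural_all(theta), varcomp_se=vc_se,
            boundary=boundary, trace=trace, model=self, method=method,
        )
        fit.meta["pieces"] = pieces
        fit.meta["vc_cov_trans"] = vc_cov
        fit.meta["vc_param_names"] = self.param_names()
        return fit

    def _max_natural_change(self, t0, t1) -> float:
        out = 0.0
        for name, t in self._pieces():
            a, b = t.natural(t0[self._slices[name]]), t.natural(t1[self._slices[name]])
            for key in a:
                va, vb = a[key], b[key]
                if isinstance(va, dict):
                    va = np.array(list(va.values()))
                    vb = np.array(list(vb.values()))
                out = max(out, float(np.max(np.abs(np.asarray(va, dtype=float)
                                                   - np.asarray(vb, dtype=float)))))
        return out

    def _approx_se(self, theta, pieces) -> dict:
        """Delta-method SEs of natural parameters from the inverse AI matrix."""
        try:
            P = self._P(pieces)
            Py = pieces["Py"]
            derivs = self._derivative_list(theta)
            W = np.column_stack([dV @ Py for dV in derivs])
            AI = 0.5 * (W.T @ (P @ W))
            cov = np.linalg.pinv(AI)
        except Exception:  # pragma: no cover
            return {}, None
        out = {}
        for name, t in self._pieces():
            sl = self._slices[name]
            out[name] = t.natural_se(theta[sl], cov[sl, sl])
        return out, cov

    # -- BLUP prediction ---------------------------------------------------
    def predict_random(self, fit: FitResult, term_name: str,
                       pred_levels: np.ndarray,
                       pred_groups: Optional[np.ndarray] = None
                       ) -> tuple[np.ndarray, np.ndarray]:
        """BLUP and PEV of a random term at arbitrary (level, group) pairs."""
        t = self.terms[term_name]
        pred_levels = np.asarray(pred_levels, dtype=int)
        pred_groups = np.zeros(len(pred_levels), dtype=int) \
            if pred_groups is None else np.asarray(pred_groups, dtype=int)
        pieces = fit.meta.get("pieces") or self._reml_pieces(fit.theta)
        theta_t = fit.theta[self._slices[term_name]]
        T = t.cross_cov(theta_t, pred_levels, pred_groups)
        u_hat = T @ pieces["Py"]
        # PEV = Var(u) - T P T'
        PT = cho_solve(pieces["L"], T.T, check_finite=False)
        ViX = pieces["ViX"]
        PT -= ViX @ np.linalg.solve(pieces["C"], ViX.T @ T.T)
        var_u = t.var_diag(theta_t, pred_levels, pred_groups)
        pev = var_u - np.einsum("ij,ji->i", T, PT)
        pev = np.clip(pev, 0.0, None)
        return u_hat, pev

    def spatial_blup(self, fit: FitResult) -> np.ndarray:
        if not isinstance(self.residual, Ar1Residual):
            raise MixedModelError("spatial BLUP requires an AR1xAR1 residual fit")
        pieces = fit.meta.get("pieces") or self._reml_pieces(fit.theta)
        return self.residual.spatial_blup(
            fit.theta[self._slices["residual"]], pieces["Py"])


def solve_mme(model: MixedModel, varcomp: dict | np.ndarray) -> FitResult:
    """Henderson-equation solution (BLUE/BLUP/PEV) at fixed variance components."""
    return model.solve(varcomp)


def reml_fit(model: MixedModel, start=None, **options) -> FitResult:
    """AI-REML fit with step-halving and simplex fallback."""
    return model.reml(start=start, **options)
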