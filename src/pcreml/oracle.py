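"""Dense brute-force REML evaluation for small instances.

Builds V = Z (H (x) Sigma_u) Z' + R and the REML projection
P = V^{-1} - V^{-1} X (X'V^{-1}X)^{-1} X'V^{-1} explicitly, and evaluates
-2 logL, its gradient and the average-information matrix on the variance
scale of the phenotypic covariance. Independent of the sparse MME path;
intended for instances of a few hundred equations.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .aireml import CovParams
from .mme import MMEBuilder

__all__ = ["OracleContext"]


class OracleContext:
    """Dense V/P machinery for a model/data pair."""

    def __init__(self, builder: MMEBuilder):
        self.b = builder
        b = builder
        # dense X from the fixed part of the MV design
        D = b.build_D("mv", None)
        self.X = D[:, : b.n_fixed].toarray()
        # per-term incidence Z_t: obs row -> (level, trait position)
        self.Z = []
        self.H = []
        for ti, t in enumerate(b.spec.random):
            qt = len(b.term_traits[ti])
            ncol = b.term_levels[ti] * qt
            rows, cols = [], []
            traits = b.term_traits[ti]
            for o in range(b.n_obs):
                s = b.obs_trait[o]
                if s in traits:
                    a = traits.index(s)
                    lev = b.term_codes[ti][b.obs_rec[o]]
                    rows.append(o)
                    cols.append(lev * qt + a)
            Z = sp.coo_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(b.n_obs, ncol)
            ).toarray()
            self.Z.append(Z)
            if t.rel == "identity":
                H = np.eye(b.term_levels[ti])
            else:
                H = np.linalg.inv(b.rels[t.rel].full.toarray())
            self.H.append(0.5 * (H + H.T))
        self.y = b.y_obs

    # -- covariance assembly ----------------------------------------------

    def R(self, covs: CovParams) -> np.ndarray:
        b = self.b
        R = np.zeros((b.n_obs, b.n_obs))
        for r in range(b.n_rec):
            traits = b.patterns[b.rec_pattern[r]]
            o0 = b.rec_first_obs[r]
            k = len(traits)
            R[o0 : o0 + k, o0 : o0 + k] = covs.sigma_e[np.ix_(traits, traits)]
        return R

    def V(self, covs: CovParams) -> np.ndarray:
        V = self.R(covs)
        for Z, H, S in zip(self.Z, self.H, covs.sigma_terms):
            V += Z @ np.kron(H, S) @ Z.T
        return V

    def projection(self, covs: CovParams) -> np.ndarray:
        V = self.V(covs)
        Vi = np.linalg.inv(V)
        XVX = self.X.T @ Vi @ self.X
        return Vi - Vi @ self.X @ np.linalg.solve(XVX, self.X.T @ Vi)

    # -- likelihood and derivatives ----------------------------------------

    def m2ll(self, covs: CovParams) -> float:
        """-2 logL with the same constant convention as the MME path."""
        V = self.V(covs)
        sign, logdet_v = np.linalg.slogdet(V)
        Vi = np.linalg.inv(V)
        XVX = self.X.T @ Vi @ self.X
        _, logdet_x = np.linalg.slogdet(XVX)
        P = Vi - Vi @ self.X @ np.linalg.solve(XVX, self.X.T @ Vi)
        return float(logdet_v + logdet_x + self.y @ P @ self.y)

    def _dV(self, covs: CovParams):
        """dV/dtheta_i for every Cholesky-log parameter, in theta order."""
        chols = covs.chols()
        out = []
        n_terms = len(covs.sigma_terms)
        for m, r, c in covs.param_index():
            L = chols[m]
            E = np.zeros_like(L)
            E[r, c] = L[r, c] if r == c else 1.0
            dS = E @ L.T + L @ E.T
            if m == n_terms:
                dV = np.zeros((self.b.n_obs, self.b.n_obs))
                b = self.b
                for rr in range(b.n_rec):
                    traits = b.patterns[b.rec_pattern[rr]]
                    o0 = b.rec_first_obs[rr]
                    k = len(traits)
                    dV[o0 : o0 + k, o0 : o0 + k] = dS[np.ix_(traits, traits)]
            else:
                Z, H = self.Z[m], self.H[m]
                dV = Z @ np.kron(H, dS) @ Z.T
            out.append(dV)
        return out

    def gradient(self, covs: CovParams) -> np.ndarray:
        """d(-2 logL)/dtheta = tr(P dV) - y'P dV P y."""
        P = self.projection(covs)
        Py = P @ self.y
        g = []
        for dV in self._dV(covs):
            g.append(np.trace(P @ dV) - Py @ dV @ Py)
        return np.array(g)

    def average_information(self, covs: CovParams) -> np.ndarray:
        """AI_ij = 1/2 y'P dV_i P dV_j P y."""
        P = self.projection(covs)
        Py = P @ self.y
        F = np.column_stack([dV @ Py for dV in self._dV(covs)])
        return 0.5 * F.T @ P @ F

    def fd_gradient(self, covs: CovParams, h: float = 1e-5) -> np.ndarray:
        """Central finite differences of -2 logL over theta."""
        theta = covs.theta()
        dims = covs.dims
        g = np.zeros_like(theta)
        for i in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            g[i] = (
                self.m2ll(CovParams.from_theta(tp, dims))
                - self.m2ll(CovParams.from_theta(tm, dims))
            ) / (2 * h)
        return g
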