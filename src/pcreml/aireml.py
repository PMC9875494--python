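"""Average-information REML for the multivariate animal model.

Implements the damped Newton loop theta^{k+1} = theta^k + omega * AI^{-1} s
on the Cholesky-log parameter scale, for both the standard multivariate (MV)
and the principal-components (PC) parameterisation of the genetic
covariances. The two parameterisations share the parameter vector theta
(elements of the Cholesky factors of every covariance matrix, diagonals on
the log scale), so likelihoods, gradients and average-information matrices
are directly comparable and the iterate sequences coincide.

-2 logL (constant dropped) is evaluated through the mixed-model equations:

  MV:  log|R| + sum_t [q_t log|H_t| + n_t log|Sigma_t|] + log|C|  + y'Py
  PC:  log|R| + sum_t  q_t log|H_t|                     + log|C*| + y'P*y

First derivatives use the sparse inverse subset of the coefficient matrix for
the trace terms; the quadratic-form derivatives are evaluated from the MME
solutions without forming P explicitly. The average information matrix is
(1/2) F' P F with working vectors f_i = (dV/dtheta_i) Py, each P-product
obtained by one extra MME solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .mme import MMEBuilder, MMESystem, ModelSpec, count_parameters
from .sparsela import Factorizer, CholFactor

__all__ = [
    "CovParams",
    "REMLState",
    "REMLResult",
    "REMLEngine",
    "loglik_mv",
    "loglik_pc",
    "reml_fit",
    "start_values",
]


# ---------------------------------------------------------------------------
# Cholesky-log parameter transform


def _chol_to_vec(L: np.ndarray) -> np.ndarray:
    q = L.shape[0]
    out = []
    for c in range(q):
        out.append(np.log(L[c, c]))
        out.extend(L[c + 1 :, c])
    return np.array(out)


def _vec_to_chol(v: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    k = 0
    for c in range(q):
        L[c, c] = np.exp(v[k])
        k += 1
        m = q - c - 1
        L[c + 1 :, c] = v[k : k + m]
        k += m
    return L


def _ntri(q: int) -> int:
    return q * (q + 1) // 2


@dataclass
class CovParams:
    """Covariance matrices of the random terms and the residual, with their
    Cholesky-log parameter vector.

    theta concatenates, term by term then residual, the lower-triangle
    elements of the Cholesky factor column by column, diagonal first within
    each column and log-transformed.
    """

    sigma_terms: list
    sigma_e: np.ndarray

    def __post_init__(self):
        self.sigma_terms = [np.asarray(S, dtype=float) for S in self.sigma_terms]
        self.sigma_e = np.asarray(self.sigma_e, dtype=float)

    @property
    def dims(self) -> list:
        return [S.shape[0] for S in self.sigma_terms] + [self.sigma_e.shape[0]]

    @property
    def matrices(self) -> list:
        return list(self.sigma_terms) + [self.sigma_e]

    def chols(self) -> list:
        return [np.linalg.cholesky(M) for M in self.matrices]

    def theta(self) -> np.ndarray:
        return np.concatenate([_chol_to_vec(L) for L in self.chols()])

    @classmethod
    def from_theta(cls, theta: np.ndarray, dims: list) -> "CovParams":
        mats, k = [], 0
        for q in dims:
            L = _vec_to_chol(theta[k : k + _ntri(q)], q)
            mats.append(L @ L.T)
            k += _ntri(q)
        if k != theta.size:
            raise ValueError("theta length does not match dimensions")
        return cls(sigma_terms=mats[:-1], sigma_e=mats[-1])

    def param_index(self) -> list:
        """(matrix index, row, col) for every element of theta."""
        out = []
        for m, q in enumerate(self.dims):
            for c in range(q):
                for r in range(c, q):
                    out.append((m, r, c))
        return out


def start_values(spec: ModelSpec, data, jitter: float = 0.0) -> CovParams:
    """Default starting values: half the pairwise-complete phenotypic
    covariance to the residual, the other half split over the random terms."""
    q = spec.q
    P = data[list(spec.traits)].cov().to_numpy()
    P = np.atleast_2d(P)
    # guard against non-PD pairwise estimates
    w, V = np.linalg.eigh(0.5 * (P + P.T))
    floor = max(1e-3 * np.mean(np.abs(w)), 1e-8)
    P = (V * np.maximum(w, floor)) @ V.T
    nt = len(spec.random)
    sig_terms = []
    for t in spec.random:
        tr = spec.term_traits(t)
        sig_terms.append(0.5 * P[np.ix_(tr, tr)] / nt + jitter * np.eye(len(tr)))
    return CovParams(sigma_terms=sig_terms, sigma_e=0.5 * P + jitter * np.eye(q))


# ---------------------------------------------------------------------------
# evaluation containers


@dataclass
class Evaluation:
    """One likelihood evaluation with its MME byproducts."""

    covs: CovParams
    sys: MMESystem
    factor: CholFactor
    m2ll: float
    components: dict
    sol: np.ndarray
    e_obs: np.ndarray  # R^{-1}(y - W sol) on the observation scale (= Py)
    yPy: float
    u_blocks: list  # per-term solutions, n_lev x q_t


@dataclass
class REMLState:
    k: int
    theta: np.ndarray
    m2ll: float
    grad: np.ndarray  # d(-2logL)/dtheta
    ai: np.ndarray
    omega: float = 1.0
    delta_m2ll: float = np.nan
    converged_l: bool = False
    converged_g: bool = False
    fallback: bool = False


@dataclass
class REMLResult:
    covs: CovParams
    theta: np.ndarray
    m2ll: float
    converged: bool
    n_iter: int
    trajectory: list
    se_theta: np.ndarray
    se_cov: list  # per matrix, standard errors of the covariance elements
    ai: np.ndarray
    message: str = ""


# ---------------------------------------------------------------------------
# engine


class REMLEngine:
    """AI-REML engine for one parameterisation of one model/data pair."""

    def __init__(self, builder: MMEBuilder, parameterisation: str = "mv",
                 ordering: str = "mmd"):
        self.builder = builder
        self.param = parameterisation.lower()
        self.ordering = ordering
        self.factorizer: Factorizer | None = None
        b = builder
        # per-pattern record lists and observation-row index blocks
        self._pat_recs = [np.nonzero(b.rec_pattern == p)[0]
                          for p in range(len(b.patterns))]
        self._pat_obs = [
            b.rec_first_obs[recs][:, None] + np.arange(len(b.patterns[p]))[None, :]
            for p, recs in enumerate(self._pat_recs)
        ]
        # cached log|H_t| contributions (parameter independent)
        self._logdet_H = []
        for ti, t in enumerate(builder.spec.random):
            if t.rel == "identity":
                self._logdet_H.append(0.0)
            else:
                self._logdet_H.append(-builder.rels[t.rel].logdet)

    # -- likelihood ------------------------------------------------------

    def evaluate(self, covs: CovParams) -> Evaluation:
        b = self.builder
        sys = b.assemble(covs, self.param)
        if self.factorizer is None:
            self.factorizer = Factorizer(
                sys.coeff, ordering=self.ordering, groups=b.eq_groups()
            )
        fac = self.factorizer.factor(sys.coeff, eqmap=sys.describe_eq)
        sol = fac.solve(sys.rhs)
        yRy = float(b.y_obs @ (sys.Rw @ b.y_obs))
        yPy = yRy - float(sys.rhs @ sol)
        log_R = 0.0
        for p, traits in enumerate(b.patterns):
            sub = covs.sigma_e[np.ix_(traits, traits)]
            log_R += len(self._pat_recs[p]) * np.linalg.slogdet(sub)[1]
        log_rel = 0.0
        for ti, t in enumerate(b.spec.random):
            qt = len(b.term_traits[ti])
            log_rel += qt * self._logdet_H[ti]
            if self.param == "mv":
                log_rel += b.term_levels[ti] * np.linalg.slogdet(
                    covs.sigma_terms[ti]
                )[1]
        m2ll = log_R + log_rel + fac.logdet + yPy
        e_obs = sys.Rw @ (b.y_obs - sys.D @ sol)
        u_blocks = []
        for ti in range(len(b.spec.random)):
            qt = len(b.term_traits[ti])
            off = b.term_offsets[ti]
            u_blocks.append(
                sol[off : off + qt * b.term_levels[ti]].reshape(-1, qt)
            )
        comps = dict(log_R=log_R, log_rel=log_rel, log_C=fac.logdet, yPy=yPy)
        return Evaluation(
            covs=covs, sys=sys, factor=fac, m2ll=m2ll, components=comps,
            sol=sol, e_obs=e_obs, yPy=yPy, u_blocks=u_blocks,
        )

    # -- derivatives -----------------------------------------------------

    def _record_gram(self, ev: Evaluation):
        """Per-pattern sums of G_r = D_r C^{-1} D_r' over records."""
        b = self.builder
        inv = ev.factor.inverse_subset()
        D = ev.sys.D
        indptr, indices, data = D.indptr, D.indices, D.data
        sums = [np.zeros((len(tr), len(tr))) for tr in b.patterns]
        pi, pj, pv, ps, pt, ppat = [], [], [], [], [], []
        for r in range(b.n_rec):
            p = b.rec_pattern[r]
            k = len(b.patterns[p])
            o0 = b.rec_first_obs[r]
            cols, vals, srow = [], [], []
            for s in range(k):
                lo, hi = indptr[o0 + s], indptr[o0 + s + 1]
                cols.append(indices[lo:hi])
                vals.append(data[lo:hi])
                srow.append(np.full(hi - lo, s))
            cols = np.concatenate(cols)
            vals = np.concatenate(vals)
            srow = np.concatenate(srow)
            m = cols.size
            ii = np.repeat(np.arange(m), m)
            jj = np.tile(np.arange(m), m)
            pi.append(cols[ii])
            pj.append(cols[jj])
            pv.append(vals[ii] * vals[jj])
            ps.append(srow[ii])
            pt.append(srow[jj])
            ppat.append(np.full(m * m, r))
        rows_all = np.concatenate(pi)
        cols_all = np.concatenate(pj)
        cv = inv.lookup(rows_all, cols_all) * np.concatenate(pv)
        s_all = np.concatenate(ps)
        t_all = np.concatenate(pt)
        rec_all = np.concatenate(ppat)
        pat_all = b.rec_pattern[rec_all]
        for p in range(len(b.patterns)):
            mask = pat_all == p
            k = len(b.patterns[p])
            np.add.at(sums[p], (s_all[mask], t_all[mask]), cv[mask])
        return sums

    def _pattern_e_outer(self, ev: Evaluation):
        """Per-pattern sums of e_r e_r' of the Py residuals."""
        return [
            ev.e_obs[obs].T @ ev.e_obs[obs] if obs.size else np.zeros((obs.shape[1],) * 2)
            for obs in self._pat_obs
        ]

    def _mv_genetic_aggregates(self, ev: Evaluation):
        """F_t = sum_ab Hinv_ab * (C^{-1} block)_ab (symmetrised) and
        Fu_t = U_t' Hinv U_t, per term."""
        b = self.builder
        inv = ev.factor.inverse_subset()
        structs = b._rel_structure("mv")
        Fs, Fus = [], []
        for ti, st in enumerate(structs):
            qt = len(b.term_traits[ti])
            vals = inv.lookup(st["rows"], st["cols"])
            off = b.term_offsets[ti]
            # weight 2 for entries from off-diagonal Hinv or strict-lower
            # within-diagonal blocks (full-matrix sums from one triangle)
            ha = (st["rows"] - off) // qt
            hb = (st["cols"] - off) // qt
            w = np.where((ha != hb) | (st["sr"] != st["sc"]), 2.0, 1.0)
            F = np.zeros((qt, qt))
            np.add.at(F, (st["sr"], st["sc"]), w * st["hdata"][st["hidx"]] * vals)
            F = 0.5 * (F + F.T)
            Fs.append(F)
            t = b.spec.random[ti]
            U = ev.u_blocks[ti]
            if t.rel == "identity":
                HU = U
            else:
                HU = b.rels[t.rel].full @ U
            Fus.append(U.T @ HU)
        return Fs, Fus

    def _pc_genetic_aggregates(self, ev: Evaluation):
        """S1_t[a,c] = sum over design entries of (Rw D C^{-1}) matched to
        dD/dQ[a,c]; S2_t[a,c] = sum e_obs * ustar component, per term."""
        b = self.builder
        inv = ev.factor.inverse_subset()
        T = (ev.sys.Rw @ ev.sys.D).tocsr()
        rnd = b.D_term >= 0
        e_obs_rows = b.D_rows[rnd]
        e_cols = b.D_cols[rnd]
        e_term = b.D_term[rnd]
        e_a = b.D_a[rnd]
        e_c = b.D_c[rnd]
        # m1_e = sum_{c2 in row o of T} T[o,c2] * Cinv[c2, col_e]
        counts = np.diff(T.indptr)[e_obs_rows]
        seg = np.repeat(np.arange(e_cols.size), counts)
        starts = T.indptr[e_obs_rows]
        flat = np.concatenate(
            [np.arange(s, s + c) for s, c in zip(starts, counts)]
        ) if e_cols.size else np.array([], dtype=np.int64)
        tcols = T.indices[flat]
        tvals = T.data[flat]
        look = inv.lookup(tcols, np.repeat(e_cols, counts))
        m1 = np.zeros(e_cols.size)
        np.add.at(m1, seg, tvals * look)
        S1s, S2s = [], []
        for ti, t in enumerate(b.spec.random):
            qt = len(b.term_traits[ti])
            mask = e_term == ti
            S1 = np.zeros((qt, qt))
            np.add.at(S1, (e_a[mask], e_c[mask]), m1[mask])
            # S2: e_obs[o] * ustar[lev, c]
            lev = b.term_codes[ti][b.obs_rec[e_obs_rows[mask]]]
            vals = ev.e_obs[e_obs_rows[mask]] * ev.u_blocks[ti][lev, e_c[mask]]
            S2 = np.zeros((qt, qt))
            np.add.at(S2, (e_a[mask], e_c[mask]), vals)
            S1s.append(S1)
            S2s.append(S2)
        return S1s, S2s

    def derivatives(self, ev: Evaluation):
        """Gradient of -2logL and the average-information matrix at ev."""
        b = self.builder
        covs = ev.covs
        chols = covs.chols()
        pinfo = covs.param_index()
        p_tot = len(pinfo)
        n_terms = len(b.spec.random)
        q = b.spec.q
        Ws = b.residual_weights(covs.sigma_e)
        pat_n = [len(r) for r in self._pat_recs]
        sumG = self._record_gram(ev)
        sumE = self._pattern_e_outer(ev)
        if self.param == "mv":
            Fs, Fus = self._mv_genetic_aggregates(ev)
            sig_invs = [np.linalg.inv(S) for S in covs.sigma_terms]
        else:
            S1s, S2s = self._pc_genetic_aggregates(ev)

        grad = np.zeros(p_tot)
        Fwork = np.zeros((b.n_obs, p_tot))
        for pi_idx, (m, r, c) in enumerate(pinfo):
            L = chols[m]
            E = np.zeros_like(L)
            E[r, c] = L[r, c] if r == c else 1.0
            if m == n_terms:  # residual parameter
                dSig = E @ L.T + L @ E.T
                g = 0.0
                for p, traits in enumerate(b.patterns):
                    dS = dSig[np.ix_(traits, traits)]
                    W = Ws[p]
                    dW = -W @ dS @ W
                    g += pat_n[p] * np.trace(W @ dS)  # d log|R|
                    g += float(np.sum(dW * sumG[p]))  # d log|C|
                    g -= float(np.sum(dS * sumE[p]))  # d y'Py
                    obs = self._pat_obs[p]
                    if obs.size:
                        Fwork[obs.ravel(), pi_idx] = (
                            ev.e_obs[obs] @ dS.T
                        ).ravel()
                grad[pi_idx] = g
            else:  # genetic parameter of term m
                ti = m
                qt = len(b.term_traits[ti])
                if self.param == "mv":
                    dSig = E @ L.T + L @ E.T
                    Si = sig_invs[ti]
                    M = Si @ dSig @ Si
                    g = b.term_levels[ti] * np.trace(Si @ dSig)
                    g += float(np.sum(Fs[ti] * (-M)))  # d log|C|
                    g -= float(np.sum(Fus[ti] * M))  # d y'Py
                    grad[pi_idx] = g
                    # f = Z (I x dSig Si) u
                    A = dSig @ Si
                    self._scatter_mv_f(Fwork, pi_idx, ti, A, ev)
                else:
                    scale = L[r, c] if r == c else 1.0
                    g = 2.0 * S1s[ti][r, c] * scale  # d log|C*|
                    g += -2.0 * S2s[ti][r, c] * scale  # d y'P*y
                    grad[pi_idx] = g
                    self._scatter_pc_f(Fwork, pi_idx, ti, r, c, scale, ev)

        # average information: AI = 1/2 F' P F via one MME solve per column
        sysm = ev.sys
        rhsF = sysm.D.T @ (sysm.Rw @ Fwork)
        solF = ev.factor.solve(rhsF)
        PF = sysm.Rw @ (Fwork - sysm.D @ solF)
        AI = 0.5 * (Fwork.T @ PF)
        AI = 0.5 * (AI + AI.T)
        return grad, AI

    def _scatter_mv_f(self, Fwork, col, ti, A, ev: Evaluation):
        """f rows for a MV genetic parameter: [A u_lev]_a at each obs row."""
        b = self.builder
        traits = b.term_traits[ti]
        sel = np.isin(b.obs_trait, traits)
        rows = np.nonzero(sel)[0]
        pos = np.searchsorted(np.asarray(traits), b.obs_trait[rows])
        lev = b.term_codes[ti][b.obs_rec[rows]]
        Fwork[rows, col] += np.einsum(
            "ij,ij->i", A[pos, :], ev.u_blocks[ti][lev, :]
        )

    def _scatter_pc_f(self, Fwork, col, ti, r, c, scale, ev: Evaluation):
        """f rows for a PC genetic parameter:
        f = Zdot u* + Z* (H x I) Zdot' P*y with dQ = scale * E_rc."""
        b = self.builder
        t = b.spec.random[ti]
        traits = b.term_traits[ti]
        sel = np.isin(b.obs_trait, traits)
        rows = np.nonzero(sel)[0]
        pos = np.searchsorted(np.asarray(traits), b.obs_trait[rows])
        lev = b.term_codes[ti][b.obs_rec[rows]]
        # part 1: Zdot u*: rows with trait position r pick component c
        m1 = pos == r
        Fwork[rows[m1], col] += scale * ev.u_blocks[ti][lev[m1], c]
        # part 2: w = Zdot' e  (only component c non-zero)
        w = np.zeros(b.term_levels[ti])
        np.add.at(w, lev[m1], scale * ev.e_obs[rows[m1]])
        if t.rel == "identity":
            v = w
        else:
            v = b.rels[t.rel].solve(w)  # H w from the stored H^{-1}
        Q = ev.sys.pct.Q[ti]
        Fwork[rows, col] += Q[pos, c] * v[lev]


# ---------------------------------------------------------------------------
# fitting loop

_MAX_STEP = 2.0  # largest |delta theta| component accepted per iterate


def reml_iterate(engine: REMLEngine, ev: Evaluation, state: REMLState,
                 max_halvings: int = 10):
    """One damped Newton update; returns (new_ev, new_state)."""
    g = state.grad
    s = -0.5 * g  # gradient of logL
    ai = state.ai
    fallback = False
    try:
        # ridge-free solve; PSD AI can still be near-singular
        delta = np.linalg.solve(ai, s)
        if not np.all(np.isfinite(delta)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        delta = np.linalg.pinv(ai) @ s
        fallback = True
    if not np.all(np.isfinite(delta)) or np.linalg.norm(delta) == 0.0:
        delta = s / max(1.0, np.linalg.norm(s))
        fallback = True
    # trust region on the Cholesky-log scale: a near-singular AI can propose
    # steps of thousands of log-units; cap the largest component instead of
    # relying on step halving alone
    mx = np.max(np.abs(delta))
    if mx > _MAX_STEP:
        delta = delta * (_MAX_STEP / mx)
    def try_steps(direction):
        omega = 1.0
        for _ in range(max_halvings + 1):
            theta_new = state.theta + omega * direction
            try:
                covs_new = CovParams.from_theta(theta_new, ev.covs.dims)
                ev_new = engine.evaluate(covs_new)
                if not np.isfinite(ev_new.m2ll):
                    raise ValueError("non-finite likelihood")
            except (np.linalg.LinAlgError, ValueError, ZeroDivisionError,
                    FloatingPointError, OverflowError):
                omega *= 0.5
                continue
            if ev_new.m2ll <= state.m2ll + 1e-8 * max(1.0, abs(state.m2ll)):
                return ev_new, omega
            omega *= 0.5
        return None

    best = try_steps(delta)
    if best is None:
        # Newton direction failed every step length: escalate a ridge on the
        # AI matrix (Levenberg-style), then plain scaled gradient ascent
        fallback = True
        dai = np.maximum(np.diag(ai), 1e-12 * max(1.0, np.abs(ai).max()))
        for lam in (1e-4, 1e-2, 1.0, 1e2):
            try:
                d2 = np.linalg.solve(ai + lam * np.diag(dai), s)
            except np.linalg.LinAlgError:
                continue
            mx = np.max(np.abs(d2))
            if mx > _MAX_STEP:
                d2 = d2 * (_MAX_STEP / mx)
            best = try_steps(d2)
            if best is not None:
                break
    if best is None:
        best = try_steps(0.1 * s / max(1.0, np.max(np.abs(s))))
    if best is None:
        # no improving step found at all; stay put and flag it
        new_state = REMLState(
            k=state.k + 1, theta=state.theta, m2ll=state.m2ll,
            grad=state.grad, ai=state.ai, omega=0.0, delta_m2ll=0.0,
            fallback=True,
        )
        return ev, new_state
    ev_new, omega = best
    grad_new, ai_new = engine.derivatives(ev_new)
    new_state = REMLState(
        k=state.k + 1,
        theta=ev_new.covs.theta(),
        m2ll=ev_new.m2ll,
        grad=grad_new,
        ai=ai_new,
        omega=omega,
        delta_m2ll=state.m2ll - ev_new.m2ll,
        fallback=fallback,
    )
    return ev_new, new_state


def reml_fit(
    builder: MMEBuilder,
    start: CovParams | None = None,
    parameterisation: str = "mv",
    maxit: int = 50,
    tol_l: float = 5e-4,
    tol_g: float = 1e-3,
    ordering: str = "mmd",
    trace: bool = False,
) -> REMLResult:
    """Iterate AI-REML to convergence.

    Converged when the -2logL change is below ``tol_l`` and the largest
    logL-gradient element is below ``tol_g``, or when the -2logL change
    stays below ``tol_l`` for three consecutive iterates. The latter handles
    boundary maxima (a covariance matrix drifting to singularity), where the
    likelihood flattens but the gradient on the Cholesky-log scale does not
    vanish.
    """
    engine = REMLEngine(builder, parameterisation, ordering=ordering)
    covs = start if start is not None else start_values(builder.spec, builder.data)
    ev = engine.evaluate(covs)
    grad, ai = engine.derivatives(ev)
    state = REMLState(k=0, theta=covs.theta(), m2ll=ev.m2ll, grad=grad, ai=ai)
    traj = [state]
    converged = False
    n_small = 0
    for _ in range(maxit):
        ev, state = reml_iterate(engine, ev, state)
        traj.append(state)
        if trace:
            print(
                f"iter {state.k:3d}  -2logL {state.m2ll:.6f}  "
                f"d {state.delta_m2ll:.3e}  omega {state.omega:.3f}"
            )
        gmax = 0.5 * np.max(np.abs(state.grad))
        state.converged_l = abs(state.delta_m2ll) < tol_l
        state.converged_g = gmax < tol_g
        n_small = n_small + 1 if state.converged_l else 0
        if (state.converged_l and state.converged_g) or n_small >= 3:
            converged = True
            break
        if state.fallback and state.omega == 0.0:
            break  # stalled: no improving step in any tried direction
    covs_hat = CovParams.from_theta(state.theta, covs.dims)
    se_theta, se_cov = _standard_errors(covs_hat, state.ai)
    return REMLResult(
        covs=covs_hat,
        theta=state.theta,
        m2ll=state.m2ll,
        converged=converged,
        n_iter=state.k,
        trajectory=traj,
        se_theta=se_theta,
        se_cov=se_cov,
        ai=state.ai,
        message="converged" if converged else "maximum iterations reached",
    )


def _standard_errors(covs: CovParams, ai: np.ndarray):
    """AI-based standard errors on the theta scale and, via the delta
    method, for each covariance-matrix element."""
    p = ai.shape[0]
    try:
        ai_inv = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        ai_inv = np.linalg.pinv(ai)
    var_theta = np.clip(np.diag(ai_inv), 0.0, None)
    se_theta = np.sqrt(var_theta)
    # Jacobian of the covariance elements w.r.t. theta (block diagonal)
    chols = covs.chols()
    pinfo = covs.param_index()
    se_cov = []
    k0 = 0
    for m, L in enumerate(chols):
        q = L.shape[0]
        nt = _ntri(q)
        J = np.zeros((nt, nt))
        elems = [(r, c) for c in range(q) for r in range(c, q)]
        for jcol, (m2, r, c) in enumerate(pinfo[k0 : k0 + nt]):
            E = np.zeros_like(L)
            E[r, c] = L[r, c] if r == c else 1.0
            dS = E @ L.T + L @ E.T
            J[:, jcol] = [dS[i, j] for i, j in elems]
        block = ai_inv[k0 : k0 + nt, k0 : k0 + nt]
        var = np.clip(np.diag(J @ block @ J.T), 0.0, None)
        S = np.zeros((q, q))
        for (i, j), v in zip(elems, np.sqrt(var)):
            S[i, j] = S[j, i] = v
        se_cov.append(S)
        k0 += nt
    return se_theta, se_cov


# ---------------------------------------------------------------------------
# convenience wrappers


def loglik_mv(builder: MMEBuilder, covs: CovParams) -> Evaluation:
    """-2 logL (and byproducts) under the standard MV parameterisation."""
    return REMLEngine(builder, "mv").evaluate(covs)


def loglik_pc(builder: MMEBuilder, covs: CovParams) -> Evaluation:
    """-2 logL (and byproducts) under the PC parameterisation."""
    return REMLEngine(builder, "pc").evaluate(covs)
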