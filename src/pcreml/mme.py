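"""Multivariate mixed-model representation and MME assembly.

Supports the standard multivariate (MV) parameterisation, where the genetic
part of the coefficient matrix is H^{-1} (x) Sigma_u^{-1}, and the equivalent
principal-components (PC) parameterisation, where trait covariances move into
the design matrix (Z* = Z (I (x) Q), with Q a Cholesky factor of Sigma_u) and
the genetic part becomes H^{-1} (x) I_q.

Equations are ordered fixed effects first (levels within factor within
trait), then random terms (components/traits within individual within term).
Identifiability: within each trait the first level of every factor after the
first is constrained to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .relmat import RelFactor

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "PCTransform",
    "MMESystem",
    "MMEBuilder",
    "count_equations",
    "count_parameters",
    "neq_from_counts",
    "nnz_accounting",
]


@dataclass(frozen=True)
class RandomTerm:
    """A random effect: name, relationship source, effect column, traits.

    ``rel`` names an entry of the relationship dictionary or 'identity'.
    ``effect`` is the data column holding 0-based level codes (for
    relationship-backed terms these index the RelFactor rows); for identity
    terms raw values are densified at assembly. ``traits`` lists covered
    trait indices (empty tuple = all traits).
    """

    name: str
    rel: str
    effect: str = "id"
    traits: tuple = ()


@dataclass(frozen=True)
class ModelSpec:
    """Traits, fixed factors (shared across traits) and random terms."""

    traits: tuple
    fixed: tuple
    random: tuple

    def __post_init__(self):
        if len(self.traits) < 1:
            raise ValueError("at least one trait required")
        if len(self.fixed) < 1:
            raise ValueError("at least one fixed factor per trait required")
        if len(self.random) < 1:
            raise ValueError("at least one random term (direct genetic) required")
        object.__setattr__(self, "traits", tuple(self.traits))
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "random", tuple(self.random))

    @property
    def q(self) -> int:
        return len(self.traits)

    def term_traits(self, t: RandomTerm) -> tuple:
        return tuple(sorted(t.traits)) if t.traits else tuple(range(self.q))


def count_parameters(spec: ModelSpec) -> int:
    """Number of (co)variance parameters at full rank: one q_t(q_t+1)/2
    triangle per random term plus the residual triangle."""
    n = 0
    for t in spec.random:
        qt = len(spec.term_traits(t))
        n += qt * (qt + 1) // 2
    q = spec.q
    return n + q * (q + 1) // 2


def neq_from_counts(fixed_levels, random_terms) -> int:
    """Equation count from structural tallies alone.

    ``fixed_levels``: per-trait iterables of level counts (all columns kept);
    ``random_terms``: iterable of (q_term, n_levels).
    """
    n = sum(int(l) for per_trait in fixed_levels for l in per_trait)
    n += sum(int(qt) * int(nl) for qt, nl in random_terms)
    return n


class PCTransform:
    """Per-random-term loading Q with Q Q' = Sigma_u (lower Cholesky)."""

    def __init__(self, sigmas: Sequence[np.ndarray]):
        self.Q = [np.linalg.cholesky(np.asarray(S, dtype=float)) for S in sigmas]
        self.Qinv = [np.linalg.inv(Q) for Q in self.Q]

    def to_trait_scale(self, ustar_blocks: Sequence[np.ndarray]) -> list:
        """Map PC solutions (n_lev x q_t per term) back to trait scale."""
        return [U @ Q.T for U, Q in zip(ustar_blocks, self.Q)]


@dataclass
class MMESystem:
    """Assembled mixed-model equations for one parameterisation."""

    parameterisation: str
    coeff: sp.csc_matrix  # lower triangle
    rhs: np.ndarray
    neq: int
    n_fixed: int
    builder: "MMEBuilder"
    C_data: sp.csc_matrix
    C_rel: sp.csc_matrix
    rel_nnz: list
    D: sp.csr_matrix
    Rw: sp.csc_matrix
    pct: PCTransform | None = None

    @property
    def nnz_coeff(self) -> int:
        return self.coeff.nnz

    def describe_eq(self, i: int) -> str:
        return self.builder.describe_eq(i)


class MMEBuilder:
    """Precomputed assembly structure for a (spec, data) pair.

    The sparsity structure of the design matrix, the residual weight matrix
    and the relationship part is computed once; repeated ``assemble`` calls
    with new covariance values reuse it, keeping the coefficient-matrix
    pattern identical across REML iterates.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame, rels: Mapping[str, RelFactor]):
        self.spec = spec
        self.rels = dict(rels)
        q = spec.q
        df = data.reset_index(drop=True)
        Y = df[list(spec.traits)].to_numpy(dtype=float)
        keep = ~np.all(np.isnan(Y), axis=1)
        self.n_dropped = int((~keep).sum())
        df = df.loc[keep].reset_index(drop=True)
        self.data = df
        self.Y = Y[keep]
        self.n_rec = len(df)
        if self.n_rec == 0:
            raise ValueError("no record with at least one observed trait")

        # observation rows: traits within record
        rec_idx, trait_idx = np.nonzero(~np.isnan(self.Y))
        self.obs_rec = rec_idx
        self.obs_trait = trait_idx
        self.y_obs = self.Y[rec_idx, trait_idx]
        self.n_obs = self.y_obs.size
        # per-record observed-trait patterns
        pat_mask = ~np.isnan(self.Y)
        pat_keys, pat_inv = np.unique(pat_mask, axis=0, return_inverse=True)
        self.patterns = [tuple(np.nonzero(k)[0]) for k in pat_keys]
        self.rec_pattern = pat_inv
        # obs-row index of each (rec, trait-in-pattern) entry
        self.rec_first_obs = np.searchsorted(rec_idx, np.arange(self.n_rec))

        # fixed-effect columns: level maps per (trait, factor)
        self._fac_str = {fac: df[fac].astype(str).to_numpy() for fac in spec.fixed}
        self.fixed_levels: dict = {}
        self.fixed_offsets: dict = {}
        off = 0
        for s, tr in enumerate(spec.traits):
            rows = rec_idx[trait_idx == s]
            for f_i, fac in enumerate(spec.fixed):
                levels = np.unique(self._fac_str[fac][rows]).tolist()
                kept = levels if f_i == 0 else levels[1:]
                self.fixed_levels[(s, fac)] = {lv: k for k, lv in enumerate(kept)}
                self.fixed_offsets[(s, fac)] = off
                off += len(kept)
        self.n_fixed = off

        # random-term levels and offsets
        self.term_levels: list = []
        self.term_codes: list = []
        self.term_offsets: list = []
        self.term_traits: list = [spec.term_traits(t) for t in spec.random]
        for t in spec.random:
            col = df[t.effect].to_numpy()
            if t.rel == "identity":
                uniq = sorted(map(str, set(col.tolist())))
                cmap = {v: k for k, v in enumerate(uniq)}
                codes = np.array([cmap[str(v)] for v in col], dtype=np.int64)
                nlev = len(uniq)
            else:
                rel = self.rels[t.rel]
                codes = np.asarray(col, dtype=np.int64)
                if codes.min() < 0 or codes.max() >= rel.n:
                    raise ValueError(
                        f"effect codes of term {t.name!r} outside relationship matrix"
                    )
                nlev = rel.n
            self.term_codes.append(codes)
            self.term_levels.append(nlev)
            self.term_offsets.append(off)
            off += nlev * len(spec.term_traits(t))
        self.neq = off

        self._build_design_structure()
        self._build_resid_structure()
        self._rel_struct: dict = {}
        self._zero_pattern: dict = {}

    # -- structure -----------------------------------------------------

    def _build_design_structure(self):
        """COO structure of the design matrix D (rows = observations).

        Entry kinds: fixed (constant 1) and random (term, trait-position a,
        component c); MV uses only c == a with value 1, PC gathers Q[a, c].
        """
        spec = self.spec
        rows, cols = [], []
        kind_term, kind_a, kind_c = [], [], []
        for o in range(self.n_obs):
            r, s = self.obs_rec[o], self.obs_trait[o]
            for fac in spec.fixed:
                lmap = self.fixed_levels[(s, fac)]
                key = self._fac_str[fac][r]
                if key in lmap:
                    rows.append(o)
                    cols.append(self.fixed_offsets[(s, fac)] + lmap[key])
                    kind_term.append(-1), kind_a.append(-1), kind_c.append(-1)
            for ti, t in enumerate(spec.random):
                traits = self.term_traits[ti]
                if s not in traits:
                    continue
                a = traits.index(s)
                qt = len(traits)
                base = self.term_offsets[ti] + self.term_codes[ti][r] * qt
                for c in range(a + 1):  # PC needs c <= a; MV keeps only c == a
                    rows.append(o)
                    cols.append(base + c)
                    kind_term.append(ti), kind_a.append(a), kind_c.append(c)
        self.D_rows = np.array(rows, dtype=np.int64)
        self.D_cols = np.array(cols, dtype=np.int64)
        self.D_term = np.array(kind_term, dtype=np.int64)
        self.D_a = np.array(kind_a, dtype=np.int64)
        self.D_c = np.array(kind_c, dtype=np.int64)
        self._mv_entry = (self.D_term < 0) | (self.D_a == self.D_c)

    def _build_resid_structure(self):
        """COO structure of the block-diagonal residual weight matrix."""
        rows, cols, pat_id, pat_pos = [], [], [], []
        for r in range(self.n_rec):
            p = self.rec_pattern[r]
            traits = self.patterns[p]
            k = len(traits)
            base = self.rec_first_obs[r]
            for i in range(k):
                for j in range(k):
                    rows.append(base + i)
                    cols.append(base + j)
                    pat_id.append(p)
                    pat_pos.append(i * k + j)
        self.R_rows = np.array(rows, dtype=np.int64)
        self.R_cols = np.array(cols, dtype=np.int64)
        self.R_pat = np.array(pat_id, dtype=np.int64)
        self.R_pos = np.array(pat_pos, dtype=np.int64)

    def _rel_structure(self, param: str):
        """Block-expansion index arrays of the relationship part, per term."""
        if param in self._rel_struct:
            return self._rel_struct[param]
        out = []
        for ti, t in enumerate(self.spec.random):
            qt = len(self.term_traits[ti])
            off = self.term_offsets[ti]
            rel = (
                RelFactor.identity(self.term_levels[ti])
                if t.rel == "identity"
                else self.rels[t.rel]
            )
            h = rel.lower.tocoo()
            ha, hb, hidx = [], [], []
            sr, sc = [], []
            for e in range(h.nnz):
                a, b = int(h.row[e]), int(h.col[e])
                if param == "mv":
                    pairs = (
                        [(i, j) for i in range(qt) for j in range(qt)]
                        if a != b
                        else [(i, j) for i in range(qt) for j in range(i + 1)]
                    )
                else:  # pc: H^{-1} (x) I_q
                    pairs = [(c, c) for c in range(qt)]
                for i, j in pairs:
                    ha.append(off + a * qt + i)
                    hb.append(off + b * qt + j)
                    hidx.append(e)
                    sr.append(i)
                    sc.append(j)
            out.append(
                dict(
                    rows=np.array(ha, dtype=np.int64),
                    cols=np.array(hb, dtype=np.int64),
                    hidx=np.array(hidx, dtype=np.int64),
                    sr=np.array(sr, dtype=np.int64),
                    sc=np.array(sc, dtype=np.int64),
                    hdata=h.data.copy(),
                )
            )
        self._rel_struct[param] = out
        return out

    # -- numeric assembly ----------------------------------------------

    def residual_weights(self, sigma_e: np.ndarray):
        """Per-pattern inverse residual blocks W_S = Sigma_e[S,S]^{-1}."""
        Ws = []
        for traits in self.patterns:
            sub = sigma_e[np.ix_(traits, traits)]
            try:
                Ws.append(np.linalg.inv(sub))
            except np.linalg.LinAlgError as err:
                raise ValueError(
                    f"singular residual submatrix for trait pattern {traits}"
                ) from err
        return Ws

    def build_Rw(self, sigma_e: np.ndarray) -> sp.csc_matrix:
        Ws = self.residual_weights(sigma_e)
        flat = [W.ravel() for W in Ws]
        vals = np.empty(self.R_rows.size)
        for p, f in enumerate(flat):
            mask = self.R_pat == p
            vals[mask] = f[self.R_pos[mask]]
        return sp.coo_matrix(
            (vals, (self.R_rows, self.R_cols)), shape=(self.n_obs, self.n_obs)
        ).tocsc()

    def build_D(self, param: str, pct: PCTransform | None) -> sp.csr_matrix:
        if param == "mv":
            m = self._mv_entry
            vals = np.ones(int(m.sum()))
            rows, cols = self.D_rows[m], self.D_cols[m]
        else:
            rows, cols = self.D_rows, self.D_cols
            vals = np.ones(rows.size)
            rnd = self.D_term >= 0
            t_arr, a_arr, c_arr = self.D_term[rnd], self.D_a[rnd], self.D_c[rnd]
            v = np.empty(t_arr.size)
            for ti in range(len(self.spec.random)):
                mask = t_arr == ti
                v[mask] = pct.Q[ti][a_arr[mask], c_arr[mask]]
            vals[rnd] = v
        return sp.coo_matrix(
            (vals, (rows, cols)), shape=(self.n_obs, self.neq)
        ).tocsr()

    def build_rel_part(self, param: str, covs) -> tuple:
        """Relationship part of C (lower triangle) and per-term nnz tallies."""
        structs = self._rel_structure(param)
        mats, tallies = [], []
        for ti, st in enumerate(structs):
            if param == "mv":
                Minv = np.linalg.inv(covs.sigma_terms[ti])
                vals = st["hdata"][st["hidx"]] * Minv[st["sr"], st["sc"]]
            else:
                vals = st["hdata"][st["hidx"]]
            K = sp.coo_matrix(
                (vals, (st["rows"], st["cols"])), shape=(self.neq, self.neq)
            ).tocsc()
            mats.append(K)
            tallies.append(st["rows"].size)
        total = mats[0]
        for K in mats[1:]:
            total = total + K
        return total.tocsc(), tallies

    def _canonical_structure(self, param: str):
        """Fixed lower-triangle structure of the coefficient matrix.

        Computed once per parameterisation from all-positive placeholder
        values (no cancellation possible), so exact numerical zeros at
        particular covariance values — which do occur, e.g. when the residual
        and genetic starting matrices are proportional — cannot shrink the
        assembled pattern. A fixed pattern across REML iterates is what makes
        the cached symbolic factorisation valid.
        """
        if param not in self._zero_pattern:
            keep = self._mv_entry if param == "mv" else slice(None)
            ones_D = sp.coo_matrix(
                (
                    np.ones(self.D_rows[keep].size),
                    (self.D_rows[keep], self.D_cols[keep]),
                ),
                shape=(self.n_obs, self.neq),
            ).tocsr()
            ones_R = sp.coo_matrix(
                (np.ones(self.R_rows.size), (self.R_rows, self.R_cols)),
                shape=(self.n_obs, self.n_obs),
            ).tocsc()
            P = sp.tril((ones_D.T @ (ones_R @ ones_D)).tocsc(), format="csc")
            for st in self._rel_structure(param):
                P = P + sp.coo_matrix(
                    (np.ones(st["rows"].size), (st["rows"], st["cols"])),
                    shape=(self.neq, self.neq),
                ).tocsc()
            P = P.tocsc()
            P.sort_indices()
            flat = (
                np.repeat(np.arange(self.neq, dtype=np.int64), np.diff(P.indptr))
                * self.neq
                + P.indices
            )
            self._zero_pattern[param] = (P.indptr.copy(), P.indices.copy(), flat)
        return self._zero_pattern[param]

    def _expand_to_canonical(self, C_num: sp.csc_matrix, param: str) -> sp.csc_matrix:
        """Scatter assembled values onto the canonical structure (scipy prunes
        entries that cancel to exactly zero; the factorisation must not)."""
        indptr, indices, flat = self._canonical_structure(param)
        C_num = C_num.tocsc()
        C_num.sort_indices()
        keynum = (
            np.repeat(np.arange(self.neq, dtype=np.int64), np.diff(C_num.indptr))
            * self.neq
            + C_num.indices
        )
        pos = np.searchsorted(flat, keynum)
        if pos.size and not np.array_equal(flat[pos], keynum):
            raise AssertionError("assembled entry outside the structural pattern")
        data = np.zeros(indices.size)
        data[pos] = C_num.data
        return sp.csc_matrix((data, indices, indptr), shape=(self.neq, self.neq))

    def assemble(self, covs, parameterisation: str = "mv") -> MMESystem:
        """Assemble coefficient matrix (lower triangle) and right-hand side."""
        param = parameterisation.lower()
        if param not in ("mv", "pc"):
            raise ValueError("parameterisation must be 'mv' or 'pc'")
        pct = PCTransform(covs.sigma_terms) if param == "pc" else None
        Rw = self.build_Rw(covs.sigma_e)
        D = self.build_D(param, pct)
        C_data = sp.tril((D.T @ (Rw @ D)).tocsc(), format="csc")
        C_rel, tallies = self.build_rel_part(param, covs)
        coeff = self._expand_to_canonical((C_data + C_rel).tocsc(), param)
        rhs = D.T @ (Rw @ self.y_obs)
        return MMESystem(
            parameterisation=param,
            coeff=coeff,
            rhs=rhs,
            neq=self.neq,
            n_fixed=self.n_fixed,
            builder=self,
            C_data=C_data,
            C_rel=C_rel,
            rel_nnz=tallies,
            D=D,
            Rw=Rw,
            pct=pct,
        )

    def eq_groups(self) -> np.ndarray:
        """Equation-group ids for block orderings: every fixed column is its
        own group; the q components of one (term, level) form one group."""
        g = np.empty(self.neq, dtype=np.int64)
        g[: self.n_fixed] = np.arange(self.n_fixed)
        gid = self.n_fixed
        for ti in range(len(self.spec.random)):
            qt = len(self.term_traits[ti])
            off = self.term_offsets[ti]
            nl = self.term_levels[ti]
            g[off : off + nl * qt] = gid + np.repeat(np.arange(nl), qt)
            gid += nl
        return g

    # -- reporting -------------------------------------------------------

    def count_equations(self) -> int:
        return self.neq

    def describe_eq(self, i: int) -> str:
        if i < self.n_fixed:
            for (s, fac), off in self.fixed_offsets.items():
                nlev = len(self.fixed_levels[(s, fac)])
                if off <= i < off + nlev:
                    inv = {v: k for k, v in self.fixed_levels[(s, fac)].items()}
                    return (
                        f"fixed {fac}={inv[i - off]} trait {self.spec.traits[s]}"
                    )
        for ti, t in enumerate(self.spec.random):
            qt = len(self.term_traits[ti])
            off = self.term_offsets[ti]
            if off <= i < off + qt * self.term_levels[ti]:
                lev, comp = divmod(i - off, qt)
                return f"random {t.name} level {lev} component {comp}"
        return f"equation {i}"


def count_equations(spec: ModelSpec, data: pd.DataFrame, rels: Mapping[str, RelFactor]) -> int:
    """Equation count for a model/data pair, without numeric assembly."""
    return MMEBuilder(spec, data, rels).neq


def nnz_accounting(sys: MMESystem) -> dict:
    """Lower-triangle non-zero tallies, total and per block."""
    nf = sys.n_fixed
    C = sys.coeff

    def block(mat, r0, r1, c0, c1):
        return mat[r0:r1, :][:, c0:c1].nnz

    n = sys.neq
    data_uu = block(sys.C_data, nf, n, nf, n)
    return {
        "parameterisation": sys.parameterisation,
        "neq": n,
        "nnz_total": C.nnz,
        "nnz_beta_beta": block(C, 0, nf, 0, nf),
        "nnz_beta_u": block(C, nf, n, 0, nf),
        "nnz_uu_data": data_uu,
        "nnz_uu_rel": int(sum(sys.rel_nnz)),
        "rel_nnz_per_term": list(sys.rel_nnz),
    }
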