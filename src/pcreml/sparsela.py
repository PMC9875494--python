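"""Sparse symmetric linear algebra for the mixed-model equations.

Provides a fill-reducing ordering, symbolic factorisation, simplicial LDL'
Cholesky, triangular solves, the log-determinant, and the Takahashi
(selected) inverse subset needed for the trace terms of the REML gradient.

All kernels operate on the upper triangle of the permuted matrix in
compressed-column form, following the classic up-looking LDL' algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numba import njit

__all__ = [
    "reorder",
    "symbolic_factor",
    "numeric_factor",
    "cholesky",
    "CholFactor",
    "InverseSubset",
    "SymbolicFactor",
    "Factorizer",
]


# above this many gather pairs the selected inverse falls back to the
# memory-free binary-search kernel; int32 indices, 4 bytes each, so the
# cached gather map tops out around 1.3 GB
_TAKA_PAIR_LIMIT = 330_000_000


class IndefiniteMatrixError(np.linalg.LinAlgError):
    """Raised when a pivot is non-positive; carries the equation index."""

    def __init__(self, k: int, label: str | None = None):
        self.equation = k
        msg = f"non-positive pivot at equation {k}"
        if label:
            msg += f" ({label})"
        super().__init__(msg)


# ---------------------------------------------------------------------------
# ordering


def _symmetrize_pattern(A: sp.spmatrix) -> sp.csc_matrix:
    A = A.tocsc()
    full = (A + A.T).tocsc()
    full.sum_duplicates()
    return full


def _mmd(full: sp.csc_matrix) -> np.ndarray:
    """Multiple-minimum-degree ordering of a symmetric pattern via SuperLU
    on a positive-definite proxy with the same structure."""
    n = full.shape[0]
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    proxy = full.copy().astype(float)
    proxy.data[:] = -1.0
    deg = np.asarray(abs(proxy).sum(axis=0)).ravel()
    proxy = (proxy + sp.diags(deg + 1.0)).tocsc()
    lu = spla.splu(
        proxy,
        permc_spec="MMD_AT_PLUS_A",
        diag_pivot_thresh=0.0,
        options={"SymmetricMode": True},
    )
    # SuperLU's perm_c[j] is the position of original column j; our
    # convention is perm[k] = original index at position k, i.e. the inverse
    return np.argsort(np.asarray(lu.perm_c, dtype=np.int64))


def _grouped_mmd(full: sp.csc_matrix, groups: np.ndarray) -> np.ndarray:
    """Minimum degree on the quotient graph of equation groups.

    Equations of one group (e.g. the q trait/component equations of one
    animal) are collapsed to a single node, ordered by minimum degree, and
    re-expanded with group members kept consecutive. Both parameterisations
    of the MME then inherit the same animal-level elimination order, which
    keeps their factor fill comparable.
    """
    n = full.shape[0]
    groups = np.asarray(groups, dtype=np.int64)
    ngr = int(groups.max()) + 1
    S = sp.csr_matrix(
        (np.ones(n), (np.arange(n), groups)), shape=(n, ngr)
    )
    coll = (S.T @ full @ S).tocsc()
    gperm = _mmd(coll)
    order = np.argsort(groups, kind="stable")
    starts = np.searchsorted(groups[order], np.arange(ngr))
    ends = np.append(starts[1:], n)
    return np.concatenate([order[starts[g] : ends[g]] for g in gperm])


def reorder(
    pattern: sp.spmatrix, method: str = "mmd", groups: np.ndarray | None = None
) -> np.ndarray:
    """Fill-reducing permutation for a symmetric pattern.

    method 'mmd' uses a multiple-minimum-degree ordering of the structure;
    'rcm' uses reverse Cuthill-McKee; 'natural' is the identity. When
    ``groups`` is given, a block ordering on the group quotient graph is
    also tried. Among the candidates (including the natural order) the one
    with the fewest factor non-zeros by symbolic factorisation wins, so the
    result is never worse than the natural ordering.
    """
    full = _symmetrize_pattern(pattern)
    n = full.shape[0]
    natural = np.arange(n, dtype=np.int64)
    if method == "natural":
        return natural
    if method == "rcm":
        perm = sp.csgraph.reverse_cuthill_mckee(full, symmetric_mode=True)
        candidates = [np.asarray(perm, dtype=np.int64)]
    elif method == "mmd":
        candidates = [_mmd(full)]
        if groups is not None:
            candidates.append(_grouped_mmd(full, groups))
    else:
        raise ValueError(f"unknown ordering method {method!r}")
    candidates.append(natural)
    counts = [_nnz_L(full, p) for p in candidates]
    return candidates[int(np.argmin(counts))]


def _permuted_upper(full: sp.csc_matrix, perm: np.ndarray) -> sp.csc_matrix:
    p = full[perm][:, perm].tocsc()
    up = sp.triu(p, format="csc")
    up.sort_indices()
    return up


def _nnz_L(full: sp.csc_matrix, perm: np.ndarray) -> int:
    up = _permuted_upper(full, perm)
    _, lnz = _ldl_symbolic(up.shape[0], up.indptr, up.indices)
    return int(lnz.sum()) + up.shape[0]


# ---------------------------------------------------------------------------
# symbolic / numeric LDL' (up-looking, after Davis's LDL)


@njit(cache=True)
def _ldl_symbolic(n, Ap, Ai):  # pragma: no cover - numba kernel
    parent = np.full(n, -1, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    for k in range(n):
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i < k and flag[i] != k:
                if parent[i] == -1:
                    parent[i] = k
                lnz[i] += 1
                flag[i] = k
                i = parent[i]
    return parent, lnz


@njit(cache=True)
def _ldl_numeric(n, Ap, Ai, Ax, parent, Lp, piv_tol):  # pragma: no cover
    Li = np.zeros(Lp[n], dtype=np.int64)
    Lx = np.zeros(Lp[n])
    D = np.zeros(n)
    Y = np.zeros(n)
    pattern = np.zeros(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    # lnz is returned: if the numeric input pattern is a strict subset of the
    # symbolic one, columns fill fewer slots than Lp allocates
    maxdiag = 0.0
    for k in range(n):
        Y[k] = 0.0
        top = n
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i > k:
                continue
            Y[i] += Ax[p]
            length = 0
            while flag[i] != k:
                pattern[length] = i
                length += 1
                flag[i] = k
                i = parent[i]
            while length > 0:
                length -= 1
                top -= 1
                pattern[top] = pattern[length]
        D[k] = Y[k]
        Y[k] = 0.0
        while top < n:
            i = pattern[top]
            yi = Y[i]
            Y[i] = 0.0
            for p in range(Lp[i], Lp[i] + lnz[i]):
                Y[Li[p]] -= Lx[p] * yi
            l_ki = yi / D[i]
            D[k] -= l_ki * yi
            Li[Lp[i] + lnz[i]] = k
            Lx[Lp[i] + lnz[i]] = l_ki
            lnz[i] += 1
            top += 1
        ad = abs(D[k])
        if ad > maxdiag:
            maxdiag = ad
        if not np.isfinite(D[k]) or D[k] <= piv_tol * maxdiag:
            return Li, Lx, D, lnz, k
    return Li, Lx, D, lnz, -1


@njit(cache=True)
def _sort_columns(n, Lp, Li, Lx):  # pragma: no cover - numba kernel
    for j in range(n):
        lo, hi = Lp[j], Lp[j + 1]
        order = np.argsort(Li[lo:hi])
        Li[lo:hi] = Li[lo:hi][order]
        Lx[lo:hi] = Lx[lo:hi][order]


@njit(cache=True)
def _lookup_one(Lp, Li, vals, diag, a, b):  # pragma: no cover - numba kernel
    # value of the selected inverse at permuted position (a, b), a != b ok
    if a == b:
        return diag[a]
    if a < b:
        a, b = b, a
    lo, hi = Lp[b], Lp[b + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        if Li[mid] == a:
            return vals[mid]
        if Li[mid] < a:
            lo = mid + 1
        else:
            hi = mid
    return 0.0


@njit(cache=True)
def _takahashi(n, Lp, Li, Lx, D):  # pragma: no cover - numba kernel
    """Selected inverse on the pattern of L (plus diagonal).

    Erisman-Tinney recurrences for C^{-1} from C = L D L' with unit lower
    triangular L; columns processed last to first, rows within a column in
    decreasing order, so every referenced entry is already available.
    """
    Z = np.zeros(Lp[n])
    Zd = np.zeros(n)
    for j in range(n - 1, -1, -1):
        lo, hi = Lp[j], Lp[j + 1]
        for q in range(hi - 1, lo - 1, -1):
            i = Li[q]
            s = 0.0
            for p in range(lo, hi):
                k = Li[p]
                if k == i:
                    s += Lx[p] * Zd[i]
                else:
                    s += Lx[p] * _lookup_one(Lp, Li, Z, Zd, i, k)
            Z[q] = -s
        s = 1.0 / D[j]
        for p in range(lo, hi):
            s -= Lx[p] * Z[p]
        Zd[j] = s
    return Z, Zd


@njit(cache=True)
def _taka_pairs(n, Lp, Li):  # pragma: no cover - numba kernel
    """Precomputed gather indices for the Takahashi recurrences.

    For every column j (processed last to first) and every off-diagonal
    entry (i, j) of L (rows descending), the recurrence sums over column j;
    the summand Z value lives at position (max(i,k), min(i,k)) of the factor
    pattern or on the diagonal. Those positions depend only on the pattern,
    so they are resolved once by binary search and replayed numerically.
    Index encoding: [0, nnz) strict-lower storage, [nnz, nnz+n) diagonal,
    nnz+n a guaranteed-zero slot.
    """
    nnz = Lp[n]
    total = np.int64(0)
    for j in range(n):
        c = Lp[j + 1] - Lp[j]
        total += c * c
    idx = np.empty(total, dtype=np.int32)
    pos = 0
    for j in range(n - 1, -1, -1):
        lo, hi = Lp[j], Lp[j + 1]
        for q in range(hi - 1, lo - 1, -1):
            i = Li[q]
            for p in range(lo, hi):
                k = Li[p]
                if k == i:
                    idx[pos] = nnz + i
                else:
                    a, b = (i, k) if i > k else (k, i)
                    l2, h2 = Lp[b], Lp[b + 1]
                    r = nnz + n  # zero slot (outside the factor pattern)
                    while l2 < h2:
                        mid = (l2 + h2) // 2
                        if Li[mid] == a:
                            r = mid
                            break
                        elif Li[mid] < a:
                            l2 = mid + 1
                        else:
                            h2 = mid
                    idx[pos] = r
                pos += 1
    return idx


@njit(cache=True)
def _takahashi_indexed(n, Lp, Li, Lx, D, idx):  # pragma: no cover
    nnz = Lp[n]
    Zall = np.zeros(nnz + n + 1)
    pos = 0
    for j in range(n - 1, -1, -1):
        lo, hi = Lp[j], Lp[j + 1]
        for q in range(hi - 1, lo - 1, -1):
            s = 0.0
            for p in range(lo, hi):
                s += Lx[p] * Zall[idx[pos]]
                pos += 1
            Zall[q] = -s
        s = 1.0 / D[j]
        for p in range(lo, hi):
            s -= Lx[p] * Zall[p]
        Zall[nnz + j] = s
    return Zall[:nnz], Zall[nnz : nnz + n]


@njit(cache=True)
def _solve_many(n, Lp, Li, Lx, D, B):  # pragma: no cover - numba kernel
    # B: n x m, solved in place (L D L') X = B
    m = B.shape[1]
    for c in range(m):
        for j in range(n):
            xj = B[j, c]
            if xj != 0.0:
                for p in range(Lp[j], Lp[j + 1]):
                    B[Li[p], c] -= Lx[p] * xj
        for j in range(n):
            B[j, c] /= D[j]
        for j in range(n - 1, -1, -1):
            s = B[j, c]
            for p in range(Lp[j], Lp[j + 1]):
                s -= Lx[p] * B[Li[p], c]
            B[j, c] = s


@njit(cache=True)
def _lookup_many(Lp, Li, vals, diag, pos_i, pos_j):  # pragma: no cover
    out = np.empty(pos_i.size)
    for t in range(pos_i.size):
        out[t] = _lookup_one(Lp, Li, vals, diag, pos_i[t], pos_j[t])
    return out


# ---------------------------------------------------------------------------
# user-facing containers


@dataclass
class SymbolicFactor:
    """Permutation, elimination tree and column pointers of L."""

    perm: np.ndarray
    parent: np.ndarray
    Lp: np.ndarray
    n: int
    taka_idx: np.ndarray = None  # cached Takahashi gather indices

    @property
    def nnz_L(self) -> int:
        return int(self.Lp[self.n]) + self.n  # strict lower + unit diagonal


def symbolic_factor(pattern: sp.spmatrix, perm: np.ndarray | None = None) -> SymbolicFactor:
    """Symbolic LDL' factorisation of a symmetric pattern under ``perm``."""
    full = _symmetrize_pattern(pattern)
    n = full.shape[0]
    if perm is None:
        perm = np.arange(n, dtype=np.int64)
    up = _permuted_upper(full, perm)
    parent, lnz = _ldl_symbolic(n, up.indptr, up.indices)
    Lp = np.zeros(n + 1, dtype=np.int64)
    Lp[1:] = np.cumsum(lnz)
    return SymbolicFactor(perm=np.asarray(perm, dtype=np.int64), parent=parent, Lp=Lp, n=n)


@dataclass
class CholFactor:
    """Numeric LDL' factor of P C P' with selected-inverse support.

    L is unit lower triangular (strict part stored column-wise, rows sorted),
    D the positive pivot vector. ``logdet`` is log|C| = sum(log D).
    ``Lp`` is the factor's own column pointer; it equals the symbolic one
    unless the numeric input pattern was a strict subset (then the factor was
    compacted and pattern-level caches on the symbolic object do not apply).
    """

    sym: SymbolicFactor
    Li: np.ndarray
    Lx: np.ndarray
    D: np.ndarray
    Lp: np.ndarray = None
    shared_pattern: bool = True
    _pos: np.ndarray = None  # inverse permutation
    _inv: "InverseSubset" = None

    def __post_init__(self):
        if self.Lp is None:
            self.Lp = self.sym.Lp
        self._pos = np.empty(self.sym.n, dtype=np.int64)
        self._pos[self.sym.perm] = np.arange(self.sym.n)

    @property
    def n(self) -> int:
        return self.sym.n

    @property
    def logdet(self) -> float:
        return float(np.sum(np.log(self.D)))

    @property
    def nnz_L(self) -> int:
        return int(self.Lp[self.n]) + self.n

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Solve C x = b for one or many right-hand sides."""
        b = np.asarray(b, dtype=float)
        one = b.ndim == 1
        B = b.reshape(self.n, -1)[self.sym.perm].copy()
        _solve_many(self.n, self.Lp, self.Li, self.Lx, self.D, B)
        out = np.empty_like(B)
        out[self.sym.perm] = B
        return out[:, 0] if one else out

    def inverse_subset(self) -> "InverseSubset":
        if self._inv is None:
            cols = np.diff(self.Lp)
            n_pairs = int(np.sum(cols.astype(np.int64) ** 2))
            if n_pairs <= _TAKA_PAIR_LIMIT:
                # pattern-fixed gather indices, computed once and replayed
                if self.shared_pattern and self.sym.taka_idx is not None:
                    idx = self.sym.taka_idx
                else:
                    idx = _taka_pairs(self.n, self.Lp, self.Li)
                    if self.shared_pattern:
                        self.sym.taka_idx = idx
                Z, Zd = _takahashi_indexed(
                    self.n, self.Lp, self.Li, self.Lx, self.D, idx
                )
            else:
                Z, Zd = _takahashi(self.n, self.Lp, self.Li, self.Lx, self.D)
            self._inv = InverseSubset(factor=self, Z=Z, Zd=Zd)
        return self._inv


@dataclass
class InverseSubset:
    """Entries of C^{-1} on the pattern of L (hence on all of C's pattern)."""

    factor: CholFactor
    Z: np.ndarray
    Zd: np.ndarray

    def lookup(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """C^{-1} values at original (row, col) positions.

        Positions must lie in the factor pattern (guaranteed for any position
        in the pattern of C); other positions return 0.
        """
        f = self.factor
        pi = f._pos[np.asarray(rows, dtype=np.int64)]
        pj = f._pos[np.asarray(cols, dtype=np.int64)]
        return _lookup_many(f.Lp, f.Li, self.Z, self.Zd, pi, pj)

    def trace_product(self, Dmat: sp.spmatrix) -> float:
        """tr(C^{-1} Dmat) for Dmat with pattern inside pattern(C)."""
        coo = Dmat.tocoo()
        vals = self.lookup(coo.col, coo.row)
        return float(np.dot(vals, coo.data))


def numeric_factor(
    C: sp.spmatrix,
    sym: SymbolicFactor,
    piv_tol: float = 1e-12,
    eqmap=None,
) -> CholFactor:
    """Numeric LDL' of symmetric C (any triangle or full) under ``sym``."""
    full = _symmetrize_half(C)
    up = _permuted_upper(full, sym.perm)
    Li, Lx, D, lnz, bad = _ldl_numeric(
        sym.n, up.indptr, up.indices, up.data, sym.parent, sym.Lp, piv_tol
    )
    if bad >= 0:
        orig = int(sym.perm[bad])
        label = eqmap(orig) if callable(eqmap) else None
        raise IndefiniteMatrixError(orig, label)
    return _finish_factor(sym, Li, Lx, D, lnz)


def _finish_factor(sym, Li, Lx, D, lnz) -> CholFactor:
    """Sort columns; compact if the numeric pattern undershot the symbolic
    allocation (possible when input entries cancelled to exact zeros)."""
    Lp_eff = np.zeros(sym.n + 1, dtype=np.int64)
    Lp_eff[1:] = np.cumsum(lnz)
    if np.array_equal(Lp_eff, sym.Lp):
        _sort_columns(sym.n, sym.Lp, Li, Lx)
        return CholFactor(sym=sym, Li=Li, Lx=Lx, D=D)
    take = np.concatenate(
        [np.arange(sym.Lp[j], sym.Lp[j] + lnz[j]) for j in range(sym.n)]
    ) if sym.n else np.array([], dtype=np.int64)
    Li2, Lx2 = Li[take], Lx[take]
    _sort_columns(sym.n, Lp_eff, Li2, Lx2)
    return CholFactor(sym=sym, Li=Li2, Lx=Lx2, D=D, Lp=Lp_eff,
                      shared_pattern=False)


def _symmetrize_half(C: sp.spmatrix) -> sp.csc_matrix:
    """Full symmetric matrix from a lower/upper triangle or full storage."""
    C = C.tocsc()
    lower = sp.tril(C, format="csc")
    if lower.nnz == C.nnz:  # triangular storage
        d = sp.diags(lower.diagonal())
        return (lower + lower.T - d).tocsc()
    return C


def cholesky(C: sp.spmatrix, ordering: str = "mmd", eqmap=None) -> CholFactor:
    """Convenience: reorder + symbolic + numeric factorisation of SPD C."""
    full = _symmetrize_half(C)
    perm = reorder(full, method=ordering)
    sym = symbolic_factor(full, perm)
    return numeric_factor(full, sym, eqmap=eqmap)


class Factorizer:
    """Reusable symbolic factorisation for repeated numeric refactors.

    The sparsity pattern of the mixed-model coefficient matrix is fixed
    across REML iterates; only the numeric values change.
    """

    def __init__(self, C: sp.spmatrix, ordering: str = "mmd",
                 groups: np.ndarray | None = None):
        # canonical lower-triangle structure (positional, keeps explicit
        # zeros: scipy value arithmetic would prune exact cancellations and
        # silently desynchronise the numeric and symbolic patterns)
        low = self._as_lower(C)
        n = low.shape[0]
        self.n = n
        self.pattern_nnz = low.nnz
        self._indptr = low.indptr.copy()
        self._indices = low.indices.copy()
        r = low.indices
        c = np.repeat(np.arange(n, dtype=np.int64), np.diff(low.indptr))
        src = np.arange(low.nnz, dtype=np.int64)
        off = r != c
        fr = np.concatenate([r, c[off]])
        fc = np.concatenate([c, r[off]])
        fs = np.concatenate([src, src[off]])
        fullpat = sp.coo_matrix(
            (np.ones(fr.size), (fr, fc)), shape=(n, n)
        ).tocsc()
        self.perm = reorder(fullpat, method=ordering, groups=groups)
        self.sym = symbolic_factor(fullpat, self.perm)
        # permuted upper structure with a gather map into the lower values
        pos = np.empty(n, dtype=np.int64)
        pos[self.perm] = np.arange(n)
        pr, pc = pos[fr], pos[fc]
        keep = pr <= pc
        pr, pc, fs = pr[keep], pc[keep], fs[keep]
        order = np.lexsort((pr, pc))
        pr, pc, fs = pr[order], pc[order], fs[order]
        self._up_indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(self._up_indptr, pc + 1, 1)
        self._up_indptr = np.cumsum(self._up_indptr)
        self._up_indices = pr
        self._gather = fs

    @staticmethod
    def _as_lower(C: sp.spmatrix) -> sp.csc_matrix:
        C = C.tocsc()
        low = sp.tril(C, format="csc")  # positional, no value pruning
        low.sort_indices()
        return low

    @property
    def nnz_L(self) -> int:
        return self.sym.nnz_L

    def factor(self, C: sp.spmatrix, eqmap=None,
               piv_tol: float = 1e-12) -> CholFactor:
        low = self._as_lower(C)
        if not (
            np.array_equal(low.indptr, self._indptr)
            and np.array_equal(low.indices, self._indices)
        ):
            raise ValueError(
                "matrix sparsity pattern differs from the symbolic "
                "factorisation; rebuild the Factorizer"
            )
        up_data = low.data[self._gather]
        Li, Lx, D, lnz, bad = _ldl_numeric(
            self.n, self._up_indptr, self._up_indices, up_data,
            self.sym.parent, self.sym.Lp, piv_tol,
        )
        if bad >= 0:
            orig = int(self.sym.perm[bad])
            label = eqmap(orig) if callable(eqmap) else None
            raise IndefiniteMatrixError(orig, label)
        return _finish_factor(self.sym, Li, Lx, D, lnz)
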