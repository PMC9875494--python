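"""Pedigree, genomic and joint (single-step) relationship structures.

This module builds the sparse inverse numerator relationship matrix A^{-1}
by Henderson's rules with exact inbreeding (Meuwissen-Luo recursion), the
A22 submatrix for genotyped animals, the genomic relationship matrix G
(VanRaden Method 1 with observed allele frequencies and a minor-allele-
frequency filter), the moment alignment of G to A22, and the single-step
joint inverse H^{-1} = A^{-1} + [0, 0; 0, G*^{-1} - A22^{-1}].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numba import njit

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "RelFactor",
    "build_A_inverse",
    "build_A22",
    "build_grm",
    "align_grm",
    "build_H_inverse",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (order, cycles, unknown ids)."""


@dataclass(frozen=True)
class Pedigree:
    """Ordered pedigree over dense integer ids 1..N.

    ``sire`` and ``dam`` are 0-based parent indices with -1 for unknown,
    aligned with animal index 0..N-1 (external id ``labels[i]``).
    Every parent must precede its offspring (topological order).
    """

    sire: np.ndarray
    dam: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        sire = np.asarray(self.sire, dtype=np.int64)
        dam = np.asarray(self.dam, dtype=np.int64)
        object.__setattr__(self, "sire", sire)
        object.__setattr__(self, "dam", dam)
        n = sire.size
        if n < 1 or dam.size != n:
            raise PedigreeError("pedigree must contain at least one animal")
        for name, par in (("sire", sire), ("dam", dam)):
            bad = np.nonzero(par >= np.arange(n))[0]
            if bad.size:
                raise PedigreeError(
                    f"{name} of animal {bad[0] + 1} does not precede it "
                    "(cycle or unordered pedigree)"
                )
            if np.any(par < -1):
                raise PedigreeError(f"negative {name} id")
        if self.labels and len(self.labels) != n:
            raise PedigreeError("labels length mismatch")

    @property
    def n(self) -> int:
        return self.sire.size

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "Pedigree":
        """Build from (animal, sire, dam) triples; 0/'NA'/'' = unknown parent.

        External ids are remapped to dense 1..N in order of appearance; the
        mapping is retained in ``labels``.
        """
        def norm(v):
            if v is None:
                return 0
            s = str(v).strip()
            if s in ("0", "NA", "", ".", "na", "nan"):
                return 0
            return s

        records = list(records)
        labels = []
        index: dict = {}
        for a, s, d in records:
            a = norm(a)
            if a == 0:
                raise PedigreeError("animal id missing in pedigree record")
            if a in index:
                raise PedigreeError(f"duplicate animal id {a!r}")
            index[a] = len(labels)
            labels.append(a)
        sire = np.full(len(labels), -1, dtype=np.int64)
        dam = np.full(len(labels), -1, dtype=np.int64)
        for i, (a, s, d) in enumerate(records):
            for arr, p in ((sire, norm(s)), (dam, norm(d))):
                if p != 0:
                    if p not in index:
                        raise PedigreeError(f"parent id {p!r} not in pedigree")
                    arr[i] = index[p]
        return cls(sire=sire, dam=dam, labels=tuple(labels))

    def index_of(self, ids) -> np.ndarray:
        """Map external ids to 0-based pedigree indices (string-normalised)."""
        lookup = (
            {str(lab).strip(): i for i, lab in enumerate(self.labels)}
            if self.labels
            else {}
        )
        out = np.empty(len(ids), dtype=np.int64)
        for k, v in enumerate(ids):
            if self.labels:
                key = str(v).strip()
                if key not in lookup and key.endswith(".0"):
                    key = key[:-2]  # ids that travelled through a float column
                if key not in lookup:
                    raise KeyError(f"id {v!r} not in pedigree")
                out[k] = lookup[key]
            else:
                out[k] = int(v) - 1
        return out


@dataclass(frozen=True)
class GenotypeMatrix:
    """SNP allele counts for a subset of pedigree animals.

    ``indices`` are 0-based pedigree indices; ``counts`` is n_geno x n_snp
    with entries in {0, 1, 2}. Allele frequencies are the observed ones,
    computed from the counts themselves. ``founder_freq`` optionally carries
    the base-population frequencies when the matrix comes from a simulation.
    """

    indices: np.ndarray
    counts: np.ndarray
    founder_freq: np.ndarray | None = None

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        cnt = np.asarray(self.counts)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "counts", cnt)
        if cnt.ndim != 2 or cnt.shape[0] != idx.size:
            raise ValueError("counts must be n_geno x n_snp")
        if cnt.size and (cnt.min() < 0 or cnt.max() > 2):
            raise ValueError("allele counts must lie in {0,1,2}")
        if np.unique(idx).size != idx.size:
            raise ValueError("duplicate genotyped individual")

    @property
    def n_geno(self) -> int:
        return self.indices.size

    @property
    def n_snp(self) -> int:
        return self.counts.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Observed allele frequency per SNP (mean count / 2)."""
        if self.n_geno == 0:
            return np.zeros(self.n_snp)
        return self.counts.mean(axis=0) / 2.0


@dataclass
class RelFactor:
    """Sparse symmetric matrix over animal ids (lower triangle stored).

    Used for inverse relationship matrices: A^{-1} (kind='pedigree-inverse'),
    H^{-1} (kind='joint-inverse') and the identity (kind='identity').
    ``logdet`` is the log-determinant of the *stored* matrix, so the
    log-determinant of the relationship matrix itself is ``-logdet``.
    """

    kind: str
    lower: sp.csc_matrix
    _full: sp.csc_matrix = field(default=None, repr=False)
    _factor: object = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.lower.shape[0]

    @property
    def full(self) -> sp.csc_matrix:
        """Full symmetric matrix (upper triangle mirrored in)."""
        if self._full is None:
            low = self.lower.tocsc()
            d = sp.diags(low.diagonal())
            self._full = (low + low.T - d).tocsc()
        return self._full

    def factorize(self):
        """Cached sparse Cholesky of the stored matrix (must be PD)."""
        if self._factor is None:
            from .sparsela import cholesky

            self._factor = cholesky(self.full)
        return self._factor

    @property
    def logdet(self) -> float:
        if self.kind == "identity":
            return 0.0
        return self.factorize().logdet

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Solve (stored matrix) x = b; for an inverse relationship matrix
        this applies the relationship matrix itself."""
        if self.kind == "identity":
            return np.array(b, dtype=float, copy=True)
        return self.factorize().solve(b)

    @classmethod
    def identity(cls, n: int) -> "RelFactor":
        return cls(kind="identity", lower=sp.identity(n, format="csc"))

    def to_coo_text(self) -> str:
        """Coordinate text export of the lower triangle, 1-based indices."""
        coo = self.lower.tocoo()
        lines = [
            f"{i + 1} {j + 1} {v:.12g}"
            for i, j, v in sorted(zip(coo.row, coo.col, coo.data))
        ]
        return "\n".join(lines) + "\n"


@njit(cache=True)
def _inbreeding(sire, dam):  # pragma: no cover - numba kernel
    """Meuwissen-Luo recursion for inbreeding coefficients.

    Returns (F, dvec) where dvec[i] is the Mendelian-sampling variance
    coefficient used in Henderson's rules.
    """
    n = sire.size
    F = np.zeros(n)
    dvec = np.ones(n)
    point = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            dvec[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0:
            dvec[i] = 0.75 - 0.25 * F[s]
        elif d >= 0:
            dvec[i] = 0.75 - 0.25 * F[d]
        else:
            dvec[i] = 1.0
        if s < 0 or d < 0:
            continue  # F stays 0 when a parent is unknown
        # A_ii = sum_j L_ij^2 D_j over the ancestry of i (Meuwissen-Luo)
        a_ii = 0.0
        point[i] = 1.0
        for j in range(i, -1, -1):
            w = point[j]
            if w == 0.0:
                continue
            point[j] = 0.0
            a_ii += w * w * dvec[j]
            js, jd = sire[j], dam[j]
            if js >= 0:
                point[js] += 0.5 * w
            if jd >= 0:
                point[jd] += 0.5 * w
        F[i] = a_ii - 1.0
    return F, dvec


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F for all animals."""
    return _inbreeding(ped.sire, ped.dam)[0]


def build_A_inverse(ped: Pedigree) -> RelFactor:
    """Sparse A^{-1} by Henderson's rules with exact inbreeding.

    Non-zeros occur only at diagonal, parent-offspring and mate-pair
    positions.
    """
    _, dvec = _inbreeding(ped.sire, ped.dam)
    n = ped.n
    rows, cols, vals = [], [], []

    def add(i, j, v):
        if i >= j:
            rows.append(i), cols.append(j), vals.append(v)
        else:
            rows.append(j), cols.append(i), vals.append(v)

    for i in range(n):
        alpha = 1.0 / dvec[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        add(i, i, alpha)
        for p in parents:
            add(i, p, -alpha / 2.0)
        if len(parents) == 2:
            s, d = parents
            if s == d:
                add(s, s, alpha)
            else:
                add(s, s, alpha / 4.0)
                add(d, d, alpha / 4.0)
                add(max(s, d), min(s, d), alpha / 4.0)  # mate pair
        elif len(parents) == 1:
            add(parents[0], parents[0], alpha / 4.0)
    lower = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    lower.sum_duplicates()
    # structural zeros from exact cancellation are kept: the pattern is
    # diagonal + parent-offspring + mate pairs by construction
    return RelFactor(kind="pedigree-inverse", lower=lower)


def tabular_A(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular recursion.

    O(N^2) memory; intended for oracles, A22 extraction and small problems.
    """
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def build_A22(ped: Pedigree, geno_idx: np.ndarray) -> np.ndarray:
    """Dense A submatrix for the genotyped animals.

    Columns of A are obtained by solving A^{-1} y = e_g with a sparse LU of
    the exact Henderson inverse, so A22 matches the tabular recursion.
    """
    geno_idx = np.asarray(geno_idx, dtype=np.int64)
    if geno_idx.size and (geno_idx.min() < 0 or geno_idx.max() >= ped.n):
        raise KeyError("genotyped index outside pedigree")
    if geno_idx.size == 0:
        return np.zeros((0, 0))
    ainv = build_A_inverse(ped).full
    lu = spla.splu(ainv.tocsc())
    rhs = np.zeros((ped.n, geno_idx.size))
    rhs[geno_idx, np.arange(geno_idx.size)] = 1.0
    cols = lu.solve(rhs)
    a22 = cols[geno_idx, :]
    return 0.5 * (a22 + a22.T)


def build_grm(gm: GenotypeMatrix, maf_min: float = 0.02) -> np.ndarray:
    """Genomic relationship matrix, VanRaden Method 1.

    Allele counts are centred by twice the observed frequency; SNPs with
    minor allele frequency strictly below ``maf_min`` are excluded from both
    the cross-product and the denominator 2*sum(p(1-p)). Frequencies are
    computed on all SNPs before filtering.
    """
    p = gm.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    if not np.any(keep):
        raise ValueError("no SNP passes the minor-allele-frequency filter")
    pk = p[keep]
    M = gm.counts[:, keep].astype(float) - 2.0 * pk
    denom = 2.0 * np.sum(pk * (1.0 - pk))
    G = (M @ M.T) / denom
    return 0.5 * (G + G.T)


def align_grm(G: np.ndarray, A22: np.ndarray) -> np.ndarray:
    """Moment alignment G* = a + b*G matching A22.

    a and b solve the 2x2 system equating the mean diagonal and the overall
    mean of G* to those of A22.
    """
    G = np.asarray(G, dtype=float)
    A22 = np.asarray(A22, dtype=float)
    if G.shape != A22.shape:
        raise ValueError("G and A22 dimensions differ")
    md_g, m_g = G.diagonal().mean(), G.mean()
    md_a, m_a = A22.diagonal().mean(), A22.mean()
    M = np.array([[1.0, md_g], [1.0, m_g]])
    if abs(np.linalg.det(M)) < 1e-12 * max(1.0, abs(md_g), abs(m_g)):
        raise np.linalg.LinAlgError(
            "degenerate alignment system (G has equal diagonal and overall means)"
        )
    a, b = np.linalg.solve(M, np.array([md_a, m_a]))
    return a + b * G


def _chol_or_none(M: np.ndarray):
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        return None


def build_H_inverse(
    ped: Pedigree,
    Gstar: np.ndarray,
    geno_idx: np.ndarray,
    blend: float = 0.01,
    A22: np.ndarray | None = None,
) -> RelFactor:
    """Single-step joint inverse H^{-1}.

    H^{-1} = A^{-1} + Delta, with Delta zero except the genotyped block,
    which equals G*^{-1} - A22^{-1}. If G* is not positive definite it is
    blended once with A22: G* <- (1-blend)*G* + blend*A22.
    """
    geno_idx = np.asarray(geno_idx, dtype=np.int64)
    ainv = build_A_inverse(ped)
    if geno_idx.size == 0:
        return RelFactor(kind="pedigree-inverse", lower=ainv.lower)
    if A22 is None:
        A22 = build_A22(ped, geno_idx)
    L = _chol_or_none(Gstar)
    if L is None:
        Gstar = (1.0 - blend) * Gstar + blend * A22
        L = _chol_or_none(Gstar)
        if L is None:
            cond = np.linalg.cond(Gstar)
            raise np.linalg.LinAlgError(
                f"aligned G not positive definite even after blending "
                f"(condition estimate {cond:.3g})"
            )
    La = _chol_or_none(A22)
    if La is None:
        raise np.linalg.LinAlgError(
            f"A22 not positive definite (condition estimate {np.linalg.cond(A22):.3g})"
        )
    ng = geno_idx.size
    Ginv = np.linalg.inv(Gstar)
    A22inv = np.linalg.inv(A22)
    delta = Ginv - A22inv
    # merge the dense genotyped block into the sparse lower triangle
    rr, cc = np.meshgrid(geno_idx, geno_idx, indexing="ij")
    mask = rr >= cc
    dcoo = sp.coo_matrix(
        (delta[mask.nonzero()], (rr[mask], cc[mask])), shape=(ped.n, ped.n)
    )
    lower = (ainv.lower + dcoo.tocsc()).tocsc()
    lower.sum_duplicates()
    return RelFactor(kind="joint-inverse", lower=lower)
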