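"""Synthetic data: generation-structured pedigrees, gene-dropped SNP
genotypes and multivariate phenotypes with contemporary groups.

The default configuration emulates the structure of a simulated livestock
data set with 21,000 recorded individuals in eight discrete generations:
generations 1-4 have 2,100 progeny of 100 sires and 1,000 dams each,
generations 5-8 have 3,150 progeny of 150 sires and 1,500 dams, records are
spread over 301 contemporary groups per generation, and SNP genotypes
(32,000 markers) are retained for 10/30/40/50% of individuals in
generations 5-8 only.

Phenotypes follow the infinitesimal model y = Xb + Zu + e with
Var(u) = A (x) Sigma_u generated by the Mendelian-sampling recursion
(founders ~ N(0, Sigma_u); offspring = parent average + within-family
deviation). By default the within-family variance is Sigma_u / 2; setting
``exact_mendelian_variance`` uses (1/2 - (F_s + F_d)/4) Sigma_u so that the
realised covariance matches A exactly under inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relmat import GenotypeMatrix, Pedigree, inbreeding

__all__ = [
    "SimConfig",
    "default_covariances",
    "dataset1_like",
    "tiny",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_all",
]


def default_covariances(q: int, var_u: float = 0.4, var_e: float = 0.6,
                        rho_u: float = 0.5, rho_e: float = 0.3):
    """Constant-correlation genetic and residual covariance matrices."""
    J = np.ones((q, q))
    I = np.eye(q)
    su = var_u * (rho_u * J + (1 - rho_u) * I)
    se = var_e * (rho_e * J + (1 - rho_e) * I)
    return su, se


def _aslist(x, n):
    if np.isscalar(x):
        return [x] * n
    x = list(x)
    if len(x) != n:
        raise ValueError("per-generation list has wrong length")
    return x


@dataclass
class SimConfig:
    """Study design of the generator; defaults follow the eight-generation
    simulated data structure described in the module docstring."""

    n_generations: int = 8
    sires_per_gen: object = (100, 100, 100, 100, 150, 150, 150, 150)
    dams_per_gen: object = (1000, 1000, 1000, 1000, 1500, 1500, 1500, 1500)
    progeny_per_gen: object = (2100, 2100, 2100, 2100, 3150, 3150, 3150, 3150)
    n_snp: int = 32_000
    n_traits: int = 5
    sigma_u: np.ndarray | None = None
    sigma_e: np.ndarray | None = None
    sigma_maternal: np.ndarray | None = None  # maternal genetic (optional)
    sigma_pe: np.ndarray | None = None  # maternal permanent env. (optional)
    n_cg_per_gen: int = 301
    cg_sd: float = 0.5
    trait_means: np.ndarray | None = None
    genotyping_prop: object = (0.0, 0.0, 0.0, 0.0, 0.1, 0.3, 0.4, 0.5)
    missing_rate: object = 0.0
    exact_mendelian_variance: bool = False
    seed: int = 20230125

    def __post_init__(self):
        g = self.n_generations
        if g < 1:
            raise ValueError("need at least one generation")
        self.sires_per_gen = [int(v) for v in _aslist(self.sires_per_gen, g)]
        self.dams_per_gen = [int(v) for v in _aslist(self.dams_per_gen, g)]
        self.progeny_per_gen = [int(v) for v in _aslist(self.progeny_per_gen, g)]
        self.genotyping_prop = [float(v) for v in _aslist(self.genotyping_prop, g)]
        self.missing_rate = [float(v) for v in _aslist(self.missing_rate, self.n_traits)]
        if any(not 0 <= p <= 1 for p in self.genotyping_prop):
            raise ValueError("genotyping proportions must be in [0,1]")
        if min(min(self.sires_per_gen), min(self.dams_per_gen),
               min(self.progeny_per_gen)) < 1:
            raise ValueError("all generation counts must be positive")
        q = self.n_traits
        su, se = default_covariances(q)
        if self.sigma_u is None:
            self.sigma_u = su
        if self.sigma_e is None:
            self.sigma_e = se
        self.sigma_u = np.asarray(self.sigma_u, dtype=float)
        self.sigma_e = np.asarray(self.sigma_e, dtype=float)
        for name in ("sigma_u", "sigma_e"):
            M = getattr(self, name)
            if M.shape != (q, q) or np.linalg.eigvalsh(M).min() <= 0:
                raise ValueError(f"{name} must be SPD of size {q}")
        if self.trait_means is None:
            self.trait_means = np.zeros(q)
        self.trait_means = np.asarray(self.trait_means, dtype=float)
        # founders: parents of generation 1
        self.n_founders = self.sires_per_gen[0] + self.dams_per_gen[0]
        for g_i in range(1, g):
            need = self.sires_per_gen[g_i] + self.dams_per_gen[g_i]
            if need > self.progeny_per_gen[g_i - 1]:
                raise ValueError(
                    f"generation {g_i + 1} needs {need} parents but the "
                    f"previous generation has {self.progeny_per_gen[g_i - 1]} progeny"
                )

    @property
    def n_animals(self) -> int:
        return self.n_founders + sum(self.progeny_per_gen)

    def generation_of(self) -> np.ndarray:
        """Generation number per pedigree index (founders = 0)."""
        gen = np.zeros(self.n_animals, dtype=np.int64)
        k = self.n_founders
        for g_i, npr in enumerate(self.progeny_per_gen):
            gen[k : k + npr] = g_i + 1
            k += npr
        return gen


def dataset1_like(**overrides) -> SimConfig:
    """The default eight-generation profile (optionally overridden)."""
    return SimConfig(**overrides)


def tiny(**overrides) -> SimConfig:
    """A three-generation miniature for tests and examples."""
    base = dict(
        n_generations=3,
        sires_per_gen=4,
        dams_per_gen=16,
        progeny_per_gen=40,
        n_snp=300,
        n_traits=2,
        n_cg_per_gen=3,
        genotyping_prop=(0.0, 0.4, 0.6),
        missing_rate=0.1,
    )
    base.update(overrides)
    return SimConfig(**base)


def two_generation(q: int, n_records: int, genomic: bool = False,
                   seed: int = 1, **overrides) -> SimConfig:
    """Compact two-generation design with ``n_records`` phenotyped animals.

    Half the records fall in each generation; sire/dam numbers scale with
    the cohort (about 10 sires and 25 dams per 100 progeny, i.e. paternal
    half-sib families of about ten). When ``genomic`` is set, 10% of each
    recorded generation is genotyped.
    """
    per_gen = max(1, n_records // 2)
    base = dict(
        n_generations=2,
        sires_per_gen=max(5, per_gen // 10),
        dams_per_gen=max(10, per_gen // 4),
        progeny_per_gen=per_gen,
        n_traits=q,
        n_snp=800,
        n_cg_per_gen=5,
        genotyping_prop=(0.1, 0.1) if genomic else (0.0, 0.0),
        missing_rate=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Discrete-generation random-mating pedigree.

    Founders (generation 0) have unknown parents; each progeny draws one
    sire and one dam uniformly from the parents selected in the previous
    generation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n = cfg.n_animals
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    prev = np.arange(cfg.n_founders)
    k = cfg.n_founders
    for g_i in range(cfg.n_generations):
        ns, nd, npr = (
            cfg.sires_per_gen[g_i],
            cfg.dams_per_gen[g_i],
            cfg.progeny_per_gen[g_i],
        )
        chosen = rng.permutation(prev)[: ns + nd]
        sires, dams = chosen[:ns], chosen[ns:]
        sire[k : k + npr] = rng.choice(sires, size=npr)
        dam[k : k + npr] = rng.choice(dams, size=npr)
        prev = np.arange(k, k + npr)
        k += npr
    return Pedigree(sire=sire, dam=dam, labels=tuple(range(1, n + 1)))


def simulate_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Gene drop of unlinked biallelic SNPs through the pedigree.

    Founder haplotypes are Bernoulli(p) with p ~ Uniform(0.05, 0.95) per
    SNP; each descendant inherits one allele per parent per locus. The
    genotyping mask retains the configured proportion per generation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n, m = ped.n, cfg.n_snp
    p = rng.uniform(0.05, 0.95, size=m)
    hap = np.zeros((2, n, m), dtype=np.uint8)
    for i in range(n):
        for h, par in enumerate((ped.sire[i], ped.dam[i])):
            if par < 0:
                hap[h, i] = rng.random(m) < p
            else:
                pick = rng.integers(0, 2, size=m)
                hap[h, i] = hap[pick, par, np.arange(m)]
    gen = cfg.generation_of()
    keep = []
    for g_i in range(cfg.n_generations + 1):
        members = np.nonzero(gen == g_i)[0]
        prop = 0.0 if g_i == 0 else cfg.genotyping_prop[g_i - 1]
        n_keep = int(round(prop * members.size))
        if n_keep:
            keep.append(rng.permutation(members)[:n_keep])
    idx = np.sort(np.concatenate(keep)) if keep else np.array([], dtype=np.int64)
    counts = (hap[0, idx].astype(np.int16) + hap[1, idx]) if idx.size else np.zeros((0, m), dtype=np.int16)
    return GenotypeMatrix(indices=idx, counts=counts, founder_freq=p)


@dataclass
class SimTruth:
    """Generating values kept alongside a simulated data set."""

    breeding_values: np.ndarray  # n_ped x q
    maternal_values: np.ndarray | None
    pe_values: np.ndarray | None
    cg_effects: np.ndarray
    generation: np.ndarray


def _mendelian_drop(ped: Pedigree, sigma: np.ndarray, rng,
                    exact: bool) -> np.ndarray:
    n, q = ped.n, sigma.shape[0]
    Lu = np.linalg.cholesky(sigma)
    u = np.zeros((n, q))
    F = inbreeding(ped) if exact else None
    z = rng.standard_normal((n, q))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            u[i] = Lu @ z[i]
            continue
        pa = np.zeros(q)
        w = 0.0
        if s >= 0:
            pa += 0.5 * u[s]
            w += 0.25
        if d >= 0:
            pa += 0.5 * u[d]
            w += 0.25
        if exact:
            fs = F[s] if s >= 0 else 0.0
            fd = F[d] if d >= 0 else 0.0
            msv = 1.0 - w - 0.25 * (fs * (s >= 0) + fd * (d >= 0))
        else:
            msv = 1.0 - w
        u[i] = pa + np.sqrt(msv) * (Lu @ z[i])
    return u


def simulate_phenotypes(ped: Pedigree, cfg: SimConfig):
    """Multivariate phenotypes for all non-founder animals.

    Returns (data, truth): ``data`` is a DataFrame with 0-based pedigree
    index column 'id', dam index column 'dam', contemporary group 'cg' and
    one column per trait ('t1'..), NaN marking missing records; ``truth``
    holds the generating effects.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    q = cfg.n_traits
    u = _mendelian_drop(ped, cfg.sigma_u, rng, cfg.exact_mendelian_variance)
    m = (
        _mendelian_drop(ped, cfg.sigma_maternal, rng, cfg.exact_mendelian_variance)
        if cfg.sigma_maternal is not None
        else None
    )
    gen = cfg.generation_of()
    rec = np.nonzero(gen > 0)[0]  # records on non-founders
    n_rec = rec.size
    # contemporary groups: unique codes per generation
    cg_local = rng.integers(0, cfg.n_cg_per_gen, size=n_rec)
    cg = (gen[rec] - 1) * cfg.n_cg_per_gen + cg_local
    n_cg = cfg.n_generations * cfg.n_cg_per_gen
    cg_eff = rng.normal(0.0, cfg.cg_sd, size=(n_cg, q))
    e = rng.standard_normal((n_rec, q)) @ np.linalg.cholesky(cfg.sigma_e).T
    Y = cfg.trait_means + u[rec] + e + cg_eff[cg]
    pe = None
    if m is not None:
        Y += m[ped.dam[rec]]
    if cfg.sigma_pe is not None:
        dams = np.unique(ped.dam[rec])
        pe_all = rng.standard_normal((ped.n, q)) @ np.linalg.cholesky(cfg.sigma_pe).T
        pe = pe_all
        Y += pe_all[ped.dam[rec]]
    for t in range(q):
        miss = rng.random(n_rec) < cfg.missing_rate[t]
        Y[miss, t] = np.nan
    data = pd.DataFrame({"id": rec, "dam": ped.dam[rec], "cg": cg})
    for t in range(q):
        data[f"t{t + 1}"] = Y[:, t]
    truth = SimTruth(
        breeding_values=u,
        maternal_values=m,
        pe_values=pe,
        cg_effects=cg_eff,
        generation=gen,
    )
    return data, truth


def simulate_all(cfg: SimConfig):
    """Pedigree, genotypes and phenotypes in one call."""
    ped = simulate_pedigree(cfg)
    gm = simulate_genotypes(ped, cfg)
    data, truth = simulate_phenotypes(ped, cfg)
    return ped, gm, data, truth
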