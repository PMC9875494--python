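"""Pre-specified simulation studies: dataset construction for the
parameterisation-equivalence and parameter-recovery analyses.

These fix the study conditions (designs, sizes, genotyping fractions) in one
place so that the test suite and the reproduction script run the same
experiments.
"""

from __future__ import annotations

import gc

import numpy as np

from . import simdata
from .aireml import reml_fit, start_values, REMLEngine
from .mme import MMEBuilder, ModelSpec, RandomTerm
from .relmat import (
    build_A22,
    build_A_inverse,
    build_grm,
    align_grm,
    build_H_inverse,
)

__all__ = [
    "animal_model_dataset",
    "EQUIVALENCE_CONDITIONS",
    "equivalence_study",
    "recovery_study",
]


def animal_model_dataset(q: int, n_records: int, genomic: bool = False,
                         seed: int = 1, **overrides):
    """Simulate a two-generation animal-model dataset and its MME builder.

    With ``genomic`` set, 10% of recorded animals are genotyped and the
    genetic term uses the single-step H^{-1}; otherwise the pedigree A^{-1}.
    Returns (builder, config).
    """
    cfg = simdata.two_generation(q, n_records, genomic=genomic, seed=seed,
                                 **overrides)
    ped = simdata.simulate_pedigree(cfg)
    data, _ = simdata.simulate_phenotypes(ped, cfg)
    if genomic:
        gm = simdata.simulate_genotypes(ped, cfg)
        a22 = build_A22(ped, gm.indices)
        gstar = align_grm(build_grm(gm), a22)
        rels = {"H": build_H_inverse(ped, gstar, gm.indices, A22=a22)}
        rel = "H"
    else:
        rels = {"A": build_A_inverse(ped)}
        rel = "A"
    spec = ModelSpec(
        traits=tuple(f"t{i + 1}" for i in range(q)),
        fixed=("cg",),
        random=(RandomTerm(name="animal", rel=rel),),
    )
    return MMEBuilder(spec, data, rels), cfg


# (q, N records, genomic) - 11 datasets. Trait counts are paired with
# record numbers a geneticist would consider estimable: a q x q genetic
# covariance has q(q+1)/2 free parameters, so the 5-trait model (15 genetic
# + 15 residual parameters) runs at N = 2,000 only. Genomic (single-step)
# variants run where the dense genotyped block stays within the simplicial
# solver's comfortable range.
EQUIVALENCE_CONDITIONS = (
    (1, 200, False), (1, 200, True), (1, 2000, False), (1, 2000, True),
    (2, 200, False), (2, 200, True), (2, 2000, False), (2, 2000, True),
    (3, 200, False), (3, 200, True),
    (5, 2000, False),
)


def condition_seed(q: int, n: int, genomic: bool, base: int = 0) -> int:
    """Deterministic per-condition seed, derived from the condition itself
    (not from list position) plus an overall base offset."""
    return int(base) + 1000 * q + n // 10 + int(genomic)


def equivalence_study(q: int, n: int, genomic: bool, seed: int | None = None) -> dict:
    """Fit one dataset under both parameterisations and compare.

    Returns the matched-parameter -2logL relative difference, the largest
    per-iterate likelihood-change difference, the largest converged-estimate
    difference (relative), and convergence flags.
    """
    if seed is None:
        seed = condition_seed(q, n, genomic)
    builder, _ = animal_model_dataset(q, n, genomic=genomic, seed=seed)
    covs0 = start_values(builder.spec, builder.data)
    m_mv = REMLEngine(builder, "mv").evaluate(covs0).m2ll
    m_pc = REMLEngine(builder, "pc").evaluate(covs0).m2ll
    rel_m2ll = abs(m_mv - m_pc) / max(1.0, abs(m_mv))
    gc.collect()  # factor/selected-inverse caches can reach gigabytes on the
    # larger systems and sit in reference cycles; free them promptly
    res_mv = reml_fit(builder, parameterisation="mv")
    gc.collect()
    res_pc = reml_fit(builder, parameterisation="pc")
    gc.collect()
    d_iter = 0.0
    for sm, sp_ in zip(res_mv.trajectory[1:], res_pc.trajectory[1:]):
        d_iter = max(
            d_iter,
            abs(sm.delta_m2ll - sp_.delta_m2ll) / max(1.0, abs(sm.delta_m2ll)),
        )
    d_est = max(
        np.abs(Sm - Sp).max() / max(1.0, np.abs(Sm).max())
        for Sm, Sp in zip(res_mv.covs.matrices, res_pc.covs.matrices)
    )
    return {
        "rel_m2ll": rel_m2ll,
        "max_iter_delta_diff": d_iter,
        "max_estimate_diff": d_est,
        "n_iter": (res_mv.n_iter, res_pc.n_iter),
        "converged": (res_mv.converged, res_pc.converged),
        "same_length": len(res_mv.trajectory) == len(res_pc.trajectory),
    }


def recovery_study(n_replicates: int = 20, q: int = 2, n_records: int = 2000,
                   seed: int = 20230125) -> dict:
    """Repeated simulation and MV REML estimation at known parameters.

    Returns per-parameter mean estimates, Monte-Carlo standard errors of the
    means, generating values and the z-scores (mean - truth)/SE.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(1, 2**31 - 1, size=n_replicates)
    ests = []
    truth_cfg = simdata.two_generation(q, n_records, seed=int(rep_seeds[0]))
    for s in rep_seeds:
        builder, cfg = animal_model_dataset(q, n_records, seed=int(s))
        res = reml_fit(builder, parameterisation="mv")
        gc.collect()
        iu = np.triu_indices(q)
        ests.append(
            np.concatenate(
                [res.covs.sigma_terms[0][iu], res.covs.sigma_e[iu]]
            )
        )
    ests = np.array(ests)
    iu = np.triu_indices(q)
    truth = np.concatenate([truth_cfg.sigma_u[iu], truth_cfg.sigma_e[iu]])
    mean = ests.mean(axis=0)
    se = ests.std(axis=0, ddof=1) / np.sqrt(n_replicates)
    names = [f"sigma_u[{i},{j}]" for i, j in zip(*iu)] + [
        f"sigma_e[{i},{j}]" for i, j in zip(*iu)
    ]
    return {
        "names": names,
        "truth": truth,
        "mean": mean,
        "se": se,
        "z": (mean - truth) / se,
        "n_replicates": n_replicates,
    }
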