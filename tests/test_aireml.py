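"""REML engine: likelihood, derivatives, AI matrix and the fitting loop.

Sparse-path quantities are checked against the dense V/P oracle and central
finite differences; MV and PC engines are checked against each other.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pcreml.aireml import (
    CovParams,
    REMLEngine,
    loglik_mv,
    loglik_pc,
    reml_fit,
    start_values,
)
from pcreml.mme import MMEBuilder, ModelSpec, RandomTerm, count_parameters
from pcreml.oracle import OracleContext
from pcreml.relmat import build_A_inverse, build_A22, build_grm, align_grm, build_H_inverse
from pcreml import simdata
from conftest import random_pedigree, toy_dataset, toy_covs


# ---------------------------------------------------------------------------
# parameter transform


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(1, 4), st.integers(0, 10_000))
def test_theta_roundtrip_is_identity(q, seed):
    rng = np.random.default_rng(seed)
    B = rng.standard_normal((q, q)) * 0.5
    su = B @ B.T + np.eye(q)
    B = rng.standard_normal((q, q)) * 0.5
    se = B @ B.T + np.eye(q)
    covs = CovParams(sigma_terms=[su], sigma_e=se)
    theta = covs.theta()
    back = CovParams.from_theta(theta, covs.dims)
    assert back.sigma_terms[0] == pytest.approx(su, abs=1e-12)
    assert back.sigma_e == pytest.approx(se, abs=1e-12)
    assert back.theta() == pytest.approx(theta, abs=1e-12)


def test_theta_length_equals_parameter_count():
    spec = ModelSpec(
        traits=("a", "b", "c"), fixed=("cg",),
        random=(RandomTerm("animal", "A"), RandomTerm("pe", "identity")),
    )
    covs = CovParams(
        sigma_terms=[np.eye(3), np.eye(3)], sigma_e=np.eye(3)
    )
    assert covs.theta().size == count_parameters(spec)


# ---------------------------------------------------------------------------
# instances used for oracle comparisons


def genomic_dataset(n=45, ng=15, q=2, seed=20):
    rng = np.random.default_rng(seed)
    ped, spec, df, rels = toy_dataset(n=n, q=q, seed=seed, missing=0.1)
    idx = np.sort(rng.choice(n, ng, replace=False))
    counts = rng.integers(0, 3, size=(ng, 500))
    from pcreml.relmat import GenotypeMatrix

    a22 = build_A22(ped, idx)
    gstar = align_grm(build_grm(GenotypeMatrix(indices=idx, counts=counts)), a22)
    hinv = build_H_inverse(ped, gstar, idx, A22=a22)
    spec = ModelSpec(traits=spec.traits, fixed=spec.fixed,
                     random=(RandomTerm("animal", "H"),))
    return MMEBuilder(spec, df, {"H": hinv})


def maternal_dataset(seed=21):
    cfg = simdata.tiny(
        seed=seed, n_traits=2, sigma_maternal=0.2 * np.eye(2),
        sigma_pe=0.1 * np.eye(2), progeny_per_gen=25, dams_per_gen=10,
        sires_per_gen=3, missing_rate=0.1,
    )
    ped, gm, df, _ = simdata.simulate_all(cfg)
    spec = ModelSpec(
        traits=("t1", "t2"), fixed=("cg",),
        random=(
            RandomTerm("animal", "A"),
            RandomTerm("maternal", "A", effect="dam"),
            RandomTerm("mat_pe", "identity", effect="dam"),
        ),
    )
    return MMEBuilder(spec, df, {"A": build_A_inverse(ped)})


def maternal_covs():
    return CovParams(
        sigma_terms=[
            np.array([[0.4, 0.1], [0.1, 0.5]]),
            np.array([[0.25, 0.05], [0.05, 0.2]]),
            np.array([[0.12, 0.02], [0.02, 0.15]]),
        ],
        sigma_e=np.array([[0.7, 0.2], [0.2, 0.9]]),
    )


def _cases():
    ped, spec, df, rels = toy_dataset(n=40, q=2, seed=42)
    yield "pedigree-q2", MMEBuilder(spec, df, rels), toy_covs(2, 42)
    ped, spec, df, rels = toy_dataset(n=25, q=3, seed=11, missing=0.2)
    yield "pedigree-q3", MMEBuilder(spec, df, rels), toy_covs(3, 11)
    yield "genomic-q2", genomic_dataset(), toy_covs(2, 20)
    yield "maternal-q2", maternal_dataset(), maternal_covs()


CASES = {name: (b, c) for name, b, c in _cases()}


@pytest.mark.parametrize("name", list(CASES))
class TestOracleAgreement:
    def test_m2ll_matches_dense(self, name):
        b, covs = CASES[name]
        orc = OracleContext(b)
        dense = orc.m2ll(covs)
        for fn in (loglik_mv, loglik_pc):
            ev = fn(b, covs)
            assert abs(ev.m2ll - dense) < 1e-6 * max(1.0, abs(dense))

    def test_mv_pc_likelihood_identical(self, name):
        b, covs = CASES[name]
        a, p = loglik_mv(b, covs).m2ll, loglik_pc(b, covs).m2ll
        assert abs(a - p) < 1e-8 * max(1.0, abs(a))

    def test_gradient_matches_dense_and_fd(self, name):
        b, covs = CASES[name]
        orc = OracleContext(b)
        gd = orc.gradient(covs)
        gfd = orc.fd_gradient(covs)
        scale = np.maximum(1.0, np.abs(gd))
        assert np.max(np.abs(gd - gfd) / scale) < 1e-4
        for param in ("mv", "pc"):
            eng = REMLEngine(b, param)
            ev = eng.evaluate(covs)
            g, _ = eng.derivatives(ev)
            assert np.max(np.abs(g - gd) / scale) < 1e-6

    def test_ai_matches_dense_and_is_psd(self, name):
        b, covs = CASES[name]
        orc = OracleContext(b)
        aid = orc.average_information(covs)
        scale = max(1.0, np.abs(aid).max())
        for param in ("mv", "pc"):
            eng = REMLEngine(b, param)
            ev = eng.evaluate(covs)
            _, ai = eng.derivatives(ev)
            assert np.abs(ai - aid).max() / scale < 1e-6
            assert np.linalg.eigvalsh(ai).min() > -1e-8 * scale

    def test_yPy_decomposition_matches_dense(self, name):
        b, covs = CASES[name]
        orc = OracleContext(b)
        P = orc.projection(covs)
        dense_yPy = float(b.y_obs @ P @ b.y_obs)
        ev = loglik_mv(b, covs)
        assert abs(ev.yPy - dense_yPy) < 1e-6 * max(1.0, abs(dense_yPy))
        # e_obs is Py on the observation scale
        assert ev.e_obs == pytest.approx(P @ b.y_obs, abs=1e-7)


def test_projection_identities():
    """P V P = P and P X = 0 for the dense oracle machinery."""
    b, covs = CASES["pedigree-q2"]
    orc = OracleContext(b)
    P = orc.projection(covs)
    V = orc.V(covs)
    assert P @ V @ P == pytest.approx(P, abs=1e-8)
    assert P @ orc.X == pytest.approx(np.zeros_like(orc.X), abs=1e-8)


def test_loglik_invariant_under_theta_roundtrip(small_builder, small_covs):
    ev1 = loglik_mv(small_builder, small_covs)
    covs2 = CovParams.from_theta(small_covs.theta(), small_covs.dims)
    ev2 = loglik_mv(small_builder, covs2)
    assert ev1.m2ll == pytest.approx(ev2.m2ll, abs=1e-9)


def test_empty_genotype_H_equals_A_loglik():
    ped, spec, df, rels = toy_dataset(n=30, q=2, seed=13)
    covs = toy_covs(2, 13)
    h = build_H_inverse(ped, np.zeros((0, 0)), np.array([], dtype=int))
    spec_h = ModelSpec(traits=spec.traits, fixed=spec.fixed,
                       random=(RandomTerm("animal", "H"),))
    m_a = loglik_mv(MMEBuilder(spec, df, rels), covs).m2ll
    m_h = loglik_mv(MMEBuilder(spec_h, df, {"H": h}), covs).m2ll
    assert m_a == pytest.approx(m_h, abs=1e-9)


# ---------------------------------------------------------------------------
# fitting behaviour


def simulated_builder(q=2, n=300, seed=1, **over):
    """Data with genuine genetic signal for fitting tests."""
    cfg = simdata.two_generation(q, n, seed=seed, **over)
    ped = simdata.simulate_pedigree(cfg)
    df, _ = simdata.simulate_phenotypes(ped, cfg)
    spec = ModelSpec(
        traits=tuple(f"t{t + 1}" for t in range(q)), fixed=("cg",),
        random=(RandomTerm("animal", "A"),),
    )
    return MMEBuilder(spec, df, {"A": build_A_inverse(ped)}), cfg


class TestFit:
    def test_mv_pc_same_trajectory_and_estimates(self):
        b, _ = simulated_builder(q=2, n=240, seed=30, missing_rate=0.1)
        rm = reml_fit(b, parameterisation="mv")
        rp = reml_fit(b, parameterisation="pc")
        assert rm.converged and rp.converged
        for sm, sp_ in zip(rm.trajectory[1:], rp.trajectory[1:]):
            assert abs(sm.delta_m2ll - sp_.delta_m2ll) < 1e-6 * max(
                1.0, abs(sm.delta_m2ll)
            )
        for Sm, Sp in zip(rm.covs.matrices, rp.covs.matrices):
            assert np.abs(Sm - Sp).max() < 1e-5 * max(1.0, np.abs(Sm).max())

    def test_monotone_m2ll_and_psd_ai(self):
        b, _ = simulated_builder(q=2, n=200, seed=31)
        res = reml_fit(b, parameterisation="mv")
        traj = res.trajectory
        for prev, cur in zip(traj, traj[1:]):
            assert cur.m2ll <= prev.m2ll + 1e-6 * max(1.0, abs(prev.m2ll))
            assert np.linalg.eigvalsh(cur.ai).min() > -1e-8 * max(
                1.0, np.abs(cur.ai).max()
            )

    def test_gradient_small_at_convergence(self):
        b, _ = simulated_builder(q=1, n=200, seed=32)
        res = reml_fit(b, parameterisation="mv", tol_g=1e-3)
        assert res.converged
        assert 0.5 * np.max(np.abs(res.trajectory[-1].grad)) < 1e-3

    def test_restart_at_optimum_changes_little(self):
        b, _ = simulated_builder(q=1, n=200, seed=33)
        res = reml_fit(b, parameterisation="mv")
        res2 = reml_fit(b, start=res.covs, parameterisation="mv")
        assert res2.n_iter <= 2
        assert abs(res2.m2ll - res.m2ll) < 1e-6 * max(1.0, abs(res.m2ll))

    def test_standard_errors_positive(self):
        b, _ = simulated_builder(q=2, n=200, seed=34)
        res = reml_fit(b, parameterisation="pc")
        assert np.all(res.se_theta > 0)
        for S in res.se_cov:
            assert np.all(np.diag(S) > 0)

    def test_balanced_half_sib_matches_anova(self):
        """Balanced one-way layout: REML equals the ANOVA estimator."""
        rng = np.random.default_rng(35)
        s, n = 20, 12
        sire_eff = rng.normal(0, np.sqrt(0.3), s)
        y = np.repeat(sire_eff, n) + rng.normal(0, 1.0, s * n) + 5.0
        df = pd.DataFrame({
            "id": np.arange(s * n), "mu": 1,
            "sire": np.repeat(np.arange(s), n), "t1": y,
        })
        spec = ModelSpec(traits=("t1",), fixed=("mu",),
                         random=(RandomTerm("sire", "identity", effect="sire"),))
        res = reml_fit(MMEBuilder(spec, df, {}), parameterisation="mv",
                       tol_l=1e-8, tol_g=1e-6)
        ybar = y.reshape(s, n).mean(axis=1)
        msb = n * np.sum((ybar - y.mean()) ** 2) / (s - 1)
        msw = np.sum((y.reshape(s, n) - ybar[:, None]) ** 2) / (s * (n - 1))
        sigma_s = (msb - msw) / n
        assert res.covs.sigma_terms[0][0, 0] == pytest.approx(sigma_s, rel=1e-3)
        assert res.covs.sigma_e[0, 0] == pytest.approx(msw, rel=1e-3)
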