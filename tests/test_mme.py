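"""Equation counting, MME assembly and the MV/PC sparsity structure."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from pcreml.aireml import CovParams
from pcreml.mme import (
    MMEBuilder,
    ModelSpec,
    PCTransform,
    RandomTerm,
    count_equations,
    count_parameters,
    neq_from_counts,
    nnz_accounting,
)
from pcreml.relmat import RelFactor, build_A_inverse
from conftest import random_pedigree, toy_dataset, toy_covs


class TestCounting:
    def test_means_only_five_traits(self):
        """Five traits, 21,000 animals, one overall mean per trait."""
        assert neq_from_counts([[1]] * 5, [(5, 21_000)]) == 105_005

    def test_one_trait_one_animal(self):
        assert neq_from_counts([[1]], [(1, 1)]) == 2

    def test_sheep_contemporary_groups(self):
        """Four traits over a 107,730-animal pedigree with per-trait
        contemporary-group counts."""
        cg = [4823, 6085, 4857, 945]
        assert neq_from_counts([[c] for c in cg], [(4, 107_730)]) == 447_630

    def test_parameter_counts(self):
        simple4 = ModelSpec(
            traits=("a", "b", "c", "d"), fixed=("cg",),
            random=(RandomTerm("animal", "A"),),
        )
        assert count_parameters(simple4) == 20
        maternal4 = ModelSpec(
            traits=("a", "b", "c", "d"), fixed=("cg",),
            random=(
                RandomTerm("animal", "A"),
                RandomTerm("maternal", "A", effect="dam"),
                RandomTerm("mat_pe", "identity", effect="dam"),
            ),
        )
        assert count_parameters(maternal4) == 40
        simple1 = ModelSpec(
            traits=("a",), fixed=("mu",), random=(RandomTerm("animal", "A"),)
        )
        assert count_parameters(simple1) == 2

    @pytest.mark.parametrize("seed", range(6))
    def test_count_matches_assembled_dimension(self, seed):
        rng = np.random.default_rng(seed)
        q = int(rng.integers(1, 4))
        ped, spec, df, rels = toy_dataset(
            n=30, q=q, seed=seed, missing=0.2, n_cg=int(rng.integers(2, 5))
        )
        b = MMEBuilder(spec, df, rels)
        covs = toy_covs(q, seed)
        sys = b.assemble(covs, "mv")
        assert count_equations(spec, df, rels) == sys.coeff.shape[0] == b.neq


class TestAssembly:
    def test_univariate_matches_textbook_mme(self):
        """q=1, one record per animal, mean only: the classic scalar
        animal-model MME with variance ratio on A-inverse."""
        ped, spec, df, rels = toy_dataset(n=15, q=1, seed=1, missing=0.0,
                                          factors=("mu",))
        df["mu"] = 1
        b = MMEBuilder(spec, df, rels)
        s2u, s2e = 0.4, 0.8
        covs = CovParams(sigma_terms=[np.array([[s2u]])], sigma_e=np.array([[s2e]]))
        sys = b.assemble(covs, "mv")
        C = (sys.coeff + sys.coeff.T - sp.diags(sys.coeff.diagonal())).toarray()
        n = ped.n
        X = np.ones((n, 1))
        Z = np.eye(n)
        Ainv = rels["A"].full.toarray()
        top = np.hstack([X.T @ X, X.T @ Z]) / s2e
        bot = np.hstack([Z.T @ X / s2e, Z.T @ Z / s2e + Ainv / s2u])
        assert C == pytest.approx(np.vstack([top, bot]), abs=1e-10)

    def test_missing_trait_contributes_only_observed_positions(self):
        ped, spec, df, rels = toy_dataset(n=10, q=2, seed=2, missing=0.0)
        df.loc[3, "t2"] = np.nan
        b = MMEBuilder(spec, df, rels)
        covs = toy_covs(2)
        sys = b.assemble(covs, "mv")
        # the record's residual weight is the scalar 1/sigma_e[0,0]
        p = b.rec_pattern[3]
        assert b.patterns[p] == (0,)
        W = b.residual_weights(covs.sigma_e)[p]
        assert W == pytest.approx(1.0 / covs.sigma_e[0, 0])

    def test_mv_solution_matches_gls(self):
        """MME solutions equal GLS beta-hat and BLUP u-hat from dense V."""
        ped, spec, df, rels = toy_dataset(n=25, q=2, seed=3, missing=0.2)
        b = MMEBuilder(spec, df, rels)
        covs = toy_covs(2, seed=3)
        sys = b.assemble(covs, "mv")
        from pcreml.sparsela import cholesky
        sol = cholesky(sys.coeff).solve(sys.rhs)
        from pcreml.oracle import OracleContext
        orc = OracleContext(b)
        V = orc.V(covs)
        Vi = np.linalg.inv(V)
        X, y = orc.X, b.y_obs
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert sol[: b.n_fixed] == pytest.approx(beta, abs=1e-6)
        G = np.kron(orc.H[0], covs.sigma_terms[0])
        u = G @ orc.Z[0].T @ Vi @ (y - X @ beta)
        assert sol[b.n_fixed :] == pytest.approx(u, abs=1e-6)

    def test_pc_identity_sigma_equals_mv(self):
        ped, spec, df, rels = toy_dataset(n=20, q=3, seed=4, missing=0.1)
        b = MMEBuilder(spec, df, rels)
        covs = CovParams(sigma_terms=[np.eye(3)], sigma_e=toy_covs(3, 4).sigma_e)
        mv = b.assemble(covs, "mv")
        pc = b.assemble(covs, "pc")
        diff = abs(mv.coeff - pc.coeff)
        assert diff.max() < 1e-12
        assert mv.rhs == pytest.approx(pc.rhs)

    def test_pc_scalar_case_scales_solutions(self):
        """q=1 with genetic variance 4: Z* = 2Z, so u-hat = 2 u*-hat."""
        ped, spec, df, rels = toy_dataset(n=15, q=1, seed=5, missing=0.0)
        covs = CovParams(sigma_terms=[np.array([[4.0]])], sigma_e=np.array([[1.0]]))
        b = MMEBuilder(spec, df, rels)
        from pcreml.sparsela import cholesky
        mv = b.assemble(covs, "mv")
        pc = b.assemble(covs, "pc")
        smv = cholesky(mv.coeff).solve(mv.rhs)
        spc = cholesky(pc.coeff).solve(pc.rhs)
        assert smv[: b.n_fixed] == pytest.approx(spc[: b.n_fixed], abs=1e-9)
        assert smv[b.n_fixed :] == pytest.approx(2.0 * spc[b.n_fixed :], abs=1e-9)

    def test_mv_pc_solution_equivalence(self):
        """beta-hat identical; u-hat = (I x Q) u*-hat."""
        ped, spec, df, rels = toy_dataset(n=30, q=3, seed=6, missing=0.15)
        b = MMEBuilder(spec, df, rels)
        covs = toy_covs(3, seed=6)
        from pcreml.sparsela import cholesky
        mv = b.assemble(covs, "mv")
        pc = b.assemble(covs, "pc")
        smv = cholesky(mv.coeff).solve(mv.rhs)
        spc = cholesky(pc.coeff).solve(pc.rhs)
        assert smv[: b.n_fixed] == pytest.approx(spc[: b.n_fixed], abs=1e-8)
        Q = pc.pct.Q[0]
        Umv = smv[b.n_fixed :].reshape(-1, 3)
        Upc = spc[b.n_fixed :].reshape(-1, 3)
        assert Umv == pytest.approx(Upc @ Q.T, abs=1e-8)

    def test_coeff_positive_definite(self):
        from pcreml.sparsela import cholesky
        ped, spec, df, rels = toy_dataset(n=25, q=2, seed=7, missing=0.1)
        b = MMEBuilder(spec, df, rels)
        for param in ("mv", "pc"):
            f = cholesky(b.assemble(toy_covs(2, 7), param).coeff)
            assert np.all(f.D > 0)

    def test_all_missing_records_dropped(self):
        ped, spec, df, rels = toy_dataset(n=12, q=2, seed=8, missing=0.0)
        df.loc[[2, 5], ["t1", "t2"]] = np.nan
        b = MMEBuilder(spec, df, rels)
        assert b.n_dropped == 2
        assert b.n_rec == 10


class TestPCTransform:
    def test_qq_prime_roundtrip(self):
        rng = np.random.default_rng(0)
        for q in (1, 2, 4):
            B = rng.standard_normal((q, q))
            S = B @ B.T + q * np.eye(q)
            pct = PCTransform([S])
            Q = pct.Q[0]
            assert Q @ Q.T == pytest.approx(S, abs=1e-12)
            assert pct.Qinv[0] @ S @ pct.Qinv[0].T == pytest.approx(
                np.eye(q), abs=1e-10
            )
            assert np.all(np.diag(Q) > 0)
            assert np.triu(Q, 1) == pytest.approx(np.zeros((q, q)))


class TestSparsityRule:
    """Each off-diagonal H^-1 element adds q^2 non-zeros under MV, q under PC."""

    def _system_pair(self, hinv_lower, q, n):
        rel = RelFactor(kind="pedigree-inverse", lower=sp.csc_matrix(hinv_lower))
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"id": np.arange(n), "mu": 1})
        for t in range(q):
            df[f"t{t + 1}"] = rng.standard_normal(n)
        spec = ModelSpec(
            traits=tuple(f"t{t + 1}" for t in range(q)),
            fixed=("mu",),
            random=(RandomTerm("animal", "H"),),
        )
        b = MMEBuilder(spec, df, {"H": rel})
        covs = toy_covs(q)
        return b.assemble(covs, "mv"), b.assemble(covs, "pc")

    @pytest.mark.parametrize("q", [1, 2, 3, 5])
    def test_one_offdiagonal_element(self, q):
        n = 6
        diag = sp.identity(n, format="lil")
        withoff = diag.copy()
        withoff[4, 1] = -0.5
        mv0, pc0 = self._system_pair(diag.tocsc(), q, n)
        mv1, pc1 = self._system_pair(withoff.tocsc(), q, n)
        assert mv1.coeff.nnz - mv0.coeff.nnz == q * q
        assert pc1.coeff.nnz - pc0.coeff.nnz == q
        # relationship-part tallies follow the same rule
        assert mv1.rel_nnz[0] - mv0.rel_nnz[0] == q * q
        assert pc1.rel_nnz[0] - pc0.rel_nnz[0] == q

    @pytest.mark.parametrize("q", [1, 2, 3])
    def test_diagonal_h_complete_records(self, q):
        """Unrelated animals: relationship-part nnz N q(q+1)/2 (MV) vs N q (PC)."""
        n = 8
        mv, pc = self._system_pair(sp.identity(n, format="csc"), q, n)
        assert mv.rel_nnz[0] == n * q * (q + 1) // 2
        assert pc.rel_nnz[0] == n * q

    def test_pc_never_more_nonzeros_complete_records(self):
        for q, seed in [(1, 0), (2, 1), (3, 2), (5, 3)]:
            ped, spec, df, rels = toy_dataset(n=20, q=q, seed=seed, missing=0.0)
            b = MMEBuilder(spec, df, rels)
            covs = toy_covs(q, seed)
            assert b.assemble(covs, "pc").coeff.nnz <= b.assemble(covs, "mv").coeff.nnz

    def test_pc_data_block_is_animal_blockdiagonal(self):
        ped, spec, df, rels = toy_dataset(n=12, q=3, seed=9, missing=0.0)
        b = MMEBuilder(spec, df, rels)
        pc = b.assemble(toy_covs(3, 9), "pc")
        uu = pc.C_data[b.n_fixed :, b.n_fixed :].tocoo()
        # every data-part entry lies inside a q x q animal-diagonal block
        assert np.all(uu.row // 3 == uu.col // 3)


def test_nnz_accounting_blocks_sum(small_builder, small_covs):
    sys = small_builder.assemble(small_covs, "mv")
    acc = nnz_accounting(sys)
    assert acc["neq"] == small_builder.neq
    assert acc["nnz_total"] == sys.coeff.nnz
    assert acc["nnz_total"] <= (
        acc["nnz_beta_beta"] + acc["nnz_beta_u"] + acc["nnz_uu_data"] + acc["nnz_uu_rel"]
    )
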