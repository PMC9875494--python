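import numpy as np
import pandas as pd
import pytest

from pcreml.relmat import Pedigree, build_A_inverse
from pcreml.mme import ModelSpec, RandomTerm, MMEBuilder
from pcreml.aireml import CovParams


def random_pedigree(n: int, n_founders: int = 10, seed: int = 0,
                    missing_parent_rate: float = 0.0) -> Pedigree:
    """Random topologically ordered pedigree for tests."""
    rng = np.random.default_rng(seed)
    recs = [(i, 0, 0) for i in range(1, n_founders + 1)]
    for i in range(n_founders + 1, n + 1):
        s = int(rng.integers(1, i))
        d = int(rng.integers(1, i))
        while d == s and i > 2:
            d = int(rng.integers(1, i))
        if rng.random() < missing_parent_rate:
            s = 0
        if rng.random() < missing_parent_rate:
            d = 0
        recs.append((i, s, d))
    return Pedigree.from_records(recs)


def toy_dataset(n: int = 40, q: int = 2, seed: int = 42, missing: float = 0.15,
                n_cg: int = 3, factors=("cg", "sex")):
    """Small animal-model dataset with an exact pedigree A-inverse."""
    rng = np.random.default_rng(seed)
    ped = random_pedigree(n, n_founders=max(4, n // 4), seed=seed)
    Y = rng.standard_normal((n, q)) * 1.2 + 0.5
    if missing:
        Y[rng.random((n, q)) < missing] = np.nan
        Y[np.all(np.isnan(Y), axis=1), 0] = 0.0  # keep every record
    cols = {"id": np.arange(n)}
    if "cg" in factors:
        cols["cg"] = rng.integers(0, n_cg, n)
    if "sex" in factors:
        cols["sex"] = rng.integers(0, 2, n)
    df = pd.DataFrame(cols)
    for t in range(q):
        df[f"t{t + 1}"] = Y[:, t]
    spec = ModelSpec(
        traits=tuple(f"t{t + 1}" for t in range(q)),
        fixed=tuple(factors),
        random=(RandomTerm(name="animal", rel="A", effect="id"),),
    )
    rels = {"A": build_A_inverse(ped)}
    return ped, spec, df, rels


def toy_covs(q: int, seed: int = 0) -> CovParams:
    rng = np.random.default_rng(seed)
    B = rng.standard_normal((q, q)) * 0.2
    su = B @ B.T + 0.4 * np.eye(q)
    B = rng.standard_normal((q, q)) * 0.2
    se = B @ B.T + 0.7 * np.eye(q)
    return CovParams(sigma_terms=[su], sigma_e=se)


@pytest.fixture(scope="session")
def small_builder():
    ped, spec, df, rels = toy_dataset()
    return MMEBuilder(spec, df, rels)


@pytest.fixture(scope="session")
def small_covs():
    return toy_covs(2)
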