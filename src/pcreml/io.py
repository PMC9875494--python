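"""Text-format loaders and writers.

Pedigree: three whitespace- or comma-separated columns animal/sire/dam,
optional header, 0 or NA for unknown parents. Genotypes: first column the
individual id, remaining columns allele counts 0/1/2 (PLINK .raw-style
metadata columns FID/PAT/MAT/SEX/PHENOTYPE are ignored). Phenotypes: CSV
with an id column, optional dam column, factor columns and one column per
trait, NA for missing. Relationship factors export as 1-based coordinate
text of the lower triangle.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mme import ModelSpec, RandomTerm
from .relmat import GenotypeMatrix, Pedigree, RelFactor

__all__ = [
    "load_pedigree",
    "write_pedigree",
    "load_genotypes",
    "write_genotypes",
    "load_phenotypes",
    "write_phenotypes",
    "write_relfactor",
    "load_model_config",
    "write_model_config",
]

_META_COLS = {"FID", "PAT", "MAT", "SEX", "PHENOTYPE"}


def _read_table(path) -> pd.DataFrame:
    text = Path(path).read_text()
    sep = "," if "," in text.splitlines()[0] else r"\s+"
    first = text.splitlines()[0].replace(",", " ").split()
    header = 0 if any(not _numeric(tok) for tok in first) else None
    return pd.read_csv(_io.StringIO(text), sep=sep, header=header, dtype=str)


def _numeric(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return tok.upper() in ("NA", ".")


def load_pedigree(path) -> Pedigree:
    df = _read_table(path)
    if df.shape[1] < 3:
        raise ValueError("pedigree file needs three columns (animal sire dam)")
    return Pedigree.from_records(df.iloc[:, :3].itertuples(index=False, name=None))


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal sire dam\n")
        for i in range(ped.n):
            lab = ped.labels[i] if ped.labels else i + 1
            s = ped.labels[ped.sire[i]] if ped.sire[i] >= 0 else 0
            d = ped.labels[ped.dam[i]] if ped.dam[i] >= 0 else 0
            fh.write(f"{lab} {s} {d}\n")


def load_genotypes(path, ped: Pedigree) -> GenotypeMatrix:
    df = _read_table(path)
    drop = [c for c in df.columns if str(c).upper() in _META_COLS]
    df = df.drop(columns=drop)
    ids = df.iloc[:, 0].tolist()
    counts = df.iloc[:, 1:].to_numpy(dtype=float)
    if counts.size and not np.all(np.isin(counts, (0.0, 1.0, 2.0))):
        raise ValueError("missing or non-{0,1,2} genotype calls are not supported")
    return GenotypeMatrix(indices=ped.index_of(ids), counts=counts.astype(np.int8))


def write_genotypes(gm: GenotypeMatrix, ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        cols = " ".join(f"snp{j + 1}" for j in range(gm.n_snp))
        fh.write(f"id {cols}\n")
        for k, idx in enumerate(gm.indices):
            lab = ped.labels[idx] if ped.labels else idx + 1
            fh.write(f"{lab} " + " ".join(map(str, gm.counts[k])) + "\n")


def load_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA", "."])
    if "id" not in df.columns:
        raise ValueError("phenotype file needs an 'id' column")
    return df


def write_phenotypes(df: pd.DataFrame, ped: Pedigree, path) -> None:
    """Write a phenotype table, mapping 0-based pedigree indices in the
    'id'/'dam' columns back to external ids."""
    out = df.copy()
    for col in ("id", "dam"):
        if col in out.columns:
            out[col] = [
                ped.labels[i] if ped.labels else i + 1 for i in out[col].astype(int)
            ]
    out.to_csv(path, index=False, na_rep="NA")


def write_relfactor(rf: RelFactor, path) -> None:
    Path(path).write_text(rf.to_coo_text())


def load_model_config(path):
    """Model configuration: traits, fixed factors, random terms and the
    parameterisation, in YAML."""
    cfg = yaml.safe_load(Path(path).read_text())
    random = tuple(
        RandomTerm(
            name=t["name"],
            rel=t.get("rel", "A"),
            effect=t.get("effect", "id"),
            traits=tuple(t.get("traits", ())),
        )
        for t in cfg["random"]
    )
    spec = ModelSpec(
        traits=tuple(cfg["traits"]), fixed=tuple(cfg["fixed"]), random=random
    )
    return spec, cfg.get("parameterisation", "mv"), cfg


def write_model_config(spec: ModelSpec, parameterisation: str, path) -> None:
    cfg = {
        "traits": list(spec.traits),
        "fixed": list(spec.fixed),
        "random": [
            {
                "name": t.name,
                "rel": t.rel,
                "effect": t.effect,
                "traits": list(t.traits),
            }
            for t in spec.random
        ],
        "parameterisation": parameterisation,
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def config_hash(path) -> str:
    """Short content hash for reproducibility headers."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]
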