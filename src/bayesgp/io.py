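"""Readers and writers for genotype/phenotype tables and run configs.

Two genotype dialects are supported: plain TSV (header row of marker ids,
first column ``sample_id``, entries 0/1/2) and PLINK-style ``.raw``
dosage exports (whitespace-delimited, FID/IID/PAT/MAT/SEX/PHENOTYPE
leader columns, marker columns suffixed with the counted allele, NA for
missing).  Missing dosages are rejected by default; mean imputation is
opt-in and logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import GenotypeMatrix, PhenotypeVector

__all__ = ["read_genotypes", "read_phenotypes", "load_fixture", "load_config"]

logger = logging.getLogger("bayesgp")

_PLINK_LEADER = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _sniff_dialect(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline().split()
    if header[:6] == _PLINK_LEADER:
        return "plink_raw"
    return "tsv"


def read_genotypes(
    path: str | Path, dialect: str = "auto", impute_mean: bool = False
) -> GenotypeMatrix:
    """Read a dosage table; entries validated to {0,1,2}.

    ``dialect="auto"`` sniffs the header.  NA entries raise (with a
    count) unless ``impute_mean`` is set, in which case each missing cell
    gets its marker's mean dosage (a warning records how many).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = _sniff_dialect(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        sample_ids = [str(s) for s in df.index]
        marker_ids = [str(m) for m in df.columns]
        values = df.to_numpy(dtype=float)
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        if list(df.columns[:6]) != _PLINK_LEADER:
            raise ValueError(
                f"{path}: not a PLINK .raw header (expected {_PLINK_LEADER})"
            )
        sample_ids = [str(s) for s in df["IID"]]
        marker_cols = list(df.columns[6:])
        # strip the counted-allele suffix (snp1_A -> snp1)
        marker_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in marker_cols]
        values = df[marker_cols].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (tsv or plink_raw)")

    missing = np.isnan(values)
    if missing.any():
        if not impute_mean:
            raise ValueError(
                f"{path}: {int(missing.sum())} missing genotype entries "
                "(rerun with impute_mean=True to mean-impute)"
            )
        col_means = np.nanmean(values, axis=0)
        fill = np.broadcast_to(col_means, values.shape)
        values = np.where(missing, fill, values)
        logger.warning(
            "mean-imputed %d missing genotype entries in %s", int(missing.sum()), path
        )
        # imputation introduces fractional dosages; round to nearest class
        values = np.clip(np.rint(values), 0, 2)

    bad = ~np.isin(values, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: dosage {values[i, j]!r} not in {{0,1,2}} at "
            f"sample {sample_ids[i]!r}, marker {marker_ids[j]!r}"
        )
    return GenotypeMatrix(values.astype(np.int8), sample_ids, marker_ids)


def read_phenotypes(
    path: str | Path, genotypes: GenotypeMatrix | None = None
) -> dict[str, PhenotypeVector]:
    """Read a phenotype table (sample_id + numeric trait columns).

    When ``genotypes`` is given, rows are aligned to its sample order (by
    id, order-independent); individuals missing a trait value are dropped
    with a logged count, and a complete lack of id overlap is an error.
    Returns ``{trait_name: PhenotypeVector}``; with ``genotypes`` the
    vectors follow the genotype row order restricted to matched ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: no 'sample_id' column")
    traits = [c for c in df.columns if c != "sample_id"]
    if not traits:
        raise ValueError(f"{path}: no trait columns")
    df["sample_id"] = df["sample_id"].astype(str)

    for t in traits:
        coerced = pd.to_numeric(df[t], errors="coerce")
        bad = coerced.isna() & df[t].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {df[t].iloc[row]!r} in trait "
                f"{t!r}, row {row + 2}"
            )
        df[t] = coerced

    if genotypes is not None:
        order = pd.Index(genotypes.sample_ids, name="sample_id")
        matched = df.set_index("sample_id").reindex(order.intersection(df["sample_id"]))
        if matched.empty:
            raise ValueError(f"{path}: no sample ids overlap the genotype table")
        unmatched = set(df["sample_id"]) - set(order)
        if unmatched:
            logger.warning("%d phenotype ids not in genotypes", len(unmatched))
        df = matched.reset_index()

    out = {}
    for t in traits:
        sub = df[["sample_id", t]].dropna()
        dropped = len(df) - len(sub)
        if dropped:
            logger.warning("trait %s: dropped %d individuals with missing values", t, dropped)
        out[t] = PhenotypeVector(sub[t].to_numpy(), trait_name=t)
        out[t].sample_ids = [str(s) for s in sub["sample_id"]]  # type: ignore[attr-defined]
    return out


def load_fixture(directory: str | Path):
    """Load a simulated panel written by :func:`bayesgp.simulate.write_fixture`."""
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    geno = read_genotypes(directory / manifest["files"]["genotypes"], dialect="tsv")
    phenos = read_phenotypes(directory / manifest["files"]["phenotypes"], genotypes=geno)
    trait = manifest["trait_name"]
    return geno, phenos[trait], manifest


_KNOWN_KEYS = {
    "genotypes", "phenotypes", "trait", "models", "chains", "iters",
    "burnin", "thin", "seed", "folds", "level", "normalize", "out",
    "priors", "selection",
}


def load_config(path: str | Path) -> dict:
    """Load and schema-check a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(
            f"{path}: unknown config keys {sorted(unknown)}; "
            f"known keys: {sorted(_KNOWN_KEYS)}"
        )
    return cfg
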