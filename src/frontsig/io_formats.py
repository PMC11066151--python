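"""Readers and writers for the package's on-disk formats.

Expression matrices and phenotype tables travel as plain TSV, gene-set
collections as standard GMT, and fitted signatures as a small versioned
JSON document.  All readers validate the container invariants and raise
instead of silently repairing (the only documented repair is de-duplication
of genes inside one GMT line, which emits a warning).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

EARLY_RELAPSE = "early_relapse"
NO_RELAPSE = "no_relapse"
GROUPS = (EARLY_RELAPSE, NO_RELAPSE)

SIGNATURE_SCHEMA_VERSION = 1

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def validate_expression_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the invariants of a genes x samples expression matrix.

    Requirements: unique gene and sample identifiers, all values finite
    numeric, at least two samples.  Returns the (float-coerced) matrix.
    """
    if expr.index.has_duplicates:
        dups = sorted(expr.index[expr.index.duplicated()].unique())
        raise ValueError(f"duplicate gene identifiers: {dups}")
    if expr.columns.has_duplicates:
        dups = sorted(expr.columns[expr.columns.duplicated()].unique())
        raise ValueError(f"duplicate sample identifiers: {dups}")
    if expr.shape[1] < 2:
        raise ValueError("expression matrix must have at least 2 samples")
    try:
        values = expr.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression values: {exc}") from exc
    if not np.isfinite(values.to_numpy()).all():
        bad = np.argwhere(~np.isfinite(values.to_numpy()))
        r, c = bad[0]
        raise ValueError(
            f"non-finite expression value at gene {values.index[r]!r}, "
            f"sample {values.columns[c]!r}"
        )
    return values


def read_expression_matrix(path: PathLike) -> pd.DataFrame:
    """Read a TSV expression matrix (rows = genes, first column gene IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric cell in column {col!r}, gene row {row!r}"
            )
    return validate_expression_matrix(df)


def write_expression_matrix(expr: pd.DataFrame, path: PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

def validate_phenotype(pheno: pd.Series, require_both_groups: bool = False) -> pd.Series:
    if pheno.index.has_duplicates:
        dups = sorted(pheno.index[pheno.index.duplicated()].unique())
        raise ValueError(f"duplicate sample identifiers in phenotype: {dups}")
    bad = sorted(set(pheno.unique()) - set(GROUPS))
    if bad:
        raise ValueError(f"unknown phenotype groups {bad}; expected {GROUPS}")
    if require_both_groups and set(pheno.unique()) != set(GROUPS):
        raise ValueError("both outcome groups must be represented")
    return pheno


def read_phenotype(path: PathLike) -> pd.Series:
    """Read a two-column phenotype TSV (sample_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("phenotype table needs columns sample_id and group")
    pheno = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values,
                      name="group")
    return validate_phenotype(pheno)


def write_phenotype(pheno: pd.Series, path: PathLike) -> None:
    pd.DataFrame({"sample_id": pheno.index, "group": pheno.values}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: PathLike) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered ``{set_name: [genes]}`` mapping.

    Each line is ``name<TAB>description<TAB>gene...``.  Duplicate genes
    within one line are removed (first occurrence kept) with a warning.
    """
    collection: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in collection:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(fields[2:]))
            if len(genes) < len(fields) - 2:
                warnings.warn(
                    f"GMT set {name!r}: duplicate genes removed", stacklevel=2
                )
            if not genes:
                raise ValueError(f"GMT line {lineno}: set {name!r} is empty")
            collection[name] = genes
    return collection


def write_gmt(collection: dict[str, list[str]], path: PathLike,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# signature JSON
# ---------------------------------------------------------------------------

def write_signature(model, path: PathLike) -> None:
    """Serialize a :class:`~frontsig.model_train_eval.SignatureModel` to JSON."""
    doc = {
        "schema_version": SIGNATURE_SCHEMA_VERSION,
        "region": model.region,
        "n_g": model.n_g,
        "n_f": model.n_f,
        "intercept": model.intercept,
        "standardization": (
            None if model.standardization is None else {
                "mean": list(map(float, model.standardization[0])),
                "sd": list(map(float, model.standardization[1])),
            }
        ),
        "modules": [
            {
                "name": m.name,
                "source_set": m.source_set,
                "genes": list(m.genes),
                "directions": [int(d) for d in m.directions],
                "coefficient": float(c),
                "train_auc": None if m.train_auc is None else float(m.train_auc),
            }
            for m, c in zip(model.modules, model.module_coefficients)
        ],
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_signature(path: PathLike):
    """Read a signature JSON document back into a ``SignatureModel``."""
    from .model_train_eval import SignatureModel
    from .module_builder import GeneModule

    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != SIGNATURE_SCHEMA_VERSION:
        raise ValueError(
            f"unknown signature schema version {version!r}; "
            f"this build reads version {SIGNATURE_SCHEMA_VERSION}"
        )
    if "modules" not in doc:
        raise ValueError("signature document missing required field 'modules'")
    modules = []
    coefficients = []
    for entry in doc["modules"]:
        modules.append(GeneModule(
            name=entry["name"],
            genes=tuple(entry["genes"]),
            directions=tuple(int(d) for d in entry["directions"]),
            source_set=entry.get("source_set", entry["name"]),
            train_auc=entry.get("train_auc"),
        ))
        coefficients.append(float(entry["coefficient"]))
    std = doc.get("standardization")
    standardization = None
    if std is not None:
        standardization = (np.asarray(std["mean"], dtype=float),
                           np.asarray(std["sd"], dtype=float))
    return SignatureModel(
        modules=modules,
        module_coefficients=np.asarray(coefficients, dtype=float),
        intercept=doc.get("intercept"),
        n_g=int(doc["n_g"]),
        n_f=int(doc["n_f"]),
        region=doc.get("region", "bulk"),
        standardization=standardization,
        metadata=doc.get("metadata", {}),
    )
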