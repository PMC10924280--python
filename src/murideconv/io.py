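"""Readers and writers for the on-disk formats.

Matrix files are TSV/CSV with genes (or cell types) in rows — the first
column holds row identifiers, the header row holds column identifiers.
The orientation is fixed; no auto-transposition is attempted, because a
silently transposed matrix is one of the classic deconvolution bugs.

Gene sets use the GMT dialect (one set per line: name, description,
tab-separated genes) with a signed extension: a gene token suffixed with
``-`` is a down-weighted (−1) gene, anything else is +1.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    UNKNOWN_LABEL,
    DeconvolutionResult,
    ExpressionMatrix,
    SignatureMatrix,
    WeightedGeneSetCollection,
)
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

COLLAPSE_POLICIES = ("sum", "mean", "max")


def _read_matrix(path: str | Path, fmt: str | None) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise FormatError(f"unknown matrix format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no data columns (wrong separator?)")
    if df.columns.str.startswith("Unnamed").any():
        raise FormatError(f"{path}: malformed header (unnamed columns)")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise FormatError(f"{path}: non-numeric column(s) {non_numeric[:3]}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][:3].tolist()
        raise FormatError(f"{path}: missing fields (ragged line?) at rows {bad}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def collapse_duplicate_genes(df: pd.DataFrame, policy: str = "sum") -> pd.DataFrame:
    """Collapse duplicate gene rows under ``sum`` (default), ``mean`` or ``max``.

    ``sum`` conserves the matrix total, which matches counts semantics.
    """
    if policy not in COLLAPSE_POLICIES:
        raise ValidationError(f"unknown duplicate policy {policy!r}")
    if not df.index.has_duplicates:
        return df
    n_dup = int(df.index.duplicated().sum())
    logger.info("collapsing %d duplicate gene row(s) with policy %r", n_dup, policy)
    grouped = df.groupby(level=0, sort=False)
    return getattr(grouped, policy)()


def read_expression(
    path: str | Path,
    fmt: str | None = None,
    unit: str = "TPM",
    duplicate_policy: str = "sum",
) -> ExpressionMatrix:
    """Read a genes × samples matrix, collapsing duplicate gene rows."""
    df = collapse_duplicate_genes(_read_matrix(path, fmt), duplicate_policy)
    return ExpressionMatrix(df, unit=unit)


def read_signature(
    path: str | Path,
    fmt: str | None = None,
    mrna_scaling_path: str | Path | None = None,
) -> SignatureMatrix:
    """Read a genes × cell-types signature, optionally with mRNA factors.

    The scaling file is a two-column TSV ``cell_type<TAB>factor``.
    """
    df = collapse_duplicate_genes(_read_matrix(path, fmt), "mean")
    scaling = None
    if mrna_scaling_path is not None:
        tab = pd.read_csv(mrna_scaling_path, sep="\t", index_col=0, header=None)
        scaling = tab.iloc[:, 0].astype(float)
        scaling.index = scaling.index.astype(str)
    return SignatureMatrix(df, mrna_scaling=scaling)


def read_gmt(path: str | Path) -> WeightedGeneSetCollection:
    """Parse a (possibly signed) GMT file into a gene-set collection."""
    entries: dict[str, list[tuple[str, int]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and ≥1 gene"
                )
            name = fields[0]
            if name in entries:
                raise ValidationError(f"{path}: duplicate gene set name {name!r}")
            genes: list[tuple[str, int]] = []
            for tok in fields[2:]:
                tok = tok.strip()
                if not tok:
                    continue
                if tok.endswith("-"):
                    genes.append((tok[:-1], -1))
                else:
                    genes.append((tok, +1))
            entries[name] = genes
    return WeightedGeneSetCollection(entries)


def write_gmt(sets: WeightedGeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ct in sets.cell_types:
            toks = [g if w == +1 else f"{g}-" for g, w in sets.entries[ct]]
            fh.write("\t".join([ct, "na", *toks]) + "\n")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


def write_signature(sig: SignatureMatrix, path: str | Path) -> None:
    sig.data.to_csv(path, sep="\t", index_label="gene")


def write_result(result: DeconvolutionResult, path: str | Path) -> None:
    """Write a result as TSV (cell types × samples).

    A leading ``#`` comment line carries the method name and estimate
    type so a round-trip read restores both.  The result's invariants
    are re-validated before writing; an out-of-simplex fraction result
    is refused.
    """
    # re-run invariant checks in case the frame was mutated after construction
    DeconvolutionResult(
        result.data,
        estimate_type=result.estimate_type,
        method_name=result.method_name,
        unknown_row=result.unknown_row,
    )
    with open(path, "w") as fh:
        fh.write(
            f"# method_name={result.method_name}\testimate_type={result.estimate_type}\n"
        )
        result.data.to_csv(fh, sep="\t", index_label="cell_type")


def read_result(path: str | Path) -> DeconvolutionResult:
    method_name, estimate_type = "unknown", "score"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].strip().split("\t"):
            if "=" in tok:
                key, val = tok.split("=", 1)
                if key == "method_name":
                    method_name = val
                elif key == "estimate_type":
                    estimate_type = val
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return DeconvolutionResult(
        df,
        estimate_type=estimate_type,
        method_name=method_name,
        unknown_row=UNKNOWN_LABEL in df.index,
    )
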