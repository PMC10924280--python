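"""Validated in-memory containers for expression data, signatures,
gene sets and deconvolution results.

All matrices keep genes (or cell types) in rows and samples in columns,
mirroring the on-disk orientation.  Containers validate their invariants
at construction time and are treated as immutable by the rest of the
package (engines return new objects rather than mutating inputs).

Estimate semantics
------------------
A :class:`DeconvolutionResult` is tagged either ``"fraction"`` — values on
the simplex, comparable both within a sample (across cell types) and
between samples — or ``"score"`` — an arbitrary-scale abundance estimate
comparable only between samples for one cell type at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Recognised expression units.  ``log2_TPM`` marks log2(TPM + 1) data;
#: engines that operate in linear space refuse it.
UNITS = ("TPM", "counts", "log2_TPM")

#: Name reserved for the unknown-content row appended by constrained
#: least squares when ``allow_unknown`` is set.
UNKNOWN_LABEL = "uncharacterized"

FRACTION_TOL = 1e-9


def _check_unique(labels: Sequence[str], what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes × samples expression matrix with a declared unit.

    Parameters
    ----------
    data
        Dense DataFrame, index = gene symbols, columns = sample ids.
    unit
        One of ``TPM``, ``counts``, ``log2_TPM``.
    """

    data: pd.DataFrame
    unit: str = "TPM"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.data.size == 0:
            raise ValidationError("empty expression matrix")
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "gene_ids")
        _check_unique(self.data.columns, "sample_ids")
        vals = self.data.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValidationError("expression matrix contains non-finite values")
        if self.unit in ("TPM", "counts") and (vals < 0).any():
            bad = self.data.index[(vals < 0).any(axis=1)][:5].tolist()
            raise ValidationError(
                f"negative values with unit {self.unit}: genes {bad}"
            )
        if self.unit == "TPM":
            colsums = vals.sum(axis=0)
            if (colsums <= 0).any():
                bad = self.data.columns[colsums <= 0].tolist()
                raise ValidationError(f"all-zero TPM sample(s): {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (order preserved, missing genes skipped)."""
        present = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[present], unit=self.unit)


@dataclass
class SignatureMatrix:
    """Genes × cell-types expected expression profile.

    ``mrna_scaling`` carries optional per-cell-type mRNA content factors
    (larger = more mRNA per cell); engines that renormalize fractions by
    mRNA content use them, everything else ignores them.
    """

    data: pd.DataFrame
    mrna_scaling: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.size == 0:
            raise ValidationError("empty signature matrix")
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "gene_ids")
        _check_unique(self.data.columns, "cell_types")
        vals = self.data.to_numpy()
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValidationError("signature values must be finite and non-negative")
        zero_cols = self.data.columns[(vals <= 0).all(axis=0)].tolist()
        if zero_cols:
            raise ValidationError(f"signature column(s) with no positive entry: {zero_cols}")
        if self.mrna_scaling is not None:
            self.mrna_scaling = pd.Series(self.mrna_scaling, dtype=float)
            missing = set(self.data.columns) - set(self.mrna_scaling.index)
            if missing:
                raise ValidationError(f"mrna_scaling missing cell types: {sorted(missing)}")
            self.mrna_scaling = self.mrna_scaling.reindex(self.data.columns)
            if (self.mrna_scaling <= 0).any() or not np.all(
                np.isfinite(self.mrna_scaling.to_numpy())
            ):
                raise ValidationError("mrna_scaling values must be strictly positive")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def cell_types(self) -> list[str]:
        return self.data.columns.tolist()

    def scaling_vector(self) -> pd.Series:
        """mRNA scaling factors, defaulting to 1.0 for every cell type."""
        if self.mrna_scaling is None:
            return pd.Series(1.0, index=self.data.columns)
        return self.mrna_scaling


@dataclass
class WeightedGeneSetCollection:
    """Named cell types, each mapping to a signed marker-gene list.

    Weights are +1 (gene up in this cell type) or −1 (gene expected
    depleted).  A plain marker set is the all-(+1) special case.
    """

    entries: Mapping[str, list[tuple[str, int]]]

    def __post_init__(self) -> None:
        self.entries = dict(self.entries)
        for ct, genes in self.entries.items():
            symbols = [g for g, _ in genes]
            if len(set(symbols)) != len(symbols):
                raise ValidationError(f"duplicate gene in set {ct!r}")
            if not any(w == +1 for _, w in genes):
                raise ValidationError(f"set {ct!r} has no +1-weighted gene")
            if any(w not in (+1, -1) for _, w in genes):
                raise ValidationError(f"set {ct!r} has a weight outside {{+1, -1}}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.entries)

    def up_genes(self, cell_type: str) -> list[str]:
        return [g for g, w in self.entries[cell_type] if w == +1]

    def down_genes(self, cell_type: str) -> list[str]:
        return [g for g, w in self.entries[cell_type] if w == -1]

    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.entries.values():
            for g, _ in genes:
                seen.setdefault(g)
        return list(seen)

    def subset(self, cell_types: Iterable[str]) -> "WeightedGeneSetCollection":
        return WeightedGeneSetCollection({ct: self.entries[ct] for ct in cell_types})


@dataclass
class DeconvolutionResult:
    """Cell-types × samples estimates produced by a deconvolution engine."""

    data: pd.DataFrame
    estimate_type: str
    method_name: str
    unknown_row: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.estimate_type not in ("fraction", "score"):
            raise ValidationError(
                f"estimate_type must be 'fraction' or 'score', got {self.estimate_type!r}"
            )
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "cell_types")
        _check_unique(self.data.columns, "sample_ids")
        if self.unknown_row and UNKNOWN_LABEL not in self.data.index:
            raise ValidationError(
                f"unknown_row set but no {UNKNOWN_LABEL!r} row present"
            )
        if self.estimate_type == "fraction":
            vals = self.data.to_numpy()
            if (vals < -FRACTION_TOL).any() or (vals > 1 + FRACTION_TOL).any():
                raise ValidationError("fraction values must lie in [0, 1]")
            colsums = vals.sum(axis=0)
            if self.unknown_row:
                if np.abs(colsums - 1.0).max() > FRACTION_TOL:
                    raise ValidationError(
                        "fraction columns with unknown row must sum to 1"
                    )
            elif (colsums > 1 + FRACTION_TOL).any():
                raise ValidationError("fraction column sums exceed 1")

    @property
    def cell_types(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def known_part(self) -> pd.DataFrame:
        """Estimates without the unknown-content row, if any."""
        if self.unknown_row:
            return self.data.drop(index=UNKNOWN_LABEL)
        return self.data
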