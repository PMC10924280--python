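"""Bundled murine deconvolution resources and the custom-signature builder.

The package ships three structural stand-ins for the published murine
resources, curated from standard immunology markers (they match the
published rosters in cardinality and intent, not gene-by-gene):

``mmcp_like``
    Marker-gene sets for 14 immune and stromal cell types, scored by
    median marker expression.
``seqimmucc_like``
    A 10-cell-type murine signature matrix for regression engines.
``finegrained_like``
    A fine-grained roster of 190 immune phenotypes (19 majors × 10
    functional states), each with a small signed marker set, groupable
    to the 19 major types via the bundled ontology.

:func:`build_signature_from_sc` implements the custom-signature
workflow: given labeled single-cell counts, it derives per-type mean
CPM profiles and selects markers by fold-change of a type's mean over
the *maximum* mean across all other types (stricter than fold over the
mean of others — a gene shared by two types cannot pass).
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    SignatureMatrix,
    WeightedGeneSetCollection,
)
from .errors import ConfigError, ValidationError
from . import io as mio

logger = logging.getLogger(__name__)

MIN_CELLS_PER_TYPE = 10


def _data_path(name: str):
    return importlib_resources.files("murideconv.data") / name


def _load_mmcp_like() -> WeightedGeneSetCollection:
    with importlib_resources.as_file(_data_path("mmcp_like.gmt")) as p:
        return mio.read_gmt(p)


def _load_finegrained_like() -> WeightedGeneSetCollection:
    with importlib_resources.as_file(_data_path("finegrained_like.gmt")) as p:
        return mio.read_gmt(p)


def _load_seqimmucc_like() -> SignatureMatrix:
    with importlib_resources.as_file(_data_path("seqimmucc_like_signature.tsv")) as p:
        return mio.read_signature(p)


@dataclass
class ResourceEntry:
    loader: Callable[[], object]
    kind: str  # "markers" | "signature"
    species: str
    n_cell_types: int
    citation_tag: str
    _cache: object | None = field(default=None, repr=False)

    def load(self):
        if self._cache is None:
            self._cache = self.loader()
        return self._cache


_REGISTRY: dict[str, ResourceEntry] = {
    "mmcp_like": ResourceEntry(
        _load_mmcp_like, "markers", "mouse", 14, "median-marker scoring roster"
    ),
    "seqimmucc_like": ResourceEntry(
        _load_seqimmucc_like, "signature", "mouse", 10, "murine regression signature"
    ),
    "finegrained_like": ResourceEntry(
        _load_finegrained_like, "markers", "mouse", 190, "fine-grained phenotype roster"
    ),
}


def list_resources() -> pd.DataFrame:
    """Tabulate the bundled resources (name, kind, species, #cell types)."""
    rows = [
        {"name": name, "kind": e.kind, "species": e.species,
         "n_cell_types": e.n_cell_types, "citation_tag": e.citation_tag}
        for name, e in _REGISTRY.items()
    ]
    return pd.DataFrame(rows).set_index("name")


def get_resource(name: str):
    """Fetch a bundled resource by name; suggests the closest name on a miss."""
    if name not in _REGISTRY:
        close = difflib.get_close_matches(name, _REGISTRY, n=1)
        hint = f"; did you mean {close[0]!r}?" if close else ""
        raise ConfigError(
            f"unknown resource {name!r}{hint} (available: {sorted(_REGISTRY)})"
        )
    return _REGISTRY[name].load()


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per column (cell or sample)."""
    colsums = counts.sum(axis=0)
    if (colsums <= 0).any():
        raise ValidationError("cannot CPM-normalize an all-zero column")
    return counts.div(colsums, axis=1) * 1e6


def build_signature_from_sc(
    sc_counts: ExpressionMatrix,
    labels: Mapping[str, str] | pd.Series,
    n_markers_per_type: int = 50,
    min_fold: float = 2.0,
) -> tuple[SignatureMatrix, WeightedGeneSetCollection]:
    """Derive a signature matrix and marker sets from labeled single cells.

    Parameters
    ----------
    sc_counts
        Cells-as-samples count matrix (unit ``counts``).
    labels
        Cell id → cell-type label; must cover every cell.
    n_markers_per_type
        Maximum markers retained per type; every retained marker must pass
        ``min_fold``.  If no gene passes for some type, that is an error
        naming the type.
    min_fold
        Required fold of the type's mean CPM over the maximum mean CPM of
        all other types.

    Returns
    -------
    (SignatureMatrix, WeightedGeneSetCollection)
        The signature holds per-type mean CPM restricted to the union of
        selected markers; the collection holds the per-type marker lists
        (all weight +1).
    """
    if sc_counts.unit != "counts":
        raise ValidationError(
            f"signature builder requires raw counts, got unit {sc_counts.unit!r}"
        )
    labels = pd.Series(labels)
    missing = set(sc_counts.sample_ids) - set(labels.index)
    if missing:
        raise ValidationError(f"{len(missing)} cell(s) without a label")
    labels = labels.reindex(sc_counts.sample_ids)
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ValidationError("need at least 2 cell types to build a signature")
    counts_per_type = labels.value_counts()
    small = counts_per_type[counts_per_type < MIN_CELLS_PER_TYPE]
    if not small.empty:
        raise ValidationError(
            f"cell type(s) with < {MIN_CELLS_PER_TYPE} cells: "
            f"{small.index.tolist()}"
        )

    norm = cpm(sc_counts.data)
    profile = pd.DataFrame(
        {t: norm.loc[:, (labels == t).to_numpy()].mean(axis=1) for t in types}
    )

    markers: dict[str, list[tuple[str, int]]] = {}
    prof_vals = profile.to_numpy()
    for j, t in enumerate(types):
        own = prof_vals[:, j]
        others = np.delete(prof_vals, j, axis=1).max(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(others > 0, own / np.maximum(others, 1e-300), np.inf)
        fold = np.where(own > 0, fold, 0.0)
        passing = np.flatnonzero(fold >= min_fold)
        if passing.size == 0:
            raise ValidationError(
                f"no gene reaches fold {min_fold} for cell type {t!r}"
            )
        # deterministic: sort by descending fold, ties by gene symbol
        order = sorted(passing, key=lambda i: (-fold[i], profile.index[i]))
        chosen = [profile.index[i] for i in order[:n_markers_per_type]]
        markers[t] = [(g, +1) for g in chosen]

    union = sorted({g for gl in markers.values() for g, _ in gl})
    sig = SignatureMatrix(profile.loc[union])
    return sig, WeightedGeneSetCollection(markers)


@dataclass
class CoverageReport:
    """Fraction of signature/marker genes present in an expression matrix."""

    per_type: dict[str, float]
    overall: float
    warning: bool

    WARN_THRESHOLD = 0.8


def validate_signature_coverage(
    sig_or_sets: SignatureMatrix | WeightedGeneSetCollection,
    expr: ExpressionMatrix,
) -> CoverageReport:
    """Report which signature/marker genes the expression matrix covers."""
    expr_genes = set(expr.gene_ids)
    if isinstance(sig_or_sets, SignatureMatrix):
        per_type_genes = {
            t: sig_or_sets.gene_ids for t in sig_or_sets.cell_types
        }
        all_genes = sig_or_sets.gene_ids
    else:
        per_type_genes = {
            t: [g for g, _ in sig_or_sets.entries[t]]
            for t in sig_or_sets.cell_types
        }
        all_genes = sig_or_sets.all_genes()
    per_type = {
        t: (sum(g in expr_genes for g in gl) / len(gl)) if gl else 0.0
        for t, gl in per_type_genes.items()
    }
    overall = (
        sum(g in expr_genes for g in all_genes) / len(all_genes) if all_genes else 0.0
    )
    warning = overall < CoverageReport.WARN_THRESHOLD
    if warning:
        logger.warning(
            "only %.0f%% of signature genes present in expression matrix",
            100 * overall,
        )
    return CoverageReport(per_type=per_type, overall=overall, warning=warning)
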