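"""Synthetic single-cell reference and pseudo-bulk mixture generator.

The simulator provides ground-truth test data for every engine in the
package.  It has two stages:

1. :func:`simulate_sc_reference` draws a labeled single-cell count
   matrix from a negative-binomial model: each cell type owns a
   disjoint block of planted marker genes whose mean is ``marker_fold``
   times the genome-wide ``base_mean``; per-cell library-size factors
   are log-normal.  NB is parameterized by (mean μ, dispersion φ) with
   variance μ + μ²/φ; ``nb_dispersion = inf`` selects the Poisson
   limit.

2. :func:`simulate_pseudobulk` mixes cells into bulk samples: per
   sample, cell counts per type are multinomial at the requested
   proportions, that many cells are drawn **with replacement** (so the
   requested fractions need not respect per-type inventories), and
   their count vectors are summed, optionally scaled by a per-type
   mRNA-content bias.

Ground truth comes in two flavors — realized *cell-count* fractions and
*mRNA-weighted* fractions (cell counts weighted by per-type mRNA bias ×
mean library size, renormalized).  Regression engines on un-normalized
signatures recover the mRNA-weighted truth; that is the default
benchmark target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import ValidationError


@dataclass
class SCSimParams:
    """Parameters of the single-cell reference simulation."""

    n_cell_types: int = 5
    n_genes: int = 2000
    n_markers_per_type: int = 40
    marker_fold: float = 6.0
    base_mean: float = 0.5
    nb_dispersion: float = 2.0
    libsize_sigma: float = 0.3
    n_cells_per_type: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_types < 1 or self.n_genes < 1 or self.n_cells_per_type < 1:
            raise ValidationError("counts must be positive")
        if self.n_markers_per_type * self.n_cell_types > self.n_genes:
            raise ValidationError(
                "n_markers_per_type × n_cell_types exceeds n_genes; "
                "marker blocks must be disjoint"
            )
        if self.marker_fold < 1:
            raise ValidationError("marker_fold must be ≥ 1")
        if self.base_mean <= 0 or self.nb_dispersion <= 0 or self.libsize_sigma < 0:
            raise ValidationError("base_mean, nb_dispersion > 0; libsize_sigma ≥ 0")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) counts; dispersion=inf is the Poisson limit."""
    if math.isinf(dispersion):
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_sc_reference(
    params: SCSimParams,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Draw the labeled single-cell count matrix described by ``params``.

    Returns a cells-as-samples :class:`ExpressionMatrix` (unit
    ``counts``) and a cell → cell-type label Series.  Fully reproducible
    from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    T, G, M = params.n_cell_types, params.n_genes, params.n_markers_per_type
    types = [f"type{t + 1}" for t in range(T)]
    genes = [f"gene{g + 1:05d}" for g in range(G)]
    n_cells = T * params.n_cells_per_type
    cells = [f"cell{c + 1:05d}" for c in range(n_cells)]
    labels = pd.Series(
        np.repeat(types, params.n_cells_per_type), index=cells, name="cell_type"
    )

    mu = np.full((T, G), params.base_mean)
    for t in range(T):
        mu[t, t * M : (t + 1) * M] *= params.marker_fold

    counts = np.empty((G, n_cells), dtype=np.int64)
    libsize = np.exp(rng.normal(0.0, params.libsize_sigma, size=n_cells))
    for c in range(n_cells):
        t = c // params.n_cells_per_type
        counts[:, c] = _nb_draw(rng, libsize[c] * mu[t], params.nb_dispersion)

    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=cells), unit="counts"
    )
    return expr, labels


@dataclass
class PseudoBulkDataset:
    """A simulated bulk dataset with its ground-truth composition."""

    expr: ExpressionMatrix
    true_fractions_cells: pd.DataFrame
    true_fractions_mrna: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, df in (
            ("true_fractions_cells", self.true_fractions_cells),
            ("true_fractions_mrna", self.true_fractions_mrna),
        ):
            colsums = df.to_numpy().sum(axis=0)
            if np.abs(colsums - 1.0).max() > 1e-9:
                raise ValidationError(f"{name} columns must sum to 1")


def _resolve_fractions(
    fractions,
    types: list[str],
    n_samples: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Normalize the many accepted fraction specs to a types × samples frame."""
    samples = [f"sample{s + 1:02d}" for s in range(n_samples)]
    if fractions is None:
        fractions = 1.0
    if isinstance(fractions, (int, float)):
        mat = rng.dirichlet(np.full(len(types), float(fractions)), size=n_samples).T
        return pd.DataFrame(mat, index=types, columns=samples)
    if isinstance(fractions, Mapping):
        missing = set(fractions) - set(types)
        if missing:
            raise ValidationError(
                f"requested cell type(s) absent from the reference: {sorted(missing)}"
            )
        vec = pd.Series(0.0, index=types)
        for t, p in fractions.items():
            vec[t] = p
        if vec.sum() <= 0:
            raise ValidationError("requested proportions sum to 0")
        vec = vec / vec.sum()
        return pd.DataFrame(
            np.tile(vec.to_numpy()[:, None], n_samples), index=types, columns=samples
        )
    if isinstance(fractions, pd.DataFrame):
        missing = set(fractions.index) - set(types)
        if missing:
            raise ValidationError(
                f"requested cell type(s) absent from the reference: {sorted(missing)}"
            )
        df = fractions.reindex(types).fillna(0.0)
        df = df / df.sum(axis=0)
        df.columns = samples[: df.shape[1]]
        return df
    raise ValidationError(f"unsupported fractions spec of type {type(fractions)}")


def simulate_pseudobulk(
    sc: ExpressionMatrix,
    labels: pd.Series | Mapping[str, str],
    fractions=None,
    n_samples: int = 20,
    n_cells_per_sample: int = 500,
    mrna_bias: Mapping[str, float] | None = None,
    seed: int = 0,
) -> PseudoBulkDataset:
    """Build pseudo-bulk samples by sampling and summing single cells.

    Parameters
    ----------
    fractions
        Either ``None``/a float α (symmetric Dirichlet(α) per sample), a
        cell-type → proportion mapping (same composition for every
        sample), or a cell-types × samples DataFrame.
    mrna_bias
        Optional per-type positive multipliers emulating differing mRNA
        content per cell; applied to every sampled cell's count vector.
    """
    labels = pd.Series(labels)
    labels = labels.reindex(sc.sample_ids)
    if labels.isna().any():
        raise ValidationError("every cell needs a label")
    types = sorted(labels.unique())
    rng = np.random.default_rng(seed)
    target = _resolve_fractions(fractions, types, n_samples, rng)
    n_samples = target.shape[1]

    bias = pd.Series(1.0, index=types)
    if mrna_bias is not None:
        for t, vv in mrna_bias.items():
            if t not in bias.index:
                raise ValidationError(f"mrna_bias names unknown cell type {t!r}")
            if vv <= 0:
                raise ValidationError("mrna_bias values must be positive")
            bias[t] = float(vv)

    counts = sc.data.to_numpy()
    cell_idx_by_type = {
        t: np.flatnonzero((labels == t).to_numpy()) for t in types
    }
    for t in types:
        if cell_idx_by_type[t].size == 0:  # unreachable with types from labels
            raise ValidationError(f"no cells of type {t!r}")
    libsize = counts.sum(axis=0)
    mean_libsize = pd.Series(
        {t: float(libsize[cell_idx_by_type[t]].mean()) for t in types}
    )

    G = sc.n_genes
    bulk = np.zeros((G, n_samples))
    realized = np.zeros((len(types), n_samples), dtype=np.int64)
    sampled_cells: list[list[str]] = []
    for s in range(n_samples):
        n_per_type = rng.multinomial(n_cells_per_sample, target.iloc[:, s].to_numpy())
        realized[:, s] = n_per_type
        chosen: list[str] = []
        col = np.zeros(G)
        for ti, t in enumerate(types):
            if n_per_type[ti] == 0:
                continue
            pick = rng.choice(cell_idx_by_type[t], size=n_per_type[ti], replace=True)
            col += counts[:, pick].sum(axis=1) * bias[t]
            chosen.extend(sc.data.columns[p] for p in pick)
        bulk[:, s] = col
        sampled_cells.append(chosen)

    samples = list(target.columns)
    frac_cells = pd.DataFrame(
        realized / n_cells_per_sample, index=types, columns=samples
    )
    mrna_weight = realized * (bias * mean_libsize).to_numpy()[:, None]
    frac_mrna = pd.DataFrame(
        mrna_weight / mrna_weight.sum(axis=0, keepdims=True),
        index=types, columns=samples,
    )

    expr = ExpressionMatrix(
        pd.DataFrame(bulk, index=sc.gene_ids, columns=samples), unit="counts"
    )
    provenance = {
        "seed": seed,
        "n_samples": n_samples,
        "n_cells_per_sample": n_cells_per_sample,
        "mrna_bias": dict(bias),
        "target_fractions": target,
        "sampled_cells": sampled_cells,
    }
    return PseudoBulkDataset(
        expr=expr,
        true_fractions_cells=frac_cells,
        true_fractions_mrna=frac_mrna,
        provenance=provenance,
    )


def simulate_dataset(
    params: SCSimParams | None = None,
    n_samples: int = 20,
    n_cells_per_sample: int = 500,
    fractions=None,
    mrna_bias: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> tuple[PseudoBulkDataset, ExpressionMatrix, pd.Series]:
    """Convenience: reference + pseudo-bulk in one call.

    ``seed`` defaults to ``params.seed``; the pseudo-bulk stage uses
    ``seed + 1`` so reference and mixing draws are independent streams.
    """
    params = params or SCSimParams()
    sc, labels = simulate_sc_reference(params)
    ds = simulate_pseudobulk(
        sc, labels,
        fractions=fractions,
        n_samples=n_samples,
        n_cells_per_sample=n_cells_per_sample,
        mrna_bias=mrna_bias,
        seed=(params.seed if seed is None else seed) + 1,
    )
    ds.provenance["sc_params"] = asdict(params)
    return ds, sc, labels
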