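"""Benchmark deconvolution estimates against known composition.

The protocol is per-cell-type, across samples: after aligning labels
through the ontology (harmonization, then fine → major grouping if
direct intersection fails), each shared cell type contributes one
Pearson correlation between its estimated and true values over the
samples, plus an RMSE when — and only when — the estimate is a
fraction (scores live on an arbitrary scale, so their RMSE against
fractions is meaningless; their correlation is not).

Correlations are withheld (reported as absent, with a flag) when fewer
than 3 paired samples remain or when either side has zero variance —
two points always correlate at ±1, and a constant vector has no
defined correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import UNKNOWN_LABEL, DeconvolutionResult
from .errors import ValidationError
from .ontology import CellTypeOntology, group_to_major, harmonize

logger = logging.getLogger(__name__)

MIN_SAMPLES_FOR_R = 3


@dataclass
class BenchmarkReport:
    """Tidy per-(method, cell type) evaluation table plus provenance."""

    table: pd.DataFrame  # columns: method, cell_type, n_samples, pearson_r, rmse, flag
    metadata: dict = field(default_factory=dict)

    def pearson(self) -> pd.Series:
        return self.table.set_index("cell_type")["pearson_r"]

    def rmse(self) -> pd.Series:
        return self.table.set_index("cell_type")["rmse"]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson correlation; NaN when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den == 0:
        return float("nan")
    return float((xc @ yc) / den)


def _align_labels(
    result: DeconvolutionResult,
    truth_labels: list[str],
    ontology: CellTypeOntology | None,
    method_key: str | None = None,
) -> DeconvolutionResult:
    if ontology is None:
        return result
    res = harmonize(result, ontology, method=method_key)
    if set(res.cell_types) & set(truth_labels):
        return res
    if ontology.hierarchy:
        return group_to_major(res, ontology)
    return res


def evaluate(
    result: DeconvolutionResult,
    truth: pd.DataFrame,
    ontology: CellTypeOntology | None = None,
    truth_flavor: str = "mrna",
    method_key: str | None = None,
) -> BenchmarkReport:
    """Score one result against a cell-types × samples truth matrix.

    Parameters
    ----------
    truth
        Ground-truth fractions, cell types in rows, samples in columns.
    ontology
        Optional label alignment; harmonization is tried first, then
        fine → major grouping if no label overlaps directly.
    truth_flavor
        Free-text note recorded in the report (which truth the caller
        passed — cell-count or mRNA-weighted fractions).
    """
    res = _align_labels(result, truth.index.tolist(), ontology, method_key)
    est = res.known_part()
    shared_types = [t for t in est.index if t in set(truth.index)]
    if not shared_types:
        raise ValidationError(
            "no shared cell types between estimate and truth; "
            f"estimate has {sorted(est.index)[:10]}, truth has "
            f"{sorted(truth.index)[:10]}"
        )
    shared_samples = [s for s in est.columns if s in set(truth.columns)]
    if not shared_samples:
        raise ValidationError("no shared sample ids between estimate and truth")
    dropped = est.shape[1] - len(shared_samples)
    if dropped:
        logger.info("%d estimate sample(s) without truth dropped", dropped)

    is_fraction = result.estimate_type == "fraction"
    rows = []
    for ct in shared_types:
        x = est.loc[ct, shared_samples].to_numpy(dtype=float)
        y = truth.loc[ct, shared_samples].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        n_dropped = int((~ok).sum())
        if n_dropped:
            logger.info("%s: %d sample pair(s) dropped for missing values", ct, n_dropped)
        x, y = x[ok], y[ok]
        n = len(x)
        flag = None
        if n < MIN_SAMPLES_FOR_R:
            r = float("nan")
            flag = "too_few_samples"
        elif np.var(y) == 0:
            r = float("nan")
            flag = "zero_truth_variance"
        else:
            r = pearson_r(x, y)
            if np.isnan(r):
                flag = "zero_estimate_variance"
        rmse = (
            float(np.sqrt(np.mean((x - y) ** 2))) if (is_fraction and n > 0) else float("nan")
        )
        rows.append(
            {
                "method": result.method_name,
                "cell_type": ct,
                "n_samples": n,
                "pearson_r": r,
                "rmse": rmse,
                "flag": flag,
            }
        )
    table = pd.DataFrame(rows)
    return BenchmarkReport(
        table=table,
        metadata={
            "truth_flavor": truth_flavor,
            "estimate_type": result.estimate_type,
            "n_shared_types": len(shared_types),
            "n_shared_samples": len(shared_samples),
        },
    )


def cross_method_table(reports: list[BenchmarkReport]) -> pd.DataFrame:
    """Long-format comparison table: one row per (method, cell type).

    Cell types missing from a method appear as explicit NA rows, so the
    table is a complete methods × cell-types grid.
    """
    cols = ["method", "cell_type", "n_samples", "pearson_r", "rmse", "flag"]
    if not reports:
        return pd.DataFrame(columns=cols)
    combined = pd.concat([r.table for r in reports], ignore_index=True)
    methods = combined["method"].unique()
    types = combined["cell_type"].unique()
    full = pd.MultiIndex.from_product(
        [methods, types], names=["method", "cell_type"]
    ).to_frame(index=False)
    out = full.merge(combined, on=["method", "cell_type"], how="left")
    return out[cols]
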