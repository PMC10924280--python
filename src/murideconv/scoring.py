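"""Gene-set–based abundance scoring engines.

Two engine families produce per-cell-type *scores* (arbitrary scale,
comparable between samples for one cell type, NOT across cell types):

:class:`MedianMarkerScorer`
    The score of cell type *t* in sample *s* is the median expression of
    *t*'s marker genes, optionally on the log2(TPM+1) scale (default).
    Robust to single aberrant markers; ignores absent markers.

:class:`SignedRankScorer`
    A signed rank statistic: per sample, genes are ranked ascending with
    mid-ranks for ties and normalized to (0, 1]; the score is the mean
    normalized rank of the up-weighted genes minus that of the
    down-weighted genes (minus 0.5 when the set has no down genes).  A
    uniformly random gene set therefore scores ≈ 0 (the exact null mean
    of an up-only set is 1/(2·n_genes), negligible for any realistic
    matrix), and the statistic is invariant under any strictly monotone
    transform of a sample's expression vector.

Both classes follow the scikit-learn transformer protocol: ``fit`` takes
a samples × genes DataFrame (gene symbols as columns) and resolves
marker coverage; ``transform`` returns a samples × cell-types DataFrame.
The module-level functions :func:`median_marker_score` and
:func:`signed_rank_score` wrap the estimators for the genes × samples
container types.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import (
    DeconvolutionResult,
    ExpressionMatrix,
    WeightedGeneSetCollection,
)
from .errors import CoverageError, ValidationError

logger = logging.getLogger(__name__)


def _as_frame(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError(
            "expected a samples × genes DataFrame with gene symbols as columns"
        )
    return X


class _BaseSetScorer(TransformerMixin, BaseEstimator):
    """Shared fit logic: resolve which marker genes the data covers."""

    def __init__(self, sets: WeightedGeneSetCollection | None = None):
        self.sets = sets

    def _resolve_sets(self) -> WeightedGeneSetCollection:
        if self.sets is None:
            raise ValidationError("no gene sets supplied")
        return self.sets

    def fit(self, X, y=None):
        X = _as_frame(X)
        sets = self._resolve_sets()
        genes = set(X.columns)
        self.present_up_: dict[str, list[str]] = {}
        self.present_down_: dict[str, list[str]] = {}
        empty = []
        for ct in sets.cell_types:
            up = [g for g in sets.up_genes(ct) if g in genes]
            down = [g for g in sets.down_genes(ct) if g in genes]
            n_absent = len(sets.up_genes(ct)) + len(sets.down_genes(ct)) - len(up) - len(down)
            if n_absent:
                logger.info("%s: %d marker gene(s) absent from data", ct, n_absent)
            if not up:
                empty.append(ct)
            self.present_up_[ct] = up
            self.present_down_[ct] = down
        if len(empty) == len(sets.cell_types):
            raise CoverageError(
                "no cell type has any marker gene present in the expression matrix"
            )
        if empty:
            logger.warning(
                "cell type(s) with zero present markers (all-missing rows): %s", empty
            )
        self.cell_types_ = list(sets.cell_types)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "cell_types_")
        return np.asarray(self.cell_types_, dtype=object)


class MedianMarkerScorer(_BaseSetScorer):
    """Median marker-gene expression score per cell type.

    Parameters
    ----------
    sets
        Marker collection; all weights must be +1.
    log_transform
        Score on log2(TPM + 1) instead of raw TPM (default True).
    """

    def __init__(
        self,
        sets: WeightedGeneSetCollection | None = None,
        log_transform: bool = True,
    ):
        super().__init__(sets=sets)
        self.log_transform = log_transform

    def _resolve_sets(self) -> WeightedGeneSetCollection:
        sets = super()._resolve_sets()
        for ct in sets.cell_types:
            if sets.down_genes(ct):
                raise ValidationError(
                    f"median marker scoring takes +1-weighted markers only; "
                    f"set {ct!r} has down-weighted genes"
                )
        return sets

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "cell_types_")
        X = _as_frame(X)
        vals = X.astype(float)
        if self.log_transform:
            vals = np.log2(vals + 1.0)
        out = pd.DataFrame(
            np.nan, index=X.index, columns=self.cell_types_, dtype=float
        )
        for ct in self.cell_types_:
            genes = self.present_up_[ct]
            if genes:
                out[ct] = vals[genes].median(axis=1)
        return out


class SignedRankScorer(_BaseSetScorer):
    """Signed mean-normalized-rank score per cell type."""

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "cell_types_")
        X = _as_frame(X)
        arr = X.to_numpy(dtype=float)
        n_genes = arr.shape[1]
        # mid-ranks per sample, normalized to (0, 1]
        ranks = rankdata(arr, axis=1, method="average") / n_genes
        rank_df = pd.DataFrame(ranks, index=X.index, columns=X.columns)
        out = pd.DataFrame(
            np.nan, index=X.index, columns=self.cell_types_, dtype=float
        )
        for ct in self.cell_types_:
            up = self.present_up_[ct]
            down = self.present_down_[ct]
            if not up:
                continue
            up_mean = rank_df[up].mean(axis=1)
            if down:
                out[ct] = up_mean - rank_df[down].mean(axis=1)
            else:
                out[ct] = up_mean - 0.5
        return out


def _score_result(
    frame: pd.DataFrame, expr: ExpressionMatrix, method_name: str, **meta
) -> DeconvolutionResult:
    return DeconvolutionResult(
        frame.T.reindex(columns=expr.sample_ids),
        estimate_type="score",
        method_name=method_name,
        metadata=meta,
    )


def median_marker_score(
    expr: ExpressionMatrix,
    markers: WeightedGeneSetCollection,
    log_transform: bool = True,
) -> DeconvolutionResult:
    """Median marker expression scores on a genes × samples matrix."""
    if expr.unit == "log2_TPM" and log_transform:
        raise ValidationError(
            "input is already log2-scale; pass log_transform=False"
        )
    est = MedianMarkerScorer(sets=markers, log_transform=log_transform)
    scores = est.fit(expr.data.T).transform(expr.data.T)
    return _score_result(
        scores, expr, "mmcp_like", log_transform=log_transform
    )


def signed_rank_score(
    expr: ExpressionMatrix, sets: WeightedGeneSetCollection
) -> DeconvolutionResult:
    """Signed rank scores on a genes × samples matrix."""
    est = SignedRankScorer(sets=sets)
    scores = est.fit(expr.data.T).transform(expr.data.T)
    return _score_result(scores, expr, "base_like")
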