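"""Signature-matrix deconvolution engines.

All three engines model a bulk sample *b* (restricted to the genes
shared with the signature *S*, genes × cell types) as a weighted
combination of cell-type profiles, ``b ≈ S f``, and differ in how they
estimate *f*:

:class:`ConstrainedLSDeconvolver`
    Weighted least squares under ``f ≥ 0`` and either ``Σf = 1`` or
    ``Σf ≤ 1``.  With the inequality constraint the slack ``1 − Σf`` is
    reported as *uncharacterized* content — cell types present in the
    mixture but absent from the signature.  Mixture and signature
    columns are both re-normalized to TPM scale (sum 10⁶) over the
    shared genes first, so the simplex constraint is meaningful.
    Produces fractions.

:class:`NuSVRDeconvolver`
    Linear ν-support-vector regression of the z-scored mixture on the
    z-scored signature columns, with ν selected from a small grid by
    minimizing the RMSE of the fitted mixture; negative coefficients are
    clipped and the rest normalized to sum 1.  Produces fractions.

:class:`ElasticNetDeconvolver`
    Elastic-net regression averaged over random gene subsets.
    Coefficients may be negative and are reported unnormalized as
    relative-abundance *scores*.

Estimators take the signature at construction, follow the scikit-learn
``fit``/``transform`` protocol on samples × genes DataFrames, and are
wrapped by :func:`cls_deconvolve`, :func:`nusvr_deconvolve` and
:func:`elasticnet_deconvolve` for the genes × samples container types.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV
from sklearn.svm import NuSVR
from sklearn.utils.validation import check_is_fitted

from .containers import (
    UNKNOWN_LABEL,
    DeconvolutionResult,
    ExpressionMatrix,
    SignatureMatrix,
)
from .errors import CoverageError, ValidationError

logger = logging.getLogger(__name__)

#: Engines refuse to run when fewer shared genes than this remain.
MIN_SHARED_GENES = 10
#: ... or when less than this fraction of signature genes is covered.
MIN_SHARED_FRACTION = 0.5
WARN_SHARED_FRACTION = 0.8

TPM_SCALE = 1e6


# --------------------------------------------------------------------------
# options containers (kept for the functional API; estimators expose the
# same knobs as constructor parameters)
# --------------------------------------------------------------------------
@dataclass
class CLSOptions:
    allow_unknown: bool = True
    mrna_renormalize: bool = False
    weights: np.ndarray | None = None


@dataclass
class SVROptions:
    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)

    def __post_init__(self) -> None:
        if not self.nu_grid or any(not 0 < nu < 1 for nu in self.nu_grid):
            raise ValidationError("nu_grid must be non-empty with values in (0, 1)")


@dataclass
class ENOptions:
    l1_ratio: float = 0.05
    n_repeats: int = 10
    subset_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.l1_ratio <= 1:
            raise ValidationError("l1_ratio must be in [0, 1]")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be ≥ 1")
        if not 0 < self.subset_fraction <= 1:
            raise ValidationError("subset_fraction must be in (0, 1]")


# --------------------------------------------------------------------------
# shared gene alignment
# --------------------------------------------------------------------------
def _as_frame(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError(
            "expected a samples × genes DataFrame with gene symbols as columns"
        )
    return X


class _BaseSignatureDeconvolver(TransformerMixin, BaseEstimator):
    def __init__(self, signature: SignatureMatrix | None = None):
        self.signature = signature

    def _signature(self) -> SignatureMatrix:
        if self.signature is None:
            raise ValidationError("no signature matrix supplied")
        return self.signature

    def fit(self, X, y=None):
        """Resolve the shared-gene space between data and signature."""
        X = _as_frame(X)
        sig = self._signature()
        shared = [g for g in sig.gene_ids if g in set(X.columns)]
        frac = len(shared) / len(sig.gene_ids)
        if len(shared) < MIN_SHARED_GENES or frac < MIN_SHARED_FRACTION:
            raise CoverageError(
                f"only {len(shared)}/{len(sig.gene_ids)} signature genes "
                f"({100 * frac:.0f}%) present in the expression matrix; need "
                f"≥ {MIN_SHARED_GENES} genes and ≥ {100 * MIN_SHARED_FRACTION:.0f}%"
            )
        if frac < WARN_SHARED_FRACTION:
            logger.warning(
                "signature coverage %.0f%% is below %.0f%% — estimates may degrade",
                100 * frac, 100 * WARN_SHARED_FRACTION,
            )
        S = sig.data.loc[shared].to_numpy(dtype=float)
        dup = [
            (sig.cell_types[i], sig.cell_types[j])
            for i in range(S.shape[1])
            for j in range(i + 1, S.shape[1])
            if np.allclose(S[:, i], S[:, j])
        ]
        if dup:
            logger.warning("signature has (near-)duplicate columns: %s", dup)
        self.shared_genes_ = shared
        self.cell_types_ = list(sig.cell_types)
        self.signature_shared_ = S
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "cell_types_")
        return np.asarray(self.cell_types_, dtype=object)

    def _mixtures(self, X) -> np.ndarray:
        """Samples × shared-genes slice of the data, as float array."""
        check_is_fitted(self, "shared_genes_")
        X = _as_frame(X)
        missing = [g for g in self.shared_genes_ if g not in X.columns]
        if missing:
            raise ValidationError(
                f"transform data lacks {len(missing)} gene(s) seen at fit time"
            )
        return X[self.shared_genes_].to_numpy(dtype=float)


# --------------------------------------------------------------------------
# constrained least squares
# --------------------------------------------------------------------------
def _solve_cls(
    S: np.ndarray,
    b: np.ndarray,
    w: np.ndarray,
    equality: bool,
) -> np.ndarray:
    """Minimize ||w^1/2 (S f − b)||² s.t. f ≥ 0 and Σf = 1 (or ≤ 1).

    Solved as a smooth quadratic program with SLSQP and an analytic
    gradient; inputs are pre-scaled so the objective is O(1).
    """
    k = S.shape[1]
    sw = np.sqrt(w)[:, None]
    Sw = S * sw
    bw = b * sw[:, 0]
    scale = np.linalg.norm(bw)
    if scale > 0:
        Sw = Sw / scale
        bw = bw / scale
    H = Sw.T @ Sw
    g0 = Sw.T @ bw

    def obj(f):
        r = Sw @ f - bw
        return 0.5 * float(r @ r)

    def grad(f):
        return H @ f - g0

    if equality:
        cons = [{"type": "eq", "fun": lambda f: f.sum() - 1.0,
                 "jac": lambda f: np.ones(k)}]
    else:
        cons = [{"type": "ineq", "fun": lambda f: 1.0 - f.sum(),
                 "jac": lambda f: -np.ones(k)}]
    x0 = np.full(k, 1.0 / k)
    res = minimize(
        obj, x0, jac=grad, bounds=[(0.0, 1.0)] * k, constraints=cons,
        method="SLSQP", options={"maxiter": 1000, "ftol": 1e-16},
    )
    f = np.clip(res.x, 0.0, None)
    if equality:
        s = f.sum()
        f = f / s if s > 0 else np.full(k, 1.0 / k)
    else:
        s = f.sum()
        if s > 1.0:
            f = f / s
    return f


class ConstrainedLSDeconvolver(_BaseSignatureDeconvolver):
    """Constrained weighted least squares with optional unknown content.

    Parameters
    ----------
    signature
        Genes × cell-types profile matrix (TPM-like scale).
    allow_unknown
        Relax ``Σf = 1`` to ``Σf ≤ 1`` and report the slack as the
        ``uncharacterized`` fraction.
    mrna_renormalize
        Divide fractions by the signature's per-type mRNA scaling
        factors and re-normalize the known part, converting
        mRNA-proportion estimates into cell-count proportions.
    weights
        Optional per-signature-gene non-negative weights (aligned to the
        signature's gene order); genes absent from the data are dropped
        together with their weights.
    """

    def __init__(
        self,
        signature: SignatureMatrix | None = None,
        allow_unknown: bool = True,
        mrna_renormalize: bool = False,
        weights: np.ndarray | None = None,
    ):
        super().__init__(signature=signature)
        self.allow_unknown = allow_unknown
        self.mrna_renormalize = mrna_renormalize
        self.weights = weights

    def fit(self, X, y=None):
        super().fit(X, y)
        sig = self._signature()
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(sig.gene_ids),):
                raise ValidationError(
                    "weights must align with the signature gene list"
                )
            if (w < 0).any() or not w.any():
                raise ValidationError("weights must be non-negative, not all zero")
            keep = [i for i, g in enumerate(sig.gene_ids) if g in self.shared_genes_]
            self.weights_ = w[keep]
        else:
            self.weights_ = np.ones(len(self.shared_genes_))
        # both sides of the fit live on TPM scale over the shared genes
        S = self.signature_shared_
        colsums = S.sum(axis=0)
        self.signature_tpm_ = S / colsums * TPM_SCALE
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "signature_tpm_")
        B = self._mixtures(X)
        rowsums = B.sum(axis=1, keepdims=True)
        if (rowsums <= 0).any():
            raise ValidationError("sample with zero expression on shared genes")
        B = B / rowsums * TPM_SCALE
        k = len(self.cell_types_)
        out = np.empty((B.shape[0], k + (1 if self.allow_unknown else 0)))
        scaling = self._signature().scaling_vector().to_numpy(dtype=float)
        for i, b in enumerate(B):
            f = _solve_cls(self.signature_tpm_, b, self.weights_, not self.allow_unknown)
            if self.mrna_renormalize:
                known = f.sum()
                if known > 0:
                    f = f / scaling
                    f = f / f.sum() * known
            if self.allow_unknown:
                out[i] = np.concatenate([f, [max(0.0, 1.0 - f.sum())]])
            else:
                out[i] = f
        cols = self.cell_types_ + ([UNKNOWN_LABEL] if self.allow_unknown else [])
        return pd.DataFrame(out, index=_as_frame(X).index, columns=cols)


# --------------------------------------------------------------------------
# nu-SVR
# --------------------------------------------------------------------------
def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / (sd if sd > 0 else 1.0)


class NuSVRDeconvolver(_BaseSignatureDeconvolver):
    """Linear ν-SVR deconvolution with ν selected per sample by fit RMSE.

    The regularization constant is fixed at ``C = 1``, as in the common
    reference implementations; only ν varies over ``nu_grid``.
    """

    def __init__(
        self,
        signature: SignatureMatrix | None = None,
        nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75),
    ):
        super().__init__(signature=signature)
        self.nu_grid = nu_grid

    def fit(self, X, y=None):
        SVROptions(nu_grid=tuple(self.nu_grid))  # validate
        super().fit(X, y)
        self.signature_z_ = np.column_stack(
            [_zscore(col) for col in self.signature_shared_.T]
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "signature_z_")
        B = self._mixtures(X)
        k = len(self.cell_types_)
        out = np.empty((B.shape[0], k))
        for i, b in enumerate(B):
            bz = _zscore(b)
            best_rmse, best_coef = math.inf, None
            for nu in self.nu_grid:
                model = NuSVR(kernel="linear", C=1.0, nu=nu)
                model.fit(self.signature_z_, bz)
                pred = model.predict(self.signature_z_)
                rmse = float(np.sqrt(np.mean((pred - bz) ** 2)))
                if rmse < best_rmse:
                    best_rmse, best_coef = rmse, model.coef_.ravel().copy()
            f = np.clip(best_coef, 0.0, None)
            if f.sum() <= 0:
                logger.warning(
                    "degenerate ν-SVR fit (all coefficients ≤ 0); uniform fallback"
                )
                f = np.full(k, 1.0 / k)
            out[i] = f / f.sum()
        return pd.DataFrame(out, index=_as_frame(X).index, columns=self.cell_types_)


# --------------------------------------------------------------------------
# elastic net
# --------------------------------------------------------------------------
class ElasticNetDeconvolver(_BaseSignatureDeconvolver):
    """Elastic-net deconvolution averaged over random gene subsets.

    Coefficients are relative abundance changes — they may be negative
    and are deliberately NOT clipped or normalized; the output is a
    score, not a fraction.
    """

    def __init__(
        self,
        signature: SignatureMatrix | None = None,
        l1_ratio: float = 0.05,
        n_repeats: int = 10,
        subset_fraction: float = 0.5,
        seed: int = 0,
    ):
        super().__init__(signature=signature)
        self.l1_ratio = l1_ratio
        self.n_repeats = n_repeats
        self.subset_fraction = subset_fraction
        self.seed = seed

    def fit(self, X, y=None):
        ENOptions(
            l1_ratio=self.l1_ratio,
            n_repeats=self.n_repeats,
            subset_fraction=self.subset_fraction,
            seed=self.seed,
        )
        super().fit(X, y)
        n_sub = math.ceil(self.subset_fraction * len(self.shared_genes_))
        if n_sub < 2:
            raise ValidationError(
                f"gene subsets of size {n_sub} are too small to fit on"
            )
        self.subset_size_ = n_sub
        self.signature_z_ = np.column_stack(
            [_zscore(col) for col in self.signature_shared_.T]
        )
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "signature_z_")
        B = self._mixtures(X)
        k = len(self.cell_types_)
        G = len(self.shared_genes_)
        rng = np.random.default_rng(self.seed)
        out = np.zeros((B.shape[0], k))
        # ElasticNetCV with an l1_ratio of 0 is plain ridge; sklearn wants
        # a tiny positive value there
        l1 = max(self.l1_ratio, 1e-6)
        for i, b in enumerate(B):
            bz = _zscore(b)
            coefs = np.zeros(k)
            for _ in range(self.n_repeats):
                idx = (
                    np.arange(G)
                    if self.subset_size_ >= G
                    else rng.choice(G, size=self.subset_size_, replace=False)
                )
                model = ElasticNetCV(
                    l1_ratio=l1,
                    alphas=30,
                    cv=3,
                    fit_intercept=True,
                    max_iter=5000,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    model.fit(self.signature_z_[idx], bz[idx])
                coefs += model.coef_
            out[i] = coefs / self.n_repeats
        return pd.DataFrame(out, index=_as_frame(X).index, columns=self.cell_types_)


# --------------------------------------------------------------------------
# functional wrappers on the genes × samples containers
# --------------------------------------------------------------------------
def _check_linear_unit(expr: ExpressionMatrix) -> None:
    if expr.unit == "log2_TPM":
        raise ValidationError(
            "regression engines operate in linear space; got log2_TPM input"
        )


def _to_result(
    frame: pd.DataFrame,
    expr: ExpressionMatrix,
    estimate_type: str,
    method_name: str,
    unknown_row: bool = False,
    **meta,
) -> DeconvolutionResult:
    return DeconvolutionResult(
        frame.T.reindex(columns=expr.sample_ids),
        estimate_type=estimate_type,
        method_name=method_name,
        unknown_row=unknown_row,
        metadata=meta,
    )


def cls_deconvolve(
    expr: ExpressionMatrix,
    sig: SignatureMatrix,
    opts: CLSOptions | None = None,
) -> DeconvolutionResult:
    """Constrained least-squares cell fractions for a genes × samples matrix."""
    opts = opts or CLSOptions()
    _check_linear_unit(expr)
    est = ConstrainedLSDeconvolver(
        signature=sig,
        allow_unknown=opts.allow_unknown,
        mrna_renormalize=opts.mrna_renormalize,
        weights=opts.weights,
    )
    frame = est.fit(expr.data.T).transform(expr.data.T)
    return _to_result(
        frame, expr, "fraction", "cls",
        unknown_row=opts.allow_unknown,
        allow_unknown=opts.allow_unknown,
        mrna_renormalize=opts.mrna_renormalize,
    )


def nusvr_deconvolve(
    expr: ExpressionMatrix,
    sig: SignatureMatrix,
    opts: SVROptions | None = None,
) -> DeconvolutionResult:
    """ν-SVR cell fractions for a genes × samples matrix."""
    opts = opts or SVROptions()
    _check_linear_unit(expr)
    est = NuSVRDeconvolver(signature=sig, nu_grid=tuple(opts.nu_grid))
    frame = est.fit(expr.data.T).transform(expr.data.T)
    return _to_result(frame, expr, "fraction", "nusvr", nu_grid=list(opts.nu_grid))


def elasticnet_deconvolve(
    expr: ExpressionMatrix,
    sig: SignatureMatrix,
    opts: ENOptions | None = None,
) -> DeconvolutionResult:
    """Elastic-net relative-abundance scores for a genes × samples matrix."""
    opts = opts or ENOptions()
    _check_linear_unit(expr)
    est = ElasticNetDeconvolver(
        signature=sig,
        l1_ratio=opts.l1_ratio,
        n_repeats=opts.n_repeats,
        subset_fraction=opts.subset_fraction,
        seed=opts.seed,
    )
    frame = est.fit(expr.data.T).transform(expr.data.T)
    return _to_result(
        frame, expr, "score", "elasticnet",
        l1_ratio=opts.l1_ratio, n_repeats=opts.n_repeats,
        subset_fraction=opts.subset_fraction, seed=opts.seed,
    )
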