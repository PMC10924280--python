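"""Method registry and the unified ``run_method`` dispatch layer.

Every engine runs behind a registered method name with unified input
(an :class:`~murideconv.containers.ExpressionMatrix`) and output (a
:class:`~murideconv.containers.DeconvolutionResult` with harmonized
labels).  For methods declared as human-signature methods, murine input
(``species="mouse"``) is first translated into human gene space through
the ortholog-mapping module, so any human signature applies to mouse
bulk data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

from .containers import DeconvolutionResult, ExpressionMatrix, SignatureMatrix
from .errors import ConfigError
from .ontology import CellTypeOntology, harmonize
from .orthologs import bundled_mouse_human_table, convert_expression
from .regression import (
    CLSOptions,
    ENOptions,
    SVROptions,
    cls_deconvolve,
    elasticnet_deconvolve,
    nusvr_deconvolve,
)
from .resources import get_resource
from .scoring import median_marker_score, signed_rank_score

logger = logging.getLogger(__name__)


@dataclass
class MethodSpec:
    runner: Callable  # (expr, resource, options) -> DeconvolutionResult
    default_resource: str | None  # bundled resource name, None = user-supplied
    species: str  # gene space the method's resource lives in
    estimate_type: str
    harmonization_key: str | None  # label dialect in the harmonization table
    description: str
    needs_user_resource: bool = False


def _human_signature_stub() -> SignatureMatrix:
    """The bundled murine signature lifted into human symbol space.

    Gene symbols are uppercased (the murine/human case convention);
    a synthetic stand-in for a real human signature, sufficient to
    exercise the mouse → human conversion path.
    """
    sig = get_resource("seqimmucc_like")
    data = sig.data.copy()
    data.index = [g.upper() for g in data.index]
    return SignatureMatrix(data, mrna_scaling=sig.mrna_scaling)


def _run_mmcp(expr, resource, options):
    return median_marker_score(expr, resource, **(options or {}))


def _run_base(expr, resource, options):
    return signed_rank_score(expr, resource)


def _run_cls(expr, resource, options):
    opts = options if isinstance(options, CLSOptions) else CLSOptions(**(options or {}))
    return cls_deconvolve(expr, resource, opts)


def _run_cls_sum1(expr, resource, options):
    opts = options if isinstance(options, CLSOptions) else CLSOptions(
        allow_unknown=False, **(options or {})
    )
    return cls_deconvolve(expr, resource, opts)


def _run_nusvr(expr, resource, options):
    opts = options if isinstance(options, SVROptions) else SVROptions(**(options or {}))
    return nusvr_deconvolve(expr, resource, opts)


def _run_elasticnet(expr, resource, options):
    opts = options if isinstance(options, ENOptions) else ENOptions(**(options or {}))
    return elasticnet_deconvolve(expr, resource, opts)


METHODS: dict[str, MethodSpec] = {
    "mmcp_like": MethodSpec(
        _run_mmcp, "mmcp_like", "mouse", "score", "mmcp_like",
        "median marker-gene scores, 14 immune/stromal cell types",
    ),
    "base_like": MethodSpec(
        _run_base, "finegrained_like", "mouse", "score", "base_like",
        "signed rank scores over 190 fine-grained immune phenotypes",
    ),
    "seqimmucc_cls": MethodSpec(
        _run_cls_sum1, "seqimmucc_like", "mouse", "fraction", "seqimmucc_like",
        "constrained least squares (Σf = 1) on the bundled murine signature",
    ),
    "seqimmucc_svr": MethodSpec(
        _run_nusvr, "seqimmucc_like", "mouse", "fraction", "seqimmucc_like",
        "ν-SVR on the bundled murine signature",
    ),
    "dcq_like": MethodSpec(
        _run_elasticnet, "seqimmucc_like", "mouse", "score", "seqimmucc_like",
        "elastic-net relative abundance scores on the bundled murine signature",
    ),
    "cls": MethodSpec(
        _run_cls, None, "mouse", "fraction", None,
        "constrained least squares with unknown content on a user signature",
        needs_user_resource=True,
    ),
    "nusvr": MethodSpec(
        _run_nusvr, None, "mouse", "fraction", None,
        "ν-SVR on a user signature", needs_user_resource=True,
    ),
    "elasticnet": MethodSpec(
        _run_elasticnet, None, "mouse", "score", None,
        "elastic-net scores on a user signature", needs_user_resource=True,
    ),
    "cls_human_sig": MethodSpec(
        _run_cls, "__human_stub__", "human", "fraction", "seqimmucc_like",
        "constrained least squares on a human-space signature "
        "(murine input converted via ortholog mapping)",
    ),
}


def list_methods() -> dict[str, str]:
    """Registered method names and one-line descriptions."""
    return {name: spec.description for name, spec in METHODS.items()}


def run_method(
    expr: ExpressionMatrix,
    method_name: str,
    resource=None,
    options=None,
    species: str = "mouse",
    ortholog_table=None,
    ontology: CellTypeOntology | None = None,
    harmonize_labels: bool = True,
) -> DeconvolutionResult:
    """Run a registered method with unified conversion and nomenclature.

    Parameters
    ----------
    resource
        A signature matrix or gene-set collection; defaults to the
        method's bundled resource where one exists.
    species
        Species of the *input* matrix.  When a human-signature method
        receives mouse input, the gene axis is converted through
        ``ortholog_table`` (default: the bundled table) first.
    ontology, harmonize_labels
        Output labels are passed through the (bundled by default)
        harmonization table unless ``harmonize_labels=False``.
    """
    if method_name not in METHODS:
        raise ConfigError(
            f"unknown method {method_name!r}; registered methods: "
            f"{sorted(METHODS)}"
        )
    spec = METHODS[method_name]
    if resource is None:
        if spec.needs_user_resource:
            raise ConfigError(
                f"method {method_name!r} requires a user-supplied signature/resource"
            )
        resource = (
            _human_signature_stub()
            if spec.default_resource == "__human_stub__"
            else get_resource(spec.default_resource)
        )

    conversion_report = None
    if spec.species == "human" and species == "mouse":
        table = ortholog_table or bundled_mouse_human_table()
        expr, conversion_report = convert_expression(expr, table)
        logger.info(
            "converted murine input to human gene space: %d/%d genes mapped",
            conversion_report.n_mapped, conversion_report.n_source_genes,
        )

    result = spec.runner(expr, resource, options)
    result.method_name = method_name
    if conversion_report is not None:
        result.metadata["ortholog_mapping"] = {
            "n_source_genes": conversion_report.n_source_genes,
            "n_mapped": conversion_report.n_mapped,
            "policies": conversion_report.policies,
        }

    if harmonize_labels:
        ontology = ontology or CellTypeOntology.bundled()
        result = harmonize(result, ontology, method=spec.harmonization_key)
    return result
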