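"""Mouse → human orthologous gene mapping for expression matrices.

Human-trained deconvolution signatures only apply to murine bulk
RNA-seq after the gene axis is translated into human symbol space.
This module performs that translation from an explicit two-column
mapping table, with configurable policies for ambiguous orthology:

* many murine genes → one human gene (``many_to_one``: ``sum`` [default],
  ``mean``, ``max``) — ``sum`` conserves total signal;
* one murine gene → many human genes (``one_to_many``: ``duplicate``,
  ``first`` [default: alphabetically smallest target, avoids double
  counting], ``drop``).

Conversion operates in linear space only (TPM or counts); summing
log-scale values is meaningless, so a log-unit input is rejected.

When no table is available, :func:`case_convention_fallback` builds one
from the standard murine/human symbol case convention (``Cd8a`` →
``CD8A``), which is correct for the large majority of one-to-one
protein-coding orthologs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .containers import ExpressionMatrix
from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

MANY_TO_ONE_POLICIES = ("sum", "mean", "max")
ONE_TO_MANY_POLICIES = ("duplicate", "first", "drop")

#: Below this mapped fraction a warning is logged (not fatal): usually a
#: wrong-species input or a table for the wrong identifier system.
LOW_MAPPING_WARN_FRACTION = 0.6


@dataclass
class GeneMappingTable:
    """Ordered (source_symbol, target_symbol) ortholog pairs."""

    pairs: list[tuple[str, str]]
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        deduped: list[tuple[str, str]] = []
        for src, tgt in self.pairs:
            if not src or not tgt or any(ch.isspace() for ch in src + tgt):
                raise ValidationError(
                    f"empty or whitespace-containing symbol in pair ({src!r}, {tgt!r})"
                )
            if (src, tgt) in seen:
                continue
            seen.add((src, tgt))
            deduped.append((src, tgt))
        n_dup = len(self.pairs) - len(deduped)
        if n_dup:
            logger.info("removed %d exact duplicate mapping pair(s)", n_dup)
        self.pairs = deduped

    def __len__(self) -> int:
        return len(self.pairs)

    def targets_of(self) -> dict[str, list[str]]:
        """source → sorted list of targets."""
        out: dict[str, list[str]] = {}
        for src, tgt in self.pairs:
            out.setdefault(src, []).append(tgt)
        return {src: sorted(set(tgts)) for src, tgts in out.items()}


@dataclass
class MappingReport:
    """Diagnostics of one expression-matrix conversion."""

    n_source_genes: int
    n_mapped: int
    n_dropped: int
    n_one_to_many: int
    n_many_to_one: int
    dropped_symbols: list[str] = field(default_factory=list)
    policies: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_mapped + self.n_dropped == self.n_source_genes


def load_mapping_table(path: str | Path) -> GeneMappingTable:
    """Load a two-column TSV with header ``source<TAB>target``."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2 or list(df.columns[:2]) != ["source", "target"]:
        raise FormatError(
            f"{path}: expected header 'source\\ttarget', got {list(df.columns)[:2]}"
        )
    if df.iloc[:, :2].isna().any().any():
        bad = df.index[df.iloc[:, :2].isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing field on data line {bad + 1}")
    pairs = list(zip(df["source"], df["target"]))
    return GeneMappingTable(pairs, provenance=str(path))


def bundled_mouse_human_table() -> GeneMappingTable:
    """The small curated mouse→human symbol table shipped with the package.

    Covers common immune/stromal-relevant genes; adequate for tests and
    demos, not a replacement for a full ortholog download.
    """
    ref = importlib_resources.files("murideconv.data") / "ortholog_mouse_human.tsv"
    with importlib_resources.as_file(ref) as p:
        table = load_mapping_table(p)
    table.provenance = "bundled immune/stromal ortholog table"
    return table


def case_convention_fallback(gene_ids: Sequence[str]) -> GeneMappingTable:
    """Map each murine symbol to its uppercase form (``Cd8a`` → ``CD8A``)."""
    pairs = [(g, g.upper()) for g in gene_ids]
    return GeneMappingTable(pairs, provenance="case-convention heuristic")


def convert_expression(
    expr: ExpressionMatrix,
    table: GeneMappingTable,
    many_to_one: str = "sum",
    one_to_many: str = "first",
) -> tuple[ExpressionMatrix, MappingReport]:
    """Translate the gene axis of ``expr`` through ``table``.

    Returns the converted matrix (target symbols in rows) and a
    :class:`MappingReport`.  Raises if no gene at all maps — that almost
    always means the wrong species or the wrong table.
    """
    if expr.unit not in ("TPM", "counts"):
        raise ValidationError(
            f"ortholog conversion requires linear-space input, got unit {expr.unit!r}"
        )
    if many_to_one not in MANY_TO_ONE_POLICIES:
        raise ValidationError(f"unknown many_to_one policy {many_to_one!r}")
    if one_to_many not in ONE_TO_MANY_POLICIES:
        raise ValidationError(f"unknown one_to_many policy {one_to_many!r}")

    targets_of = table.targets_of()
    source_genes = expr.gene_ids
    assignments: list[tuple[str, str]] = []  # (source present in expr, target)
    dropped: list[str] = []
    n_one_to_many = 0
    for g in source_genes:
        tgts = targets_of.get(g)
        if not tgts:
            dropped.append(g)
            continue
        if len(tgts) > 1:
            n_one_to_many += 1
            if one_to_many == "drop":
                dropped.append(g)
                continue
            if one_to_many == "first":
                tgts = tgts[:1]
        for t in tgts:
            assignments.append((g, t))

    if not assignments:
        raise ValidationError(
            "no gene of the input maps through the table — wrong species or wrong table?"
        )

    src_list = [s for s, _ in assignments]
    tgt_list = [t for _, t in assignments]
    contrib = expr.data.loc[src_list]
    contrib.index = pd.Index(tgt_list, name="gene")
    grouped = contrib.groupby(level=0, sort=True)
    out = getattr(grouped, many_to_one)()

    sources_per_target: dict[str, set[str]] = {}
    for s, t in assignments:
        sources_per_target.setdefault(t, set()).add(s)
    n_many_to_one = sum(1 for srcs in sources_per_target.values() if len(srcs) > 1)

    n_mapped = len(set(src_list))
    report = MappingReport(
        n_source_genes=len(source_genes),
        n_mapped=n_mapped,
        n_dropped=len(source_genes) - n_mapped,
        n_one_to_many=n_one_to_many,
        n_many_to_one=n_many_to_one,
        dropped_symbols=dropped,
        policies={"many_to_one": many_to_one, "one_to_many": one_to_many,
                  "table": table.provenance},
    )
    frac = n_mapped / max(len(source_genes), 1)
    if frac < LOW_MAPPING_WARN_FRACTION:
        logger.warning(
            "only %.0f%% of source genes mapped (%d/%d) — check species and table",
            100 * frac, n_mapped, len(source_genes),
        )
    return ExpressionMatrix(out, unit=expr.unit), report
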