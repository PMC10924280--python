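"""Common cell-type nomenclature and fine → major grouping.

Every engine names cell types in its own dialect; the ontology layer
first *harmonizes* raw labels onto a controlled vocabulary and can then
*group* fine-grained phenotypes into major cell types.

Aggregation semantics differ by estimate type: fractions are additive
mass, so a major type's fraction is the SUM of its members; scores are
on an arbitrary per-set scale, so the major score is the MEAN of its
members (summing would inflate types with many sub-phenotypes).  Both
modes can be forced via ``agg``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path

import pandas as pd

from .containers import UNKNOWN_LABEL, DeconvolutionResult
from .errors import ValidationError

logger = logging.getLogger(__name__)

UNASSIGNED_LABEL = "unassigned"


@dataclass
class CellTypeOntology:
    """Harmonization table, fine→major hierarchy and major-type roster."""

    harmonization: dict[tuple[str, str], str] = field(default_factory=dict)
    hierarchy: dict[str, str] = field(default_factory=dict)
    major_roster: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = sorted(set(self.hierarchy.values()) - set(self.major_roster))
        if bad:
            raise ValidationError(
                f"hierarchy maps to label(s) outside the major roster: {bad[:5]}"
            )

    @classmethod
    def bundled(cls) -> "CellTypeOntology":
        """The default ontology shipped with the package (19 major types)."""
        data = importlib_resources.files("murideconv.data")
        with importlib_resources.as_file(data / "harmonization.tsv") as p:
            harm_df = pd.read_csv(p, sep="\t")
        with importlib_resources.as_file(data / "hierarchy_fine_major.tsv") as p:
            hier_df = pd.read_csv(p, sep="\t")
        with importlib_resources.as_file(data / "major_roster.tsv") as p:
            roster_df = pd.read_csv(p, sep="\t")
        return cls.from_frames(harm_df, hier_df, roster_df["major"].tolist())

    @classmethod
    def from_frames(
        cls,
        harmonization: pd.DataFrame | None,
        hierarchy: pd.DataFrame | None,
        major_roster: list[str] | None = None,
    ) -> "CellTypeOntology":
        harm: dict[tuple[str, str], str] = {}
        if harmonization is not None:
            for _, row in harmonization.iterrows():
                harm[(str(row["method"]), str(row["raw"]))] = str(row["canonical"])
        hier: dict[str, str] = {}
        if hierarchy is not None:
            dup = hierarchy["fine"][hierarchy["fine"].duplicated()]
            if not dup.empty:
                raise ValidationError(
                    f"fine label(s) with multiple major parents: {dup.tolist()[:5]}"
                )
            hier = dict(zip(hierarchy["fine"].astype(str), hierarchy["major"].astype(str)))
        if major_roster is None:
            major_roster = sorted(set(hier.values()))
        return cls(harmonization=harm, hierarchy=hier, major_roster=list(major_roster))

    @classmethod
    def from_files(
        cls,
        harmonization_path: str | Path | None = None,
        hierarchy_path: str | Path | None = None,
    ) -> "CellTypeOntology":
        harm = (
            pd.read_csv(harmonization_path, sep="\t")
            if harmonization_path
            else None
        )
        hier = pd.read_csv(hierarchy_path, sep="\t") if hierarchy_path else None
        return cls.from_frames(harm, hier)


def harmonize(
    result: DeconvolutionResult,
    ontology: CellTypeOntology,
    method: str | None = None,
) -> DeconvolutionResult:
    """Replace raw engine labels by canonical vocabulary labels.

    Labels without a harmonization entry pass through unchanged (logged).
    Two raw labels of the same method mapping to one canonical label is
    an error — it would silently merge distinct estimates.  ``method``
    overrides the harmonization-table key (useful when several methods
    share one signature's label dialect).
    """
    method = method or result.method_name
    new_labels = []
    n_pass = 0
    for raw in result.cell_types:
        canon = ontology.harmonization.get((method, raw))
        if canon is None:
            n_pass += 1
            new_labels.append(raw)
        else:
            new_labels.append(canon)
    if n_pass:
        logger.info(
            "%d label(s) of method %r had no harmonization entry and pass through",
            n_pass, method,
        )
    dupes = pd.Index(new_labels)
    if dupes.has_duplicates:
        coll = dupes[dupes.duplicated()].unique().tolist()
        raise ValidationError(
            f"harmonization collision for method {method!r}: {coll}"
        )
    data = result.data.copy()
    data.index = new_labels
    return DeconvolutionResult(
        data,
        estimate_type=result.estimate_type,
        method_name=result.method_name,
        unknown_row=result.unknown_row,
        metadata={**result.metadata, "harmonized": True},
    )


def group_to_major(
    result: DeconvolutionResult,
    ontology: CellTypeOntology,
    agg: str | None = None,
) -> DeconvolutionResult:
    """Aggregate fine-grained cell types into major types.

    ``agg`` defaults to ``sum`` for fractions and ``mean`` for scores.
    Labels absent from the hierarchy are pooled into ``"unassigned"``
    with a warning; the unknown-content row, when present, is kept as is.
    """
    if agg is None:
        agg = "sum" if result.estimate_type == "fraction" else "mean"
    if agg not in ("sum", "mean"):
        raise ValidationError(f"unknown aggregation {agg!r}")
    mapped = []
    unmapped = []
    for ct in result.cell_types:
        if ct == UNKNOWN_LABEL and result.unknown_row:
            mapped.append(UNKNOWN_LABEL)
        elif ct in ontology.hierarchy:
            mapped.append(ontology.hierarchy[ct])
        else:
            mapped.append(UNASSIGNED_LABEL)
            unmapped.append(ct)
    if unmapped:
        logger.warning(
            "%d label(s) not in hierarchy pooled into %r: %s",
            len(unmapped), UNASSIGNED_LABEL, unmapped[:5],
        )
    grouped = getattr(
        result.data.groupby(pd.Index(mapped, name="cell_type"), sort=True), agg
    )()
    return DeconvolutionResult(
        grouped,
        estimate_type=result.estimate_type,
        method_name=result.method_name,
        unknown_row=result.unknown_row,
        metadata={**result.metadata, "grouped": agg},
    )
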