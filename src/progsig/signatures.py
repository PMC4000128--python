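"""Declarative multi-gene signature definitions and gene-level mapping.

A signature is data, not code: a JSON document naming its scoring
archetype, its genes with per-archetype parameters, a risk direction,
and population calibration proportions. Five archetypes cover the
published breast-cancer signatures:

``centroid_subtype``
    Nearest-centroid molecular subtyping (Intrinsic/PAM50-style) with a
    risk-of-relapse score formed as a linear combination of the per-class
    centroid correlations (ROR-S).
``centroid_risk``
    Correlation to a single reference centroid, oriented so higher =
    higher risk (70-gene / wound-response style).
``weighted_sum``
    Weighted average of gene expression, optionally with separate gene
    sets per patient stratum (76-gene style: separate ER+ and ER- genes).
``difference_of_means``
    Mean of an up-regulated set minus mean of a down-regulated set,
    rescaled to an invariant range (genomic-grade-index style).
``grouped_threshold``
    Reference-gene normalization, per-group means with optional clipping,
    then a weighted group sum plus intercept (unscaled Oncotype DX
    recurrence score / EndoPredict style).

Definitions are validated against ``schemas/signature.schema.json``
(shipped with the package) via the pydantic models below.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .matrix import ExpressionMatrix

Archetype = Literal[
    "centroid_subtype",
    "centroid_risk",
    "weighted_sum",
    "difference_of_means",
    "grouped_threshold",
]


class GeneEntry(BaseModel):
    """One gene's role in a signature."""

    model_config = ConfigDict(extra="forbid")

    gene_id: str
    weight: float = 1.0
    group: Optional[str] = None  # group label (grouped_threshold) or up/down set
    stratum: Optional[str] = None  # patient stratum this gene applies to
    is_reference: bool = False  # reference (normalization) gene


class GroupSpec(BaseModel):
    """Aggregation parameters for one gene group of a grouped_threshold scorer."""

    model_config = ConfigDict(extra="forbid")

    weight: float = 1.0
    clip_low: Optional[float] = None
    clip_high: Optional[float] = None


class CalibrationSpec(BaseModel):
    """Ordered risk-group labels with population proportions (low -> high risk)."""

    model_config = ConfigDict(extra="forbid")

    labels: list[str]
    proportions: list[float]

    @model_validator(mode="after")
    def _check(self) -> "CalibrationSpec":
        if len(self.labels) != len(self.proportions):
            raise ValueError("labels and proportions must have equal length")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {sum(self.proportions)}")
        if any(p < 0 for p in self.proportions):
            raise ValueError("proportions must be nonnegative")
        return self


class SignatureDefinition(BaseModel):
    """A complete, validated description of one prognostic signature."""

    model_config = ConfigDict(extra="forbid")

    name: str
    archetype: Archetype
    genes: list[GeneEntry] = Field(default_factory=list)
    class_order: list[str] = Field(default_factory=list)
    centroids: dict[str, dict[str, float]] = Field(default_factory=dict)
    ror_coefficients: dict[str, float] = Field(default_factory=dict)
    reference_class: Optional[str] = None
    groups: dict[str, GroupSpec] = Field(default_factory=dict)
    intercept: float = 0.0
    risk_direction: Literal[1, -1] = 1
    subtype_correlation: Literal["spearman", "pearson"] = "spearman"
    ror_correlation: Literal["pearson", "spearman"] = "pearson"
    calibration: dict[str, CalibrationSpec] = Field(default_factory=dict)
    provenance: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "SignatureDefinition":
        seen: set[tuple[str, Optional[str]]] = set()
        for g in self.genes:
            key = (g.gene_id, g.stratum)
            if key in seen:
                raise ValueError(f"{self.name}: duplicate gene entry {key}")
            seen.add(key)
        if self.archetype in ("centroid_subtype", "centroid_risk"):
            if not self.centroids:
                raise ValueError(f"{self.name}: centroid archetype requires centroids")
            if not self.class_order:
                self.class_order = list(self.centroids)
            if set(self.class_order) != set(self.centroids):
                raise ValueError(f"{self.name}: class_order must match centroid classes")
            gene_sets = {frozenset(c) for c in self.centroids.values()}
            if len(gene_sets) != 1:
                raise ValueError(f"{self.name}: all centroids must cover the same genes")
        if self.archetype == "centroid_subtype":
            if set(self.ror_coefficients) != set(self.centroids):
                raise ValueError(
                    f"{self.name}: ror_coefficients must name every centroid class"
                )
        if self.archetype == "centroid_risk":
            if self.reference_class is None or self.reference_class not in self.centroids:
                raise ValueError(f"{self.name}: reference_class must name a centroid")
        if self.archetype == "weighted_sum" and not self.genes:
            raise ValueError(f"{self.name}: weighted_sum requires gene entries")
        if self.archetype == "difference_of_means":
            labels = {g.group for g in self.genes}
            if not {"up", "down"} <= labels:
                raise ValueError(
                    f"{self.name}: difference_of_means needs genes in groups 'up' and 'down'"
                )
        if self.archetype == "grouped_threshold":
            if not self.groups:
                raise ValueError(f"{self.name}: grouped_threshold requires group specs")
            member_groups = {g.group for g in self.genes if not g.is_reference}
            missing = member_groups - set(self.groups) - {None}
            if missing:
                raise ValueError(f"{self.name}: genes reference undeclared groups {missing}")
        return self

    @property
    def gene_ids(self) -> list[str]:
        """All distinct gene ids the signature needs, in declaration order."""
        ids: list[str] = []
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id not in seen:
                ids.append(g.gene_id)
                seen.add(g.gene_id)
        for cls in self.class_order or list(self.centroids):
            for gid in self.centroids.get(cls, {}):
                if gid not in seen:
                    ids.append(gid)
                    seen.add(gid)
        return ids

    @property
    def stratified(self) -> bool:
        return any(g.stratum is not None for g in self.genes)


class MappedSignature(BaseModel):
    """Result of intersecting a signature's genes with an expression matrix."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    definition: SignatureDefinition
    matched: list[str]
    unmatched: list[str]

    @property
    def name(self) -> str:
        return self.definition.name

    @property
    def coverage_fraction(self) -> float:
        total = len(self.matched) + len(self.unmatched)
        return len(self.matched) / total if total else 0.0


class LowCoverageError(ValueError):
    """Too few of a signature's genes are present in the expression matrix."""

    def __init__(self, name: str, coverage: float, threshold: float, unmatched: list[str]):
        self.signature = name
        self.coverage = coverage
        self.unmatched = unmatched
        super().__init__(
            f"signature {name!r}: coverage {coverage:.1%} below minimum "
            f"{threshold:.0%}; unmatched genes: {unmatched[:10]}"
            + ("..." if len(unmatched) > 10 else "")
        )


def map_signature(
    sig: SignatureDefinition,
    expr: ExpressionMatrix,
    *,
    min_coverage: float = 0.5,
    warn_coverage: float = 0.8,
) -> MappedSignature:
    """Intersect a signature's gene list with the matrix's genes.

    Raises :class:`LowCoverageError` when fewer than ``min_coverage`` of
    the signature's genes are present; warns between ``min_coverage``
    and ``warn_coverage``. Published signatures routinely lose a third
    or more of their genes when mapped across array platforms, so scoring
    proceeds on the intersection above the floor.
    """
    present = set(expr.values.index)
    matched = [g for g in sig.gene_ids if g in present]
    unmatched = [g for g in sig.gene_ids if g not in present]
    mapped = MappedSignature(definition=sig, matched=matched, unmatched=unmatched)
    cov = mapped.coverage_fraction
    if cov < min_coverage:
        raise LowCoverageError(sig.name, cov, min_coverage, unmatched)
    if cov < warn_coverage:
        warnings.warn(
            f"signature {sig.name!r}: coverage {cov:.1%} below {warn_coverage:.0%}",
            stacklevel=2,
        )
    return mapped


def load_signature(path: str | Path) -> SignatureDefinition:
    """Load and validate one signature definition from a JSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    return SignatureDefinition.model_validate(doc)


def save_signature(sig: SignatureDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(sig.model_dump(exclude_none=True), fh, indent=1)


def load_signature_dir(directory: str | Path) -> list[SignatureDefinition]:
    """Load every ``*.json`` signature definition in a directory (sorted by name)."""
    paths = sorted(Path(directory).glob("*.json"))
    if not paths:
        raise FileNotFoundError(f"no signature definitions (*.json) in {directory}")
    return [load_signature(p) for p in paths]


def signature_schema() -> dict:
    """Return the JSON schema signature documents are validated against."""
    schema_path = Path(__file__).parent / "schemas" / "signature.schema.json"
    with open(schema_path) as fh:
        return json.load(fh)


def coverage_table(mapped: list[MappedSignature]) -> pd.DataFrame:
    """Summarize mapping coverage, one row per signature."""
    rows = [
        {
            "signature": m.name,
            "n_matched": len(m.matched),
            "n_total": len(m.matched) + len(m.unmatched),
            "coverage": m.coverage_fraction,
        }
        for m in mapped
    ]
    return pd.DataFrame(rows).set_index("signature")
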