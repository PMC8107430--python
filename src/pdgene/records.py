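"""Domain records for the five curated evidence layers.

Every observation extracted from the literature is one record attributed to
a gene and a study: a rare variant carried by a patient, a gene-level copy
number variant (CNV), or a gene-level association from a GWAS,
differential-expression (DEG) or differential-methylation (DMG) study.
Gene symbols are opaque, case-sensitive strings; no alias resolution is
attempted. Coordinates are 1-based inclusive. Missing optional values are
``None``, never zero.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Union


class Layer(str, enum.Enum):
    """The five evidence layers."""

    RARE_VARIANT = "rare_variant"
    CNV = "cnv"
    GWAS_SNP = "gwas_snp"
    DEG = "deg"
    DMG = "dmg"


#: Association layers share one record type.
ASSOCIATION_LAYERS = frozenset({Layer.GWAS_SNP, Layer.DEG, Layer.DMG})


class Consequence(str, enum.Enum):
    FRAMESHIFT_INDEL = "frameshift_indel"
    SPLICING = "splicing"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    MISSENSE = "missense"
    OTHER = "other"


#: Consequences counted as loss of function.
LOF_CONSEQUENCES = frozenset(
    {
        Consequence.FRAMESHIFT_INDEL,
        Consequence.SPLICING,
        Consequence.STOP_GAIN,
        Consequence.STOP_LOSS,
    }
)


class CNVType(str, enum.Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"
    UNKNOWN = "unknown"


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    NA = "na"


class ValidationError(ValueError):
    """A record violates a field invariant.

    Carries the offending row/column when raised by the TSV readers so the
    curator can locate the bad cell.
    """

    def __init__(self, message: str, row: Optional[int] = None, column: Optional[str] = None):
        loc = ""
        if row is not None:
            loc += f" (row {row}"
            if column is not None:
                loc += f", column {column!r}"
            loc += ")"
        super().__init__(message + loc)
        self.row = row
        self.column = column


def _check(cond: bool, message: str) -> None:
    if not cond:
        raise ValidationError(message)


def _finite(x: Optional[float]) -> bool:
    return x is None or math.isfinite(x)


@dataclass(frozen=True)
class VariantRecord:
    """One rare-variant observation in one patient from one study.

    ``maf`` is the minor allele frequency in a population reference (gnomAD
    in the source data); ``patho_score`` is a missense pathogenicity score
    in [0, 1] (ReVe-like); ``aao`` is the carrier's age at onset in years.
    All three may be absent.
    """

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    maf: Optional[float] = None
    patho_score: Optional[float] = None
    study_id: str = ""
    patient_id: Optional[str] = None
    aao: Optional[float] = None

    def __post_init__(self) -> None:
        _check(bool(self.gene), "gene must be non-empty")
        _check(self.pos >= 1, f"pos must be >= 1, got {self.pos}")
        _check(_finite(self.maf), "maf must be finite")
        _check(_finite(self.patho_score), "patho_score must be finite")
        _check(_finite(self.aao), "aao must be finite")
        if self.maf is not None:
            _check(0.0 <= self.maf <= 1.0, f"maf must be in [0,1], got {self.maf}")
        if self.patho_score is not None:
            _check(
                0.0 <= self.patho_score <= 1.0,
                f"patho_score must be in [0,1], got {self.patho_score}",
            )
        if self.aao is not None:
            _check(self.aao > 0, f"aao must be > 0, got {self.aao}")

    @property
    def layer(self) -> Layer:
        return Layer.RARE_VARIANT


@dataclass(frozen=True)
class CNVRecord:
    """One gene-level copy-number variant from one study."""

    gene: str
    cnv_type: CNVType = CNVType.UNKNOWN
    study_id: str = ""

    def __post_init__(self) -> None:
        _check(bool(self.gene), "gene must be non-empty")

    @property
    def layer(self) -> Layer:
        return Layer.CNV


@dataclass(frozen=True)
class AssociationRecord:
    """A gene-level association (GWAS SNP, DEG or DMG) with its p-value."""

    gene: str
    layer_tag: Layer
    p_value: float
    marker_id: Optional[str] = None
    direction: Direction = Direction.NA
    study_id: str = ""

    def __post_init__(self) -> None:
        _check(bool(self.gene), "gene must be non-empty")
        _check(self.layer_tag in ASSOCIATION_LAYERS, f"layer must be one of {sorted(l.value for l in ASSOCIATION_LAYERS)}, got {self.layer_tag}")
        _check(
            math.isfinite(self.p_value) and 0.0 < self.p_value <= 1.0,
            f"p_value must be in (0,1], got {self.p_value}",
        )

    @property
    def layer(self) -> Layer:
        return self.layer_tag


#: Any record from any layer; the layer tag is recoverable via ``.layer``.
EvidenceRecord = Union[VariantRecord, CNVRecord, AssociationRecord]
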