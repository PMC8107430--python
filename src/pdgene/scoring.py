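"""Per-record evidence scores, per-gene combination, and five-grade mapping.

Each evidence record earns a score: rare variants 1–5 by functional class,
CNVs a fixed 5 (they disrupt gene function outright), and association
records (GWAS SNP / DEG / DMG) 0–3 by p-value bin. A gene's combined score
sums contributions over its integrated studies and maps onto five grades:

======================  =================
grade                   combined score
======================  =================
high confidence         >= 20
strong associated       [10, 20)
suggestive associated   [5, 10)
minimal evidence        [3, 5)
uncertain evidence      [0, 3)
======================  =================

Under the default aggregation each (gene, study, layer) triple contributes
once — its best record score — so one study listing many carriers of the
same gene cannot dominate the sum; the plain sum over all records is
available as a mode.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .classify import ClassificationConfig, VariantClass, classify_variant
from .records import (
    AssociationRecord,
    CNVRecord,
    EvidenceRecord,
    Layer,
    VariantRecord,
)


class Grade(str, enum.Enum):
    HIGH = "high"
    STRONG = "strong"
    SUGGESTIVE = "suggestive"
    MINIMAL = "minimal"
    UNCERTAIN = "uncertain"


#: Lower bound of each grade interval (half-open above, closed below).
GRADE_CUTS: List[Tuple[float, Grade]] = [
    (20.0, Grade.HIGH),
    (10.0, Grade.STRONG),
    (5.0, Grade.SUGGESTIVE),
    (3.0, Grade.MINIMAL),
    (0.0, Grade.UNCERTAIN),
]


class StudyAggregation(str, enum.Enum):
    """How records collapse into per-(gene, study, layer) contributions."""

    MAX_PER_STUDY_LAYER = "max_per_study_layer"
    SUM_ALL_RECORDS = "sum_all_records"


_DEFAULT_VARIANT_SCORES: Dict[VariantClass, float] = {
    VariantClass.RARE_LOF: 5.0,
    VariantClass.RARE_DMIS: 4.0,
    VariantClass.RARE_TMIS: 2.0,
    VariantClass.OTHER: 1.0,
}

#: (p-value ceiling, score), most stringent first.
_DEFAULT_PVALUE_BINS: Tuple[Tuple[float, float], ...] = (
    (5e-8, 3.0),
    (1e-5, 2.0),
    (0.05, 1.0),
)


@dataclass(frozen=True)
class ScoreMap:
    """Configurable score assignments per evidence layer.

    The defaults are this package's declared values within the published
    1–5 (rare variant), 5 (CNV) and 1–3 (association) ranges; every entry
    is overridable.
    """

    rare_variant_scores: Mapping[VariantClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_VARIANT_SCORES)
    )
    cnv_score: float = 5.0
    pvalue_bins: Tuple[Tuple[float, float], ...] = _DEFAULT_PVALUE_BINS
    study_aggregation: StudyAggregation = StudyAggregation.MAX_PER_STUDY_LAYER

    def __post_init__(self) -> None:
        for cls, s in self.rare_variant_scores.items():
            if not 1.0 <= s <= 5.0:
                raise ValueError(f"rare variant score for {cls} must be in [1,5], got {s}")
        thresholds = [t for t, _ in self.pvalue_bins]
        if thresholds != sorted(thresholds):
            raise ValueError("pvalue_bins must be ordered most stringent first")
        for _, s in self.pvalue_bins:
            if s not in (0.0, 1.0, 2.0, 3.0):
                raise ValueError(f"p-value bin scores must be in {{0,1,2,3}}, got {s}")

    def pvalue_score(self, p: float) -> float:
        for ceiling, score in self.pvalue_bins:
            if p <= ceiling:
                return score
        return 0.0


@dataclass(frozen=True)
class GeneScoreCard:
    """One gene's layer subtotals, combined score and grade."""

    gene: str
    layer_subtotals: Mapping[Layer, float]
    combined_score: float
    grade: Grade


def score_record(
    record: EvidenceRecord,
    variant_class: Optional[VariantClass] = None,
    score_map: ScoreMap = ScoreMap(),
) -> float:
    """Score a single evidence record.

    ``variant_class`` is required for rare-variant records (obtain it from
    :func:`pdgene.classify.classify_variant`) and must be absent otherwise.
    """
    if isinstance(record, VariantRecord):
        if variant_class is None:
            raise ValueError("rare-variant records require a variant_class")
        return float(score_map.rare_variant_scores[variant_class])
    if variant_class is not None:
        raise ValueError("variant_class only applies to rare-variant records")
    if isinstance(record, CNVRecord):
        return float(score_map.cnv_score)
    if isinstance(record, AssociationRecord):
        return score_map.pvalue_score(record.p_value)
    raise TypeError(f"not an evidence record: {type(record).__name__}")


def combine_gene_scores(
    scored: Sequence[Tuple[EvidenceRecord, float]],
    score_map: ScoreMap = ScoreMap(),
) -> List[GeneScoreCard]:
    """Combine scored records into per-gene scorecards, sorted by gene symbol.

    Under ``MAX_PER_STUDY_LAYER`` each (gene, study, layer) triple
    contributes its maximum record score once; under ``SUM_ALL_RECORDS``
    every record contributes.
    """
    contributions: Dict[str, Dict[Layer, float]] = {}
    if score_map.study_aggregation is StudyAggregation.MAX_PER_STUDY_LAYER:
        best: Dict[Tuple[str, str, Layer], float] = {}
        for record, score in scored:
            key = (record.gene, record.study_id, record.layer)
            best[key] = max(best.get(key, float("-inf")), score)
        for (gene, _study, layer), score in best.items():
            layer_map = contributions.setdefault(gene, {})
            layer_map[layer] = layer_map.get(layer, 0.0) + score
    else:
        for record, score in scored:
            layer_map = contributions.setdefault(record.gene, {})
            layer_map[record.layer] = layer_map.get(record.layer, 0.0) + score

    cards = []
    for gene in sorted(contributions):
        subtotals = {layer: contributions[gene].get(layer, 0.0) for layer in Layer}
        combined = sum(subtotals.values())
        cards.append(
            GeneScoreCard(
                gene=gene,
                layer_subtotals=subtotals,
                combined_score=combined,
                grade=assign_grade(combined),
            )
        )
    return cards


def assign_grade(combined_score: float) -> Grade:
    """Map a combined score onto the five-grade scale.

    Intervals are half-open below 20 so a score of exactly 20 is HIGH,
    exactly 5 is SUGGESTIVE, and anything below 3 is UNCERTAIN.
    """
    if combined_score < 0:
        raise ValueError(f"combined score must be >= 0, got {combined_score}")
    for cut, grade in GRADE_CUTS:
        if combined_score >= cut:
            return grade
    return Grade.UNCERTAIN  # pragma: no cover — 0.0 cut is exhaustive


def score_evidence(
    records: Sequence[EvidenceRecord],
    classification: ClassificationConfig = ClassificationConfig(),
    score_map: ScoreMap = ScoreMap(),
) -> List[GeneScoreCard]:
    """Classify, score and combine a mixed-layer evidence collection."""
    scored = []
    for record in records:
        cls = classify_variant(record, classification) if isinstance(record, VariantRecord) else None
        scored.append((record, score_record(record, cls, score_map)))
    return combine_gene_scores(scored, score_map)


def grade_counts(cards: Sequence[GeneScoreCard]) -> Dict[Grade, int]:
    counts = {g: 0 for g in Grade}
    for card in cards:
        counts[card.grade] += 1
    return counts


def write_scorecards(cards: Sequence[GeneScoreCard], path: Union[str, Path]) -> None:
    """Write the scorecard TSV: gene, five layer subtotals, combined score, grade."""
    with open(path, "w", encoding="utf-8") as fh:
        header = ["gene"] + [layer.value for layer in Layer] + ["combined_score", "grade"]
        fh.write("\t".join(header) + "\n")
        for card in cards:
            row = [card.gene]
            row += [repr(card.layer_subtotals[layer]) for layer in Layer]
            row += [repr(card.combined_score), card.grade.value]
            fh.write("\t".join(row) + "\n")


def read_scorecards(path: Union[str, Path]) -> List[GeneScoreCard]:
    """Read a scorecard TSV written by :func:`write_scorecards`."""
    cards = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            cells = dict(zip(header, line.rstrip("\n").split("\t")))
            subtotals = {layer: float(cells[layer.value]) for layer in Layer}
            cards.append(
                GeneScoreCard(
                    gene=cells["gene"],
                    layer_subtotals=subtotals,
                    combined_score=float(cells["combined_score"]),
                    grade=Grade(cells["grade"]),
                )
            )
    return cards
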