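"""Functional classification of rare variants.

Each variant falls into exactly one of four classes from its consequence,
minor allele frequency (MAF) and missense pathogenicity score:

* ``RARE_LOF`` — loss-of-function consequence (frameshift indel, splicing,
  stop-gain, stop-loss) with MAF strictly below the rarity threshold;
* ``RARE_DMIS`` — rare missense with pathogenicity score strictly above the
  deleteriousness threshold;
* ``RARE_TMIS`` — rare missense at or below that threshold (tolerated);
* ``OTHER`` — everything else (common variants, synonymous, etc.).

Default thresholds: MAF < 0.01 defines rare; score > 0.7 defines
deleterious. Both inequalities are strict.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .records import LOF_CONSEQUENCES, Consequence, VariantRecord

logger = logging.getLogger(__name__)


class VariantClass(str, enum.Enum):
    RARE_LOF = "rare_lof"
    RARE_DMIS = "rare_dmis"
    RARE_TMIS = "rare_tmis"
    OTHER = "other"


class MissingScorePolicy(str, enum.Enum):
    """Where a rare missense variant lands when its pathogenicity score is absent."""

    TMIS = "tmis"
    OTHER = "other"


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds and missing-data policy for variant classification.

    Attributes
    ----------
    maf_threshold
        Variants with MAF strictly below this are rare (default 0.01).
    dmis_threshold
        Missense variants with pathogenicity score strictly above this are
        deleterious (default 0.7).
    missing_maf_is_rare
        Treat absent MAF as rare; absence from population databases is
        conventionally read as rarity (default True).
    missing_score_class
        Class for a rare missense with no pathogenicity score
        (default TMIS, with a logged warning).
    """

    maf_threshold: float = 0.01
    dmis_threshold: float = 0.7
    missing_maf_is_rare: bool = True
    missing_score_class: MissingScorePolicy = MissingScorePolicy.TMIS

    def __post_init__(self) -> None:
        if not 0.0 < self.maf_threshold < 1.0:
            raise ValueError(f"maf_threshold must be in (0,1), got {self.maf_threshold}")
        if not 0.0 <= self.dmis_threshold <= 1.0:
            raise ValueError(f"dmis_threshold must be in [0,1], got {self.dmis_threshold}")


def classify_variant(
    v: VariantRecord, cfg: ClassificationConfig = ClassificationConfig()
) -> VariantClass:
    """Assign the variant to exactly one of the four functional classes."""
    if v.maf is None:
        rare = cfg.missing_maf_is_rare
    else:
        rare = v.maf < cfg.maf_threshold
    if not rare:
        return VariantClass.OTHER
    if v.consequence in LOF_CONSEQUENCES:
        return VariantClass.RARE_LOF
    if v.consequence is Consequence.MISSENSE:
        if v.patho_score is None:
            logger.warning(
                "rare missense %s:%s %s>%s in %s has no pathogenicity score; "
                "classifying as %s",
                v.chrom, v.pos, v.ref, v.alt, v.gene,
                cfg.missing_score_class.value,
            )
            return (
                VariantClass.RARE_TMIS
                if cfg.missing_score_class is MissingScorePolicy.TMIS
                else VariantClass.OTHER
            )
        if v.patho_score > cfg.dmis_threshold:
            return VariantClass.RARE_DMIS
        return VariantClass.RARE_TMIS
    return VariantClass.OTHER


def classify_table(
    records: Sequence[VariantRecord],
    cfg: ClassificationConfig = ClassificationConfig(),
) -> Tuple[Dict[VariantClass, int], List[VariantClass]]:
    """Classify every variant; return per-class counts and row-aligned labels.

    The four counts always sum to ``len(records)``.
    """
    labels = [classify_variant(v, cfg) for v in records]
    counts = Counter(labels)
    return {c: counts.get(c, 0) for c in VariantClass}, labels
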