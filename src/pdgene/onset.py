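"""Gene-level age-at-onset (AAO) aggregation and genotype–onset comparison.

Genes with enough curated onset ages (more than five by default) are
summarized by their median AAO and binned: juvenile onset (median <= 30
years), early onset (30–50 years), late onset (> 50 years). Within a gene,
onset ages of loss-of-function (LoF) carriers are compared with those of
deleterious-missense (Dmis) carriers by a two-sided Mann–Whitney rank-sum
test — exact enumeration at small sample sizes, normal approximation with
tie correction otherwise — when both groups have more than three values.
Raw p-values are reported per gene; a Benjamini–Hochberg column is emitted
alongside for transparency.
"""

from __future__ import annotations

import enum
import logging
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .classify import ClassificationConfig, VariantClass, classify_variant
from .records import VariantRecord

logger = logging.getLogger(__name__)


class OnsetBin(str, enum.Enum):
    JUVENILE = "juvenile"
    EARLY = "early"
    LATE = "late"


class RankTest(str, enum.Enum):
    """Mann–Whitney variant: exact enumeration or normal approximation."""

    MANN_WHITNEY_EXACT = "mann_whitney_exact"
    MANN_WHITNEY_NORMAL = "mann_whitney_normal"
    AUTO = "auto"  # exact when both groups <= 25 and no ties


@dataclass(frozen=True)
class AAOConfig:
    """Inclusion thresholds, onset bin edges and test choice.

    ``min_gene_n = 6`` implements "more than five" onset values per gene;
    ``min_group_n = 4`` implements "more than three" per variant class.
    """

    min_gene_n: int = 6
    min_group_n: int = 4
    juvenile_max: float = 30.0
    early_max: float = 50.0
    test: RankTest = RankTest.AUTO
    exact_max_n: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.juvenile_max < self.early_max:
            raise ValueError("need 0 < juvenile_max < early_max")
        if self.min_gene_n < 1 or self.min_group_n < 1:
            raise ValueError("minimum counts must be >= 1")


@dataclass(frozen=True)
class GeneOnsetSummary:
    gene: str
    n: int
    median_aao: float
    bin: OnsetBin


class Direction(str, enum.Enum):
    LOF_EARLIER = "lof_earlier"
    LOF_LATER = "lof_later"
    NONE = "none"


@dataclass(frozen=True)
class OnsetComparison:
    gene: str
    n_lof: int
    n_dmis: int
    median_lof: float
    median_dmis: float
    p_value: float
    direction: Direction


def classify_onset(median: float, cfg: AAOConfig = AAOConfig()) -> OnsetBin:
    """Bin a median onset age: <= 30 juvenile, (30, 50] early, > 50 late."""
    if median <= 0:
        raise ValueError(f"median AAO must be positive, got {median}")
    if median <= cfg.juvenile_max:
        return OnsetBin.JUVENILE
    if median <= cfg.early_max:
        return OnsetBin.EARLY
    return OnsetBin.LATE


def summarize_gene(
    gene: str, aao_values: Sequence[float], cfg: AAOConfig = AAOConfig()
) -> Optional[GeneOnsetSummary]:
    """Median onset and bin for one gene, or ``None`` below the inclusion cutoff.

    The median of an even count is the midpoint of the two central order
    statistics. Non-positive onset ages are rejected.
    """
    bad = [a for a in aao_values if a <= 0]
    if bad:
        raise ValueError(f"{gene}: non-positive AAO value(s) {bad}")
    n = len(aao_values)
    if n < cfg.min_gene_n:
        logger.info("%s excluded: %d AAO value(s) < required %d", gene, n, cfg.min_gene_n)
        return None
    med = statistics.median(aao_values)
    return GeneOnsetSummary(gene=gene, n=n, median_aao=med, bin=classify_onset(med, cfg))


def mannwhitney_pvalue(
    x: Sequence[float], y: Sequence[float], test: RankTest = RankTest.AUTO,
    exact_max_n: int = 25,
) -> float:
    """Two-sided Mann–Whitney rank-sum p-value.

    ``AUTO`` uses exact enumeration when both groups have at most
    ``exact_max_n`` values and there are no ties, otherwise the normal
    approximation with tie correction and continuity correction.
    """
    if test is RankTest.AUTO:
        small = len(x) <= exact_max_n and len(y) <= exact_max_n
        no_ties = len(set(x) | set(y)) == len(x) + len(y)
        test = RankTest.MANN_WHITNEY_EXACT if small and no_ties else RankTest.MANN_WHITNEY_NORMAL
    method = "exact" if test is RankTest.MANN_WHITNEY_EXACT else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def compare_lof_dmis(
    gene: str,
    lof_aaos: Sequence[float],
    dmis_aaos: Sequence[float],
    cfg: AAOConfig = AAOConfig(),
) -> Optional[OnsetComparison]:
    """Compare LoF against Dmis onset ages within one gene.

    Returns ``None`` when either group is below ``min_group_n``. Direction
    is read from the group medians.
    """
    for name, vals in (("LoF", lof_aaos), ("Dmis", dmis_aaos)):
        bad = [a for a in vals if a <= 0]
        if bad:
            raise ValueError(f"{gene}: non-positive {name} AAO value(s) {bad}")
    if len(lof_aaos) < cfg.min_group_n or len(dmis_aaos) < cfg.min_group_n:
        logger.info(
            "%s excluded from LoF/Dmis comparison: n_lof=%d, n_dmis=%d, need %d each",
            gene, len(lof_aaos), len(dmis_aaos), cfg.min_group_n,
        )
        return None
    med_lof = statistics.median(lof_aaos)
    med_dmis = statistics.median(dmis_aaos)
    p = mannwhitney_pvalue(lof_aaos, dmis_aaos, cfg.test, cfg.exact_max_n)
    if med_lof < med_dmis:
        direction = Direction.LOF_EARLIER
    elif med_lof > med_dmis:
        direction = Direction.LOF_LATER
    else:
        direction = Direction.NONE
    return OnsetComparison(
        gene=gene, n_lof=len(lof_aaos), n_dmis=len(dmis_aaos),
        median_lof=med_lof, median_dmis=med_dmis, p_value=p, direction=direction,
    )


def collect_gene_aaos(
    variants: Iterable[VariantRecord],
    classification: ClassificationConfig = ClassificationConfig(),
) -> Tuple[Dict[str, List[float]], Dict[str, Dict[VariantClass, List[float]]]]:
    """Group onset ages by gene and by (gene, variant class).

    Records without an onset age are skipped. A patient carrying both a LoF
    and a Dmis variant of the same gene is ambiguous for the class-wise
    comparison and is excluded from it (logged), though their onset still
    counts toward the gene-level aggregate once per variant record.
    """
    per_gene: Dict[str, List[float]] = {}
    per_class: Dict[str, Dict[VariantClass, List[float]]] = {}
    carrier_classes: Dict[Tuple[str, str], set] = {}
    with_patient: List[Tuple[VariantRecord, VariantClass]] = []
    for v in variants:
        if v.aao is None:
            continue
        per_gene.setdefault(v.gene, []).append(v.aao)
        cls = classify_variant(v, classification)
        if v.patient_id is not None:
            carrier_classes.setdefault((v.gene, v.patient_id), set()).add(cls)
            with_patient.append((v, cls))
        else:
            per_class.setdefault(v.gene, {}).setdefault(cls, []).append(v.aao)
    ambiguous = {
        key for key, classes in carrier_classes.items()
        if {VariantClass.RARE_LOF, VariantClass.RARE_DMIS} <= classes
    }
    for gene, patient in sorted(ambiguous):
        logger.info(
            "%s: patient %s carries both LoF and Dmis; excluded from class comparison",
            gene, patient,
        )
    for v, cls in with_patient:
        if (v.gene, v.patient_id) not in ambiguous:
            per_class.setdefault(v.gene, {}).setdefault(cls, []).append(v.aao)
    return per_gene, per_class


def analyze_onsets(
    variants: Iterable[VariantRecord],
    cfg: AAOConfig = AAOConfig(),
    classification: ClassificationConfig = ClassificationConfig(),
) -> Tuple[List[GeneOnsetSummary], List[OnsetComparison], List[float]]:
    """Run both onset analyses over a variant collection.

    Returns the included gene summaries (sorted by median onset), the
    LoF-vs-Dmis comparisons (sorted by gene), and the Benjamini–Hochberg
    adjusted p-values aligned with the comparisons.
    """
    per_gene, per_class = collect_gene_aaos(variants, classification)
    summaries = []
    for gene in sorted(per_gene):
        s = summarize_gene(gene, per_gene[gene], cfg)
        if s is not None:
            summaries.append(s)
    summaries.sort(key=lambda s: (s.median_aao, s.gene))

    comparisons = []
    for gene in sorted(per_class):
        lof = per_class[gene].get(VariantClass.RARE_LOF, [])
        dmis = per_class[gene].get(VariantClass.RARE_DMIS, [])
        c = compare_lof_dmis(gene, lof, dmis, cfg)
        if c is not None:
            comparisons.append(c)
    if comparisons:
        adjusted = list(
            multipletests([c.p_value for c in comparisons], method="fdr_bh")[1]
        )
    else:
        adjusted = []
    return summaries, comparisons, adjusted


def write_onset_tables(
    summaries: Sequence[GeneOnsetSummary],
    comparisons: Sequence[OnsetComparison],
    adjusted: Sequence[float],
    summary_path: Union[str, Path],
    comparison_path: Union[str, Path],
) -> None:
    """Write the gene onset-summary TSV and the LoF/Dmis comparison TSV."""
    with open(summary_path, "w", encoding="utf-8") as fh:
        fh.write("gene\tn\tmedian_aao\tonset_bin\n")
        for s in summaries:
            fh.write(f"{s.gene}\t{s.n}\t{s.median_aao!r}\t{s.bin.value}\n")
    with open(comparison_path, "w", encoding="utf-8") as fh:
        fh.write(
            "gene\tn_lof\tn_dmis\tmedian_lof\tmedian_dmis\tp_value\tp_bh\tdirection\n"
        )
        for c, q in zip(comparisons, adjusted):
            fh.write(
                f"{c.gene}\t{c.n_lof}\t{c.n_dmis}\t{c.median_lof!r}\t"
                f"{c.median_dmis!r}\t{c.p_value!r}\t{q!r}\t{c.direction.value}\n"
            )
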