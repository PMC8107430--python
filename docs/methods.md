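# Methods

## Evidence model

A curated observation is one record in one of five layers: rare variant,
CNV, GWAS SNP, DEG, DMG. Records carry the gene symbol (an opaque,
case-sensitive string — no alias resolution), the study identifier, and
layer-specific fields. Variant coordinates are 1-based inclusive. Missing
optional values are represented as `None` in memory and as empty cells in
the TSV dialects (`NA` accepted on input); missing is never conflated with
zero. Validation is total: every malformed cell raises an error naming its
data row and column, and no row is ever silently dropped. A CNV spanning
several genes must be supplied pre-split, one gene per row; the package
does not attribute multi-gene events.

## Variant classification

Classification is a total function of (consequence, MAF, pathogenicity
score) with strict inequalities: rare means MAF < 0.01, deleterious
missense means score > 0.7, so a variant at exactly MAF = 0.01 is not
rare and a score of exactly 0.7 is tolerated. Two curation realities need
a policy:

* **Missing MAF** defaults to rare (absence from population reference
  databases is conventionally read as rarity); configurable.
* **Missing pathogenicity score** on a rare missense defaults to Tmis with
  a logged warning (the conservative reading — no claim of
  deleteriousness without a score); configurable to "other".

Both thresholds are parameters of `ClassificationConfig`.

## Scoring and grading

Per-record scores sit inside fixed ranges: rare variants 1–5, CNV exactly
5, associations 0–3 by p-value bin. The specific values inside those
ranges (LoF 5, Dmis 4, Tmis 2, other 1; bins 5×10⁻⁸ → 3, 10⁻⁵ → 2,
0.05 → 1, else 0) are this package's declared defaults, exposed in
`ScoreMap` and overridable; an association with p > 0.05 contributes
nothing.

Combination is per (gene, study, layer): each such triple contributes its
single best record score, and triples are summed. This stops one study
that lists thirty carriers of the same gene from outscoring thirty
independent studies; the literal sum over all records is kept as
`StudyAggregation.SUM_ALL_RECORDS` for sensitivity analysis. Adding a
record can therefore never lower a gene's score (monotonicity, property
tested).

The printed grade ranges overlap at their endpoints (10–20 vs ≥ 20, and so
on); they are resolved as half-open intervals anchored on the two
unambiguous ends, "≥ 20" and "< 3": [20, ∞), [10, 20), [5, 10), [3, 5),
[0, 3). Exactly 20 is high, exactly 5 is suggestive.

## Interconnectivity permutation test

The network is built from a STRING-dialect edge list (integer combined
score 0–1000; score/1000 is the confidence) keeping edges strictly above
0.4, dropping self-loops and duplicate pairs with logged counts. Storage
is a `networkx.Graph`; the permutation engine works on a cached boolean
adjacency matrix.

Statistics: for one set, the within-set edge count and the count of
members with ≥ 1 within-set edge; for two disjoint sets A and B, the A–B
edge count and the count of B members with ≥ 1 edge into A. Genes absent
from the network contribute nothing, and null sets are drawn at the size
of the in-network membership, so absent genes cannot inflate
significance.

Null model: replicates draw sets of matched size uniformly **without
degree matching** from the universe, which defaults to all network nodes;
a custom universe list is accepted. For cross statistics both sets are
redrawn jointly (disjointness guaranteed); holding A fixed and redrawing B
is available as `CrossMode.FIX_A_RESAMPLE_B`. The empirical p-value uses
the add-one estimator (r+1)/(N+1), ties counting toward r (conservative);
it is never exactly 0, and when r = 0 the result carries a floor flag and
prints as "p < 1/N" — at the default N = 10⁶, "p < 1.0e-06". Results are
bit-reproducible given the seed. `within_permutation_pair` scores both
within-set statistics on one shared replicate stream; `permutation_test`
draws an independent stream per call.

Correctness is anchored on an exhaustive-enumeration oracle
(`exact_within_pvalue`) that enumerates every subset of a small universe;
Monte-Carlo p-values are required to land within 3 standard errors of the
enumerated value, and label-permutation invariance of the null is checked
through the same oracle.

## Age-at-onset analysis

Gene summaries use the standard midpoint median and require more than five
onset values (≥ 6); bins are juvenile ≤ 30 y, early (30, 50] y, late
> 50 y (the bin edges 30 and 50 belong to the earlier bin, forced by the
"> 50" late definition). The LoF-vs-Dmis comparison requires more than
three values (≥ 4) per group and uses the two-sided Mann–Whitney rank-sum
test — chosen as the standard robust two-sample location test for small,
non-normal onset samples; exact enumeration when both groups have ≤ 25
values and no ties, otherwise the normal approximation with tie and
continuity correction (scipy's implementation, cross-checked in tests
against brute-force enumeration of all rank assignments). Direction is
read from group medians. Raw per-gene p-values are reported;
a Benjamini–Hochberg column is written alongside for transparency but is
not used for selection. A patient recorded with both a LoF and a Dmis
variant of the same gene is excluded from that gene's comparison (logged)
while still counting in the gene-level aggregate.

## Synthetic-data generator

The generator emulates a multi-study curated evidence base at desk scale,
with recoverable ground truth:

* **Evidence**: five grade tiers (defaults 25 high, 38 strong, 61
  suggestive, 88 minimal, 200 uncertain — tens of well-supported genes
  over a long weak tail, the shape of a curated disease database). Each
  tier's recipe assigns single-record studies per gene (e.g. high = 2 CNV
  studies + 2 LoF studies = 20 points). Recipes are checked against the
  active `ScoreMap` before any file is written: a recipe whose score falls
  outside its intended grade interval is a configuration error. Every
  study identifier is distinct, so intended scores are identical under
  both aggregation modes.
* **Network**: a planted-partition construction over 2,000 nodes —
  within-module pairs wired with `p_within` (1.0 plants a clique),
  background pairs with `p_background` = 0.001 (mean background degree
  ≈ 2, sparse like a confidence-filtered PPI network). Default modules of
  63 and 61 nodes coincide with the high+strong and suggestive tier genes.
  Edge confidences are drawn above the 0.4 filter so the loader keeps
  every generated edge; a node roster file keeps isolated nodes in the
  sampling universe.
* **Onset ages**: normal noise truncated at 1 year (gamma available for
  the right skew of real onset distributions), three gene blocks with
  means 25/40/58 y and SD 8 y mirroring juvenile/early/late onset genes,
  30 carriers per gene (15 LoF + 15 Dmis), and a planted LoF shift of 6 y
  in the juvenile block.

One integer seed feeds one named RNG stream per generator
(`default_rng([seed, stream_id])`), so regenerating one artifact never
perturbs another and equal seeds give byte-identical files.

What the generator does **not** emulate: duplicate case reports,
publication bias, pathogenicity-score error, degree-correlated evidence
(hub genes attracting more studies), or linkage between evidence layers.
Passing recovery tests therefore demonstrates that the pipeline inverts
its own declared generative model — not that curated literature data meet
that model's assumptions.

## Problem sizes and numerical choices

The acceptance computation uses the full study conditions: a 2,000-node
network, a planted 63-gene clique, 10⁶ permutation replicates (about 45 s
on one CPU; the per-replicate cost is one 63×63 adjacency slice).
Repeated-seed error-rate studies use 200 seeds at 30 carriers per group:
with no planted shift the comparison rejects at ≈ 5% (3σ binomial band),
and a 1.5 SD planted shift is detected in ≥ 90% of seeds. Test-suite
permutation counts elsewhere are scaled to what the enumeration oracles
need (3-standard-error agreement), not more.

Determinism contracts: permutation results, generator output and CLI
artifacts are bit-identical under a fixed seed; floats are serialized with
`repr` for lossless round-trips.

## Known limitations

* No degree-matched null: hub-heavy gene sets will look interconnected
  partly because of degree. A degree-aware null would need an explicit
  design decision about matching tolerance and is left out of scope.
* Gene symbols are not harmonized across nomenclature releases; input
  curation is trusted.
* The CNV layer treats every event as fully disruptive (fixed score),
  regardless of dosage direction.
* The exact rank-sum path is undefined under ties (it falls back to the
  corrected normal approximation automatically).
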