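# pdgene

Multi-layer genetic-evidence scoring and gene prioritization for
Parkinson's disease (PD), with permutation testing of protein-interaction
interconnectivity and genotype–age-at-onset analysis.

## The problem

Hundreds of studies report genetic findings in PD across very different
kinds of evidence: rare variants carried by patients, gene-level copy
number variants (CNVs), genome-wide association (GWAS) signals,
differential expression (DEG) and differential methylation (DMG). This
package is for researchers who curate such evidence and want to (1) rank
genes by the combined weight of evidence, (2) ask whether the top-ranked
genes are more interconnected in a protein–protein interaction (PPI)
network than chance allows, and (3) ask whether the *kind* of variant a
patient carries shifts their age at onset (AAO).

## The model

**Variant classes.** Each rare variant (minor allele frequency
MAF < 0.01) is classified from its consequence and pathogenicity score:
LoF (frameshift indel, splicing, stop-gain, stop-loss), Dmis (missense,
score > 0.7), Tmis (missense, score ≤ 0.7); everything else is "other".

**Evidence score.** Each record earns a score *s*: rare variants 1–5 by
class (defaults LoF 5, Dmis 4, Tmis 2, other 1), CNVs a fixed 5, and
association records 0–3 by p-value bin (p ≤ 5×10⁻⁸ → 3, p ≤ 10⁻⁵ → 2,
p ≤ 0.05 → 1). A gene's combined score is

&nbsp;&nbsp;&nbsp;&nbsp;S(g) = Σ_(study × layer) max s,

the best record per (study, layer) summed over all integrated studies
(plain summation over records is available as a mode). Grades:
**high** S ≥ 20, **strong** 10 ≤ S < 20, **suggestive** 5 ≤ S < 10,
**minimal** 3 ≤ S < 5, **uncertain** S < 3.

**Interconnectivity test.** Over a STRING-style edge list filtered at
confidence > 0.4, a gene set of size k is scored by its within-set edge
count and its count of members with ≥ 1 within-set edge (plus cross-set
analogues for two disjoint sets). N random size-k sets are drawn uniformly
from the network nodes; the empirical p-value is (r+1)/(N+1), r being the
replicates at or above the observed value, reported as "p < 1/N" when
r = 0.

**Onset analysis.** Genes with more than five AAO values are binned by
median onset — juvenile ≤ 30 y, early 30–50 y, late > 50 y — and, per gene
with more than three values in both groups, LoF and Dmis carrier onsets
are compared with a two-sided Mann–Whitney rank-sum test (exact at small
n).

A seeded synthetic-data generator plants grade tiers, network cliques, and
onset shifts with known ground truth, so every stage's recovery can be
verified end to end.

## Worked example

The `analysis/` scripts run the whole study on synthetic data
(`python analysis/01_simulate.py` … `04_onset_analysis.py`), or in one
command:

```sh
pdgene --seed 1 run-all --out-dir results/run
```

From `02_classify_and_score.py`:

```
variant classes: {'rare_lof': 88, 'rare_dmis': 126, 'rare_tmis': 200}
grade counts: {'high': 25, 'strong': 38, 'suggestive': 61, 'minimal': 88, 'uncertain': 200}
ground-truth grade recovery: 412/412 genes
```

Every synthetic gene re-grades to the tier the generator intended — the
scoring engine inverts the planted evidence recipes exactly. From
`03_network_permutation.py` (100,000 replicates):

```
  within high_strong: 63 of 63 connected, 1953 interconnections (p < 1.0e-05, p < 1.0e-05)
  cross_edges: observed 4, p = 0.952
```

The 63 high+strong genes sit on a planted clique, so all 63 are connected
with 1953 within-set interactions and no random set comes close (the p
floor); the cross-set statistic, with no planted cross wiring, is
indistinguishable from chance — the test rejects exactly where structure
was planted. From `04_onset_analysis.py`:

```
31 genes with enough onset data; bins: {'juvenile': 10, 'early': 11, 'late': 10}
31 LoF-vs-Dmis comparisons; 5 significant at p < 0.05:
  G0004: median LoF 14.51 y vs Dmis 28.03 y, p = 0.000174 (lof_earlier)
```

The three planted onset blocks are recovered as 10 juvenile, 11 early and
10 late genes, and the 6-year LoF shift planted in the juvenile block
surfaces as significantly earlier LoF onset.

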