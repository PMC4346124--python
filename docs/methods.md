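# Methods

`cnalineage` classifies gland-forming gastric intramucosal neoplasms into
lineages of different genomic copy-number instability from array-CGH
(aCGH) tumour/reference profiles, and pairs that genomic classification
with mucin-phenotype statistics. This note documents the models, the
defaults and the numerical choices, and what the synthetic cohort
generator does and does not emulate.

## From probes to gene-level copy-number calls

An aCGH experiment co-hybridises labelled tumour (T) and reference (R)
DNA to oligonucleotide probes; each probe reports `log2(T/R)`, which is
`log2(copy/2)` for a pure diploid-referenced sample. Because probe-level
data from FFPE, whole-genome-amplified DNA are noisy, probe ratios are
averaged within each gene before any inference: for gene *g* and sample
*s*,

    v(s, g) = mean over probes p in g of log2ratio(s, p)

A probe belongs to a gene iff its midpoint lies within the gene interval
(coordinates are 0-based half-open throughout, as in BED). The midpoint
rule makes the assignment unambiguous for probes straddling gene edges;
a probe whose midpoint falls in no gene is dropped with a logged count,
and a gene that acquires no probes is dropped from the matrix (there is
nothing to average). Missing probe ratios are excluded from the mean,
never imputed; a (sample, gene) value is missing only when all the
gene's probes were missing.

Copy-number alterations (CNAs) are called by thresholding:
gain if `v > 0.3219`, loss if `v < -0.3219` (0.3219 = log2 1.25, i.e. a
1.25-fold change). Comparisons are strict (exclusive) to match the
definition's `>` / `<`; an inclusive mode exists as an option. There is
no segmentation (CBS/HMM): thresholding of gene averages is the method.

Per-sample **CNA burden** is the count and fraction of non-missing genes
called gain or loss. **Arm penetrance** is the percentage of samples in
a group carrying an arm-level event; a sample carries an arm gain (loss)
when at least 50% of the arm's called genes are gained (lost). The 50%
arm rule is this package's operational definition — the source analyses
report chromosome-level calls without specifying one — and is
configurable (`arm_fraction`).

## Lineage clustering

Samples are clustered by **uncentred correlation distance** under
**complete linkage** (the Cluster 3.0 conventions). The distance is
Pearson's formula without mean-centring — the cosine of the raw
vectors:

    d(x, y) = 1 - (sum_i x_i y_i) / (sqrt(sum x_i^2) sqrt(sum y_i^2)),  d in [0, 2]

Not centring matters here: a flat profile at 0 carries no direction, so
what correlates two samples is *which genes deviate and in which
direction*, exactly the shared-CNA signal the classification relies on.
Missing values are handled pairwise-complete (at least two shared
positions required); an all-zero vector has no defined distance and is
an error rather than a silent 0.

Complete linkage merges the two clusters whose *maximum* pairwise member
distance is smallest; heights are therefore non-decreasing toward the
root. Ties are broken toward the pair whose smallest original item
indices sort first, which makes the agglomeration deterministic and
order-stable for a given input order. The implementation is checked
against a naive O(n^3) re-agglomeration oracle and against SciPy's
complete-linkage heights in the test suite.

### Gene-size model selection

Larger genes contain more probes, so their averaged values are less
noisy. Clustering is repeated over a sweep of minimum-probes-per-gene
thresholds (default 10, 6, 4, 3, 2; the gene count grows as the
threshold falls) and the working threshold is chosen by two standards:

1. **Pair adjacency** — samples known to come from the same tumour
   (mucosal and deep parts of one lesion) should sit at neighbouring
   positions in the tree. "Neighbouring" is implemented as the sibling
   relation (the two samples merge with each other before either merges
   with anything else) because displayed leaf adjacency is ambiguous
   under left/right flips of a dendrogram; a `leaf-order` mode
   reproduces the looser displayed-order criterion.
2. **Constitution stability** — the k=3 sample partition must be
   identical (as a set partition) to the partition at the next smaller
   threshold.

The selected threshold is the largest one satisfying both (maximal
same-tumour adjacency across thresholds, and partition equal to the next
smaller threshold's). The sweep runs on the combined mucosal+deep sample
set, where the same-tumour pairs exist; the final k=3 lineage call then
reclusters the mucosal samples at the selected threshold.

### Labelling

The three clusters are named from their mean CNA burden and size:
*stable* is the cluster with the lowest mean burden; of the remaining
two, *unstable* is the larger (the dominant high-instability lineage
that also contains the invasive tumours) and *intermediate* the other.
This ordering rule reproduces the reference configuration in which the
intermediate cluster has a slightly higher mean burden than the much
larger unstable cluster. Exact burden ties are refused in auto mode
(manual labelling must be supplied); a size tie falls back to
higher-burden-is-unstable.

## Differential-CNA screen

For each of five contrasts — stable vs intermediate, stable vs unstable,
intermediate vs unstable, stable/intermediate vs unstable, stable vs
unstable/intermediate — every gene's averaged log2 values are compared
with Welch's unequal-variance t-test (Welch–Satterthwaite degrees of
freedom) and Bonferroni-corrected with m = the number of genes actually
tested in that contrast. Contrast multiplicity is reported, not
corrected. A gene enters the selected set when significant (adjusted
p <= alpha, default 0.05) in at least one contrast; the per-contrast
sets and their intersection are also emitted, since the combination rule
is a reporting choice rather than part of the statistic. Genes that
cannot be tested (fewer than two values in a group, or zero variance in
both groups) are recorded as untestable, never silently dropped. The
selected genes feed a two-dimensional supervised clustering (same
distance and linkage on both axes) written as Cluster 3.0
`.cdt`/`.gtr`/`.atr` files; merge scores in the tree files are written
as similarity `1 - distance`, the convention those viewers expect.

Calibration of the screen is part of the test surface: under a null
simulation the family-wise error stays below alpha (Bonferroni is
conservative), and planted effects of 0.6 on the log2 scale at n=15 per
group and probe-average noise 0.1 are recovered with sensitivity >= 95%.

## Mucin phenotype statistics

Percent positivity per marker is binned at the 5 / 30 / 60% boundaries
into the ordinal scores `-`, `+`, `++`, `+++` (lower bound inclusive:
5% is `+`, 30% is `++`, 60% is `+++`). A marker is *positive* at `+` or
above — the only threshold the scoring system supplies. Gastric
positivity is MUC5AC and/or MUC6; intestinal positivity is MUC2 and/or
CD10; the four combinations map to G (gastric only), GI (both), I
(intestinal only), N (neither).

Trend in a binary outcome across ordered groups uses the
Cochran–Armitage statistic with default scores 1..k and a two-sided
asymptotic normal p. The default outcome is "expresses gastric markers
(G or GI) vs not", the dichotomy the group comparisons report; a full
phenotype ordering is a config option flagged as an interpretation. The
asymptotic p is validated against a permutation null in the tests; the
validation uses k >= 3 ordered groups because at k = 2 the trend
statistic's lattice is coarse enough that any continuity-free
asymptotic p deviates from the exact permutation p by the atom size — a
property of the statistic, not of an implementation. Fisher's exact
test (2x2) is two-sided by probability ordering (summing hypergeometric
probabilities of tables at most as probable as observed) and is checked
exhaustively against integer enumeration for all tables with N <= 30.

## Synthetic cohort generator

The generator exists so that every downstream stage is testable against
known ground truth without any downloads. It emulates the *structure* of
an FFPE aCGH study, not its biology:

- **Miniature genome**: 8 chromosomes named chr5, chr7, chr8, chr13,
  chr17, chr18, chr20, chr21 (so the recurrent arm events of gastric
  neoplasia exist by name at reduced scale), ~100 genes each, gene
  probe counts drawn from a skewed 2–12 distribution so the >=2 ... >=10
  sweep is exercisable; centromere at 40% of chromosome length.
- **Lineage archetypes** (`LineageSpec`): whole-arm events fire first,
  then per-gene focal events override. Defaults:

  | lineage      | focal rate | arm events (probability)                                   |
  |--------------|-----------:|------------------------------------------------------------|
  | stable       | 0.02       | 7q gain (1.0)                                               |
  | intermediate | 0.10       | 17p loss (1.0), 18q loss (0.7), 13q loss (0.4)              |
  | unstable     | 0.18       | 8q gain (1.0), 20q gain (0.8), 5q loss (0.5), 21q loss (0.4)|

  Each lineage carries one *defining* core arm at probability 1.0 and
  the signatures are disjoint across lineages. This is the archetype
  idealisation of observed clusters, in which a core CNA profile
  discriminates the lineages and signature genes reach 70–90%
  within-cluster penetrance: a defining event makes the simulated
  ground-truth label meaningful and recoverable (at zero noise,
  exactly). The unstable signature carries the canonical gastric-cancer
  events (8q and 20q gains, 5q and 21q losses); 7q/13q gains and
  17p/18q losses are classic gland-forming-neoplasm alterations used
  here as the other lineages' signatures. Focal rates give the
  stable < intermediate <= unstable burden ordering, which is enforced
  at configuration time. Gains are copy 3, losses copy 1.
- **Measurement model**: each probe emits
  `log2(copy_eff/2) + bias_gene - bias_gene + N(0, probe_sd)`, with the
  tumour and reference channels computed explicitly so the per-gene
  amplification bias (reproducible across samples, emulating WGA bias)
  cancels exactly in the ratio — by construction, as in the real T/R
  design. `copy_eff` mixes neoplastic and diploid stromal copies via a
  purity factor (default 1.0; the source material was ~90% neoplastic).
  `probe_sd` defaults to 0.25, a deliberate calibration choice in the
  range reported for FFPE+WGA material — no quantitative noise level is
  available to estimate it from — and `gene_bias_sd` to 0.5.
- **Paired structure**: mucosal/deep parts of one tumour share a
  profile, the deep part diverging at `part_divergence` (default 0.005
  per gene); concurrent separate lesions of one patient derive from a
  patient-level base profile, each lesion diverging at
  `concurrent_divergence` (default 0.05). A divergence hit toggles a
  gene (altered -> diploid, diploid -> random gain/loss). The defaults
  emulate, qualitatively, near-identical same-tumour pairs versus
  moderately similar concurrent pairs (not fitted to the 15/16 and 3/5
  adjacency counts). Deep parts attach to Vienna-group-Cd lesions.
- **Cohort defaults**: 11 stable / 10 intermediate / 12 unstable
  mucosal lesions with Vienna-group compositions mirroring the study's
  skew (stable and intermediate from non-invasive groups A/B, unstable
  containing the invasive Cm/Cd tumours), 3 same-tumour pairs, 2
  concurrent pairs. Tumour sizes and mucin-phenotype IHC percentages
  are drawn per Vienna group from the study-scale distributions (group
  A entirely intestinal-type; invasive groups mixed with occasional
  null phenotype).
- **Determinism**: all randomness derives from one seed through named
  sub-streams split per sample, so identical configs are byte-identical
  and adding samples does not perturb earlier ones. The gene-bias
  stream is keyed to the genome, not the cohort seed, because the bias
  is a property of the assay.

What the generator does **not** model: WGA chemistry, dye effects,
spatial array artefacts, raw two-channel intensities, segmentation-scale
correlation of probe noise along the genome, subclonal heterogeneity,
and germline CNVs (which cancel in the T/R design). Passing recovery
tests therefore show that the pipeline's inference is correct under its
own assumptions at realistic noise, not that real FFPE cohorts will
cluster this cleanly.

## Numerical and I/O choices

- Distances are clipped to [0, 2] against floating-point drift; the
  diagonal is exactly 0.
- Probe-to-gene averaging sorts measurements (stable sort by gene,
  sample, probe) before aggregating, so results are invariant to probe
  input order.
- Floats are written with 10 significant digits; write->read
  round-trips are identity to that precision.
- Readers reject inverted intervals and missing required columns with
  line numbers / column names; non-numeric ratios are flagged missing
  with a warning, never dropped.
- Full scanner feature-extraction files are not parsed. External data
  enter through a two-table import: a series-matrix-style table
  (probe x sample log2 ratios) plus a platform position table
  (probe -> chrom/start/end), converted to the canonical probe TSV. If
  an accession provides only raw two-channel data, the log ratios must
  be computed upstream.

## Problem sizes in the test and acceptance runs

The default miniature genome (800 genes, ~3,900 probes, 36-sample
cohorts) keeps a full pipeline run around one second, so the acceptance
surface uses replication instead of scale: 20 replicate cohorts for
noisy lineage recovery, 200 simulated families for the null
calibration of the differential screen, 100 random instances for the
clustering oracle, exhaustive enumeration for Fisher (N <= 30) and the
phenotype classifier (4^4 score combinations).

## Known limitations

- The arm-level calling rule (>= 50% of arm genes) and the union rule
  for combining the five differential contrasts are this package's
  operational definitions of procedures the source describes only at
  the result level; both are configurable/reported alongside.
- Auto-labelling assumes the burden/size structure described above; a
  cohort whose intermediate cluster is larger than its unstable one
  needs manual labelling.
- The Cochran–Armitage p is asymptotic; for very small tables an exact
  or permutation p should be preferred.
- Uncentred-correlation clustering cannot cohere a lineage that has no
  shared signal: a "stable" group defined only by absence of events is
  recovered by exclusion, not by mutual similarity.
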