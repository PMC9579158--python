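# Methods

## Scope and data model

`dyscore` scores per-gene transcriptomic dysregulation across several
independent case/control RNA-seq datasets and ranks genes by the
cross-dataset score. A cohort is a list of `ExpressionDataset` objects,
each holding a raw count matrix, a matched TPM matrix (every column sums
to 1e6) and per-sample metadata (subject, condition, mapping rate).
Datasets are tagged `bulk` or `single_cell`; single-cell datasets carry a
`umi_based` flag separating droplet data (UMI counts) from
Patch-seq-like data (read counts per cell). Mapping rates are consumed
as metadata — the package does not process alignments.

## Quality control

A gene is *detected* in a sample iff its count is ≥ 1. Inclusion rules,
with strict boundary semantics throughout (the stated values themselves
pass):

| rule | applies to | fails when |
|---|---|---|
| LOW_MAPPING | single cell (bulk: optional) | mapping rate < 0.50 |
| LOW_GENES | all | detected genes < 1000 |
| LOW_HK (count dialect) | bulk, Patch-seq-like | detected housekeeping genes < 65 |
| LOW_HK (fraction dialect) | droplet single cell | detected fraction of the housekeeping list < 66 % |
| DOUBLET_GENES | single cell | detected genes > 8000 |
| DOUBLET_UMI | droplet single cell | total UMIs > 37,500 |

The two housekeeping dialects coexist deliberately: droplet data are
judged against a fraction of the curated list (98 genes by default),
other data against an absolute count. Bulk samples get no default
mapping-rate cut (an optional `min_mapping_rate_bulk` is available)
because high-coverage bulk libraries with moderate mapping rates can
still be perfectly usable. All failing rules are recorded per sample as
reason codes, and `pass` is true iff no reason applies, which makes
filtering idempotent and auditable.

## Differential expression

Per dataset, each expressed gene (TPM ≥ 1 in at least
`ceil(0.10 · n_samples)` samples) is tested twice:

* **Count route.** Bulk: a negative-binomial GLM Wald test on raw counts
  with median-of-ratios size factors as offsets. The NB dispersion is a
  per-gene method-of-moments estimate from normalized counts (pooled
  within-group variance), floored at 1e-8; the GLM itself is fitted with
  statsmodels. This is a deliberate re-implementation of the style of
  test used by dedicated bulk DE tools — validated by type-I-error
  calibration and by rank agreement with pydeseq2 in the test suite, not
  by exact equality with any external tool. Failed fits fall back to a
  rank-sum test on normalized counts. Single cell: Wilcoxon rank-sum on
  counts-per-10k-normalized counts.
* **TPM route.** Wilcoxon rank-sum on raw TPM values.

Wilcoxon p-values are exact (full enumeration) when both groups have ≤ 8
observations and the pooled sample is tie-free, and use the
tie-corrected normal approximation without continuity correction
otherwise, so identical groups return exactly p = 1. A vectorized
implementation of the asymptotic path is used genome-wide and is tested
against the per-gene reference.

The two p-values are combined by the logit method: with k = 2,
L = −Σ log(pᵢ/(1−pᵢ)) scaled by √(3(5k+4)/(kπ²(5k+2))) and referred to
the upper tail of Student's t with 5k+4 = 14 degrees of freedom. Inputs
are clamped to [1e-15, 1−1e-15]. The combination is one-sided in the
statistic, anchored by (0.5, 0.5) → 0.5. Log₂ fold changes are computed
per route from group means with pseudocounts (1 on the normalized-count
scale, 0.01 on the TPM scale — chosen as small relative to typical
expression on each scale) and averaged arithmetically. Unexpressed genes
carry p = 1 on every route and zero fold change.

**A calibration caveat worth knowing.** The two routes test the same
samples and are strongly dependent — for single-cell data, per-gene
Wilcoxon on TPM and on library-normalized counts are rank-identical
whenever gene lengths are constant within a gene, so the two p-values
coincide; for bulk the correlation is ≈ 0.85. The logit combination
assumes independent p-values, so the combined p is anti-conservative
under the null: on a fully null synthetic dataset the fraction of genes
with combined p < 0.05 is ≈ 0.11, not 0.05, even though each individual
test is well calibrated (measured Wilcoxon 0.054, NB Wald 0.065–0.07 at
α = 0.05). This is a property of the dual-test-then-combine design
itself. It does not bias the *ranking* (the desirability mapping is
monotone in p) but it means combined p-values must not be read as
calibrated significance statements.

## Dysregulation scoring

Per dataset, three desirabilities on (0.01, 1]:

* **d_p** — 1 at the dataset's minimum observed combined p, 0.01 for
  p > 0.05, linear in p between. The lower anchor is the per-dataset
  minimum by default (`p_low_cut="min"`); a fixed numeric anchor is
  configurable. If a dataset's minimum p is itself above 0.05 (no
  signal anywhere), every gene receives 0.01 rather than raising — the
  mapping degenerates gracefully; an explicitly configured numeric
  lower cut ≥ 0.05 is a hard error.
* **d_fc** — 0.01 at fold change ≤ 1.25, 1 at ≥ 2, linear in the fold
  change 2^|log₂FC| between. Magnitude only; direction is handled by the
  concordance factor, since up- and down-regulated genes are equally
  interesting.
* **d_mb** — 1 for genes with transcript detection in adult midbrain,
  0.25 otherwise. The annotation is consumed as a boolean; genes absent
  from it count as detected.

Linear interpolation between cut points is used for both mappings, the
default shape of the desirability-function approach.

`D_dataset` is the weighted geometric mean with weights (1, 0.5, 0.01) —
the midbrain term is a soft prior at 1 % of the p-value weight — and
unexpressed genes are floored at `D_dataset = 0.01`.

`D_overall` is the weighted geometric mean of all per-dataset scores at
equal weight together with the concordance desirability at one tenth of
the total weight (for six datasets, w_c = 6·(0.1/0.9) = 2/3, giving
w_c/(6 + w_c) = 0.10 exactly). Concordance is the signed-majority
fraction c = |n_up − n_down|/(n_up + n_down) over the expressed datasets
with non-zero fold change (zeros excluded from both counts; a single
expressed dataset gives c = 1; no usable dataset gives an undefined
concordance recorded as NaN with the 0.01 floor applied). The
desirability is 0.01 + 0.99·c. Placing the concordance term *inside*
the geometric mean keeps D_overall in (0, 1] by construction. A gene at
the floor everywhere scores exactly 0.01.

Group scores over dataset subsets (e.g. single-cell-only or bulk-only
strength) are plain geometric means without a concordance term.

Ranking is by decreasing D_overall with deterministic tie-breaks: lower
sum of combined p-values across datasets, then lexicographic gene id.
The ranked universe is the union of genes expressed in at least one
dataset; genes expressed nowhere are excluded from ranking entirely.

## Pre-ranked gene-set enrichment

The engine consumes a ranked gene → score list and a GMT collection
restricted to the universe (inclusive size bounds, defaults 15–500).
The enrichment score is the classic weighted running-sum statistic:
walking down the list, member hits add |score|^w / N_R (w = 1 by
default, N_R the sum of hit weights) and misses subtract 1/(N − N_hits);
ES is the extremum of the running sum with its sign, and the leading
edge holds the hits at or before a positive extremum (after it for a
negative one).

Significance uses gene-tag permutations: per set, `n_permutations`
random same-size member draws from the universe (a single seeded
generator consumed in set-name-sorted order, so results do not depend on
collection insertion order). NES divides ES by the mean magnitude of
same-sign null ES of that set (mean-division normalization; if a sign
stratum is empty the overall mean |null ES| is used). The nominal p is
the same-sign null tail fraction. FDR-q follows the sign-stratified
pooled-NES procedure — observed-vs-null tail-fraction ratio, clamped to
[0, 1], then monotonized by a running minimum from the least extreme
|NES| toward the most extreme so a stronger enrichment never reports a
larger q. FWER-p is the fraction of permutations whose maximum same-sign
NES across all sets reaches the observed NES (sign-stratified max-NES
null). The label-permutation control shuffles the gene ↔ score
assignment with a given seed and reruns the full analysis; on a sound
input it should return no significant sets.

The null ES distribution is computed vectorized from sorted hit
positions only (the running-sum extrema occur immediately after hits or
immediately before them/at the end), which the tests verify against
brute-force prefix enumeration.

## Synthetic cohorts

The generator emulates the six-dataset study design: two single-cell
datasets (the first droplet/UMI-based, the second Patch-seq-like) and
four bulk datasets, 4 subjects per condition × 40 cells for single cell
and 10 subjects per condition for bulk (≈ 80 bulk samples cohort-wide).
Counts are gamma-Poisson (negative binomial) with per-gene relative
abundances drawn log-normal (σ = 1.25), subject-level library-size
factors (log-normal, σ = 0.2) and cell-level factors on top for single
cell. Defaults: bulk library mean 5e5; single-cell library mean 1.5e4
UMIs, clipped at 3.2e4 so clean cells sit safely below the 37,500-UMI
doublet cut; gene length constant 1 kb so TPM ∝ CPM (a length vector is
accepted for length-effect testing); NB dispersion 0.15 for background
and planted genes and 0.05 for housekeeping genes, which also get 8×
abundance — stable, highly expressed, as housekeeping genes are.

Planted DE genes receive a multiplicative condition effect of magnitude
2^|log₂FC| split symmetrically between the groups (cases ×2^(+fc/2),
controls ×2^(−fc/2)). The symmetric split matters: applying the full
effect to one group inflates that group's expected library mass, and
because TPM is compositional every null gene then shifts concordantly in
the opposite direction — precise housekeeping genes pick this up as
spurious, concordant signal. With the symmetric split the two groups'
expected library composition is identical and null genes stay null. A
configurable fraction of planted genes is direction-concordant across
datasets; the rest flip sign per dataset with probability 1/2, drawn
from each dataset's own random stream. Seeding uses one master
`SeedSequence` spawned into a global stream (gene universe, planted
structure) plus one child per dataset in order, so adding a dataset
never perturbs existing ones and everything is bit-reproducible.

Planted QC failures are realized so the intended rule is unambiguously
violated (mapping rate drawn in [0.20, 0.45]; all but ~500 genes zeroed;
housekeeping genes zeroed down to ~38 detected; UMI totals regenerated
at 1.3–1.8 × 37,500). Planting the >8000-genes doublet failure requires
a gene universe larger than 8000; the generator refuses it otherwise,
and that rule is unit-tested directly on constructed metrics instead.

What the generator does *not* emulate: batch effects beyond library-size
variation, gene–gene correlation, zero-inflation beyond what the NB
produces at low means, length-varying transcripts (by default), and
dataset-specific expressed universes as extreme as real cross-platform
cohorts. Passing tests therefore demonstrate correct mechanics and
honest parameter recovery under a clean NB world, not robustness to all
real-data pathologies.

## Verification strategy and observed behavior

* Exact scoring constants and the weighted geometric means are checked
  against 50-digit `mpmath` arithmetic (max abs error < 1e-12 on 1000
  random inputs).
* The ES implementation is checked against brute-force prefix
  enumeration on 100 random small instances (1e-12).
* The logit combination is checked against an independent
  high-precision evaluation and against `scipy.stats.combine_pvalues`.
* The NB Wald test is calibrated (type-I error 0.065 at α = 0.05 on 200
  null genes, n = 20/20) and agrees in ranking with pydeseq2 (Spearman
  > 0.9 on a 60-gene instance).
* Parameter recovery on a 5000-gene cohort with 200 concordant planted
  genes at |log₂FC| = 2 (fixed seed): planted genes reach a median rank
  of ~100/5000; housekeeping genes' median rank falls in the lower half
  (~3400/5000), outside the top quartile; the planted set attains
  FWER-p < 0.05, and the label-permutation control returns zero sets at
  FDR-q < 0.01.

Problem sizes in the test suite (hundreds to a few thousand genes, tens
of samples, 100–1000 permutations) are the package's chosen desk-scale
study conditions for routine verification.

## Known limitations

* The combined p-value is anti-conservative under the null (see the
  calibration caveat); consumers should rely on the desirability ranking
  or on single-route p-values for calibrated inference.
* The NB Wald test uses method-of-moments dispersions without shrinkage;
  at very small n it is less powerful and slightly more liberal than
  shrinkage-based tools.
* Concordance uses the signed-majority fraction; other discordance
  penalties are plausible and the functional form is isolated in
  `concordance_factor` so alternatives can be swapped.
* Fold-change desirability ignores direction by design; a gene strongly
  up in half the datasets and strongly down in the rest is penalized
  only through the concordance term.
* No covariate adjustment, batch correction or fold-change shrinkage.
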