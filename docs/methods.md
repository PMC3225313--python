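# Methods

`lncarray` reimplements, as one tested pipeline, the analysis chain used to
characterize long noncoding RNAs (lncRNAs) transcribed from intronic and
intergenic regions and measured on a replicated spotted cDNA microarray:
probe classification, expression preprocessing and detection, permutation
differential expression, matched-null genomic-context enrichment, RNA-seq
intron/exon co-expression, and qPCR relative quantification. This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic world does and does not establish.

## Probe classification (`lncarray.intervals`)

Coordinates are 0-based half-open everywhere; GFF3 is converted on input,
BED is native. A probe is classified against RefSeq-style gene models into
five classes:

- **protein_coding** — fully covered by exonic space of a coding gene;
- **exonic** — overlaps an exon/intron boundary (possible intron
  retention); exon overlap always dominates, so a probe touching any
  coding exon can never be intronic or intergenic;
- **intronic** — fully inside a single intron of a coding gene, touching
  no exon; the host gene is recorded;
- **known_lncRNA** — fully inside a noncoding-biotype gene model;
- **intergenic** — overlapping no annotated gene span. A probe on a
  chromosome absent from the annotation is intergenic (with a warning).

Alignment filtering keeps probes with identity AND coverage ≥ 0.90
(inclusive, "at least 90%"). GC content excludes ambiguous bases from both
numerator and denominator, so GC of an all-N interval is undefined (NaN)
rather than 0. UTR proximity ("within 1 kb") and the 10 kb distance cap
are inclusive boundaries. Small-RNA overlap is reported both for the raw
probe interval and for the interval padded 1 kb on both sides (the typical
length scale of microRNA precursors), clamped at position 0.

## Synthetic world (`lncarray.simulate`)

The generator's defaults restate the targeted study design: a 3,355-probe
array (2,371 protein-coding / 74 known lncRNA / 722 intronic / 188
intergenic), 38 samples (9 NT normal, 15 T primary tumor, 6 M metastasis,
8 CP pancreatitis), each hybridized on 2 slides with probes spotted in
duplicate (4 replicate measurements), 9 RNA-seq libraries, and triplicate
qPCR for 3 targets plus the HMBS reference in 11 primary + 6 metastasis
samples.

Values neither stated by the design nor derivable from it were fixed once
at what a microarray practitioner would call realistic, before any test
was run, and are not revisited:

| parameter | default | rationale |
|---|---|---|
| log2 baseline per probe | N(8, 1.5) | mid-range spotted-array intensity |
| biological sd (per sample) | 0.5 log2 | typical inter-patient variability |
| measurement sd (per spot) | 0.3 log2 | replicate spot noise |
| batch offset | 0.5 log2 per batch | visible but sub-biological artifact |
| missing fraction | 0.05 | flagged/failed spots |
| probe length | 300–600 bp | EST-derived probes |
| genome | 4 × 8 Mb | fits 680 non-overlapping genes |
| GC composition | 0.41 ± 0.15 sinusoid, 400 kb period | makes GC matching non-trivial |
| feature background | 10/Mb Poisson | H3K4me3-peak-like genome-wide density |
| peak width / CpG width | 500 / 800 bp | typical track element sizes |
| RNA-seq | NB-like (Poisson-lognormal), mean 30 RPKM, 0.3 log2 dispersion | bulk RNA-seq scale |
| qPCR noise | 0.2 Ct per replicate | routine SYBR assay precision |

Intensities are simulated on the log2 scale and exponentiated, so planted
log-fold effects are exact. Each output type (genome, genes, probes,
tracks, expression, RNA-seq, qPCR) draws from its own child RNG stream of
the master seed, so changing one configuration block never perturbs the
other outputs. Feature planting is deterministic (a chosen fraction
`f_enrich` of intronic/intergenic probes receives one peak, CpG island,
CAGE cluster and conserved element within `d_enrich` of its 5' anchor);
the background is Poisson. `f_enrich = 0` is therefore an exact null.

What the generator does **not** model: scanner physics, dye bias,
cross-hybridization, spatial slide artifacts, clustered (non-uniform)
background feature placement, multi-exon "exon models" for RNA-seq
flanks, or amplification-efficiency variation in qPCR. A green test
establishes that the statistics behave correctly under the stated noise
model, not that they are robust to these unmodeled artifacts.

## Expression preprocessing (`lncarray.preprocess`)

The stage order is fixed and enforced by the driver:

1. **Quantile normalization** across slides (each slide's vector is both
   spot columns stacked). Ties receive the mean of their pooled quantile
   values via average ranks; missing entries are ignored and preserved,
   never zero-filled. With unequal valid counts the common quantile curve
   is interpolated on the (k − ½)/m grid.
2. **Low-intensity filter**: per slide, the lowest 50% of valid
   intensities are invalidated — exactly floor(n_valid × fraction)
   entries, ties broken by stable order for determinism.
3. **Replicate collapse**: per-sample probe mean when ≥ 3 of the 4
   replicates are valid, else missing. A sample mapping to ≠ 4
   measurements is a structural error.
4. **Detection calls**: a probe is detected in a histology group when the
   valid-sample fraction is ≥ 0.75 (inclusive), and expressed when
   detected in ≥ 1 group.
5. **Batch adjustment** on expressed probes: per-probe location/scale
   correction to the pooled mean/variance, with moment-based
   empirical-Bayes shrinkage of the batch parameters toward their
   across-probe average (on by default). This is deliberately *not* a
   bit-compatible reimplementation of the canonical ComBat program: the
   claim being reproduced is batch-effect removal, which the simpler
   model satisfies and the simulation verifies (planted-offset removal
   and restoration of the null false-positive rate). A batch confounded
   1:1 with histology is refused.

The histology label "PA" is accepted as a synonym of CP on input.
Optional k-nearest-neighbor imputation (k = 10, Euclidean over shared
samples) is provided but off by default; the collapse/detection rules
already control missingness.

## Differential expression (`lncarray.diffexpr`)

Two-class SAM-style analysis. Per probe,
d_i = (mean₁ − mean₂) / (s_i + s₀), with s_i the pooled two-sample
scatter and the fudge factor s₀ chosen by the canonical
coefficient-of-variation criterion: over candidates {0, 5th, 10th, …,
100th percentile of s_i}, choose the value minimizing the CV of
window-wise MADs of d across 100 s_i-percentile windows. The null is
label permutations (all distinct assignments enumerated when fewer than
`n_perm` exist — this makes small designs exactly reproducible and
oracle-checkable). For a threshold delta, the cutpoints are the first
order statistics whose deviation from the permutation-expected order
statistics exceeds ±delta;

FDR(delta) = median permutation false-call count / observed call count,

with no π₀ correction. The reported called set is the one at the smallest
delta with FDR at or below the requested level; per-probe q-values are
the smallest FDR over deltas at which the probe is called, which makes
the called sets nested across thresholds. Missing values are excluded
pairwise per probe; probes with fewer than 2 valid samples in either
group are never called. SAM runs on batch-adjusted values by default
(flag available). Multi-class analysis is out of scope.

Heatmap support reproduces the presentation conventions: samples ordered
by Pearson correlation to the mean primary-tumor profile over the
signature (undefined correlations placed last and flagged), and rows
standardized to population z-scores (zero-variance rows flagged and
zero-filled).

## Genomic-context enrichment (`lncarray.context`)

The question is whether expressed intronic/intergenic lncRNA loci carry
promoter-associated features (H3K4me3 peaks, CpG islands, CAGE tag
clusters) closer than chance. Preprocessing: peaks with p ≥ 10⁻⁵ are
removed (strict <), overlapping CAGE tags are single-linkage clustered
and clusters with < 5 tags discarded, and any feature overlapping an
annotated 5'UTR is removed so known gene starts cannot drive the signal.

The null model is `n_sets` (default 100) random interval sets drawn from
the declared sampling space (intron space or intergenic space), matched
1:1 to the query in number, exact length, and GC content within ±0.02.
Exact GC matching is generally infeasible, so the tolerance doubles each
time 1,000 candidates are exhausted and the achieved tolerance is
recorded per interval; candidate positions are drawn uniformly over all
pool placements that fit the exact length (O(1) GC lookups via
per-chromosome prefix sums). Hard invariants — exact length match, GC
within recorded tolerance, containment in the sampling space — are
asserted in the test suite on every run.

Nearest distances are unsigned, capped at 10 kb (inclusive), and censored
beyond the cap rather than stacked at it; censoring applies symmetrically
to query and null sets. H3K4me3 and CpG use boundary mode (0 on overlap,
else the minimal gap); CAGE uses the strand-aware 5'-start mode, with
unknown strand falling back to boundary mode. The decision rule is
deliberately strict: the observed distribution is called enriched only if
the two-sample KS test (asymptotic p by default; exact switchable for
n < 25) rejects at α = 0.05 against **every** null set. Distributions
with fewer than 10 uncensored distances are "untestable" — this happens
honestly in the default world for the 71 expressed intergenic queries
against a 10/Mb background, where most nearest features lie beyond the
10 kb cap.

Conserved-element enrichment uses a one-sided (greater) Fisher exact test
of query overlap counts against the 100 null sets pooled into a single
control margin (the contingency construction is this package's choice; a
per-set majority rule is available behind a flag). The normalized bar
value divides overlapping-query counts by the total elements per track.

## RNA-seq intron/exon co-expression (`lncarray.rnaseq`)

RPKM = count × 10⁹ / (length × library size). A locus triplet (upstream
exon, intron, downstream exon) is eligible when all three features are
detected — RPKM strictly above 0 by default; the detection floor is
configurable because the source analysis does not state one — in ≥ 4 of
9 libraries. Pearson correlations over per-library RPKM vectors are
classified with strict boundaries: positive r > 0.5, negative r < −0.5,
poor otherwise (r = 0.5 is poor). The intron's headline class uses the
flank with the larger |r|; both per-flank values are always retained.
Note that at n = 9 libraries the sampling distribution of r places
roughly 17% of truly independent pairs outside (−0.5, 0.5), so "poor"
rates near 75–85% — not ~100% — are the correct null expectation.

## qPCR quantification (`lncarray.qpcr`)

Replicate Ct values are collapsed by mean; ΔCt = Ct(target) − Ct(HMBS)
per sample; ΔΔCt = ΔCt − mean ΔCt over primary-tumor samples, so the
baseline-group mean ΔΔCt is 0 by construction; fold = 2^(−ΔΔCt). Group
comparison defaults to the two-sided Wilcoxon rank-sum on ΔΔCt (robust at
n = 6–11; a Welch t-test on ΔCt is switchable) — the source analysis does
not name its test, so its printed p-values are not asserted anywhere.
Intronic-vs-host-mRNA co-expression is the Pearson correlation of log2
fold profiles (equivalently −ΔΔCt), since linear-scale folds are
log-normal. No amplification-efficiency correction is applied.

## Numerical choices and degenerate inputs

- All tie-breaks (low-intensity filter, s₀ grid, sample ordering) use
  stable sorts; every stochastic step takes an explicit seed and is
  bit-reproducible.
- 0/0 in the SAM statistic (all-equal data) yields d = 0, never NaN.
- Constant expression profiles: correlation-based sample ordering flags
  them and places them last; zero-variance heatmap rows are zero-filled;
  zero-variance RPKM vectors flag the locus out of the class tallies;
  all-tied qPCR groups return p = 1 with a degenerate flag.
- Empty feature tracks censor every distance and mark the decision
  untestable instead of raising.

## Known limitations

- The location/scale batch model removes linear batch structure only;
  nonlinear batch-by-probe interactions would survive it.
- The uniform feature background understates the clustering of real
  chromatin marks near genes, which makes the matched-null test easier
  than on real tracks at equal densities.
- The matched-null sampler matches marginal GC and length but not
  higher-order sequence composition (CpG dinucleotide density,
  repeats).
- Intronic probes are planted independently of expression level, so the
  synthetic world has no abundance/class confounding; claims about the
  50% intensity filter interacting with probe class are outside what the
  tests establish.
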