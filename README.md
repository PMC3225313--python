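# lncarray

Expression and genomic-context analysis of long noncoding RNAs (lncRNAs)
transcribed from intronic and intergenic regions, as measured on
replicated spotted cDNA microarrays.

Many tumor transcriptome studies interrogate custom arrays that carry
probes for putative lncRNAs alongside protein-coding genes, then ask two
questions: *which transcripts are differentially expressed across tissue
histologies*, and *are the noncoding loci independent transcriptional
units rather than splicing debris*? `lncarray` packages that full
analysis chain — originally the domain of one-off scripts — as a tested,
seed-reproducible library with a CLI, aimed at computational biologists
reanalyzing such platforms or benchmarking the statistics behind them.

## What it implements

- **Probe classification** (`lncarray.intervals`): strand-aware 0-based
  half-open intervals; probes classified against gene models as
  protein_coding / exonic / intronic / known_lncRNA / intergenic (exon
  overlap dominates); alignment filtering at ≥ 90% identity and coverage;
  GC content excluding ambiguous bases; UTR-proximity (≤ 1 kb) and
  small-RNA overlap (± 1 kb extension) flags.
- **Preprocessing** (`lncarray.preprocess`): quantile normalization
  across slides, per-slide 50% low-intensity filtering, 2 slides × 2
  spots → per-sample means requiring ≥ 3/4 valid replicates, detection
  in a histology group at ≥ 75% valid samples, location/scale batch
  adjustment, inter-slide correlation QC.
- **Differential expression** (`lncarray.diffexpr`): SAM-style moderated
  statistic d = (x̄₁ − x̄₂)/(s + s₀), s₀ by the coefficient-of-variation
  grid search, label-permutation null (exhaustive when enumerable),
  FDR(Δ) = median permutation false calls / observed calls, signature
  composition by genomic class, heatmap sample ordering and z-scores.
- **Genomic context** (`lncarray.context`): the matched-null engine —
  100 random interval sets matched to the query in number, exact length
  and GC (± 0.02, adaptively relaxed and recorded); H3K4me3 peak filter
  (p < 10⁻⁵), CAGE tag clustering (≥ 5 tags), 5'UTR feature removal;
  nearest-feature distances capped at 10 kb; the strict decision rule
  *enriched ⇔ all 100 KS p-values < 0.05*; one-sided Fisher enrichment
  of conserved-element overlap; expression-breadth counting.
- **RNA-seq co-expression** (`lncarray.rnaseq`): RPKM, the ≥ 4-of-9
  library eligibility rule, and intron-vs-flanking-exon Pearson classes
  (r > 0.5 / −0.5 ≤ r ≤ 0.5 / r < −0.5).
- **qPCR** (`lncarray.qpcr`): 2^(−ΔΔCt) against a reference gene
  baselined on the primary-tumor mean, rank-sum group comparison,
  intronic-vs-host-mRNA correlation.
- **Synthetic world** (`lncarray.simulate`): a seeded generator for every
  input — toy genome with a GC gradient, gene models, probes placed per
  class with recorded truth, feature tracks with plantable enrichment,
  replicated intensity matrices with planted signatures and batches,
  RNA-seq triplet counts, qPCR Ct tables — so the whole pipeline runs
  and is testable with no downloads.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Generate a synthetic bundle and run the expression arm:

```bash
lncarray simulate --seed 4 --outdir data/
lncarray preprocess --intensities data/intensities.tsv \
    --samples data/samples.tsv --outdir out/
lncarray diff --matrix out/expression.tsv --samples data/samples.tsv \
    --probes data/probes.bed --groups T:NT,CP --fdr 0.10 \
    --nperm 1000 --seed 1 --outdir out/
```

Or drive everything from Python. The end-to-end run on the default world
(`python scripts/acceptance.py --seed 1 --out results/acceptance.json`)
prints, among other lines:

```
detection by class (expressed/total): intergenic=71/188, intronic=311/722,
  known_lncRNA=41/74, protein_coding=1083/2371
tumor signature (FDR<=10%): 16 probes, composition {'protein_coding': 11,
  'intronic': 3, 'known_lncRNA': 1, 'intergenic': 1}
intronic x h3k4me3: 311 queries, decision ENRICHED (max KS p 7.54e-16)
intronic x cage: 311 queries, decision ENRICHED (max KS p 7.11e-15)
qPCR lnc_target_1: metastasis fold 3.75, p 0.0002
```

Reading this: about 43% of intronic lncRNA probes pass the detection
rules (a lower fraction than protein-coding probes, as expected for less
abundant noncoding transcripts); the two-class permutation analysis
recovers a mixed coding/noncoding tumor signature at FDR ≤ 10%; the
expressed intronic loci carry promoter-associated marks (H3K4me3, CAGE
starts) significantly closer than *every one* of 100 GC/length-matched
random intron sets — the hallmark of independent transcriptional units —
and the planted 4-fold qPCR change in metastases is recovered with a
significant rank-sum p-value.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole analysis from scratch on the seeded default
synthetic world — genome and probe generation, preprocessing and
detection accounting, both SAM signatures (tumor vs non-tumor at
FDR ≤ 10%, metastasis vs primary at FDR ≤ 5%), matched-null KS decisions
for H3K4me3 and CAGE over intronic and intergenic queries,
conserved-element Fisher tests, RPKM intron/exon correlation tallies,
expression breadth, and ΔΔCt fold changes — logging each result, and
writes the target JSON to `--out`.
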