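"""Seeded synthetic-data generators for every input the pipeline consumes.

The default configuration restates the study design the pipeline targets:
a 3,355-probe array (2,371 protein-coding / 74 known lncRNA / 722 intronic /
188 intergenic probes), 38 samples in 4 histology groups (9 NT / 15 T /
6 M / 8 CP) each measured on 2 slides x 2 spots, 9 RNA-seq libraries, and
triplicate qPCR with a stable reference gene. Feature tracks (H3K4me3
peaks with p-values, CpG islands, CAGE tags, conserved elements, small
RNAs) are a Poisson background plus deterministic planting near transcript
boundaries, so enrichment signal and noise are separable by construction.

Every output type draws from its own child RNG stream: changing one config
block never perturbs the other outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel,
    GenomicInterval,
    ProbeRecord,
)
from . import io as lio

_STREAMS = {
    "genome": 1, "genes": 2, "probes": 3, "tracks": 4,
    "expression": 5, "rnaseq": 6, "qpcr": 7,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


@dataclass
class SimulationConfig:
    """One seeded description of the synthetic world.

    Counts and group sizes default to the study design; noise scales are the
    package's realism choices (see docs/methods.md). All log-scale values are
    log2.
    """

    seed: int = 0

    # genome / annotation
    n_chromosomes: int = 4
    chromosome_length: int = 8_000_000
    n_genes: int = 600
    n_noncoding_genes: int = 80
    exons_per_gene: tuple[int, int] = (4, 10)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (1500, 6000)
    intergenic_gap: tuple[int, int] = (2000, 10000)
    gc_base: float = 0.41
    gc_amplitude: float = 0.15
    gc_period: int = 400_000

    # probes (array composition)
    probe_counts: dict = field(
        default_factory=lambda: {
            "protein_coding": 2371,
            "known_lncRNA": 74,
            "intronic": 722,
            "intergenic": 188,
        }
    )
    probe_length: tuple[int, int] = (300, 600)

    # expression matrix
    samples_per_group: dict = field(
        default_factory=lambda: {"NT": 9, "T": 15, "M": 6, "CP": 8}
    )
    slides_per_sample: int = 2
    spots_per_slide: int = 2
    n_batches: int = 2
    batch_offset: float = 0.5          # log2 units between consecutive batches
    baseline_mean: float = 8.0         # log2 intensity
    baseline_sd: float = 1.5
    biological_sd: float = 0.5         # per sample, per probe
    measurement_sd: float = 0.3        # per replicate spot
    missing_fraction: float = 0.05
    signature_size: int = 50
    effect_size: float = 1.0           # planted log2 shift
    signature_group: str = "T"

    # feature tracks
    peak_width: int = 500
    background_density_per_mb: float = 10.0
    f_enrich: float = 0.4
    d_enrich: int = 500
    cage_tags_per_cluster: int = 6
    cage_tag_length: int = 20
    noisy_peak_fraction: float = 0.2   # H3K4me3 peaks with p >= 1e-5

    # RNA-seq
    n_rnaseq_libraries: int = 9
    n_rnaseq_loci: int = 120
    rnaseq_library_size: int = 5_000_000
    rnaseq_mean_rpkm: float = 30.0
    rnaseq_dispersion: float = 0.3     # sd of the shared log2 rate
    correlated_fraction: float = 1 / 3

    # qPCR
    qpcr_targets: int = 3
    qpcr_replicates: int = 3
    reference_ct: float = 25.0
    target_ct_offset: float = 4.0
    qpcr_group_shift: float = -2.0     # planted delta-Ct in metastasis
    qpcr_noise_sd: float = 0.2
    qpcr_samples: dict = field(
        default_factory=lambda: {"primary": 11, "metastasis": 6}
    )

    def __post_init__(self) -> None:
        for k, v in self.probe_counts.items():
            if v < 0:
                raise ValueError(f"negative probe count for {k}")
        for frac in (self.missing_fraction, self.f_enrich, self.noisy_peak_fraction,
                     self.correlated_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.samples_per_group.values()) <= 0:
            raise ValueError("sample counts must be positive")


# ------------------------------------------------------------------ genome

@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    genes: list[GeneModel]
    probes: list[ProbeRecord]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        lio.write_fasta(self.sequences, outdir / "genome.fa")
        lio.write_gff3(self.genes, outdir / "genes.gff3")
        lio.write_probes_bed(self.probes, outdir / "probes.bed")


def _simulate_sequence(cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    """Bases drawn with a sinusoidal GC gradient so GC matching is non-trivial."""
    seqs = {}
    for c in range(cfg.n_chromosomes):
        n = cfg.chromosome_length
        pos = np.arange(n)
        phase = rng.uniform(0, 2 * np.pi)
        gc = cfg.gc_base + cfg.gc_amplitude * np.sin(
            2 * np.pi * pos / cfg.gc_period + phase
        )
        gc = np.clip(gc, 0.05, 0.95)
        u = rng.random(n)
        v = rng.random(n)
        bases = np.where(
            u < gc, np.where(v < 0.5, b"G", b"C"), np.where(v < 0.5, b"A", b"T")
        ).astype("S1")
        seqs[f"chr{c + 1}"] = bases.tobytes().decode()
    return seqs


def _simulate_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Non-overlapping genes tiled along chromosomes, coding then noncoding
    interleaved at random."""
    total = cfg.n_genes + cfg.n_noncoding_genes
    biotypes = np.array(
        ["protein_coding"] * cfg.n_genes + ["noncoding"] * cfg.n_noncoding_genes
    )
    rng.shuffle(biotypes)
    genes: list[GeneModel] = []
    per_chrom = int(np.ceil(total / cfg.n_chromosomes))
    gi = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = int(rng.integers(*cfg.intergenic_gap))
        for _ in range(per_chrom):
            if gi >= total:
                break
            n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            p = pos
            for e in range(n_ex):
                elen = int(rng.integers(*cfg.exon_length))
                exons.append(GenomicInterval(chrom, p, p + elen, strand))
                p += elen
                if e < n_ex - 1:
                    p += int(rng.integers(*cfg.intron_length))
            if p >= cfg.chromosome_length - cfg.intergenic_gap[1]:
                break
            first, last = exons[0], exons[-1]
            utr_a = [GenomicInterval(chrom, first.start,
                                     first.start + max(20, first.length // 4), strand)]
            utr_b = [GenomicInterval(chrom, last.end - max(20, last.length // 4),
                                     last.end, strand)]
            utr5, utr3 = (utr_a, utr_b) if strand == "+" else (utr_b, utr_a)
            biotype = biotypes[gi]
            genes.append(
                GeneModel(
                    f"gene_{gi + 1:04d}", chrom, strand, exons, biotype,
                    utr5=utr5 if biotype == "protein_coding" else [],
                    utr3=utr3 if biotype == "protein_coding" else [],
                )
            )
            gi += 1
            pos = p + int(rng.integers(*cfg.intergenic_gap))
    if gi < total:
        raise ValueError(
            f"genome too small: placed {gi} of {total} genes; increase "
            "chromosome_length or n_chromosomes"
        )
    return genes


def _sub_interval(
    parent: GenomicInterval, length: int, rng: np.random.Generator, margin: int = 1
) -> GenomicInterval | None:
    lo, hi = parent.start + margin, parent.end - margin - length
    if hi < lo:
        return None
    s = int(rng.integers(lo, hi + 1))
    return GenomicInterval(parent.chrom, s, s + length, parent.strand)


def _simulate_probes(
    cfg: SimulationConfig, genes: list[GeneModel], rng: np.random.Generator
) -> list[ProbeRecord]:
    coding = [g for g in genes if g.biotype == "protein_coding"]
    noncoding = [g for g in genes if g.biotype == "noncoding"]
    spans = sorted(
        (g.span for g in genes), key=lambda s: (s.chrom, s.start)
    )
    probes: list[ProbeRecord] = []
    pid = 0

    def plen() -> int:
        return int(rng.integers(*cfg.probe_length))

    def place(cls: str) -> ProbeRecord | None:
        nonlocal pid
        L = plen()
        for _ in range(200):
            if cls == "protein_coding":
                g = coding[rng.integers(len(coding))]
                exon = g.exons[rng.integers(len(g.exons))]
                iv = _sub_interval(exon, min(L, max(exon.length - 4, 10)), rng)
                host = ""
            elif cls == "known_lncRNA":
                g = noncoding[rng.integers(len(noncoding))]
                exon = g.exons[rng.integers(len(g.exons))]
                iv = _sub_interval(exon, min(L, max(exon.length - 4, 10)), rng)
                host = ""
            elif cls == "intronic":
                g = coding[rng.integers(len(coding))]
                introns = g.introns
                if not introns:
                    continue
                intron = introns[rng.integers(len(introns))]
                iv = _sub_interval(intron, L, rng)
                host = g.gene_id
            elif cls == "intergenic":
                chrom_spans = [s for s in spans]
                c = f"chr{int(rng.integers(cfg.n_chromosomes)) + 1}"
                on_c = [s for s in chrom_spans if s.chrom == c]
                gaps = []
                prev = 0
                for s in on_c:
                    if s.start - prev > L + 400:
                        gaps.append((prev + 200, s.start - 200))
                    prev = max(prev, s.end)
                if cfg.chromosome_length - prev > L + 400:
                    gaps.append((prev + 200, cfg.chromosome_length - 200))
                if not gaps:
                    continue
                lo, hi = gaps[rng.integers(len(gaps))]
                s0 = int(rng.integers(lo, hi - L + 1))
                iv = GenomicInterval(c, s0, s0 + L, "+" if rng.random() < 0.5 else "-")
                host = ""
            else:  # exonic: straddle an exon 3' boundary (not in defaults)
                g = coding[rng.integers(len(coding))]
                exon = g.exons[rng.integers(len(g.exons))]
                s0 = max(exon.start + 1, exon.end - L // 2)
                iv = GenomicInterval(g.chrom, s0, s0 + L, g.strand)
                host = ""
            if iv is not None:
                pid += 1
                return ProbeRecord(f"probe_{pid:05d}", iv, cls, host)
        return None

    for cls, count in cfg.probe_counts.items():
        for _ in range(count):
            rec = place(cls)
            if rec is None:
                raise ValueError(
                    f"could not place a {cls} probe; genome too small for the "
                    "requested composition"
                )
            probes.append(rec)
    return probes


def generate_genome(cfg: SimulationConfig) -> SyntheticGenome:
    sequences = _simulate_sequence(cfg, _rng(cfg.seed, "genome"))
    genes = _simulate_genes(cfg, _rng(cfg.seed, "genes"))
    probes = _simulate_probes(cfg, genes, _rng(cfg.seed, "probes"))
    return SyntheticGenome(sequences, genes, probes)


# ------------------------------------------------------------------ tracks

@dataclass
class FeatureTracks:
    h3k4me3: pd.DataFrame        # chrom, start, end, p_value, planted
    cpg_islands: pd.DataFrame    # chrom, start, end, planted
    cage_tags: pd.DataFrame      # chrom, start, end, cluster (planted id or -1)
    conserved: dict[str, pd.DataFrame]  # vertebrate / placental / primate
    small_rnas: pd.DataFrame

    def write(self, outdir) -> None:
        """BED3 for plain tracks; the peak track uses the BED6+1 dialect
        (p-value in column 7)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        def bed6(df: pd.DataFrame, extra=None) -> pd.DataFrame:
            out = df[["chrom", "start", "end"]].copy()
            out["name"] = [f"feature_{i}" for i in range(len(df))]
            out["score"] = 0
            out["strand"] = "."
            if extra is not None:
                out["extra"] = df[extra].to_numpy()
            return out

        bed6(self.h3k4me3, extra="p_value").to_csv(
            outdir / "h3k4me3.bed", sep="\t", header=False, index=False
        )
        for fname, df in (
            ("cpg_islands.bed", self.cpg_islands),
            ("cage_tags.bed", self.cage_tags),
            ("small_rnas.bed", self.small_rnas),
        ):
            df[["chrom", "start", "end"]].to_csv(
                outdir / fname, sep="\t", header=False, index=False
            )
        for name, df in self.conserved.items():
            df[["chrom", "start", "end"]].to_csv(
                outdir / f"conserved_{name}.bed", sep="\t", header=False,
                index=False,
            )


def _background_intervals(
    cfg: SimulationConfig, rng: np.random.Generator, width: int
) -> pd.DataFrame:
    rows = []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        n = rng.poisson(cfg.background_density_per_mb * cfg.chromosome_length / 1e6)
        starts = rng.integers(0, cfg.chromosome_length - width, size=n)
        for s in np.sort(starts):
            rows.append((chrom, int(s), int(s) + width))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_feature_tracks(
    cfg: SimulationConfig, genome: SyntheticGenome
) -> FeatureTracks:
    """Poisson background plus deterministic planting near probe boundaries.

    A fraction `f_enrich` of intronic probes (and intergenic probes, for the
    intergenic analyses) receives one planted H3K4me3 peak, CpG island and
    CAGE cluster within `d_enrich` bp of its 5' boundary, and one conserved
    element overlapping it.
    """
    rng = _rng(cfg.seed, "tracks")
    enrichable = [
        p for p in genome.probes if p.genomic_class in ("intronic", "intergenic")
    ]
    n_plant = int(round(cfg.f_enrich * len(enrichable)))
    planted = (
        list(rng.choice(len(enrichable), size=n_plant, replace=False))
        if n_plant
        else []
    )
    planted_probes = [enrichable[i] for i in planted]

    def near_boundary(p: ProbeRecord, width: int) -> tuple[str, int, int]:
        anchor = p.interval.five_prime
        off = int(rng.integers(0, cfg.d_enrich + 1))
        side = -1 if rng.random() < 0.5 else 1
        s = max(0, anchor + side * off - width // 2)
        return p.interval.chrom, s, s + width

    # H3K4me3: background with mixed p-values + planted strong peaks
    bg = _background_intervals(cfg, rng, cfg.peak_width)
    noisy = rng.random(len(bg)) < cfg.noisy_peak_fraction
    pvals = np.where(
        noisy,
        10 ** rng.uniform(-5, -2, size=len(bg)),     # fails the p<1e-5 filter
        10 ** rng.uniform(-12, -5.01, size=len(bg)),
    )
    h3k = bg.assign(p_value=pvals, planted=False)
    rows = []
    for p in planted_probes:
        chrom, s, e = near_boundary(p, cfg.peak_width)
        rows.append((chrom, s, e, 10 ** rng.uniform(-12, -6), True))
    h3k = pd.concat(
        [h3k, pd.DataFrame(rows, columns=h3k.columns)], ignore_index=True
    ) if rows else h3k

    # CpG islands
    cpg = _background_intervals(cfg, rng, 800).assign(planted=False)
    rows = []
    for p in planted_probes:
        chrom, s, e = near_boundary(p, 800)
        rows.append((chrom, s, e, True))
    cpg = pd.concat(
        [cpg, pd.DataFrame(rows, columns=cpg.columns)], ignore_index=True
    ) if rows else cpg

    # CAGE tags: background singleton tags + planted clusters of >= 5 tags
    tag_rows = []
    bg_tags = _background_intervals(cfg, rng, cfg.cage_tag_length)
    for r in bg_tags.itertuples():
        tag_rows.append((r.chrom, r.start, r.end, -1))
    for ci, p in enumerate(planted_probes):
        chrom, s, _ = near_boundary(p, cfg.cage_tag_length)
        for t in range(cfg.cage_tags_per_cluster):
            jitter = int(rng.integers(0, cfg.cage_tag_length // 2 + 1))
            tag_rows.append(
                (chrom, s + jitter, s + jitter + cfg.cage_tag_length, ci)
            )
    cage = pd.DataFrame(tag_rows, columns=["chrom", "start", "end", "cluster"])

    # conserved elements, one track per clade with decreasing totals
    conserved = {}
    for name, scale in (("vertebrate", 1.0), ("placental", 0.7), ("primate", 0.4)):
        bg = _background_intervals(cfg, rng, 200)
        keep = rng.random(len(bg)) < scale
        track = bg[keep].reset_index(drop=True)
        rows = []
        for p in planted_probes:
            if rng.random() < scale:
                iv = p.interval
                s = int(rng.integers(iv.start, max(iv.start + 1, iv.end - 200)))
                rows.append((iv.chrom, s, s + 200))
        if rows:
            track = pd.concat(
                [track, pd.DataFrame(rows, columns=track.columns)],
                ignore_index=True,
            )
        conserved[name] = track

    small = _background_intervals(cfg, rng, 80)
    return FeatureTracks(h3k, cpg, cage, conserved, small)


# ------------------------------------------------------------- expression

def simulate_expression_matrix(cfg: SimulationConfig, probes: list[ProbeRecord]):
    """Raw replicated intensity matrix plus the planted-signature truth table.

    Intensities are log-normal: log2 = probe baseline + sample biological
    effect + planted shift + batch offset + replicate noise, exponentiated at
    the end. Returns ``(ExpressionMatrix, truth DataFrame)``.
    """
    from .preprocess import ExpressionMatrix

    rng = _rng(cfg.seed, "expression")
    probe_ids = [p.probe_id for p in probes]
    n_probes = len(probe_ids)

    sample_rows = []
    for grp, n in cfg.samples_per_group.items():
        for i in range(n):
            sample_rows.append((f"{grp}{i + 1:02d}", grp))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "histology"])
    # batches assigned round-robin within histology so batch is never
    # confounded with group
    samples["batch"] = [
        f"batch{(i % cfg.n_batches) + 1}"
        for grp, sub in samples.groupby("histology", sort=False)
        for i in range(len(sub))
    ]

    slide_rows = []
    for r in samples.itertuples():
        for s in range(cfg.slides_per_sample):
            slide_rows.append(
                (f"{r.sample_id}_s{s + 1}", r.sample_id, r.histology, r.batch)
            )
    slides = pd.DataFrame(
        slide_rows, columns=["slide_id", "sample_id", "histology", "batch"]
    ).set_index("slide_id")

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n_probes)

    n_sig = min(cfg.signature_size, n_probes) if cfg.effect_size != 0 else 0
    sig_idx = rng.choice(n_probes, size=n_sig, replace=False) if n_sig else []
    direction = rng.choice([-1.0, 1.0], size=n_sig)
    truth = pd.DataFrame(
        {
            "probe_id": [probe_ids[i] for i in sig_idx],
            "direction": ["up" if d > 0 else "down" for d in direction],
            "effect": direction * cfg.effect_size,
            "group": cfg.signature_group,
        }
    )

    shift = np.zeros(n_probes)
    shift[list(sig_idx)] = direction * cfg.effect_size

    batch_levels = sorted(samples["batch"].unique())
    batch_shift = {b: i * cfg.batch_offset for i, b in enumerate(batch_levels)}

    cols = {}
    for r in samples.itertuples():
        bio = rng.normal(0.0, cfg.biological_sd, size=n_probes)
        mean = baseline + bio + batch_shift[r.batch]
        if r.histology == cfg.signature_group:
            mean = mean + shift
        for s in range(cfg.slides_per_sample):
            sid = f"{r.sample_id}_s{s + 1}"
            for spot in range(1, cfg.spots_per_slide + 1):
                log2 = mean + rng.normal(0.0, cfg.measurement_sd, size=n_probes)
                vals = np.exp2(log2)
                if cfg.missing_fraction > 0:
                    miss = rng.random(n_probes) < cfg.missing_fraction
                    vals = np.where(miss, np.nan, vals)
                cols[(sid, spot)] = vals

    values = pd.DataFrame(cols, index=probe_ids)
    values.columns = pd.MultiIndex.from_tuples(values.columns,
                                               names=["slide_id", "spot"])
    matrix = ExpressionMatrix(
        values, samples.set_index("sample_id")[["histology", "batch"]], slides
    )
    return matrix, truth


# ---------------------------------------------------------------- RNA-seq

def simulate_rnaseq(cfg: SimulationConfig):
    """Per-locus (up exon, intron, down exon) counts across libraries.

    Flanking exons always share a locus rate (they belong to one mRNA); the
    intron shares it only for the planted correlated fraction. Returns
    ``(counts long DataFrame, library sizes Series, truth DataFrame,
    detection matrix)``; the detection matrix (probe-level breadth input)
    marks each locus intron detected per library.
    """
    rng = _rng(cfg.seed, "rnaseq")
    libs = [f"lib{i + 1}" for i in range(cfg.n_rnaseq_libraries)]
    lib_sizes = pd.Series(
        rng.integers(
            int(0.6 * cfg.rnaseq_library_size), int(1.4 * cfg.rnaseq_library_size),
            size=len(libs),
        ),
        index=libs, name="library_size",
    )
    n_corr = int(round(cfg.correlated_fraction * cfg.n_rnaseq_loci))
    correlated = np.zeros(cfg.n_rnaseq_loci, dtype=bool)
    correlated[:n_corr] = True
    rng.shuffle(correlated)

    rows = []
    truth_rows = []
    for i in range(cfg.n_rnaseq_loci):
        locus = f"locus_{i + 1:04d}"
        lens = {
            "up_exon": int(rng.integers(150, 400)),
            "intron": int(rng.integers(300, 1200)),
            "down_exon": int(rng.integers(150, 400)),
        }
        # library-specific shared rate (log2-normal around the mean RPKM)
        exon_rate = cfg.rnaseq_mean_rpkm
        shared = exon_rate * 2 ** rng.normal(0, 1.0, size=len(libs))
        if correlated[i]:
            intron_rate = shared * 0.5
        else:
            intron_rate = (
                exon_rate * 0.5 * 2 ** rng.normal(0, 1.0, size=len(libs))
            )
        for role, L in lens.items():
            rate = intron_rate if role == "intron" else shared
            noisy = rate * 2 ** rng.normal(0, cfg.rnaseq_dispersion, size=len(libs))
            lam = noisy * L * lib_sizes.to_numpy() / 1e9
            counts = rng.poisson(lam)
            rows.append([locus, role, L] + list(counts))
        truth_rows.append((locus, bool(correlated[i])))

    counts = pd.DataFrame(
        rows, columns=["locus_id", "feature_role", "length_bp"] + libs
    )
    truth = pd.DataFrame(truth_rows, columns=["locus_id", "correlated"])
    introns = counts[counts["feature_role"] == "intron"].set_index("locus_id")
    detection = introns[libs] > 0
    return counts, lib_sizes, truth, detection


def simulate_library_detections(
    cfg: SimulationConfig, probe_ids: list[str]
) -> pd.DataFrame:
    """Per-probe, per-library detection indicators with a bimodal breadth
    (broadly expressed vs tissue-restricted transcripts)."""
    rng = _rng(cfg.seed, "rnaseq")
    n = len(probe_ids)
    libs = [f"lib{i + 1}" for i in range(cfg.n_rnaseq_libraries)]
    broad = rng.random(n) < 0.25
    p_detect = np.where(broad, 0.95, 0.15)
    mat = rng.random((n, len(libs))) < p_detect[:, None]
    return pd.DataFrame(mat, index=probe_ids, columns=libs)


# ------------------------------------------------------------------- qPCR

def simulate_qpcr(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Triplicate Ct table for target genes plus a stable reference gene.

    The planted effect is a `qpcr_group_shift` delta-Ct in metastasis samples
    (negative shift = higher expression = fold > 1 under 2^-ddCt). Returns
    ``(CtTable, truth)``.
    """
    rng = _rng(cfg.seed, "qpcr")
    genes = [f"lnc_target_{i + 1}" for i in range(cfg.qpcr_targets)]
    rows = []
    for grp, n in cfg.qpcr_samples.items():
        for i in range(n):
            sample = f"{grp[:4]}_{i + 1:02d}"
            # sample-wide loading factor moves all genes together
            loading = rng.normal(0, 0.3)
            ref = cfg.reference_ct + loading
            reps = ref + rng.normal(0, cfg.qpcr_noise_sd, size=cfg.qpcr_replicates)
            rows.append(["HMBS", sample, grp] + list(reps))
            for g in genes:
                ct = cfg.reference_ct + cfg.target_ct_offset + loading
                if grp == "metastasis":
                    ct += cfg.qpcr_group_shift
                reps = ct + rng.normal(0, cfg.qpcr_noise_sd,
                                       size=cfg.qpcr_replicates)
                rows.append([g, sample, grp] + list(reps))
    cols = ["gene", "sample", "group"] + [
        f"rep{j + 1}_ct" for j in range(cfg.qpcr_replicates)
    ]
    table = pd.DataFrame(rows, columns=cols)
    truth = pd.DataFrame(
        {"gene": genes, "shift_ct": cfg.qpcr_group_shift,
         "expected_fold": 2.0 ** -cfg.qpcr_group_shift}
    )
    return table, truth


# ------------------------------------------------------------------ bundle

def write_all(cfg: SimulationConfig, outdir) -> None:
    """Generate every input and write it under `outdir` (CLI entry point)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(cfg)
    genome.write(outdir)
    tracks = simulate_feature_tracks(cfg, genome)
    tracks.write(outdir / "tracks")
    matrix, truth = simulate_expression_matrix(cfg, genome.probes)
    long = matrix.values.stack(["slide_id", "spot"], future_stack=True)
    long.index.names = ["probe_id", "slide_id", "spot"]
    long = long.rename("intensity").reset_index()
    long.to_csv(outdir / "intensities.tsv", sep="\t", index=False)
    matrix.slides.reset_index().to_csv(outdir / "samples.tsv", sep="\t",
                                       index=False)
    counts, lib_sizes, rnaseq_truth, _ = simulate_rnaseq(cfg)
    counts.to_csv(outdir / "rnaseq_counts.tsv", sep="\t", index=False)
    lib_sizes.to_frame().to_csv(outdir / "library_sizes.tsv", sep="\t")
    ct, qpcr_truth = simulate_qpcr(cfg)
    ct.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    truth_bundle = {
        "config": asdict(cfg),
        "expression_signature": truth.to_dict(orient="records"),
        "rnaseq_correlated": rnaseq_truth.to_dict(orient="records"),
        "qpcr": qpcr_truth.to_dict(orient="records"),
    }
    (outdir / "truth.json").write_text(json.dumps(truth_bundle, indent=2,
                                                  default=str))
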