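"""High-level replicate workflows chaining the generators to the analyses.

These are the units that calibration and power studies run many times: one
seeded synthetic world in, one decision/performance measurement out. They
are also what the demonstration script drives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import context as ctx
from . import diffexpr as de
from . import preprocess as pp
from .intervals import (
    GenomeGC,
    GenomicInterval,
    ProbeRecord,
    intron_intervals,
    probe_frame,
)
from .simulate import (
    SimulationConfig,
    generate_genome,
    simulate_expression_matrix,
    simulate_feature_tracks,
)


def ks_decision_replicate(
    seed: int,
    f_enrich: float,
    n_query: int = 100,
    n_sets: int = 100,
    d_enrich: int = 500,
    track: str = "h3k4me3",
) -> ctx.EnrichmentDecision:
    """One matched-null KS experiment on a fresh synthetic genome.

    Generates a compact genome whose intronic probes are the query set,
    plants features near a fraction `f_enrich` of them, draws `n_sets`
    GC/length-matched null sets from the intron space, and runs the strict
    all-p<alpha KS decision against the peak track.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_chromosomes=2,
        chromosome_length=1_000_000,
        n_genes=40,
        n_noncoding_genes=4,
        probe_counts={
            "protein_coding": 5,
            "known_lncRNA": 2,
            "intronic": n_query,
            "intergenic": 10,
        },
        f_enrich=f_enrich,
        d_enrich=d_enrich,
    )
    genome = generate_genome(cfg)
    tracks = simulate_feature_tracks(cfg, genome)
    gc = GenomeGC(genome.sequences)
    pf = probe_frame(genome.probes)
    query = pf[pf["genomic_class"] == "intronic"]
    space = intron_intervals(genome.genes)
    nulls = ctx.sample_matched_null(
        query, space, gc, n_sets=n_sets, seed=seed, space="intronic"
    )
    if track == "h3k4me3":
        feats = ctx.filter_peaks(tracks.h3k4me3)
    elif track == "cpg":
        feats = tracks.cpg_islands
    else:
        raise ValueError(f"unknown track {track!r}")
    feats = ctx.remove_5utr_features(feats, genome.genes)
    obs = ctx.nearest_distance(query, feats, mode="boundary")
    null_dists = [
        ctx.nearest_distance(s.set_index("query_id"), feats, mode="boundary")
        for s in nulls.sets
    ]
    return ctx.ks_enrichment(obs, null_dists)


@dataclass
class SamPerformance:
    sensitivity: float
    fdp: float
    n_called: int


def _flat_probes(n: int) -> list[ProbeRecord]:
    return [
        ProbeRecord(
            f"p{i:04d}", GenomicInterval("chr1", 100 * i + 1, 100 * i + 60),
            "intronic",
        )
        for i in range(n)
    ]


def sam_replicate(
    seed: int,
    n_probes: int = 1000,
    signature_size: int = 50,
    effect_size: float = 1.0,
    n_perm: int = 1000,
    fdr_threshold: float = 0.10,
) -> SamPerformance:
    """One planted-signature SAM experiment: 15 tumor vs 9 normal samples,
    replicates collapsed to per-sample log2 means, no batch structure.

    Returns sensitivity over the planted set and the realized false
    discovery proportion.
    """
    cfg = SimulationConfig(
        seed=seed,
        samples_per_group={"NT": 9, "T": 15},
        n_batches=1,
        missing_fraction=0.0,
        signature_size=signature_size,
        effect_size=effect_size,
    )
    probes = _flat_probes(n_probes)
    matrix, truth = simulate_expression_matrix(cfg, probes)
    log2 = pp.ExpressionMatrix(
        np.log2(matrix.values), matrix.samples, matrix.slides
    )
    collapsed = pp.collapse_replicates(log2)
    result = de.sam_two_class(
        collapsed.values, collapsed.samples["histology"], ("T", "NT"),
        n_perm=n_perm, fdr_threshold=fdr_threshold, seed=seed,
    )
    called = set(result.called)
    planted = set(truth["probe_id"])
    tp = len(called & planted)
    sensitivity = tp / len(planted) if planted else float("nan")
    fdp = (len(called) - tp) / len(called) if called else 0.0
    return SamPerformance(sensitivity, fdp, len(called))


def batch_false_positive_rate(
    seed: int, adjust: bool, batch_offset: float = 1.0, n_probes: int = 400
) -> float:
    """Call rate of SAM at FDR 10% on null data whose batches are unevenly
    distributed over the two histology groups (partial confounding), with
    and without batch adjustment."""
    cfg = SimulationConfig(
        seed=seed,
        samples_per_group={"NT": 9, "T": 15},
        n_batches=2,
        batch_offset=batch_offset,
        missing_fraction=0.0,
        effect_size=0.0,
    )
    probes = _flat_probes(n_probes)
    matrix, _ = simulate_expression_matrix(cfg, probes)
    # skew batch membership toward one group to make batch matter
    samples = matrix.samples.copy()
    ids = list(samples.index)
    t_ids = [s for s in ids if samples.loc[s, "histology"] == "T"]
    nt_ids = [s for s in ids if samples.loc[s, "histology"] == "NT"]
    for s in t_ids[: len(t_ids) * 3 // 4]:
        samples.loc[s, "batch"] = "batch1"
    for s in nt_ids[: len(nt_ids) * 3 // 4]:
        samples.loc[s, "batch"] = "batch2"
    rng = np.random.default_rng([seed, 99])
    offsets = {
        b: i * batch_offset for i, b in enumerate(sorted(samples["batch"].unique()))
    }
    log2 = np.log2(matrix.values)
    # re-apply the skewed batch offsets at the slide level
    for sid in matrix.slides.index:
        sample = matrix.slides.loc[sid, "sample_id"]
        old = matrix.slides.loc[sid, "batch"]
        new = samples.loc[sample, "batch"]
        if old != new:
            log2[sid] = log2[sid] + (offsets[new] - offsets[old])
    slides = matrix.slides.copy()
    slides["batch"] = samples.loc[slides["sample_id"], "batch"].to_numpy()
    m = pp.ExpressionMatrix(log2, samples, slides)
    collapsed = pp.collapse_replicates(m)
    if adjust:
        collapsed = pp.batch_adjust(collapsed)
    result = de.sam_two_class(
        collapsed.values, collapsed.samples["histology"], ("T", "NT"),
        n_perm=300, fdr_threshold=0.10, seed=seed,
    )
    return int(result.table["called"].sum()) / n_probes
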