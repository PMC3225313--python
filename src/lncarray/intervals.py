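"""Genomic interval model and probe classification.

Coordinates are 0-based, half-open ``[start, end)`` throughout the package.
Probes (EST-derived array elements) are classified against a set of gene
models into the five genomic classes used on the array platform:

* ``protein_coding`` -- fully inside exonic space of a coding gene;
* ``exonic``         -- overlaps an exon/intron boundary (possible intron
                        retention; excluded from the lncRNA classes);
* ``intronic``       -- fully inside one intron of a coding gene, touching
                        no exon;
* ``known_lncRNA``   -- fully inside a noncoding-biotype gene model;
* ``intergenic``     -- overlaps no annotated gene span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

GENOMIC_CLASSES = (
    "protein_coding",
    "known_lncRNA",
    "intronic",
    "intergenic",
    "exonic",
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware half-open genomic span ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Strand-aware 5' anchor; falls back to `start` on unknown strand."""
        return self.end - 1 if self.strand == "-" else self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Unsigned gap in bp; 0 for overlapping or adjacent intervals."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        if self.overlaps(other):
            return 0
        return max(other.start - self.end, self.start - other.end, 0)

    def extended(self, pad: int) -> "GenomicInterval":
        """Pad both ends by `pad` bp, clamping start at 0."""
        return GenomicInterval(
            self.chrom, max(0, self.start - pad), self.end + pad, self.strand
        )


@dataclass
class GeneModel:
    """A gene as an ordered, non-overlapping exon chain plus UTR annotation."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    biotype: str = "protein_coding"  # or "noncoding"
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        if self.biotype not in ("protein_coding", "noncoding"):
            raise ValueError(f"unknown biotype {self.biotype!r}")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    @property
    def utrs(self) -> list[GenomicInterval]:
        return list(self.utr5) + list(self.utr3)


@dataclass(frozen=True)
class ProbeRecord:
    """An array probe with its genomic class and (for intronic) host locus."""

    probe_id: str
    interval: GenomicInterval
    genomic_class: str
    host_gene_id: str = ""
    alignment_identity: float = 1.0
    alignment_coverage: float = 1.0

    def __post_init__(self) -> None:
        if self.genomic_class not in GENOMIC_CLASSES:
            raise ValueError(f"unknown genomic class {self.genomic_class!r}")


@dataclass(frozen=True)
class AlignmentRecord:
    probe_id: str
    interval: GenomicInterval
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ValueError("identity and coverage must lie in [0, 1]")


def index_genes(genes: Iterable[GeneModel]) -> dict[str, list[GeneModel]]:
    """Group gene models by chromosome, sorted by span start."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.span.start)
    return by_chrom


def classify_probe(
    interval: GenomicInterval,
    genes: Iterable[GeneModel] | Mapping[str, list[GeneModel]],
) -> tuple[str, str]:
    """Assign one of the five genomic classes to `interval`.

    Returns ``(genomic_class, host_gene_id)``; the host is set only for the
    intronic class. Exon overlap dominates: a probe touching any coding exon
    can never be intronic/intergenic. A probe on a chromosome absent from the
    annotation is intergenic (with a warning).
    """
    if not isinstance(genes, Mapping):
        genes = index_genes(genes)
    if interval.chrom not in genes:
        warnings.warn(
            f"chromosome {interval.chrom!r} absent from gene set; "
            "classifying probe as intergenic",
            stacklevel=2,
        )
        return "intergenic", ""

    hits = [g for g in genes[interval.chrom] if g.span.overlaps(interval)]
    if not hits:
        return "intergenic", ""

    coding = [g for g in hits if g.biotype == "protein_coding"]
    coding_exons = [e for g in coding for e in g.exons]
    exon_overlaps = [e for e in coding_exons if e.overlaps(interval)]
    if exon_overlaps:
        covered = _covered_by_exons(interval, exon_overlaps)
        return ("protein_coding" if covered else "exonic"), ""

    for g in coding:
        for intron in g.introns:
            if intron.contains(interval):
                return "intronic", g.gene_id

    noncoding = [g for g in hits if g.biotype == "noncoding"]
    if noncoding:
        # fully-contained is the defining case; partial overlap with a
        # noncoding model (and nothing coding) still counts as known lncRNA
        return "known_lncRNA", ""

    # overlaps a coding span but neither exon nor a single intron contains it:
    # straddles annotation without touching exons -- treat as exonic boundary
    return "exonic", ""


def _covered_by_exons(
    interval: GenomicInterval, exons: Sequence[GenomicInterval]
) -> bool:
    """True iff the union of `exons` covers `interval` completely."""
    pieces = sorted(
        (max(e.start, interval.start), min(e.end, interval.end))
        for e in exons
        if e.overlaps(interval)
    )
    pos = interval.start
    for s, e in pieces:
        if s > pos:
            return False
        pos = max(pos, e)
    return pos >= interval.end


def classify_probes(
    intervals: Mapping[str, GenomicInterval],
    genes: Iterable[GeneModel] | Mapping[str, list[GeneModel]],
) -> list[ProbeRecord]:
    """Classify a named probe set; convenience wrapper over `classify_probe`."""
    if not isinstance(genes, Mapping):
        genes = index_genes(genes)
    records = []
    for probe_id, iv in intervals.items():
        cls, host = classify_probe(iv, genes)
        records.append(ProbeRecord(probe_id, iv, cls, host))
    return records


def filter_alignments(
    records: Iterable[AlignmentRecord],
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
) -> list[AlignmentRecord]:
    """Keep alignments with identity AND coverage at or above the thresholds.

    Both boundaries are inclusive ("at least 90%").
    """
    if not (0.0 <= min_identity <= 1.0 and 0.0 <= min_coverage <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    return [
        r
        for r in records
        if r.identity >= min_identity and r.coverage >= min_coverage
    ]


def gc_content(interval: GenomicInterval, genome) -> float:
    """GC fraction of `interval`, case-insensitive; N/ambiguous bases are
    excluded from numerator and denominator. Returns NaN if no unambiguous
    base remains.

    `genome` is any mapping of chromosome name to a sliceable sequence
    (dict of str, pyfaidx.Fasta, ...).
    """
    seq = str(genome[interval.chrom][interval.start : interval.end]).upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


class GenomeGC:
    """O(1) GC lookup over a genome via per-chromosome prefix sums.

    Used heavily by the matched-null sampler where millions of candidate
    intervals are scored.
    """

    def __init__(self, genome: Mapping[str, str]):
        self._gc: dict[str, np.ndarray] = {}
        self._acgt: dict[str, np.ndarray] = {}
        self.lengths: dict[str, int] = {}
        for chrom in genome.keys():
            seq = np.frombuffer(str(genome[chrom]).upper().encode(), dtype="S1")
            is_gc = (seq == b"G") | (seq == b"C")
            is_at = (seq == b"A") | (seq == b"T")
            self._gc[chrom] = np.concatenate(
                ([0], np.cumsum(is_gc, dtype=np.int64))
            )
            self._acgt[chrom] = np.concatenate(
                ([0], np.cumsum(is_gc | is_at, dtype=np.int64))
            )
            self.lengths[chrom] = len(seq)

    def gc(self, chrom: str, start, end) -> np.ndarray:
        """Vectorized GC fraction for arrays of starts/ends on one chromosome."""
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        gc = self._gc[chrom][end] - self._gc[chrom][start]
        n = self._acgt[chrom][end] - self._acgt[chrom][start]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, gc / np.maximum(n, 1), np.nan)

    def gc_interval(self, interval: GenomicInterval) -> float:
        return float(self.gc(interval.chrom, interval.start, interval.end))


def probe_frame(probes: Iterable[ProbeRecord]) -> pd.DataFrame:
    """Probe intervals as a chrom/start/end/strand frame indexed by probe id."""
    rows = [
        (p.probe_id, p.interval.chrom, p.interval.start, p.interval.end,
         p.interval.strand, p.genomic_class)
        for p in probes
    ]
    return pd.DataFrame(
        rows,
        columns=["probe_id", "chrom", "start", "end", "strand",
                 "genomic_class"],
    ).set_index("probe_id")


def intron_intervals(genes: Iterable[GeneModel]) -> list[GenomicInterval]:
    """All introns of protein-coding genes (the intronic sampling space)."""
    return [
        intron
        for g in genes
        if g.biotype == "protein_coding"
        for intron in g.introns
    ]


def intergenic_intervals(
    genes: Iterable[GeneModel], chrom_lengths: Mapping[str, int]
) -> list[GenomicInterval]:
    """Complement of gene spans per chromosome (the intergenic space)."""
    spans: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        spans.setdefault(g.chrom, []).append(g.span)
    out = []
    for chrom, length in chrom_lengths.items():
        prev = 0
        for s in sorted(spans.get(chrom, []), key=lambda s: s.start):
            if s.start > prev:
                out.append(GenomicInterval(chrom, prev, s.start))
            prev = max(prev, s.end)
        if length > prev:
            out.append(GenomicInterval(chrom, prev, length))
    return out


def utr_proximity(
    probes: Iterable[ProbeRecord],
    genes: Iterable[GeneModel],
    max_dist: int = 1000,
) -> pd.DataFrame:
    """Flag intergenic probes as near_UTR/distal by gap to the nearest UTR.

    The `max_dist` boundary is inclusive ("within 1 kb"); overlap counts as
    gap 0.
    """
    utrs_by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in genes:
        for u in g.utrs:
            utrs_by_chrom.setdefault(u.chrom, []).append(u)
    rows = []
    for p in probes:
        best = None
        for u in utrs_by_chrom.get(p.interval.chrom, []):
            d = p.interval.gap_to(u)
            best = d if best is None else min(best, d)
        flag = "near_UTR" if best is not None and best <= max_dist else "distal"
        rows.append((p.probe_id, best if best is not None else np.nan, flag))
    return pd.DataFrame(rows, columns=["probe_id", "utr_distance", "flag"]).set_index(
        "probe_id"
    )


def small_rna_overlap(
    probes: Iterable[ProbeRecord],
    small_rnas: Iterable[GenomicInterval],
    extension: int = 1000,
) -> pd.DataFrame:
    """Report small-RNA overlap per probe, unextended and with a +/- pad.

    The pad mimics extending EST probe coordinates to the typical length of a
    microRNA precursor; a start pushed below 0 is clamped.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for s in small_rnas:
        by_chrom.setdefault(s.chrom, []).append(s)
    rows = []
    for p in probes:
        cands = by_chrom.get(p.interval.chrom, [])
        plain = any(p.interval.overlaps(s) for s in cands)
        padded = p.interval.extended(extension)
        ext = any(padded.overlaps(s) for s in cands)
        rows.append((p.probe_id, plain, ext))
    return pd.DataFrame(
        rows, columns=["probe_id", "hit", "hit_extended"]
    ).set_index("probe_id")
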