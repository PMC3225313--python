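"""Readers and writers for BED, GFF3, FASTA and the package's TSV tables.

BED is handled natively in the internal 0-based half-open convention; GFF3
(1-based, closed) is converted on ingestion. ChIP peak tracks use a
"BED6+1" dialect with the peak p-value in a seventh column.
"""

from __future__ import annotations

import textwrap
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pyfaidx

from .intervals import GeneModel, GenomicInterval, ProbeRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6(+1) into a DataFrame with canonical column names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    if ncol < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    cols = BED6_COLUMNS[: min(ncol, 6)]
    if ncol == 7:
        cols = BED6_COLUMNS + ["p_value"]
    df.columns = cols + list(df.columns[len(cols) :])
    if "strand" not in df:
        df["strand"] = "."
    if "name" not in df:
        df["name"] = [f"feature_{i}" for i in range(len(df))]
    return df


def bed_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]


def read_bed_intervals(path) -> list[GenomicInterval]:
    return bed_to_intervals(read_bed(path))


def write_bed(
    intervals: Iterable[GenomicInterval],
    path,
    names: Iterable[str] | None = None,
    scores: Iterable | None = None,
    p_values: Iterable[float] | None = None,
) -> None:
    ivs = list(intervals)
    names = list(names) if names is not None else [
        f"feature_{i}" for i in range(len(ivs))
    ]
    scores = list(scores) if scores is not None else [0] * len(ivs)
    pvals = list(p_values) if p_values is not None else None
    rows = []
    for i, iv in enumerate(ivs):
        row = [iv.chrom, iv.start, iv.end, names[i], scores[i], iv.strand]
        if pvals is not None:
            row.append(pvals[i])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_probes_bed(probes: Iterable[ProbeRecord], path) -> None:
    """BED6 with ``probe_id|genomic_class`` in the name field."""
    probes = list(probes)
    write_bed(
        (p.interval for p in probes),
        path,
        names=[f"{p.probe_id}|{p.genomic_class}" for p in probes],
    )


def read_probes_bed(path) -> list[ProbeRecord]:
    df = read_bed(path)
    records = []
    for r in df.itertuples():
        probe_id, cls = str(r.name).split("|", 1)
        records.append(
            ProbeRecord(
                probe_id,
                GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand),
                cls,
            )
        )
    return records


# ---------------------------------------------------------------- GFF3

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        span = g.span
        biotype = g.biotype
        lines.append(
            "\t".join(
                [
                    g.chrom, "lncarray", "gene", str(span.start + 1),
                    str(span.end), ".", g.strand, ".",
                    f"ID={g.gene_id};biotype={biotype}",
                ]
            )
        )
        for kind, parts in (
            ("exon", g.exons),
            ("five_prime_UTR", g.utr5),
            ("three_prime_UTR", g.utr3),
        ):
            for i, e in enumerate(parts):
                lines.append(
                    "\t".join(
                        [
                            g.chrom, "lncarray", kind, str(e.start + 1),
                            str(e.end), ".", g.strand, ".",
                            f"ID={g.gene_id}.{kind}.{i};Parent={g.gene_id}",
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _attr(attributes: str, key: str) -> str:
    for part in attributes.split(";"):
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return ""


def read_gff3(path) -> list[GeneModel]:
    """Read gene/exon/UTR features into GeneModels (GFF3 1-based -> 0-based)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=_GFF_COLS
    )
    order: list[str] = []
    meta: dict[str, tuple[str, str, str]] = {}
    for r in df[df["type"] == "gene"].itertuples():
        gid = _attr(r.attributes, "ID")
        order.append(gid)
        meta[gid] = (
            r.seqid,
            r.strand,
            _attr(r.attributes, "biotype") or "protein_coding",
        )
    parts: dict[str, dict[str, list[GenomicInterval]]] = {
        gid: {"exon": [], "five_prime_UTR": [], "three_prime_UTR": []}
        for gid in order
    }
    for r in df[df["type"].isin(["exon", "five_prime_UTR", "three_prime_UTR"])].itertuples():
        gid = _attr(r.attributes, "Parent")
        chrom, strand, _ = meta[gid]
        parts[gid][r.type].append(
            GenomicInterval(chrom, int(r.start) - 1, int(r.end), strand)
        )
    out = []
    for gid in order:
        chrom, strand, biotype = meta[gid]
        out.append(
            GeneModel(
                gid, chrom, strand,
                exons=parts[gid]["exon"],
                biotype=biotype,
                utr5=parts[gid]["five_prime_UTR"],
                utr3=parts[gid]["three_prime_UTR"],
            )
        )
    return out


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            fh.write("\n".join(textwrap.wrap(str(seq), width)))
            fh.write("\n")


def read_fasta(path) -> pyfaidx.Fasta:
    """Indexed FASTA access; sequences slice like strings."""
    return pyfaidx.Fasta(str(path))
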