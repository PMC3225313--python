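"""Matched-null enrichment engine for promoter-associated genomic features.

Tests whether a query interval set (e.g. intronic lncRNA loci) sits closer
to promoter-associated features (H3K4me3 peaks, CpG islands, CAGE tag
clusters) than expected by chance. The null model is a collection of
random interval sets drawn from a declared genomic space (intronic or
intergenic regions), matched 1:1 to the query in number, length and GC
content. The decision rule is deliberately strict: the observed distance
distribution is declared enriched only if the two-sample KS test rejects
against EVERY one of the null sets (all p < alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, GenomicInterval, GenomeGC


# -------------------------------------------------------------- features

def filter_peaks(peaks: pd.DataFrame, p_threshold: float = 1e-5) -> pd.DataFrame:
    """Keep peaks with p strictly below `p_threshold` (noise filter)."""
    if "p_value" not in peaks.columns:
        raise ValueError("peak table lacks a p_value column")
    return peaks[peaks["p_value"] < p_threshold].reset_index(drop=True)


@dataclass
class CageTagCluster:
    interval: GenomicInterval
    tag_count: int


def cluster_cage_tags(tags: pd.DataFrame, min_tags: int = 5) -> pd.DataFrame:
    """Single-linkage merge of overlapping tags; clusters with fewer than
    `min_tags` members are discarded. The cluster interval is the union
    span of its member tags. Returns chrom/start/end/tag_count."""
    rows = []
    for chrom, sub in tags.groupby("chrom"):
        sub = sub.sort_values("start", kind="stable")
        cur_s = cur_e = None
        n = 0
        for r in sub.itertuples():
            if cur_e is None or r.start >= cur_e:  # half-open: touch != overlap
                if cur_e is not None and n >= min_tags:
                    rows.append((chrom, cur_s, cur_e, n))
                cur_s, cur_e, n = r.start, r.end, 1
            else:
                cur_e = max(cur_e, r.end)
                n += 1
        if cur_e is not None and n >= min_tags:
            rows.append((chrom, cur_s, cur_e, n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tag_count"])


def remove_5utr_features(
    features: pd.DataFrame, genes: list[GeneModel], window: int = 0
) -> pd.DataFrame:
    """Drop features overlapping any annotated 5'UTR (optionally padded).

    Removes the contribution of known-gene start sites before measuring
    promoter-feature enrichment near the query transcripts.
    """
    utrs: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        for u in g.utr5:
            utrs.setdefault(u.chrom, []).append(
                (max(0, u.start - window), u.end + window)
            )
    if not any(utrs.values()):
        warnings.warn("gene models carry no 5'UTR annotation; no-op",
                      stacklevel=2)
        return features.reset_index(drop=True)
    keep = []
    for r in features.itertuples():
        hit = any(
            r.start < e and s < r.end for s, e in utrs.get(r.chrom, [])
        )
        keep.append(not hit)
    return features[np.asarray(keep, dtype=bool)].reset_index(drop=True)


# ----------------------------------------------------------- matched null

@dataclass
class MatchedNullCollection:
    """100-ish random interval sets matched 1:1 to a query set.

    Every null interval has exactly the length of its query partner, lies
    inside the declared sampling space, and matches its partner's GC content
    within the recorded achieved tolerance (the base tolerance doubles each
    time `max_attempts` candidates are exhausted).
    """

    sets: list[pd.DataFrame]     # chrom, start, end, gc, achieved_tol, query_id
    space: str
    gc_tolerance: float
    seed: int

    @property
    def n_sets(self) -> int:
        return len(self.sets)


def sample_matched_null(
    query: pd.DataFrame,
    space_intervals: list[GenomicInterval],
    genome_gc: GenomeGC,
    n_sets: int = 100,
    gc_tol: float = 0.02,
    max_attempts: int = 1000,
    seed: int = 0,
    space: str = "intronic",
) -> MatchedNullCollection:
    """Draw `n_sets` random interval sets matched to `query` in number,
    length and GC content, from within `space_intervals`.

    `query` needs chrom/start/end columns; GC is computed via `genome_gc`.
    Candidates are drawn uniformly over positions in the pool that fit the
    exact query length; the first candidate within the (adaptively doubled)
    GC tolerance is accepted.
    """
    rng = np.random.default_rng(seed)
    pool = sorted(space_intervals, key=lambda iv: (iv.chrom, iv.start))
    pool_chroms = np.array([iv.chrom for iv in pool])
    pool_starts = np.array([iv.start for iv in pool])
    pool_ends = np.array([iv.end for iv in pool])
    pool_lens = pool_ends - pool_starts

    q_len = (query["end"] - query["start"]).to_numpy()
    if (q_len > pool_lens.max()).any():
        bad = query.index[q_len > pool_lens.max()][0]
        raise ValueError(
            f"query interval {bad!r} is longer than every pool region"
        )
    q_gc = np.array(
        [float(genome_gc.gc(r.chrom, r.start, r.end)) for r in query.itertuples()]
    )

    # accepted[qi][si] = (chrom, start, gc, tol)
    accepted: list[list[tuple]] = []
    batch = 256
    for qi in range(len(query)):
        L = int(q_len[qi])
        target = q_gc[qi]
        fits = pool_lens >= L
        fit_idx = np.where(fits)[0]
        weights = (pool_lens[fit_idx] - L + 1).astype(float)
        cumw = np.cumsum(weights)

        def draw(m: int):
            """m candidate (chrom, start, gc) triples, uniform over positions."""
            r = np.searchsorted(cumw, rng.random(m) * cumw[-1], side="right")
            ridx = fit_idx[r]
            offs = rng.integers(0, pool_lens[ridx] - L + 1)
            starts = pool_starts[ridx] + offs
            gcs = np.empty(m)
            chroms = pool_chroms[ridx]
            for chrom in np.unique(chroms):
                sel = chroms == chrom
                gcs[sel] = genome_gc.gc(chrom, starts[sel], starts[sel] + L)
            return chroms, starts, gcs

        per_query: list[tuple] = []
        tol = gc_tol
        attempts = 0
        buf_c, buf_s, buf_g = draw(batch)
        pos = 0
        while len(per_query) < n_sets:
            if pos >= len(buf_s):
                buf_c, buf_s, buf_g = draw(batch)
                pos = 0
            c, s, g = buf_c[pos], int(buf_s[pos]), float(buf_g[pos])
            pos += 1
            attempts += 1
            if np.isnan(target) or abs(g - target) <= tol:
                per_query.append((c, s, g, tol))
                attempts = 0
            elif attempts >= max_attempts:
                tol *= 2.0
                attempts = 0
        accepted.append(per_query)

    sets = []
    for si in range(n_sets):
        rows = [
            (
                accepted[qi][si][0], accepted[qi][si][1],
                accepted[qi][si][1] + int(q_len[qi]), accepted[qi][si][2],
                accepted[qi][si][3], query.index[qi],
            )
            for qi in range(len(query))
        ]
        sets.append(
            pd.DataFrame(
                rows,
                columns=["chrom", "start", "end", "gc", "achieved_tol",
                         "query_id"],
            )
        )
    return MatchedNullCollection(sets, space, gc_tol, seed)


# ------------------------------------------------------------- distances

@dataclass
class DistanceDistribution:
    """Capped nearest-feature distances for one query set vs one track."""

    distances: pd.Series        # per query id; NaN where censored
    max_dist: int
    mode: str

    @property
    def uncensored(self) -> np.ndarray:
        return self.distances.dropna().to_numpy()

    @property
    def n_censored(self) -> int:
        return int(self.distances.isna().sum())


def _nearest_gap(q_start, q_end, f_starts, f_ends) -> float:
    """Minimal unsigned gap from [q_start, q_end) to sorted features on one
    chromosome; 0 on overlap. Features sorted by start with cummax'd ends."""
    i = np.searchsorted(f_starts, q_end, side="left")
    best = np.inf
    if i < len(f_starts):
        best = min(best, f_starts[i] - q_end)
    if i > 0:
        # closest preceding feature end (ends cummax'd so index i-1 has the
        # rightmost end among features starting before q_end)
        e = f_ends[i - 1]
        if e > q_start:
            return 0.0
        best = min(best, q_start - e)
    return float(best)


def nearest_distance(
    query: pd.DataFrame,
    features: pd.DataFrame,
    mode: str = "boundary",
    max_dist: int = 10_000,
) -> DistanceDistribution:
    """Nearest-feature distance per query interval, censored above `max_dist`.

    boundary mode: 0 on overlap, else the minimal gap between the feature
    and either query boundary. five_prime_start mode: distance to the
    strand-aware 5' end of the query (unknown strand falls back to boundary
    mode for that query). The `max_dist` cap is inclusive.
    """
    if mode not in ("boundary", "five_prime_start"):
        raise ValueError(f"unknown mode {mode!r}")
    feats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in features.groupby("chrom"):
        sub = sub.sort_values("start", kind="stable")
        starts = sub["start"].to_numpy()
        ends = np.maximum.accumulate(sub["end"].to_numpy())
        feats[chrom] = (starts, ends)
    empty = len(features) == 0

    out = {}
    for r in query.itertuples():
        chrom = r.chrom
        if empty or chrom not in feats:
            out[r.Index] = np.nan
            continue
        f_starts, f_ends = feats[chrom]
        strand = getattr(r, "strand", ".")
        if mode == "five_prime_start" and strand in ("+", "-"):
            point = r.end - 1 if strand == "-" else r.start
            d = _nearest_gap(point, point + 1, f_starts, f_ends)
        else:
            d = _nearest_gap(r.start, r.end, f_starts, f_ends)
        out[r.Index] = d if d <= max_dist else np.nan
    dist = pd.Series(out, name="distance")
    if empty:
        warnings.warn("empty feature track: all query distances censored",
                      stacklevel=2)
    return DistanceDistribution(dist, max_dist, mode)


# --------------------------------------------------------------- decision

@dataclass
class EnrichmentDecision:
    p_values: np.ndarray
    alpha: float
    all_significant: bool
    untestable: bool = False
    reason: str = ""


def ks_enrichment(
    observed: DistanceDistribution,
    nulls: list[DistanceDistribution],
    alpha: float = 0.05,
    min_n: int = 10,
    method: str = "asymp",
) -> EnrichmentDecision:
    """Two-sample two-sided KS of the observed distances against each null
    set; enrichment is declared only if every p-value is below `alpha`."""
    obs = observed.uncensored
    if len(obs) < min_n:
        return EnrichmentDecision(
            np.array([]), alpha, False, untestable=True,
            reason=f"only {len(obs)} uncensored observed distances",
        )
    ps = []
    for nd in nulls:
        x = nd.uncensored
        if len(x) < min_n:
            return EnrichmentDecision(
                np.array([]), alpha, False, untestable=True,
                reason="a null set has too few uncensored distances",
            )
        ps.append(stats.ks_2samp(obs, x, method=method).pvalue)
    ps = np.asarray(ps)
    return EnrichmentDecision(ps, alpha, bool((ps < alpha).all()))


def distance_histogram(
    distributions: dict[str, DistanceDistribution | list[DistanceDistribution]],
    bin_width: int,
) -> pd.DataFrame:
    """Binned distance counts per series ([k*w, (k+1)*w) bins + censored).

    A list-valued series (the null collection) is reported as the per-bin
    mean over its sets plus min/max envelope columns.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    max_dist = None
    for v in distributions.values():
        dd = v[0] if isinstance(v, list) else v
        max_dist = dd.max_dist if max_dist is None else max(max_dist, dd.max_dist)
    edges = np.arange(0, max_dist + 2 * bin_width, bin_width)
    labels = [f"[{edges[i]},{edges[i + 1]})" for i in range(len(edges) - 1)]

    def counts(dd: DistanceDistribution) -> np.ndarray:
        h, _ = np.histogram(dd.uncensored, bins=edges)
        return h

    out = {}
    for name, v in distributions.items():
        if isinstance(v, list):
            mat = np.vstack([counts(dd) for dd in v])
            out[f"{name}_mean"] = mat.mean(axis=0)
            out[f"{name}_min"] = mat.min(axis=0)
            out[f"{name}_max"] = mat.max(axis=0)
            out[f"{name}_censored"] = np.mean([dd.n_censored for dd in v])
        else:
            out[name] = counts(v)
            out[f"{name}_censored"] = v.n_censored
    return pd.DataFrame(out, index=pd.Index(labels, name="bin"))


def conserved_overlap_enrichment(
    query: pd.DataFrame,
    nulls: MatchedNullCollection,
    tracks: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per conservation track: query overlap count, the normalized bar value
    (overlapping queries / total elements in the track), and a one-sided
    Fisher exact p against the pooled null sets."""
    rows = []
    for name, track in tracks.items():
        if len(track) == 0:
            raise ValueError(f"empty conserved track {name!r}")
        if len(query) == 0:
            rows.append((name, 0, np.nan, np.nan, np.nan, "untestable"))
            continue
        q_hits = _count_overlapping(query, track)
        null_hits = sum(_count_overlapping(s, track) for s in nulls.sets)
        null_total = sum(len(s) for s in nulls.sets)
        table = [
            [q_hits, len(query) - q_hits],
            [null_hits, null_total - null_hits],
        ]
        p = stats.fisher_exact(table, alternative="greater").pvalue
        rows.append(
            (
                name, q_hits, q_hits / len(track),
                null_hits / null_total if null_total else np.nan, p,
                "significant" if p < alpha else "ns",
            )
        )
    return pd.DataFrame(
        rows,
        columns=["track", "query_overlap", "normalized_overlap",
                 "null_overlap_fraction", "fisher_p", "call"],
    ).set_index("track")


def _count_overlapping(query: pd.DataFrame, track: pd.DataFrame) -> int:
    """Number of query intervals overlapping >= 1 track element."""
    n = 0
    feats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in track.groupby("chrom"):
        sub = sub.sort_values("start", kind="stable")
        feats[chrom] = (
            sub["start"].to_numpy(),
            np.maximum.accumulate(sub["end"].to_numpy()),
        )
    for r in query.itertuples():
        if r.chrom not in feats:
            continue
        f_starts, f_ends = feats[r.chrom]
        if _nearest_gap(r.start, r.end, f_starts, f_ends) == 0:
            n += 1
    return n


def expression_breadth(
    probe_ids: list[str], detections: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Per-probe count of libraries where the probe is detected, plus the
    grouped histogram over counts (0..n_libraries)."""
    sub = detections.reindex(probe_ids, fill_value=False)
    counts = sub.sum(axis=1).astype(int)
    hist = counts.value_counts().reindex(
        range(detections.shape[1] + 1), fill_value=0
    )
    hist.index.name = "n_libraries"
    return counts, hist
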