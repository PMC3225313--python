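"""Matched-null engine: peak/CAGE preprocessing, nearest distances with a
brute-force oracle, KS decision rule and Fisher conserved-element test."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from lncarray import context as ctx
from lncarray.intervals import (
    GenomeGC,
    GenomicInterval,
    intron_intervals,
    probe_frame,
)
from lncarray.simulate import SimulationConfig, generate_genome, simulate_feature_tracks


def _df(rows, cols=("chrom", "start", "end")):
    return pd.DataFrame(rows, columns=list(cols))


class TestFilterPeaks:
    def test_strict_inequality_boundary(self):
        peaks = _df(
            [("chr1", 0, 10, 1e-6), ("chr1", 20, 30, 1e-5), ("chr1", 40, 50, 0.01)],
            cols=("chrom", "start", "end", "p_value"),
        )
        out = ctx.filter_peaks(peaks)
        assert out["start"].tolist() == [0]

    def test_empty_input(self):
        out = ctx.filter_peaks(
            _df([], cols=("chrom", "start", "end", "p_value"))
        )
        assert out.empty


class TestCageClustering:
    def test_five_overlapping_tags_kept_four_discarded(self):
        five = [("chr1", i * 5, i * 5 + 20) for i in range(5)]
        four = [("chr1", 1000 + i * 5, 1000 + i * 5 + 20) for i in range(4)]
        out = ctx.cluster_cage_tags(_df(five + four), min_tags=5)
        assert len(out) == 1
        assert out.iloc[0]["tag_count"] == 5
        assert out.iloc[0]["start"] == 0 and out.iloc[0]["end"] == 40

    def test_gap_separates_clusters(self):
        a = [("chr1", i, i + 10) for i in range(0, 30, 5)]       # 6 tags
        b = [("chr1", 500 + i, 510 + i) for i in range(0, 30, 5)]
        out = ctx.cluster_cage_tags(_df(a + b), min_tags=5)
        assert len(out) == 2

    def test_touching_tags_do_not_merge(self):
        # half-open: [0,10) and [10,20) share no base
        tags = _df([("chr1", 0, 10)] * 5 + [("chr1", 10, 20)] * 5)
        out = ctx.cluster_cage_tags(tags, min_tags=5)
        assert len(out) == 2


class TestRemove5utr:
    def test_overlap_rules(self, toy_genes):
        # geneA 5'UTR [100,150); geneB 5'UTR [6300,6400)
        feats = _df(
            [("chr1", 120, 130), ("chr1", 1150, 1250), ("chr1", 149, 200),
             ("chr1", 3000, 3100)]
        )
        out = ctx.remove_5utr_features(feats, toy_genes)
        # inside 5'UTR and 1-bp overlap removed; 3'UTR overlap retained
        assert out["start"].tolist() == [1150, 3000]

    def test_no_utr_annotation_warns_noop(self, toy_genes):
        for g in toy_genes:
            g.utr5 = []
        feats = _df([("chr1", 120, 130)])
        with pytest.warns(UserWarning, match="no 5'UTR"):
            out = ctx.remove_5utr_features(feats, toy_genes)
        assert len(out) == 1


@pytest.fixture(scope="module")
def world():
    cfg = SimulationConfig(
        seed=21, n_chromosomes=2, chromosome_length=1_000_000,
        n_genes=40, n_noncoding_genes=4,
        probe_counts={"protein_coding": 5, "known_lncRNA": 2,
                      "intronic": 60, "intergenic": 10},
    )
    genome = generate_genome(cfg)
    gc = GenomeGC(genome.sequences)
    pf = probe_frame(genome.probes)
    query = pf[pf["genomic_class"] == "intronic"]
    space = intron_intervals(genome.genes)
    nulls = ctx.sample_matched_null(query, space, gc, n_sets=20, seed=3)
    return genome, gc, query, space, nulls


class TestMatchedNull:
    def test_exact_length_match_every_set(self, world):
        _, _, query, _, nulls = world
        q_len = (query["end"] - query["start"]).to_numpy()
        for s in nulls.sets:
            assert ((s["end"] - s["start"]).to_numpy() == q_len).all()

    def test_gc_within_recorded_tolerance(self, world):
        _, gc, query, _, nulls = world
        q_gc = np.array(
            [float(gc.gc(r.chrom, r.start, r.end)) for r in query.itertuples()]
        )
        for s in nulls.sets:
            dev = np.abs(s["gc"].to_numpy() - q_gc)
            assert (dev <= s["achieved_tol"].to_numpy() + 1e-12).all()

    def test_containment_in_sampling_space(self, world):
        _, _, _, space, nulls = world
        for s in nulls.sets[:5]:
            for r in s.itertuples():
                iv = GenomicInterval(r.chrom, r.start, r.end)
                assert any(p.contains(iv) for p in space)

    def test_gradient_genome_mean_gc_deviation_within_tol(self, world):
        """The generator plants a sinusoidal GC gradient; matching still
        achieves the base tolerance on average."""
        _, gc, query, _, nulls = world
        q_gc = np.array(
            [float(gc.gc(r.chrom, r.start, r.end)) for r in query.itertuples()]
        )
        devs = [
            np.abs(s["gc"].to_numpy() - q_gc).mean() for s in nulls.sets
        ]
        assert np.mean(devs) <= nulls.gc_tolerance

    def test_oversized_query_rejected(self, world):
        _, gc, _, space, _ = world
        huge = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10_000_000]},
            index=["q0"],
        )
        with pytest.raises(ValueError, match="longer than every pool"):
            ctx.sample_matched_null(huge, space, gc, n_sets=1, seed=0)


class TestNearestDistance:
    def test_overlap_and_gap_examples(self):
        feats = _df([("chr1", 100, 200)])
        query = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [150, 300],
             "end": [400, 400], "strand": [".", "."]},
            index=["overlap", "gap"],
        )
        dd = ctx.nearest_distance(query, feats)
        assert dd.distances["overlap"] == 0
        assert dd.distances["gap"] == 100

    def test_censoring_above_cap(self):
        feats = _df([("chr1", 0, 10)])
        query = pd.DataFrame(
            {"chrom": ["chr1"], "start": [20_000], "end": [20_100]},
            index=["far"],
        )
        dd = ctx.nearest_distance(query, feats, max_dist=10_000)
        assert dd.n_censored == 1
        assert len(dd.uncensored) == 0

    def test_five_prime_mode_uses_strand(self):
        feats = _df([("chr1", 0, 10)])
        query = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 100],
             "end": [200, 200], "strand": ["+", "-"]},
            index=["plus", "minus"],
        )
        dd = ctx.nearest_distance(query, feats, mode="five_prime_start")
        assert dd.distances["plus"] == 90     # 5' end at 100
        assert dd.distances["minus"] == 189   # 5' end at 199

    def test_empty_track_all_censored_with_warning(self):
        query = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10]}, index=["q"]
        )
        with pytest.warns(UserWarning, match="empty feature track"):
            dd = ctx.nearest_distance(query, _df([]))
        assert dd.n_censored == 1

    def test_matches_brute_force_all_pairs_scan(self):
        """Random instance vs exhaustive oracle, boundary and 5' modes."""
        rng = np.random.default_rng(17)
        feats = []
        for _ in range(300):
            chrom = rng.choice(["chr1", "chr2"])
            s = int(rng.integers(0, 100_000))
            feats.append((chrom, s, s + int(rng.integers(10, 500))))
        feats = _df(feats)
        qrows = []
        for i in range(150):
            chrom = rng.choice(["chr1", "chr2"])
            s = int(rng.integers(0, 100_000))
            qrows.append(
                (chrom, s, s + int(rng.integers(20, 800)),
                 rng.choice(["+", "-", "."]))
            )
        query = pd.DataFrame(
            qrows, columns=["chrom", "start", "end", "strand"],
            index=[f"q{i}" for i in range(150)],
        )
        for mode in ("boundary", "five_prime_start"):
            dd = ctx.nearest_distance(query, feats, mode=mode, max_dist=10_000)
            for r in query.itertuples():
                if mode == "five_prime_start" and r.strand in ("+", "-"):
                    qs = r.end - 1 if r.strand == "-" else r.start
                    qe = qs + 1
                else:
                    qs, qe = r.start, r.end
                best = np.inf
                for f in feats.itertuples():
                    if f.chrom != r.chrom:
                        continue
                    if f.start < qe and qs < f.end:
                        best = 0
                        break
                    best = min(best, max(f.start - qe, qs - f.end))
                expected = best if best <= 10_000 else np.nan
                got = dd.distances[r.Index]
                assert (np.isnan(expected) and np.isnan(got)) or got == expected


class TestKsDecision:
    def _dist(self, values, max_dist=10_000):
        return ctx.DistanceDistribution(
            pd.Series(np.asarray(values, dtype=float)), max_dist, "boundary"
        )

    def test_identical_null_blocks_decision(self):
        rng = np.random.default_rng(0)
        obs = rng.uniform(0, 10_000, 100)
        nulls = [self._dist(rng.uniform(0, 10_000, 100)) for _ in range(10)]
        nulls[3] = self._dist(obs.copy())      # one null equals the observed
        dec = ctx.ks_enrichment(self._dist(obs), nulls)
        assert dec.p_values[3] > 0.9
        assert not dec.all_significant

    def test_extreme_separation_fires(self):
        rng = np.random.default_rng(1)
        obs = self._dist(np.zeros(200))
        nulls = [self._dist(rng.uniform(0, 10_000, 200)) for _ in range(20)]
        dec = ctx.ks_enrichment(obs, nulls)
        assert dec.all_significant
        assert (dec.p_values < 1e-10).all()

    def test_too_few_uncensored_untestable(self):
        obs = self._dist([1.0] * 5)
        nulls = [self._dist(np.arange(50))]
        dec = ctx.ks_enrichment(obs, nulls)
        assert dec.untestable and not dec.all_significant


class TestDistanceHistogram:
    def _dist(self, values):
        return ctx.DistanceDistribution(
            pd.Series(np.asarray(values, dtype=float)), 10_000, "boundary"
        )

    def test_single_zero_distance(self):
        h = ctx.distance_histogram({"q": self._dist([0.0])}, bin_width=500)
        assert h["q"].iloc[0] == 1
        assert h["q"].sum() == 1

    def test_counts_conserved_and_null_mean(self):
        rng = np.random.default_rng(2)
        obs = self._dist(rng.uniform(0, 9_000, 80))
        nulls = [self._dist(rng.uniform(0, 9_000, 80)) for _ in range(10)]
        h = ctx.distance_histogram({"obs": obs, "null": nulls}, bin_width=1000)
        assert h["obs"].sum() == 80
        manual = np.mean(
            [np.histogram(n.uncensored, bins=np.arange(0, 12_000, 1000))[0]
             for n in nulls],
            axis=0,
        )
        assert np.allclose(h["null_mean"].to_numpy()[: len(manual)], manual)


class TestConservedOverlap:
    def _nulls(self, sets):
        return ctx.MatchedNullCollection(sets, "intronic", 0.02, 0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        """50/100 query hits vs 1000/10000 pooled null hits: the one-sided p
        equals the exhaustive hypergeometric tail sum."""
        query = pd.DataFrame(
            {"chrom": "chr1",
             "start": np.arange(100) * 1000,
             "end": np.arange(100) * 1000 + 100},
        )
        track = _df([("chr1", i * 1000, i * 1000 + 50) for i in range(50)])
        null_rows = []
        for i in range(10_000):
            s = 10_000_000 + i * 1000
            null_rows.append(("chr1", s, s + 100))
        nulls_df = pd.DataFrame(null_rows, columns=["chrom", "start", "end"])
        # plant 1000 null hits by moving them onto the track
        nulls_df.iloc[:1000, 1] = track["start"].iloc[0]
        nulls_df.iloc[:1000, 2] = track["start"].iloc[0] + 100
        nulls = self._nulls([nulls_df])
        out = ctx.conserved_overlap_enrichment(query, nulls, {"vertebrate": track})
        row = out.loc["vertebrate"]
        assert row["query_overlap"] == 50

        # brute-force hypergeometric tail: P(X >= 50) drawing 100 from
        # an urn of 10100 with 1050 successes
        N, K, n = 10_100, 1_050, 100
        tail = sum(
            comb(K, k) * comb(N - K, n - k) for k in range(50, n + 1)
        ) / comb(N, n)
        assert row["fisher_p"] == pytest.approx(tail, rel=1e-9)

    def test_equal_fractions_p_near_one(self):
        query = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 1000], "end": [100, 1100]}
        )
        track = _df([("chr1", 0, 50)])
        null_df = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 5000], "end": [100, 5100]}
        )
        nulls = self._nulls([null_df] * 5)
        out = ctx.conserved_overlap_enrichment(query, nulls, {"primate": track})
        assert out.loc["primate", "fisher_p"] > 0.5

    def test_empty_query_untestable(self):
        track = _df([("chr1", 0, 50)])
        nulls = self._nulls([pd.DataFrame(columns=["chrom", "start", "end"])])
        out = ctx.conserved_overlap_enrichment(
            pd.DataFrame(columns=["chrom", "start", "end"]), nulls,
            {"primate": track},
        )
        assert out.loc["primate", "call"] == "untestable"


class TestExpressionBreadth:
    def test_counts_and_histogram(self):
        det = pd.DataFrame(
            {f"lib{i}": [True] * 2 + [False] * 2 for i in range(9)},
            index=["a", "b", "c", "d"],
        )
        det.loc["c", "lib0"] = True
        counts, hist = ctx.expression_breadth(["a", "b", "c", "d", "zzz"], det)
        assert counts["a"] == 9 and counts["c"] == 1 and counts["d"] == 0
        assert counts["zzz"] == 0  # unknown probe counted as undetected
        assert hist.sum() == 5
        assert hist[9] == 2
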