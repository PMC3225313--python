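"""Quantile normalization, filtering, replicate collapse, detection and
batch adjustment on the replicated-array design."""

import numpy as np
import pandas as pd
import pytest

from lncarray import preprocess as pp
from lncarray.simulate import SimulationConfig, simulate_expression_matrix
from lncarray.intervals import ProbeRecord, GenomicInterval


def _matrix(slide_values: dict, histology=None, batch=None):
    """Build a one-spot-per-slide ExpressionMatrix from {slide: values}.

    Slides named s1..sn map to samples x1..xn (one slide per sample is only
    used for slide-level operations, not replicate collapse).
    """
    slides = list(slide_values)
    n = len(next(iter(slide_values.values())))
    values = pd.DataFrame(
        {(s, 1): vals for s, vals in slide_values.items()},
        index=[f"g{i}" for i in range(n)],
    )
    values.columns = pd.MultiIndex.from_tuples(values.columns,
                                               names=["slide_id", "spot"])
    sheet = pd.DataFrame(
        {
            "slide_id": slides,
            "sample_id": [f"x{i}" for i in range(len(slides))],
            "histology": histology or ["T"] * len(slides),
            "batch": batch or ["b1"] * len(slides),
        }
    ).set_index("slide_id")
    samples = sheet.groupby("sample_id")[["histology", "batch"]].first()
    return pp.ExpressionMatrix(values, samples, sheet)


class TestQuantileNormalize:
    def test_two_slide_rank_mean(self):
        m = _matrix({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]})
        out = pp.quantile_normalize(m)
        for s in ("s1", "s2"):
            assert np.allclose(
                np.sort(out.values[s].to_numpy().ravel()), [2.5, 3.5, 4.5]
            )

    def test_single_slide_identity(self):
        m = _matrix({"s1": [3.0, 1.0, 2.0]})
        out = pp.quantile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_equal_slide_means_after_normalization(self):
        rng = np.random.default_rng(0)
        m = _matrix({f"s{i}": rng.lognormal(3, 1, 100) for i in range(6)})
        out = pp.quantile_normalize(m)
        means = [out.slide_vector(s).mean() for s in out.slide_ids]
        assert np.ptp(means) < 1e-9

    def test_missing_preserved_and_ignored(self):
        m = _matrix({"s1": [1.0, np.nan, 3.0], "s2": [4.0, 5.0, 6.0]})
        out = pp.quantile_normalize(m)
        assert np.isnan(out.values[("s1", 1)]["g1"])
        assert out.values[("s2", 1)].notna().all()

    def test_all_missing_slide_rejected(self):
        m = _matrix({"s1": [np.nan, np.nan], "s2": [1.0, 2.0]})
        with pytest.raises(ValueError, match="all-missing"):
            pp.quantile_normalize(m)


class TestFilterLowIntensity:
    def test_half_filtered_per_slide(self):
        m = _matrix({"s1": [1.0, 2.0, 3.0, 4.0]})
        out = pp.filter_low_intensity(m, 0.5)
        col = out.values[("s1", 1)]
        assert np.isnan(col["g0"]) and np.isnan(col["g1"])
        assert col["g2"] == 3.0 and col["g3"] == 4.0

    def test_threshold_is_per_slide_not_global(self):
        m = _matrix({"s1": [1.0, 2.0], "s2": [10.0, 20.0]})
        out = pp.filter_low_intensity(m, 0.5)
        assert np.isnan(out.values[("s1", 1)]["g0"])
        assert np.isnan(out.values[("s2", 1)]["g0"])
        assert out.values[("s2", 1)]["g1"] == 20.0

    def test_exact_floor_count_with_ties(self):
        m = _matrix({"s1": [5.0] * 7})
        out = pp.filter_low_intensity(m, 0.5)
        assert int(out.values[("s1", 1)].isna().sum()) == 3  # floor(7*0.5)

    def test_counts_missing_as_invalid_base(self):
        m = _matrix({"s1": [1.0, np.nan, 3.0, 4.0, 5.0]})
        out = pp.filter_low_intensity(m, 0.5)
        # 4 valid -> floor(2) lowest dropped
        assert int(out.values[("s1", 1)].isna().sum()) == 3


class TestCollapseReplicates:
    def _replicate_matrix(self, quad):
        """One sample, 2 slides x 2 spots with the 4 given values."""
        values = pd.DataFrame(
            {
                ("sa_s1", 1): [quad[0]], ("sa_s1", 2): [quad[1]],
                ("sa_s2", 1): [quad[2]], ("sa_s2", 2): [quad[3]],
            },
            index=["g0"],
        )
        values.columns = pd.MultiIndex.from_tuples(
            values.columns, names=["slide_id", "spot"]
        )
        slides = pd.DataFrame(
            {
                "slide_id": ["sa_s1", "sa_s2"],
                "sample_id": ["sa", "sa"],
                "histology": ["T", "T"],
                "batch": ["b1", "b1"],
            }
        ).set_index("slide_id")
        samples = slides.groupby("sample_id")[["histology", "batch"]].first()
        return pp.ExpressionMatrix(values, samples, slides)

    @pytest.mark.parametrize(
        "quad,expected",
        [
            ((1.0, 2.0, 3.0, np.nan), 2.0),
            ((1.0, 2.0, np.nan, np.nan), np.nan),
            ((2.0, 2.0, 2.0, 2.0), 2.0),
        ],
    )
    def test_three_of_four_rule(self, quad, expected):
        out = pp.collapse_replicates(self._replicate_matrix(quad))
        got = out.values.loc["g0", "sa"]
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_wrong_replicate_count_is_structural_error(self):
        m = _matrix({"s1": [1.0], "s2": [2.0]})  # 1 measurement per sample
        with pytest.raises(ValueError, match="expected 4"):
            pp.collapse_replicates(m)


class TestDetectionCalls:
    def _sample_matrix(self, valid_per_group):
        """4 samples per group; `valid_per_group` maps group -> n valid."""
        cols, vals = [], []
        for g, n_valid in valid_per_group.items():
            for i in range(4):
                cols.append(f"{g}{i}")
                vals.append(1.0 if i < n_valid else np.nan)
        values = pd.DataFrame([vals], index=["g0"], columns=cols)
        samples = pd.DataFrame(
            {
                "histology": [c[:-1] for c in cols],
                "batch": "b1",
            },
            index=pd.Index(cols, name="sample_id"),
        )
        return pp.ExpressionMatrix(values, samples, None)

    def test_inclusive_75_percent_boundary(self):
        det = pp.detection_calls(self._sample_matrix({"NT": 3, "T": 0}))
        assert bool(det.detected.loc["g0", "NT"])   # 3/4 = 0.75 inclusive
        assert not det.detected.loc["g0", "T"]
        assert bool(det.expressed["g0"])

    def test_two_of_four_not_detected(self):
        det = pp.detection_calls(self._sample_matrix({"NT": 2}))
        assert not det.detected.loc["g0", "NT"]
        assert not det.expressed["g0"]

    def test_expressed_is_or_over_groups(self):
        det = pp.detection_calls(self._sample_matrix({"NT": 0, "M": 4}))
        assert bool(det.expressed["g0"])

    def test_detection_monotone_in_min_frac(self):
        cfg = SimulationConfig(seed=2, effect_size=0.0)
        probes = [
            ProbeRecord(f"p{i}", GenomicInterval("chr1", i * 10 + 1, i * 10 + 6),
                        "intronic")
            for i in range(150)
        ]
        m, _ = simulate_expression_matrix(cfg, probes)
        collapsed = pp.collapse_replicates(pp.filter_low_intensity(
            pp.quantile_normalize(m)))
        counts = [
            int(pp.detection_calls(collapsed, f).expressed.sum())
            for f in (0.5, 0.75, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


class TestBatchAdjust:
    def _batch_matrix(self, offset=1.0, n=50, seed=0, confound=False):
        rng = np.random.default_rng(seed)
        base = rng.normal(8, 1, size=(n, 8))
        cols = [f"x{i}" for i in range(8)]
        batch = ["b1"] * 4 + ["b2"] * 4
        hist = (["T"] * 4 + ["NT"] * 4) if confound else ["T", "NT"] * 4
        vals = base.copy()
        vals[:, 4:] += offset
        values = pd.DataFrame(vals, columns=cols,
                              index=[f"g{i}" for i in range(n)])
        samples = pd.DataFrame(
            {"histology": hist, "batch": batch},
            index=pd.Index(cols, name="sample_id"),
        )
        return pp.ExpressionMatrix(values, samples, None)

    def test_constant_offset_removed(self):
        m = self._batch_matrix(offset=1.0)
        out = pp.batch_adjust(m, shrink=False)
        b1 = out.values[[f"x{i}" for i in range(4)]].mean(axis=1)
        b2 = out.values[[f"x{i}" for i in range(4, 8)]].mean(axis=1)
        assert np.allclose(b1, b2, atol=1e-9)

    def test_single_batch_identity(self):
        m = self._batch_matrix()
        m.samples["batch"] = "b1"
        out = pp.batch_adjust(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_confounded_design_refused(self):
        with pytest.raises(ValueError, match="confounded"):
            pp.batch_adjust(self._batch_matrix(confound=True))

    def test_shrunk_adjustment_still_removes_most_offset(self):
        m = self._batch_matrix(offset=1.0, n=200)
        out = pp.batch_adjust(m, shrink=True)
        b1 = out.values[[f"x{i}" for i in range(4)]].to_numpy().mean()
        b2 = out.values[[f"x{i}" for i in range(4, 8)]].to_numpy().mean()
        assert abs(b1 - b2) < 0.1


class TestInterslideCorrelation:
    def test_duplicate_slides_give_one(self):
        m = _matrix({"s1": [1.0, 2.0, 3.0] * 4, "s2": [1.0, 2.0, 3.0] * 4})
        assert pp.interslide_correlation(m, min_shared=5) == pytest.approx(1.0)

    def test_independent_slides_near_zero(self):
        rng = np.random.default_rng(3)
        m = _matrix({f"s{i}": rng.normal(size=1000) for i in range(4)})
        assert abs(pp.interslide_correlation(m)) < 0.1

    def test_normalization_does_not_decrease_correlation_with_shared_signal(self):
        deltas = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            signal = rng.normal(8, 1.5, size=400)
            slides = {
                f"s{i}": np.exp2(signal + rng.normal(0, 0.5, size=400)
                                 + rng.normal(0, 0.4))
                for i in range(6)
            }
            m = _matrix(slides)
            raw = pp.interslide_correlation(m)
            norm = pp.interslide_correlation(pp.quantile_normalize(m))
            deltas.append(norm - raw)
        assert np.mean(deltas) >= -1e-6

    def test_sparse_pair_skipped_with_warning(self):
        m = _matrix({
            "s1": [1.0, 2.0] + [np.nan] * 20,
            "s2": [np.nan, np.nan] + list(np.linspace(1, 5, 20)),
            "s3": [1.0, 2.0] + list(np.linspace(1, 5, 20)),
        })
        with pytest.warns(UserWarning, match="fewer than"):
            pp.interslide_correlation(m)


class TestPipelineDriver:
    def test_stage_order_and_outputs(self):
        cfg = SimulationConfig(seed=6, signature_size=10)
        probes = [
            ProbeRecord(f"p{i}", GenomicInterval("chr1", i * 10 + 1, i * 10 + 6),
                        "intronic")
            for i in range(200)
        ]
        m, _ = simulate_expression_matrix(cfg, probes)
        res = pp.run_pipeline(m)
        n_samples = sum(cfg.samples_per_group.values())
        assert res.collapsed.values.shape == (200, n_samples)
        # detection restricts the adjusted matrix to expressed probes
        assert set(res.adjusted.values.index) == set(
            res.detection.expressed[res.detection.expressed].index
        )
        assert res.interslide_correlation_normalized > 0.5

    def test_pa_histology_synonym_normalized(self):
        values = pd.DataFrame({"x0": [1.0], "x1": [2.0]}, index=["g0"])
        samples = pd.DataFrame(
            {"histology": ["PA", "T"], "batch": ["b1", "b1"]},
            index=pd.Index(["x0", "x1"], name="sample_id"),
        )
        m = pp.ExpressionMatrix(values, samples, None)
        assert m.samples["histology"].tolist() == ["CP", "T"]
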