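"""Bin tiling, depth aggregation, copy-number estimation and median centering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from azfcnv import (
    AmpliconClassDef,
    compute_bin_depths,
    estimate_copy_numbers,
    make_bins,
    median_center,
    single_sample_mode,
    summarize_class_depths,
)
from azfcnv.depth import (
    AGGREGATE_DEPTH_CUTOFF,
    Bin,
    BinDepthTable,
    ClassDepthSummary,
    ClassStats,
    Mode,
    choose_mode,
    read_depth_table,
    write_depth_table,
)
from azfcnv.errors import (
    CohortTooSmallError,
    DefinitionError,
    DepthSourceError,
    NormalizationError,
)
from conftest import make_profile


def one_class(length, class_id="green", copies=3, start=0):
    return AmpliconClassDef(class_id, copies, (("chrY", start, start + length),))


class TestMakeBins:
    def test_partial_bin_kept_when_at_least_half(self):
        bins = make_bins([one_class(3500)], 1000)
        assert [b.length for b in bins] == [1000, 1000, 1000, 500]

    def test_partial_bin_dropped_when_under_half(self):
        bins = make_bins([one_class(1400)], 1000)
        assert [b.length for b in bins] == [1000]

    def test_class_with_no_bins_is_an_error(self):
        with pytest.raises(DefinitionError):
            make_bins([one_class(400)], 1000)

    def test_bin_size_floor(self):
        with pytest.raises(ValueError):
            make_bins([one_class(3500)], 99)

    @settings(max_examples=100, derandomize=True)
    @given(
        length=st.integers(min_value=600, max_value=50_000),
        bin_size=st.integers(min_value=100, max_value=5000),
    )
    def test_tiling_matches_brute_force_oracle(self, length, bin_size):
        """Total tiled length equals an independent one-line tiler's."""

        def oracle(L, bs):
            lens = [min(bs, L - p) for p in range(0, L, bs)]
            return [x for x in lens if 2 * x >= bs]

        expected = oracle(length, bin_size)
        if not expected:
            with pytest.raises(DefinitionError):
                make_bins([one_class(length)], bin_size)
            return
        bins = make_bins([one_class(length)], bin_size)
        assert [b.length for b in bins] == expected
        assert bins[0].start == 0
        assert all(b1.end == b2.start for b1, b2 in zip(bins, bins[1:]))


class TestComputeBinDepths:
    def _bins(self):
        return make_bins([one_class(2000)], 1000)

    def test_uniform_depth(self):
        src = pd.DataFrame(
            {"contig": "chrY", "pos": np.arange(2000), "depth": 10.0}
        )
        t = compute_bin_depths(src, self._bins())
        assert np.allclose(t.mean_depth, 10.0)

    def test_half_covered_bin(self):
        src = pd.DataFrame(
            {"contig": "chrY", "pos": np.arange(500), "depth": 10.0}
        )
        t = compute_bin_depths(src, self._bins())
        assert np.allclose(t.mean_depth, [5.0, 0.0])

    def test_random_depths_match_direct_average(self):
        rng = np.random.default_rng(11)
        depths = rng.integers(0, 50, size=2000).astype(float)
        src = pd.DataFrame({"contig": "chrY", "pos": np.arange(2000), "depth": depths})
        t = compute_bin_depths(src, self._bins())
        assert np.allclose(t.mean_depth, [depths[:1000].mean(), depths[1000:].mean()])

    def test_missing_contig_is_named(self):
        src = pd.DataFrame({"contig": "chr1", "pos": [0], "depth": [1.0]})
        with pytest.raises(DepthSourceError, match="chrY"):
            compute_bin_depths(src, self._bins())


class TestSummaries:
    def _table(self, means, lengths=None):
        lengths = lengths or [1000] * len(means)
        pos = 0
        bins = []
        for ln in lengths:
            bins.append(Bin("chrY", pos, pos + ln, "green"))
            pos += ln
        return BinDepthTable("s", bins, np.asarray(means, dtype=float))

    def test_median_is_robust_to_outlier_bin(self):
        s = summarize_class_depths(self._table([1, 2, 100]))
        assert s.per_class["green"].median_bin_depth == 2

    def test_aggregate_equals_mean_for_equal_length_bins(self):
        s = summarize_class_depths(self._table([1, 2, 100]))
        assert s.per_class["green"].aggregate_depth == pytest.approx(103 / 3)

    def test_modes_agree_on_constant_depth(self):
        s = summarize_class_depths(self._table([7, 7, 7], [1000, 1000, 500]))
        st_ = s.per_class["green"]
        assert st_.median_bin_depth == st_.aggregate_depth == 7

    def test_aggregate_weights_by_bin_length(self):
        s = summarize_class_depths(self._table([10, 0], [1000, 500]))
        assert s.per_class["green"].aggregate_depth == pytest.approx(10000 / 1500)


def _summary(ctrl_depth, class_depths):
    per = {"ctrl": ClassStats(ctrl_depth, ctrl_depth, 10, 10_000)}
    for cid, d in class_depths.items():
        per[cid] = ClassStats(d, d, 10, 10_000)
    return ClassDepthSummary("s", per)


class TestEstimateCopyNumbers:
    def test_ratio_scales_by_reference_copies(self, toy):
        defs, _ = toy
        p = estimate_copy_numbers(
            _summary(10.0, {"green": 10.0, "red": 5.0}), defs, Mode.MEDIAN_BIN
        )
        assert p.raw_cn["green"] == pytest.approx(3.0)  # ratio 1.0 x 3 copies
        assert p.raw_cn["red"] == pytest.approx(2.0)  # ratio 0.5 x 4 copies

    def test_zero_control_depth_signals_call_failure(self, toy):
        defs, _ = toy
        with pytest.raises(NormalizationError):
            estimate_copy_numbers(
                _summary(0.0, {"green": 1.0, "red": 1.0}), defs, Mode.AGGREGATE
            )

    def test_mode_auto_selects_aggregate_at_ultra_low_coverage(self, toy):
        defs, _ = toy
        low = _summary(AGGREGATE_DEPTH_CUTOFF / 2, {"green": 1.0, "red": 1.0})
        high = _summary(AGGREGATE_DEPTH_CUTOFF * 5, {"green": 1.0, "red": 1.0})
        assert choose_mode(low, defs) is Mode.AGGREGATE
        assert choose_mode(high, defs) is Mode.MEDIAN_BIN
        assert estimate_copy_numbers(low, defs).mode is Mode.AGGREGATE

    @settings(
        max_examples=50,
        derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance_of_copy_numbers(self, toy, k):
        """Multiplying every depth by k > 0 leaves raw_cn unchanged."""
        defs, _ = toy
        base = estimate_copy_numbers(
            _summary(8.0, {"green": 6.0, "red": 4.0}), defs, Mode.AGGREGATE
        )
        scaled = estimate_copy_numbers(
            _summary(8.0 * k, {"green": 6.0 * k, "red": 4.0 * k}),
            defs,
            Mode.AGGREGATE,
        )
        for c in base.raw_cn:
            assert scaled.raw_cn[c] == pytest.approx(base.raw_cn[c], rel=1e-9)


class TestMedianCentering:
    def test_global_bias_is_removed(self, toy):
        defs, _ = toy
        # cohort of wild types with class "red" inflated x1.2
        profiles = [
            make_profile({"green": 3.0 * f, "red": 4.0 * 1.2 * f})
            for f in (0.97, 1.0, 1.02, 0.99, 1.01)
        ]
        centered = median_center(profiles, defs)
        red = np.median([p.centered_cn["red"] for p in centered])
        assert red == pytest.approx(4.0)

    def test_identical_profiles_center_to_reference_exactly(self, toy):
        defs, _ = toy
        profiles = [make_profile({"green": 2.7, "red": 4.4}) for _ in range(5)]
        centered = median_center(profiles, defs)
        for p in centered:
            assert p.centered_cn == pytest.approx({"green": 3.0, "red": 4.0})

    def test_centering_is_idempotent(self, toy):
        defs, _ = toy
        rng = np.random.default_rng(5)
        profiles = [
            make_profile(
                {"green": 3 * rng.uniform(0.9, 1.1), "red": 4 * rng.uniform(0.9, 1.1)}
            )
            for _ in range(9)
        ]
        once = median_center(profiles, defs)
        twice = median_center(once, defs)
        for p1, p2 in zip(once, twice):
            assert p2.centered_cn == pytest.approx(p1.centered_cn, rel=1e-12)

    def test_centering_equivariant_under_class_bias(self, toy):
        """Biasing all samples' class depth by b, then centering, equals
        centering the unbiased cohort."""
        defs, _ = toy
        rng = np.random.default_rng(8)
        raws = [
            {"green": 3 * rng.uniform(0.9, 1.1), "red": 4 * rng.uniform(0.9, 1.1)}
            for _ in range(9)
        ]
        plain = median_center([make_profile(r) for r in raws], defs)
        biased = median_center(
            [
                make_profile({"green": r["green"] * 1.3, "red": r["red"] * 0.8})
                for r in raws
            ],
            defs,
        )
        for p1, p2 in zip(plain, biased):
            assert p2.centered_cn == pytest.approx(p1.centered_cn, rel=1e-12)

    def test_small_cohort_requires_explicit_single_sample_mode(self, toy):
        defs, _ = toy
        profiles = [make_profile({"green": 3.0, "red": 4.0})] * 2
        with pytest.raises(CohortTooSmallError, match="single_sample_mode"):
            median_center(profiles, defs)
        p = single_sample_mode(profiles[0])
        assert p.centered_cn == p.raw_cn
        assert "uncentered_single_sample" in p.flags

    def test_zero_median_class_left_uncentered_and_flagged(self, toy):
        defs, _ = toy
        profiles = [make_profile({"green": 0.0, "red": 4.0}) for _ in range(4)]
        centered = median_center(profiles, defs)
        for p in centered:
            assert p.centered_cn["green"] == 0.0
            assert any(f.startswith("uncentered_zero_median") for f in p.flags)


def test_depth_table_tsv_round_trip(tmp_path, mini):
    defs, catalog, bins = mini
    from azfcnv import SimSampleSpec, simulate_depths

    t = simulate_depths(
        SimSampleSpec("reference", coverage=5.0, seed=4), defs, bins, catalog, "rt"
    )
    path = tmp_path / "rt.tsv"
    write_depth_table(t, path, {"seed": 4})
    back = read_depth_table(path, bins=bins)
    assert back.sample_id == "rt"
    assert np.allclose(back.mean_depth, t.mean_depth)
    assert np.array_equal(back.read_count, t.read_count)
    assert back.read_length == t.read_length
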