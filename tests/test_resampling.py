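"""Age interpolation, proportion matrix and influx resampling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from paleodiv import (
    AgeDepthModel,
    build_proportion_matrix,
    derive_sample_ages,
    find_min_window,
    median_resolution,
    resample_counts,
)

from conftest import make_record


class TestDeriveSampleAges:
    def test_linear_model(self, record_factory):
        samples, _ = record_factory([100, 200], [[1]])
        model = AgeDepthModel(depths=np.array([0.0, 100.0]),
                              ages=np.array([0.0, 1000.0]))
        top, base = derive_sample_ages(model, _samples_at_depths(samples, 10, 20))
        np.testing.assert_allclose([top[0], base[0]], [100.0, 200.0])

    def test_piecewise_segments(self):
        model = AgeDepthModel(depths=np.array([0.0, 50.0, 100.0]),
                              ages=np.array([0.0, 200.0, 1000.0]))
        samples, _ = make_record([0, 1], [[1]])
        top, base = derive_sample_ages(model, _samples_at_depths(samples, 40, 60))
        np.testing.assert_allclose([top[0], base[0]], [160.0, 360.0])

    def test_control_point_exact(self):
        model = AgeDepthModel(depths=np.array([0.0, 50.0, 100.0]),
                              ages=np.array([0.0, 200.0, 1000.0]))
        samples, _ = make_record([0, 1], [[1]])
        top, base = derive_sample_ages(model, _samples_at_depths(samples, 50, 100))
        assert top[0] == 200.0 and base[0] == 1000.0

    def test_outside_model_range_raises(self):
        model = AgeDepthModel(depths=np.array([10.0, 100.0]),
                              ages=np.array([0.0, 1000.0]))
        samples, _ = make_record([0, 1], [[1]])
        with pytest.raises(ValueError, match="extrapolat"):
            derive_sample_ages(model, _samples_at_depths(samples, 5, 20))


def _samples_at_depths(samples, top, bottom):
    samples.depth_top = np.array([float(top)])
    samples.depth_bottom = np.array([float(bottom)])
    return samples


class TestProportionMatrix:
    def test_single_sample_single_bin(self):
        pm = build_proportion_matrix([[0.0, 50.0]], w=50, origin=0.0)
        np.testing.assert_allclose(pm.entries, [[1.0]])

    def test_even_split(self):
        pm = build_proportion_matrix([[0.0, 100.0]], w=50, origin=0.0)
        np.testing.assert_allclose(pm.entries[:, 0], [0.5, 0.5])

    def test_three_samples_two_bins(self):
        pm = build_proportion_matrix(
            [[0.0, 30.0], [30.0, 90.0], [90.0, 120.0]], w=60, origin=0.0
        )
        expected = np.array([[1.0, 0.5, 0.0], [0.0, 0.5, 1.0]])
        np.testing.assert_allclose(pm.entries, expected)

    def test_bad_w_rejected(self):
        with pytest.raises(ValueError):
            build_proportion_matrix([[0.0, 10.0]], w=0, origin=0.0)

    @given(
        st.lists(st.floats(1.0, 50.0), min_size=1, max_size=8),
        st.floats(1.0, 40.0),
        st.floats(-20.0, 5.0),
    )
    def test_columns_sum_to_at_most_one(self, spans, w, origin_shift):
        bounds = np.concatenate([[0.0], np.cumsum(spans)])
        spans2 = np.column_stack([bounds[:-1], bounds[1:]])
        pm = build_proportion_matrix(spans2, w=w, origin=origin_shift)
        assert np.all(pm.entries >= 0) and np.all(pm.entries <= 1 + 1e-12)
        colsum = pm.entries.sum(axis=0)
        assert np.all(colsum <= 1 + 1e-9)
        # full coverage iff the span lies inside the binned interval
        hi_edge = pm.bin_edges[-1] + pm.w
        inside = (spans2[:, 0] >= origin_shift - 1e-12) & (spans2[:, 1] <= hi_edge + 1e-12)
        np.testing.assert_allclose(colsum[inside], 1.0, atol=1e-9)

    def test_oracle_equivalence_fuzzed(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(1, 8)
            bounds = np.cumsum(rng.uniform(1, 40, n + 1)) - 5.0
            spans = np.column_stack([bounds[:-1], bounds[1:]])
            w = float(rng.uniform(2, 50))
            origin = float(bounds[0] - rng.uniform(0, 10))
            pm = build_proportion_matrix(spans, w=w, origin=origin)
            for b, edge in enumerate(pm.bin_edges):
                for s, (t, base) in enumerate(spans):
                    ov = max(0.0, min(base, edge + w) - max(t, edge))
                    assert pm.entries[b, s] == pytest.approx(ov / (base - t), abs=1e-12)


class TestResampleCounts:
    def test_hand_computed_influx(self, record_factory):
        # 10 counts / 5 cm^3 over 0-100 BP and 0-1 cm: conc 2, sed 0.01
        samples, model = record_factory([0, 100], [[10]], volumes=[5], rate=0.01)
        rec = resample_counts(samples, model, 100)
        assert rec.n_bins == 1
        assert rec.concentration.iloc[0, 0] == pytest.approx(2.0)
        assert rec.sed_rate[0] == pytest.approx(0.01)
        assert rec.influx.iloc[0, 0] == pytest.approx(0.02)

    def test_halving_w_preserves_concentration(self, record_factory):
        samples, model = record_factory([0, 100], [[10]], volumes=[5], rate=0.01)
        rec = resample_counts(samples, model, 50)
        assert rec.n_bins == 2
        np.testing.assert_allclose(rec.concentration.to_numpy(), 2.0)
        np.testing.assert_allclose(rec.influx.to_numpy(), 0.02)
        np.testing.assert_allclose(rec.binned_counts.to_numpy(), 5.0)

    def test_influx_identity(self, record_factory):
        samples, model = record_factory(
            [0, 40, 110, 200], [[3, 0], [1, 5], [2, 2]], volumes=[4, 5, 6]
        )
        rec = resample_counts(samples, model, 20)
        np.testing.assert_allclose(
            rec.influx.to_numpy(),
            rec.concentration.to_numpy() * rec.sed_rate[:, None],
            atol=1e-12,
        )
        assert np.all(rec.influx.to_numpy() >= 0)
        assert np.all(np.diff(rec.bin_edges) == 20)

    def test_mass_conservation_when_fully_covered(self, record_factory):
        samples, model = record_factory(
            [0, 40, 110, 200], [[3, 0], [1, 5], [2, 2]], volumes=[4, 5, 6]
        )
        rec = resample_counts(samples, model, 20)  # 20 divides 200: full cover
        np.testing.assert_allclose(
            rec.binned_counts.sum(axis=0), samples.counts.sum(axis=0), atol=1e-9
        )

    def test_refinement_consistency(self, record_factory):
        samples, model = record_factory(
            [0, 40, 110, 200], [[3, 0], [1, 5], [2, 2]], volumes=[4, 5, 6]
        )
        fine = resample_counts(samples, model, 10)
        coarse = resample_counts(samples, model, 20)
        agg = fine.binned_counts.to_numpy().reshape(-1, 2, 2).sum(axis=1)
        np.testing.assert_allclose(agg, coarse.binned_counts.to_numpy(), atol=1e-9)

    def test_partial_edge_bins_dropped(self, record_factory):
        samples, model = record_factory([0, 90], [[9]])
        rec = resample_counts(samples, model, 60)  # second bin only half covered
        assert rec.n_bins == 1
        np.testing.assert_allclose(rec.coverage, 1.0)


class TestWindowSearch:
    def test_median_resolution(self, record_factory):
        samples, model = record_factory([0, 50, 150, 300], [[1], [1], [1]])
        assert median_resolution(samples, model) == 100

    def test_median_resolution_even(self, record_factory):
        samples, model = record_factory([0, 50, 150], [[1], [1]])
        assert median_resolution(samples, model) == 75

    def test_min_window_bounded_by_max_resolution(self, record_factory):
        samples, model = record_factory([0, 30, 70, 120], [[2], [1], [4]])
        w = find_min_window(samples, model)
        assert w <= 50

    def test_empty_sample_forces_larger_w(self, record_factory):
        # middle sample (40 yr) is empty: w must bridge it
        samples, model = record_factory([0, 40, 80, 120], [[5], [0], [5]])
        w = find_min_window(samples, model)
        rec = resample_counts(samples, model, w)
        assert np.all(rec.binned_counts.sum(axis=1) > 0)
        assert w > 1

    def test_all_zero_record_rejected(self, record_factory):
        samples, model = record_factory([0, 40, 80], [[0], [0]])
        with pytest.raises(ValueError, match="no counts"):
            find_min_window(samples, model)

    def test_unreachable_w_reports_gap(self, record_factory):
        samples, model = record_factory([0, 10, 200, 210], [[5], [0], [5]])
        with pytest.raises(ValueError, match="gap"):
            find_min_window(samples, model, w_max=20)
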