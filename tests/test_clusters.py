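import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polarsig import (
    DetectionParams,
    FluorFrame,
    SimParams,
    ZeroSignalError,
    background_correct,
    call_cell,
    classify_pattern,
    cluster_positions,
    has_cluster,
    normalize_to_cell_max,
    render_cell,
    segment_max_vector,
    simulate_snapshot,
    summarize_population,
)

from conftest import frame_from_segment_values, make_rect_mesh


def brute_force_has_cluster(vector, intensity_threshold, fraction_threshold):
    """Independent oracle: literal count over entries, strict inequalities."""
    n_above = 0
    for x in vector:
        if x > intensity_threshold:
            n_above += 1
    return n_above / len(vector) < fraction_threshold


class TestSegmentMaxVector:
    def test_strongest_pixel_per_segment(self, rect_mesh):
        img = np.zeros(rect_mesh.image_shape, dtype=float).ravel()
        img[rect_mesh.segments[0][:3]] = [1.0, 5.0, 3.0]
        frame = FluorFrame(img.reshape(rect_mesh.image_shape), 0.065,
                           background_corrected=True)
        v = segment_max_vector(rect_mesh, frame)
        assert v[0] == 5.0

    def test_all_zero_cell_gives_zero_vector(self, rect_mesh):
        frame = frame_from_segment_values(rect_mesh, np.zeros(rect_mesh.n_segments))
        assert np.allclose(segment_max_vector(rect_mesh, frame), 0.0)

    def test_synthetic_spot_argmax_in_spot_segment(self, noise_free):
        img, mesh, _ = render_cell(6.0, 0.7, [(0.30, 200.0)], noise_free)
        frame = FluorFrame(img - noise_free.background_level, 0.065,
                           background_corrected=True)
        v = segment_max_vector(mesh, frame)
        from polarsig import segment_relative_positions
        pos = segment_relative_positions(mesh)
        assert abs(pos[int(np.argmax(v))] - 0.30) <= 2.0 / mesh.n_segments


class TestNormalizeToCellMax:
    def test_basic(self):
        assert np.allclose(normalize_to_cell_max([2, 4, 8]), [0.25, 0.5, 1.0])

    def test_scale_invariance(self):
        v = np.array([1.0, 3.0, 7.0, 2.0])
        assert np.allclose(normalize_to_cell_max(v), normalize_to_cell_max(v * 123.0))

    def test_zero_vector_zero_signal_verdict(self):
        with pytest.raises(ZeroSignalError):
            normalize_to_cell_max([0.0, 0.0, 0.0])


class TestHasCluster:
    def test_flat_profile_negative(self, det_params):
        assert not has_cluster(np.ones(20), det_params)

    def test_single_peak_of_twenty_positive(self, det_params):
        v = np.full(20, 0.5)
        v[7] = 1.0
        assert has_cluster(v, det_params)

    def test_exact_ten_percent_boundary_negative(self, det_params):
        # two of twenty above threshold: fraction exactly 0.10, not < 0.10
        v = np.full(20, 0.5)
        v[3], v[11] = 0.9, 1.0
        assert not has_cluster(v, det_params)

    def test_value_exactly_at_threshold_does_not_count(self, det_params):
        v = np.full(20, 0.75)
        v[0] = 1.0
        # only the single 1.0 lies strictly above 0.75
        assert has_cluster(v, det_params)

    def test_empty_vector_rejected(self, det_params):
        with pytest.raises(ValueError):
            has_cluster(np.array([]), det_params)

    def test_nonzero_denominator_flag(self):
        params = DetectionParams(denominator="nonzero")
        v = np.zeros(40)
        v[0] = 1.0
        v[1:4] = 0.5
        # denominator 4 (nonzero entries): 1/4 = 0.25 >= 0.1 -> negative
        assert not has_cluster(v, params)

    def test_oracle_equivalence_seeded_vectors(self, det_params):
        rng = np.random.default_rng(2024)
        for _ in range(2000):
            n = int(rng.integers(5, 201))
            kind = rng.integers(3)
            if kind == 0:
                v = rng.uniform(0, 1, n)
            elif kind == 1:
                v = rng.beta(2, 5, n)
            else:
                v = np.clip(rng.normal(0.6, 0.25, n), 0, None)
            if v.max() > 0:
                v = v / v.max()
            expected = brute_force_has_cluster(
                v, det_params.intensity_threshold, det_params.fraction_threshold)
            assert has_cluster(v, det_params) == expected

    @given(st.lists(st.floats(0.0, 1.0), min_size=5, max_size=60),
           st.floats(0.5, 0.95))
    @settings(max_examples=100, deadline=None)
    def test_raising_intensity_threshold_never_true_to_false(self, values, thr):
        base = DetectionParams()
        v = np.asarray(values)
        lo = has_cluster(v, base.replace(intensity_threshold=min(thr, 0.949)))
        hi = has_cluster(v, base.replace(intensity_threshold=0.95))
        # higher cut -> fewer supra entries -> verdict can only go false->true
        assert not (lo and not hi)


class TestClusterPositions:
    def test_single_supra_segment_at_first_midpoint(self, det_params):
        mesh = make_rect_mesh(n_segments=20)
        v = np.full(20, 0.3)
        v[0] = 1.0
        assert cluster_positions(v, mesh, det_params) == [pytest.approx(0.025)]

    def test_runs_at_both_ends(self, det_params):
        mesh = make_rect_mesh(n_segments=30)
        v = np.full(30, 0.3)
        v[0], v[29] = 0.9, 1.0
        p0, p1 = cluster_positions(v, mesh, det_params)
        assert p0 < 0.5 < p1

    def test_run_position_is_run_maximum(self, det_params):
        mesh = make_rect_mesh(n_segments=40)
        v = np.full(40, 0.1)
        v[10:13] = [0.8, 1.0, 0.9]
        (pos,) = cluster_positions(v, mesh, det_params)
        assert pos == pytest.approx((11 + 0.5) / 40)

    def test_requires_positive_verdict(self, det_params):
        mesh = make_rect_mesh(n_segments=10)
        with pytest.raises(ValueError):
            cluster_positions(np.ones(10), mesh, det_params)

    def test_two_spot_cell_positions_within_one_segment(self, noise_free):
        img, mesh, truth = render_cell(6.0, 0.7, [(0.02, 200.0), (0.98, 200.0)],
                                       noise_free)
        frame = FluorFrame(img - noise_free.background_level, 0.065,
                           background_corrected=True)
        v = normalize_to_cell_max(segment_max_vector(mesh, frame))
        got = cluster_positions(v, mesh, DetectionParams())
        assert len(got) == 2
        for g, t in zip(sorted(got), sorted(truth["cluster_positions"])):
            assert abs(g - t) <= 1.5 / mesh.n_segments


class TestClassifyPattern:
    @pytest.mark.parametrize("positions,pattern,midcell", [
        ([0.03], "unipolar", False),
        ([0.02, 0.98], "bipolar", False),
        ([0.5], "midcell", True),
        ([], "none", False),
        ([0.03, 0.5], "unipolar", True),
        ([0.02, 0.55, 0.97], "bipolar", True),
        ([0.25], "none", False),
    ])
    def test_window_rules(self, det_params, positions, pattern, midcell):
        got_pattern, got_midcell = classify_pattern(positions, det_params)
        assert got_pattern == pattern
        assert got_midcell == midcell


class TestSummarizePopulation:
    def test_all_bipolar_hundred_percent(self, det_params, noise_free):
        p = SimParams(seed=1, pattern_probs={"bipolar": 1.0},
                      poisson_noise=False, read_noise_sd=0.0)
        frame, meshes, _ = simulate_snapshot(10, p)
        corr = background_correct(frame, meshes)
        calls = [call_cell(m, corr, det_params) for m in meshes]
        table = summarize_population(calls, det_params)
        row = table[table.group == "all"].iloc[0]
        assert row.bipolar_pct == 100.0

    def test_length_boundary_at_six_point_five(self, det_params):
        short = make_rect_mesh(n_segments=98, seg_px=1, cell_id="s")  # 6.37 µm
        long = make_rect_mesh(n_segments=100, seg_px=1, cell_id="l")  # 6.50 µm
        frame_s = frame_from_segment_values(short, np.full(98, 1.0))
        frame_l = frame_from_segment_values(long, np.full(100, 1.0))
        cs = call_cell(short, frame_s, det_params)
        cl = call_cell(long, frame_l, det_params)
        assert cs.length_class == "short"
        assert cl.length_class == "long"

    def test_percentages_sum_to_hundred(self, det_params):
        p = SimParams(seed=2)
        frame, meshes, _ = simulate_snapshot(60, p)
        corr = background_correct(frame, meshes)
        calls = [call_cell(m, corr, det_params) for m in meshes]
        table = summarize_population(calls, det_params)
        for _, row in table.iterrows():
            assert row.unipolar_pct + row.bipolar_pct + row.none_pct == pytest.approx(100.0)

    def test_empty_input_rejected(self, det_params):
        with pytest.raises(ValueError):
            summarize_population([], det_params)

    def test_zero_signal_cells_counted_none_with_annotation(self, det_params, rect_mesh):
        frame = frame_from_segment_values(rect_mesh, np.zeros(rect_mesh.n_segments))
        call = call_cell(rect_mesh, frame, det_params)
        assert call.zero_signal and call.pattern == "none" and not call.has_cluster
        table = summarize_population([call], det_params)
        assert table[table.group == "all"].iloc[0].zero_signal_n == 1
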