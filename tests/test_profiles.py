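import numpy as np
import pytest

from polarsig import (
    FluorFrame,
    NoBackgroundError,
    SimParams,
    ZeroSignalError,
    background_correct,
    cell_profile,
    orient_profile,
    polar_allocation_frame,
    polar_fraction,
    population_profile,
    render_cell,
    simulate_snapshot,
)
from polarsig.profiles import CellProfile

from conftest import frame_from_segment_values, make_rect_mesh


class TestBackgroundCorrect:
    def test_constant_background_removed(self, rect_mesh):
        img = np.full(rect_mesh.image_shape, 50.0)
        frame = FluorFrame(img, pixel_size=0.065)
        out = background_correct(frame, [rect_mesh], smooth_sigma_px=0.0)
        non_cell = ~rect_mesh.mask()
        assert np.allclose(out.image[non_cell], 0.0)
        assert out.background_corrected

    def test_known_background_recovered_within_noise(self):
        p = SimParams(seed=2)
        frame, meshes, _ = simulate_snapshot(20, p)
        union = np.zeros(frame.shape, dtype=bool)
        for m in meshes:
            union |= m.mask()
        out = background_correct(frame, meshes)
        # median of corrected non-cell pixels should sit near zero
        resid = np.median(frame.image[~union]) - p.background_level
        assert abs(resid) < p.read_noise_sd
        assert abs(np.median(out.image[~union])) < p.read_noise_sd

    def test_fully_covered_image_rejected(self, rect_mesh):
        frame = FluorFrame(np.ones(rect_mesh.image_shape), pixel_size=0.065)
        full = np.ones(rect_mesh.image_shape, dtype=bool)
        with pytest.raises(NoBackgroundError):
            background_correct(frame, [full])


class TestCellProfile:
    def test_segment_means_normalized_to_cell_max(self, rect_mesh):
        vals = np.zeros(rect_mesh.n_segments)
        vals[:3] = [2.0, 4.0, 8.0]
        frame = frame_from_segment_values(rect_mesh, vals)
        prof = cell_profile(rect_mesh, frame)
        assert np.allclose(prof.values[:3], [0.25, 0.5, 1.0])

    def test_uniform_cell_all_values_equal(self, rect_mesh):
        frame = frame_from_segment_values(rect_mesh, np.full(rect_mesh.n_segments, 7.0))
        prof = cell_profile(rect_mesh, frame)
        assert np.allclose(prof.values, 1.0)

    def test_zero_signal_cell_flagged_not_divided(self, rect_mesh):
        frame = frame_from_segment_values(rect_mesh, np.zeros(rect_mesh.n_segments))
        prof = cell_profile(rect_mesh, frame)
        assert prof.zero_signal
        assert np.allclose(prof.values, 0.0)

    def test_bipolar_cell_profile_peaks_at_an_end(self, noise_free):
        img, mesh, _ = render_cell(6.0, 0.7, [(0.0, 200.0), (1.0, 200.0)], noise_free)
        frame = FluorFrame(img - noise_free.background_level, 0.065,
                           background_corrected=True)
        prof = cell_profile(mesh, frame, statistic="max")
        k = int(np.argmax(prof.values))
        assert k in (0, mesh.n_segments - 1)

    def test_scale_invariance(self, rect_mesh):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 9, rect_mesh.n_segments)
        f1 = frame_from_segment_values(rect_mesh, vals)
        f2 = frame_from_segment_values(rect_mesh, vals * 37.5)
        assert np.allclose(cell_profile(rect_mesh, f1).values,
                           cell_profile(rect_mesh, f2).values)


class TestOrientProfile:
    def _profile(self, values):
        n = len(values)
        pos = (np.arange(n) + 0.5) / n
        return CellProfile("c", pos, np.asarray(values, dtype=float))

    def test_brightest_pole_reverses_when_needed(self):
        prof = self._profile([0.2, 0.5, 1.0])
        out = orient_profile(prof, "brightest_pole")
        assert out.values[0] == 1.0
        assert np.all(np.diff(out.positions) > 0)

    def test_brightest_pole_keeps_order_when_zero_end_brighter(self):
        prof = self._profile([1.0, 0.5, 0.2])
        out = orient_profile(prof, "brightest_pole")
        assert np.array_equal(out.values, prof.values)

    def test_symmetric_tie_keeps_input_order(self):
        prof = self._profile([0.8, 0.3, 0.8])
        out = orient_profile(prof, "brightest_pole")
        assert np.array_equal(out.values, prof.values)

    def test_old_pole_requires_hint(self):
        prof = self._profile([0.1, 1.0])
        with pytest.raises(ValueError):
            orient_profile(prof, "old_pole")

    def test_old_pole_hint_maps_old_pole_to_zero(self):
        prof = self._profile([0.1, 0.5, 1.0])
        out = orient_profile(prof, "old_pole", old_pole_hint=1)
        assert out.values[0] == 1.0
        out0 = orient_profile(prof, "old_pole", old_pole_hint=0)
        assert np.array_equal(out0.values, prof.values)


class TestPopulationProfile:
    def test_identical_profiles_zero_sd(self):
        n = 30
        pos = (np.arange(n) + 0.5) / n
        vals = np.linspace(0.2, 1.0, n)
        profs = [CellProfile(str(i), pos, vals) for i in range(5)]
        pop = population_profile(profs, n_bins=50)
        assert np.allclose(pop.sd, 0.0)
        assert pop.n_cells == 5

    def test_mirrored_profiles_equal_after_orientation(self):
        n = 40
        pos = (np.arange(n) + 0.5) / n
        vals = np.linspace(1.0, 0.1, n)
        a = CellProfile("a", pos, vals)
        b = CellProfile("b", (1 - pos)[::-1], vals[::-1])  # mirrored copy
        oa = orient_profile(a, "brightest_pole")
        ob = orient_profile(b, "brightest_pole")
        grid = (np.arange(100) + 0.5) / 100
        assert np.allclose(np.interp(grid, oa.positions, oa.values),
                           np.interp(grid, ob.positions, ob.values))

    def test_mean_bounded_by_inputs_and_order_invariant(self):
        rng = np.random.default_rng(1)
        n = 25
        pos = (np.arange(n) + 0.5) / n
        profs = [CellProfile(str(i), pos, rng.uniform(0, 1, n)) for i in range(8)]
        pop = population_profile(profs)
        stack = np.stack([np.interp(pop.grid, p.positions, p.values) for p in profs])
        assert np.all(pop.mean <= stack.max(axis=0) + 1e-12)
        assert np.all(pop.mean >= stack.min(axis=0) - 1e-12)
        pop2 = population_profile(profs[::-1])
        assert np.allclose(pop.sd, pop2.sd)

    def test_requires_two_profiles(self):
        with pytest.raises(ValueError):
            population_profile([])

    def test_synthetic_bipolar_population_peaks_at_both_ends(self):
        p = SimParams(seed=6, pattern_probs={"bipolar": 1.0})
        frame, meshes, _ = simulate_snapshot(100, p)
        corr = background_correct(frame, meshes)
        profs = [orient_profile(cell_profile(m, corr, statistic="max"),
                                "brightest_pole") for m in meshes]
        pop = population_profile(profs, n_bins=100)
        half = 50
        # population mean peaks inside the outermost 10% of bins at both ends
        assert int(np.argmax(pop.mean[:half])) < 10
        assert int(np.argmax(pop.mean[half:])) >= 40


class TestPolarFraction:
    def test_uniform_cell_gives_window_share(self, rect_mesh):
        frame = frame_from_segment_values(rect_mesh, np.full(rect_mesh.n_segments, 5.0))
        assert polar_fraction(rect_mesh, frame, 0.1) == pytest.approx(0.2, abs=1e-9)

    def test_all_signal_in_terminal_segment(self, rect_mesh):
        vals = np.zeros(rect_mesh.n_segments)
        vals[0] = 9.0
        frame = frame_from_segment_values(rect_mesh, vals)
        assert polar_fraction(rect_mesh, frame, 0.1) == 1.0

    def test_nineteen_percent_allocation_recovered(self, noise_free):
        _, mesh, _ = render_cell(6.0, 0.7, [], noise_free)
        frame = polar_allocation_frame(mesh, 0.19)
        assert polar_fraction(mesh, frame, 0.1) == pytest.approx(0.19, abs=1e-9)

    def test_monotone_in_window(self, rect_mesh):
        rng = np.random.default_rng(2)
        frame = frame_from_segment_values(rect_mesh, rng.uniform(1, 5, rect_mesh.n_segments))
        fracs = [polar_fraction(rect_mesh, frame, w) for w in (0.05, 0.1, 0.2, 0.3, 0.45)]
        assert np.all(np.diff(fracs) >= 0)

    def test_zero_total_intensity_rejected(self, rect_mesh):
        frame = frame_from_segment_values(rect_mesh, np.zeros(rect_mesh.n_segments))
        with pytest.raises(ZeroSignalError):
            polar_fraction(rect_mesh, frame)
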