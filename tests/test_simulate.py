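"""Synthetic-data generators: determinism, design values, ground truth."""

import numpy as np
import pytest

from gietkit import (
    ImageSimSpec,
    TraceSimSpec,
    simulate_image_stack,
    simulate_ruler_dataset,
    simulate_traces,
)

Q3 = np.array([[-0.6, 0.5, 0.1], [0.4, -0.8, 0.4], [0.1, 0.5, -0.6]])


def spec3(curve, **kw):
    defaults = dict(
        heights_nm=(4.7, 6.8, 11.2),
        curve=curve,
        rate_matrix_per_s=Q3,
        n_traces=20,
        n_frames=200,
    )
    defaults.update(kw)
    return TraceSimSpec(**defaults)


class TestSimulateTraces:
    def test_identical_seeds_identical_output(self, dy647_curve):
        s = spec3(dy647_curve)
        t1, p1 = simulate_traces(s, seed=99)
        t2, p2 = simulate_traces(s, seed=99)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.intensity, b.intensity)
        for a, b in zip(p1, p2):
            assert np.array_equal(a, b)

    def test_design_state_means_follow_curve(self, dy647_curve):
        """Heights of the three reference states map to ~0.25/0.41/0.69
        of the on-glass intensity."""
        s = spec3(dy647_curve, on_glass_mean=1000.0)
        means = s.state_means()
        assert means[0] == pytest.approx(250.0, abs=10.0)
        assert means[1] == pytest.approx(410.0, abs=10.0)
        assert means[2] == pytest.approx(690.0, abs=10.0)

    def test_frozen_chain_keeps_state(self, dy647_curve):
        s = spec3(dy647_curve, rate_matrix_per_s=np.zeros((3, 3)))
        _, paths = simulate_traces(s, seed=4)
        for p in paths:
            assert len(np.unique(p)) == 1

    def test_empirical_means_match_design(self, dy647_curve):
        """Law of large numbers: per-state empirical means within 1%."""
        s = spec3(dy647_curve, n_traces=40, n_frames=2500)
        traces, paths = simulate_traces(s, seed=8)
        y = np.concatenate([t.intensity for t in traces])
        st = np.concatenate(paths)
        design = s.state_means()
        for k in range(3):
            assert np.mean(y[st == k]) == pytest.approx(design[k], rel=0.01)

    def test_bleaching_drops_to_background(self, dy647_curve):
        s = spec3(dy647_curve, bleach_rate_per_s=2.0, background_sd=5.0,
                  n_frames=400)
        traces, paths = simulate_traces(s, seed=3)
        bleached = [p for p in paths if np.any(p == -1)]
        assert len(bleached) > 0
        for tr, p in zip(traces, paths):
            if np.any(p == -1):
                tail = tr.intensity[p == -1]
                assert np.abs(np.mean(tail)) < 50.0

    def test_heights_outside_curve_rejected(self, dy647_curve):
        s = spec3(dy647_curve, heights_nm=(4.7, 6.8, 50.0))
        with pytest.raises(ValueError):
            simulate_traces(s, seed=0)

    def test_invalid_rate_matrix_rejected(self, dy647_curve):
        with pytest.raises(ValueError):
            spec3(dy647_curve, rate_matrix_per_s=np.ones((3, 3)))


class TestSimulateImageStack:
    def test_zero_spots_pure_noise(self):
        spec = ImageSimSpec(frame_size_px=32, n_spots=0)
        stack, truth = simulate_image_stack(spec, seed=0)
        assert truth.empty
        assert stack.shape == (1, 32, 32)
        assert abs(float(np.mean(stack)) - spec.background) < 5.0

    def test_expected_spot_count_from_density(self):
        # 256 px * 107 nm = 27.4 um field; 0.5/um^2 -> ~375 expected
        spec = ImageSimSpec(frame_size_px=256, spot_density_per_um2=0.5)
        counts = [
            len(simulate_image_stack(spec, seed=s)[1]) for s in range(5)
        ]
        expected = 0.5 * (256 * 107 / 1000) ** 2
        assert np.mean(counts) == pytest.approx(expected, rel=0.25)

    def test_min_separation_enforced(self):
        spec = ImageSimSpec(frame_size_px=64, n_spots=5, min_separation_nm=800.0)
        _, truth = simulate_image_stack(spec, seed=1)
        pos = truth[["x_px", "y_px"]].to_numpy()
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                assert np.hypot(*(pos[i] - pos[j])) >= 800.0 / 107.0

    def test_infeasible_density_raises(self):
        spec = ImageSimSpec(frame_size_px=32, n_spots=50,
                            min_separation_nm=2000.0)
        with pytest.raises(ValueError, match="infeasible"):
            simulate_image_stack(spec, seed=0)

    def test_intensity_matrix_drives_brightness(self):
        spec = ImageSimSpec(frame_size_px=48, n_spots=1, n_frames=2,
                            read_noise_sd=0.0)
        bright = np.array([[4000.0, 500.0]])
        stack, truth = simulate_image_stack(spec, seed=2, intensities=bright)
        sums = stack.sum(axis=(1, 2)).astype(float)
        assert sums[0] > sums[1]


class TestSimulateRulers:
    def test_noise_free_ratios_on_curve(self, fam_curve):
        meas = simulate_ruler_dataset(43.0, (5.1, 11.9), fam_curve,
                                      noise_cv=0.0, seed=0)
        import math

        for m in meas:
            d = m.l_dna_nm * math.sin(math.radians(43.0)) + 2.5
            assert m.ratio == pytest.approx(fam_curve(d), rel=1e-9)

    def test_lipid_dye_labelled(self, fam_curve):
        meas = simulate_ruler_dataset(43.0, (0.0, 5.1), fam_curve, seed=0)
        assert meas[0].label_end == "lipid_dye"
        assert meas[1].label_end == "3prime"

    def test_seeded(self, fam_curve):
        a = simulate_ruler_dataset(43.0, (5.1, 8.5), fam_curve, 0.03, seed=5)
        b = simulate_ruler_dataset(43.0, (5.1, 8.5), fam_curve, 0.03, seed=5)
        assert [m.ratio for m in a] == [m.ratio for m in b]

    def test_invalid_angle(self, fam_curve):
        with pytest.raises(ValueError):
            simulate_ruler_dataset(0.0, (5.1,), fam_curve, seed=0)
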