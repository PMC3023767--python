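"""Shape metrics, area-oscillation timing, kymograph protrusion rules."""

import numpy as np
import pandas as pd
import pytest

from acidhesion import synthetic_data as sd
from acidhesion.morphodynamics import (
    AreaSeries,
    EdgeTrace,
    area_oscillation,
    detect_protrusions,
    extract_edge_trace,
    shape_metrics,
    summarize_protrusions,
)


class TestShapeMetrics:
    def test_fine_circle_has_unit_circularity(self):
        verts, _, _ = sd.simulate_shapes("circle_ngon", {"radius": 10.0, "n_vertices": 1024})
        assert shape_metrics(outline=verts).circularity == pytest.approx(1.0, abs=1e-4)

    def test_square_circularity_is_pi_over_four(self):
        verts, _, _ = sd.simulate_shapes("rectangle", {"width": 2.0, "height": 2.0})
        assert shape_metrics(outline=verts).circularity == pytest.approx(np.pi / 4, rel=1e-12)

    def test_star_matches_independent_geometry_oracle(self):
        verts, _, _ = sd.simulate_shapes("star", {"n_arms": 5, "r_outer": 8.0, "r_inner": 3.0})
        m = shape_metrics(outline=verts)
        # independent shoelace + edge-sum evaluation
        area = 0.0
        perim = 0.0
        n = len(verts)
        for i in range(n):
            x0, y0 = verts[i]
            x1, y1 = verts[(i + 1) % n]
            area += x0 * y1 - x1 * y0
            perim += np.hypot(x1 - x0, y1 - y0)
        area = abs(area) / 2
        assert m.circularity == pytest.approx(4 * np.pi * area / perim**2, rel=1e-12)

    def test_scale_invariance_of_circularity(self):
        verts, _, _ = sd.simulate_shapes("star", {"n_arms": 6, "r_outer": 5.0, "r_inner": 2.0})
        c1 = shape_metrics(outline=verts).circularity
        c2 = shape_metrics(outline=7.3 * verts).circularity
        assert c2 == pytest.approx(c1, rel=1e-12)

    def test_self_intersecting_polygon_rejected(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2]], dtype=float)
        with pytest.raises(ValueError, match="self-intersecting"):
            shape_metrics(outline=bowtie)

    def test_disk_mask_circularity_near_one(self):
        yy, xx = np.mgrid[:64, :64]
        mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        m = shape_metrics(mask=mask)
        assert m.circularity == pytest.approx(1.0, abs=0.1)

    def test_multi_component_mask_rejected(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[10:14, 10:14] = True
        with pytest.raises(ValueError, match="component"):
            shape_metrics(mask=mask)


class TestAreaOscillation:
    def test_triangular_wave_peak_delay(self):
        dt = 5.0
        times = dt * np.arange(0, 97)
        switches = np.array([60.0, 180.0, 300.0])
        areas = np.full(times.size, 500.0)
        for ts in switches:
            ramp = (times >= ts) & (times <= ts + 30)
            decay = (times > ts + 30) & (times <= ts + 60)
            areas[ramp] += 10.0 * (times[ramp] - ts)
            areas[decay] += 300.0 - 10.0 * (times[decay] - ts - 30)
        out = area_oscillation(AreaSeries(times, areas, switches))
        np.testing.assert_allclose(out["time_to_peak_min"], 30.0)
        assert (out["amplitude_ratio"] > 1.0).all()

    def test_constant_area_flagged_undefined(self):
        times = 5.0 * np.arange(30)
        series = AreaSeries(times, np.full(30, 400.0), np.array([30.0]))
        out = area_oscillation(series)
        assert bool(out["undefined_peak"].iloc[0])
        assert np.isnan(out["time_to_peak_min"].iloc[0])
        assert out["amplitude_ratio"].iloc[0] == 1.0

    def test_window_past_series_end_warns(self):
        times = 5.0 * np.arange(10)
        series = AreaSeries(times, np.linspace(400, 500, 10), np.array([30.0]))
        with pytest.warns(UserWarning, match="truncated"):
            area_oscillation(series, window_min=120.0)


class TestEdgeExtraction:
    def test_binary_kymograph_recovered_exactly(self):
        n_space, n_frames = 60, 40
        edge = 10 + np.round(5 * np.sin(np.arange(n_frames) / 5)).astype(int)
        img = np.zeros((n_space, n_frames))
        for j in range(n_frames):
            img[: edge[j] + 1, j] = 1.0
        trace = extract_edge_trace(img, pixel_size=0.1, frame_interval=5.0, threshold=0.5)
        np.testing.assert_array_equal(trace.positions, edge)

    def test_uniform_image_rejected(self):
        with pytest.raises(ValueError):
            extract_edge_trace(np.ones((10, 10)), pixel_size=0.1, frame_interval=5.0)

    def test_noisy_kymograph_within_one_pixel_rms(self):
        rng = np.random.default_rng(12)
        n_space, n_frames = 80, 100
        edge = 30 + np.round(10 * np.sin(np.arange(n_frames) / 8)).astype(int)
        img = np.zeros((n_space, n_frames))
        for j in range(n_frames):
            img[: edge[j] + 1, j] = 1.0
        img += rng.normal(0, 0.15, img.shape)
        trace = extract_edge_trace(img, pixel_size=0.1, frame_interval=5.0, threshold=0.5)
        rms = np.sqrt(np.mean((trace.positions - edge) ** 2))
        assert rms <= 1.0


class TestProtrusions:
    def test_worked_example_velocity_and_lifetime(self):
        # 2 px/frame for 10 frames, 5-frame plateau, 5 s/frame, 0.1 µm/px
        cfg = sd.KymoSimConfig(n_frames=60, events=[(5, 2.0, 10, 5)], noise_sd=0.0, seed=0)
        trace, _ = sd.simulate_kymograph(cfg)
        events = detect_protrusions(trace)
        assert len(events) == 1
        e = events[0]
        assert e.height_px == pytest.approx(20.0)
        assert e.velocity_px_per_frame == pytest.approx(2.0)
        assert e.velocity_um_per_min == pytest.approx(2.4)
        assert e.lifetime_s == pytest.approx(75.0)

    def test_three_pixel_event_neglected(self):
        cfg = sd.KymoSimConfig(n_frames=40, events=[(5, 1.0, 3, 2)], noise_sd=0.0, seed=0)
        trace, _ = sd.simulate_kymograph(cfg)
        assert detect_protrusions(trace) == []

    def test_offset_invariance(self):
        cfg = sd.KymoSimConfig(n_frames=60, events=[(5, 2.0, 10, 5)], noise_sd=0.3, seed=3)
        trace, _ = sd.simulate_kymograph(cfg)
        base = detect_protrusions(trace)
        shifted = EdgeTrace(
            positions=trace.positions + 57.0,
            pixel_size=trace.pixel_size,
            frame_interval=trace.frame_interval,
        )
        moved = detect_protrusions(shifted)
        assert [e.height_px for e in moved] == pytest.approx(
            [e.height_px for e in base], abs=1e-9
        )
        assert [e.start_frame for e in moved] == [e.start_frame for e in base]

    def test_lower_min_height_never_loses_events(self):
        cfg = sd.KymoSimConfig(
            n_frames=120, events=[(5, 2.0, 10, 5), (50, 1.0, 5, 0)], noise_sd=0.2, seed=4
        )
        trace, _ = sd.simulate_kymograph(cfg)
        n_low = len(detect_protrusions(trace, min_height_px=2.0))
        n_high = len(detect_protrusions(trace, min_height_px=4.0))
        assert n_low >= n_high

    def test_noisy_recall_and_accuracy(self):
        rng = np.random.default_rng(21)
        events, t = [], 5
        for _ in range(50):
            slope = float(rng.uniform(1.0, 3.0))
            ramp = int(rng.integers(5, 14))
            if slope * ramp < 6:
                slope = 6.0 / ramp
            plat = int(rng.integers(0, 8))
            events.append((t, slope, ramp, plat))
            t += ramp + plat + int(np.ceil(slope * ramp / 2.0)) + int(rng.integers(4, 10))
        cfg = sd.KymoSimConfig(n_frames=t + 10, events=events, noise_sd=0.3, seed=22)
        trace, truth = sd.simulate_kymograph(cfg)
        det = detect_protrusions(trace)
        starts = np.array([e.start_frame for e in det])
        matched, vel_err, life_err = 0, [], []
        for _, row in truth.iterrows():
            gaps = np.abs(starts - row.start_frame)
            if gaps.size and gaps.min() <= 2:
                matched += 1
                e = det[int(gaps.argmin())]
                vel_err.append(
                    e.velocity_um_per_min - row.slope_px_per_frame * 0.1 / 5.0 * 60.0
                )
                life_err.append(e.lifetime_s - (row.ramp_frames + row.plateau_frames) * 5.0)
        true_vel = (truth.slope_px_per_frame * 0.1 / 5.0 * 60.0).mean()
        true_life = ((truth.ramp_frames + truth.plateau_frames) * 5.0).mean()
        assert matched / len(truth) >= 0.95
        assert abs(np.mean(vel_err)) / true_vel <= 0.10
        assert abs(np.mean(life_err)) / true_life <= 0.10


class TestProtrusionSummary:
    def _events(self, vels, lifes, cond="x"):
        return pd.DataFrame(
            {"condition": cond, "velocity_um_per_min": vels, "lifetime_s": lifes}
        )

    def test_identical_events_sem_zero(self):
        out = summarize_protrusions(self._events([2.0, 2.0, 2.0], [60.0, 60.0, 60.0]))
        assert out["velocity_sem"].iloc[0] == 0.0
        assert out["lifetime_sem"].iloc[0] == 0.0

    def test_two_point_sem(self):
        out = summarize_protrusions(self._events([1.0, 3.0], [30.0, 60.0]))
        assert out["velocity_mean"].iloc[0] == pytest.approx(2.0)
        assert out["velocity_sem"].iloc[0] == pytest.approx(1.0)

    def test_condition_ordering_preserved(self):
        fast_short = self._events([3.0, 3.2, 2.8], [30.0, 35.0, 32.0], cond="pH7.4")
        slow_long = self._events([1.0, 1.2, 0.9], [80.0, 85.0, 90.0], cond="pH6.5")
        out = summarize_protrusions(pd.concat([fast_short, slow_long], ignore_index=True))
        out = out.set_index("condition")
        assert out.loc["pH7.4", "velocity_mean"] > out.loc["pH6.5", "velocity_mean"]
        assert out.loc["pH6.5", "lifetime_mean"] > out.loc["pH7.4", "lifetime_mean"]
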