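"""Rupture detection, F_R / k_eff estimation, gating and f_b statistics."""

import numpy as np
import pandas as pd
import pytest

from acidhesion import synthetic_data as sd
from acidhesion.force_spectroscopy import (
    CellBindingSummary,
    ForceCurve,
    GateThresholds,
    analyze_curve,
    binding_frequency,
    classify_specific,
    detect_ruptures,
    effective_loading_rate,
    events_to_frame,
    relative_binding_frequency,
    rupture_force,
    summarize_condition,
)


def _flat_curve(n=200, force=0.0, **kw):
    return ForceCurve(
        displacement=np.arange(n, dtype=float),
        force=np.full(n, force),
        velocity=5000.0,
        spring_constant=25.0,
        **kw,
    )


def _single_event_curve(f_r=80.0, k_eff=0.6, noise_sd=0.0, seed=0):
    cfg = sd.CurveSimConfig(
        n_curves=1,
        noise_sd=noise_sd,
        specific_fraction=1.0,
        specific_force_dist=(f_r, 0.0),
        specific_stiffness_dist=(k_eff, 0.0),
        events_per_curve_dist={1: 1.0},
        seed=seed,
    )
    curves, truth = sd.simulate_force_curves(cfg)
    return curves[0], int(truth["index_of_minimum"].iloc[0])


class TestDetection:
    def test_noiseless_event_found_at_planted_minimum(self):
        curve, idx = _single_event_curve()
        assert detect_ruptures(curve) == [idx]

    def test_flat_noise_only_trace_rarely_fires(self):
        cfg = sd.CurveSimConfig(
            n_curves=500, noise_sd=5.0, events_per_curve_dist={0: 1.0}, seed=13
        )
        curves, _ = sd.simulate_force_curves(cfg)
        n_with_detections = sum(bool(detect_ruptures(c)) for c in curves)
        assert n_with_detections / len(curves) <= 0.01

    def test_noisy_recall_and_localization(self):
        cfg = sd.CurveSimConfig(
            n_curves=300,
            noise_sd=5.0,
            specific_fraction=1.0,
            specific_force_dist=(80.0, 15.0),
            events_per_curve_dist={1: 1.0},
            seed=17,
        )
        curves, truth = sd.simulate_force_curves(cfg)
        hits, offsets = 0, []
        for c in curves:
            planted = int(truth.loc[truth.curve_id == c.curve_id, "index_of_minimum"].iloc[0])
            det = detect_ruptures(c)
            near = [i for i in det if abs(i - planted) <= 5]
            if near:
                hits += 1
                offsets.append(abs(near[0] - planted))
        assert hits / len(curves) >= 0.95
        assert np.median(offsets) <= 2

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            ForceCurve(
                displacement=np.arange(8.0),
                force=np.zeros(8),
                velocity=5000.0,
                spring_constant=25.0,
            )


class TestEstimators:
    def test_rupture_force_of_clean_event(self):
        curve, idx = _single_event_curve(f_r=80.0)
        assert rupture_force(curve, idx) == pytest.approx(80.0, abs=1e-9)

    def test_constant_trace_gives_zero_force(self):
        curve = _flat_curve(force=-10.0)
        assert rupture_force(curve, 100) == 0.0

    def test_rupture_force_noise_bound(self):
        # planted 120 pN, noise 5 pN: each estimate within 3(5/sqrt(50)+5) pN
        errs = []
        for seed in range(40):
            curve, idx = _single_event_curve(f_r=120.0, k_eff=0.8, noise_sd=5.0, seed=seed)
            det = detect_ruptures(curve)
            near = [i for i in det if abs(i - idx) <= 5]
            assert near
            errs.append(rupture_force(curve, near[0]) - 120.0)
        bound = 3 * (5 / np.sqrt(50) + 5)
        assert np.mean(np.abs(errs)) < bound
        assert np.mean(errs) == pytest.approx(0.0, abs=bound)

    def test_loading_rate_exact_on_linear_ramp(self):
        n = 200
        disp = np.arange(n, dtype=float)
        force = -0.4 * disp  # constant slope -0.4 pN/nm
        curve = ForceCurve(disp, force, velocity=5000.0, spring_constant=25.0)
        k_eff, f_prime = effective_loading_rate(curve, 150)
        assert k_eff == pytest.approx(0.4, abs=1e-12)
        assert f_prime == pytest.approx(2000.0, abs=1e-9)

    def test_zero_slope_gives_zero_rate(self):
        curve = _flat_curve()
        k_eff, f_prime = effective_loading_rate(curve, 150)
        assert k_eff == 0.0 and f_prime == 0.0

    def test_insufficient_pre_samples_flagged(self):
        curve = _flat_curve()
        k_eff, f_prime = effective_loading_rate(curve, 10, m_pre=30)
        assert np.isnan(k_eff) and np.isnan(f_prime)

    def test_slope_estimate_within_regression_se(self):
        # closed-form LS slope SE: sigma / sqrt(sum((x - xbar)^2))
        m_pre = 30
        sxx = np.sum((np.arange(m_pre) - (m_pre - 1) / 2) ** 2)
        se = 5.0 / np.sqrt(sxx)
        within = 0
        n_trials = 100
        for seed in range(n_trials):
            curve, idx = _single_event_curve(f_r=120.0, k_eff=0.8, noise_sd=5.0, seed=seed)
            det = detect_ruptures(curve)
            near = [i for i in det if abs(i - idx) <= 5]
            assert near
            k_hat, _ = effective_loading_rate(curve, near[0], m_pre=m_pre)
            if abs(k_hat - 0.8) <= 3 * se:
                within += 1
        assert within / n_trials >= 0.95


class TestGate:
    @pytest.mark.parametrize(
        "f_r, f_prime, quadrant, specific",
        [
            (60.0, 2500.0, "II", True),
            (50.0, 2500.0, "I", False),  # boundary excluded: strict inequality
            (60.0, 1500.0, "IV", False),
            (40.0, 1500.0, "III", False),
            (60.0, 2000.0, "IV", False),
        ],
    )
    def test_quadrant_assignment(self, f_r, f_prime, quadrant, specific):
        q, s = classify_specific(f_r, f_prime)
        assert (q, s) == (quadrant, specific)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_specific(np.nan, 2500.0)

    def test_gate_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        f_r = rng.uniform(0, 150, 500)
        f_p = rng.uniform(0, 5000, 500)
        base = sum(classify_specific(a, b)[1] for a, b in zip(f_r, f_p))
        for gate in (GateThresholds(60.0, 2000.0), GateThresholds(50.0, 2500.0)):
            harder = sum(classify_specific(a, b, gate)[1] for a, b in zip(f_r, f_p))
            assert harder <= base

    def test_f_prime_consistency_on_emitted_events(self):
        cfg = sd.CurveSimConfig(n_curves=30, noise_sd=5.0, seed=23)
        curves, _ = sd.simulate_force_curves(cfg)
        for c in curves:
            for e in analyze_curve(c):
                if e.quantifiable:
                    assert e.F_prime == pytest.approx(e.k_eff * c.velocity, rel=1e-12)


class TestBindingFrequency:
    def _events(self, cell, cond, n_spec, n_tot):
        flags = [True] * n_spec + [False] * (n_tot - n_spec)
        return pd.DataFrame(
            {
                "curve_id": "c",
                "cell_id": cell,
                "condition": cond,
                "index_of_minimum": 0,
                "F_R_pN": 0.0,
                "k_eff_pN_per_nm": 0.0,
                "F_prime_pN_per_s": 0.0,
                "quadrant": "",
                "specific": flags,
                "quantifiable": True,
            }
        )

    def test_simple_fraction(self):
        s = binding_frequency(self._events("a", "x", 30, 200))
        assert s[0].f_b == pytest.approx(0.15)

    def test_zero_specific(self):
        s = binding_frequency(self._events("a", "x", 0, 200))
        assert s[0].f_b == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            binding_frequency(pd.DataFrame(columns=["cell_id", "condition", "specific"]))

    def test_relative_normalization(self):
        summaries = [
            CellBindingSummary("a", "ref", 10, 1, 0.1),
            CellBindingSummary("b", "ref", 10, 2, 0.2),
            CellBindingSummary("c", "test", 10, 3, 0.3),
        ]
        out = relative_binding_frequency(summaries, "ref")
        assert out[2].f_b_rel == pytest.approx(2.0)
        ref_mean = np.mean([s.f_b_rel for s in out if s.condition == "ref"])
        assert ref_mean == pytest.approx(1.0)

    def test_zero_reference_mean_rejected(self):
        summaries = [CellBindingSummary("a", "ref", 10, 0, 0.0)]
        with pytest.raises(ValueError):
            relative_binding_frequency(summaries, "ref")

    def test_condition_summary_sem(self):
        summaries = [
            CellBindingSummary("a", "x", 10, 1, 0.1),
            CellBindingSummary("b", "x", 10, 3, 0.3),
        ]
        out = summarize_condition(summaries)
        assert out["f_b_mean"].iloc[0] == pytest.approx(0.2)
        assert out["f_b_sem"].iloc[0] == pytest.approx(0.1)

    def test_binomial_sampling_of_f_b(self):
        rng = np.random.default_rng(5)
        p_true, n = 0.17, 200
        flags = rng.random(n) < p_true
        ev = self._events("a", "x", int(flags.sum()), n)
        s = binding_frequency(ev)
        assert abs(s[0].f_b - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n)


class TestNoiselessEndToEnd:
    def test_exact_recovery_of_planted_parameters(self):
        cfg = sd.CurveSimConfig(
            n_curves=10, noise_sd=0.0, specific_fraction=0.5, seed=31
        )
        curves, truth = sd.simulate_force_curves(cfg)
        for c in curves:
            rows = truth[truth.curve_id == c.curve_id]
            events = [e for e in analyze_curve(c, jump_threshold=4.0) if e.quantifiable]
            assert len(events) == len(rows)
            for e, (_, row) in zip(events, rows.iterrows()):
                assert e.index_of_minimum == row.index_of_minimum
                assert e.F_R == pytest.approx(row.F_R_pN, abs=1e-8)
                assert e.k_eff == pytest.approx(row.k_eff_pN_per_nm, abs=1e-8)
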