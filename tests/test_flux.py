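"""The signaling-strength statistic: unit behavior, oracle equivalence,
invariances."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autobcr.flux import (
    SignalingResult,
    average_replicates,
    baseline_threshold,
    cal_sir_aut,
    classify_signaling,
    q_aut,
    signaling_strength,
    unresponsive_fraction,
)
from autobcr.io import FluxProtocol, FluxSeries, gate_events
from autobcr.simulate import FluxSimParams, simulate_flux_experiment

from oracles import brute_force_signaling_strength, quantile_linear


def _series(time_s, sir, gfp=1000.0):
    """Build a series with ch485 = 100 and ch405 = sir * 100."""
    sir = np.asarray(sir, dtype=float)
    return FluxSeries(
        events=pd.DataFrame(
            {
                "time_s": np.asarray(time_s, dtype=float),
                "ch405": sir * 100.0,
                "ch485": np.full(len(sir), 100.0),
                "gfp": np.full(len(sir), gfp),
            }
        )
    )


def _three_phase_series(baseline_sir, autonomous_sir, crosslink_sir, protocol):
    """Evenly spaced events carrying the given SIR values per phase."""
    t_b = np.linspace(0, protocol.t_4oht_s, len(baseline_sir), endpoint=False)
    t_a = np.linspace(
        protocol.t_4oht_s, protocol.autonomous_end_s, len(autonomous_sir), endpoint=False
    )
    t_x = np.linspace(
        protocol.autonomous_end_s, protocol.crosslink_end_s, len(crosslink_sir), endpoint=False
    )
    return _series(
        np.concatenate([t_b, t_a, t_x]),
        np.concatenate([baseline_sir, autonomous_sir, crosslink_sir]),
    )


class TestBaselineThreshold:
    def test_constant_baseline(self, protocol):
        s = _three_phase_series([2.5] * 30, [2.5] * 30, [2.5] * 30, protocol)
        assert baseline_threshold(s, protocol) == 2.5

    def test_order_statistic_rule_1_to_100(self, protocol):
        vals = np.arange(1.0, 101.0)
        s = _three_phase_series(vals, [1.0] * 30, [1.0] * 30, protocol)
        expected = quantile_linear(vals, 0.95)
        assert baseline_threshold(s, protocol) == pytest.approx(expected, abs=1e-12)

    def test_too_few_baseline_events(self, protocol):
        s = _three_phase_series([1.0] * 5, [1.0] * 50, [1.0] * 50, protocol)
        with pytest.raises(ValueError, match="baseline"):
            baseline_threshold(s, protocol)


class TestUnresponsiveFraction:
    def test_all_above_threshold(self, protocol):
        s = _three_phase_series([1.0] * 30, [1.0] * 30, [5.0] * 60, protocol)
        u, peak = unresponsive_fraction(s, protocol, threshold=2.0)
        assert u == 0.0
        assert peak in protocol.crosslink_bins

    def test_all_below_threshold_gives_u_one(self, protocol):
        s = _three_phase_series([1.0] * 30, [1.0] * 30, [1.0] * 60, protocol)
        u, _ = unresponsive_fraction(s, protocol, threshold=2.0)
        assert u == 1.0
        with pytest.raises(ValueError, match="u >= 1|correction"):
            q_aut(s, protocol, threshold=2.0, u=u)

    def test_no_full_bin_error(self):
        proto = FluxProtocol(crosslink_end_s=550.0, bin_width_s=20.0)
        s = _three_phase_series([1.0] * 30, [1.0] * 30, [1.0] * 5, proto)
        with pytest.raises(ValueError, match="bin"):
            unresponsive_fraction(s, proto, threshold=2.0)

    def test_generator_u_true_recovered(self, protocol):
        params = FluxSimParams(n_cells=8000, p_aut=0.3, u_true=0.2, seed=17)
        series, _ = simulate_flux_experiment(params, protocol)
        gated = gate_events(series, gfp_min=500.0)
        thr = baseline_threshold(gated, protocol)
        u, _ = unresponsive_fraction(gated, protocol, thr)
        n_bin = sum(
            1 for t in gated.time_s if protocol.autonomous_end_s <= t < protocol.crosslink_end_s
        ) / len(protocol.crosslink_bins)
        sd = np.sqrt(0.2 * 0.8 / n_bin)
        assert abs(u - 0.2) < 3 * sd + 0.03


class TestQAut:
    def test_zero_raw_stays_zero(self, protocol):
        s = _three_phase_series([1.0] * 30, [0.5] * 30, [5.0] * 60, protocol)
        assert q_aut(s, protocol, threshold=2.0, u=0.3) == 0.0

    def test_identity_correction_at_u_zero(self, protocol):
        sir = [3.0] * 45 + [0.5] * 55  # 45% above threshold
        s = _three_phase_series([1.0] * 30, sir, [5.0] * 60, protocol)
        assert q_aut(s, protocol, threshold=2.0, u=0.0) == pytest.approx(0.45)

    def test_cap_at_one(self, protocol):
        sir = [3.0] * 50 + [0.5] * 50
        s = _three_phase_series([1.0] * 30, sir, [5.0] * 60, protocol)
        assert q_aut(s, protocol, threshold=2.0, u=0.5) == 1.0


class TestCalSir:
    def test_ratio_one_when_distributions_match(self, protocol):
        s = _three_phase_series([1.0] * 30, [4.0] * 30, [4.0] * 60, protocol)
        assert cal_sir_aut(s, protocol, threshold=2.0) == pytest.approx(1.0)

    def test_zero_convention_without_responders(self, protocol):
        s = _three_phase_series([1.0] * 30, [0.5] * 30, [4.0] * 60, protocol)
        assert cal_sir_aut(s, protocol, threshold=2.0) == 0.0

    def test_half_amplitude_noise_free(self, protocol):
        """a_aut = a_max / 2 in a noise-free step model gives ratio 0.5."""
        params = FluxSimParams(
            n_cells=3000, p_aut=1.0, u_true=0.0, a_aut=2.0, a_max=4.0,
            noise_cv=0.0, response_lag_s=0.0, transduced_fraction=1.0, seed=1,
        )
        series, _ = simulate_flux_experiment(params, protocol)
        thr = baseline_threshold(series, protocol)
        assert cal_sir_aut(series, protocol, thr) == pytest.approx(0.5, abs=1e-12)


class TestComposite:
    def test_oracle_equivalence_small_fixture(self, protocol):
        """Full statistic matches the independent per-event oracle to 1e-12."""
        params = FluxSimParams(n_cells=200, p_aut=0.5, u_true=0.1, seed=42)
        series, _ = simulate_flux_experiment(params, protocol)
        res = signaling_strength(series, protocol)
        thr, u, q, cal, strength = brute_force_signaling_strength(
            series.time_s, series.events["ch405"], series.events["ch485"], protocol
        )
        assert res.baseline_threshold == pytest.approx(thr, abs=1e-12)
        assert res.unresponsive_fraction == pytest.approx(u, abs=1e-12)
        assert res.q_aut == pytest.approx(q, abs=1e-12)
        assert res.cal_sir_aut == pytest.approx(cal, abs=1e-12)
        assert res.strength == pytest.approx(strength, abs=1e-12)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        """Rescaling both Indo-1 channels leaves every result field unchanged."""
        protocol = FluxProtocol()
        params = FluxSimParams(n_cells=400, p_aut=0.5, seed=3)
        series, _ = simulate_flux_experiment(params, protocol)
        res = signaling_strength(series, protocol)
        scaled = FluxSeries(events=series.events.assign(
            ch405=series.events["ch405"] * scale, ch485=series.events["ch485"] * scale
        ))
        res2 = signaling_strength(scaled, protocol)
        assert res2.q_aut == pytest.approx(res.q_aut, rel=1e-9)
        assert res2.cal_sir_aut == pytest.approx(res.cal_sir_aut, rel=1e-9)
        assert res2.strength == pytest.approx(res.strength, rel=1e-9)
        assert res2.unresponsive_fraction == pytest.approx(res.unresponsive_fraction, rel=1e-9)

    def test_strength_monotone_in_responder_fraction(self, protocol):
        """More autonomous responders never means lower expected strength."""
        means = []
        for p_aut in (0.1, 0.4, 0.7, 1.0):
            vals = []
            for seed in range(4):
                params = FluxSimParams(n_cells=2000, p_aut=p_aut, u_true=0.0, seed=seed)
                series, _ = simulate_flux_experiment(params, protocol)
                gated = gate_events(series, gfp_min=500.0)
                vals.append(signaling_strength(gated, protocol).strength)
            means.append(np.mean(vals))
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))

    def test_stage_annotated_error(self, protocol):
        s = _three_phase_series([1.0] * 5, [1.0] * 30, [1.0] * 30, protocol)
        with pytest.raises(ValueError, match=r"\[baseline_threshold\]"):
            signaling_strength(s, protocol)

    def test_bounds(self, protocol):
        params = FluxSimParams(n_cells=1000, p_aut=0.8, u_true=0.1, seed=5)
        series, _ = simulate_flux_experiment(params, protocol)
        res = signaling_strength(gate_events(series, gfp_min=500.0), protocol)
        assert 0.0 <= res.q_aut <= 1.0
        assert res.strength >= 0.0
        assert res.strength == pytest.approx(res.q_aut * res.cal_sir_aut, abs=1e-15)


class TestReplicatesAndClassification:
    def test_average(self):
        assert average_replicates([0.4, 0.6]) == pytest.approx(0.5)
        assert average_replicates([0.7]) == pytest.approx(0.7)
        vals = [0.1, 0.2, 0.7]
        assert average_replicates(vals) == pytest.approx(sum(vals) / 3)

    def test_average_accepts_results(self):
        r = SignalingResult(
            baseline_threshold=1.0, q_aut=0.5, cal_sir_aut=0.8, strength=0.4,
            unresponsive_fraction=0.0, peak_bin=(540.0, 560.0), n_events={},
        )
        assert average_replicates([r, 0.6]) == pytest.approx(0.5)

    def test_average_empty_error(self):
        with pytest.raises(ValueError, match="empty"):
            average_replicates([])

    def test_classification_and_tie_rule(self):
        assert classify_signaling(0.9, [0.05, 0.1]) == "signaling"
        assert classify_signaling(0.1, [0.05, 0.1]) == "non_signaling"  # tie
        assert classify_signaling(0.01, [0.05, 0.1]) == "non_signaling"
        with pytest.raises(ValueError, match="control"):
            classify_signaling(0.5, [])
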