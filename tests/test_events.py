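"""Trace idealization, dwell statistics, and empirical open probability."""

import numpy as np
import pandas as pd
import pytest

import lipidpore as lp
from lipidpore.events import EventList, _empty_events
from lipidpore.synth import CurrentTrace, _lowpass

FS = 10_000.0


def _trace(current, voltage=0.19, meta=None):
    n = len(current)
    return CurrentTrace(np.arange(n) / FS, current, np.full(n, voltage),
                        meta or {"level_V": voltage})


def _gating_trace(pe, gk, g_single, v, duration, seed, noise_sd=1e-12,
                  g_leak=0.37e-9, n_pores=1):
    """Trace built directly from the gating simulator, returning the true counts."""
    counts = lp.simulate_gating(pe, gk, n_pores, v, duration, seed=seed)
    rng = np.random.default_rng(seed + 1)
    cur = (g_leak + g_single * counts) * v + rng.normal(0, noise_sd, len(counts))
    cur = _lowpass(cur, FS, lp.NoiseModel(current_noise_sd_A=noise_sd))
    return _trace(cur, v), counts


def test_constant_trace_has_no_events():
    ev = lp.idealize(_trace(np.full(5000, 50e-12)))
    assert len(ev) == 0 and ev.n_levels == 1
    assert ev.fraction_time_open == 0.0


def test_square_wave_boundaries_recovered_to_one_sample():
    current = np.zeros(8000)
    openings = [(1000, 1800), (3000, 3550), (6000, 7200)]
    for a, b in openings:
        current[a:b] = 13e-12
    ev = lp.idealize(_trace(current), min_event_s=0.002)
    assert len(ev) == len(openings)
    for (a, b), (_, row) in zip(openings, ev.events.iterrows()):
        assert abs(row["start_s"] * FS - a) <= 1
        assert abs(row["end_s"] * FS - b) <= 1
    assert ev.step_amplitude_A == pytest.approx(13e-12, rel=0.02)


def test_idealize_recovers_simulated_channel():
    """Paper-scale SNR: 68 pS steps at 190 mV, 30 ms lifetime, 1 pA noise."""
    pe = lp.PoreEnergetics(1.9855, -55.0, 0.0)     # P_open(0.19 V) ~ 0.5
    gk = lp.GatingKinetics(0.03)
    trace, counts = _gating_trace(pe, gk, 68e-12, 0.19, 20.0, seed=7)
    ev = lp.idealize(lp.baseline_correct(trace))
    true_step = 68e-12 * 0.19                       # 12.9 pA
    assert ev.step_amplitude_A == pytest.approx(true_step, rel=0.10)
    true_openings = int(np.sum(np.diff(counts) > 0))
    assert len(ev) == pytest.approx(true_openings, rel=0.20)
    # single-channel conductance from the modal step
    g = lp.single_channel_conductance(ev.step_amplitude_A, 0.19)
    assert g == pytest.approx(68e-12, rel=0.10)


def test_step_estimate_invariant_to_offset_and_drift():
    pe = lp.PoreEnergetics(1.9855, -55.0, 0.0)
    gk = lp.GatingKinetics(0.03)
    trace, _ = _gating_trace(pe, gk, 68e-12, 0.19, 10.0, seed=11)
    ev0 = lp.idealize(lp.baseline_correct(trace))
    drifted = CurrentTrace(trace.time_s,
                           trace.current_A + 20e-12 + 1e-12 * trace.time_s,
                           trace.voltage_V, trace.metadata)
    bc = lp.baseline_correct(drifted)
    assert abs(bc.metadata["baseline_drift_removed_A_per_s"] - 1e-12) < 0.1e-12
    ev1 = lp.idealize(bc)
    assert ev1.step_amplitude_A == pytest.approx(ev0.step_amplitude_A, rel=0.05)


def test_baseline_correct_edge_cases():
    flat = _trace(np.full(5000, 10e-12))
    assert np.allclose(lp.baseline_correct(flat).current_A, 10e-12, atol=1e-18)
    ramp = _trace(5e-12 * np.arange(5000) / FS)
    out = lp.baseline_correct(ramp)
    assert np.ptp(out.current_A) < 0.02 * np.ptp(ramp.current_A)
    with pytest.raises(ValueError):
        lp.baseline_correct(_trace(np.zeros(5)))


def test_two_superposed_channels_give_three_levels():
    rng = np.random.default_rng(5)
    counts = np.zeros(40_000)
    counts[5000:15000] += 1
    counts[10000:25000] += 1      # overlap: level 2
    cur = 13e-12 * counts + rng.normal(0, 0.5e-12, len(counts))
    ev = lp.idealize(_trace(_lowpass(cur, FS, lp.NoiseModel())))
    assert ev.n_levels == 3
    assert sorted(ev.events["level_index"].unique()) == [1, 2]


def test_openings_below_baseline_at_negative_voltage():
    current = np.zeros(8000)
    current[2000:4000] = -13e-12   # opening carries negative current at V < 0
    ev = lp.idealize(_trace(current, voltage=-0.19))
    assert len(ev) == 1
    assert ev.step_amplitude_A == pytest.approx(-13e-12, rel=0.02)


def test_dwell_time_stats():
    one = EventList(pd.DataFrame([{"start_s": 0.1, "end_s": 0.15,
                                   "level_index": 1, "amplitude_A": 13e-12}]),
                    0.0, 13e-12, 2, 1.0, open_time_s=0.05)
    st = lp.dwell_time_stats(one)
    assert st["mean_open_s"] == pytest.approx(0.05)
    assert st["n_open"] == 1 and st["n_closed"] == 0

    empty = EventList(_empty_events(), 0.0, 0.0, 1, 1.0)
    assert lp.dwell_time_stats(empty)["n_open"] == 0


def test_dwell_means_from_exact_idealization():
    """Noise-free square-wave idealization reproduces the exponential dwell means."""
    pe = lp.PoreEnergetics(0.0, 0.0, 0.0)
    gk = lp.GatingKinetics(0.02)
    counts = lp.simulate_gating(pe, gk, 1, 0.1, 60.0, seed=9)
    cur = 13e-12 * counts
    ev = lp.idealize(_trace(cur, 0.1), min_event_s=0.0)
    st = lp.dwell_time_stats(ev)
    assert st["n_open"] >= 500
    se = 0.02 / np.sqrt(st["n_open"])
    assert abs(st["mean_open_s"] - 0.02) < 3 * se + 2 / FS
    assert st["close_rate_per_s"] == pytest.approx(1 / st["mean_open_s"])


def test_empirical_open_probability_table():
    always_closed = EventList(_empty_events(), 0.0, 0.0, 1, 2.0)
    always_open = EventList(
        pd.DataFrame([{"start_s": 0.0, "end_s": 2.0, "level_index": 1,
                       "amplitude_A": 13e-12}]),
        0.0, 13e-12, 2, 2.0, open_time_s=2.0, mean_level=1.0)
    table = lp.empirical_open_probability({-0.1: always_closed, 0.19: always_open},
                                          n_pores=1)
    by_v = table.set_index("voltage_V")
    assert by_v.loc[-0.1, "fraction_time_open"] == 0.0
    assert by_v.loc[0.19, "fraction_time_open"] == 1.0
    assert by_v.loc[0.19, "p_open_per_pore"] == 1.0


def test_empirical_open_probability_matches_model_across_voltages():
    """The whole stack: simulate -> idealize -> occupancy equals Boltzmann P_open."""
    pe = lp.PoreEnergetics(1.0, -40.0, 0.0)
    gk = lp.GatingKinetics(0.03)
    lists, pops = {}, {}
    for v in (0.1, 0.15, 0.19):
        trace, counts = _gating_trace(pe, gk, 68e-12, v, 30.0, seed=int(v * 1000))
        lists[v] = lp.idealize(lp.baseline_correct(trace))
        pops[v] = lp.open_probability(pe, v)
    table = lp.empirical_open_probability(lists, n_pores=1).set_index("voltage_V")
    for v, p in pops.items():
        tau_c = 1.0 / (gk.k_open_per_s(pe, v) + gk.k_close_per_s)
        se = np.sqrt(2 * p * (1 - p) * tau_c / 30.0)
        assert abs(table.loc[v, "p_open_per_pore"] - p) < 3 * se + 0.01
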