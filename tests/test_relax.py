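"""Biexponential relaxation: forward model and shared-tau fitting."""

import numpy as np
import pytest

import lipidpore as lp
from lipidpore.relax import TransientDecomposition, transient_amplitudes
from lipidpore.synth import CurrentTrace

TAU0, TAUM = 258e-6, 1.74e-3


def _trace_from_curve(t, current, level, fs=10_000.0, n_pre=100):
    tt = np.arange(len(t) + n_pre) / fs
    cc = np.concatenate([np.zeros(n_pre), current])
    vv = np.concatenate([np.zeros(n_pre), np.full(len(t), level)])
    return CurrentTrace(tt, cc, vv, {"level_V": level, "pre_step_s": n_pre / fs,
                                     "sample_rate_Hz": fs})


def _synthetic_series(levels, td=None, noise=0.0, seed=0, fs=10_000.0):
    td = td or TransientDecomposition(100e-12, 110e-12, 0.37e-9, 0.5e-9, 0.0, 2e-12)
    rng = np.random.default_rng(seed)
    t = np.arange(0, 0.05, 1 / fs)
    traces = []
    for v in levels:
        cur = lp.forward_transient(td, v, TAU0, TAUM, t)
        if noise:
            cur = cur + rng.normal(0, noise, len(t))
        traces.append(_trace_from_curve(t, cur, v, fs))
    return traces, td


def test_transient_amplitudes_arithmetic():
    td = TransientDecomposition(100e-12, 100e-12, 0.3e-9, 0.3e-9)
    a0, am = transient_amplitudes(td, 0.0, 0.1, TAU0, TAUM)
    assert a0 == pytest.approx(100e-12 * 0.1 / TAU0)          # 38.76 nA
    assert a0 == pytest.approx(38.76e-9, rel=1e-3)
    assert am == 0.0                                           # no structural change


def test_forward_transient_limits():
    td = TransientDecomposition(100e-12, 100e-12, 0.3e-9, 0.3e-9)
    t = np.array([0.0, 1e-3, 0.1])
    # dV = 0 and no structural change: constant g_b * V_a
    cur = lp.forward_transient(td, 0.1, TAU0, TAUM, t, v_before=0.1)
    assert np.allclose(cur, 0.3e-9 * 0.1)
    # tail equals the steady-state plateau g_a V_a
    td2 = TransientDecomposition(100e-12, 115e-12, 0.3e-9, 0.9e-9, 0.0, 3e-12)
    tail = lp.forward_transient(td2, 0.15, TAU0, TAUM, np.array([0.5]))
    assert tail[0] == pytest.approx(0.9e-9 * 0.15, rel=1e-9)
    with pytest.raises(ValueError):
        lp.forward_transient(td, 0.1, TAUM, TAU0, t)


def test_forward_transient_term_by_term():
    """Full curve equals the hand-evaluated three-term expression."""
    td = TransientDecomposition(100e-12, 112e-12, 0.37e-9, 0.61e-9, 0.0, 2.5e-12)
    va, vb = 0.125, 0.0
    t = np.linspace(0, 0.02, 200)
    dv = va - vb
    expected = (td.cap_before_F / TAU0 * dv * np.exp(-t / TAU0)
                + (td.delta_cap_F * va + td.delta_pol_charge_C) * np.exp(-t / TAUM) / TAUM
                + (td.g_before_S + td.delta_g_S * (1 - np.exp(-t / TAUM))) * va)
    assert np.allclose(lp.forward_transient(td, va, TAU0, TAUM, t, vb), expected, rtol=1e-12)


def test_fit_recovers_shared_taus_and_amplitudes():
    """fit o forward is the identity on (tau0, taum, plateau, A0, Am) for clean data."""
    levels = [0.05, 0.1, 0.15, 0.2, -0.1, -0.2]
    traces, td = _synthetic_series(levels)
    rf = lp.fit_biexponential_series(traces)
    assert rf.tau_fast_s == pytest.approx(TAU0, rel=0.01)
    assert rf.tau_slow_s == pytest.approx(TAUM, rel=0.01)
    for _, row in rf.jumps.iterrows():
        v = row["level_V"]
        a0, am = transient_amplitudes(td, 0.0, v, TAU0, TAUM)
        assert row["plateau_A"] == pytest.approx(td.g_after_S * v, rel=0.01)
        assert row["amp_fast_A"] == pytest.approx(a0, rel=0.01)
        assert row["amp_slow_A"] == pytest.approx(am, rel=0.05)


def test_fit_with_fixed_fast_tau():
    traces, _ = _synthetic_series([0.1, 0.2])
    rf = lp.fit_biexponential_series(traces, fixed_tau_fast_s=TAU0)
    assert rf.tau_fast_s == TAU0
    assert rf.tau_slow_s == pytest.approx(TAUM, rel=0.01)


def test_single_exponential_input_gives_one_null_amplitude():
    t = np.arange(0, 0.05, 1e-4)
    cur = 50e-12 + 2e-10 * np.exp(-t / TAUM)
    rf = lp.fit_biexponential_series([_trace_from_curve(t, cur, 0.1)])
    amps = np.abs(rf.jumps[["amp_fast_A", "amp_slow_A"]].to_numpy()[0])
    assert min(amps) < 0.02 * max(amps)
    assert rf.jumps["plateau_A"][0] == pytest.approx(50e-12, rel=0.02)


def test_plateau_matches_tail_mean():
    traces, td = _synthetic_series([0.1, 0.2, -0.15], noise=2e-12, seed=4)
    rf = lp.fit_biexponential_series(traces, window_s=0.04)
    for trace, (_, row) in zip(traces, rf.jumps.iterrows()):
        j = 100
        tail = trace.current_A[j:][trace.time_s[j:] - trace.time_s[j] > 0.03]
        se = np.std(tail, ddof=1) / np.sqrt(len(tail))
        # the exponential terms are < 1e-7 of A by 0.03 s (>17 tau_m), so the
        # fitted constant must agree with the raw tail mean up to noise
        assert abs(row["plateau_A"] - np.mean(tail)) < 3 * se + 1e-15


def test_per_jump_taus_close_to_shared_on_shared_data():
    traces, _ = _synthetic_series([0.05, 0.1, 0.15, 0.2])
    shared = lp.fit_biexponential_series(traces, shared_taus=True)
    per = lp.fit_biexponential_series(traces, shared_taus=False)
    for col, ref in (("tau_fast_s", shared.tau_fast_s), ("tau_slow_s", shared.tau_slow_s)):
        assert np.all(np.abs(per.jumps[col] - ref) / ref < 0.05)


def test_amplitude_voltage_classification():
    levels = np.array([0.05, 0.1, 0.15, 0.2, -0.05, -0.1, -0.15, -0.2])
    # rectified I-V profile: leak plus gated pores on the positive branch
    cs = lp.ConductanceSet(g_leak_S=0.3e-9, g_pores_S=1.5e-9)
    pe = lp.PoreEnergetics(2.0, -60.0, -0.15)
    env = lp.Environment()
    iv_current = lp.steady_state_current(cs, pe, env, levels)
    iv = lp.IVProfile(levels, iv_current, np.zeros(8), np.full(8, 10))

    lin = 2e-10 * levels
    nl = iv_current - np.sum(levels * iv_current) / np.sum(levels ** 2) * levels
    both_linear = lp.RelaxationFit(TAU0, TAUM, __import__("pandas").DataFrame({
        "level_V": levels, "amp_fast_A": lin, "amp_slow_A": 0.5 * lin,
        "plateau_A": iv_current, "rss": 0.0}))
    out = lp.amplitude_voltage_analysis(both_linear, iv)
    assert out["amp_fast"]["classification"] == "linear"
    assert out["amp_slow"]["classification"] == "linear"

    # fast amplitude tracking the conductance change after the jump (Delta g V)
    rect = lp.RelaxationFit(TAU0, TAUM, __import__("pandas").DataFrame({
        "level_V": levels, "amp_fast_A": lin + 3e-10 * nl / np.max(np.abs(nl)),
        "amp_slow_A": 0.5 * lin, "plateau_A": iv_current, "rss": 0.0}))
    out = lp.amplitude_voltage_analysis(rect, iv)
    assert out["amp_fast"]["classification"] == "rectified"
    assert out["amp_slow"]["classification"] == "linear"

    with pytest.raises(ValueError):
        lp.amplitude_voltage_analysis(
            lp.RelaxationFit(TAU0, TAUM, both_linear.jumps.iloc[:3]), iv)
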