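"""Steady-state I-V extraction, model fitting, and depth comparison."""

import numpy as np
import pytest

import lipidpore as lp
from lipidpore.steady import IVProfile

from conftest import make_equilibrium_series


def _profile_from_model(cs, pe, env, levels=None, sd=0.0, n=100):
    levels = np.asarray(levels if levels is not None else lp.build_protocol().levels_V)
    i = lp.steady_state_current(cs, pe, env, levels)
    return IVProfile(levels, i, np.full(len(levels), sd), np.full(len(levels), n))


def test_correct_offset_cancels_constant():
    prot = lp.VoltageProtocol(levels_V=(0.1,), step_s=0.3)
    cs = lp.ConductanceSet(g_leak_S=1e-9)
    pe = lp.PoreEnergetics(2, 50, 0.2)
    nm = lp.NoiseModel(current_noise_sd_A=0.0, filter_cutoff_Hz=None)
    tp = lp.TransientParams(amp_fast_A_per_V=0.0, amp_slow_A_per_V=0.0)
    tr = lp.simulate_trace(prot, cs, pe, lp.Environment(), tp=tp, nm=nm, seed=0)[0]
    shifted = lp.CurrentTrace(tr.time_s, tr.current_A + 5e-12, tr.voltage_V, tr.metadata)
    corrected = lp.correct_offset(shifted)
    assert np.allclose(corrected.current_A, tr.current_A, atol=1e-20)
    # idempotent on an already-centred trace
    again = lp.correct_offset(corrected)
    assert np.allclose(again.current_A, corrected.current_A, atol=1e-20)


def test_correct_offset_requires_holding_segment():
    tr = lp.CurrentTrace(np.arange(10) / 1e4, np.zeros(10), np.full(10, 0.1),
                         {"holding_V": 0.0})
    with pytest.raises(ValueError):
        lp.correct_offset(tr)


def test_extract_iv_constant_traces():
    traces = []
    for v, i in ((0.1, 5e-12), (-0.1, -5e-12)):
        t = np.arange(31_500) / 1e4
        volt = np.full(31_500, v)
        volt[:500] = 0.0
        traces.append(lp.CurrentTrace(t, np.full(31_500, i), volt,
                                      {"level_V": v, "pre_step_s": 0.05,
                                       "holding_V": 0.0}))
    prof = lp.extract_iv(traces)
    assert np.allclose(prof.mean_current_A, [5e-12, -5e-12])
    assert np.allclose(prof.sd_current_A, 0.0)
    with pytest.raises(ValueError):
        lp.extract_iv(traces, window_s=(3.0, 1.5))


def test_extract_iv_matches_forward_model(patch_energetics, env):
    """Noise-free simulated tails reproduce the steady-state model at every level."""
    cs = lp.ConductanceSet(g_leak_S=0.37e-9, g_pores_S=1.5e-9)
    traces = make_equilibrium_series(cs, patch_energetics, env, seed=0, noise_sd_A=0.0)
    prof = lp.extract_iv([lp.correct_offset(t) for t in traces])
    expected = lp.steady_state_current(cs, patch_energetics, env, prof.voltages_V)
    assert np.allclose(prof.mean_current_A, expected, rtol=1e-6, atol=1e-16)


def test_extract_iv_discard_first_flags_outlier(patch_energetics, env):
    cs = lp.ConductanceSet(g_leak_S=0.37e-9, g_pores_S=1.5e-9)
    traces = make_equilibrium_series(cs, patch_energetics, env, seed=0)
    prof = lp.extract_iv(traces, discard_first=True)
    assert prof.excluded[0] and prof.usable.sum() == 16


def test_fit_linear_exact_and_noisy():
    levels = np.asarray(lp.build_protocol().levels_V)
    exact = IVProfile(levels, 372e-12 * levels, np.zeros(17), np.full(17, 100))
    assert lp.fit_linear(exact).g_leak_S == pytest.approx(372e-12, rel=1e-12)

    rng = np.random.default_rng(0)
    noisy = IVProfile(levels, 372e-12 * levels + rng.normal(0, 2e-12, 17),
                      np.full(17, 2e-12), np.full(17, 1))
    fit = lp.fit_linear(noisy)
    se = 2e-12 / np.sqrt(np.sum(levels ** 2))
    assert abs(fit.g_leak_S - 372e-12) < 3 * se

    zero = IVProfile(levels, np.zeros(17), np.zeros(17), np.full(17, 100))
    assert lp.fit_linear(zero).g_leak_S == 0.0
    with pytest.raises(ValueError):
        lp.fit_linear(IVProfile([0.1], [1e-12], [0.0], [1]))


def test_fit_iv_recovers_generating_parameters(patch_energetics, env):
    """Free-leak fit on Eq.-5 data with 2 pA noise recovers g_L and V0."""
    cs = lp.ConductanceSet(g_leak_S=0.37e-9, g_pores_S=1.5e-9)
    traces = make_equilibrium_series(cs, patch_energetics, env, seed=1)
    prof = lp.extract_iv([lp.correct_offset(t) for t in traces], discard_first=True)
    fit = lp.fit_iv(prof, "free_leak")
    assert fit.g_leak_S == pytest.approx(0.37e-9, rel=0.05)
    assert fit.offset_V == pytest.approx(0.2, abs=0.015)
    # the extremal open probability is reported at -V0 (self-consistency)
    assert fit.min_open_probability == pytest.approx(
        lp.open_probability(fit.energetics, -fit.offset_V))
    assert fit.min_open_probability_voltage_V == pytest.approx(-fit.offset_V)


def test_fit_iv_nested_models_rss_ordering(patch_energetics, env):
    cs = lp.ConductanceSet(g_leak_S=0.37e-9, g_pores_S=1.5e-9)
    traces = make_equilibrium_series(cs, patch_energetics, env, seed=2)
    prof = lp.extract_iv([lp.correct_offset(t) for t in traces], discard_first=True)
    free = lp.fit_iv(prof, "free_leak")
    pores = lp.fit_iv(prof, "pores_only")
    fixed = lp.fit_iv(prof, "fixed_leak", fixed_g_leak_S=0.372e-9)
    assert pores.g_leak_S == 0.0
    assert fixed.g_leak_S == 0.372e-9
    assert free.residual_sum_squares <= pores.residual_sum_squares * (1 + 1e-9)
    assert free.residual_sum_squares <= fixed.residual_sum_squares * (1 + 1e-9)


def test_fit_iv_symmetric_blm_profile_has_no_offset(blm_energetics, env):
    cs = lp.ConductanceSet(g_leak_S=270e-12, g_pores_S=863e-12)
    traces = make_equilibrium_series(cs, blm_energetics, env, seed=3)
    prof = lp.extract_iv([lp.correct_offset(t) for t in traces], discard_first=True)
    fit = lp.fit_iv(prof, "free_leak")
    assert abs(fit.offset_V) < 0.010


def test_fit_iv_preconditions():
    prof = IVProfile([0.1, 0.2, 0.3], [1e-12, 2e-12, 3e-12],
                     [0, 0, 0], [1, 1, 1])
    with pytest.raises(ValueError):
        lp.fit_iv(prof, "free_leak")
    full = _profile_from_model(lp.ConductanceSet(0.3e-9, 1e-9),
                               lp.PoreEnergetics(2, -60, 0.1), lp.Environment())
    with pytest.raises(ValueError):
        lp.fit_iv(full, "fixed_leak")


def test_fit_self_consistency_on_own_forward_model(env):
    """Fitting the model's own noise-free output returns the generating curve."""
    cs = lp.ConductanceSet(g_leak_S=0.3e-9, g_pores_S=1.2e-9)
    pe = lp.PoreEnergetics(2.0, -80.0, 0.15)
    prof = _profile_from_model(cs, pe, env)
    fit = lp.fit_iv(prof, "free_leak")
    assert np.allclose(fit.predict(prof.voltages_V), prof.mean_current_A,
                       atol=1e-4 * np.max(np.abs(prof.mean_current_A)))
    assert fit.offset_V == pytest.approx(0.15, abs=5e-3)


def test_detect_negative_slope():
    env = lp.Environment()
    # strong gating on the negative branch pulls dI/dV below zero near -75 mV
    cs = lp.ConductanceSet(g_leak_S=0.1e-9, g_pores_S=3e-9)
    pe = lp.PoreEnergetics(0.0, -100.0, 0.2)
    prof = _profile_from_model(cs, pe, env)
    intervals = lp.detect_negative_slope(prof)
    assert intervals and all(hi < 0 for _, hi in intervals)

    mono = _profile_from_model(lp.ConductanceSet(g_leak_S=1e-9),
                               lp.PoreEnergetics(2, 50, 0.2), env)
    assert lp.detect_negative_slope(mono) == []

    v = np.linspace(-0.2, 0.2, 9)
    falling = IVProfile(v, -1e-12 * np.arange(9), np.zeros(9), np.full(9, 10))
    (lo, hi), = lp.detect_negative_slope(falling)
    assert lo == pytest.approx(-0.2) and hi == pytest.approx(0.2)


def test_compare_depths_percent_changes(patch_energetics, env):
    base = lp.IVFitResult("free_leak", 1.0e-9, 2.0e-9, 0.24, 4, 40, 0.0)
    deep = lp.IVFitResult("free_leak", 1.32e-9, 2.74e-9, 0.22, 4, 40, 0.0)
    out = lp.compare_depths({"1mm": [base], "3mm": [deep]})
    ch = out["changes"].set_index("quantity")["percent_change"]
    assert ch["g_leak"] == pytest.approx(32.0)
    assert ch["g_pores"] == pytest.approx(37.0)
    same = lp.compare_depths({"a": [base], "b": [base]})
    assert np.allclose(same["changes"]["percent_change"], 0.0)
    with pytest.raises(ValueError):
        lp.compare_depths({"a": [lp.IVFitResult("free_leak", 0.0, 1e-9, 0.2, 4, 40, 0.0)],
                           "b": [base]})


def test_compare_depths_roundtrip_through_simulation(patch_energetics, env):
    """Depth factors applied by the generator are recovered by the fits."""
    cs = lp.ConductanceSet(g_leak_S=0.37e-9, g_pores_S=1.5e-9)
    fits = {}
    for depth, (fl, fp) in ((1.0, (1.0, 1.0)), (3.0, (1.32, 1.37))):
        scaled, _ = lp.depth_condition(cs, depth, fl, fp)
        traces = make_equilibrium_series(scaled, patch_energetics, env, seed=int(depth))
        prof = lp.extract_iv([lp.correct_offset(t) for t in traces], discard_first=True)
        fits[depth] = [lp.fit_iv(prof, "free_leak")]
    ch = lp.compare_depths(fits)["changes"].set_index("quantity")["percent_change"]
    assert ch["g_leak"] == pytest.approx(32.0, abs=5.0)
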