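"""Synthetic voltage-clamp trace generator.

Emulates the droplet patch-clamp step protocol (holding at 0 V, steps from
+200 to −200 mV in −25 mV increments, 3.1 s per step, 10 kHz sampling, 2 kHz
causal low-pass) driven by the two-process conduction model: a constant leak
plus N identical pores gating as independent two-state Markov channels whose
equilibrium occupancy is the Boltzmann open probability of
:mod:`lipidpore.core`.  Post-jump capacitive/structural transients are
superposed as a biexponential, and white current noise is added before the
low-pass filter, as in the recording hardware.

Two geometries are modelled: ``patch`` (curved membrane on a ~um pipette tip,
nonzero polarization offset V0, rectified I-V) and ``BLM`` (flat black lipid
membrane on a ~100 um aperture, V0 forced to 0, symmetric I-V).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import signal

from .core import ConductanceSet, Environment, PoreEnergetics, open_probability, pore_free_energy

__all__ = [
    "VoltageProtocol",
    "GatingKinetics",
    "TransientParams",
    "NoiseModel",
    "CurrentTrace",
    "build_protocol",
    "simulate_gating",
    "simulate_trace",
    "depth_condition",
]

_DMU_CLAMP = 700.0  # exp() overflow guard for the equilibrium constant


@dataclass(frozen=True)
class VoltageProtocol:
    """Step protocol: holding segment followed by one voltage step per level."""

    levels_V: tuple[float, ...]
    holding_V: float = 0.0
    pre_step_s: float = 0.05
    step_s: float = 3.1
    sample_rate_Hz: float = 10_000.0

    def __post_init__(self) -> None:
        if self.pre_step_s <= 0 or self.step_s <= 0 or self.sample_rate_Hz <= 0:
            raise ValueError("durations and sample rate must be positive")
        if len(self.levels_V) == 0:
            raise ValueError("protocol needs at least one level")

    @property
    def n_levels(self) -> int:
        return len(self.levels_V)

    @property
    def total_stepped_s(self) -> float:
        """Summed duration of the stepped segments (excludes holding)."""
        return self.n_levels * self.step_s


@dataclass(frozen=True)
class GatingKinetics:
    """Two-state pore kinetics.

    The closing rate is voltage independent, k_close = 1/mean_open_lifetime
    (single-channel conductance and open lifetime do not depend on voltage in
    the recordings this emulates); all voltage dependence sits in the opening
    rate, k_open(V) = k_close * K(V), so detailed balance gives the Boltzmann
    equilibrium occupancy exactly.
    """

    mean_open_lifetime_s: float = 0.03

    def __post_init__(self) -> None:
        if self.mean_open_lifetime_s <= 0:
            raise ValueError("mean open lifetime must be positive")

    @property
    def k_close_per_s(self) -> float:
        return 1.0 / self.mean_open_lifetime_s

    def k_open_per_s(self, pe: PoreEnergetics, v: float) -> float:
        dmu = float(np.clip(pore_free_energy(pe, v), -_DMU_CLAMP, _DMU_CLAMP))
        return self.k_close_per_s * math.exp(-dmu)


@dataclass(frozen=True)
class TransientParams:
    """Post-jump biexponential transient I = A0 e^{-t/tau0} + Am e^{-t/taum}.

    Amplitudes scale linearly with the jump size dV; the per-volt coefficients
    are generator knobs (the structural amplitudes of a real membrane are
    fitted, not predicted).  ``decomposition``, when given, overrides them with
    the exact amplitudes of the charge/conductance relaxation model
    (see :func:`lipidpore.relax.transient_amplitudes`).
    """

    tau_fast_s: float = 258e-6
    tau_slow_s: float = 1.74e-3
    amp_fast_A_per_V: float = 2e-9
    amp_slow_A_per_V: float = 5e-10
    decomposition: "object | None" = None  # lipidpore.relax.TransientDecomposition

    def __post_init__(self) -> None:
        if not (0 < self.tau_fast_s < self.tau_slow_s):
            raise ValueError("require 0 < tau_fast < tau_slow")

    def amplitudes(self, v_before: float, v_after: float) -> tuple[float, float]:
        """(A0, Am) for a jump v_before -> v_after."""
        if self.decomposition is not None:
            from .relax import transient_amplitudes

            return transient_amplitudes(self.decomposition, v_before, v_after,
                                        self.tau_fast_s, self.tau_slow_s)
        dv = v_after - v_before
        return self.amp_fast_A_per_V * dv, self.amp_slow_A_per_V * dv


@dataclass(frozen=True)
class NoiseModel:
    """White current noise plus an optional causal low-pass (Bessel) filter."""

    current_noise_sd_A: float = 2e-12
    filter_cutoff_Hz: float | None = 2000.0
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.current_noise_sd_A < 0:
            raise ValueError("noise sd must be non-negative")
        if self.filter_cutoff_Hz is not None and self.filter_cutoff_Hz <= 0:
            raise ValueError("filter cutoff must be positive")


@dataclass
class CurrentTrace:
    """Sampled current with the commanded voltage and full provenance metadata."""

    time_s: np.ndarray
    current_A: np.ndarray
    voltage_V: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_A = np.asarray(self.current_A, dtype=float)
        self.voltage_V = np.asarray(self.voltage_V, dtype=float)
        if not (len(self.time_s) == len(self.current_A) == len(self.voltage_V)):
            raise ValueError("time, current and voltage must have equal length")
        if len(self.time_s) > 1:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time must increase uniformly")

    @property
    def sample_rate_Hz(self) -> float:
        return 1.0 / (self.time_s[1] - self.time_s[0])


def build_protocol(start_V: float = 0.200, stop_V: float = -0.200, step_V: float = -0.025,
                   step_s: float = 3.1, pre_step_s: float = 0.05,
                   sample_rate_Hz: float = 10_000.0, holding_V: float = 0.0) -> VoltageProtocol:
    """Inclusive arithmetic sequence of step levels from start to stop.

    The default covers +200 to −200 mV in −25 mV steps: 17 levels, 52.7 s of
    stepped recording.
    """
    if step_V == 0:
        if start_V != stop_V:
            raise ValueError("zero step with distinct endpoints")
        levels = (float(start_V),)
    else:
        n_float = (stop_V - start_V) / step_V
        n = round(n_float)
        if n < 0 or not math.isclose(n_float, n, abs_tol=1e-9):
            raise ValueError("(stop - start) must be a non-negative integer multiple of step")
        levels = tuple(float(start_V + i * step_V) for i in range(n + 1))
    return VoltageProtocol(levels_V=levels, holding_V=holding_V,
                           pre_step_s=pre_step_s, step_s=step_s,
                           sample_rate_Hz=sample_rate_Hz)


def _simulate_single_pore(times: np.ndarray, seg_bounds: np.ndarray,
                          k_open_seg: np.ndarray, k_close: float,
                          init_open: bool, rng: np.random.Generator) -> np.ndarray:
    """Exact continuous-time two-state trajectory of one pore on ``times``.

    ``seg_bounds`` are the start times of piecewise-constant-voltage segments
    (ending at times[-1]+dt); ``k_open_seg`` the opening rate per segment.
    Returns a boolean open/closed array.
    """
    t_end = times[-1] + (times[1] - times[0] if len(times) > 1 else 1.0)
    toggles: list[float] = []
    t = 0.0
    open_now = init_open
    seg = 0
    n_seg = len(seg_bounds)
    while t < t_end:
        seg_stop = seg_bounds[seg + 1] if seg + 1 < n_seg else t_end
        rate = k_close if open_now else k_open_seg[seg]
        if rate <= 0:
            t = seg_stop  # absorbing within this segment
        else:
            dwell = rng.exponential(1.0 / rate)
            if t + dwell < seg_stop:
                t += dwell
                toggles.append(t)
                open_now = not open_now
                continue
            t = seg_stop
        if seg + 1 < n_seg:
            seg += 1
        else:
            break
    if not toggles:
        return np.full(len(times), init_open, dtype=bool)
    n_before = np.searchsorted(np.asarray(toggles), times, side="right")
    return (n_before % 2 == 0) == init_open


def simulate_gating(pe: PoreEnergetics, gk: GatingKinetics, n_pores: int, v: float,
                    duration_s: float, seed, sample_rate_Hz: float = 10_000.0,
                    init_v: float | None = None) -> np.ndarray:
    """Aggregate open-pore count of ``n_pores`` independent two-state pores.

    Each pore follows a continuous-time Markov chain with voltage-independent
    closing rate and opening rate k_close*K(v); initial states are drawn from
    the equilibrium distribution at ``init_v`` (default ``v``).  Returns the
    open count sampled at ``sample_rate_Hz``.
    """
    if n_pores < 0:
        raise ValueError("n_pores must be non-negative")
    rng = np.random.default_rng(seed)
    n_samples = max(1, int(round(duration_s * sample_rate_Hz)))
    times = np.arange(n_samples) / sample_rate_Hz
    if n_pores == 0:
        return np.zeros(n_samples)
    p_init = open_probability(pe, v if init_v is None else init_v)
    k_open = gk.k_open_per_s(pe, v)
    seg_bounds = np.array([0.0])
    k_open_seg = np.array([k_open])
    count = np.zeros(n_samples)
    for _ in range(n_pores):
        init_open = bool(rng.random() < p_init)
        count += _simulate_single_pore(times, seg_bounds, k_open_seg,
                                       gk.k_close_per_s, init_open, rng)
    return count


def _lowpass(x: np.ndarray, fs: float, nm: NoiseModel) -> np.ndarray:
    if nm.filter_cutoff_Hz is None:
        return x
    if nm.filter_cutoff_Hz >= fs / 2:
        raise ValueError("filter cutoff must be below the Nyquist frequency")
    sos = signal.bessel(nm.filter_order, nm.filter_cutoff_Hz, btype="low",
                        fs=fs, output="sos", norm="mag")
    # causal, like the hardware Bessel filter; seed the state at the first
    # sample value so the holding baseline carries no startup transient
    zi = signal.sosfilt_zi(sos) * x[0]
    y, _ = signal.sosfilt(sos, x, zi=zi)
    return y


def simulate_trace(protocol: VoltageProtocol, cs: ConductanceSet, pe: PoreEnergetics,
                   env: Environment, gk: GatingKinetics | None = None,
                   tp: TransientParams | None = None, nm: NoiseModel | None = None,
                   seed=0, mode: Literal["patch", "BLM"] = "patch",
                   gating: Literal["stochastic", "equilibrium"] = "stochastic",
                   drift_A_per_s: float = 0.0,
                   extra_metadata: dict | None = None) -> list[CurrentTrace]:
    """Simulate one :class:`CurrentTrace` per protocol level.

    I(t) = biexponential transient + (g_L + g_single n_open(t))(V(t) − E0)
    (+ optional linear baseline drift) + white noise, then causal low-pass.
    ``mode='BLM'`` forces the polarization offset V0 to zero (flat membrane).
    With ``gating='equilibrium'`` the pore term is the deterministic ensemble
    mean g_p P_open(V) — the large-N limit used for clean forward-model data.
    Per-level random streams are spawned deterministically from ``seed``.
    """
    gk = gk or GatingKinetics()
    tp = tp or TransientParams()
    nm = nm or NoiseModel()
    if mode == "BLM":
        pe = replace(pe, offset_V=0.0)
    elif mode != "patch":
        raise ValueError("mode must be 'patch' or 'BLM'")

    fs = protocol.sample_rate_Hz
    n_pre = int(round(protocol.pre_step_s * fs))
    n_step = int(round(protocol.step_s * fs))
    n = n_pre + n_step
    times = np.arange(n) / fs
    t_jump = n_pre / fs

    if cs.g_single_S is not None:
        g_single = cs.g_single_S
        n_pores = cs.n_pores if cs.n_pores is not None else (
            int(round(cs.g_pores_S / g_single)) if g_single > 0 else 0)
    elif cs.n_pores:
        g_single = cs.g_pores_S / cs.n_pores
        n_pores = cs.n_pores
    else:
        g_single, n_pores = 0.0, 0

    streams = np.random.SeedSequence(seed).spawn(protocol.n_levels)
    traces: list[CurrentTrace] = []
    for lvl_idx, (level, ss) in enumerate(zip(protocol.levels_V, streams)):
        rng = np.random.default_rng(ss)
        voltage = np.full(n, level)
        voltage[:n_pre] = protocol.holding_V

        if gating == "equilibrium" or n_pores == 0:
            g_pore_tot = np.where(
                times < t_jump,
                cs.g_pores_S * open_probability(pe, protocol.holding_V),
                cs.g_pores_S * open_probability(pe, level))
        elif gating == "stochastic":
            seg_bounds = np.array([0.0, t_jump])
            k_open_seg = np.array([gk.k_open_per_s(pe, protocol.holding_V),
                                   gk.k_open_per_s(pe, level)])
            p_init = open_probability(pe, protocol.holding_V)
            count = np.zeros(n)
            for _ in range(n_pores):
                init_open = bool(rng.random() < p_init)
                count += _simulate_single_pore(times, seg_bounds, k_open_seg,
                                               gk.k_close_per_s, init_open, rng)
            g_pore_tot = g_single * count
        else:
            raise ValueError("gating must be 'stochastic' or 'equilibrium'")

        current = (cs.g_leak_S + g_pore_tot) * (voltage - env.nernst_V)
        a0, am = tp.amplitudes(protocol.holding_V, level)
        ts = times[n_pre:] - t_jump
        current[n_pre:] += a0 * np.exp(-ts / tp.tau_fast_s) + am * np.exp(-ts / tp.tau_slow_s)
        if drift_A_per_s:
            current += drift_A_per_s * times
        if nm.current_noise_sd_A > 0:
            current = current + rng.normal(0.0, nm.current_noise_sd_A, n)
        current = _lowpass(current, fs, nm)

        meta = {
            "level_V": level,
            "level_index": lvl_idx,
            "holding_V": protocol.holding_V,
            "pre_step_s": protocol.pre_step_s,
            "step_s": protocol.step_s,
            "sample_rate_Hz": fs,
            "seed": int(seed) if np.isscalar(seed) else seed,
            "mode": mode,
            "gating": gating,
            "g_leak_S": cs.g_leak_S,
            "g_pores_S": cs.g_pores_S,
            "g_single_S": g_single,
            "n_pores": n_pores,
            "dmu0_kT": pe.dmu0_kT,
            "alpha_kT_per_V2": pe.alpha_kT_per_V2,
            "offset_V": pe.offset_V,
            "nernst_V": env.nernst_V,
            "temperature_K": env.temperature_K,
            "mean_open_lifetime_s": gk.mean_open_lifetime_s,
            "tau_fast_s": tp.tau_fast_s,
            "tau_slow_s": tp.tau_slow_s,
            "amp_fast_A_per_V": tp.amp_fast_A_per_V,
            "amp_slow_A_per_V": tp.amp_slow_A_per_V,
            "noise_sd_A": nm.current_noise_sd_A,
            "filter_cutoff_Hz": nm.filter_cutoff_Hz,
            "filter_order": nm.filter_order,
            "drift_A_per_s": drift_A_per_s,
        }
        if extra_metadata:
            meta.update(extra_metadata)
        traces.append(CurrentTrace(times, current, voltage, meta))
    return traces


def depth_condition(cs: ConductanceSet, depth_mm: float, g_leak_factor: float = 1.0,
                    g_pores_factor: float = 1.0) -> tuple[ConductanceSet, dict]:
    """Scale conductances for an immersion-depth condition.

    Larger pipette depth raises the hydrostatic pressure across the patch and
    empirically increases both the leak and the pore conductance; the mapping
    is a user-configured multiplicative rule, not a mechanistic model.  The
    single-pore conductance scales with the pore factor (pore count fixed).
    Returns the scaled set plus metadata labels.
    """
    if depth_mm < 0:
        raise ValueError("depth must be non-negative")
    scaled = ConductanceSet(
        g_leak_S=cs.g_leak_S * g_leak_factor,
        g_pores_S=cs.g_pores_S * g_pores_factor,
        g_single_S=None if cs.g_single_S is None else cs.g_single_S * g_pores_factor,
        n_pores=cs.n_pores,
    )
    labels = {"depth_mm": depth_mm, "g_leak_factor": g_leak_factor,
              "g_pores_factor": g_pores_factor}
    return scaled, labels
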