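"""Post-jump relaxation: forward transient model and biexponential fitting.

After a voltage jump V_b → V_a the membrane current relaxes on two time
scales: a fast one, tau0, from charging the (constant part of the) membrane
capacitor through the electrolyte, and a slow one, taum, from structural
relaxation of the membrane that changes its capacitance C_m, its spontaneous
polarization charge A·P0, and its conductance g.  The total current is

    I(t) = (C_m,b/tau0) dV e^{-t/tau0}
         + (dC_m V_a + d(A P0)) e^{-t/taum} / taum
         + (g_b + dg (1 - e^{-t/taum})) V_a
         = g_a V_a + A0 e^{-t/tau0} + Am e^{-t/taum}

with A0 = C_m,b dV / tau0 and Am = (dC_m V_a + d(A P0))/taum - dg V_a, and a
steady-state plateau g_a V_a.  The structural decomposition (dC_m, d(A P0),
dg) is not identifiable from the three fitted numbers (plateau, A0, Am) of a
single jump, so fitting works on the lumped amplitudes only and the
decomposition is offered strictly as a forward model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .steady import IVProfile
from .synth import CurrentTrace

__all__ = [
    "TransientDecomposition",
    "RelaxationFit",
    "transient_amplitudes",
    "forward_transient",
    "fit_biexponential_series",
    "amplitude_voltage_analysis",
]


@dataclass(frozen=True)
class TransientDecomposition:
    """Structural state before/after a jump: capacitance, conductance, polarization charge."""

    cap_before_F: float
    cap_after_F: float
    g_before_S: float
    g_after_S: float
    pol_charge_before_C: float = 0.0
    pol_charge_after_C: float = 0.0

    def __post_init__(self) -> None:
        if self.cap_before_F < 0 or self.cap_after_F < 0:
            raise ValueError("capacitances must be non-negative")

    @property
    def delta_cap_F(self) -> float:
        return self.cap_after_F - self.cap_before_F

    @property
    def delta_g_S(self) -> float:
        return self.g_after_S - self.g_before_S

    @property
    def delta_pol_charge_C(self) -> float:
        return self.pol_charge_after_C - self.pol_charge_before_C


@dataclass
class RelaxationFit:
    """Shared (or per-jump) relaxation times plus per-jump amplitudes.

    ``jumps`` has one row per jump: level_V, amp_fast_A, amp_slow_A,
    plateau_A, rss (and per-jump tau columns when taus are not shared).
    """

    tau_fast_s: float
    tau_slow_s: float
    jumps: pd.DataFrame
    shared_taus: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.tau_fast_s < self.tau_slow_s):
            raise ValueError("require 0 < tau_fast < tau_slow")


def transient_amplitudes(td: TransientDecomposition, v_before: float, v_after: float,
                         tau_fast_s: float, tau_slow_s: float) -> tuple[float, float]:
    """Lumped biexponential amplitudes (A0, Am) implied by a decomposition."""
    dv = v_after - v_before
    a0 = td.cap_before_F * dv / tau_fast_s
    am = (td.delta_cap_F * v_after + td.delta_pol_charge_C) / tau_slow_s \
        - td.delta_g_S * v_after
    return a0, am


def forward_transient(td: TransientDecomposition, v_after: float, tau_fast_s: float,
                      tau_slow_s: float, t: np.ndarray, v_before: float = 0.0) -> np.ndarray:
    """Exact post-jump current of the charge/conductance relaxation model.

    The t → inf limit is the steady-state plateau g_a V_a.
    """
    if not (0 < tau_fast_s < tau_slow_s):
        raise ValueError("require 0 < tau_fast < tau_slow")
    t = np.asarray(t, dtype=float)
    a0, am = transient_amplitudes(td, v_before, v_after, tau_fast_s, tau_slow_s)
    plateau = td.g_after_S * v_after
    return plateau + a0 * np.exp(-t / tau_fast_s) + am * np.exp(-t / tau_slow_s)


def _jump_segment(trace: CurrentTrace, exclude_initial_s: float,
                  window_s: float) -> tuple[np.ndarray, np.ndarray, float]:
    """(t_rel, current, level) of the post-jump fitting segment."""
    pre = trace.metadata.get("pre_step_s")
    if pre is not None:
        j = int(round(pre * trace.sample_rate_Hz))
    else:
        changed = trace.voltage_V != trace.voltage_V[0]
        if not np.any(changed):
            raise ValueError("trace contains no voltage jump")
        j = int(np.argmax(changed))
    t_rel = trace.time_s[j:] - trace.time_s[j]
    i = trace.current_A[j:]
    sel = (t_rel >= exclude_initial_s) & (t_rel <= window_s)
    if sel.sum() < 4:
        raise ValueError("fewer samples than parameters in the jump segment")
    level = trace.metadata.get("level_V", float(trace.voltage_V[-1]))
    return t_rel[sel], i[sel], level


def _linear_amplitudes(t: np.ndarray, i: np.ndarray, tau0: float,
                       taum: float) -> tuple[np.ndarray, float]:
    """Per-jump linear LSQ of (plateau, A0, Am) given the taus."""
    design = np.column_stack([np.ones_like(t), np.exp(-t / tau0), np.exp(-t / taum)])
    coef, *_ = np.linalg.lstsq(design, i, rcond=None)
    rss = float(np.sum((i - design @ coef) ** 2))
    return coef, rss


def _fit_taus(segments: Sequence[tuple[np.ndarray, np.ndarray]], dt: float,
              fixed_tau_fast_s: float | None) -> tuple[float, float]:
    """Grid-refined Nelder–Mead search over (log tau0, log(taum - tau0))."""
    t_max = max(seg[0][-1] for seg in segments)

    def total_rss(tau0: float, taum: float) -> float:
        if not (dt / 10 < tau0 < taum < 10 * t_max):
            return np.inf
        return sum(_linear_amplitudes(t, i, tau0, taum)[1] for t, i in segments)

    if fixed_tau_fast_s is not None:
        tau0 = fixed_tau_fast_s
        grid = np.geomspace(2 * tau0, 5 * t_max, 25)
        taum0 = grid[int(np.argmin([total_rss(tau0, tm) for tm in grid]))]
        res = minimize(lambda x: total_rss(tau0, tau0 + np.exp(x[0])),
                       x0=[np.log(taum0 - tau0)], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 0.0, "maxiter": 500})
        return tau0, tau0 + float(np.exp(res.x[0]))

    tau0_grid = np.geomspace(1.5 * dt, max(20 * dt, 2e-3), 10)
    best = (np.inf, 3 * dt, 30 * dt)
    for tau0 in tau0_grid:
        for taum in np.geomspace(2.5 * tau0, 5 * t_max, 12):
            r = total_rss(tau0, taum)
            if r < best[0]:
                best = (r, tau0, taum)
    _, tau0, taum = best
    res = minimize(lambda x: total_rss(np.exp(x[0]), np.exp(x[0]) + np.exp(x[1])),
                   x0=[np.log(tau0), np.log(taum - tau0)], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 0.0, "maxiter": 2000})
    tau0 = float(np.exp(res.x[0]))
    return tau0, tau0 + float(np.exp(res.x[1]))


def fit_biexponential_series(traces: Sequence[CurrentTrace],
                             exclude_initial_s: float = 1e-4,
                             shared_taus: bool = True,
                             window_s: float = 0.05,
                             fixed_tau_fast_s: float | None = None) -> RelaxationFit:
    """Fit I(t) = plateau + A0 e^{-t/tau0} + Am e^{-t/taum} to every jump.

    Two stages: a global search over the (shared) relaxation times, with the
    amplitudes profiled out by linear least squares per jump, then the final
    per-jump amplitudes at the optimal times.  The first ``exclude_initial_s``
    of each segment (the instrument's time resolution) is dropped.  With
    ``shared_taus`` disabled each jump gets its own pair of times; the
    reported top-level taus are then the medians.
    """
    if not traces:
        raise ValueError("no traces to fit")
    segs, levels = [], []
    for trace in traces:
        t, i, level = _jump_segment(trace, exclude_initial_s, window_s)
        segs.append((t, i))
        levels.append(level)
    dt = segs[0][0][1] - segs[0][0][0] if len(segs[0][0]) > 1 else 1e-4

    rows = []
    if shared_taus:
        tau0, taum = _fit_taus(segs, dt, fixed_tau_fast_s)
        for (t, i), level in zip(segs, levels):
            coef, rss = _linear_amplitudes(t, i, tau0, taum)
            rows.append({"level_V": level, "plateau_A": coef[0], "amp_fast_A": coef[1],
                         "amp_slow_A": coef[2], "rss": rss})
    else:
        taus = []
        for (t, i), level in zip(segs, levels):
            tj0, tjm = _fit_taus([(t, i)], dt, fixed_tau_fast_s)
            coef, rss = _linear_amplitudes(t, i, tj0, tjm)
            rows.append({"level_V": level, "plateau_A": coef[0], "amp_fast_A": coef[1],
                         "amp_slow_A": coef[2], "rss": rss,
                         "tau_fast_s": tj0, "tau_slow_s": tjm})
            taus.append((tj0, tjm))
        tau0 = float(np.median([a for a, _ in taus]))
        taum = float(np.median([b for _, b in taus]))
    return RelaxationFit(tau_fast_s=tau0, tau_slow_s=taum,
                         jumps=pd.DataFrame(rows), shared_taus=shared_taus)


def amplitude_voltage_analysis(rf: RelaxationFit, iv: IVProfile,
                               corr_threshold: float = 0.7) -> dict:
    """Classify each amplitude's voltage dependence as linear or rectified.

    Fits A(V) = a V per amplitude; the residual pattern is correlated with the
    nonlinear part of the I-V profile (I − g_lin V).  A correlation above the
    threshold marks the amplitude as tracking the rectification.
    """
    if len(rf.jumps) < 5:
        raise ValueError("need at least 5 jumps for the amplitude analysis")
    v = rf.jumps["level_V"].to_numpy()
    iv_nl = _nonlinear_part(iv, v)
    out = {}
    for column, key in (("amp_fast_A", "amp_fast"), ("amp_slow_A", "amp_slow")):
        a = rf.jumps[column].to_numpy()
        denom = float(np.sum(v * v))
        slope = float(np.sum(v * a) / denom) if denom > 0 else 0.0
        resid = a - slope * v
        scale = max(float(np.max(np.abs(a))), 1e-30)
        if np.std(resid) < 1e-6 * scale or np.std(iv_nl) == 0:
            corr = 0.0
        else:
            corr = float(np.corrcoef(resid, iv_nl)[0, 1])
        out[key] = {
            "slope_A_per_V": slope,
            "residual_rms_A": float(np.sqrt(np.mean(resid ** 2))),
            "correlation_with_iv_nonlinearity": corr,
            "classification": "rectified" if abs(corr) > corr_threshold else "linear",
        }
    return out


def _nonlinear_part(iv: IVProfile, at_voltages: np.ndarray) -> np.ndarray:
    """I(V) minus its best through-origin linear fit, sampled at given voltages."""
    mask = iv.usable
    v = iv.voltages_V[mask]
    i = iv.mean_current_A[mask]
    denom = float(np.sum(v * v))
    g_lin = float(np.sum(v * i) / denom) if denom > 0 else 0.0
    nl = i - g_lin * v
    idx = np.array([int(np.argmin(np.abs(v - vv))) for vv in at_voltages])
    return nl[idx]
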