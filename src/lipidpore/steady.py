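"""Steady-state I-V extraction and two-process model fitting.

The steady-state current at each step level is estimated from the tail of the
trace (the last half of the 3 s step, after all transients have decayed) and
fitted with I = (g_L + g_p P_open(V))(V − E0) under three scenarios:

* ``pores_only`` — all conduction by gated pores (g_L = 0);
* ``fixed_leak`` — leak fixed to a value measured on a linear profile of the
  same membrane, pores free;
* ``free_leak`` — leak and pore parameters all free (nested superset of the
  other two, so its residual sum of squares is never larger).

A plain ``linear`` fit (slope through I(E0) = 0) serves profiles without pore
activity.  Utilities compare fits across immersion-depth conditions and flag
voltage intervals of negative slope dI/dV < 0, a signature that cannot occur
without a voltage-dependent conductance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import lmfit
import numpy as np
import pandas as pd

from .core import ConductanceSet, Environment, PoreEnergetics, open_probability, steady_state_current
from .synth import CurrentTrace

__all__ = [
    "IVProfile",
    "IVFitResult",
    "FitFailure",
    "correct_offset",
    "extract_iv",
    "fit_linear",
    "fit_iv",
    "detect_negative_slope",
    "compare_depths",
]

Scenario = Literal["pores_only", "fixed_leak", "free_leak", "linear"]


class FitFailure(RuntimeError):
    """Raised when no optimizer start converges; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class IVProfile:
    """Per-level steady-state current statistics with exclusion flags."""

    voltages_V: np.ndarray
    mean_current_A: np.ndarray
    sd_current_A: np.ndarray
    n_samples: np.ndarray
    excluded: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voltages_V = np.asarray(self.voltages_V, dtype=float)
        self.mean_current_A = np.asarray(self.mean_current_A, dtype=float)
        self.sd_current_A = np.asarray(self.sd_current_A, dtype=float)
        self.n_samples = np.asarray(self.n_samples, dtype=int)
        if self.excluded is None:
            self.excluded = np.zeros(len(self.voltages_V), dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        k = len(self.voltages_V)
        if not all(len(a) == k for a in (self.mean_current_A, self.sd_current_A,
                                         self.n_samples, self.excluded)):
            raise ValueError("profile arrays must have equal length")
        if not np.all(np.isfinite(self.mean_current_A)):
            raise ValueError("non-finite current means")
        if np.any(self.sd_current_A < 0):
            raise ValueError("negative current sd")

    @property
    def usable(self) -> np.ndarray:
        return ~self.excluded

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "voltage_V": self.voltages_V,
            "mean_current_A": self.mean_current_A,
            "sd_current_A": self.sd_current_A,
            "n_samples": self.n_samples,
            "excluded": self.excluded,
        })


@dataclass
class IVFitResult:
    """Fitted two-process parameters for one I-V profile.

    ``min_open_probability`` is the open probability at V = −V0, the extremum
    of the quadratic free energy (a minimum of P_open in the rectified
    alpha < 0 regime, a maximum for alpha > 0).
    """

    scenario: Scenario
    g_leak_S: float
    g_pores_S: float
    offset_V: float
    dmu0_kT: float
    alpha_kT_per_V2: float
    residual_sum_squares: float
    stderr: dict = field(default_factory=dict)
    min_open_probability: float = float("nan")
    min_open_probability_voltage_V: float = float("nan")
    nernst_V: float = 0.0
    n_points: int = 0

    @property
    def energetics(self) -> PoreEnergetics:
        return PoreEnergetics(self.dmu0_kT, self.alpha_kT_per_V2, self.offset_V)

    def predict(self, v) -> np.ndarray:
        """Model current at voltages ``v``."""
        if self.scenario == "linear":
            return self.g_leak_S * (np.asarray(v, dtype=float) - self.nernst_V)
        cs = ConductanceSet(g_leak_S=self.g_leak_S, g_pores_S=self.g_pores_S)
        env = Environment(nernst_V=self.nernst_V)
        return steady_state_current(cs, self.energetics, env, v)


def correct_offset(trace: CurrentTrace) -> CurrentTrace:
    """Subtract the holding-segment mean current from the whole trace.

    The holding segment is identified as the samples at the holding voltage
    preceding the step (per the protocol metadata, falling back to the leading
    run of constant voltage).
    """
    holding = trace.metadata.get("holding_V")
    if holding is not None:
        mask = trace.voltage_V == holding
        jump = np.argmax(~mask) if np.any(~mask) else len(mask)
    else:
        jump = int(np.argmax(trace.voltage_V != trace.voltage_V[0]))
        if jump == 0 and np.all(trace.voltage_V == trace.voltage_V[0]):
            raise ValueError("trace has no holding segment distinct from the step")
    if jump == 0:
        raise ValueError("trace has no holding segment")
    offset = float(np.mean(trace.current_A[:jump]))
    meta = dict(trace.metadata)
    meta["offset_corrected_A"] = offset
    return CurrentTrace(trace.time_s, trace.current_A - offset, trace.voltage_V, meta)


def _jump_index(trace: CurrentTrace) -> int:
    pre = trace.metadata.get("pre_step_s")
    if pre is not None:
        return int(round(pre * trace.sample_rate_Hz))
    changed = trace.voltage_V != trace.voltage_V[0]
    return int(np.argmax(changed)) if np.any(changed) else 0


def extract_iv(traces: Sequence[CurrentTrace], window_s: tuple[float, float] = (1.5, 3.0),
               discard_first: bool = False) -> IVProfile:
    """Per-level mean/sd of the current in a window relative to step onset.

    The default window averages the last 1.5 s of a 3 s step, well past the
    millisecond transients.  ``discard_first`` flags the first level of the
    series as excluded (the first jump of a series typically has not
    equilibrated and is an outlier).
    """
    lo, hi = window_s
    if hi <= lo:
        raise ValueError("empty extraction window")
    volts, means, sds, counts = [], [], [], []
    for trace in traces:
        j = _jump_index(trace)
        t_rel = trace.time_s - trace.time_s[min(j, len(trace.time_s) - 1)]
        sel = (t_rel >= lo) & (t_rel < hi)
        if not np.any(sel):
            raise ValueError("extraction window lies outside the step duration")
        seg = trace.current_A[sel]
        volts.append(trace.metadata.get("level_V", float(trace.voltage_V[-1])))
        means.append(float(np.mean(seg)))
        sds.append(float(np.std(seg, ddof=1)) if len(seg) > 1 else 0.0)
        counts.append(int(len(seg)))
    excluded = np.zeros(len(volts), dtype=bool)
    if discard_first and len(volts):
        excluded[0] = True
    return IVProfile(np.array(volts), np.array(means), np.array(sds),
                     np.array(counts), excluded)


def _weights(profile: IVProfile, mask: np.ndarray) -> np.ndarray:
    sd = profile.sd_current_A[mask]
    n = np.maximum(profile.n_samples[mask], 1)
    se = sd / np.sqrt(n)
    if np.all(se > 0):
        return 1.0 / se
    return np.ones(mask.sum())


def fit_linear(profile: IVProfile, e0_V: float = 0.0) -> IVFitResult:
    """Least-squares conductance with the intercept pinned at I(E0) = 0."""
    mask = profile.usable
    if mask.sum() < 2:
        raise ValueError("need at least 2 usable points for a linear fit")
    v = profile.voltages_V[mask] - e0_V
    i = profile.mean_current_A[mask]
    w = _weights(profile, mask) ** 2
    denom = float(np.sum(w * v * v))
    g = float(np.sum(w * v * i) / denom) if denom > 0 else 0.0
    resid = i - g * v
    rss = float(np.sum(resid ** 2))
    dof = mask.sum() - 1
    var_g = rss / dof / float(np.sum(v * v)) if dof > 0 and np.sum(v * v) > 0 else 0.0
    return IVFitResult(scenario="linear", g_leak_S=g, g_pores_S=0.0, offset_V=0.0,
                       dmu0_kT=float("nan"), alpha_kT_per_V2=float("nan"),
                       residual_sum_squares=rss, stderr={"g_leak_S": float(np.sqrt(var_g))},
                       nernst_V=e0_V, n_points=int(mask.sum()))


_V0_STARTS = np.arange(-0.3, 0.3001, 0.05)
_ALPHA_STARTS = (40.0, -40.0)


def _model_current(params: lmfit.Parameters, v: np.ndarray, e0: float) -> np.ndarray:
    pe = PoreEnergetics(params["dmu0"].value, params["alpha"].value, params["v0"].value)
    g = params["gl"].value + params["gp"].value * open_probability(pe, v)
    return g * (v - e0)


def fit_iv(profile: IVProfile, scenario: Scenario = "free_leak",
           fixed_g_leak_S: float | None = None, e0_V: float = 0.0,
           max_nfev: int = 500) -> IVFitResult:
    """Weighted nonlinear least squares of the two-process model.

    Multi-starts over a grid of V0 initial values (−0.3 … 0.3 V in 0.05 V
    steps) and both signs of alpha; the best residual sum of squares wins,
    ties broken toward smaller |V0|.
    """
    if scenario == "linear":
        return fit_linear(profile, e0_V)
    mask = profile.usable
    if mask.sum() < 6:
        raise ValueError("need at least 6 usable points for a nonlinear scenario")
    if scenario == "fixed_leak" and fixed_g_leak_S is None:
        raise ValueError("scenario 'fixed_leak' requires fixed_g_leak_S")
    if scenario not in ("pores_only", "fixed_leak", "free_leak"):
        raise ValueError(f"unknown scenario {scenario!r}")

    v = profile.voltages_V[mask]
    i = profile.mean_current_A[mask]
    w = _weights(profile, mask)
    scale = max(np.max(np.abs(i)), 1e-12) / max(np.max(np.abs(v - e0_V)), 1e-3)

    def residual(params):
        return w * (_model_current(params, v, e0_V) - i)

    best = None
    best_key = None
    diagnostics = []
    for v0_start in _V0_STARTS:
        for alpha_start in _ALPHA_STARTS:
            params = lmfit.Parameters()
            gl0 = 0.0 if scenario == "pores_only" else (
                fixed_g_leak_S if scenario == "fixed_leak" else 0.5 * scale)
            params.add("gl", value=gl0, min=0.0,
                       vary=scenario == "free_leak")
            params.add("gp", value=2.0 * scale, min=0.0, max=1e3 * scale)
            params.add("v0", value=float(v0_start), min=-0.35, max=0.35)
            params.add("dmu0", value=2.0, min=-50.0, max=50.0)
            params.add("alpha", value=alpha_start, min=-2000.0, max=2000.0)
            try:
                out = lmfit.minimize(residual, params, method="leastsq",
                                     max_nfev=max_nfev, xtol=1e-12, ftol=1e-12)
            except Exception as exc:  # pragma: no cover - defensive
                diagnostics.append((v0_start, alpha_start, str(exc)))
                continue
            rss = float(np.sum((_model_current(out.params, v, e0_V) - i) ** 2))
            key = (round(rss / max(np.sum(i ** 2), 1e-30), 10), abs(out.params["v0"].value))
            if best is None or key < best_key:
                best, best_key = out, key
    if best is None:
        raise FitFailure("no optimizer start converged", diagnostics)

    p = best.params
    pe = PoreEnergetics(p["dmu0"].value, p["alpha"].value, p["v0"].value)
    rss = float(np.sum((_model_current(p, v, e0_V) - i) ** 2))
    stderr = {name: (p[name].stderr if p[name].stderr is not None else float("nan"))
              for name in ("gl", "gp", "v0", "dmu0", "alpha")}
    return IVFitResult(
        scenario=scenario,
        g_leak_S=float(p["gl"].value),
        g_pores_S=float(p["gp"].value),
        offset_V=float(p["v0"].value),
        dmu0_kT=float(p["dmu0"].value),
        alpha_kT_per_V2=float(p["alpha"].value),
        residual_sum_squares=rss,
        stderr=stderr,
        min_open_probability=float(open_probability(pe, -p["v0"].value)),
        min_open_probability_voltage_V=float(-p["v0"].value),
        nernst_V=e0_V,
        n_points=int(mask.sum()),
    )


def detect_negative_slope(profile: IVProfile) -> list[tuple[float, float]]:
    """Voltage intervals where dI/dV is negative beyond the noise threshold.

    Centered finite differences on the voltage-sorted usable points; a point
    is flagged when its difference quotient is below −2 propagated standard
    errors.  Returns merged (v_lo, v_hi) intervals, empty when none.
    """
    mask = profile.usable
    if mask.sum() < 3:
        raise ValueError("need at least 3 usable points")
    order = np.argsort(profile.voltages_V[mask])
    v = profile.voltages_V[mask][order]
    i = profile.mean_current_A[mask][order]
    se = profile.sd_current_A[mask][order] / np.sqrt(np.maximum(profile.n_samples[mask][order], 1))

    flagged = []
    for k in range(1, len(v) - 1):
        dv = v[k + 1] - v[k - 1]
        q = (i[k + 1] - i[k - 1]) / dv
        q_se = np.sqrt(se[k + 1] ** 2 + se[k - 1] ** 2) / dv
        if q < -2.0 * q_se:
            flagged.append(k)
    intervals: list[tuple[float, float]] = []
    for k in flagged:
        lo, hi = v[k - 1], v[k + 1]
        if intervals and lo <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], hi)
        else:
            intervals.append((lo, hi))
    return intervals


def compare_depths(fits_by_condition: Mapping[object, Iterable[IVFitResult]]) -> dict:
    """Summarize fits per condition and percent changes between conditions.

    Returns ``{"conditions": DataFrame, "changes": DataFrame}`` with, per
    condition, mean/sd of the voltage offset and mean conductances, and for
    each consecutive pair (a, b) of conditions the percent change
    100 (b − a)/a of g_L and g_p.
    """
    rows = []
    for label, fits in fits_by_condition.items():
        fits = list(fits)
        if not fits:
            raise ValueError(f"condition {label!r} has no fits")
        v0 = np.array([f.offset_V for f in fits])
        rows.append({
            "condition": label,
            "n_fits": len(fits),
            "v0_mean_V": float(np.mean(v0)),
            "v0_sd_V": float(np.std(v0, ddof=1)) if len(v0) > 1 else 0.0,
            "g_leak_mean_S": float(np.mean([f.g_leak_S for f in fits])),
            "g_pores_mean_S": float(np.mean([f.g_pores_S for f in fits])),
        })
    conditions = pd.DataFrame(rows)
    changes = []
    for a, b in zip(rows[:-1], rows[1:]):
        for quantity in ("g_leak_mean_S", "g_pores_mean_S"):
            ref = a[quantity]
            if ref == 0:
                raise ValueError(f"zero reference {quantity} in condition {a['condition']!r}")
            changes.append({
                "from": a["condition"],
                "to": b["condition"],
                "quantity": quantity.replace("_mean_S", ""),
                "percent_change": 100.0 * (b[quantity] - ref) / ref,
            })
    return {"conditions": conditions, "changes": pd.DataFrame(changes)}
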