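"""Idealization of current traces into discrete conduction levels.

Quantized current steps in a lipid bilayer trace are read off exactly as for
protein single-channel records: estimate the closed-state baseline, find the
discrete amplitude levels from the sample histogram, then threshold with
hysteresis (enter an open level at half the step amplitude, leave it at 0.35
of the step) and discard events shorter than the filter's resolution.  Levels
are assumed equally spaced (identical pores); the spacing is the modal gap
between adjacent histogram peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .synth import CurrentTrace

__all__ = [
    "EventList",
    "baseline_correct",
    "idealize",
    "dwell_time_stats",
    "empirical_open_probability",
]


@dataclass
class EventList:
    """Idealized openings of one trace.

    ``events`` rows: start_s, end_s, level_index (>= 1), amplitude_A (signed,
    relative to baseline).  ``n_levels`` counts distinct conduction levels
    including the closed one.  ``mean_level`` is the time-averaged occupancy
    (sum of open pores), used for per-pore open-probability estimates.
    """

    events: pd.DataFrame
    baseline_A: float
    step_amplitude_A: float
    n_levels: int
    duration_s: float
    open_time_s: float = 0.0
    mean_level: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def fraction_time_open(self) -> float:
        return self.open_time_s / self.duration_s if self.duration_s > 0 else 0.0


_EVENT_COLUMNS = ["start_s", "end_s", "level_index", "amplitude_A"]


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=_EVENT_COLUMNS)


def baseline_correct(trace: CurrentTrace, window_s: float = 0.25,
                     percentile: float = 10.0) -> CurrentTrace:
    """Remove a linear drift fitted robustly to the lower envelope.

    The trace is cut into windows; a low percentile of each window tracks the
    closed-state level even when channels are open much of the time.  A line
    through those points gives the drift slope, which is subtracted (the
    intercept is untouched, so a drift-free trace passes through unchanged).
    """
    if len(trace.time_s) <= 10:
        raise ValueError("trace too short for baseline correction")
    fs = trace.sample_rate_Hz
    win = max(int(round(window_s * fs)), 10)
    n_win = len(trace.current_A) // win
    if n_win < 2:
        return trace
    t_mid, env = [], []
    for k in range(n_win):
        seg = trace.current_A[k * win:(k + 1) * win]
        env.append(np.percentile(seg, percentile))
        t_mid.append(trace.time_s[k * win + win // 2])
    slope = np.polyfit(np.asarray(t_mid), np.asarray(env), 1)[0]
    corrected = trace.current_A - slope * (trace.time_s - trace.time_s[0])
    meta = dict(trace.metadata)
    meta["baseline_drift_removed_A_per_s"] = float(slope)
    return CurrentTrace(trace.time_s, corrected, trace.voltage_V, meta)


def _find_levels(current: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Histogram peak positions and the smoothed histogram used to find them."""
    lo, hi = np.min(current), np.max(current)
    span = hi - lo
    if span == 0:
        return np.array([lo]), np.zeros(1)
    nbins = 200
    counts, edges = np.histogram(current, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = _signal.windows.gaussian(15, 2.5)
    smooth = _signal.convolve(counts.astype(float), kernel / kernel.sum(), mode="same")
    # zero-pad so that modes at the histogram edges are still found
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _ = _signal.find_peaks(padded, prominence=0.05 * smooth.max(),
                                  distance=max(3, nbins // 40))
    peaks = peaks - 1
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(smooth))])
    return centers[peaks], smooth


def _quantize(deviation: np.ndarray, step: float, enter: float, exit_: float) -> np.ndarray:
    """Level index per sample via threshold crossing with hysteresis."""
    levels = np.zeros(len(deviation), dtype=np.int32)
    level = 0
    for k, d in enumerate(deviation):
        while d > (level + enter) * step:
            level += 1
        while level > 0 and d < (level - 1 + exit_) * step:
            level -= 1
        levels[k] = level
    return levels


def _runs(levels: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, stop, level) runs of constant level; stop is exclusive."""
    out = []
    start = 0
    for k in range(1, len(levels) + 1):
        if k == len(levels) or levels[k] != levels[start]:
            out.append((start, k, int(levels[start])))
            start = k
    return out


def idealize(trace: CurrentTrace, min_event_s: float = 0.002,
             enter_fraction: float = 0.5, exit_fraction: float = 0.35,
             direction: Literal["up", "down", "auto"] = "auto") -> EventList:
    """Idealize a (baseline-corrected) trace into discrete conduction levels.

    A unimodal amplitude histogram means no channels: the result has
    ``n_levels = 1`` and an empty event table, not an error.  ``direction``
    says whether openings move the current up or down; ``auto`` infers it
    from the sign of the commanded voltage (driving force).
    """
    current = trace.current_A
    duration = len(current) / trace.sample_rate_Hz
    peak_amps, _ = _find_levels(current)

    if direction == "auto":
        v_mean = float(np.mean(trace.voltage_V)) if len(trace.voltage_V) else 0.0
        sign = -1.0 if v_mean < 0 else 1.0
    else:
        sign = 1.0 if direction == "up" else -1.0

    if len(peak_amps) < 2:
        return EventList(_empty_events(), baseline_A=float(peak_amps[0]),
                         step_amplitude_A=0.0, n_levels=1, duration_s=duration,
                         metadata=dict(trace.metadata))

    ordered = np.sort(sign * peak_amps)  # baseline first along the opening direction
    baseline = float(ordered[0])
    step = float(np.median(np.diff(ordered)))
    deviation = sign * current - baseline
    levels = _quantize(deviation, step, enter_fraction, exit_fraction)

    # refine baseline and step from the quantized samples (histogram peak
    # positions are smeared toward each other by the recording filter) and
    # requantize once with the unbiased estimates
    if np.any(levels == 0) and np.any(levels == 1):
        base_ref = float(np.median(deviation[levels == 0]))
        step_ref = float(np.median(deviation[levels == 1])) - base_ref
        if step_ref > 0:
            baseline += base_ref
            step = step_ref
            deviation = sign * current - baseline
            levels = _quantize(deviation, step, enter_fraction, exit_fraction)

    # merge filter-limited glitches into the preceding level
    min_samples = max(1, int(round(min_event_s * trace.sample_rate_Hz)))
    runs = [list(r) for r in _runs(levels)]
    changed = True
    while changed and len(runs) > 1:
        changed = False
        k = 0
        while k < len(runs):
            a, b, lvl = runs[k]
            if b - a < min_samples and len(runs) > 1:
                runs[k][2] = runs[k - 1][2] if k > 0 else runs[k + 1][2]
                # coalesce with equal-level neighbours
                if k + 1 < len(runs) and runs[k + 1][2] == runs[k][2]:
                    runs[k][1] = runs[k + 1][1]
                    del runs[k + 1]
                if k > 0 and runs[k - 1][2] == runs[k][2]:
                    runs[k - 1][1] = runs[k][1]
                    del runs[k]
                    k -= 1
                changed = True
            k += 1

    rows = []
    fs = trace.sample_rate_Hz
    n_samples = 0.0
    open_samples = 0
    level_sum = 0.0
    max_level = 0
    for a, b, lvl in runs:
        n_samples += b - a
        level_sum += lvl * (b - a)
        max_level = max(max_level, lvl)
        if lvl >= 1:
            open_samples += b - a
            rows.append({"start_s": trace.time_s[a],
                         "end_s": trace.time_s[b - 1] + 1.0 / fs,
                         "level_index": lvl,
                         "amplitude_A": sign * lvl * step})
    events = pd.DataFrame(rows) if rows else _empty_events()
    return EventList(events, baseline_A=float(sign * baseline),
                     step_amplitude_A=float(sign * step),
                     n_levels=max_level + 1, duration_s=duration,
                     open_time_s=open_samples / fs,
                     mean_level=float(level_sum / n_samples),
                     metadata=dict(trace.metadata))


def dwell_time_stats(ev: EventList) -> dict:
    """Mean dwell times and exponential rates for open and closed periods.

    Contiguous time at level >= 1 counts as one open dwell; interior gaps
    between open dwells are closed dwells (leading/trailing censored periods
    are excluded from closed statistics).
    """
    if len(ev) == 0:
        return {"n_open": 0, "n_closed": 0, "mean_open_s": float("nan"),
                "mean_closed_s": float("nan"), "open_rate_per_s": float("nan"),
                "close_rate_per_s": float("nan")}
    # merge touching events (level changes within one open dwell)
    starts = ev.events["start_s"].to_numpy()
    ends = ev.events["end_s"].to_numpy()
    open_spans = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - open_spans[-1][1] < 1e-12:
            open_spans[-1][1] = e
        else:
            open_spans.append([s, e])
    open_dwells = np.array([e - s for s, e in open_spans])
    closed_dwells = np.array([open_spans[k + 1][0] - open_spans[k][1]
                              for k in range(len(open_spans) - 1)])
    mean_open = float(np.mean(open_dwells))
    mean_closed = float(np.mean(closed_dwells)) if len(closed_dwells) else float("nan")
    return {
        "n_open": int(len(open_dwells)),
        "n_closed": int(len(closed_dwells)),
        "mean_open_s": mean_open,
        "mean_closed_s": mean_closed,
        "close_rate_per_s": 1.0 / mean_open if mean_open > 0 else float("nan"),
        "open_rate_per_s": (1.0 / mean_closed
                            if len(closed_dwells) and mean_closed > 0 else float("nan")),
    }


def empirical_open_probability(eventlists_by_voltage: Mapping[float, EventList],
                               n_pores: int | None = None) -> pd.DataFrame:
    """Fraction of time with at least one open pore, per voltage.

    With ``n_pores`` given, also reports the per-pore open probability
    (time-averaged occupancy divided by the pore count), directly comparable
    to the Boltzmann open probability of the thermodynamic model.
    """
    rows = []
    for v, ev in sorted(eventlists_by_voltage.items()):
        row = {"voltage_V": v, "fraction_time_open": ev.fraction_time_open,
               "mean_level": ev.mean_level, "n_events": len(ev)}
        if n_pores:
            row["p_open_per_pore"] = ev.mean_level / n_pores
        rows.append(row)
    return pd.DataFrame(rows)
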