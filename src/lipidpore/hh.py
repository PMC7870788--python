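"""Hodgkin–Huxley potassium gating as the comparison standard.

The delayed-rectifier K+ conductance is g_K = g_K,0 * n^4 with a single gate
variable n relaxing mono-exponentially after a voltage jump,

    n(V, t) = n_inf(V) - (n_inf(V) - n_inf(V_before)) exp(-t / tau_n(V)),
    n_inf = alpha_n / (alpha_n + beta_n),   tau_n = 1 / (alpha_n + beta_n),

with the classic rate parameterization (voltage in volts, rates in 1/s):

    alpha_n(V) = 1e4 (V + 0.055) / (1 - exp(-(V + 0.055)/0.010))
    beta_n(V)  = 125 exp(-(V + 0.065)/0.08)

alpha_n has a removable singularity at V = -55 mV handled by its analytic
limit.  The steady-state open probability n_inf^4 of this channel is what the
rectified lipid-pore open probabilities are compared against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import PoreEnergetics, open_probability

__all__ = [
    "HHPotassium",
    "alpha_n",
    "beta_n",
    "n_inf",
    "tau_n",
    "n_of_t",
    "k_open_probability",
    "g_K",
    "compare_open_probabilities",
]

# rate-function constants, immutable as classically printed
_A_SCALE = 1.0e4   # 1/(V s)
_A_SHIFT = 0.055   # V
_A_SLOPE = 0.010   # V
_B_SCALE = 125.0   # 1/s
_B_SHIFT = 0.065   # V
_B_SLOPE = 0.08    # V

_SINGULARITY_EPS = 1e-7


@dataclass(frozen=True)
class HHPotassium:
    """Maximum conductance of the four-gate K+ channel."""

    g_max_S: float = 1.0

    def __post_init__(self) -> None:
        if self.g_max_S < 0:
            raise ValueError("g_max must be non-negative")


def alpha_n(v):
    """Opening rate of one n-gate, 1/s."""
    v = np.asarray(v, dtype=float)
    x = v + _A_SHIFT
    with np.errstate(over="ignore"):
        denom = -np.expm1(-x / _A_SLOPE)
        regular = np.where(np.abs(x) < _SINGULARITY_EPS, np.nan, denom)
        out = np.where(np.abs(x) < _SINGULARITY_EPS,
                       _A_SCALE * _A_SLOPE,              # analytic limit x/(1-e^(-x/s)) -> s
                       _A_SCALE * x / np.where(np.isnan(regular), 1.0, regular))
    return out if out.ndim else float(out)


def beta_n(v):
    """Closing rate of one n-gate, 1/s."""
    v = np.asarray(v, dtype=float)
    out = _B_SCALE * np.exp(-(v + _B_SHIFT) / _B_SLOPE)
    return out if out.ndim else float(out)


def n_inf(v):
    """Steady-state gate value alpha/(alpha+beta), strictly in (0, 1)."""
    a, b = np.asarray(alpha_n(v)), np.asarray(beta_n(v))
    out = a / (a + b)
    return out if out.ndim else float(out)


def tau_n(v):
    """Gate relaxation time 1/(alpha+beta), seconds."""
    a, b = np.asarray(alpha_n(v)), np.asarray(beta_n(v))
    out = 1.0 / (a + b)
    return out if out.ndim else float(out)


def n_of_t(v_after: float, v_before: float, t):
    """Gate value after a jump v_before -> v_after, exact single-exponential."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    ninf_a = n_inf(v_after)
    out = ninf_a - (ninf_a - n_inf(v_before)) * np.exp(-t / tau_n(v_after))
    return out if out.ndim else float(out)


def k_open_probability(v):
    """Steady-state open probability of the K+ channel, n_inf^4."""
    out = np.asarray(n_inf(v)) ** 4
    return out if out.ndim else float(out)


def g_K(v_after: float, t, g_max_S: float = 1.0, v_before: float = -0.065):
    """Time-dependent potassium conductance g_K,0 * n^4 after a voltage jump."""
    out = g_max_S * np.asarray(n_of_t(v_after, v_before, t)) ** 4
    return out if out.ndim else float(out)


def compare_open_probabilities(hh: HHPotassium, pe_list: Sequence[PoreEnergetics],
                               v_grid) -> pd.DataFrame:
    """Tabulate HH K+ and lipid-pore open probabilities on a common grid.

    The comparison is visual/tabular; no similarity statistic is asserted.
    """
    v_grid = np.asarray(v_grid, dtype=float)
    if v_grid.size == 0:
        raise ValueError("voltage grid must be non-empty")
    data = {"voltage_V": v_grid, "p_open_K": np.asarray(k_open_probability(v_grid))}
    for idx, pe in enumerate(pe_list):
        data[f"p_open_pore_{idx}"] = np.asarray(open_probability(pe, v_grid))
    return pd.DataFrame(data)


def hh_table(v_min: float = -0.1, v_max: float = 0.05, step: float = 0.005) -> pd.DataFrame:
    """Rates, steady state, time constant and open probability on a grid."""
    v = np.arange(v_min, v_max + step / 2, step)
    return pd.DataFrame({
        "voltage_V": v,
        "alpha_n_per_s": np.asarray(alpha_n(v)),
        "beta_n_per_s": np.asarray(beta_n(v)),
        "n_inf": np.asarray(n_inf(v)),
        "tau_n_s": np.asarray(tau_n(v)),
        "p_open_K": np.asarray(k_open_probability(v)),
    })
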