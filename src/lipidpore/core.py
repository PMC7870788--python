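"""Thermodynamic model of voltage-gated lipid pores and small biophysical utilities.

A protein-free lipid bilayer near its melting transition conducts through two
processes: a voltage-independent leak of conductance ``g_L`` and transient
aqueous pores that open and close by thermodynamic fluctuation.  The free
energy of a pore relative to the closed state is quadratic in voltage,

    dmu(V) = dmu(0) + alpha * [(V + V0)^2 - V0^2]        (in units of kT)

where ``V0`` is a voltage offset produced by a spontaneous polarization of the
membrane (e.g. from curvature via flexoelectricity).  With the equilibrium
constant ``K = exp(-dmu)`` the open probability is the Boltzmann form
``P_open = K / (1 + K)``.

Sign note: with the quadratic written as above, a positive ``alpha`` places the
*maximum* of ``P_open`` at ``V = -V0``; the outward-rectified regime seen in
patch experiments (pores opening away from ``-V0``, minimum open probability at
``-V0``) corresponds to ``alpha < 0``.  Both signs are accepted; ``alpha = 0``
degenerates to voltage-independent pores and is allowed for test fixtures.

All quantities are SI (volts, amperes, siemens, farads, seconds, kelvin);
energies are dimensionless multiples of kT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.constants import R as GAS_CONSTANT
from scipy.constants import physical_constants

FARADAY = physical_constants["Faraday constant"][0]

__all__ = [
    "PoreEnergetics",
    "ConductanceSet",
    "Environment",
    "MembraneCapacitor",
    "PipetteCircuit",
    "pore_free_energy",
    "open_probability",
    "steady_state_current",
    "nernst_potential",
    "resistance_from_conductance",
    "conductance_from_resistance",
    "single_channel_conductance",
    "hydrostatic_pressure",
    "max_aperture_curvature",
    "membrane_charge",
    "effective_capacitance",
]


@dataclass(frozen=True)
class PoreEnergetics:
    """Parameters of the quadratic pore free energy.

    dmu0_kT
        Free energy of an open pore at V = 0, in units of kT.
    alpha_kT_per_V2
        Curvature of the quadratic voltage dependence, kT/V^2.  Either sign
        (see module docstring); zero gives voltage-independent pores.
    offset_V
        Voltage offset V0 (volts).  The free energy is extremal at V = -V0.
    """

    dmu0_kT: float
    alpha_kT_per_V2: float
    offset_V: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dmu0_kT", "alpha_kT_per_V2", "offset_V"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"PoreEnergetics.{name} must be finite")


@dataclass(frozen=True)
class ConductanceSet:
    """Leak and pore conductances (siemens).

    ``g_pores_S`` is the total conductance of all N pores when open,
    g_p = N * g_pore.  When both ``n_pores`` and ``g_single_S`` are given they
    must be consistent with ``g_pores_S``.
    """

    g_leak_S: float
    g_pores_S: float = 0.0
    g_single_S: float | None = None
    n_pores: int | None = None

    def __post_init__(self) -> None:
        if self.g_leak_S < 0 or self.g_pores_S < 0:
            raise ValueError("conductances must be non-negative")
        if self.g_single_S is not None and self.g_single_S < 0:
            raise ValueError("g_single_S must be non-negative")
        if self.n_pores is not None and self.n_pores < 0:
            raise ValueError("n_pores must be non-negative")
        if self.n_pores is not None and self.g_single_S is not None:
            if not np.isclose(self.g_pores_S, self.n_pores * self.g_single_S,
                              rtol=1e-9, atol=1e-18):
                raise ValueError("g_pores_S must equal n_pores * g_single_S")

    @classmethod
    def from_pores(cls, g_leak_S: float, n_pores: int, g_single_S: float) -> "ConductanceSet":
        return cls(g_leak_S=g_leak_S, g_pores_S=n_pores * g_single_S,
                   g_single_S=g_single_S, n_pores=n_pores)


@dataclass(frozen=True)
class Environment:
    """Bath/pipette conditions: temperature and the Nernst potential E0.

    If both concentrations are given, ``nernst_V`` must agree with
    (RT/zF) ln(c_out/c_in); with identical buffers on both sides E0 = 0.
    """

    temperature_K: float = 297.0
    nernst_V: float = 0.0
    ion_valence: int = 1
    conc_out: float | None = None
    conc_in: float | None = None

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")
        if (self.conc_out is None) != (self.conc_in is None):
            raise ValueError("give both or neither concentration")
        if self.conc_out is not None:
            if self.conc_out <= 0 or self.conc_in <= 0:
                raise ValueError("concentrations must be positive")
            e0 = nernst_potential(self.conc_out, self.conc_in,
                                  self.ion_valence, self.temperature_K)
            if not np.isclose(e0, self.nernst_V, rtol=1e-6, atol=1e-9):
                raise ValueError(
                    f"nernst_V={self.nernst_V} inconsistent with concentrations ({e0:.6g} V)")


@dataclass(frozen=True)
class MembraneCapacitor:
    """Membrane capacitance with a spontaneous-polarization offset charge.

    Stored charge is q = C_m V + A P0; the polarization term can be folded into
    an effective capacitance C_m* = C_m (1 + V0/V).
    """

    capacitance_F: float
    area_m2: float = 0.0
    polarization_C_per_m2: float = 0.0

    def __post_init__(self) -> None:
        if self.capacitance_F < 0 or self.area_m2 < 0:
            raise ValueError("capacitance and area must be non-negative")


@dataclass(frozen=True)
class PipetteCircuit:
    """Series resistance and wall capacitance of the pipette.

    Carried for completeness; in practice the pipette resistance is orders of
    magnitude below the membrane resistance and is not used in fitting.
    """

    series_resistance_Ohm: float = 0.0
    pipette_capacitance_F: float = 0.0

    def __post_init__(self) -> None:
        if self.series_resistance_Ohm < 0 or self.pipette_capacitance_F < 0:
            raise ValueError("pipette circuit elements must be non-negative")


def pore_free_energy(pe: PoreEnergetics, v):
    """Pore free energy dmu(V) in kT: dmu(0) + alpha[(V+V0)^2 - V0^2].

    Equals ``dmu0_kT`` at V = 0 and at V = -2 V0; extremal at V = -V0.
    """
    v = np.asarray(v, dtype=float)
    out = pe.dmu0_kT + pe.alpha_kT_per_V2 * ((v + pe.offset_V) ** 2 - pe.offset_V ** 2)
    return out if out.ndim else float(out)


def open_probability(pe: PoreEnergetics, v):
    """Equilibrium open probability K/(1+K) with K = exp(-dmu/kT).

    Computed as a logistic in -dmu, which neither overflows nor loses the
    complementarity P_open + P_closed = 1 for large |dmu|.
    """
    dmu = np.asarray(pore_free_energy(pe, v), dtype=float)
    from scipy.special import expit

    p = expit(-dmu)
    return p if p.ndim else float(p)


def steady_state_current(cs: ConductanceSet, pe: PoreEnergetics, env: Environment, v):
    """Steady-state two-process current I = (g_L + g_p P_open(V)) (V - E0)."""
    v = np.asarray(v, dtype=float)
    g = cs.g_leak_S + cs.g_pores_S * open_probability(pe, v)
    out = g * (v - env.nernst_V)
    return out if out.ndim else float(out)


def nernst_potential(conc_out: float, conc_in: float, z: int = 1,
                     temperature_K: float = 297.0) -> float:
    """Nernst potential E0 = (RT/zF) ln(c_out/c_in), in volts."""
    if conc_out <= 0 or conc_in <= 0:
        raise ValueError("concentrations must be positive")
    if z == 0:
        raise ValueError("ion valence must be nonzero")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT * temperature_K / (z * FARADAY) * math.log(conc_out / conc_in)


def resistance_from_conductance(g_S: float) -> float:
    """Membrane resistance 1/g (ohms)."""
    if g_S <= 0:
        raise ValueError("conductance must be positive")
    return 1.0 / g_S


def conductance_from_resistance(r_Ohm: float) -> float:
    """Inverse of :func:`resistance_from_conductance`."""
    if r_Ohm <= 0:
        raise ValueError("resistance must be positive")
    return 1.0 / r_Ohm


def single_channel_conductance(step_current_A: float, v: float, e0: float = 0.0) -> float:
    """Single-pore conductance from a quantized current step: I_step/(V - E0)."""
    if v == e0:
        raise ValueError("driving force V - E0 must be nonzero")
    return step_current_A / (v - e0)


def hydrostatic_pressure(depth_m: float, density_kg_m3: float = 1000.0,
                         gravity_m_s2: float = 9.81) -> float:
    """Hydrostatic pressure rho*g*h across a membrane at immersion depth h."""
    if depth_m < 0:
        raise ValueError("depth must be non-negative")
    return density_kg_m3 * gravity_m_s2 * depth_m


def max_aperture_curvature(aperture_diameter_m: float) -> float:
    """Maximum curvature of a membrane cap spanning a circular aperture.

    The most curved shape is a hemisphere whose radius equals the aperture
    radius, so c_max = 1/(d/2) = 2/d.  A 1 um pipette tip allows 1/(500 nm);
    a 100 um BLM aperture allows 100x less — the geometric argument for why
    flexoelectric voltage offsets vanish in BLM recordings.
    """
    if aperture_diameter_m <= 0:
        raise ValueError("aperture diameter must be positive")
    return 2.0 / aperture_diameter_m


def membrane_charge(mc: MembraneCapacitor, v: float) -> float:
    """Stored charge q = C_m V + A P0 (coulombs)."""
    return mc.capacitance_F * v + mc.area_m2 * mc.polarization_C_per_m2


def effective_capacitance(mc: MembraneCapacitor, v0_V: float, v: float) -> float:
    """Effective capacitance C_m* = C_m (1 + V0/V) folding polarization into C.

    Undefined at V = 0 (the polarization charge is then not expressible as a
    capacitance).
    """
    if v == 0:
        raise ValueError("effective capacitance undefined at V = 0")
    return mc.capacitance_F * (1.0 + v0_V / v)
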