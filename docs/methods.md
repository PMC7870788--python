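# Methods

## The two-process conduction model

A protein-free lipid bilayer held near the upper edge of its melting
transition is modelled with two parallel conduction pathways:

1. a **leak** of constant conductance `g_L` (seal and membrane defects, no
   discrete events), and
2. **N identical pores** of single-pore conductance `g_pore` that gate as
   two-state (open/closed) systems.  The open/closed free-energy difference
   in units of kT is quadratic in the applied voltage,

   Δμ(V) = Δμ(0) + α[(V + V₀)² − V₀²],

   and the equilibrium open probability is P_open = K/(1+K) with
   K = exp(−Δμ).  V₀ is a voltage offset produced by a spontaneous membrane
   polarization; geometrically, a membrane patch on a ~1 µm pipette tip can
   curve up to c = 2/d (hemispherical cap), so flexoelectric polarization —
   and hence V₀ — is expected in patch geometry but not on a ~100 µm BLM
   aperture, where the maximum curvature is two orders of magnitude smaller.

The steady-state current is I = (g_L + g_p P_open(V))(V − E₀) with
g_p = N·g_pore and E₀ the Nernst potential ((RT/zF)·ln(c_out/c_in); zero for
identical buffers on both sides).

### Sign convention for α

With the quadratic written as above and K = exp(−Δμ), a **positive** α makes
P_open *maximal* at V = −V₀, while a **negative** α makes it *minimal* there
and rising symmetrically away from it.  The outward-rectified recordings this
package emulates (pores opening at voltages far from −V₀, minimum open
probability at −V₀) therefore correspond to α < 0 in this parameterization.
Both signs are accepted by `PoreEnergetics`; α = 0 degenerates to
voltage-independent pores and is used only in test fixtures.  The recovery
fixture (Δμ(0) = 4 kT, α = +40 kT/V², V₀ = 0.2 V) keeps the historically
stated positive-α values; the BLM and single-channel fixtures use α < 0.
`open_probability` is computed as a logistic in −Δμ, which cannot overflow;
the open interval (0,1) holds exactly in real arithmetic and up to double
rounding (|Δμ| ≲ 37 kT) in floats.

## Synthetic traces — what the generator emulates

`simulate_trace` reproduces the step protocol of droplet patch-clamp
recordings: holding at 0 V for 50 ms, then one 3.1 s step per level from
+200 to −200 mV in −25 mV increments (17 levels, 52.7 s of stepped
recording), sampled at 10 kHz and passed through a causal 4-pole Bessel
low-pass at 2 kHz (unit DC gain, like the recording hardware).  Per level the
current is

I(t) = A₀e^(−t/τ₀) + A_m e^(−t/τ_m) + (g_L + g_pore·n_open(t))(V − E₀)
       [+ optional linear drift] + white noise,

with noise added before the filter.  Defaults: τ₀ = 258 µs, τ_m = 1.74 ms,
2 pA noise SD, transient amplitudes proportional to the jump size (2 nA/V
fast, 0.5 nA/V slow — plausible lumped scales; real structural amplitudes are
membrane-specific and are fitted, never predicted).

**Gating dynamics.**  Only the equilibrium occupancy and the 10–100 ms open
lifetime scale are constrained by observation, so the simulator adopts the
minimal kinetics consistent with both: a voltage-independent closing rate
k_close = 1/(mean open lifetime) (default 30 ms) and all voltage dependence
in the opening rate, k_open(V) = k_close·K(V), which yields the Boltzmann
occupancy exactly by detailed balance.  Each pore is an independent
continuous-time Markov chain simulated by exact exponential dwell sampling,
with initial states drawn from the equilibrium distribution at the
pre-jump voltage.  `gating="equilibrium"` replaces the stochastic pore count
by its ensemble mean g_p·P_open(V) — the large-N limit, used for clean
forward-model data.

**Seeding.**  One master seed; per-level streams are spawned via
`numpy.random.SeedSequence`, so every trace is independently and bit-exactly
reproducible from its recorded metadata.

**What it does not emulate:** membrane rupture, the occasional
non-equilibrating 200 mV first jump (the extraction step instead flags the
first level of each series as an outlier), pipette series-resistance and
capacitance charging (two orders of magnitude below the membrane), and any
mechanistic model of electrostriction — capacitance changes enter only as
lumped transient amplitudes.  Passing tests therefore show that the analysis
chain is correct and well-calibrated on data obeying the stated model, not
that real membranes obey it.

## Steady-state I-V fitting

Steady-state points are tail averages over 1.5–3.0 s after the jump
(all transients < 2 ms decay completely); each trace is first offset-corrected
by subtracting its holding-segment mean.  Fits minimize weighted least
squares of the per-level means (weights 1/SE²; unweighted when noise-free),
under four scenarios: `pores_only` (g_L = 0), `fixed_leak` (g_L supplied from
a linear profile of the same membrane), `free_leak` (all free), and `linear`
(slope through I(E₀) = 0).  `free_leak` nests the other two, so its RSS is
never larger — this ordering is asserted in the tests.

**Identifiability.**  When P_open ≪ 1 over the observed range, g_p and
exp(−Δμ(0)) enter the current only through their product, so the individual
values are degenerate while g_L, V₀ and the product are well determined; the
recovery studies therefore score g_L and V₀ only.  Rather than the
reparameterization-by-p_min route, the fitter works in the natural
parameters with bounds (g_L, g_p ≥ 0; |V₀| ≤ 0.35 V; |Δμ(0)| ≤ 50 kT;
|α| ≤ 2000 kT/V²) and a multi-start over V₀ ∈ {−0.3 … 0.3 V, 0.05 V steps}
crossed with both α signs; the lowest residual wins, ties broken toward
smaller |V₀|.  This proved numerically robust across the regimes tested
while keeping the reported parameters directly interpretable.  The open
probability at −V₀ (the extremum) is reported with every fit.

Negative-slope regions (dI/dV < 0, impossible without a voltage-dependent
conductance) are flagged from centered finite differences on the sorted
profile when the quotient falls below −2 propagated standard errors.  Depth
conditions are compared as per-condition mean ± SD of V₀ and pairwise
percent changes 100·(b−a)/a of g_L and g_p; the generator's depth rule is a
user-configured multiplicative scaling, not a mechanistic pressure model.

## Relaxation fitting

The biexponential fit is two-stage for robustness: a global search over the
shared pair (τ₀, τ_m) — coarse log-spaced grid followed by Nelder–Mead in
(log τ₀, log(τ_m − τ₀)), which enforces the ordering by construction — with
the per-jump amplitudes (plateau, A₀, A_m) profiled out by exact linear least
squares at each candidate pair.  The first 100 µs of each segment (the
instrument's time resolution) is excluded; the default fit window is 50 ms
(≈ 29 τ_m).  τ₀ may optionally be fixed (in real recordings it is dominated
by the anti-aliasing filter's time constant).  The structural decomposition
(ΔC_m, Δ(A·P₀), Δg) maps onto only three observables per jump (plateau, A₀,
A_m) and is therefore not identifiable from a fit; it is provided strictly
as a forward model, and the fitter reports lumped amplitudes only.

Amplitude-voltage classification fits A(V) = a·V per amplitude and
correlates the residuals with the nonlinear part of the I-V profile
(I − g_lin·V); |correlation| > 0.7 marks the amplitude as "rectified".  Which
physical amplitude tracks rectification is an empirical matter — the
observation that the *fast* amplitude does (suggesting pore opening rides
the fast timescale) is reproduced by the synthetic construction in
`analysis/03`, and the classifier reports it without interpretation.

## Event idealization

Discrete conduction steps are read with the standard single-channel recipe:
(1) robust linear drift removal using a low-percentile "lower envelope" per
250 ms window (tracks the closed level even at high open probability; only
the slope is removed, so drift-free traces pass through unchanged);
(2) amplitude-histogram mode finding (200 bins, Gaussian-smoothed, zero-padded
so edge modes are found); one mode means no channels (`n_levels = 1`, empty
event list); (3) half-amplitude threshold crossing with hysteresis — enter
level l+1 at (l+0.5)·step above baseline, fall back below (l−0.65)·step —
with levels assumed equally spaced (identical pores) and the spacing refined
from the medians of the quantized level-0/level-1 samples, which undoes the
peak-position bias introduced by filter smearing; (4) events shorter than
2 ms (≥ 4 samples at the 2 kHz bandwidth) are merged into their neighbour.
Openings are read upward or downward according to the sign of the driving
force.  Known limitation: merging filter-limited glitches also absorbs true
sub-resolution dwells, so apparent mean open times exceed the generating
lifetime by roughly the fraction of dwells shorter than the dead time
(~10–15% at 30 ms lifetime); the dwell statistics are exact on idealizations
run with the dead time disabled, as the tests verify.  Empirical open
probability is reported both as the fraction of time at level ≥ 1 and, given
the pore count, as the time-averaged occupancy per pore — the quantity
directly comparable to the Boltzmann P_open.

## Hodgkin–Huxley reference

The K⁺ gate uses the classic rate functions (V in volts, rates in s⁻¹):
α_n = 10⁴(V+0.055)/(1−e^(−(V+0.055)/0.010)), β_n = 125·e^(−(V+0.065)/0.08).
The removable singularity of α_n at −55 mV is handled by its analytic limit
(10⁴·0.010 = 100 s⁻¹) inside a 10⁻⁷ V guard band, using `expm1` elsewhere.
The closed-form jump response n(V,t) is verified against numerical
integration of dn/dt = α(1−n) − βn to 10⁻⁸.  The comparison with lipid-pore
open probabilities is tabular only; no similarity statistic is asserted.
The sodium gate is out of scope (no rate functions are available for it in
this formulation).

## Statistical checks and problem sizes

Stochastic checks use 3-standard-error bands with the *correct* standard
error for time-averaged two-state Markov data, Var ≈ 2p(1−p)τ_c/(T·N) with
τ_c = 1/(k_open+k_close) — the naive binomial SE would be ~25× too small at
10 kHz sampling.  Problem sizes were chosen so each check is decisive yet
quick: ten 17-level series for parameter recovery (g_L within 5%, V₀ within
15 mV, ≥ 9/10 seeds); 10 pores × 60 s per level for the occupancy check;
20–30 s single-pore recordings for idealization (step amplitude within 10%,
event count within 20%); noise-free round trips for the relaxation (1%) and
HH (10⁻⁸) identities.  Across-seed summaries use medians, which are robust
to the occasional fit landing in a secondary optimum.  The acceptance script
(`scripts/acceptance.py --seed N --out file.json`) recomputes all of these
from scratch and completes in well under a minute.

## Numerical choices

- Internal units are SI throughout; energies are dimensionless kT multiples
  (temperature lives in `Environment`); the reporting layer uses mV and pS.
- Equilibrium constants clamp Δμ to ±700 kT before exponentiation.
- lmfit/`leastsq` with xtol = ftol = 10⁻¹², ≤ 500 function evaluations per
  start, drives the I-V fits; Nelder–Mead with fatol = 0 drives the τ search.
- The trace file format is TSV with a commented JSON header that fully
  reconstructs the generating configuration; round-tripping is bit-exact
  (`%.17g`).  Run configurations are pydantic-validated (unknown keys
  rejected) and hashed (SHA-256) into every output table.
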