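"""Fit the post-jump transients with shared relaxation times.

Builds a series of jumps from the structural relaxation forward model (fast
capacitor charging at tau0 = 258 us, slow membrane relaxation at
tau_m = 1.74 ms), fits all jumps with one shared pair of time constants and
per-jump amplitudes, and classifies the voltage dependence of each amplitude
against the rectified I-V profile.
"""

import sys
from pathlib import Path

import numpy as np

import lipidpore as lp
from lipidpore.synth import CurrentTrace

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"
TAU0, TAUM = 258e-6, 1.74e-3
FS = 10_000.0


def main() -> None:
    rng = np.random.default_rng(SEED)
    levels = [0.05, 0.1, 0.15, 0.2, -0.05, -0.1, -0.15, -0.2]
    # The conductance after the jump follows the gated steady-state model.
    # Pore opening is fast, so the conductance relaxation Delta g rides the
    # fast time constant: the fast amplitude inherits the rectification of
    # the I-V profile while the slow (structural) amplitude stays linear in V.
    cs = lp.ConductanceSet(g_leak_S=0.3e-9, g_pores_S=1.5e-9)
    pe = lp.PoreEnergetics(2.0, -60.0, -0.15)
    env = lp.Environment()
    c_mb, dc = 100e-12, 4e-12

    t = np.arange(0, 0.05, 1 / FS)
    traces = []
    for v in levels:
        g_after = cs.g_leak_S + cs.g_pores_S * lp.open_probability(pe, v)
        delta_g = g_after - cs.g_leak_S
        a0 = c_mb * v / TAU0 - delta_g * v          # charging + fast pore opening
        am = dc * v / TAUM                           # slow structural change
        cur = g_after * v + a0 * np.exp(-t / TAU0) + am * np.exp(-t / TAUM)
        cur = cur + rng.normal(0, 2e-12, len(t))
        tt = np.arange(len(t) + 500) / FS
        cc = np.concatenate([rng.normal(0, 2e-12, 500), cur])
        vv = np.concatenate([np.zeros(500), np.full(len(t), v)])
        traces.append(CurrentTrace(tt, cc, vv, {"level_V": v, "pre_step_s": 0.05,
                                                "sample_rate_Hz": FS}))

    rf = lp.fit_biexponential_series(traces)
    rf.jumps.to_csv(OUT / "relaxation_fits.tsv", sep="\t", index=False)
    print(f"shared relaxation times: tau0 = {rf.tau_fast_s * 1e6:.0f} us "
          f"(generator 258 us), tau_m = {rf.tau_slow_s * 1e3:.2f} ms (generator 1.74 ms)")

    iv_i = lp.steady_state_current(cs, pe, env, np.array(levels))
    iv = lp.IVProfile(np.array(levels), iv_i, np.zeros(len(levels)),
                      np.full(len(levels), 10))
    cls = lp.amplitude_voltage_analysis(rf, iv)
    for key, info in cls.items():
        print(f"{key}: {info['classification']} "
              f"(slope {info['slope_A_per_V'] * 1e9:.2f} nA/V, "
              f"corr with I-V nonlinearity {info['correlation_with_iv_nonlinearity']:.2f})")
    import json
    (OUT / "relaxation_classification.json").write_text(json.dumps(cls, indent=2))


if __name__ == "__main__":
    main()
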