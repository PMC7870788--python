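"""Simulate the synthetic voltage-clamp data sets used by the later analyses.

Generates three conditions and writes the trace files plus a summary:
  * a rectified patch recording (polarization offset V0 = 200 mV),
  * the same membrane in the large-N ensemble limit (clean I-V data),
  * a symmetric BLM recording (V0 forced to 0, pores gating stochastically).
"""

import sys
from pathlib import Path

import lipidpore as lp
from lipidpore.traceio import write_trace

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "traces"


def main() -> None:
    prot = lp.build_protocol()
    env = lp.Environment()
    conditions = {
        "patch_stochastic": dict(
            cs=lp.ConductanceSet.from_pores(0.37e-9, 100, 15e-12),
            pe=lp.PoreEnergetics(4.0, 40.0, 0.2), mode="patch", gating="stochastic"),
        "patch_ensemble": dict(
            cs=lp.ConductanceSet(g_leak_S=0.37e-9, g_pores_S=1.5e-9),
            pe=lp.PoreEnergetics(4.0, 40.0, 0.2), mode="patch", gating="equilibrium"),
        "blm_stochastic": dict(
            cs=lp.ConductanceSet.from_pores(270e-12, 12, 863e-12 / 12),
            pe=lp.PoreEnergetics(4.0, -100.0, 0.0), mode="BLM", gating="stochastic"),
    }
    for name, cond in conditions.items():
        traces = lp.simulate_trace(prot, cond["cs"], cond["pe"], env, seed=SEED,
                                   mode=cond["mode"], gating=cond["gating"],
                                   extra_metadata={"condition": name})
        outdir = OUT / name
        for tr in traces:
            write_trace(tr, outdir / f"trace_{tr.metadata['level_V'] * 1e3:+.0f}mV.tsv")
        print(f"{name}: {len(traces)} traces x {len(traces[0].time_s)} samples "
              f"-> {outdir}")
    print(f"protocol: {prot.n_levels} levels, {prot.total_stepped_s:.1f} s stepped")


if __name__ == "__main__":
    main()
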