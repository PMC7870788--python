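"""Compare lipid-pore open probabilities with the Hodgkin-Huxley K+ gate.

Tabulates n-gate rates, the steady state n_inf, tau_n and P_open,K = n_inf^4
on a physiological voltage window, together with rectified lipid-pore
parameterizations whose open probability rises over the same window.
"""

from pathlib import Path

import numpy as np

import lipidpore as lp
from lipidpore.hh import HHPotassium, hh_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = hh_table(-0.1, 0.05, 0.005)
    table.to_csv(OUT / "hh_gate_table.tsv", sep="\t", index=False)
    rest = table.iloc[int(np.argmin(np.abs(table["voltage_V"] + 0.065)))]
    print(f"at rest (-65 mV): alpha_n = {rest['alpha_n_per_s']:.1f}/s, "
          f"beta_n = {rest['beta_n_per_s']:.1f}/s, n_inf = {rest['n_inf']:.4f}, "
          f"tau_n = {rest['tau_n_s'] * 1e3:.2f} ms, P_open,K = {rest['p_open_K']:.4f}")

    # lipid parameterizations in the rectified regime with different offsets
    pes = [lp.PoreEnergetics(1.0, -80.0, 0.15),
           lp.PoreEnergetics(2.0, -120.0, 0.20),
           lp.PoreEnergetics(1.5, -100.0, 0.25)]
    cmp = lp.compare_open_probabilities(HHPotassium(), pes,
                                        np.arange(-0.1, 0.0501, 0.005))
    cmp.to_csv(OUT / "hh_vs_lipid_open_probability.tsv", sep="\t", index=False)
    rising = all(np.all(np.diff(cmp[c]) > 0) for c in cmp.columns[1:])
    print(f"all open-probability curves monotonically rising on [-100, +50] mV: {rising}")


if __name__ == "__main__":
    main()
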