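"""Calibration script for the synaptic strengths that the circuit does
not pin down analytically.

The per-input peak conductances g_syn_e (ANF->MSO) and g_syn_i
(GBC->MSO) are free parameters of the network.  This script documents
and reproduces how their defaults were fixed, in this order:

1. g_syn_e: with inhibition off, sweep the excitatory strength and keep
   the coincidence-detector regime -- a bell-shaped 125 Hz ITD-rate
   function whose best-ITD sits at the built-in 100 us contralateral
   axonal delay, with a healthy peak rate and a deep trough (unilateral
   volleys alone must not drive the cell).
2. g_syn_i: with g_syn_e frozen, sweep the inhibitory strength until the
   fitted 125 Hz best-ITD of the right hemisphere reaches the
   contralateral-leading target of about -470 us while the peak rate
   stays usable for decoding.

Run:  python scripts/calibrate.py [--seed 3] [--n 40]
"""

import argparse

import numpy as np

from mso_itd.decoding import fit_itd_rate
from mso_itd.network import NetworkConfig, itd_rate_curve


def sweep(freq, ge_values, gi_values, n, seed):
    grid = np.linspace(-1e-3, 1e-3, 15)
    print("# stage 1: excitatory strength (inhibition off)")
    for ge in ge_values:
        net = NetworkConfig(n_per_population=n, cf=freq, g_syn_e=ge,
                            g_syn_i=0.0, rng_seed=seed)
        df = itd_rate_curve(freq, grid, net)
        fit = fit_itd_rate(df.itd, df.rate_right)
        print(f"g_syn_e={ge:5.1f} nS: best-ITD {fit.b * 1e6:+6.0f} us, "
              f"peak {df.rate_right.max():6.1f} sp/s, "
              f"trough {df.rate_right.min():5.1f} sp/s")
    print("# stage 2: inhibitory strength (g_syn_e at default)")
    for gi in gi_values:
        net = NetworkConfig(n_per_population=n, cf=freq, g_syn_i=gi,
                            rng_seed=seed)
        df = itd_rate_curve(freq, grid, net)
        fit = fit_itd_rate(df.itd, df.rate_right)
        print(f"g_syn_i={gi:5.1f} nS: best-ITD {fit.b * 1e6:+6.0f} us, "
              f"peak {df.rate_right.max():6.1f} sp/s")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--n", type=int, default=40)
    args = ap.parse_args()
    sweep(125.0,
          ge_values=(10.0, 14.0, 16.0, 18.0, 20.0, 22.0),
          gi_values=(10.0, 20.0, 25.0, 30.0, 35.0),
          n=args.n, seed=args.seed)
    print(f"frozen defaults: g_syn_e={NetworkConfig().g_syn_e} nS, "
          f"g_syn_i={NetworkConfig().g_syn_i} nS")
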