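"""Validate the frequency-domain FLIM estimator on simulated phase stacks.

Two studies: (i) noiseless mono-exponential stacks across the lifetime
range 0.5-6 ns at 75.1 and 40 MHz must return the input lifetime to
machine precision; (ii) Poisson-noise stacks at ~1e4 counts/pixel must show
an ROI-mean phase-lifetime bias below 1% across seeds.

Writes results/flim_recovery.csv and results/flim_poisson_bias.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fretchar import flim, synth

OUT = Path(__file__).resolve().parent.parent / "results"


def noiseless_sweep() -> pd.DataFrame:
    rows = []
    for f_hz in (75.1e6, 40e6):
        for tau in np.arange(0.5, 6.01, 0.5):
            stack, _, _ = synth.gen_phase_stack((float(tau),), (1.0,), f_hz=f_hz, shape=(2, 2))
            est = flim.roi_phasor(flim.fit_phasor(stack), np.ones((2, 2), bool))
            pair = flim.lifetimes_from_phasor(est, f_hz)
            rows.append(
                {
                    "f_mhz": f_hz / 1e6,
                    "tau_true_ns": tau,
                    "tau_phase_err": pair.tau_phase_ns - tau,
                    "tau_mod_err": pair.tau_mod_ns - tau,
                }
            )
    return pd.DataFrame(rows)


def poisson_bias(seed: int, n_seeds: int = 100, tau: float = 3.8) -> pd.DataFrame:
    roi = np.ones((16, 16), bool)
    estimates = []
    for i in range(n_seeds):
        stack, _, _ = synth.gen_phase_stack(
            (tau,), (1.0,), counts_per_pixel=1e4, shape=(16, 16),
            noise_model="poisson", seed=seed + i,
        )
        est = flim.roi_phasor(flim.fit_phasor(stack), roi)
        estimates.append(
            flim.lifetimes_from_phasor(est, stack.modulation_frequency_hz).tau_phase_ns
        )
    estimates = np.asarray(estimates)
    return pd.DataFrame(
        [
            {
                "tau_true_ns": tau,
                "n_seeds": n_seeds,
                "tau_phase_mean_ns": estimates.mean(),
                "bias_pct": (estimates.mean() - tau) / tau * 100,
                "sd_ns": estimates.std(ddof=1),
            }
        ]
    )


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)
    sweep = noiseless_sweep()
    sweep.to_csv(OUT / "flim_recovery.csv", index=False)
    worst = max(sweep.tau_phase_err.abs().max(), sweep.tau_mod_err.abs().max())
    print(f"noiseless sweep: worst |error| = {worst:.2e} ns over {len(sweep)} conditions")

    bias = poisson_bias(args.seed)
    bias.to_csv(OUT / "flim_poisson_bias.csv", index=False)
    print(
        f"Poisson (1e4 counts, 16x16 ROI, {int(bias.n_seeds[0])} seeds): "
        f"ROI-mean tau_phi = {bias.tau_phase_mean_ns[0]:.4f} ns "
        f"(bias {bias.bias_pct[0]:+.3f}%)"
    )


if __name__ == "__main__":
    main()
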