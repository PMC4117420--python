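"""Calibrate the simulation temperature.

The couplings (J0=5, J1=2, J2=1, Jsurf=10) are fixed magnitudes; the
temperature is the free dial and is chosen to balance film fluidity against
ordering.  This script scans the inverse temperature beta with P6-only runs
of fixed length and reports the ordered-film size (largest bonded cluster)
each beta attains: too hot and the film never condenses, too cold and it
jams as a frozen polycrystal.  The package default (DEFAULT_BETA = 0.08 in
hydrofilm.experiments) is the argmax of this scan.

Writes results/calibration.csv.

Usage: python analysis/00_calibrate_temperature.py [--sweeps 3000] [--cells 10]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from hydrofilm.lattice import LatticeConfig
from hydrofilm.mc_engine import MCParams, run_simulation
from hydrofilm.spin_model import ModelParams, build_interaction_table

BETAS = (0.05, 0.08, 0.1, 0.12, 0.15, 0.2, 0.3, 0.5, 1.0)
SEEDS = (11, 12, 13)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sweeps", type=int, default=3000)
    ap.add_argument("--cells", type=int, default=10)
    ap.add_argument("--out", default="results/calibration.csv")
    args = ap.parse_args()

    table = build_interaction_table(False)
    mp = ModelParams(p3_enabled=False)
    n = 14 * args.cells
    rows = []
    for beta in BETAS:
        finals, occs = [], []
        for seed in SEEDS:
            series, _ = run_simulation(
                LatticeConfig(n, n), table, mp,
                MCParams(sweeps=args.sweeps, seed=seed, beta=beta,
                         record_every=max(1, args.sweeps // 30)))
            finals.append(int(series.data["largest_cluster"].iloc[-1]))
            occs.append(float(series.data["n_occupied"].iloc[-1]) / (n * n))
        rows.append({"beta": beta,
                     "mean_largest_cluster": float(np.mean(finals)),
                     "mean_occupancy": float(np.mean(occs))})
        print(f"beta={beta}: largest={np.mean(finals):.0f} "
              f"occupancy={np.mean(occs):.3f}")
    df = pd.DataFrame(rows)
    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)
    best = df.loc[df["mean_largest_cluster"].idxmax(), "beta"]
    print(f"\nbest beta (largest ordered film in {args.sweeps} sweeps): {best}")


if __name__ == "__main__":
    main()
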