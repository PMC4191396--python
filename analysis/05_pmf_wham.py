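#!/usr/bin/env python
"""Umbrella-sampling reweighting of the zeta g- -> t transition.

Generates umbrella windows every 10 deg along zeta (harmonic bias,
k = 0.02 kcal mol^-1 deg^-2) from a model double-well free energy with a
~1 kcal/mol asymmetry between the g- and t basins, and reconstructs the
profile with WHAM.  The recovered barrier and basin offset are compared
with the generating curve.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cgtwist.synthgen import generate_umbrella_samples
from cgtwist.thermo import wham

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def model_free_energy(x):
    x = np.asarray(x, dtype=float)
    # minima near 270 (g-) and 360 (t), ~3.5 kcal/mol barrier near 315
    return 3.0 * np.sin(np.pi * (x - 270.0) / 90.0) ** 2 + (x - 270.0) / 90.0


def main():
    RESULTS.mkdir(exist_ok=True)
    centers = np.arange(270.0, 361.0, 10.0)
    windows = generate_umbrella_samples(model_free_energy, centers, k=0.02,
                                        n_per_window=5000, seed=401)
    res = wham(windows, grid_step=1.0)
    pd.DataFrame({"zeta_deg": res.grid,
                  "free_energy_kcal": np.round(res.free_energy, 4)}) \
        .to_csv(RESULTS / "wham_profile.tsv", sep="\t", index=False)

    mask = (res.grid >= 270) & (res.grid <= 360)
    est = res.free_energy[mask]
    grid = res.grid[mask]
    truth = model_free_energy(grid)
    truth -= truth.min()
    barrier_est = est.max() - est.min()
    barrier_true = truth.max() - truth.min()
    t_basin = est[grid > 340].min() - est.min()
    t_basin_true = truth[grid > 340].min()
    print(f"WHAM converged in {res.n_iterations} iterations "
          f"(residual {res.max_residual:.1e} kcal/mol)")
    print(f"barrier: recovered {barrier_est:.2f} vs generating {barrier_true:.2f} kcal/mol")
    print(f"t-basin offset: recovered {t_basin:.2f} vs generating {t_basin_true:.2f} kcal/mol")
    print(f"max |error| over profile: {np.abs(est - truth).max():.3f} kcal/mol")
    print("wrote results/wham_profile.tsv")


if __name__ == "__main__":
    main()
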