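#!/usr/bin/env python
"""Apparent-permeability estimator validated by forward-model inversion.

Simulates dextran leakage over a single perfused vessel (3 x 5 min
frames) at known permeabilities spanning 1e-7 .. 1e-5 cm/s, inverts the
series with the estimator, and scores recovery noise-free, under 5%
Gaussian noise, and at the P = 0 null.

Writes results/permeability_recovery.csv.  Run: python analysis/03_permeability_recovery.py
"""

import numpy as np
import pandas as pd

from vesselquant import permeability, phantom
from vesselquant.validation import null_permeability

SEED = 1
OUT = "results/permeability_recovery.csv"


def main() -> None:
    spec = phantom.single_vessel_phantom(radius_px=10.0)
    _, truth = phantom.generate_network_phantom(spec)
    rng = np.random.default_rng(SEED)
    rows = []
    for P_true in (1e-7, 1e-6, 1e-5):
        leak = phantom.LeakageSpec(P_true_cm_per_s=P_true, n_frames=4)
        series = phantom.simulate_leakage_series(truth, leak)
        res = permeability.permeability_series(series, truth.mask)
        errs = []
        for s in rng.integers(0, 2**31 - 1, size=20):
            noisy = phantom.LeakageSpec(
                P_true_cm_per_s=P_true, n_frames=4, noise_sigma=9.0, seed=int(s)
            )
            r = permeability.permeability_series(
                phantom.simulate_leakage_series(truth, noisy), truth.mask
            )
            errs.append(abs(r.P_cm_per_s - P_true) / P_true)
        rows.append(
            {
                "P_true_cm_per_s": P_true,
                "P_recovered_cm_per_s": res.P_cm_per_s,
                "noise_free_rel_err": abs(res.P_cm_per_s - P_true) / P_true,
                "noisy_median_rel_err": float(np.median(errs)),
            }
        )
    null = null_permeability(SEED)
    df = pd.DataFrame(rows)
    df.to_csv(OUT, index=False)
    print(df.to_string(index=False))
    print(
        f"null: mean P = {null['mean_P_cm_per_s']:.2e} cm/s "
        f"(|mean|/s.e. = {null['abs_mean_over_se']:.2f}, n = 20 seeds)"
    )
    print(f"table -> {OUT}")


if __name__ == "__main__":
    main()
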