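"""Thermal ensembles of the symmetric TET dimer.

Runs independently seeded Langevin trajectories at a low (kBT = 0.01) and a
high (kBT = 1.5) bath temperature and prints the ensemble-averaged acceptor
occupation.  At high temperature the symmetric dimer shuttles the electron
back and forth so its late-time average settles at 1/2.
"""

import numpy as np

from tetdimer import IntegratorConfig, ensemble_stats, get_preset, run_ensemble

params = get_preset("tet").params
config = IntegratorConfig(t_max=300.0)
for kBT in (0.01, 1.5):
    members = run_ensemble(params, kBT=kBT, n_runs=20, base_seed=42,
                           config=config)
    stats = ensemble_stats(members)
    half = len(stats["times"]) // 2
    late_mean = stats["mean_P_A"][half:].mean()
    late_std = stats["std_P_A"][half:].mean()
    print(f"kBT={kBT:5.2f}  late-time <P_A>={late_mean:.3f}  "
          f"ensemble std={late_std:.3f}")
print("The pure symmetric degeneracy point has no preferred site: noise")
print("kicks the dimer off its stationary donor state and, at high")
print("temperature, the acceptor occupation equilibrates to 0.5 with a")
print("large run-to-run spread.")
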