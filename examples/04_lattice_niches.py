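"""Spatial niches on the scaled lattice (n = 100, N = 10 000).

Runs the three reference environments — frozen, well mixed, and
influx-dominated — and classifies the steady state of each.  Takes a few
minutes on one CPU.
"""

import numpy as np

from infosoup import SimConfig, classify_niche, interaction_complexity, run

ENVIRONMENTS = {
    "frozen (c=0, v=0, phi=0)": SimConfig(n=100, c=0, v=0.0, phi=0.0,
                                          iterations=2_000_000, seed=1,
                                          record_every=2000),
    "well mixed (c=1000, v=25, phi=0)": SimConfig(n=100, c=1000, v=25.0, phi=0.0,
                                                  iterations=200_000, seed=1,
                                                  record_every=1000),
    "influx dominated (phi=1)": SimConfig(n=100, c=1000, v=25.0, phi=1.0,
                                          iterations=100_000, seed=1,
                                          record_every=1000),
}

for name, cfg in ENVIRONMENTS.items():
    res = run(cfg, stop_window=50_000, stop_tol=0.005)
    f = res.series.tail_mean(50_000)
    label = classify_niche(f, res.lattice.survivors())
    print(f"{name}:")
    print(f"  niche {label.label}; survivors {sorted(res.lattice.survivors())}")
    print(f"  f(T2)+f(T4) = {f[1] + f[3]:.3f}, f(T15) = {f[14]:.3f}, "
          f"C_mu = {interaction_complexity(f):.2f} bits")
print()
print("The frozen lattice selects the single-transition network {1,2,4,8}")
print("with T2+T4 near 85%; mixing selects the nine-type niche dominated")
print("by T15; overwhelming influx erases all structure (near-uniform).")
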