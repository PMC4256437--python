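"""Stationary device-noise fixture and error percentiles.

Emulates a GPS logger sitting on a fixed point: fixes scatter around the
true position with 1 m Gaussian noise per axis plus a small constant
bias.  The absolute error (distance to the true point) feels the bias;
the relative error (distance to the fixes' centroid) does not — its 95th
percentile ~ 2.45 m is what calibrates the simulator's noise scale.
"""

import numpy as np

from grazetrack import device_accuracy_percentiles

rng = np.random.default_rng(0)
true_point = (0.0, 0.0)
bias = np.array([2.0, 1.5])
fixes = rng.normal(0.0, 1.0, size=(4000, 2)) + bias

pct = device_accuracy_percentiles(fixes, true_point)
for kind in ("absolute", "relative"):
    q50, q95 = pct[kind][0.5], pct[kind][0.95]
    print(f"{kind:8s} error: median {q50:.2f} m   95th pct {q95:.2f} m")
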