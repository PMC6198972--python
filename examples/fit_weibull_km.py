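"""Weibull fitting from (pseudo-)digitized Kaplan-Meier points.

Generates synthetic digitized points from the published crizotinib PFS
curve — exact survival values with multiplicative digitization noise —
then recovers the curve by weighted log-log regression and reports the
fit diagnostics and the implied median PFS.
"""

import numpy as np

from alkcea.survival import WeibullCurve, fit_weibull, median_survival
from alkcea.synthetic_data import SyntheticKmSpec, generate_km_points

truth = WeibullCurve(scale=0.0211, shape=1.5326, time_unit="month")
times = tuple(np.arange(1.0, 31.0))  # monthly digitization over 30 months

for noise in (0.0, 0.02):
    pts = generate_km_points(SyntheticKmSpec(truth, times, noise, seed=1))
    fit = fit_weibull(pts)
    print(f"noise sd {noise:.2f}: scale={fit.scale:.5f} "
          f"shape={fit.shape:.4f} r2={fit.fit_r2:.4f} "
          f"median={median_survival(fit):.2f} months")

print()
print(f"truth:         scale={truth.scale:.5f} shape={truth.shape:.4f} "
      f"median={median_survival(truth):.2f} months")
print("Reading: noise-free digitization recovers the curve exactly (r2=1);")
print("2% multiplicative noise still recovers both parameters to ~1-2%.")
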