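"""Synthetic inputs for testing and demonstration.

Two generators cover everything the pipeline consumes:

* :func:`generate_km_points` emulates the digitization of a published
  Kaplan-Meier curve — exact Weibull survival values perturbed by
  multiplicative log-normal noise (digitization error scales with curve
  height, and the noise keeps survival strictly positive), then forced
  non-increasing.
* :func:`generate_parameter_bundle` draws every ranged parameter uniformly
  within its published range, yielding a random but fully valid model
  configuration for property-based fuzzing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterBundle, default_paper_parameters
from .survival import KmPoints, WeibullCurve, weibull_survival

__all__ = ["SyntheticKmSpec", "generate_km_points", "generate_parameter_bundle"]


@dataclass(frozen=True)
class SyntheticKmSpec:
    """Recipe for pseudo-digitized KM points.

    ``noise_sd`` is the standard deviation of the log-scale multiplicative
    perturbation; 0 puts the points exactly on the curve.
    """

    curve: WeibullCurve
    times: tuple
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValueError("times must be a non-empty 1-D sequence")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "times", tuple(float(x) for x in t))


def generate_km_points(spec: SyntheticKmSpec) -> KmPoints:
    """Generate KM points ``S_i = S(t_i) * exp(eps_i)`` with seeded Gaussian
    ``eps_i`` of sd ``noise_sd``, clipped into (0, 1] and made non-increasing
    by a running minimum.  Deterministic given the spec's seed."""
    t = np.asarray(spec.times, dtype=float)
    s = weibull_survival(spec.curve, t)
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if spec.noise_sd > 0.0:
        rng = np.random.default_rng(spec.seed)
        s = s * np.exp(rng.normal(0.0, spec.noise_sd, size=len(t)))
    tiny = np.finfo(float).tiny
    s = np.clip(s, tiny, 1.0)
    s = np.minimum.accumulate(s)
    return KmPoints(tuple(t), tuple(s))


def generate_parameter_bundle(seed: int,
                              base: ParameterBundle | None = None
                              ) -> ParameterBundle:
    """A random valid bundle: every ranged parameter drawn uniformly within
    its range (fixed-range parameters keep their base).  The result passes
    the same validation as a loaded config, so it can drive fuzz tests of
    the whole pipeline.  Reproducible from the seed."""
    if base is None:
        base = default_paper_parameters()
    rng = np.random.default_rng(seed)
    values: dict[str, float] = {}
    for name, spec in base.specs.items():
        if spec.has_range:
            values[name] = float(rng.uniform(spec.low, spec.high))
    # utilities must stay ordered: redraw the progressed utility below the
    # sampled progression-free utility if the independent draws crossed
    if values.get("u_progressed", 0.0) > values.get("u_pfs", 1.0):
        values["u_progressed"] = float(
            rng.uniform(base.spec("u_progressed").low, values["u_pfs"]))
    return base.with_values(values)
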