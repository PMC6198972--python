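"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis re-evaluates the ICER of a strategy pair with a
single parameter pushed to each end of its published range, everything else
held at base; entries are ranked by the span between the two ICERs.

The probabilistic analysis draws every non-fixed parameter from its assigned
family — triangular for ranged costs (mode at the base value), beta for
probabilities, proportions and utilities (method of moments with mean at the
base value and sd = range/4, reading the published range as an approximate
95% interval) — evaluates all strategies on the same draw, and summarises
the draws as a cost-effectiveness acceptability curve (CEAC) and an
incremental scatter.  A beta whose mean sits on a bound (test sensitivity
and specificity, base 1) admits no proper method-of-moments solution, so
sampling falls back to uniform on the range and notes it via ``logging``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import StrategyResult, evaluate_all, evaluate_strategy, icer
from .decision_tree import StrategySpec
from .parameters import ParameterBundle, ParameterSpec

__all__ = ["TornadoEntry", "one_way", "tornado", "sample_triangular",
           "sample_beta_from_range", "sample_parameter", "run_psa",
           "psa_frame", "ceac", "quadrant_counts", "DEFAULT_PSA_SEED"]

logger = logging.getLogger(__name__)

DEFAULT_PSA_SEED = 20161023


@dataclass(frozen=True)
class TornadoEntry:
    """One bar of the tornado: the ICER at both ends of one parameter."""

    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _icer_value(a: StrategyResult, b: StrategyResult) -> float:
    """ICER as a signed number for tornado spans.

    Dominance has no finite ratio; for ranking purposes a dominant
    comparison reports the (negative or zero) cost difference per QALY via
    the raw ratio when effects differ, and NaN when effects are tied.
    """
    inc = icer(a, b)
    if inc.icer is not None:
        return inc.icer
    if inc.delta_effect != 0.0:
        return inc.delta_cost / inc.delta_effect
    return float("nan")


def one_way(bundle: ParameterBundle, parameter: str,
            strategy: str = "ngs", comparator: str = "control"
            ) -> TornadoEntry:
    """ICER of ``strategy`` vs ``comparator`` with ``parameter`` at each end
    of its range, all else at base.  The input bundle is never mutated."""
    spec = bundle.spec(parameter)  # raises KeyError naming valid parameters
    out = {}
    for end, value in (("low", spec.low), ("high", spec.high)):
        b = bundle.with_values({parameter: value})
        results = evaluate_all(b, (strategy, comparator))
        out[end] = _icer_value(results[strategy], results[comparator])
    return TornadoEntry(parameter, spec.low, spec.high, out["low"], out["high"])


def tornado(bundle: ParameterBundle, strategy: str = "ngs",
            comparator: str = "control",
            parameters: Sequence[str] | None = None,
            include_assumed_ranges: bool = False) -> pd.DataFrame:
    """One-way analysis over every ranged parameter, sorted by descending
    span.  Weibull curve parameters have no published ranges and are not
    varied; the discount-rate range (an assumption) joins only on request."""
    if parameters is None:
        parameters = bundle.ranged_parameter_names(include_assumed_ranges)
    entries = [one_way(bundle, p, strategy, comparator) for p in parameters]
    df = pd.DataFrame({
        "parameter": [e.parameter for e in entries],
        "low_value": [e.low_value for e in entries],
        "high_value": [e.high_value for e in entries],
        "low_icer": [e.icer_at_low for e in entries],
        "high_icer": [e.icer_at_high for e in entries],
        "span": [e.span for e in entries],
    })
    return df.sort_values("span", ascending=False,
                          kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# PSA sampling
# ---------------------------------------------------------------------------

def sample_triangular(low: float, mode: float, high: float,
                      rng: np.random.Generator, size=None):
    """Triangular draw(s) with support exactly [low, high] and mode at the
    base value; degenerate ranges return the mode."""
    if not (low <= mode <= high):
        raise ValueError(f"need low <= mode <= high, got ({low}, {mode}, {high})")
    if low == high:
        return mode if size is None else np.full(size, mode)
    return rng.triangular(low, mode, high, size=size)


def beta_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments (alpha, beta) for a beta with the given mean/sd.

    Requires 0 < mean < 1 and sd^2 < mean(1-mean).
    """
    var = sd * sd
    if not (0.0 < mean < 1.0) or var <= 0.0 or var >= mean * (1.0 - mean):
        raise ValueError("moments incompatible with a beta distribution")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def sample_beta_from_range(base: float, low: float, high: float,
                           rng: np.random.Generator, size=None):
    """Beta draw(s) with mean ``base`` and sd ``(high - low)/4``.

    Degenerate ranges return the base.  When the implied moments admit no
    beta (mean on a bound, or variance too large) the draw falls back to
    uniform on [low, high], logged once per call site.
    """
    if not (0.0 <= low <= base <= high <= 1.0):
        raise ValueError(
            f"need 0 <= low <= base <= high <= 1, got ({low}, {base}, {high})")
    if low == high:
        return base if size is None else np.full(size, base)
    sd = (high - low) / 4.0
    try:
        a, b = beta_moments(base, sd)
    except ValueError:
        _warn_uniform_fallback(base, sd, low, high)
        return rng.uniform(low, high, size=size)
    return rng.beta(a, b, size=size)


@lru_cache(maxsize=None)
def _warn_uniform_fallback(base: float, sd: float, low: float,
                           high: float) -> None:
    """Log the beta->uniform fallback once per distinct parameterisation."""
    logger.warning(
        "beta(mean=%g, sd=%g) on [%g, %g] has no method-of-moments "
        "solution; sampling uniform on the range instead",
        base, sd, low, high)


def sample_parameter(spec: ParameterSpec, rng: np.random.Generator) -> float:
    """One PSA draw for a single parameter according to its family."""
    if spec.distribution == "fixed" or not spec.has_range:
        return spec.base
    if spec.distribution == "triangular":
        return float(sample_triangular(spec.low, spec.base, spec.high, rng))
    if spec.distribution == "beta":
        return float(sample_beta_from_range(spec.base, spec.low, spec.high, rng))
    raise AssertionError(f"unreachable distribution {spec.distribution!r}")


@dataclass(frozen=True)
class PsaSample:
    """One Monte-Carlo draw: sampled values plus per-strategy outcomes."""

    draw: int
    values: Mapping[str, float]
    results: Mapping[str, StrategyResult]


def run_psa(bundle: ParameterBundle,
            strategies: Sequence[str] = ("control", "ngs", "pcr"),
            n: int = 1000, seed: int = DEFAULT_PSA_SEED) -> list[PsaSample]:
    """Monte-Carlo propagation of parameter uncertainty.

    Every non-fixed parameter is redrawn each iteration and all strategies
    are evaluated on the same draw (common random parameters), so
    between-strategy comparisons are paired.  Identical (seed, n) give
    identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sampled_names = [name for name, spec in bundle.specs.items()
                     if spec.distribution != "fixed" and spec.has_range]
    samples: list[PsaSample] = []
    for i in range(n):
        values = {name: sample_parameter(bundle.spec(name), rng)
                  for name in sampled_names}
        b = bundle.with_values(values)
        results = {
            name: evaluate_strategy(StrategySpec.from_bundle(name, b), b)
            for name in strategies
        }
        samples.append(PsaSample(i, values, results))
    return samples


def psa_frame(samples: Sequence[PsaSample]) -> pd.DataFrame:
    """Long-format (draw, strategy, cost, qalys) table of PSA output."""
    rows = [
        {"draw": s.draw, "strategy": name,
         "cost": r.total_cost, "qalys": r.qalys}
        for s in samples for name, r in s.results.items()
    ]
    return pd.DataFrame(rows)


def ceac(samples: Sequence[PsaSample], wtp_grid: Sequence[float],
         strategy: str = "ngs", comparator: str = "control") -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay the curve reports the fraction of draws in
    which ``strategy`` has the higher net monetary benefit.  At WTP 0 this
    is the fraction of draws where it is cheaper; as WTP grows it tends to
    the fraction where it gains QALYs.
    """
    if len(samples) == 0:
        raise ValueError("need at least one PSA sample")
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise ValueError("WTP grid must be non-empty")
    d_cost = np.array([s.results[strategy].total_cost
                       - s.results[comparator].total_cost for s in samples])
    d_eff = np.array([s.results[strategy].qalys
                      - s.results[comparator].qalys for s in samples])
    prob = [(w * d_eff - d_cost > 0).mean() for w in wtp]
    return pd.DataFrame({"wtp": wtp, f"prob_{strategy}": prob})


def quadrant_counts(samples: Sequence[PsaSample], strategy: str = "ngs",
                    comparator: str = "control") -> dict[str, int]:
    """Incremental-plane quadrant counts (NE: dearer & better, SE: cheaper &
    better, SW: cheaper & worse, NW: dearer & worse); ties go east/north."""
    counts = {"NE": 0, "SE": 0, "SW": 0, "NW": 0}
    for s in samples:
        d_cost = s.results[strategy].total_cost - s.results[comparator].total_cost
        d_eff = s.results[strategy].qalys - s.results[comparator].qalys
        if d_eff >= 0:
            counts["NE" if d_cost >= 0 else "SE"] += 1
        else:
            counts["NW" if d_cost >= 0 else "SW"] += 1
    return counts
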