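"""Three-state Markov cohort engine.

States: progression-free (PFS), progressed disease (PD), dead.  Each cycle a
progression-free patient may progress (per-cycle probability taken from the
treatment's Weibull PFS curve, so the trace reproduces the fitted curve
exactly) and a progressed patient may die (constant per-cycle probability
derived from the 5.4-month median post-progression survival).  There is no
direct PFS->death shortcut and no recovery.

Accrual walks the trace once, pricing each state:

* PFS on chemotherapy — pemetrexed (dosed by body-surface area, billed by
  whole 500-mg vial by default) plus other chemotherapy drugs plus severe-
  adverse-event management, for the first ``chemo_max_cycles`` cycles only;
  routine follow-up every cycle.
* PFS on crizotinib — drug cost per day on treatment, subject to the
  patient-assistance-program window; follow-up every cycle.
* PD — salvage chemotherapy for the ``salvage_uptake`` fraction during their
  first ``salvage_max_cycles`` cycles in the state, supportive care
  otherwise.
* Death transition — a one-off terminal palliative-care cost.

Utilities weight state residence into QALYs; every stream is discounted
continuously-compounded-free at ``(1+r)**(-t_years)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_tree import Subcohort, curve_for_role
from .parameters import ParameterBundle, RunSettings
from .survival import WeibullCurve, per_cycle_transition_prob

__all__ = ["CohortTrace", "AccrualResult", "discount_factor",
           "run_trace", "accrue", "evaluate_subcohort"]

_OCC_TOL = 1e-9


def discount_factor(t_years, annual_rate: float):
    """Present-value multiplier ``(1 + rate)**(-t_years)``; 1 at t=0 or rate=0."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    t = np.asarray(t_years, dtype=float)
    out = np.power(1.0 + annual_rate, -t)
    return float(out) if np.isscalar(t_years) or t.ndim == 0 else out


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy of one subcohort over the model horizon.

    Row ``k`` is the state of the cohort at the *start* of cycle ``k``;
    ``new_deaths[k]`` is the fraction dying during cycle ``k-1`` (0 at k=0),
    i.e. deaths are recorded on arrival.  There are ``n_cycles`` transition
    intervals and ``n_cycles + 1`` rows.
    """

    cycle: np.ndarray        # int, 0..n
    time_years: np.ndarray
    pfs: np.ndarray
    progressed: np.ndarray
    dead: np.ndarray
    new_deaths: np.ndarray
    new_progressions: np.ndarray   # fraction progressing during cycle k-1
    discount: np.ndarray

    def __post_init__(self) -> None:
        total = self.pfs + self.progressed + self.dead
        if np.any(np.abs(total - 1.0) > _OCC_TOL):
            raise ValueError("state occupancy must sum to 1 every cycle")
        if np.any(np.diff(self.dead) < -_OCC_TOL):
            raise ValueError("dead fraction must be non-decreasing")
        if np.any(np.diff(self.pfs) > _OCC_TOL):
            raise ValueError("progression-free fraction must be non-increasing")

    @property
    def n_cycles(self) -> int:
        return len(self.cycle) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": self.cycle, "time_years": self.time_years,
            "pfs": self.pfs, "progressed": self.progressed, "dead": self.dead,
            "new_deaths": self.new_deaths, "discount": self.discount,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class AccrualResult:
    """Discounted and undiscounted totals for one (sub)cohort of weight 1."""

    cost: float
    qalys: float
    pf_ly: float
    overall_ly: float
    undiscounted_cost: float
    undiscounted_qalys: float
    undiscounted_pf_ly: float
    undiscounted_overall_ly: float

    def __post_init__(self) -> None:
        if self.pf_ly > self.overall_ly + 1e-12:
            raise ValueError("progression-free LYs cannot exceed overall LYs")

    def scaled(self, w: float) -> "AccrualResult":
        return AccrualResult(*(w * getattr(self, f) for f in (
            "cost", "qalys", "pf_ly", "overall_ly",
            "undiscounted_cost", "undiscounted_qalys",
            "undiscounted_pf_ly", "undiscounted_overall_ly")))

    def plus(self, other: "AccrualResult") -> "AccrualResult":
        return AccrualResult(*(getattr(self, f) + getattr(other, f) for f in (
            "cost", "qalys", "pf_ly", "overall_ly",
            "undiscounted_cost", "undiscounted_qalys",
            "undiscounted_pf_ly", "undiscounted_overall_ly")))


def _units_per_cycle(curve: WeibullCurve, settings: RunSettings) -> float:
    """One model cycle expressed in the curve's own time unit."""
    if curve.time_unit == "cycle":
        return 1.0
    if curve.time_unit == "month":
        return settings.cycle_days / settings.days_per_month
    return settings.cycle_days / curve.days_per_unit(settings.cycle_days)


def run_trace(curve: WeibullCurve, p_death_progressed: float,
              settings: RunSettings, annual_discount: float = 0.0
              ) -> CohortTrace:
    """Run the Markov chain for one subcohort governed by ``curve``.

    Within a cycle, progression and death-from-PD are applied to the cycle's
    starting occupancy; a patient who progresses during a cycle is first at
    risk of death in the next one.
    """
    if not (0.0 <= p_death_progressed <= 1.0):
        raise ValueError("p_death_progressed must lie in [0, 1]")
    n = settings.n_cycles
    if n < 1:
        raise ValueError("horizon must span at least one cycle")
    upc = _units_per_cycle(curve, settings)

    pfs = np.empty(n + 1)
    pd_ = np.empty(n + 1)
    dead = np.empty(n + 1)
    new_deaths = np.zeros(n + 1)
    new_prog = np.zeros(n + 1)
    pfs[0], pd_[0], dead[0] = 1.0, 0.0, 0.0

    for k in range(n):
        p_prog = per_cycle_transition_prob(curve, k, upc)
        progressing = pfs[k] * p_prog
        dying = pd_[k] * p_death_progressed
        pfs[k + 1] = pfs[k] - progressing
        pd_[k + 1] = pd_[k] + progressing - dying
        dead[k + 1] = dead[k] + dying
        new_prog[k + 1] = progressing
        new_deaths[k + 1] = dying

    cycles = np.arange(n + 1)
    t_years = cycles * settings.cycle_years
    return CohortTrace(
        cycle=cycles, time_years=t_years,
        pfs=pfs, progressed=pd_, dead=dead,
        new_deaths=new_deaths, new_progressions=new_prog,
        discount=discount_factor(t_years, annual_discount),
    )


def _pd_by_state_age(trace: CohortTrace, p_death: float,
                     max_age: int) -> np.ndarray:
    """Fraction in PD at each cycle that entered within the last ``max_age``
    cycles (inclusive of the entry cycle).  Governs the salvage window."""
    n = trace.n_cycles
    young = np.zeros(n + 1)
    surv = (1.0 - p_death) ** np.arange(max_age)
    for k in range(n + 1):
        j_hi = min(max_age, k + 1)
        # entrants at cycles k-j+1 ... wait: entered at cycle k-j, aged j
        acc = 0.0
        for j in range(j_hi):
            acc += trace.new_progressions[k - j] * surv[j]
        young[k] = acc
    return young


def _crizotinib_paid_days_per_cycle(settings: RunSettings) -> np.ndarray:
    """Days of crizotinib billed to the payer in each cycle on drug."""
    n = settings.n_cycles
    cd = settings.cycle_days
    if not settings.pap.enabled:
        return np.full(n, cd)
    start = np.arange(n) * cd
    return np.clip(settings.pap.paid_days - start, 0.0, cd)


def pemetrexed_cycle_cost(price_per_500mg: float, bsa: float,
                          whole_vials: bool = True) -> float:
    """Pemetrexed drug cost per cycle at 500 mg/m^2 dosing.

    Billed per whole 500-mg vial by default (hospital charging convention);
    ``whole_vials=False`` bills the exact milligram dose pro rata.
    """
    dose_mg = 500.0 * bsa
    if whole_vials:
        return math.ceil(dose_mg / 500.0) * price_per_500mg
    return dose_mg / 500.0 * price_per_500mg


def accrue(trace: CohortTrace, treatment: str, bundle: ParameterBundle
           ) -> AccrualResult:
    """Price a trace under the bundle's costs/utilities and discount rate.

    ``treatment`` is 'chemo' or 'crizotinib' and controls progression-free
    drug costs only; progressed-state and terminal costs are
    treatment-independent.
    """
    if treatment not in ("chemo", "crizotinib"):
        raise ValueError(f"unknown treatment {treatment!r}")
    settings = bundle.run
    n = trace.n_cycles
    cyr = settings.cycle_years
    rate = bundle.discount

    # occupancy during interval k = occupancy at its start (rows 0..n-1);
    # optional half-cycle correction averages start and end occupancy.
    if settings.half_cycle_correction:
        pfs_occ = 0.5 * (trace.pfs[:-1] + trace.pfs[1:])
        pd_occ = 0.5 * (trace.progressed[:-1] + trace.progressed[1:])
    else:
        pfs_occ = trace.pfs[:-1]
        pd_occ = trace.progressed[:-1]

    t = trace.time_years[:-1]
    disc = discount_factor(t, rate)
    # transition events land at the *end* of their interval
    disc_end = discount_factor(trace.time_years[1:], rate)

    k = np.arange(n)

    # ---- progression-free costs -------------------------------------------
    followup = bundle["followup_per_cycle"] * pfs_occ
    if treatment == "chemo":
        pem = pemetrexed_cycle_cost(
            bundle["pemetrexed_per_500mg"], bundle["body_surface_area"],
            settings.pemetrexed_whole_vials)
        chemo_cycle = (pem + bundle["chemo_other_per_cycle"]
                       + bundle["sae_initial_chemo_per_cycle"])
        drug = np.where(k < settings.chemo_max_cycles, chemo_cycle, 0.0) * pfs_occ
    else:
        paid_days = _crizotinib_paid_days_per_cycle(settings)
        drug = bundle["crizotinib_per_day"] * paid_days * pfs_occ

    # ---- progressed-state costs -------------------------------------------
    p_death = bundle["p_death_progressed_per_cycle"]
    uptake = bundle["salvage_uptake"]
    young = _pd_by_state_age(trace, p_death, settings.salvage_max_cycles)
    if settings.half_cycle_correction:
        young_occ = 0.5 * (young[:-1] + young[1:])
    else:
        young_occ = young[:-1]
    young_occ = np.minimum(young_occ, pd_occ)
    old_occ = pd_occ - young_occ
    pd_cost = (uptake * (bundle["salvage_per_cycle"] * young_occ
                         + bundle["supportive_per_cycle"] * old_occ)
               + (1.0 - uptake) * bundle["supportive_per_cycle"] * pd_occ)

    # ---- terminal cost -----------------------------------------------------
    terminal = bundle["palliative_terminal"] * trace.new_deaths[1:]

    cost_stream = followup + drug + pd_cost
    cost = float(np.sum(cost_stream * disc) + np.sum(terminal * disc_end))
    cost_undisc = float(np.sum(cost_stream) + np.sum(terminal))

    # ---- effects -----------------------------------------------------------
    u_pfs, u_pd = bundle["u_pfs"], bundle["u_progressed"]
    sae_du = bundle["sae_disutility_per_chemo_cycle"]
    utility = u_pfs * pfs_occ + u_pd * pd_occ
    if treatment == "chemo" and sae_du > 0.0:
        utility = utility - sae_du * np.where(
            k < settings.chemo_max_cycles, pfs_occ, 0.0)
    qalys = float(np.sum(utility * disc) * cyr)
    qalys_undisc = float(np.sum(utility) * cyr)
    pf_ly = float(np.sum(pfs_occ * disc) * cyr)
    pf_ly_undisc = float(np.sum(pfs_occ) * cyr)
    overall_ly = float(np.sum((pfs_occ + pd_occ) * disc) * cyr)
    overall_ly_undisc = float(np.sum(pfs_occ + pd_occ) * cyr)

    return AccrualResult(
        cost=cost, qalys=qalys, pf_ly=pf_ly, overall_ly=overall_ly,
        undiscounted_cost=cost_undisc, undiscounted_qalys=qalys_undisc,
        undiscounted_pf_ly=pf_ly_undisc,
        undiscounted_overall_ly=overall_ly_undisc,
    )


def evaluate_subcohort(sub: Subcohort, bundle: ParameterBundle
                       ) -> AccrualResult:
    """Trace + accrual for one decision-tree branch (unit weight)."""
    curve = curve_for_role(sub.pfs_curve_role, bundle)
    trace = run_trace(curve, bundle["p_death_progressed_per_cycle"],
                      bundle.run, bundle.discount)
    return accrue(trace, sub.treatment, bundle)
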