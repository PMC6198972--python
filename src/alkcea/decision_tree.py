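"""Test-and-treat decision tree.

A strategy is either the untested control (everyone receives chemotherapy)
or a test-guided arm: patients are screened for ALK rearrangement and
test-positives receive crizotinib while test-negatives receive standard
chemotherapy.  With prevalence p, sensitivity se and specificity sp the arm
splits into four subcohorts:

    true positive   p * se          crizotinib, crizotinib PFS curve
    false negative  p * (1 - se)    chemotherapy, chemotherapy PFS curve
    true negative   (1 - p) * sp    chemotherapy, chemotherapy PFS curve
    false positive  (1 - p) * (1 - se... sp)  crizotinib, *supportive-care* PFS

False positives are ALK-negative patients treated with crizotinib: they pay
for the drug but, lacking the target, their progression-free survival is
taken to equal that of supportive care — the chemotherapy curve worsened by
the inverse of the chemotherapy-vs-supportive-care hazard ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .parameters import PapPolicy, ParameterBundle, TestCharacteristics
from .survival import WeibullCurve

__all__ = ["StrategySpec", "Subcohort", "expand_strategy",
           "supportive_pfs_curve", "STRATEGY_NAMES"]

STRATEGY_NAMES = ("control", "ngs", "pcr")

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class StrategySpec:
    """One arm of the comparison: a test (or none) plus drug-pricing policy."""

    name: str
    test: TestCharacteristics
    pap: PapPolicy

    def __post_init__(self) -> None:
        if self.name == "control" and self.test.name != "none":
            raise ValueError("the control strategy carries no test")

    @classmethod
    def from_bundle(cls, name: str, bundle: ParameterBundle) -> "StrategySpec":
        if name not in STRATEGY_NAMES:
            raise KeyError(f"strategy must be one of {STRATEGY_NAMES}, got {name!r}")
        test = bundle.test("none" if name == "control" else name)
        return cls(name=name, test=test, pap=bundle.run.pap)


@dataclass(frozen=True)
class Subcohort:
    """A weighted branch of the decision tree.

    ``treatment`` decides what the patient is given (and billed for);
    ``pfs_curve_role`` decides which survival curve governs progression.
    The two differ only for false positives, who take crizotinib but follow
    the supportive-care curve.
    """

    label: str          # TP | FP | TN | FN | untested
    weight: float
    treatment: str      # crizotinib | chemo
    pfs_curve_role: str  # crizotinib | chemo | supportive

    def __post_init__(self) -> None:
        if self.label not in ("TP", "FP", "TN", "FN", "untested"):
            raise ValueError(f"unknown subcohort label {self.label!r}")
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"subcohort weight must lie in [0, 1], got {self.weight}")
        if self.treatment not in ("crizotinib", "chemo"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.pfs_curve_role not in ("crizotinib", "chemo", "supportive"):
            raise ValueError(f"unknown curve role {self.pfs_curve_role!r}")


def expand_strategy(spec: StrategySpec, prevalence: float
                    ) -> tuple[list[Subcohort], float]:
    """Expand a strategy into subcohorts and the per-patient upfront test cost.

    Control returns a single untested chemotherapy subcohort of weight 1 and
    zero test cost.  Weights always sum to 1.  Zero-weight branches are kept
    (they cost nothing to run and keep report shapes stable).
    """
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError("prevalence must lie in [0, 1]")
    if spec.test.name == "none":
        return ([Subcohort("untested", 1.0, "chemo", "chemo")], 0.0)

    se, sp = spec.test.sensitivity, spec.test.specificity
    subcohorts = [
        Subcohort("TP", prevalence * se, "crizotinib", "crizotinib"),
        Subcohort("FN", prevalence * (1.0 - se), "chemo", "chemo"),
        Subcohort("TN", (1.0 - prevalence) * sp, "chemo", "chemo"),
        Subcohort("FP", (1.0 - prevalence) * (1.0 - sp), "crizotinib", "supportive"),
    ]
    total = sum(s.weight for s in subcohorts)
    assert abs(total - 1.0) < _WEIGHT_TOL, f"weights sum to {total}"
    return subcohorts, spec.test.cost_per_patient


def supportive_pfs_curve(chemo_curve: WeibullCurve,
                         hr_chemo_vs_supportive: float) -> WeibullCurve:
    """Supportive-care PFS implied by the chemotherapy curve and the
    chemotherapy-vs-supportive-care hazard ratio.

    Under proportional hazards ``S_supportive = S_chemo ** (1/hr)``, i.e. the
    Weibull scale is divided by the hazard ratio.  ``hr`` is expected in
    (0, 1] (chemotherapy beneficial); hr = 1 returns the curve unchanged.
    """
    if hr_chemo_vs_supportive <= 0:
        raise ValueError("hazard ratio must be > 0")
    if hr_chemo_vs_supportive > 1.0:
        import warnings

        warnings.warn(
            "hr_chemo_vs_supportive > 1 reverses the direction of benefit "
            "(supportive care would outlast chemotherapy)",
            stacklevel=2,
        )
    return replace(chemo_curve,
                   scale=chemo_curve.scale / hr_chemo_vs_supportive,
                   fit_r2=None)


def curve_for_role(role: str, bundle: ParameterBundle) -> WeibullCurve:
    """Resolve a subcohort's curve role against the bundle's fitted curves."""
    if role == "crizotinib":
        return bundle.pfs_crizotinib
    if role == "chemo":
        return bundle.pfs_chemo
    if role == "supportive":
        return supportive_pfs_curve(bundle.pfs_chemo,
                                    bundle["hr_chemo_vs_supportive"])
    raise ValueError(f"unknown curve role {role!r}")
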