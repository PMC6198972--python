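"""Model inputs: parameter specifications, defaults, config loading.

Every scalar input is carried as a :class:`ParameterSpec` holding its
base-case value, its deterministic-sensitivity range, and the distribution
family used for probabilistic sensitivity analysis (PSA).  A
:class:`ParameterBundle` is an immutable registry of those specs plus the two
progression-free-survival Weibull curves and the global run settings; model
code reads base values, and the sensitivity machinery produces *new* bundles
with overridden values rather than mutating anything.

Base-case values are the published Chinese cost-effectiveness inputs for
ALK-tested first-line crizotinib versus pemetrexed-cisplatin chemotherapy:
drug/test/care costs in 2016 US dollars, health-state utilities 0.804
(progression-free) and 0.321 (progressed), 5% annual discounting, a 10-year
horizon, and a willingness-to-pay threshold of $32,000 per QALY.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

from .survival import WeibullCurve

__all__ = [
    "ConfigError",
    "ValidationError",
    "ParameterSpec",
    "PapPolicy",
    "RunSettings",
    "TestCharacteristics",
    "ParameterBundle",
    "default_paper_parameters",
    "load_config",
    "loads_config",
    "serialize_bundle",
    "bsa_mosteller",
]

DISTRIBUTIONS = ("triangular", "beta", "fixed")


class ConfigError(ValueError):
    """A config document is missing or malformed."""


class ValidationError(ValueError):
    """A parameter value violates its declared constraints."""


@dataclass(frozen=True)
class ParameterSpec:
    """One scalar model input with its uncertainty description.

    ``low <= base <= high`` always; ``distribution='beta'`` additionally
    requires the range to sit inside [0, 1]; ``'fixed'`` means PSA draws
    always return the base value (the range, if any, is still available to
    one-way sensitivity analysis).
    """

    name: str
    base: float
    low: float | None = None
    high: float | None = None
    distribution: str = "fixed"
    units: str = ""

    def __post_init__(self) -> None:
        low = self.base if self.low is None else self.low
        high = self.base if self.high is None else self.high
        object.__setattr__(self, "low", float(low))
        object.__setattr__(self, "high", float(high))
        object.__setattr__(self, "base", float(self.base))
        if self.distribution not in DISTRIBUTIONS:
            raise ValidationError(
                f"{self.name}: unknown distribution {self.distribution!r} "
                f"(choose from {DISTRIBUTIONS})"
            )
        if not (self.low <= self.base <= self.high):
            raise ValidationError(
                f"{self.name}: require low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.distribution == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ValidationError(
                f"{self.name}: beta distribution needs range within [0, 1], "
                f"got ({self.low}, {self.high})"
            )

    @property
    def has_range(self) -> bool:
        return self.high > self.low

    def with_value(self, value: float) -> "ParameterSpec":
        """Copy with the base replaced (range widened if needed so the spec
        stays internally valid for sampled values)."""
        return replace(
            self,
            base=float(value),
            low=min(self.low, float(value)),
            high=max(self.high, float(value)),
        )


@dataclass(frozen=True)
class PapPolicy:
    """Crizotinib patient-assistance-program pricing.

    Modelled as: the payer funds the first ``paid_days`` days of crizotinib
    per patient, after which the manufacturer supplies the drug free of
    charge.  ``enabled=False`` charges full price for the whole time on drug.
    The default ``paid_days`` is calibrated (see :func:`alkcea.cea.calibrate`
    and docs/calibration.md) to reproduce the published with-program
    incremental cost-effectiveness of the NGS-guided strategy.
    """

    enabled: bool = True
    paid_days: int = 19

    def __post_init__(self) -> None:
        if self.paid_days < 0:
            raise ValidationError("paid_days must be >= 0")


@dataclass(frozen=True)
class RunSettings:
    """Global run conventions: horizon, cycle grid, discounting, pricing.

    The defaults are the package's calibrated conventions: 30-day (monthly)
    cycles and a 12-cycle salvage window, chosen by grid search against the
    published base-case table (docs/calibration.md) because the published
    progressed-state life-years are consistent with monthly cycles at the
    printed 0.086 per-cycle death probability, while the 21-day
    chemotherapy-administration cycle is what reproduces 0.086 from the
    5.4-month median in the first place.  Both remain configurable.
    """

    horizon_years: float = 10.0
    cycle_days: float = 30.0
    days_per_month: float = 30.0
    annual_discount: float = 0.05
    wtp_per_qaly: float = 32000.0
    pap: PapPolicy = field(default_factory=PapPolicy)
    chemo_max_cycles: int = 4
    salvage_max_cycles: int = 12
    half_cycle_correction: bool = False
    pemetrexed_whole_vials: bool = True

    def __post_init__(self) -> None:
        if self.horizon_years <= 0:
            raise ValidationError("horizon_years must be > 0")
        if self.cycle_days <= 0:
            raise ValidationError("cycle_days must be > 0")
        if not (0.0 <= self.annual_discount < 1.0):
            raise ValidationError("annual_discount must lie in [0, 1)")
        if self.wtp_per_qaly < 0:
            raise ValidationError("wtp_per_qaly must be >= 0")
        if self.chemo_max_cycles < 0 or self.salvage_max_cycles < 0:
            raise ValidationError("cycle caps must be >= 0")

    @property
    def n_cycles(self) -> int:
        """Transition cycles spanning the horizon (10 y, 21 d -> 174)."""
        return int(math.floor(self.horizon_years * 365.25 / self.cycle_days))

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25


@dataclass(frozen=True)
class TestCharacteristics:
    """A diagnostic test arm: accuracy plus per-patient cost.

    ``name='none'`` denotes the untested control strategy (zero cost, no
    branching).
    """

    name: str
    sensitivity: float = 1.0
    specificity: float = 1.0
    cost_per_patient: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValidationError(f"{self.name}: sensitivity must lie in [0, 1]")
        if not (0.0 <= self.specificity <= 1.0):
            raise ValidationError(f"{self.name}: specificity must lie in [0, 1]")
        if self.cost_per_patient < 0:
            raise ValidationError(f"{self.name}: test cost must be >= 0")
        if self.name == "none" and self.cost_per_patient != 0:
            raise ValidationError("the untested strategy cannot carry a test cost")


# ---------------------------------------------------------------------------
# the parameter registry
# ---------------------------------------------------------------------------

def _triangular(name, base, low, high, units=""):
    return ParameterSpec(name, base, low, high, "triangular", units)


def _beta(name, base, low, high, units=""):
    return ParameterSpec(name, base, low, high, "beta", units)


def _fixed(name, base, low=None, high=None, units=""):
    return ParameterSpec(name, base, low, high, "fixed", units)


def _default_specs() -> dict[str, ParameterSpec]:
    """The published base-case inputs, transcribed field for field.

    Notes on PSA families: costs are triangular (mode at base) except the
    crizotinib daily price, which is held fixed and explored through the
    assistance-program scenarios and the half-price one-way case;
    probabilities, proportions and utilities are beta; test sensitivity and
    specificity have base 1, which admits no proper beta, so sampling falls
    back to uniform on the printed range.  The hazard ratio and body-surface
    area are bounded physical quantities sampled triangularly.  The discount
    rate is fixed in PSA but carries a 0-8% one-way range.
    """
    specs = [
        # -- key clinical data ------------------------------------------------
        _triangular("hr_chemo_vs_supportive", 0.77, 0.71, 0.83,
                    "hazard ratio, chemotherapy vs supportive care"),
        _beta("p_death_progressed_per_cycle", 0.086, 0.08, 0.093,
              "probability per cycle"),
        _beta("alk_prevalence", 0.065, 0.014, 0.116, "proportion"),
        _triangular("body_surface_area", 1.72, 1.5, 1.9, "m^2"),
        _beta("salvage_uptake", 0.566, 0.26, 0.72, "proportion"),
        _fixed("post_progression_median_os", 5.4, units="months"),
        # -- test characteristics (uniform fallback in PSA: base at bound) ---
        _beta("ngs_sensitivity", 1.0, 0.95, 1.0, "probability"),
        _beta("ngs_specificity", 1.0, 0.95, 1.0, "probability"),
        _beta("pcr_sensitivity", 1.0, 0.95, 1.0, "probability"),
        _beta("pcr_specificity", 1.0, 0.95, 1.0, "probability"),
        # -- costs, 2016 USD --------------------------------------------------
        _triangular("pemetrexed_per_500mg", 2083.97, 857.14, 2126.51, "USD/500 mg"),
        _triangular("chemo_other_per_cycle", 518.4, 388.8, 648.0, "USD/cycle"),
        _fixed("crizotinib_per_day", 238.1, 119.05, 238.1, "USD/day"),
        _triangular("followup_per_cycle", 55.6, 41.7, 69.4, "USD/cycle"),
        _triangular("salvage_per_cycle", 2352.7, 1921.1, 4383.3, "USD/cycle"),
        _triangular("palliative_terminal", 2042.91, 793.65, 5456.19, "USD, one-off"),
        _triangular("supportive_per_cycle", 337.5, 158.7, 793.7, "USD/cycle"),
        _triangular("sae_initial_chemo_per_cycle", 507.4, 189.7, 825.0, "USD/cycle"),
        _triangular("ngs_test_cost", 1014.49, 869.57, 1159.42, "USD/patient"),
        _triangular("pcr_test_cost", 660.75, 440.50, 881.01, "USD/patient"),
        # -- utilities (+/-25% of the mean, upper end capped at 1) ------------
        _beta("u_pfs", 0.804, 0.603, 1.0, "utility"),
        _beta("u_progressed", 0.321, 0.24075, 0.40125, "utility"),
        _fixed("sae_disutility_per_chemo_cycle", 0.0, 0.0, 0.0, "utility decrement"),
        # -- run-level scalars ------------------------------------------------
        _fixed("annual_discount", 0.05, 0.0, 0.08, "per year"),
    ]
    return {s.name: s for s in specs}


#: Parameters excluded from the one-way tornado even though a range exists:
#: the discount range is an assumption, not a published interval.
_CURVE_PARAM_NAMES = ("crizotinib_scale", "crizotinib_shape",
                      "chemo_scale", "chemo_shape")


@dataclass(frozen=True)
class ParameterBundle:
    """Immutable bundle of every model input for one run.

    ``specs`` maps parameter name to :class:`ParameterSpec`;
    ``pfs_crizotinib`` / ``pfs_chemo`` are the fitted Weibull PFS curves
    (each with its own time unit); ``run`` holds the global settings.
    """

    specs: Mapping[str, ParameterSpec]
    pfs_crizotinib: WeibullCurve
    pfs_chemo: WeibullCurve
    run: RunSettings

    def __post_init__(self) -> None:
        object.__setattr__(self, "specs", dict(self.specs))
        u_pfs = self["u_pfs"]
        u_pd = self["u_progressed"]
        if not (0.0 <= u_pd <= u_pfs <= 1.0):
            raise ValidationError(
                f"utilities must satisfy 0 <= u_progressed <= u_pfs <= 1, "
                f"got ({u_pd}, {u_pfs})"
            )

    def __getitem__(self, name: str) -> float:
        try:
            return self.specs[name].base
        except KeyError:
            raise KeyError(
                f"unknown parameter {name!r}; valid names: {sorted(self.specs)}"
            ) from None

    def spec(self, name: str) -> ParameterSpec:
        try:
            return self.specs[name]
        except KeyError:
            raise KeyError(
                f"unknown parameter {name!r}; valid names: {sorted(self.specs)}"
            ) from None

    def with_values(self, values: Mapping[str, float]) -> "ParameterBundle":
        """New bundle with the named base values replaced (ranges kept)."""
        new = dict(self.specs)
        for name, value in values.items():
            if name not in new:
                raise KeyError(
                    f"unknown parameter {name!r}; valid names: {sorted(new)}"
                )
            new[name] = new[name].with_value(value)
        return replace(self, specs=new)

    def with_run(self, **kwargs) -> "ParameterBundle":
        """New bundle with run settings replaced (e.g. pap=..., cycle_days=...)."""
        return replace(self, run=replace(self.run, **kwargs))

    @property
    def discount(self) -> float:
        return self["annual_discount"]

    def test(self, name: str) -> TestCharacteristics:
        """Test characteristics for strategy ``name`` ('ngs'|'pcr'|'none')."""
        if name == "none":
            return TestCharacteristics("none")
        if name not in ("ngs", "pcr"):
            raise KeyError("test name must be 'ngs', 'pcr' or 'none'")
        return TestCharacteristics(
            name=name,
            sensitivity=self[f"{name}_sensitivity"],
            specificity=self[f"{name}_specificity"],
            cost_per_patient=self[f"{name}_test_cost"],
        )

    def ranged_parameter_names(self, include_assumed: bool = False) -> list[str]:
        """Parameters eligible for one-way sensitivity analysis.

        ``include_assumed`` adds ranges that are modelling assumptions rather
        than published intervals (currently the discount rate).
        """
        assumed = () if include_assumed else ("annual_discount",)
        return [
            n for n, s in self.specs.items()
            if s.has_range and n not in assumed
        ]


def default_paper_parameters(pap_enabled: bool = True) -> ParameterBundle:
    """The full published base case.

    PFS curves: crizotinib Weibull(scale 0.0211, shape 1.5326, r^2 0.972) and
    pemetrexed-cisplatin Weibull(scale 0.0663, shape 0.8604, r^2 0.991).  The
    two printed parameter pairs are mutually inconsistent under any single
    time unit (they would give chemotherapy the longer median PFS), so each
    curve carries its own calibrated unit: months for crizotinib (median
    9.8 months, matching the source trial) and weeks for chemotherapy.
    """
    return ParameterBundle(
        specs=_default_specs(),
        pfs_crizotinib=WeibullCurve(0.0211, 1.5326, time_unit="month", fit_r2=0.972),
        pfs_chemo=WeibullCurve(0.0663, 0.8604, time_unit="week", fit_r2=0.991),
        run=RunSettings(pap=PapPolicy(enabled=pap_enabled)),
    )


def bsa_mosteller(weight_kg: float, height_cm: float) -> float:
    """Mosteller body-surface area ``sqrt(weight * height / 3600)`` in m^2.

    The reference patient (65 kg, 164 cm) gives 1.72 m^2, the figure used to
    dose pemetrexed.
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be > 0")
    return math.sqrt(weight_kg * height_cm / 3600.0)


# ---------------------------------------------------------------------------
# config serialization
# ---------------------------------------------------------------------------

_SECTION_OF = {
    "hr_chemo_vs_supportive": "clinical",
    "p_death_progressed_per_cycle": "clinical",
    "alk_prevalence": "clinical",
    "body_surface_area": "clinical",
    "salvage_uptake": "clinical",
    "post_progression_median_os": "clinical",
    "ngs_sensitivity": "tests", "ngs_specificity": "tests",
    "pcr_sensitivity": "tests", "pcr_specificity": "tests",
    "ngs_test_cost": "tests", "pcr_test_cost": "tests",
    "pemetrexed_per_500mg": "costs", "chemo_other_per_cycle": "costs",
    "crizotinib_per_day": "costs", "followup_per_cycle": "costs",
    "salvage_per_cycle": "costs", "palliative_terminal": "costs",
    "supportive_per_cycle": "costs", "sae_initial_chemo_per_cycle": "costs",
    "u_pfs": "utilities", "u_progressed": "utilities",
    "sae_disutility_per_chemo_cycle": "utilities",
    "annual_discount": "run",
}

_RUN_FIELDS = ("horizon_years", "cycle_days", "days_per_month",
               "wtp_per_qaly", "chemo_max_cycles", "salvage_max_cycles",
               "half_cycle_correction", "pemetrexed_whole_vials")


def serialize_bundle(bundle: ParameterBundle) -> str:
    """Render a bundle as the YAML config dialect `load_config` reads.

    Round-trip identity: ``loads_config(serialize_bundle(b)) == b``.
    """
    doc: dict = {"clinical": {}, "costs": {}, "utilities": {}, "tests": {},
                 "run": {}}
    for name, spec in bundle.specs.items():
        section = _SECTION_OF.get(name, "run")
        doc[section][name] = {
            "base": spec.base, "low": spec.low, "high": spec.high,
            "distribution": spec.distribution,
        }
        if spec.units:
            doc[section][name]["units"] = spec.units
    for role, curve in (("crizotinib", bundle.pfs_crizotinib),
                        ("chemo", bundle.pfs_chemo)):
        entry = {"scale": curve.scale, "shape": curve.shape,
                 "time_unit": curve.time_unit}
        if curve.fit_r2 is not None:
            entry["fit_r2"] = curve.fit_r2
        doc["clinical"][f"pfs_{role}"] = entry
    run = bundle.run
    for f in _RUN_FIELDS:
        doc["run"][f] = getattr(run, f)
    doc["run"]["pap"] = {"enabled": run.pap.enabled, "paid_days": run.pap.paid_days}
    return yaml.safe_dump(doc, sort_keys=True)


def loads_config(text: str) -> ParameterBundle:
    """Parse a YAML config string into a validated bundle (see load_config)."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config is not valid YAML: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping of sections")

    known_sections = {"clinical", "costs", "utilities", "tests", "run"}
    unknown = set(doc) - known_sections
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")

    defaults = default_paper_parameters()
    specs = dict(defaults.specs)
    curves = {"crizotinib": defaults.pfs_crizotinib, "chemo": defaults.pfs_chemo}
    run_kwargs: dict = {}
    pap_kwargs: dict = {}

    for section, entries in doc.items():
        if entries is None:
            continue
        if not isinstance(entries, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key, value in entries.items():
            if section == "clinical" and key in ("pfs_crizotinib", "pfs_chemo"):
                role = key.removeprefix("pfs_")
                if not isinstance(value, dict) or not {"scale", "shape"} <= set(value):
                    raise ConfigError(f"{key}: need 'scale' and 'shape' fields")
                curves[role] = WeibullCurve(
                    scale=float(value["scale"]), shape=float(value["shape"]),
                    time_unit=value.get("time_unit", curves[role].time_unit),
                    fit_r2=value.get("fit_r2"),
                )
            elif section == "run" and key == "pap":
                if not isinstance(value, dict):
                    raise ConfigError("run.pap must be a mapping")
                pap_kwargs = {k: value[k] for k in ("enabled", "paid_days")
                              if k in value}
                extra = set(value) - {"enabled", "paid_days"}
                if extra:
                    raise ConfigError(f"run.pap: unknown fields {sorted(extra)}")
            elif section == "run" and key in _RUN_FIELDS:
                run_kwargs[key] = value
            elif key in specs:
                expected = _SECTION_OF.get(key)
                if expected is not None and expected != section:
                    raise ConfigError(
                        f"parameter {key!r} belongs in section {expected!r}, "
                        f"found in {section!r}"
                    )
                old = specs[key]
                if isinstance(value, dict):
                    extra = set(value) - {"base", "low", "high",
                                          "distribution", "units"}
                    if extra:
                        raise ConfigError(
                            f"{key}: unknown fields {sorted(extra)}")
                    if "base" not in value:
                        raise ConfigError(f"{key}: missing required field 'base'")
                    specs[key] = ParameterSpec(
                        name=key,
                        base=float(value["base"]),
                        low=value.get("low"),
                        high=value.get("high"),
                        distribution=value.get("distribution", old.distribution),
                        units=value.get("units", old.units),
                    )
                else:  # bare scalar: override base, collapse the range
                    specs[key] = ParameterSpec(
                        key, float(value), distribution="fixed", units=old.units)
            else:
                raise ConfigError(
                    f"unknown key {key!r} in section {section!r}")

    if pap_kwargs:
        run_kwargs["pap"] = PapPolicy(**pap_kwargs)
    run = replace(defaults.run, **run_kwargs) if run_kwargs else defaults.run
    return ParameterBundle(
        specs=specs,
        pfs_crizotinib=curves["crizotinib"],
        pfs_chemo=curves["chemo"],
        run=run,
    )


def load_config(path) -> ParameterBundle:
    """Load and validate a YAML config file.

    Any field omitted falls back to the built-in published base case, so the
    empty document reproduces :func:`default_paper_parameters` exactly.
    Range violations and unknown keys raise :class:`ConfigError` /
    :class:`ValidationError` naming the offending field.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    return loads_config(text)
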