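# Methods

## The decision problem

Advanced (stage IIIB/IV) non-small-cell lung cancer patients in China can be
screened for ALK rearrangement before first-line therapy. Test-positive
patients receive crizotinib, an oral ALK inhibitor, until progression;
test-negative (and untested control) patients receive pemetrexed–cisplatin
chemotherapy. The package asks, from the healthcare-system perspective:
what do the two screening routes (an NGS panel at $1,014.49/patient, a
multiplex PCR assay at $660.75/patient) buy, per quality-adjusted life-year,
relative to chemotherapy for all — and how does the answer depend on the
manufacturer's patient assistance program (PAP) that caps crizotinib
spending?

## Model structure

A decision tree expands each strategy into subcohorts by test outcome.
With prevalence *p*, sensitivity *se*, specificity *sp*:

| branch | weight | drug | PFS curve |
|---|---|---|---|
| true positive | p·se | crizotinib | crizotinib Weibull |
| false negative | p·(1−se) | chemotherapy | chemotherapy Weibull |
| true negative | (1−p)·sp | chemotherapy | chemotherapy Weibull |
| false positive | (1−p)·(1−sp) | crizotinib | supportive care |

False positives lack the drug target: they pay for crizotinib but their
progression follows the supportive-care curve, obtained from the
chemotherapy curve via the proportional-hazards transform S^(1/HR) with
HR = 0.77 (chemotherapy vs supportive care). That HR is an overall-survival
ratio in its source; re-using it as a PFS factor is the only quantitative
link the inputs provide and is flagged as an assumption.

Each subcohort then runs through a three-state Markov cohort
(progression-free → progressed → dead, no recovery, no direct
progression-free → death shortcut) over a 10-year horizon. The
progression-free → progressed probability for cycle *k* is
1 − S(t_{k+1})/S(t_k) on the treatment's Weibull curve
S(t) = exp(−λ t^γ), so the trace reproduces the fitted curve exactly
(telescoping identity, property-tested). The progressed → dead probability
is constant at 0.086 per cycle, the exponential equivalent of the
5.4-month median post-progression survival. Transitions act on
start-of-cycle occupancy; patients progressing in a cycle are first at risk
of death in the next one.

## Accrual

Costs (2016 USD, undiscounted list):

* progression-free on chemotherapy — pemetrexed 500 mg/m² at BSA 1.72 m²
  (Mosteller, 65 kg/164 cm), billed per whole 500-mg vial (2 vials ×
  $2,083.97; Chinese hospital charging convention, pro-rata billing
  available by config) + $518.40 other chemotherapy drugs + $507.40
  severe-adverse-event management, all for the first 4 cycles only;
  $55.60 follow-up every progression-free cycle;
* progression-free on crizotinib — $238.10/day on drug; under the PAP the
  payer funds only the first `paid_days` (calibrated default 19) days,
  free supply thereafter; follow-up as above;
* progressed — 56.6% of patients receive salvage chemotherapy
  ($2,352.70/cycle) for their first `salvage_max_cycles` (calibrated
  default 12) cycles in the state, then supportive care; the rest receive
  supportive care ($337.50/cycle) throughout — implemented with a state-age
  (tunnel) decomposition of progressed occupancy;
* dying — a one-off $2,042.91 terminal palliative cost attached to the
  death transition.

Effects: utilities 0.804 (progression-free) and 0.321 (progressed) weight
state residence into QALYs; adverse-event disutilities during initial
chemotherapy are configurable decrements defaulting to zero because their
source publishes them only graphically. Every stream is discounted at
(1.05)^(−t) with t in years from model start; test costs are charged
undiscounted at t = 0. Optional half-cycle correction (off by default, as
nothing in the source indicates it) averages start- and end-of-cycle
occupancy.

## Incremental statistics and sensitivity analysis

ICER = ΔC/ΔE versus the control strategy, with dominance short-circuits;
NMB = E·WTP − C at WTP $32,000/QALY. One-way analysis re-evaluates the ICER
at each end of every published parameter range (tornado, sorted by span);
the Weibull parameters have no published ranges and are excluded by
default, and the discount rate's 0–8% range is an assumption joined on
request. The PSA (default 1,000 draws, seed 20161023) samples triangular
distributions (mode at base) for ranged costs, and method-of-moments beta
distributions (mean at base, sd = range/4, reading the published range as
an approximate 95% interval) for probabilities, proportions and utilities.
Test sensitivity/specificity (base 1.0) admit no proper beta with mean on
the bound, so they fall back to uniform on [0.95, 1], logged. The
crizotinib daily price is fixed in the PSA (its uncertainty is explored via
the PAP scenarios and the half-price one-way case), as is the discount
rate. The HR and body-surface area, which are neither costs nor
probabilities, are sampled triangularly. All strategies are evaluated on
common random parameter draws, so comparisons are paired; CEACs report the
fraction of draws with positive incremental NMB.

## Weibull fitting from digitized curves

`fit_weibull` linearizes S(t) = exp(−λ t^γ) to
ln(−ln S) = γ ln t + ln λ and fits a *weighted* least-squares line with
weights (ln S)²: by the delta method, multiplicative digitization noise of
fixed relative size inflates the transformed ordinate's variance by
1/(ln S)², and unweighted regression lets near-1 early points dominate
(tripling the median scale error at realistic noise). The reported r² is
the weighted coefficient of determination, matching the regression
diagnostic published alongside the curve parameters. Points with S ∈ {0, 1}
are excluded (transform undefined) and fewer than three usable points are
an error.

## Synthetic data

`generate_km_points` emulates curve digitization: exact Weibull survival
times a log-normal multiplicative perturbation (keeps S > 0; digitization
error scales with curve height), clipped to (0, 1] and forced non-increasing
by a running minimum. Default test conditions use 30 evenly spaced points
and noise sd 0.02. `generate_parameter_bundle` draws every ranged parameter
uniformly within its published range (re-drawing the progressed utility
below the sampled progression-free utility when independent draws cross),
yielding valid bundles for pipeline fuzzing. What these generators do *not*
emulate: censoring, risk-set granularity, correlated digitization errors
along a curve, or joint parameter correlation — so passing tests certify
the arithmetic and its invariants, not robustness to real digitization
artefacts.

## Calibrated conventions

Four conventions the source leaves open (per-curve time units, cycle
length, salvage duration, PAP payment window) are fixed by the committed
grid-search calibration described in [calibration.md](calibration.md):
crizotinib curve in months, chemotherapy curve in weeks, 30-day cycles
(121 over the horizon), 12 salvage cycles, 19 paid crizotinib days. All
remain configurable, and `cea.calibrate` re-scores any grid against any
targets.

## Numerical choices

* Per-cycle probabilities are computed on the cumulative-hazard scale with
  `expm1`, keeping them exact in [0, 1) for extreme parameters.
* Occupancy conservation is enforced at 1e−9; subcohort weights at 1e−12.
* Internal arithmetic is unrounded; display rounding (whole dollars, 3-dp
  life-years) happens only in reports.
* The horizon spans floor(horizon_years × 365.25 / cycle_days) transition
  cycles; state membership for accrual is start-of-cycle occupancy, and
  transition events (terminal costs) are discounted at their end-of-cycle
  time.
* Degenerate inputs: zero ranges are point masses in both DSA and PSA;
  prevalence 0 or 1 collapse the tree; `hr > 1` warns (benefit direction
  reversed) rather than failing.

## Known limitations

* The printed crizotinib Weibull curve caps the achievable incremental
  QALYs of a test-and-treat strategy near 0.021 per tested patient, about
  half the published 0.040; the published PCR ICER, no-PAP ICER and PSA
  acceptance proportion are unreachable under any convention this package
  exposes (quantified in calibration.md). The corresponding acceptance
  tests are left failing by design rather than loosened.
* One chemotherapy PFS curve serves ALK-positive and ALK-negative patients
  alike (only one is published).
* No background all-cause mortality, no treatment waning, no individual
  (microsimulation) mode, no correlated PSA sampling, no value-of-
  information analysis, no currency/inflation adjustment.
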