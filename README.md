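# alkcea

Cost-effectiveness of ALK-rearrangement testing followed by first-line
crizotinib versus standard chemotherapy for advanced non-small-cell lung
cancer in China — a tested, configurable decision-tree + Markov cohort
model with deterministic and probabilistic sensitivity analysis.

**Who it is for:** health-economics analysts who want the published Chinese
base case reproducible end-to-end, and modellers who want its machinery —
Weibull survival extrapolation, test-and-treat decision trees, three-state
cohort simulation, tornado/PSA/CEAC — as a library with every assumption a
config value.

## The model

A screening test (NGS panel, $1,014.49/patient, or multiplex PCR,
$660.75/patient; both with sensitivity = specificity = 1, range 0.95–1)
splits a cohort with ALK prevalence 0.065 into subcohorts: test-positives
receive crizotinib ($238.10/day until progression, optionally capped by a
patient assistance program), test-negatives and the untested control
receive pemetrexed–cisplatin (4 × 21-day cycles, dosed at BSA 1.72 m²).
Each subcohort runs a three-state Markov cohort — progression-free (PFS),
progressed, dead — for 10 years:

* PFS → progressed follows the treatment's Weibull curve
  S(t) = exp(−λ t^γ): crizotinib (λ = 0.0211, γ = 1.5326), chemotherapy
  (λ = 0.0663, γ = 0.8604); false positives follow the supportive-care
  curve S^(1/0.77).
* progressed → dead is 0.086 per cycle (5.4-month median post-progression
  survival); salvage chemotherapy reaches 56.6% of progressed patients.

QALYs weight state time by utilities 0.804 (PFS) and 0.321 (progressed);
costs and QALYs are discounted at 5%/year. Strategies are compared by
ICER = ΔC/ΔE and net monetary benefit at a willingness-to-pay of
$32,000/QALY. Because the source leaves several conventions open (and its
printed inputs are not fully self-consistent), the shipped defaults are
fixed by a committed calibration — see `docs/calibration.md` and
`docs/methods.md`.

## Worked example

```bash
python examples/base_case.py
```

prints (abridged):

```
--- with PAP ---
strategy    cost  pf_ly  overall_ly  qalys  icer_vs_control
 control 29810.0  0.515       1.408  0.701              NaN
     ngs 30110.0  0.542       1.434  0.722          14112.0
     pcr 29756.0  0.542       1.434  0.722              NaN

--- without PAP ---
strategy    cost  pf_ly  overall_ly  qalys  icer_vs_control
 control 29810.0  0.515       1.408  0.701              NaN
     ngs 35069.0  0.542       1.434  0.722         247182.0
     pcr 34716.0  0.542       1.434  0.722         230558.0
```

Per patient tested: the control strategy costs $29,810 and yields 0.701
QALYs (0.515 progression-free life-years of 1.408 total). With the
assistance program, NGS-guided screening adds 0.021 QALYs at $14,112 per
QALY gained — cost-effective at the $32,000 threshold — while the cheaper
PCR assay is outright cost-saving (dominant, hence no ratio). Without the
program the incremental cost per QALY exceeds $200,000 and neither test
strategy is justifiable. Other capabilities, one script each, under
`examples/`: `tornado.py` (one-way sensitivity), `psa_ceac.py`
(probabilistic analysis + CEAC), `fit_weibull_km.py` (curve fitting from
digitized Kaplan–Meier points), `calibration_search.py` (convention
calibration).

The same analyses are available from the shell:

```bash
alkcea base-case --out runs/base      # Table-style CSV + manifest
alkcea dsa --strategy ngs --out runs/dsa
alkcea psa --n 1000 --seed 20161023 --out runs/psa
alkcea synth km --scale 0.0211 --shape 1.5326 --out runs/km.csv
alkcea fit-weibull --km runs/km.csv
```

All inputs live in a YAML config (`src/alkcea/data/paper_defaults.yaml` is
the fully commented published base case); every run writes a manifest with
the config hash and seeds.

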