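# Methods

## The decision problem

`lungcea` implements a decision-analytic Markov cohort model comparing two
configurations of a national adult lung-transplant service:

* **Standard service** — standard donor-lung transplants only.
* **EVLP service** — the same service plus ex-vivo lung perfusion (EVLP),
  a technique that reconditions donor lungs initially judged unusable.
  EVLP activity is modelled as a proportional *uplift* on the standard
  transplant probability (base case 10%): for every ten standard
  transplants in a cycle, one additional EVLP transplant is performed.

The cohort is 1000 adults entering the waiting list. States: *waiting
list*, *removed from the list* (too ill to transplant; absorbing),
*death* (absorbing), *transplant year 1* (standard or EVLP), and
*post-year-1 survival* (standard or EVLP). Cycle length is one year,
horizon is lifetime (the waiting list drains geometrically; a 60-cycle cap
with a residual-occupancy assertion enforces this), and both costs and
health outcomes are discounted at 3.5% per year with the first model year
undiscounted. Outcomes are discounted life-years and QALYs (SF-6D
utilities); costs are 2016/17 GBP from the UK NHS perspective.

Because EVLP transplants are an extra exit from the waiting list, the EVLP
service leaves fewer patients on the list each cycle: deterministic counts
per 1000 patients are 721 standard transplants in the standard service
versus 675 standard + 67.5 EVLP in the EVLP service. The cumulative
standard-transplant count has the closed form
`p1 + r1*p2 + r1*r2*p3/(1-r3)` (band transplant probabilities `pi`, remain
probabilities `ri`), which the engine reproduces to 1e-9 and the test
suite uses as an independent oracle.

## Survival extrapolation

Post-transplant survival enters without tunnel states. The published
survival points (1 y: 0.772, 3 y: 0.72, 5 y: 0.53, 10 y: 0.34) are joined
piecewise linearly with S(0)=1 and S(25)=0 (25 years taken as maximum
post-transplant life expectancy); the trapezoid area gives a mean
post-transplant survival of 8.353 years. The `survival` module also
exposes the decomposition into the year-1 area `0.5*(1+s1)` and the
conditional remainder `(AUC - 0.5*(1+s1))/s1` (9.672 years).

Interpolation is linear because it is the simplest curve consistent with
area-under-the-curve extrapolation and the stated endpoint; step-function
integration would lower the AUC by 0.5 years.

## Accrual convention

Printed tables pin the flows but not the within-cycle accounting, so the
accrual convention was treated as a calibration object: candidate
conventions (exit timing, transplant-bundle booking cycle, year-1
duration, post-year-1 survival allocation, waiting-list accrual basis)
were evaluated against all nine published base-case quantities (both
arms' mean cost, life-years and QALYs, plus the three increments), and
the following convention was frozen before any acceptance comparison:

1. **Waiting list.** Patients remaining listed through cycle *t* accrue a
   full year of waiting cost (£23,829/y at the point value), waiting
   utility (0.563) and one life-year at discount factor `(1+r)^-(t-1)`.
   Patients exiting during cycle *t* accrue half a year of waiting
   utility and life-years (they leave mid-cycle on average) and no
   waiting-list cost: the annual list-management cost is charged to
   patients listed for the full year, while the exit year's costs are
   carried by the transplant episode (or by death/removal, which accrue
   nothing).
2. **Transplant episode.** The surgery cost (standard £51,778; EVLP
   £137,527, which embeds the 53:18 assessment-to-transplant conversion
   ratio) is booked in the exit cycle. The recovery year occupies the
   following cycle: year-1 post-transplant cost, a full year at the
   year-1 utility (0.702) and one life-year — standard cohort-Markov
   accrual with no half-cycle correction.
3. **Post year 1.** The fraction s1 surviving the recovery year is
   credited the mean post-transplant survival (the full 8.353-year AUC)
   as additional years: the 2-years-onwards utility (0.734) and one
   life-year per year, the year-2 cost in the first such year and the
   year-3+ cost thereafter, discounted year by year with the final
   fractional year prorated.
4. **Removed state.** Absorbing with no accrual in the base case.

Point (3) credits survivors with the full AUC rather than the
conditional remainder 9.672: the source model applies its estimated mean
post-transplant survival to each recipient in the post-year-1 state, and
only this reading reproduces the published incremental results
(incremental life-years 0.040 and QALYs 0.045; the conditional-remainder
allocation yields ~0.066 for both and an ICER of ~£66k instead of £90k).
The choice is a documented property of the reconstruction, not a claim
about transplant biology; the `survival` module still provides the
conditional decomposition.

No single linear accrual convention can reproduce *all* nine published
numbers simultaneously (the published between-arm ratio of
`QALY - u_wait*LY` implies a discounted-entrant ratio of 1.0445 where the
transition arithmetic that reproduces the published transplant counts
exactly gives 1.0336). The frozen convention prioritises the incremental
results; absolute levels land within ~0.2% (costs), ~3% (life-years) and
~4% (QALYs) of the published values.

## Parameter uncertainty

Every uncertain parameter carries a distribution: Beta for probabilities
and utilities, Gamma for costs, with the published shape parameters used
*as printed*. For several published rows the distribution mean differs
from the printed point value (e.g. the waiting-list cost Gamma has mean
£24,672 against a printed mean of £23,829, and the EVLP uplift Beta(18,
184) has mean 0.089 against a labelled 10%). The reconstruction keeps
both: deterministic runs use the printed point values (validated by the
deterministic transplant counts), while the PSA samples the printed
distributions — the configuration that reproduces the published PSA
means, including the £69,954 standard-service mean cost and the published
95% CIs, almost exactly. The method-of-moments fitters
(`beta_from_mean_count`, `beta_from_mean_variance`, `gamma_from_mean_se`)
are available for deriving internally consistent specifications from
data, and are what `synthetic.estimate_parameters` uses.

The published 3-year survival Beta (α printed as 25.19, implying a mean
of 0.207 against a printed mean 0.72) is treated as a typographic
truncation of α≈225.19 and refit at the printed mean with the implied
total count 321.7.

PSA mechanics: 1000 draws by default; per draw a single sampled parameter
set feeds both arms (common random numbers), so shared quantities —
transitions, survival, utilities, waiting cost — are identical across
arms within a draw and the percentile intervals on the increments are
coherent. Slots duplicated per transplant type (survival and utilities in
the base case) receive one draw while their laws are identical and
diverge automatically when a scenario splits them. Independently sampled
transition rows may sum above 1; the engine renormalizes the exit
probabilities proportionally and clamps the remain probability at zero
(affects a small fraction of draws, dominated by the highly dispersed
year-3+ rows). Independently sampled survival points may violate
monotonicity (~7% of draws); they are clamped sequentially
(s3≤s1, s5≤s3, s10≤s5). Summary intervals are 2.5/97.5 percentiles of
the draws, not normal approximations.

## Cost-effectiveness statistics

The ICER divides mean incremental cost by mean incremental effect, with
dominance flagged instead of a ratio when signs disagree. CEAC
probabilities come from per-draw net-monetary-benefit comparison
(`NMB = λ·QALY − cost`); ties and boundary draws are resolved in favour
of the standard service (the incumbent). The default willingness-to-pay
grid is £0–£150,000 in £1,000 steps. Headline ICERs are reported raw and
rounded (nearest £10,000 for the base case, £1,000 for scenarios),
matching the publication's presentation.

Base-case reconstruction (1000 draws): incremental cost ≈ £4,000 (95% CI
≈ £1.7k–£7.0k), incremental QALYs ≈ 0.045, incremental life-years
≈ 0.040, ICER ≈ £90,000/QALY; >99.9% probability the standard service is
more cost-effective at £20,000/QALY. The share of draws with *negative*
incremental QALYs converges to ≈0.3% in this reconstruction against a
published 1.1% — the published interval for incremental QALYs implies a
slightly fatter lower tail than the published Beta/Gamma laws generate
under shared draws; the discrepancy is documented rather than tuned away.

## Scenarios and exploratory analyses

Nine scenarios are parameter transformations applied before the standard
pipeline: (1) pre-trial waiting-list transitions; (2) uplift 20%;
(3) EVLP transplant cost at a 45% conversion rate (£119,672); (4) at a
1:1 conversion rate (£89,455); (5) literature utilities
(0.31/0.83/0.82); (6) two standard-only services (pre-trial vs
within-trial transitions); (7) trial one-year survival per transplant
type (0.80 standard, 0.67 EVLP; later survival points retained, the AUC
recomputed, and the 3-year point clamped to the year-1 value to keep the
curve monotone); (8) post-transplant care costs equalised across arms
with the EVLP transplant cost at £95,750 — the cost-equalisation applies
to the annual post-transplant rows as well as the episode cost, which is
what the published incremental cost requires; (9) waiting-list cost
+120% (£50,830). Scenario tables report PSA means for costs/outcomes and
deterministic transplant counts.

Scenario reconstructions land within a few percent of the published
ICERs for scenarios 1–5; scenario 7's QALY ICER divides by a near-zero,
noise-dominated increment (the robust findings — standard service
dominant on life-years, QALY ICER far beyond any threshold — are what
the tests assert); scenarios 6 and 9 are internally inconsistent in the
publication itself (scenario 6's within-trial arm is parameter-identical
to the base-case standard arm yet is printed with a different cost) and
are implemented from their stated designs rather than their printed
numbers.

Exploratory analyses: (a) crediting removed-from-list patients with 1, 3
or 6 months of palliative care (£1,173 or £1,644/month; utility 0.563 or
0.31) before death — all twelve combinations move both arms almost
equally and leave the ICER at ≈£90,000; (b) restoring the EVLP arm's
standard-transplant activity to the standard-service level (46 extra
standard transplants per 1000), with one further waiting-list year as
the counterfactual for an untransplanted patient: net cost ≈ £56k and
QALY gain ≈ 4.1 per extra transplant, and an ICER between services of
≈ £29k/QALY. The counterfactual definition is the one reading of this
under-specified analysis that reproduces the published figures and is a
modelling choice, not an estimate of true waiting-list survival.

## Synthetic pseudo-trials

`synthetic.generate_trial` emulates the *structure* of the study's
patient-level data: 184 standard + 18 EVLP recipients with per-patient
utilities (listing, 3 and 12 months) from the published Beta laws and
transplant-episode costs from the published Gamma laws; a 53-assessment
EVLP log with Binomial(53, 18/53) conversions; and a 251-patient
waiting-list cohort followed three years with multinomial exits at the
published band probabilities. The 3-month utility law (not published) is
a Beta at the midpoint mean 0.633 with effective n = 400. One-year
survival flags use the model's registry value 0.772. The generator does
not emulate recruitment, censoring, SF-36 item responses, correlation
between repeated measures within a patient, or per-stage cost
composition — so parameter-recovery tests demonstrate estimator
correctness on this structure, not robustness to real trial messiness.

`estimate_parameters` inverts the generator (moments fits and observed
proportions) and passes registry-sourced quantities through from the base
case, mirroring the study's mixed derivation. Recovery is tested at 100×
the trial size against the generating-law means; for the rarest
waiting-list exit (p = 0.02) binomial noise exceeds 2% relative even at
that size, so transition rows are tested at `max(2%, 3 binomial SE)`.

## Numerical choices and problem sizes

* Cohort conservation is maintained to 1e-6 persons per cycle; the
  waiting-list residual at the horizon must be below 1e-6 of the cohort.
* Discount factors are exact powers; the post-year-1 stream's final
  fractional year is prorated linearly.
* Currency is real GBP floats throughout; presentation rounding happens
  only at reporting.
* Default seeds: 1234 for analyses; all stochastic outputs are
  reproducible from (configuration, seed, version).
* Test-suite problem sizes: 1000-draw PSAs for base-case checks (4000
  for the scenario-4 check, 500 per removed-state combination), a
  100,000-patient microsimulation oracle, and 100×-scale pseudo-trials —
  sizes at which Monte-Carlo error is well below the tolerances tested.

## Known limitations

* Closed cohort of 1000: no dynamic waiting-list inflow, re-listing or
  re-transplantation; no age/sex-structured background mortality.
* Survival extrapolation is a fixed piecewise-linear curve; no
  parametric (Weibull/exponential) alternatives or time-varying hazards.
* Utilities and survival are common to both transplant types in the base
  case by design; evidence of a true EVLP difference would require the
  scenario-7 machinery, whose QALY ICER is noise-dominated.
* The accrual convention is a reconstruction calibrated to published
  outputs of a spreadsheet model; where the publication is internally
  inconsistent (absolute QALY levels, scenarios 6 and 9, the
  north-west-quadrant share) this package reproduces its own declared
  convention rather than every printed digit, and the deviations are
  stated above.
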