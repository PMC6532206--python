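# lungcea

A Markov cohort cost-utility model of the UK adult lung-transplant
service, comparing a service that adds **ex-vivo lung perfusion (EVLP)**
— a technique that reconditions donor lungs initially judged unusable,
increasing the donor pool — against the standard-transplant-only service.

It is written for health economists and HTA analysts who want a tested,
scriptable re-implementation of this published decision model: a
deterministic cohort engine, a full probabilistic sensitivity analysis
(PSA), ICER / cost-effectiveness-plane / CEAC statistics, the nine
published scenario analyses and two exploratory analyses, and a
pseudo-trial generator so the whole pipeline is testable without any
patient-level data.

## The model

A cohort of 1000 adults starts on the transplant waiting list. Each
one-year cycle a listed patient is removed from the list (too ill;
absorbing), dies, receives a standard transplant with probability
*p*<sub>tx</sub>, or — in the EVLP service — receives an EVLP transplant
with probability *u*·*p*<sub>tx</sub> (uplift *u* = 0.10), otherwise
remains listed. Transplant recipients pass through a year-1 state (one-year
survival *s*₁ = 0.772) into a post-year-1 state that credits survivors
with the mean post-transplant survival obtained by area-under-the-curve
extrapolation of registry survival (piecewise-linear through the 1/3/5/10
year points, zero at 25 years: AUC = 8.353 years). States accrue SF-6D
utilities and 2016/17 GBP costs; everything is discounted at 3.5%/year.

Cost-effectiveness is summarised by the incremental cost-effectiveness
ratio ICER = ΔC/ΔE from a 1000-draw PSA (Beta distributions on
probabilities and utilities, Gamma on costs, common draws across arms),
the CE-plane quadrant shares, and the cost-effectiveness acceptability
curve from per-draw net monetary benefit λ·QALY − cost.

See `docs/methods.md` for the accrual convention, the distribution
handling and the calibration notes.

## Worked example

```python
import lungcea as lc

params = lc.load_base_case()
std = lc.run_deterministic(params, "standard")
evlp = lc.run_deterministic(params, "evlp")
print(f"standard service: {std.n_std_tx:.0f} transplants, "
      f"cost {std.mean_cost:,.0f}, QALYs {std.mean_qaly:.3f}")
print(f"EVLP service:     {evlp.n_std_tx:.0f} standard + {evlp.n_evlp_tx:.1f} EVLP, "
      f"cost {evlp.mean_cost:,.0f}, QALYs {evlp.mean_qaly:.3f}")

psa = lc.run_psa(params, n_sims=1000, seed=1)
inc = lc.summarize_incrementals(psa)
print(f"incremental cost  {inc.inc_cost:,.0f}  "
      f"(95% CI {inc.inc_cost_ci[0]:,.0f} to {inc.inc_cost_ci[1]:,.0f})")
print(f"incremental QALYs {inc.inc_qaly:.3f}  "
      f"(95% CI {inc.inc_qaly_ci[0]:.3f} to {inc.inc_qaly_ci[1]:.3f})")
print(f"ICER {inc.icer_qaly} per QALY (~{inc.icer_qaly.rounded(10000):,.0f})")
curve = lc.ceac(psa)
print(f"P(standard more cost-effective at 20k/QALY) = {curve.at(20000)[1]:.3f}")
```

prints

```
standard service: 721 transplants, cost 68,977, QALYs 3.815
EVLP service:     675 standard + 67.5 EVLP, cost 73,319, QALYs 3.866
incremental cost  4,019  (95% CI 1,727 to 6,910)
incremental QALYs 0.045  (95% CI 0.014 to 0.086)
ICER 89,665 per QALY (~90,000)
P(standard more cost-effective at 20k/QALY) = 1.000
```

Reading: adding EVLP performs 21 extra transplants per 1000 listed
patients (67.5 EVLP, partly offset by 46 fewer standard transplants
because EVLP exits deplete the list), gains ~0.045 QALYs per patient, and
costs ~£4,000 more per patient — about £90,000 per QALY, well above the
usual UK willingness-to-pay range of £20,000–£30,000. Under a 1:1
assessment-to-transplant conversion rate (scenario 4) the EVLP episode
cost falls to £89,455 and the ICER drops into the £23–26k range.

The same analyses are available from the shell:

```bash
lungcea --mode deterministic --out results/
lungcea --mode psa --n-sims 1000 --seed 1 --out results/
lungcea --mode scenarios --out results/           # all nine + base case
lungcea --mode scenarios --scenario 4 --out results/
lungcea --mode exploratory --out results/
lungcea --mode synthetic --seed 1 --out results/  # pseudo-trial + re-estimation
```

Outputs are delimited-text tables (cohort traces, per-draw PSA table,
CEAC curve, scenario table) plus a YAML echo of every parameter; runs are
bit-reproducible given the seed.

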