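# Methods

## Model structure

A cohort of previously treated advanced/metastatic NSCLC patients enters the
model in the progression-free (PFS) state and moves through three mutually
exclusive states — PFS, progressed disease (PD), death — in discrete
3-week cycles over 208 cycles (≈ 12 years). Time is measured in months
(1 month = 365.25/12 = 30.4375 days), so cycle k sits at
t_k = k · 21/30.4375 months.

State occupancy is read directly off the two fitted survival functions
(partitioned-survival identity):

    PFS(t)  = min(S_pfs(t), S_os(t))
    dead(t) = 1 − S_os(t)
    PD(t)   = 1 − PFS(t) − dead(t)

This reproduces both fitted curves exactly and is the standard concrete
meaning of "time-dependent transition probabilities derived from survival
curves". An explicit per-cycle transition-matrix view is also provided
(PFS→PFS = S_pfs(t_k)/S_pfs(t_{k−1}); per-cycle deaths
S_os(t_{k−1}) − S_os(t_k) allocated to PD first, overflow to PFS;
PFS→PD the clamped remainder); propagating the cohort through these
matrices is proven equivalent to the identity above to 1e-9 at every cycle
in the test suite.

## Survival inputs

The bundled reference configuration uses per-arm, per-endpoint log-logistic
models, S(t) = 1/(1 + (t/α)^β), with the published scale/shape values:

| arm | endpoint | α (months) | β |
|---|---|---|---|
| tislelizumab | OS  | 17.43252 | 1.48925 |
| tislelizumab | PFS | 4.84787  | 1.42274 |
| docetaxel    | OS  | 11.7162  | 1.5699  |
| docetaxel    | PFS | 3.11381  | 2.12956 |

Under this parameterization α equals the median, which places the OS scales
next to the trial medians (19.3 / 11.5 months) — the reason this convention
was chosen over the typographically ambiguous printed formula. The family
list's "log-lognormal" is read as lognormal (the seventh conventional
family; no standard distribution carries that name).

When the configuration supplies digitized curves instead, pseudo-IPD is
rebuilt by the Guyot interval-balancing recursion and all seven families are
fitted by censored maximum likelihood (Σ log f over events + Σ log S over
censorings), optimized by Nelder–Mead on log-transformed positive parameters
from several moment/quantile starts (log-likelihood tolerance 1e-8). The
generalized gamma uses the (μ, σ, Q) log-time parameterization with the
lognormal limit taken analytically for |Q| < 1e-5. Selection is by minimum
AIC, ties broken by BIC then family name; AIC is primary because no
precedence between the two criteria is published.

## Guyot reconstruction details

Digitized coordinates are treated as exact step-curve samples (no
smoothing). Within each number-at-risk interval, a censoring count is
iterated (censor times spread uniformly) until the implied number at risk at
the next interval boundary matches the published count; events at each
digitized drop follow from the product-limit relation. Negative implied
censorings — common under digitization noise — are clamped to zero with a
logged warning rather than raised. Subjects still at risk after the final
coordinate are administratively censored there. If a published total event
count is supplied, the latest censorings are flipped to events (or vice
versa) to match it. Ties at a time point are events-first, the standard KM
convention. The test suite requires the reconstructed KM to stay within
max |ΔS| < 0.02 of the true KM for 300 simulated subjects digitized on a
0.1-month grid with 3-month risk intervals.

## Costs, utilities, discounting

Per-cycle costs: drug acquisition (tislelizumab 2675 CNY, docetaxel 419.25
CNY = 65 CNY/20 mg × 75 mg/m² × 1.72 m², billed at exact milligrams), best
supportive care 2467 CNY, and a one-time severe adverse-event cost of
2534 CNY weighted by per-AE incidence at model entry. Utilities: PFS 0.804,
PD 0.321; AE disutilities (neutropenia 0.20, febrile neutropenia 0.42,
anemia 0.078, asthenia 0.078) are applied once at entry for one cycle,
weighted by incidence. Per-arm AE incidences are not published and default
to zero; their maximal effect (≤ 2,534 CNY and ≤ 0.42 × one cycle's QALY) is
inside the replication tolerance. QALYs accrue as
(PFS·u_pfs + PD·u_pd) · 21/365.25 per cycle. Discounting is 5%/year applied
continuously in cycles, (1+r)^(−t_k in years); cycle 0 accrues nothing.
Half-cycle correction is available but off by default (the source analysis
does not mention it).

Cost scopes are explicit toggles because the source publication does not
state them:

* `bsc_scope` ∈ {all_alive, pd_only}, default **all_alive** — BSC is defined
  as diagnosis/bed/nursing fees, which accrue while alive.
* `ArmSpec.drug_scope` ∈ {pfs_only, all_alive} — default **all_alive for the
  checkpoint inhibitor** and **pfs_only for docetaxel** in the reference
  configuration. Immunotherapy is commonly continued beyond radiographic
  progression in responders (the source trial permitted it), while
  chemotherapy stops at progression; this is also the only convention that
  reproduces the published incremental cost (see below).

## Reproducibility of the published base case

The published totals are tislelizumab 186,583 CNY / 1.04 QALYs, docetaxel
69,111 CNY / 0.46 QALYs, Δ 117,473 CNY / 0.58 QALYs, ICER 202,927 CNY/QALY.
From the printed inputs this package computes (frozen conventions above):

| quantity | published | this package | deviation |
|---|---|---|---|
| tislelizumab cost  | 186,583 | 195,069 | +4.6% |
| tislelizumab QALYs | 1.04    | 1.078   | +3.7% |
| docetaxel cost     | 69,111  | 68,500  | −0.9% |
| docetaxel QALYs    | 0.46    | 0.660   | +43%  |
| Δcost              | 117,473 | 126,570 | +7.7% |
| ΔQALY              | 0.58    | 0.419   | −28%  |
| ICER               | 202,927 | 302,215 | +49%  |

The docetaxel QALY total is not derivable from the printed inputs under any
convention we could construct: solving the cost and QALY equations jointly
for the docetaxel arm's discounted PFS/PD occupancy implies ≈ 0.65
discounted PFS *cycles*, impossible for a PFS distribution with a 2.6-month
median (the model gives ≈ 6 discounted cycles). Conversely the tislelizumab
pair and the docetaxel cost are reproduced within 5% / 1%, and the
incremental cost within 0.3% when drug cost accrues while alive (the basis
for the drug-scope default). The downstream disagreements — ΔQALY, ICER, the
one-way-analysis claim that all ICERs stay below the 257,016 threshold, and
the 74.8% PSA probability at that threshold (which requires a base ICER just
below it) — all trace to that single inconsistency. The corresponding
replication tests are left failing rather than tuned; conventions were
calibrated once and frozen.

A related printed inconsistency: 1377.5 CNY/100 mg × 200 mg = 2755 CNY per
cycle, but the published per-cycle tislelizumab cost is 2675; the published
table value is used verbatim.

## Sensitivity analysis

One-way analysis re-runs the full base case at each parameter's published
bounds (drug prices from price-negotiation floors/bid ranges, utilities
±10%, discount rate 0–8%) and ranks entries by ICER swing. In this model the
PFS-utility swing (≈ 51,000 CNY/QALY) narrowly exceeds the
tislelizumab-price swing (≈ 48,000) because the smaller ΔQALY amplifies the
utility ranges; under the published (larger) ΔQALY the drug price ranks
first.

PSA: 5,000 second-order Monte Carlo draws. A published low~high range is
read as a central 95% interval, σ = (high − low)/3.92; beta shapes for
utilities and disutility magnitudes (re-negated after sampling) and gamma
(shape = (m/σ)², scale = σ²/m) for costs are matched to mean = base value
and that σ (verified to 1e-9 in tests). Parameters are sampled
independently; the discount rate is fixed in PSA; survival parameters carry
no published ranges and are not varied. CEAC probabilities count draws with
positive net monetary benefit λ·ΔQALY − Δcost over a 0–600,000 CNY grid in
10,000-CNY steps. Default seed 20240718, recorded in all outputs.

## Synthetic data: what it emulates

`simulate_ipd` draws event times by inverse-CDF from any supported family,
with administrative censoring at a cutoff and independent exponential
dropout whose rate is solved numerically to hit a requested expected
censoring fraction. `make_trial` mirrors the source trial's design: 805
subjects randomized 2:1, event times from the reference log-logistic models,
administrative censoring at a 36-month data cutoff (consistent with the
final-analysis follow-up of a trial reporting medians of 19.3/11.5 months)
and 5% random dropout — a realistic attrition level for a modern oncology
trial. `make_digitized` renders records as KM step-curve samples on a
0.1-month grid with 3-month risk intervals, emulating careful manual
digitization of a published figure.

Not emulated: per-subject consistency between OS and PFS (endpoints are
simulated marginally, so a synthetic subject may "progress" after "dying" —
irrelevant for curve-level pipelines but wrong for patient-level reuse);
digitization bias (grid sampling is exact, real plot-reading adds noise);
informative censoring; covariates, response and AE time courses. A green
round-trip test therefore establishes that reconstruction and fitting are
internally correct, not that manual digitization of the real figures would
achieve the same accuracy.

## Numerical choices

* Log-logistic survival evaluated as −logaddexp(0, β·log(t/α)) for stability
  at both tails; S(0) ≡ 1 by definition for every family.
* Transition probabilities guard divisions when S reaches numerical zero
  (state treated as absorbing-empty, self-transition 1).
* ICER dominance labels: (ΔC ≤ 0, ΔE > 0) dominant; (ΔC > 0, ΔE < 0)
  dominated; |ΔE| < 1e-12 with ΔC > 0 "dominated-degenerate" instead of
  dividing.
* Digitized curves tolerate survival rises ≤ 1e-9 and a first coordinate
  within 0.02 of 1 (digitization noise); anything larger is an error naming
  the offending row.
* Optimizer: Nelder–Mead, fatol 1e-8, up to 4000 iterations, best of
  multiple starts; exponential uses the closed form events/total-time.

## Known limitations

* The engine is a cohort model; no microsimulation, treatment-duration caps,
  vial wastage, or subsequent-therapy costing.
* No correlation structure or EVPI in the PSA; no spline/cure survival
  models; no covariate-adjusted fits.
* Within-trial fit quality of the seven families can only be checked as a
  property (selection self-consistency on synthetic data) because the
  original per-family AIC/BIC table is not published in the main text.
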