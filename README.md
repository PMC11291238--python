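# nsclc-cea

Cost-effectiveness modelling of a PD-1 checkpoint inhibitor (tislelizumab)
versus docetaxel as second/third-line treatment for advanced or metastatic
non-small-cell lung cancer, from the Chinese healthcare-system perspective.
The package re-implements, as tested and reusable code, the full
health-economic workflow behind a published trial-based cost-utility
analysis:

1. **KM curve reconstruction** — digitized Kaplan–Meier step-curve
   coordinates plus number-at-risk tables are converted to pseudo individual
   patient data by the Guyot interval-balancing algorithm.
2. **Parametric survival extrapolation** — seven families (exponential,
   Weibull, gamma, generalized gamma, Gompertz, log-logistic, lognormal) are
   fitted to the right-censored pseudo-IPD by maximum likelihood and ranked
   by AIC (BIC tiebreak). The base case uses log-logistic models,
   S(t) = 1 / (1 + (t/α)^β), whose scale α equals the median.
3. **Three-state cohort model** — PFS / progressed disease / death over 208
   three-week cycles (12 years), with state occupancy from the
   partitioned-survival identity
   `PFS = min(S_pfs, S_os)`, `dead = 1 − S_os`, `PD = remainder`,
   an equivalent per-cycle transition-matrix view, per-cycle drug / best
   supportive care / adverse-event costs, utility-weighted life-years and 5%
   annual discounting, yielding the ICER = ΔCost / ΔQALY.
4. **Sensitivity analysis** — one-way (tornado) analysis over published
   parameter ranges, and a 5,000-draw second-order Monte Carlo PSA
   (moment-matched beta distributions for utilities, gamma for costs) with
   cost-effectiveness acceptability curves by net-monetary-benefit counting.

It is aimed at health-economics researchers and students who want a
transparent, scriptable version of what is usually locked inside TreeAge
models: every stage is a plain Python function, every artifact a CSV/JSON
file.

## Worked example

```python
from nsclc_cea import make_reference_config, run_arm, icer

cfg = make_reference_config()          # bundled published model inputs
for arm in cfg.arms:
    trace, outcome = run_arm(arm, cfg.inputs)
    print(f"{outcome.arm:13s} cost {outcome.total_cost:9.0f} CNY   "
          f"QALYs {outcome.total_qalys:.3f}")
res = icer(*[run_arm(a, cfg.inputs)[1] for a in cfg.arms])
print(f"dCost {res.delta_cost:.0f}  dQALY {res.delta_qalys:.3f}  "
      f"ICER {res.icer:.0f} CNY/QALY")
```

prints

```
tislelizumab  cost    195069 CNY   QALYs 1.078
docetaxel     cost     68500 CNY   QALYs 0.660
dCost 126570  dQALY 0.419  ICER 302215 CNY/QALY
```

i.e. under the bundled inputs the checkpoint inhibitor gains 0.419
discounted QALYs at an extra discounted cost of 126,570 CNY, an ICER of
~302,000 CNY per QALY — above the willingness-to-pay threshold of 257,016
CNY/QALY (3× China's 2022 per-capita GDP). The published analysis reports a
lower ICER (202,927); docs/methods.md documents why its per-arm totals are
not fully derivable from its printed inputs and which conventions this
package froze.

The same run from the shell:

```sh
nsclc-cea make-config --out model.yaml
nsclc-cea all --config model.yaml --out results/
```

The digitized-curve pathway (reconstruct → fit → select → model) runs on
synthetic fixtures:

```sh
nsclc-cea make-fixtures --out fixtures/ --seed 1
nsclc-cea reconstruct fixtures/tislelizumab_os_coords.csv \
    fixtures/tislelizumab_os_risk.csv --out ipd_os.csv
nsclc-cea fit ipd_os.csv --out fits_os.csv
```

## Layout

```
src/nsclc_cea/
  curves.py       digitized-curve I/O, Guyot reconstruction, KM estimator
  fitting.py      censored MLE for seven families, AIC/BIC selection
  model.py        three-state cohort trace, costing, QALYs, ICER, dosing
  sensitivity.py  tornado, moment matching, PSA, CEAC
  synthetic.py    simulated trials, digitized fixtures, reference config
  pipeline.py     configuration-driven orchestration + run manifest
  cli.py          `nsclc-cea` command-line interface
```
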