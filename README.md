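# psmcea

Partitioned-survival cost-effectiveness analysis of second-line
**camrelizumab versus chemotherapy** (docetaxel/irinotecan) for advanced or
metastatic oesophageal squamous cell carcinoma, for health-economics
analysts who want a scriptable, testable re-implementation of this class of
oncology evaluation.

The model has three mutually exclusive states — progression-free disease
(PFD), progressive disease (PD), death — whose occupancy comes directly from
parametric survival curves: `PFD(t) = S_PFS(t)`,
`PD(t) = S_OS(t) − S_PFS(t)`, `dead(t) = 1 − S_OS(t)`. Curves are
log-logistic, `S(t) = 1/(1 + λt^γ)` with t in months (Weibull as the
alternative family), fitted by right-censored maximum likelihood to
pseudo individual-patient data reconstructed from digitized Kaplan–Meier
coordinates, and selected by AIC/BIC. Discounted costs (drug, follow-up,
best supportive care, grade ≥3 adverse events) and QALYs accrue per monthly
cycle over 10 years, yielding the incremental cost-effectiveness ratio
`ICER = ΔCost/ΔQALY`, a tornado (one-way) analysis, and a 10,000-draw
probabilistic analysis summarized as a cost-effectiveness acceptability
curve.

## Worked example

```python
from psmcea import CostEffectivenessModel

model = CostEffectivenessModel.from_config()   # packaged base-case inputs
res = model.fit(scenario=1)                    # fixed treatment courses
print(res.summary())
```

```
Partitioned-survival cost-effectiveness results [fixed_courses]
                camrelizumab  chemotherapy  incremental
QALYs total           1.0332        0.4460       0.5872
QALYs PFD             0.2426        0.1576       0.0849
QALYs PD              0.7907        0.2884       0.5023
Life-years            1.6888        0.7128       0.9760
Cost total        4,940.4340    2,513.9598   2,426.4741
Cost drug         1,952.0297    1,161.3145     790.7152
Cost follow-up    1,044.1305      440.6955     603.4351
Cost BSC          1,912.5870      697.6043   1,214.9827
Cost SAE             31.6868      214.3456    -182.6588
ICER ($/QALY): 4,132.21
```

Reading this: camrelizumab yields 0.59 more discounted QALYs at $2,426 extra
cost, i.e. $4,132 per QALY gained — well under the willingness-to-pay
threshold of one-times per-capita GDP ($10,503.52/QALY). Scenario 2
(`model.fit(2)`) keeps both arms on treatment until progression. The
probabilistic side:

```python
from psmcea import run_psa
from psmcea.config import load_config

psa = run_psa(load_config(), n=10_000, seed=1)
print(psa.probability_cost_effective(10_503.52))   # -> 0.9971
```

Note that the packaged configuration is a *replication* fixture: it keeps
two documented quirks of the source analysis (non-drug unit costs at their
yuan magnitudes via `costs.non_drug_unit_scale`, and an internally
inconsistent camrelizumab OS scale parameter) so that published figures can
be compared like for like. `docs/methods.md` details both and how to run a
strict all-USD reanalysis.

## Command line

```bash
psmcea validate                         # check a config
psmcea base-case --scenario 1 --family loglogistic --out out/
psmcea owsa --out out/                  # tornado table + plot
psmcea psa --seed 1 -n 10000 --out out/ # draws, CEAC, scatter
psmcea full --seed 1 --out out/         # 2 scenarios x 2 families + OWSA + PSA
psmcea make-fixtures --out fixtures/    # synthetic trial data with known truth
```

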