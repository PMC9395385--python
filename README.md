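# sfeperf

Multifactor performance assessment for supercritical CO₂ extraction (SFE) of
plant material with an ethanol–water co-solvent. Choosing an operating
condition for an SFE unit by yield alone ignores what the condition costs to
run and how hazardous the solvent system becomes; `sfeperf` integrates the
three views — solubility, operational cost and chemical safety — into a
single rank-based index and selects the best condition. It is aimed at
process engineers evaluating lab-scale SFE data for scale-up.

## What it computes

**Response-surface models.** A three-factor central composite design (CCD) —
pressure *A*, temperature *B*, water-in-ethanol *C*, coded as
(actual − centre)/step — carries two measured responses: overall yield
(g/g %) and solubility of the extract in CO₂ ((g/g)·10³). Yield is fitted
with a two-factor-interaction (2FI) polynomial and solubility with a full
quadratic, by ordinary least squares on the coded scale. Fit quality is
reported as R², adjusted R², predicted R² (from the PRESS leave-one-out
statistic) and a lack-of-fit F-test against pure error from the six centre
replicates.

**Operational cost.** Annual direct cost from raw materials (CRM), utilities
(CUT) and labour (COL), aggregated as

```
OC = 2.73·COL + 1.23·(CUT + CRM)        [RM/year]
```

Across conditions the cost varies through the water fraction of the
co-solvent (water displaces purchased ethanol).

**Chemical safety.** For each water level the mixture flash point is solved
from Le Chatelier's rule, Σᵢ xᵢγᵢP_sat,i(T)/P_sat,i(T_fp,i) = 1, with
Antoine vapour pressures and van Laar activity coefficients. Four logistic
scores on [0, 100] — flammability S_FL(flash point), toxicity S_TX(TLV-STEL),
reactivity S_R(NFPA) and explosiveness S_EXP(UEL−LEL) — sum to the Chemical
Safety Total Score, CSTS (higher = more hazardous).

**Overall performance index.** Each criterion column is ranked 1…n with n
for the best condition (highest solubility, lowest OC, lowest CSTS); the
overall index is the unweighted sum

```
I_performance = I_solubility + I_cost + I_safety
```

and the condition maximising it is selected.

## Worked example

```python
from sfeperf import datasets, fit_model, anova, assess_conditions

frame = datasets.load_design_response()   # packaged 20-run CCD + responses
table = datasets.load_design_table()

est = fit_model(table, frame["yield_pct"], "2fi")
print(f"R2={est.r2_:.4f}  adjR2={est.adj_r2_:.4f}  predR2={est.pred_r2_:.4f}")
print({t: round(c, 2) for t, c in zip(est.terms_, est.coef_)})

perf = assess_conditions(frame, datasets.load_cost_config(),
                         datasets.load_chemicals())
print(perf.best_condition)
```

prints

```
R2=0.9538  adjR2=0.9324  predR2=0.8970
{'A': 3.19, 'B': 1.11, 'C': 3.11, 'AB': -0.05, 'AC': 2.11, 'BC': 0.77}
(21.0, 65.0, 33.0)
```

Pressure (A = 3.19) and water content (C = 3.11) are the strongest yield
effects, with a large synergistic A·C interaction (2.11): extra water helps
mainly at high pressure. The assessment picks 21 MPa, 65 °C and 33 % water
in ethanol — not the condition with the highest solubility, but the one
combining mid-table solubility with the cheapest (least ethanol) and safest
(highest flash point) co-solvent.

The same steps are exposed on the command line:

```
sfeperf fit --response yield_pct --model 2fi
sfeperf cost --water-pct 33
sfeperf safety --water-pct 7
sfeperf index
sfeperf compare
```

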