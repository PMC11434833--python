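# peritopk

Population pharmacokinetics / pharmacodynamics of **continuously infused
piperacillin–tazobactam in critically ill patients with an open abdomen
under vacuum-assisted closure (OA/VAC)**.

In these patients the peritoneal cavity is an open, drained space: drug
distributes from plasma into peritoneal fluid and is partly removed with
the fluid by the negative-pressure (VAC) system. Whether that extra
clearance route causes antibiotic underdosing at the infection site is a
quantitative question. `peritopk` provides the full modelling chain for
it, aimed at pharmacometricians and infectious-disease/ICU researchers:

* a **two-compartment plasma–peritoneal model** with elimination from
  both compartments, solved exactly for piecewise-constant infusions —
  central volume `V1`, peritoneal volume `V2`, exchange clearance `Q`,
  renal clearance `Cl1`, VAC-route clearance `Cl2`, with the steady
  state `C1ss = R/(Cl1 + Q·Cl2/(Q+Cl2))` and the partition ratio
  `C2ss/C1ss = Q/(Q+Cl2)`;
* a **nonlinear mixed-effects layer** (log-normal parameters; age and
  weight on `V1`, renal-function category on `Cl1`; inter-occasion
  variability on `Cl1`; proportional residual error) with the published
  final parameter sets for both drugs built in;
* a **SAEM estimator** with MAP priors, fixed parameters,
  likelihood-ratio covariate testing, subject-level bootstrap, and
  simulation diagnostics (NPDE, prediction-corrected VPC, weighted
  residuals);
* a **synthetic cohort generator** reproducing the study design (renal
  groups, regimens 12/16/20 g per day after a 4 g/0.5 g load, sparse
  T0/T1 sampling, pooled VAC-fluid and urine collections) so every stage
  is testable without patient data;
* a **Monte Carlo PTA/FTA engine** for the 100% fT>MIC target (and the
  4×MIC family) in plasma and at the peritoneal site, per renal group,
  regimen, and MIC grid, with ECOFF summaries.

## Worked example

```python
import peritopk as pk
from peritopk.pta import default_regimens

pip = pk.piperacillin_params()          # published final model

# typical category-A patient (normal renal function), 66 y, 83 kg
cov = pk.CovariateVector(age=66, weight=83, renal_category="A")
p = pk.individual_params(pip, cov)
print(p.V1, p.Cl1)                      # 30.25 L, 38.74 L/h

c1, c2 = pk.steady_state(p, 16000 / 24) # 16 g/day continuous infusion
print(c1, c2, pk.diffusion_ratio(c2, c1))
# 15.41 mg/L plasma, 12.49 mg/L peritoneal, 81.1 % diffusion

reg = {r.label: r for r in default_regimens("piperacillin")}["16g_day"]
grid = pk.simulate_pta(pip, reg, "A", n=10000, seed=42)
for mic in (4.0, 8.0, 16.0, 32.0):
    print(mic, grid.pta("16g_day", "A", "C1", mic),
          grid.pta("16g_day", "A", "C2", mic))
# MIC 4:  96.9 % plasma, 94.5 % peritoneal
# MIC 8:  82.2 %         73.9 %
# MIC 16: 48.5 %         36.2 %
# MIC 32: 13.3 %          7.1 %

fta = pk.compute_fta(grid, {4.0: 0.3, 8.0: 0.5, 16.0: 0.2},
                     compartment="C2")
print(fta.fta_pct, fta.success)         # 72.5 %, below the 85 % bar
```

Reading: the typical patient on 16 g/day keeps unbound piperacillin
above an MIC of 8 mg/L at the peritoneal site in ~74 % of simulated
patients, but above the Pseudomonas ECOFF of 16 mg/L in only ~36 % —
which is why renal-function-adjusted dosing up to 20 g/2.5 g per day is
the relevant comparison (run the other regimens/groups the same way).

A full pipeline (simulate → fit → diagnose → bootstrap → exposure → PTA)
is driven by a YAML config:

```bash
peritopk run --config config.yaml
peritopk pta --drug PIP --regimen 16g_day --group A --n 10000 --seed 42 --out pta.csv
```

Fitting a dataset directly:

```python
design = pk.CohortDesign(n_patients=45)
cohort = pk.generate_cohort(design, pk.piperacillin_params(),
                            pk.tazobactam_params(), seed=7)
dataset = pk.cohort_to_dataset(cohort)

from peritopk.estimation import FitSpec, fit_population
fit = fit_population(dataset, FitSpec.for_drug("piperacillin", seed=1))
print(fit.summary())
```

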