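# Methods

`peritopk` models the pharmacokinetics of piperacillin and tazobactam
given by continuous intravenous infusion to critically ill patients whose
abdomen is left open under vacuum-assisted closure (OA/VAC), and turns
the fitted population model into dosing guidance via Monte Carlo
probability-of-target-attainment (PTA) simulation.  This note records the
model, the synthetic study design, the estimation algorithm, and the
design choices made where the design was genuinely open.

## Structural model

A two-compartment mammillary model with elimination from both
compartments:

    dA1/dt = R_inf(t) - (k10 + k12) A1 + k21 A2
    dA2/dt = k12 A1 - (k21 + k20) A2

with `k10 = Cl1/V1` (renal or renal-replacement elimination from plasma),
`k12 = Q/V1`, `k21 = Q/V2` (plasma–peritoneum exchange), and
`k20 = Cl2/V2` (drug removed with peritoneal fluid by the VAC system).
Concentrations are unbound throughout; units are mg, L, h, mg/L.  The
input is piecewise-constant (a 30-min loading infusion, then a
continuous infusion), so every segment is solved exactly with the
closed-form 2×2 matrix exponential; `simulate_profile` is therefore exact
to floating point, and the steady state has the closed forms

    C1ss = R / (Cl1 + Q·Cl2/(Q + Cl2)),     C2ss/C1ss = Q / (Q + Cl2).

The second identity says the steady-state peritoneal-to-plasma partition
is set purely by the competition between back-transfer (Q) and VAC
removal (Cl2) — it is the backbone of several tests and of the PTA
engine.

Intercompartmental clearance Q is carried in L/h (consistent with the
parameter table's units); treating it as a first-order constant in 1/h
would contradict the reported magnitudes.

## Population model

All individual parameters are log-normal.  For piperacillin:

    log V1  = log V1pop + βage·age + βwt·weight + ηV1
    log Cl1 = log Cl1pop + βB·[cat=B] + βC·[cat=C] + ηCl1 + η_occ,Cl1
    log Cl2 = log Cl2pop + ηCl2
    V2 fixed (5 L);  Q a single population value (no random effect)

Tazobactam is identical except V1 has no covariates and Q is fixed at
20 L/h.  Renal-function categories: A = normal (reference), B = CRRT,
C = moderate impairment, D = augmented renal clearance, with D pooled
into A.  Covariates enter uncentered, exactly as the model equations are
written; the published parameter sets are shipped as
`piperacillin_params()` / `tazobactam_params()`.  Inter-occasion
variability (SD γ) applies to Cl1 only, with occasion 1 covering the
loading dose and occasion 2 the steady-state sampling window; the switch
is placed at 24 h, and the kinetic state is carried across it so
profiles are continuous.  Observations follow a proportional error model
`y = c(1 + b·ε)` with separate coefficients for plasma (bC1) and
peritoneal (bC2) samples; negative draws are floored at zero with a
warning, since the proportional model is otherwise unbounded below at
large b.

A centered-covariate variant is not implemented: all estimation here is
exercised through self-consistent simulate-then-fit loops, so a single
coding, used consistently, is sufficient; fitting external datasets
produced under a centered coding would require re-expressing their
intercepts.

## Synthetic cohort

No patient-level data are available, so `generate_cohort` emulates the
study design: 45 patients by default; renal categories drawn with
probabilities 22/45, 12/45, 8/45, 3/45 (A/B/C/D); age and total body
weight drawn from normal approximations matched to the published median
and interquartile range (σ ≈ IQR/1.349, truncated to 18–95 y and
40–160 kg); regimens assigned by category (A,B → 16 g/2 g per day,
C → 12 g/1.5 g, D → 20 g/2.5 g, all after a 4 g/0.5 g load over 30 min);
a plasma sample at the end of the load (T0) and plasma + peritoneal
samples at T1 ~ Uniform(48, 72) h.  Pooled VAC-fluid and urine
collections over [T0, T1] are mass-balance summaries of the simulated
profile (collected amount = ∫ clearance × concentration dt, divided by
the collected volume, with daily fluid productions of 1–3 L VAC and
1–4 L urine); a capture fraction `f_vac` (default 1, i.e. model-faithful)
scales the VAC recovery, since a calibration near 0.13 is needed to
reproduce clinically reported calculated VAC clearances — the
discrepancy between the model's peritoneal clearance and the much
smaller ratio-based VAC clearance observed clinically is surfaced as a
parameter, not resolved.  Observations below the assay quantification
limits (0.5 mg/L piperacillin, 1.5 mg/L tazobactam) are flagged and
excluded from fitting (M1 handling).  Below-quantification handling,
pre-dose troughs for patients already on treatment (off by default), and
all distributions are `CohortDesign` fields.

What the generator does not emulate: assay batch effects, time-varying
covariates within an occasion, drug degradation in the VAC canister, and
CRRT circuit mechanics.  Passing recovery tests therefore demonstrates
the internal consistency of the estimator with this generative model,
not fidelity to any particular clinical dataset.

## Estimation

`fit_population` implements a stochastic-approximation EM (SAEM):

* **E-step** — per subject, Metropolis-within-Gibbs over the latent
  vector (ηV1, ηCl1, κ_occ1, κ_occ2, ηCl2), with per-latent adaptive
  proposal scales (targeting ~35% acceptance) plus a joint proposal that
  moves all latents together (the component-wise kernel cannot walk
  ridges).
* **M-step** — the population layer is linear Gaussian in the individual
  log-parameters, so fixed effects are closed-form (penalised)
  regressions on smoothed sufficient statistics; the Cl1 occasion pair
  is compound-symmetric and its MLE splits into a between/within
  decomposition; error coefficients come from relative residuals.
* **MAP priors** — normal priors on V1pop (both drugs) and, for
  piperacillin, Qpop, centred at 20 with the published SDs (1, 5, 3),
  enter as one-off penalties.
* **Q without variability** — during burn-in Q receives an artificial
  per-subject variability annealed to zero, so it co-moves with the
  latents (the standard device for no-variability parameters); during
  the smoothing phase it is refined by a penalised 1-D profile search.
* **Annealing and guards** — residual and random-effect SDs may not
  shrink faster than a geometric schedule during burn-in (keeps the
  kernel mobile, permits near-noiseless data), may not grow more than
  20% per iteration (blocks a runaway of weakly identified variances on
  small datasets), and are floored at 1e-4 so latents are never
  permanently pinned by a transient collapse.
* **Model selection over the trajectory** — SAEM trajectories are not
  monotone in the marginal likelihood, so the fit checkpoints the
  MAP-penalised Laplace marginal along the smoothing phase (including
  the initial state) and returns the best state seen.  A fit
  warm-started from a nested model's estimate can therefore never end
  worse than that estimate, which makes likelihood-ratio statistics
  non-negative by construction.
* **Noise-free endgame** — when the estimated proportional errors fall
  below 0.1 the latent posterior is effectively a point mass and EM
  stalls on a saddle (misfit absorbed by the error term is invisible to
  the Gaussian-layer M-step); the fit then switches to a deterministic
  profile optimisation of the fixed effects (BFGS plus a simplex
  finisher) with the error terms refreshed from the residuals at the
  latent modes.  Realistic fits (b ≈ 0.2–0.4) never enter this branch.

The marginal log-likelihood is a Laplace approximation at the
empirical-Bayes modes, with the per-subject log-determinant bounded
below by the latent prior precision (the marginal can never exceed the
data likelihood at the mode; this also repairs indefinite
finite-difference Hessians).  `lrt_compare` refers 2·ΔlogL to χ²(df)
with retention at p < 0.05.  Standard errors are a stochastic
approximation of the Fisher information — outer products of per-subject
posterior-mean complete-data scores accumulated over the smoothing
phase, with MAP prior precisions added; they are descriptive, and
`bootstrap_ci` (subject-level resampling, percentile intervals, default
1000 replicates, failures counted and excluded) is the reference
uncertainty measure.

Default iteration counts (300 burn-in + 150 smoothing, 2 MH sweeps per
iteration) fit a 200-subject sparse-design cohort in 2–3 minutes on one
CPU; replicate studies (bootstrap, type-I-error experiments) use smaller
budgets set at the call site.

### Identifiability of Q and Cl2

With V2 = 5 L and Q ≈ 20–24 L/h the peritoneal compartment equilibrates
with a half-life of ~8 minutes.  A design whose earliest sample is at
the end of the 30-min load therefore carries almost no information about
Q: in self-consistent recovery experiments the penalized marginal
likelihood is nearly flat in (Q, Cl2) at a fixed partition ratio, the Q
posterior is dominated by its MAP prior, and Cl2 = Q(1−r)/r inherits a
downward bias of roughly 15–25%.  This is a property of the sparse
design, not of the code — recovering the clearances requires samples
during the distribution phase, which is how the clearance-recovery
experiments in `scripts/acceptance.py` are designed.  Relatedly, the
log-effect of a renal category whose clearance is a negligible share of
elimination (category-B tazobactam, 0.026 L/h of ~2.6 L/h total) is a
one-sided bound rather than a point estimate, for any estimator.

## Diagnostics

`diagnostics` simulates `n_sim` replicate datasets under the model:
IWRES from the empirical-Bayes predictions, simulation-based population
weighted residuals, NPDE via per-subject decorrelation (Cholesky of the
simulated covariance) and the inverse-normal rank transform (clamped to
(1/2K, 1−1/2K)), and a prediction-corrected VPC binned on the population
prediction (observed 10/50/90th percentiles against simulated 90%
bands).  NPDE is refused below 50 simulations.  On self-simulated data
the NPDE is standard normal; the acceptance suite checks mean, variance
and tail mass at ~2000 observations.

## PTA / FTA engine

Under a continuous infusion the 100% fT>MIC target is equivalent to
Css > MIC, so `simulate_pta` evaluates the closed-form steady state for
each of n = 10,000 Monte Carlo patients (covariates from the cohort
design distributions, fresh inter-individual effects, one
occasion-level Cl1 deviation so the variance matches a sampling window)
per renal group and regimen, over the MIC grids 1–64 mg/L (piperacillin)
and 0.125–16 mg/L (tazobactam), for both the MIC and 4×MIC target
families and both compartments.  Css exactly equal to the MIC counts as
failure.  Group D is merged into A and a standalone D run is refused.  A
time-course mode (simulating the load and taking the minimum
concentration over a horizon) exists for sensitivity analysis.  FTA
weights PTA by a MIC frequency distribution; success requires
FTA > 85% strictly; `ecoff_report` projects the grids at the ECOFF MICs
8 and 16 mg/L.

## Exposure metrics

`calculated_clearance` implements the ratio formula
(volume × fluid concentration)/(serum Css × duration); at steady state
with full capture it recovers Cl1 from urine and the effective VAC
clearance Cl2·Q/(Q+Cl2) from VAC fluid — the identity holds within 5%
once the collection interval is long enough that the loading transient
is a negligible share of the pooled amount (the T0–T1 interval of the
clinical design contributes a ~5–7% transient surplus).  The peritoneal
diffusion ratio is 100·C2ss/C1ss.  Empirical underdosing is a strict
threshold on the peritoneal steady-state concentration: 16 mg/L for
piperacillin; for tazobactam both printed profiles are available
(2 mg/L default, 4 mg/L as `high_level_blp`).

## Known limitations

* SAEM on near-unidentifiable corners (variance splits between IIV and
  IOV from one occasion-pair observation; Q from post-distribution
  samples) returns boundary or prior-dominated values — flagged above.
* Standard errors are first-order and can understate uncertainty for
  variance parameters; use the bootstrap.
* The workflow runs single-process; Monte Carlo and bootstrap seeds are
  per-task, so results do not depend on any parallelism.
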