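"""Population estimation for the plasma-peritoneal model.

The estimator is a stochastic-approximation EM (SAEM) scheme in the
style long established for nonlinear mixed-effects models:

* E-step — per subject, a Metropolis-within-Gibbs kernel samples the
  log-scale random effects (eta_V1, eta_Cl1, kappa_occ1, kappa_occ2,
  eta_Cl2) from their conditional posterior given the data and current
  population parameters, with per-latent adaptive proposal scales.
* M-step — because all individual parameters are log-normal, the
  population layer is a linear Gaussian model in the sampled individual
  log-parameters ("phi"), so fixed effects and variabilities have
  closed-form updates from smoothed sufficient statistics.  Cl1 carries
  inter-occasion variability: its two per-occasion log-values form a
  compound-symmetric bivariate normal whose MLE splits into a
  between/within decomposition.
* Normal MAP priors on selected fixed effects (V1pop and, for
  piperacillin, Qpop) enter as one-off penalties; parameters without
  random effects (Q) are updated by a penalised profile search over the
  conditional data likelihood.
* Residual variances are annealed downward during burn-in (they may not
  shrink faster than a geometric schedule), which keeps the MCMC kernel
  mobile early on and permits near-noiseless datasets to be fitted.

The marginal log-likelihood is computed by a Laplace approximation at the
empirical-Bayes modes, which makes likelihood-ratio comparisons between
nested covariate models deterministic given the fits.  Standard errors
come from a stochastic approximation of the Fisher information (outer
products of per-subject posterior-mean complete-data scores, with MAP
prior precisions added).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .population import (
    OCCASION_SWITCH_H,
    PopulationParams,
    RandomEffects,
)
from .structural import DoseSchedule, propagate_segment

__all__ = [
    "FitSpec",
    "FitResult",
    "DiagnosticsBundle",
    "IdentifiabilityError",
    "fit_population",
    "lrt_compare",
    "bootstrap_ci",
    "diagnostics",
    "default_init",
]

_LOG2PI = math.log(2.0 * math.pi)
_SD_FLOOR = 1e-6          # smallest admissible error SD
_OMEGA_FLOOR = 1e-4       # smallest admissible random-effect SD: keeps the
                          # latents alive so a transient variance collapse
                          # during estimation cannot permanently pin them
_ACTIVE_SD = 1e-5         # latents with prior SD below this are pinned at 0


class IdentifiabilityError(ValueError):
    """Raised when the requested covariate model is not identifiable."""


# ---------------------------------------------------------------------------
# Fit specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitSpec:
    """What to estimate, what to fix, and how hard to try.

    ``v1_covariates`` is a subset of ("age", "weight"); ``cl1_covariates``
    a subset of ("catB", "catC", "age", "weight").  ``fix_q`` pins the
    intercompartmental clearance; otherwise ``q_prior`` (mean, sd) defines
    a normal MAP prior for its estimation.  ``v1_prior`` is the normal MAP
    prior on V1pop.  V2 is always fixed at ``v2_value``.
    """

    drug: str
    v1_covariates: tuple = ()
    cl1_covariates: tuple = ("catB", "catC")
    fix_q: float | None = None
    q_prior: tuple | None = None
    v1_prior: tuple | None = None
    v2_value: float = 5.0
    estimate_iov: bool = True
    n_burn: int = 300
    n_smooth: int = 150
    mcmc_sweeps: int = 2
    seed: int = 0
    occasion_switch: float = OCCASION_SWITCH_H

    @classmethod
    def for_drug(cls, drug: str, **overrides) -> "FitSpec":
        """The final-model specification for either drug."""
        if drug == "piperacillin":
            base = dict(
                drug=drug,
                v1_covariates=("age", "weight"),
                cl1_covariates=("catB", "catC"),
                fix_q=None,
                q_prior=(20.0, 3.0),
                v1_prior=(20.0, 1.0),
            )
        elif drug == "tazobactam":
            base = dict(
                drug=drug,
                v1_covariates=(),
                cl1_covariates=("catB", "catC"),
                fix_q=20.0,
                q_prior=None,
                v1_prior=(20.0, 5.0),
            )
        else:
            raise ValueError(f"unknown drug {drug!r}")
        base.update(overrides)
        return cls(**base)


def default_init(spec: FitSpec) -> PopulationParams:
    """Generic, deliberately vague starting values for a fit."""
    return PopulationParams(
        drug=spec.drug,
        V1pop=20.0, V2pop=spec.v2_value,
        Qpop=spec.fix_q if spec.fix_q is not None else 20.0,
        Cl1pop=10.0, Cl2pop=3.0,
        omegaV1=0.3, omegaCl1=0.3, omegaCl2=0.3,
        gammaCl1=0.3 if spec.estimate_iov else 0.0,
        bC1=0.3, bC2=0.3,
    )


# ---------------------------------------------------------------------------
# Dataset parsing and the fast per-subject predictor
# ---------------------------------------------------------------------------

class _Subj:
    """Pre-compiled per-subject data: observation arrays and a propagation plan."""

    __slots__ = (
        "sid", "obs_t", "obs_y", "obs_comp", "obs_occ", "plan",
        "x_v1", "x_cl1", "category", "age", "weight",
    )

    def __init__(self, sid, obs, doses, age, weight, category, spec):
        self.sid = sid
        self.age = age
        self.weight = weight
        self.category = category
        obs = sorted(obs, key=lambda o: (o[0], o[1]))
        self.obs_t = [o[0] for o in obs]
        self.obs_comp = [o[1] for o in obs]          # 0 plasma, 1 peritoneal
        self.obs_y = [o[2] for o in obs]
        sched = DoseSchedule(tuple(doses))
        t_max = self.obs_t[-1]
        switch = spec.occasion_switch
        marks = sorted(
            {b for b in sched.breakpoints() if 0.0 < b < t_max}
            | {switch}
            | set(self.obs_t)
        )
        marks = [m for m in marks if 0.0 < m <= t_max]
        plan = []
        prev = 0.0
        for m in marks:
            occ = 0 if prev < switch else 1
            emits = [
                (j, self.obs_comp[j])
                for j, tt in enumerate(self.obs_t)
                if tt == m
            ]
            plan.append((m - prev, sched.rate_at(prev), occ, emits))
            prev = m
        self.plan = plan
        cat = "A" if category == "D" else category
        cov = {"age": age, "weight": weight,
               "catB": 1.0 if cat == "B" else 0.0,
               "catC": 1.0 if cat == "C" else 0.0}
        self.x_v1 = np.array([cov[c] for c in spec.v1_covariates])
        self.x_cl1 = np.array([cov[c] for c in spec.cl1_covariates])
        self.obs_occ = [0 if t < switch else 1 for t in self.obs_t]


def _predict_subj(subj, v1, cl1_occ, cl2, q, v2):
    """Predicted concentrations at the subject's observation times."""
    out = [0.0] * len(subj.obs_t)
    a1 = a2 = 0.0
    k12 = q / v1
    k21 = q / v2
    k20 = cl2 / v2
    for dt, rate, occ, emits in subj.plan:
        k10 = cl1_occ[occ] / v1
        a1, a2 = propagate_segment(k10, k12, k21, k20, rate, a1, a2, dt)
        for j, comp in emits:
            out[j] = a1 / v1 if comp == 0 else a2 / v2
    return out


def _data_ll(subj, preds, b1, b2):
    ll = 0.0
    for y, f, comp in zip(subj.obs_y, preds, subj.obs_comp):
        b = b1 if comp == 0 else b2
        sd = b * f
        if sd <= 0.0:
            return -math.inf
        u = (y - f) / sd
        ll += -0.5 * u * u - math.log(sd) - 0.5 * _LOG2PI
    return ll


def _parse_dataset(dataset: pd.DataFrame, spec: FitSpec,
                   check_identifiability: bool = True) -> list[_Subj]:
    df = dataset[dataset["DRUG"] == spec.drug]
    if df.empty:
        raise ValueError(f"dataset has no rows for drug {spec.drug!r}")
    subs = []
    for sid, g in df.groupby("ID"):
        doses = [
            (r.TIME, r.DUR, r.RATE)
            for r in g[g["EVID"] == 1].itertuples()
        ]
        obs_rows = g[
            (g["EVID"] == 0)
            & (g["MDV"] == 0)
            & (g["MATRIX"].isin(["plasma", "peritoneal"]))
            & (g["LLOQ_FLAG"] == 0)
        ]
        obs = []
        for r in obs_rows.itertuples():
            if r.TIME <= 0:
                continue  # pre-dose troughs carry no information for a drug-naive model
            obs.append((float(r.TIME), 0 if r.MATRIX == "plasma" else 1, float(r.DV)))
        if not obs or not doses:
            continue
        first = g.iloc[0]
        subs.append(_Subj(sid, obs, doses, float(first.AGE), float(first.WT),
                          str(first.RENAL_CAT), spec))
    n_plasma = sum(1 for s in subs if any(c == 0 for c in s.obs_comp))
    if n_plasma < 2:
        raise ValueError("need at least 2 subjects with plasma observations")
    for name, X in (("V1", np.array([s.x_v1 for s in subs])),
                    ("Cl1", np.array([s.x_cl1 for s in subs]))):
        if X.shape[1] and check_identifiability:
            full = np.column_stack([np.ones(len(subs)), X])
            if np.linalg.matrix_rank(full) < full.shape[1]:
                raise IdentifiabilityError(
                    f"covariate design for {name} is rank deficient "
                    "(e.g. all subjects in one renal category with category effects free)"
                )
    return subs


# ---------------------------------------------------------------------------
# Fit result containers
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of a population fit."""

    params: PopulationParams
    spec: FitSpec
    betas_v1: dict
    betas_cl1: dict
    se: dict
    rse: dict
    loglik: float
    ebes: dict                      # subject id -> RandomEffects
    converged: bool
    trace: pd.DataFrame
    n_subjects: int
    n_obs: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, val in self._named_estimates():
            se = self.se.get(name, float("nan"))
            rse = self.rse.get(name, float("nan"))
            rows.append({"parameter": name, "estimate": val, "se": se, "rse_pct": rse})
        return pd.DataFrame(rows)

    def _named_estimates(self):
        p = self.params
        out = [("V1pop", p.V1pop)]
        out += [(f"betaV1_{c}", b) for c, b in self.betas_v1.items()]
        out += [("V2pop", p.V2pop), ("Qpop", p.Qpop), ("Cl1pop", p.Cl1pop)]
        out += [(f"betaCl1_{c}", b) for c, b in self.betas_cl1.items()]
        out += [("Cl2pop", p.Cl2pop),
                ("omegaV1", p.omegaV1), ("omegaCl1", p.omegaCl1),
                ("omegaCl2", p.omegaCl2), ("gammaCl1", p.gammaCl1),
                ("bC1", p.bC1), ("bC2", p.bC2)]
        return out


# ---------------------------------------------------------------------------
# The SAEM engine
# ---------------------------------------------------------------------------

class _State:
    """Mutable population-parameter state during SAEM."""

    def __init__(self, spec: FitSpec, init: PopulationParams):
        self.spec = spec
        self.mu_v1 = math.log(init.V1pop)
        self.beta_v1 = np.array(
            [getattr(init, f"betaV1_{c}", 0.0) for c in spec.v1_covariates]
        )
        self.mu_cl1 = math.log(init.Cl1pop)
        self.beta_cl1 = np.array(
            [_init_beta(init, c) for c in spec.cl1_covariates]
        )
        self.mu_cl2 = math.log(init.Cl2pop)
        self.q = spec.fix_q if spec.fix_q is not None else init.Qpop
        self.v2 = spec.v2_value
        self.om_v1 = max(init.omegaV1, _SD_FLOOR)
        self.om_cl1 = max(init.omegaCl1, _SD_FLOOR)
        self.om_cl2 = max(init.omegaCl2, _SD_FLOOR)
        self.gam = max(init.gammaCl1, _SD_FLOOR) if spec.estimate_iov else 0.0
        self.b1 = max(init.bC1, _SD_FLOOR)
        self.b2 = max(init.bC2, _SD_FLOOR)
        # artificial variability on Q during burn-in (annealed to zero);
        # lets a no-variability parameter co-move with the latents
        self.om_q = 0.0

    _FIELDS = ("mu_v1", "beta_v1", "mu_cl1", "beta_cl1", "mu_cl2", "q",
               "om_v1", "om_cl1", "om_cl2", "gam", "b1", "b2", "om_q")

    def snapshot(self) -> dict:
        return {f: (getattr(self, f).copy()
                    if isinstance(getattr(self, f), np.ndarray)
                    else getattr(self, f))
                for f in self._FIELDS}

    def restore(self, snap: dict) -> None:
        for f, v in snap.items():
            setattr(self, f, v.copy() if isinstance(v, np.ndarray) else v)

    def prior_sds(self):
        return (self.om_v1, self.om_cl1, self.gam, self.gam, self.om_cl2,
                self.om_q)

    def indiv(self, subj, v):
        """(V1, (Cl1_occ1, Cl1_occ2), Cl2) for latent vector v.

        Log-parameters are clamped to +/-40 so that stray optimizer
        proposals cannot overflow the kinetics.
        """
        v1 = _cexp(self.mu_v1 + float(subj.x_v1 @ self.beta_v1) + v[0])
        base = self.mu_cl1 + float(subj.x_cl1 @ self.beta_cl1) + v[1]
        cl1 = (_cexp(base + v[2]), _cexp(base + v[3]))
        cl2 = _cexp(self.mu_cl2 + v[4])
        q = self.q * math.exp(v[5]) if v[5] else self.q
        return v1, cl1, cl2, q

    def to_params(self) -> PopulationParams:
        spec = self.spec
        kw = dict(
            drug=spec.drug,
            V1pop=math.exp(self.mu_v1),
            V2pop=self.v2,
            Qpop=self.q,
            Cl1pop=math.exp(self.mu_cl1),
            Cl2pop=math.exp(self.mu_cl2),
            omegaV1=_zero_floor(self.om_v1),
            omegaCl1=_zero_floor(self.om_cl1),
            omegaCl2=_zero_floor(self.om_cl2),
            gammaCl1=_zero_floor(self.gam),
            bC1=self.b1,
            bC2=self.b2,
            fixed=tuple(
                ["V2pop"] + (["Qpop"] if spec.fix_q is not None else [])
            ),
            map_priors={
                k: v for k, v in (
                    ("V1pop", spec.v1_prior), ("Qpop", spec.q_prior)
                ) if v is not None
            },
        )
        for c, b in zip(spec.v1_covariates, self.beta_v1):
            kw[f"betaV1_{c}"] = float(b)
        for c, b in zip(spec.cl1_covariates, self.beta_cl1):
            if c in ("catB", "catC"):
                kw[f"betaCl1_{c}"] = float(b)
            elif c == "age":
                kw["betaCl1_age"] = float(b)
        return PopulationParams(**kw)


def _init_beta(init, c):
    if c == "catB":
        return init.betaCl1_catB
    if c == "catC":
        return init.betaCl1_catC
    if c == "age":
        return init.betaCl1_age
    return 0.0


def _zero_floor(sd):
    return 0.0 if sd <= 2 * _SD_FLOOR else sd


def _cexp(x):
    return math.exp(min(max(x, -40.0), 40.0))


def _subject_ll(state, subj, v):
    v1, cl1, cl2, q = state.indiv(subj, v)
    try:
        preds = _predict_subj(subj, v1, cl1, cl2, q, state.v2)
    except (ZeroDivisionError, OverflowError):
        return -math.inf      # degenerate kinetics from a stray proposal
    ll = _data_ll(subj, preds, state.b1, state.b2)
    return ll if not math.isnan(ll) else -math.inf


def fit_population(
    dataset: pd.DataFrame,
    spec: FitSpec,
    init: PopulationParams | None = None,
) -> FitResult:
    """Fit the population model to a long-format dataset by SAEM.

    Only plasma and peritoneal observation rows enter the likelihood;
    VAC-fluid and urine rows, dose rows, and below-LLOQ observations are
    excluded.  The run is deterministic for a fixed ``spec.seed``.
    """
    if init is None:
        init = default_init(spec)
    subs = _parse_dataset(dataset, spec)
    state = _State(spec, init)
    rng = np.random.default_rng(spec.seed)
    n = len(subs)
    n_lat = 6

    # per-subject latent state and adaptive proposal scales
    lat = np.zeros((n, n_lat))
    scales = np.full((n, n_lat + 1), 0.4)   # last column: joint proposal
    acc = np.zeros((n, n_lat + 1))
    tries = np.zeros((n, n_lat + 1))
    cur_ll = np.array([_subject_ll(state, s, lat[i]) for i, s in enumerate(subs)])

    X_v1 = np.column_stack([np.ones(n)] + [np.array([s.x_v1 for s in subs]).T[j]
                                           for j in range(len(spec.v1_covariates))]) \
        if spec.v1_covariates else np.ones((n, 1))
    X_cl1 = np.column_stack([np.ones(n)] + [np.array([s.x_cl1 for s in subs]).T[j]
                                            for j in range(len(spec.cl1_covariates))]) \
        if spec.cl1_covariates else np.ones((n, 1))
    XtX_v1 = X_v1.T @ X_v1
    XtX_cl1 = X_cl1.T @ X_cl1
    n_obs_c = [sum(1 for s in subs for c in s.obs_comp if c == comp)
               for comp in (0, 1)]

    trace_rows = []
    total_iter = spec.n_burn + spec.n_smooth
    anneal0 = dict(om_v1=state.om_v1, om_cl1=state.om_cl1, om_cl2=state.om_cl2,
                   gam=state.gam, b1=state.b1, b2=state.b2)

    box = {"stats": None, "score_sum": None, "score_n": 0, "alpha_k": 0}

    def active_latents():
        prior_sds = state.prior_sds()
        act = [j for j, sd in enumerate(prior_sds) if sd >= _ACTIVE_SD]
        if not spec.estimate_iov:
            act = [j for j in act if j not in (2, 3)]
        return act, prior_sds

    def refresh_ll():
        cur_ll[:] = [_subject_ll(state, s, lat[i]) for i, s in enumerate(subs)]

    def e_step(it):
        act, prior_sds = active_latents()
        for _ in range(spec.mcmc_sweeps):
            for j in act:
                sd = prior_sds[j]
                step = scales[:, j] * rng.standard_normal(n)
                for i, s in enumerate(subs):
                    prop = lat[i].copy()
                    prop[j] += step[i]
                    new_ll = _subject_ll(state, s, prop)
                    if not math.isfinite(cur_ll[i]):
                        d = 0.0 if math.isfinite(new_ll) else -math.inf
                    else:
                        d = (new_ll - cur_ll[i]
                             - 0.5 * (prop[j] ** 2 - lat[i, j] ** 2) / sd ** 2)
                    tries[i, j] += 1
                    if d >= 0 or rng.random() < math.exp(max(d, -700.0)):
                        lat[i, j] = prop[j]
                        cur_ll[i] = new_ll
                        acc[i, j] += 1
            # joint proposal: correlated move across all active latents,
            # helps along the ridges the component-wise kernel cannot walk
            zj = rng.standard_normal((n, len(act)))
            for i, s in enumerate(subs):
                prop = lat[i].copy()
                prop[act] += scales[i, n_lat] * zj[i] * 0.5
                new_ll = _subject_ll(state, s, prop)
                if not math.isfinite(cur_ll[i]):
                    d = 0.0 if math.isfinite(new_ll) else -math.inf
                else:
                    d = new_ll - cur_ll[i]
                    for j in act:
                        d -= 0.5 * (prop[j] ** 2 - lat[i, j] ** 2) / prior_sds[j] ** 2
                tries[i, n_lat] += 1
                if d >= 0 or rng.random() < math.exp(max(d, -700.0)):
                    lat[i] = prop
                    cur_ll[i] = new_ll
                    acc[i, n_lat] += 1
        # adapt proposal scales toward ~35% acceptance
        if it % 20 == 0:
            with np.errstate(invalid="ignore"):
                rate = np.where(tries > 0, acc / np.maximum(tries, 1), 0.35)
            scales[:] = np.clip(scales * np.exp(0.6 * (rate - 0.35)), 1e-8, 5.0)
            acc[:] = 0.0
            tries[:] = 0.0

    def iteration(it, *, burn, freeze_fixed=False, collect_scores=False,
                  smooth_k=None):
        if spec.fix_q is None and burn:
            state.om_q = 0.4 * ((1e-5) ** (1.0 / max(spec.n_burn, 1))) ** it
        else:
            state.om_q = 0.0
            lat[:, 5] = 0.0
        e_step(it)
        # In the effectively noise-free regime the latent posterior
        # collapses to its mode and a random-walk kernel would need
        # O((shift/width)^2) iterations to track it, so snap each
        # subject's latents to their joint-posterior mode instead; with
        # realistic residual error this never triggers and the posterior
        # is explored by MCMC alone.
        noise_free = max(state.b1, state.b2) < 0.1
        if noise_free and it % 5 == 0:
            act, prior_sds = active_latents()
            if act:
                for i, s in enumerate(subs):
                    res = optimize.minimize(
                        lambda v: _joint_neg(state, s, v, act, prior_sds),
                        lat[i, act], method="Nelder-Mead",
                        options={"maxiter": 150, "fatol": 1e-10},
                    )
                    if res.fun <= _joint_neg(state, s, lat[i, act], act,
                                             prior_sds):
                        lat[i, act] = res.x
                refresh_ll()
        off_v1 = X_v1 @ np.concatenate([[state.mu_v1], state.beta_v1])
        off_cl1 = X_cl1 @ np.concatenate([[state.mu_cl1], state.beta_cl1])
        z_v1 = off_v1 + lat[:, 0]
        z1 = off_cl1 + lat[:, 1] + lat[:, 2]
        z2 = off_cl1 + lat[:, 1] + lat[:, 3]
        z_cl2 = state.mu_cl2 + lat[:, 4]
        m = 0.5 * (z1 + z2)
        res_c = [0.0, 0.0]
        for i, s in enumerate(subs):
            v1, cl1, cl2, q_i = state.indiv(s, lat[i])
            preds = _predict_subj(s, v1, cl1, cl2, q_i, state.v2)
            for y, f, comp in zip(s.obs_y, preds, s.obs_comp):
                if f > 0 and math.isfinite(f):
                    res_c[comp] += ((y - f) / f) ** 2
        z_q = math.log(state.q) + lat[:, 5]
        cur = {
            "Szx_v1": X_v1.T @ z_v1, "Szz_v1": float(z_v1 @ z_v1),
            "Sxm": X_cl1.T @ m, "Smm": float(m @ m),
            "Sdd": float(((z1 - z2) ** 2).sum()),
            "S1_cl2": float(z_cl2.sum()), "S2_cl2": float(z_cl2 @ z_cl2),
            "S1_q": float(z_q.mean()),
            "res1": res_c[0], "res2": res_c[1],
        }
        if burn or smooth_k is None:
            alpha = 1.0
        else:
            alpha = 1.0 / smooth_k ** 0.75
        if box["stats"] is None or (burn and alpha == 1.0):
            box["stats"] = cur
        else:
            box["stats"] = {k: (1 - alpha) * box["stats"][k] + alpha * cur[k]
                            for k in box["stats"]}
        _mstep(state, spec, box["stats"], XtX_v1, XtX_cl1, n, n_obs_c,
               freeze_fixed=freeze_fixed)
        if spec.fix_q is None and not freeze_fixed:
            if burn:
                # closed-form-ish update against the artificial Q layer
                _update_q_latent(state, spec, box["stats"]["S1_q"], n)
            else:
                _update_q(state, spec, subs, lat, alpha)
        if burn:
            # annealing: variances may not collapse faster than a geometric
            # schedule reaching ~1e-5 of their start by the end of burn-in
            fac = ((1e-5) ** (1.0 / max(spec.n_burn, 1))) ** it
            state.om_v1 = max(state.om_v1, anneal0["om_v1"] * fac)
            state.om_cl1 = max(state.om_cl1, anneal0["om_cl1"] * fac)
            state.om_cl2 = max(state.om_cl2, anneal0["om_cl2"] * fac)
            if spec.estimate_iov:
                state.gam = max(state.gam, anneal0["gam"] * fac)
            state.b1 = max(state.b1, anneal0["b1"] * fac)
            state.b2 = max(state.b2, anneal0["b2"] * fac)
        refresh_ll()
        row = {
            "iteration": len(trace_rows) + 1, "V1pop": math.exp(state.mu_v1),
            "Cl1pop": math.exp(state.mu_cl1), "Cl2pop": math.exp(state.mu_cl2),
            "Qpop": state.q, "omegaV1": state.om_v1, "omegaCl1": state.om_cl1,
            "omegaCl2": state.om_cl2, "gammaCl1": state.gam,
            "bC1": state.b1, "bC2": state.b2,
        }
        for c_, b_ in zip(spec.v1_covariates, state.beta_v1):
            row[f"betaV1_{c_}"] = float(b_)
        for c_, b_ in zip(spec.cl1_covariates, state.beta_cl1):
            row[f"betaCl1_{c_}"] = float(b_)
        trace_rows.append(row)
        if collect_scores:
            sc = _complete_scores(state, spec, subs, lat,
                                  z_v1, z1, z2, z_cl2, off_v1, off_cl1)
            box["score_sum"] = sc if box["score_sum"] is None \
                else box["score_sum"] + sc
            box["score_n"] += 1

    def penalized_marginal():
        _, _, ll = _laplace_loglik(state, spec, subs, lat, maxiter=600)
        score = ll
        if spec.v1_prior is not None:
            pm, psd = spec.v1_prior
            score += -0.5 * ((_cexp(state.mu_v1) - pm) / psd) ** 2
        if spec.fix_q is None and spec.q_prior is not None:
            pm, psd = spec.q_prior
            score += -0.5 * ((state.q - pm) / psd) ** 2
        return score

    # The stochastic trajectory is not monotone in the marginal likelihood
    # and can wander between optima; checkpoint the (MAP-penalised)
    # marginal along the smoothing phase and keep the best state seen.
    best = {"score": -math.inf, "snap": None, "lat": None}

    def checkpoint():
        score = penalized_marginal()
        if score > best["score"]:
            best["score"] = score
            best["snap"] = state.snapshot()
            best["lat"] = lat.copy()

    # the initial state is itself a candidate: a fit may never end worse
    # than where it started (relevant when warm-starting the full model of
    # a nested comparison from the reduced model's estimate)
    checkpoint()

    # phase 1: annealed burn-in; phase 2: smoothed stochastic approximation
    for it in range(1, spec.n_burn + 1):
        iteration(it, burn=True)
    ckpt_every = max(spec.n_smooth // 5, 10)
    for k in range(1, spec.n_smooth + 1):
        iteration(spec.n_burn + k, burn=False, collect_scores=True, smooth_k=k)
        if k % ckpt_every == 0 or k == spec.n_smooth:
            checkpoint()
    if best["snap"] is not None:
        state.restore(best["snap"])
        lat[:] = best["lat"]
        refresh_ll()

    # In the effectively noise-free regime the EM update of the fixed
    # effects can reach a saddle: with the latent variances collapsed the
    # latents are pinned at zero, any residual population-level misfit is
    # absorbed by the error terms, and the Gaussian-layer M-step no longer
    # feels it.  There the marginal likelihood reduces to a penalised
    # nonlinear regression, which a direct profile optimisation finishes.
    if max(state.b1, state.b2) < 0.1:
        for _ in range(3):
            _mode_refine(state, spec, subs, lat, n_obs_c)

    # ----- wrap up ------------------------------------------------------------
    trace = pd.DataFrame(trace_rows)
    converged = _check_convergence(trace, spec)
    _, ebes, loglik = _laplace_loglik(state, spec, subs, lat)
    se, rse = _standard_errors(state, spec, box["score_sum"], box["score_n"])
    params = state.to_params()
    betas_v1 = dict(zip(spec.v1_covariates, map(float, state.beta_v1)))
    betas_cl1 = dict(zip(spec.cl1_covariates, map(float, state.beta_cl1)))
    return FitResult(
        params=params, spec=spec, betas_v1=betas_v1, betas_cl1=betas_cl1,
        se=se, rse=rse, loglik=loglik, ebes=ebes, converged=converged,
        trace=trace, n_subjects=len(subs),
        n_obs=sum(len(s.obs_y) for s in subs),
    )


def _capped(new, old):
    """Limit per-iteration growth of a variability/error SD.

    A variance whose latents are weakly identified can run away under the
    un-smoothed burn-in update (looser prior -> wider latents -> larger
    sample variance); a generous multiplicative cap per iteration blocks
    the feedback loop while leaving plenty of room for genuine growth
    over the course of a run.  2.5 on a log-scale SD (>1000% CV) is far
    beyond anything physiological.
    """
    return min(new, max(old * 1.2, old + 0.02), 2.5)


def _mstep(state, spec, st, XtX_v1, XtX_cl1, n, n_obs_c, freeze_fixed=False):
    # --- V1: penalised Gaussian regression ---------------------------------
    theta0 = np.concatenate([[state.mu_v1], state.beta_v1])

    def rss(theta):
        return max(
            st["Szz_v1"] - 2 * theta @ st["Szx_v1"] + theta @ XtX_v1 @ theta,
            1e-12,
        )

    if freeze_fixed:
        theta = theta0
        om2 = rss(theta) / n
    elif spec.v1_prior is None:
        theta = np.linalg.solve(XtX_v1, st["Szx_v1"])
        om2 = rss(theta) / n
    else:
        pm, psd = spec.v1_prior
        om2 = max(state.om_v1 ** 2, _SD_FLOOR ** 2)
        theta = theta0
        for _ in range(3):
            def obj(th, om2=om2):
                return (rss(th) / (2 * om2)
                        + (math.exp(th[0]) - pm) ** 2 / (2 * psd ** 2))
            res = optimize.minimize(obj, theta, method="BFGS")
            theta = res.x
            om2 = rss(theta) / n
    state.mu_v1 = float(theta[0])
    state.beta_v1 = np.asarray(theta[1:])
    state.om_v1 = max(_capped(math.sqrt(max(om2, 0.0)), state.om_v1),
                      _OMEGA_FLOOR)

    # --- Cl1: compound-symmetric bivariate layer ----------------------------
    if freeze_fixed:
        theta = np.concatenate([[state.mu_cl1], state.beta_cl1])
    else:
        theta = np.linalg.solve(XtX_cl1, st["Sxm"])
    state.mu_cl1 = float(theta[0])
    state.beta_cl1 = np.asarray(theta[1:])
    sig_m2 = max(
        (st["Smm"] - 2 * theta @ st["Sxm"] + theta @ XtX_cl1 @ theta) / n, 0.0
    )
    if spec.estimate_iov:
        gam2 = st["Sdd"] / (2.0 * n)
        state.gam = max(_capped(math.sqrt(gam2), state.gam), _OMEGA_FLOOR)
        state.om_cl1 = max(
            _capped(math.sqrt(max(sig_m2 - gam2 / 2.0, 0.0)), state.om_cl1),
            _OMEGA_FLOOR,
        )
    else:
        state.gam = 0.0
        state.om_cl1 = max(_capped(math.sqrt(sig_m2), state.om_cl1),
                           _OMEGA_FLOOR)

    # --- Cl2 ----------------------------------------------------------------
    mu = st["S1_cl2"] / n
    state.mu_cl2 = float(mu)
    state.om_cl2 = max(
        _capped(math.sqrt(max(st["S2_cl2"] / n - mu * mu, 0.0)), state.om_cl2),
        _OMEGA_FLOOR,
    )

    # --- proportional error -------------------------------------------------
    if n_obs_c[0]:
        state.b1 = max(math.sqrt(st["res1"] / n_obs_c[0]), _SD_FLOOR)
    if n_obs_c[1]:
        state.b2 = max(math.sqrt(st["res2"] / n_obs_c[1]), _SD_FLOOR)


def _mode_refine(state, spec, subs, lat, n_obs_c):
    """Profile refinement of the fixed effects for near-noiseless data.

    Maximises, over the population means and covariate effects (and Q when
    estimated), the per-subject joint density profiled over the latents,
    plus the MAP prior terms.  Latent modes warm-start from the current
    sample; afterwards the error terms are refreshed from the residuals at
    the modes.  Only used when the estimated proportional errors are
    essentially zero, where the latent posterior is a point mass and this
    profile equals the marginal likelihood.
    """
    prior_sds = state.prior_sds()
    # latents whose prior SD is tiny contribute nothing to the profile but
    # would make the inner optimisation noisy: treat them as pinned here
    act = [j for j, sd in enumerate(prior_sds) if sd >= 1e-3]
    if not spec.estimate_iov:
        act = [j for j in act if j not in (2, 3)]
    theta0 = np.concatenate([
        [state.mu_v1], state.beta_v1, [state.mu_cl1], state.beta_cl1,
        [state.mu_cl2],
    ])
    if spec.fix_q is None:
        theta0 = np.append(theta0, math.log(state.q))
    warm = lat.copy()
    # floor the residual weights during the search: with near-zero errors
    # the optimum location is unchanged (residuals go to zero regardless)
    # but the curvature would otherwise overwhelm finite-difference
    # gradients
    state.b1 = max(state.b1, 1e-5)
    state.b2 = max(state.b2, 1e-5)

    def set_theta(th):
        k = 0
        state.mu_v1 = float(th[k]); k += 1
        nb = len(state.beta_v1)
        state.beta_v1 = np.asarray(th[k:k + nb]); k += nb
        state.mu_cl1 = float(th[k]); k += 1
        nb = len(state.beta_cl1)
        state.beta_cl1 = np.asarray(th[k:k + nb]); k += nb
        state.mu_cl2 = float(th[k]); k += 1
        if spec.fix_q is None:
            state.q = _cexp(float(th[k]))

    def neg(th):
        set_theta(th)
        tot = 0.0
        for i, s in enumerate(subs):
            if act:
                res = optimize.minimize(
                    lambda v: _joint_neg(state, s, v, act, prior_sds),
                    warm[i, act], method="Nelder-Mead",
                    options={"maxiter": 200, "fatol": 1e-10},
                )
                warm[i, act] = res.x
                tot += res.fun
            else:
                tot += _joint_neg(state, s, np.zeros(0), act, prior_sds)
        if spec.v1_prior is not None:
            pm, psd = spec.v1_prior
            tot += 0.5 * ((_cexp(state.mu_v1) - pm) / psd) ** 2
        if spec.fix_q is None and spec.q_prior is not None:
            pm, psd = spec.q_prior
            tot += 0.5 * ((state.q - pm) / psd) ** 2
        return tot if math.isfinite(tot) else 1e15

    if act:
        # inner latent optimisations make the objective noisy: use a
        # bounded direct-search method
        bounds = [(t - 1.5, t + 1.5) for t in theta0]
        res = optimize.minimize(
            neg, theta0, method="Powell", bounds=bounds,
            options={"maxfev": 60 * len(theta0), "xtol": 1e-6, "ftol": 1e-10},
        )
    else:
        # latents pinned: the profile is smooth; quasi-Newton makes the
        # big moves, a simplex pass finishes where the extreme curvature
        # ratio defeats finite-difference gradients
        res = optimize.minimize(neg, theta0, method="BFGS",
                                options={"maxiter": 500})
        res = optimize.minimize(
            neg, res.x, method="Nelder-Mead",
            options={"maxiter": 4000, "fatol": 1e-10, "xatol": 1e-8,
                     "adaptive": True},
        )
    if res.fun > neg(theta0):
        res.x = theta0
    set_theta(res.x)
    neg(res.x)                      # refresh warm-started modes at optimum
    lat[:] = warm
    # refresh the proportional errors from the residuals at the modes
    res_c = [0.0, 0.0]
    for i, s in enumerate(subs):
        v1, cl1, cl2, q_i = state.indiv(s, lat[i])
        preds = _predict_subj(s, v1, cl1, cl2, q_i, state.v2)
        for y, f, comp in zip(s.obs_y, preds, s.obs_comp):
            if f > 0 and math.isfinite(f):
                res_c[comp] += ((y - f) / f) ** 2
    if n_obs_c[0]:
        state.b1 = max(math.sqrt(res_c[0] / n_obs_c[0]), _SD_FLOOR)
    if n_obs_c[1]:
        state.b2 = max(math.sqrt(res_c[1] / n_obs_c[1]), _SD_FLOOR)


def _update_q_latent(state, spec, zbar, n):
    """Penalised update of Q from the sampled artificial Q-deviations.

    The sampled per-subject log-Q values have mean ``zbar``; with the
    artificial variability ``om_q`` their layer is Gaussian, so the
    update balances the sample mean against the MAP prior on Q.  The
    per-subject deviations are kept, so the sampled individual Q values
    shift with the population value exactly as the other latents do.
    """
    om_q = max(state.om_q, _SD_FLOOR)

    if spec.q_prior is None:
        state.q = _cexp(zbar)
        return

    pm, psd = spec.q_prior

    def obj(mu):
        return (n * (mu - zbar) ** 2 / (2.0 * om_q ** 2)
                + (_cexp(mu) - pm) ** 2 / (2.0 * psd ** 2))

    res = optimize.minimize_scalar(
        obj, bounds=(math.log(1.0), math.log(120.0)), method="bounded",
        options={"xatol": 1e-4},
    )
    state.q = _cexp(res.x)


def _update_q(state, spec, subs, lat, alpha):
    """Penalised profile update of Q over the conditional data likelihood."""

    def neg(q):
        old = state.q
        state.q = q
        tot = 0.0
        for i, s in enumerate(subs):
            tot += _subject_ll(state, s, lat[i])
        state.q = old
        if spec.q_prior is not None:
            pm, psd = spec.q_prior
            tot += -0.5 * ((q - pm) / psd) ** 2
        return -tot

    res = optimize.minimize_scalar(
        neg, bounds=(1.0, 120.0), method="bounded",
        options={"xatol": 1e-2, "maxiter": 25},
    )
    state.q = float(state.q + alpha * (res.x - state.q))


def _check_convergence(trace, spec):
    if len(trace) < 20:
        return False
    tail = trace.iloc[-max(spec.n_smooth // 2, 10):]
    for col in ("V1pop", "Cl1pop", "Cl2pop"):
        x = tail[col].to_numpy()
        if np.ptp(x) > 0.25 * max(abs(x.mean()), 1e-9):
            return False
    return True


# ---------------------------------------------------------------------------
# Laplace marginal log-likelihood and empirical-Bayes estimates
# ---------------------------------------------------------------------------

def _joint_neg(state, subj, v, active, prior_sds):
    full = np.zeros(6)
    full[active] = v
    ll = _subject_ll(state, subj, full)
    for j in active:
        ll += -0.5 * (full[j] / prior_sds[j]) ** 2 \
            - math.log(prior_sds[j]) - 0.5 * _LOG2PI
    return -ll


def _laplace_loglik(state, spec, subs, lat, maxiter=2000):
    """EBE modes and the Laplace approximation to the marginal log-likelihood.

    Returns ``(modes, ebes, loglik)`` where ``modes`` is the (n, 5) array
    of per-subject joint-posterior modes (inactive latents at zero).
    """
    prior_sds = state.prior_sds()
    active = [j for j, sd in enumerate(prior_sds) if sd >= _ACTIVE_SD]
    if not spec.estimate_iov:
        active = [j for j in active if j not in (2, 3)]
    total = 0.0
    ebes = {}
    modes = np.zeros((len(subs), 6))
    if not active:
        # every random effect degenerate: likelihood is a plain product
        for s in subs:
            total += -_joint_neg(state, s, np.zeros(0), active, prior_sds)
            ebes[s.sid] = RandomEffects()
        return modes, ebes, float(total)
    for i, s in enumerate(subs):
        x0 = lat[i, active]
        res = optimize.minimize(
            lambda v: _joint_neg(state, s, v, active, prior_sds),
            x0, method="Nelder-Mead",
            options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": maxiter},
        )
        mode = res.x
        d = len(active)
        h = 1e-4
        H = np.zeros((d, d))
        f0 = res.fun
        if not math.isfinite(f0):
            total += -1e10
            continue
        for a in range(d):
            ea = np.zeros(d); ea[a] = h
            fpa = _joint_neg(state, s, mode + ea, active, prior_sds)
            fma = _joint_neg(state, s, mode - ea, active, prior_sds)
            H[a, a] = (fpa - 2 * f0 + fma) / h ** 2
            for b_ in range(a + 1, d):
                eb = np.zeros(d); eb[b_] = h
                fpp = _joint_neg(state, s, mode + ea + eb, active, prior_sds)
                fpm = _joint_neg(state, s, mode + ea - eb, active, prior_sds)
                fmp = _joint_neg(state, s, mode - ea + eb, active, prior_sds)
                fmm = _joint_neg(state, s, mode - ea - eb, active, prior_sds)
                H[a, b_] = H[b_, a] = (fpp - fpm - fmp + fmm) / (4 * h ** 2)
        sign, logdet = np.linalg.slogdet(H)
        # the joint posterior is at least as concentrated as the latent
        # prior, so logdet(H) is bounded below by the prior log-precision;
        # this also repairs indefinite finite-difference Hessians, which
        # would otherwise inflate the Gaussian volume term
        prior_logdet = float(np.sum([-2.0 * math.log(prior_sds[j])
                                     for j in active]))
        if sign <= 0 or not math.isfinite(logdet):
            logdet = prior_logdet
        logdet = max(logdet, prior_logdet)
        total += -f0 + 0.5 * d * _LOG2PI - 0.5 * logdet
        full = np.zeros(6)
        full[active] = mode
        modes[i] = full
        ebes[s.sid] = RandomEffects(
            eta_v1=float(full[0]), eta_cl1=float(full[1]),
            eta_cl2=float(full[4]),
            eta_occ_cl1=(float(full[2]), float(full[3])),
        )
    return modes, ebes, float(total)


# ---------------------------------------------------------------------------
# Standard errors (stochastic Fisher approximation)
# ---------------------------------------------------------------------------

def _score_names(spec):
    names = ["V1pop"] + [f"betaV1_{c}" for c in spec.v1_covariates]
    names += ["Cl1pop"] + [f"betaCl1_{c}" for c in spec.cl1_covariates]
    names += ["Cl2pop"]
    if spec.fix_q is None:
        names += ["Qpop"]
    names += ["omegaV1", "omegaCl1", "omegaCl2"]
    if spec.estimate_iov:
        names += ["gammaCl1"]
    names += ["bC1", "bC2"]
    return names


def _complete_scores(state, spec, subs, lat, z_v1, z1, z2, z_cl2, off_v1, off_cl1):
    """Per-subject complete-data scores at the current sample (n x p)."""
    n = len(subs)
    names = _score_names(spec)
    p = len(names)
    S = np.zeros((n, p))
    om_v1, om_cl1, om_cl2, gam = state.om_v1, state.om_cl1, state.om_cl2, state.gam
    v1pop = math.exp(state.mu_v1)
    cl1pop = math.exp(state.mu_cl1)
    cl2pop = math.exp(state.mu_cl2)
    # compound-symmetric inverse for the Cl1 pair
    a = om_cl1 ** 2 + gam ** 2
    c = om_cl1 ** 2
    det = a * a - c * c if gam >= _ACTIVE_SD else None
    col = {nm: k for k, nm in enumerate(names)}
    for i, s in enumerate(subs):
        r_v1 = z_v1[i] - off_v1[i]
        S[i, col["V1pop"]] = r_v1 / (om_v1 ** 2 * v1pop)
        for j, cname in enumerate(spec.v1_covariates):
            S[i, col[f"betaV1_{cname}"]] = r_v1 * s.x_v1[j] / om_v1 ** 2
        S[i, col["omegaV1"]] = -1.0 / om_v1 + r_v1 ** 2 / om_v1 ** 3
        r1 = z1[i] - off_cl1[i]
        r2 = z2[i] - off_cl1[i]
        if det is not None:
            # Sigma = [[a, c], [c, a]]; w = Sigma^{-1} r; trace identities give
            # d/d(omega) = omega [ (w1+w2)^2 - sum(Sigma^{-1}) ],
            # d/d(gamma) = gamma [ w1^2 + w2^2 - tr(Sigma^{-1}) ]
            w1 = (a * r1 - c * r2) / det
            w2 = (a * r2 - c * r1) / det
            S[i, col["omegaCl1"]] = om_cl1 * ((w1 + w2) ** 2 - 2.0 * (a - c) / det)
            S[i, col["gammaCl1"]] = gam * (w1 ** 2 + w2 ** 2 - 2.0 * a / det)
            S[i, col["Cl1pop"]] = (w1 + w2) / cl1pop
            for j, cname in enumerate(spec.cl1_covariates):
                S[i, col[f"betaCl1_{cname}"]] = (w1 + w2) * s.x_cl1[j]
        else:
            mbar = 0.5 * (r1 + r2)
            S[i, col["Cl1pop"]] = 2.0 * mbar / (om_cl1 ** 2 * cl1pop)
            for j, cname in enumerate(spec.cl1_covariates):
                S[i, col[f"betaCl1_{cname}"]] = 2.0 * mbar * s.x_cl1[j] / om_cl1 ** 2
            S[i, col["omegaCl1"]] = -2.0 / om_cl1 + (r1 ** 2 + r2 ** 2) / om_cl1 ** 3
            if spec.estimate_iov:
                S[i, col["gammaCl1"]] = 0.0
        r_cl2 = z_cl2[i] - state.mu_cl2
        S[i, col["Cl2pop"]] = r_cl2 / (om_cl2 ** 2 * cl2pop)
        S[i, col["omegaCl2"]] = -1.0 / om_cl2 + r_cl2 ** 2 / om_cl2 ** 3
        # residual error scores
        vv1, cl1, cl2, qq = state.indiv(s, lat[i])
        preds = _predict_subj(s, vv1, cl1, cl2, qq, state.v2)
        sb1 = sb2 = 0.0
        for y, f, comp in zip(s.obs_y, preds, s.obs_comp):
            if f <= 0:
                continue
            b = state.b1 if comp == 0 else state.b2
            u = (y - f) / (b * f)
            if comp == 0:
                sb1 += (u * u - 1.0) / b
            else:
                sb2 += (u * u - 1.0) / b
        S[i, col["bC1"]] = sb1
        S[i, col["bC2"]] = sb2
        if spec.fix_q is None:
            h = 1e-3 * max(state.q, 1.0)
            old = state.q
            state.q = old + h
            lp = _subject_ll(state, s, lat[i])
            state.q = old - h
            lm = _subject_ll(state, s, lat[i])
            state.q = old
            S[i, col["Qpop"]] = (lp - lm) / (2 * h)
    return S


def _standard_errors(state, spec, score_sum, score_n):
    names = _score_names(spec)
    se = {}
    rse = {}
    if score_sum is None or score_n == 0:
        return se, rse
    sbar = score_sum / score_n            # posterior-mean scores, n x p
    info = sbar.T @ sbar
    # MAP prior precisions
    col = {nm: k for k, nm in enumerate(names)}
    if spec.v1_prior is not None:
        info[col["V1pop"], col["V1pop"]] += 1.0 / spec.v1_prior[1] ** 2
    if spec.fix_q is None and spec.q_prior is not None:
        info[col["Qpop"], col["Qpop"]] += 1.0 / spec.q_prior[1] ** 2
    try:
        cov = np.linalg.pinv(info)
    except np.linalg.LinAlgError:
        return se, rse
    params = state.to_params()
    for nm in names:
        v = max(cov[col[nm], col[nm]], 0.0)
        se[nm] = math.sqrt(v)
    ests = dict(FitResult(
        params=params, spec=spec,
        betas_v1=dict(zip(spec.v1_covariates, state.beta_v1)),
        betas_cl1=dict(zip(spec.cl1_covariates, state.beta_cl1)),
        se={}, rse={}, loglik=0.0, ebes={}, converged=True,
        trace=pd.DataFrame(), n_subjects=0, n_obs=0,
    )._named_estimates())
    for nm in names:
        est = ests.get(nm, float("nan"))
        rse[nm] = 100.0 * se[nm] / abs(est) if est not in (0.0,) and est == est \
            else float("nan")
    return se, rse


# ---------------------------------------------------------------------------
# Likelihood-ratio test and bootstrap
# ---------------------------------------------------------------------------

def marginal_loglik(
    dataset: pd.DataFrame,
    spec: FitSpec,
    params: PopulationParams,
) -> float:
    """Laplace marginal log-likelihood of ``params`` on ``dataset``.

    Useful for evaluating candidate parameter vectors without running the
    estimator — e.g. scoring a nested model at the shared parameters of a
    richer fit so a likelihood-ratio comparison is not distorted by
    unequal convergence of the two stochastic fits.
    """
    subs = _parse_dataset(dataset, spec, check_identifiability=False)
    state = _State(spec, params)
    lat = np.zeros((len(subs), 6))
    _, _, ll = _laplace_loglik(state, spec, subs, lat, maxiter=800)
    return ll


def lrt_compare(nested: FitResult, full: FitResult, df: int) -> float:
    """p-value of the likelihood-ratio test between nested covariate models.

    ``2 * (logL_full - logL_nested)`` is referred to a chi-square with
    ``df`` degrees of freedom; a covariate is retained at p < 0.05.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = full.loglik - nested.loglik
    if delta < -1e-6:
        warnings.warn(
            f"full model log-likelihood below nested ({delta:.3g}); "
            "possible convergence failure", stacklevel=2,
        )
    stat = max(2.0 * delta, 0.0)
    return float(stats.chi2.sf(stat, df))


def bootstrap_ci(
    dataset: pd.DataFrame,
    spec: FitSpec,
    n_reps: int = 1000,
    seed: int = 0,
    init: PopulationParams | None = None,
    level: float = 0.95,
) -> dict:
    """Subject-level nonparametric bootstrap percentile intervals.

    Subjects are resampled with replacement; each replicate is refitted
    with a replicate-specific SAEM seed derived from ``seed``.  Replicates
    that fail (e.g. a resample that loses a covariate level) are recorded
    and excluded.
    """
    rng = np.random.default_rng(seed)
    ids = np.array(sorted(dataset.loc[dataset["DRUG"] == spec.drug, "ID"].unique()))
    estimates = []
    failures = 0
    alpha = (1.0 - level) / 2.0
    for rep in range(n_reps):
        take = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for new_id, sid in enumerate(take, start=1):
            part = dataset[(dataset["ID"] == sid)
                           & (dataset["DRUG"] == spec.drug)].copy()
            part["ID"] = new_id
            parts.append(part)
        boot = pd.concat(parts, ignore_index=True)
        rep_spec = replace(spec, seed=int(rng.integers(2 ** 31 - 1)))
        try:
            fit = fit_population(boot, rep_spec, init=init)
        except (IdentifiabilityError, ValueError, np.linalg.LinAlgError):
            failures += 1
            continue
        estimates.append(dict(fit._named_estimates()))
    if not estimates:
        raise RuntimeError("all bootstrap replicates failed")
    table = pd.DataFrame(estimates)
    ci = {
        nm: (float(np.percentile(table[nm], 100 * alpha)),
             float(np.percentile(table[nm], 100 * (1 - alpha))))
        for nm in table.columns
    }
    return {"ci": ci, "n_success": len(estimates), "n_failed": failures,
            "estimates": table, "resample_seed": seed}


# ---------------------------------------------------------------------------
# Diagnostics: R^2, weighted residuals, NPDE, VPC
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsBundle:
    """Goodness-of-fit bundle for a fitted (or asserted) population model."""

    table: pd.DataFrame          # per-observation: obs, preds, IWRES, PWRES, NPDE
    r2: dict                     # (compartment, predicted-type) -> R^2
    vpc: pd.DataFrame            # prediction-corrected VPC summary
    n_sim: int


def diagnostics(
    fit,
    dataset: pd.DataFrame,
    n_sim: int = 500,
    seed: int = 0,
    vpc_bins: int = 6,
) -> DiagnosticsBundle:
    """Simulation-based diagnostics of a population model against a dataset.

    ``fit`` may be a :class:`FitResult` or a bare :class:`PopulationParams`
    (with the matching :class:`FitSpec` semantics derived from the drug).
    NPDE uses ``n_sim`` model simulations with per-subject decorrelation
    (Cholesky of the simulated covariance) and the inverse-normal rank
    transform; the VPC bins observations on the population prediction and
    prediction-corrects them.
    """
    if n_sim < 50:
        raise ValueError("n_sim < 50 gives unstable NPDE; refuse to compute")
    if isinstance(fit, FitResult):
        params, spec, ebes = fit.params, fit.spec, fit.ebes
    else:
        params = fit
        spec = FitSpec.for_drug(params.drug)
        ebes = None
    # simulation-based diagnostics need no estimable covariate design
    subs = _parse_dataset(dataset, spec, check_identifiability=False)
    state = _State(spec, params)
    # keep the exact variabilities handed in (no annealing here)
    state.om_v1 = max(params.omegaV1, _SD_FLOOR)
    state.om_cl1 = max(params.omegaCl1, _SD_FLOOR)
    state.om_cl2 = max(params.omegaCl2, _SD_FLOOR)
    state.gam = max(params.gammaCl1, _SD_FLOOR) if spec.estimate_iov else 0.0
    state.b1, state.b2 = params.bC1, params.bC2
    prior_sds = state.prior_sds()
    active = [j for j, sd in enumerate(prior_sds) if sd >= _ACTIVE_SD]
    rng = np.random.default_rng(seed)

    if ebes is None:
        ebes = {}
        for i, s in enumerate(subs):
            if active:
                res = optimize.minimize(
                    lambda v: _joint_neg(state, s, v, active, prior_sds),
                    np.zeros(len(active)), method="Nelder-Mead",
                    options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 2000},
                )
                mode = res.x
            else:
                mode = np.zeros(0)
            full = np.zeros(6)
            full[active] = mode
            ebes[s.sid] = RandomEffects(
                eta_v1=float(full[0]), eta_cl1=float(full[1]),
                eta_cl2=float(full[4]),
                eta_occ_cl1=(float(full[2]), float(full[3])),
            )

    rows = []
    vpc_rows = []
    for s in subs:
        e = ebes[s.sid]
        v_ind = np.array([e.eta_v1, e.eta_cl1, e.eta_occ_cl1[0],
                          e.eta_occ_cl1[1], e.eta_cl2, 0.0])
        v1, cl1, cl2, _ = state.indiv(s, v_ind)
        f_ind = np.array(_predict_subj(s, v1, cl1, cl2, state.q, state.v2))
        v1p, cl1p, cl2p, _ = state.indiv(s, np.zeros(6))
        f_pop = np.array(_predict_subj(s, v1p, cl1p, cl2p, state.q, state.v2))
        ni = len(s.obs_y)
        sims = np.empty((n_sim, ni))
        for k in range(n_sim):
            v = rng.standard_normal(6) * np.array(prior_sds)
            vv1, vcl1, vcl2, _ = state.indiv(s, v)
            f = np.array(_predict_subj(s, vv1, vcl1, vcl2, state.q, state.v2))
            bvec = np.where(np.array(s.obs_comp) == 0, state.b1, state.b2)
            sims[k] = f * (1.0 + bvec * rng.standard_normal(ni))
        mean_sim = sims.mean(axis=0)
        cov_sim = np.cov(sims, rowvar=False).reshape(ni, ni)
        cov_sim += np.eye(ni) * (np.trace(cov_sim) / ni * 1e-10 + 1e-12)
        L = np.linalg.cholesky(cov_sim)
        y = np.array(s.obs_y)
        dec_obs = np.linalg.solve(L, y - mean_sim)
        dec_sim = np.linalg.solve(L, (sims - mean_sim).T).T
        pde = (dec_sim < dec_obs).mean(axis=0)
        pde = np.clip(pde, 1.0 / (2 * n_sim), 1.0 - 1.0 / (2 * n_sim))
        npde = stats.norm.ppf(pde)
        sd_sim = sims.std(axis=0, ddof=1)
        pwres = (y - mean_sim) / sd_sim
        bvec = np.where(np.array(s.obs_comp) == 0, state.b1, state.b2)
        iwres = (y - f_ind) / (bvec * np.maximum(f_ind, 1e-12))
        for j in range(ni):
            rows.append({
                "ID": s.sid, "TIME": s.obs_t[j],
                "MATRIX": "plasma" if s.obs_comp[j] == 0 else "peritoneal",
                "DV": y[j], "IPRED": f_ind[j], "PRED": f_pop[j],
                "IWRES": iwres[j], "PWRES": pwres[j], "NPDE": npde[j],
            })
            vpc_rows.append({
                "pred": f_pop[j], "obs_pc": y[j],
                "sim_pc": sims[:, j],
                "matrix": "plasma" if s.obs_comp[j] == 0 else "peritoneal",
            })

    table = pd.DataFrame(rows)
    r2 = {}
    for mat in ("plasma", "peritoneal"):
        sub = table[table["MATRIX"] == mat]
        if len(sub) >= 3:
            for kind in ("IPRED", "PRED"):
                r = np.corrcoef(sub["DV"], sub[kind])[0, 1]
                r2[(mat, "individual" if kind == "IPRED" else "population")] = r * r
    vpc = _vpc_table(vpc_rows, vpc_bins)
    return DiagnosticsBundle(table=table, r2=r2, vpc=vpc, n_sim=n_sim)


def _vpc_table(vpc_rows, n_bins):
    """Prediction-corrected VPC: observed percentiles vs simulated bands."""
    if not vpc_rows:
        return pd.DataFrame()
    preds = np.array([r["pred"] for r in vpc_rows])
    edges = np.quantile(preds, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = [r for r, p in zip(vpc_rows, preds) if lo <= p < hi]
        if len(sel) < 3:
            continue
        med = np.median([r["pred"] for r in sel])
        # prediction correction: rescale each observation to the bin-median pred
        obs_pc = np.array([r["obs_pc"] * med / max(r["pred"], 1e-12) for r in sel])
        sim_pc = np.stack(
            [r["sim_pc"] * med / max(r["pred"], 1e-12) for r in sel], axis=1
        )
        row = {"pred_lo": lo, "pred_hi": hi, "n": len(sel)}
        for q, nm in ((10, "p10"), (50, "p50"), (90, "p90")):
            row[f"obs_{nm}"] = float(np.percentile(obs_pc, q))
            per_sim = np.percentile(sim_pc, q, axis=1)
            row[f"sim_{nm}_lo"] = float(np.percentile(per_sim, 5))
            row[f"sim_{nm}_hi"] = float(np.percentile(per_sim, 95))
        out.append(row)
    return pd.DataFrame(out)
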