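"""Statistical population layer of the plasma-peritoneal model.

Maps population fixed effects + covariates + log-normal random effects to
individual structural parameters, and applies the proportional residual
error model.  For both drugs the individual model is

    log V1  = log V1pop  + bV1_age*age + bV1_weight*weight + eta_V1
    log V2  = log V2pop                                   (fixed)
    log Q   = log Qpop                                    (no variability)
    log Cl1 = log Cl1pop + bCl1_catB*[cat=B] + bCl1_catC*[cat=C]
              (+ bCl1_age*age, optional) + eta_Cl1 + eta_occ_Cl1
    log Cl2 = log Cl2pop + eta_Cl2

where eta_* ~ N(0, omega^2) are inter-individual effects, eta_occ_Cl1 ~
N(0, gamma^2) is an inter-occasion effect on the central clearance, and
renal category D (augmented renal clearance) is pooled with the reference
category A.  Tazobactam carries no covariates on V1.  Observations follow
a proportional error model y = c * (1 + b*eps), eps ~ N(0,1), with
separate coefficients for plasma (bC1) and peritoneal (bC2) samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .structural import DoseSchedule, StructuralParams, propagate_segment, rate_constants

__all__ = [
    "PopulationParams",
    "CovariateVector",
    "RandomEffects",
    "individual_params",
    "sample_random_effects",
    "apply_residual_error",
    "log_likelihood",
    "predict_concentrations",
    "piperacillin_params",
    "tazobactam_params",
    "load_population_params",
    "save_population_params",
    "OCCASION_SWITCH_H",
]

RENAL_CATEGORIES = ("A", "B", "C", "D")

#: Start (h) of the second sampling occasion.  Occasion 1 covers the
#: loading dose and the end-of-load sample; occasion 2 covers the
#: steady-state sampling window at >= 48 h.
OCCASION_SWITCH_H = 24.0


@dataclass(frozen=True)
class PopulationParams:
    """Population parameters for one drug (fixed effects, variability, error)."""

    drug: str
    V1pop: float
    V2pop: float
    Qpop: float
    Cl1pop: float
    Cl2pop: float
    betaV1_age: float = 0.0
    betaV1_weight: float = 0.0
    betaCl1_age: float = 0.0
    betaCl1_catB: float = 0.0
    betaCl1_catC: float = 0.0
    omegaV1: float = 0.0
    omegaCl1: float = 0.0
    omegaCl2: float = 0.0
    gammaCl1: float = 0.0
    bC1: float = 0.0
    bC2: float = 0.0
    # estimation annotations (not used when simulating)
    fixed: tuple = ("V2pop",)
    map_priors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("V1pop", "V2pop", "Qpop", "Cl1pop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.Cl2pop < 0:
            raise ValueError("Cl2pop must be >= 0")
        for name in ("omegaV1", "omegaCl1", "omegaCl2", "gammaCl1", "bC1", "bC2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CovariateVector:
    """Individual covariates entering the model."""

    age: float
    weight: float
    renal_category: str
    occasion: int = 1

    def __post_init__(self) -> None:
        if self.renal_category not in RENAL_CATEGORIES:
            raise ValueError(
                f"unknown renal category {self.renal_category!r}; expected one of {RENAL_CATEGORIES}"
            )
        if self.age <= 0 or self.weight <= 0:
            raise ValueError("age and weight must be > 0")

    @property
    def effective_category(self) -> str:
        """Category used in the model: D (ARC) is pooled with reference A."""
        return "A" if self.renal_category == "D" else self.renal_category


@dataclass(frozen=True)
class RandomEffects:
    """Log-scale random effects for one individual.

    ``eta_occ_cl1`` holds one inter-occasion deviation per occasion.
    """

    eta_v1: float = 0.0
    eta_cl1: float = 0.0
    eta_cl2: float = 0.0
    eta_occ_cl1: tuple = (0.0, 0.0)


def individual_params(
    pop: PopulationParams,
    cov: CovariateVector,
    eta: RandomEffects = RandomEffects(),
    occasion: int | None = None,
) -> StructuralParams:
    """Individual structural parameters for one occasion.

    Covariates enter uncentered on the log scale, exactly as the model is
    written; all parameters are log-normal and therefore positive.
    """
    occ = cov.occasion if occasion is None else occasion
    occ_effects = eta.eta_occ_cl1
    if not 1 <= occ <= len(occ_effects):
        raise ValueError(f"occasion {occ} outside available occasion effects")
    cat = cov.effective_category
    v1 = pop.V1pop * math.exp(
        pop.betaV1_age * cov.age + pop.betaV1_weight * cov.weight + eta.eta_v1
    )
    beta_cat = {"A": 0.0, "B": pop.betaCl1_catB, "C": pop.betaCl1_catC}[cat]
    cl1 = pop.Cl1pop * math.exp(
        pop.betaCl1_age * cov.age + beta_cat + eta.eta_cl1 + occ_effects[occ - 1]
    )
    cl2 = pop.Cl2pop * math.exp(eta.eta_cl2)
    return StructuralParams(V1=v1, V2=pop.V2pop, Q=pop.Qpop, Cl1=cl1, Cl2=cl2)


def sample_random_effects(
    pop: PopulationParams,
    n: int,
    n_occasions: int = 2,
    rng: np.random.Generator | None = None,
) -> list[RandomEffects]:
    """Draw ``n`` independent random-effect vectors.

    Inter-individual effects have SDs (omegaV1, omegaCl1, omegaCl2) and
    occasion effects SD gammaCl1; all draws are independent (the model
    assumes no correlation between random effects).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    ev1 = rng.normal(0.0, pop.omegaV1, size=n)
    ecl1 = rng.normal(0.0, pop.omegaCl1, size=n)
    ecl2 = rng.normal(0.0, pop.omegaCl2, size=n)
    eocc = rng.normal(0.0, pop.gammaCl1, size=(n, n_occasions))
    return [
        RandomEffects(
            eta_v1=float(ev1[i]),
            eta_cl1=float(ecl1[i]),
            eta_cl2=float(ecl2[i]),
            eta_occ_cl1=tuple(float(x) for x in eocc[i]),
        )
        for i in range(n)
    ]


def apply_residual_error(
    true_conc,
    compartment: str,
    pop: PopulationParams,
    rng: np.random.Generator | None = None,
):
    """Apply proportional observation noise y = c*(1 + b*eps), eps~N(0,1).

    ``compartment`` selects the error coefficient: ``"plasma"`` uses bC1,
    ``"peritoneal"`` uses bC2.  Negative draws (possible at large b) are
    floored at zero with a warning, since concentrations cannot be
    negative.
    """
    if compartment == "plasma":
        b = pop.bC1
    elif compartment == "peritoneal":
        b = pop.bC2
    else:
        raise ValueError(f"unknown compartment {compartment!r}")
    rng = np.random.default_rng(rng)
    c = np.asarray(true_conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("true concentration must be >= 0")
    y = c * (1.0 + b * rng.standard_normal(size=c.shape))
    if np.any(y < 0):
        warnings.warn("proportional-error draw below zero floored at 0", stacklevel=2)
        y = np.maximum(y, 0.0)
    return float(y) if y.shape == () else y


def predict_concentrations(
    pop: PopulationParams,
    cov: CovariateVector,
    eta: RandomEffects,
    schedule: DoseSchedule,
    times: Sequence[float],
    compartments: Sequence[str],
    occasion_switch: float = OCCASION_SWITCH_H,
) -> np.ndarray:
    """Noise-free predicted concentrations at observation times.

    Central clearance switches from its occasion-1 to its occasion-2 value
    at ``occasion_switch`` hours; the kinetic state is carried across the
    switch, so the profile is continuous.  ``compartments`` maps each time
    to ``"plasma"`` (C1) or ``"peritoneal"`` (C2).
    """
    t = np.asarray(times, dtype=float)
    comps = np.asarray(compartments)
    bad = set(np.unique(comps)) - {"plasma", "peritoneal"}
    if bad:
        raise ValueError(f"unknown compartment(s) {sorted(bad)!r}")
    p_by_occ = [individual_params(pop, cov, eta, occasion=o) for o in (1, 2)]
    a1_out = np.zeros_like(t)
    a2_out = np.zeros_like(t)
    a1 = a2 = 0.0
    t_max = float(t.max()) if t.size else 0.0
    bks = sorted(
        {b for b in schedule.breakpoints() + [occasion_switch] if 0.0 < b < t_max}
    ) + [t_max]
    lo = 0.0
    for hi in bks:
        if hi <= lo:
            continue
        p = p_by_occ[0] if lo < occasion_switch else p_by_occ[1]
        k = rate_constants(p)
        rate = schedule.rate_at(lo)
        mask = (t > lo) & (t <= hi)
        if np.any(mask):
            a1_out[mask], a2_out[mask] = propagate_segment(
                k["k10"], k["k12"], k["k21"], k["k20"], rate, a1, a2, t[mask] - lo
            )
        a1, a2 = propagate_segment(
            k["k10"], k["k12"], k["k21"], k["k20"], rate, a1, a2, hi - lo
        )
        lo = hi
    # concentrations: volumes are occasion-independent, so the profile is
    # continuous across the occasion switch
    return np.where(
        comps == "plasma", a1_out / p_by_occ[0].V1, a2_out / p_by_occ[0].V2
    )


def log_likelihood(
    pop: PopulationParams,
    cov: CovariateVector,
    eta: RandomEffects,
    schedule: DoseSchedule,
    times: Sequence[float],
    compartments: Sequence[str],
    values: Sequence[float],
    occasion_switch: float = OCCASION_SWITCH_H,
) -> float:
    """Joint log density of one subject's observations and random effects.

    Observation terms are N(y; c, (b*c)^2) with the compartment-specific
    proportional coefficient; random-effect terms are their normal
    log-priors.  Plasma and peritoneal samples enter the likelihood;
    VAC-fluid and urine records are excluded upstream.  A zero predicted
    concentration with a non-zero observation contributes -inf.
    """
    preds = predict_concentrations(
        pop, cov, eta, schedule, times, compartments, occasion_switch
    )
    ll = 0.0
    for y, c, comp in zip(values, preds, compartments):
        b = pop.bC1 if comp == "plasma" else pop.bC2
        sd = b * c
        if sd <= 0:
            if abs(y - c) > 0:
                return -math.inf
            continue
        ll += -0.5 * ((y - c) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)
    for e, w in (
        (eta.eta_v1, pop.omegaV1),
        (eta.eta_cl1, pop.omegaCl1),
        (eta.eta_cl2, pop.omegaCl2),
    ):
        ll += _normal_logpdf(e, w)
    for k in eta.eta_occ_cl1:
        ll += _normal_logpdf(k, pop.gammaCl1)
    return ll


def _normal_logpdf(x: float, sd: float) -> float:
    if sd <= 0:
        return 0.0 if x == 0 else -math.inf
    return -0.5 * (x / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)


# ---------------------------------------------------------------------------
# Published (final-model) parameter sets
# ---------------------------------------------------------------------------

def piperacillin_params() -> PopulationParams:
    """Final population parameters for unbound piperacillin.

    Age and total body weight are covariates on V1 (uncentered, per year /
    per kg on the log scale) and renal category on Cl1; V2 is fixed at
    5 L; Q and V1 were estimated under normal MAP priors centred at 20.
    """
    return PopulationParams(
        drug="piperacillin",
        V1pop=21.213,
        V2pop=5.0,
        Qpop=23.833,
        Cl1pop=38.739,
        Cl2pop=5.567,
        betaV1_age=-0.016,
        betaV1_weight=0.017,
        betaCl1_catB=-2.016,
        betaCl1_catC=-1.243,
        omegaV1=0.225,
        omegaCl1=0.661,
        omegaCl2=0.123,
        gammaCl1=0.391,
        bC1=0.207,
        bC2=0.239,
        fixed=("V2pop",),
        map_priors={"Qpop": (20.0, 3.0), "V1pop": (20.0, 1.0)},
    )


def tazobactam_params() -> PopulationParams:
    """Final population parameters for unbound tazobactam.

    No covariates on V1; renal category on Cl1; V2 fixed at 5 L and Q
    fixed at 20 L/h; V1 estimated under a normal MAP prior N(20, 5^2).
    """
    return PopulationParams(
        drug="tazobactam",
        V1pop=23.248,
        V2pop=5.0,
        Qpop=20.0,
        Cl1pop=7.013,
        Cl2pop=3.003,
        betaCl1_catB=-5.602,
        betaCl1_catC=-2.303,
        omegaV1=0.351,
        omegaCl1=0.569,
        omegaCl2=0.243,
        gammaCl1=0.967,
        bC1=0.371,
        bC2=0.372,
        fixed=("V2pop", "Qpop"),
        map_priors={"V1pop": (20.0, 5.0)},
    )


# ---------------------------------------------------------------------------
# Parameter file I/O (flat key-value YAML)
# ---------------------------------------------------------------------------

def save_population_params(pop: PopulationParams, path) -> None:
    d = asdict(pop)
    d["fixed"] = list(d["fixed"])
    d["map_priors"] = {k: list(v) for k, v in d["map_priors"].items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_population_params(path) -> PopulationParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["fixed"] = tuple(d.get("fixed", ()))
    d["map_priors"] = {k: tuple(v) for k, v in d.get("map_priors", {}).items()}
    return PopulationParams(**d)
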