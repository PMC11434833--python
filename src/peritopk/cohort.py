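"""Synthetic cohort generation emulating the open-abdomen/VAC study design.

Generates virtual patients with the study's covariate structure (age,
total body weight, renal-function category), assigns the renal-function-
adjusted piperacillin-tazobactam regimen, simulates true concentration
profiles under the population model, and emits sparse multi-matrix
observations:

* T0 — plasma sample at the end of the 30-min loading infusion;
* T1 — plasma and peritoneal samples during the steady-state window
  (48-72 h), plus pooled VAC-fluid and urine collections over [T0, T1].

VAC-fluid and urine concentrations are mass-balance summaries of the
simulated profile: the drug amount removed by the corresponding clearance
over the collection interval divided by the collected fluid volume.  A
capture fraction ``f_vac`` scales the amount actually recovered from the
VAC circuit.  Observations below the assay's lower limit of
quantification are flagged (and excluded from fitting downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import (
    OCCASION_SWITCH_H,
    CovariateVector,
    PopulationParams,
    RandomEffects,
    individual_params,
    predict_concentrations,
    sample_random_effects,
)
from .structural import DoseSchedule, rate_constants, propagate_segment

__all__ = [
    "CohortDesign",
    "ObservationRecord",
    "Subject",
    "Cohort",
    "generate_cohort",
    "cohort_to_dataset",
    "write_dataset",
    "read_dataset",
    "REGIMEN_BY_CATEGORY",
    "DATASET_COLUMNS",
]

#: Daily continuous dose (mg/24 h) per renal category, after the common
#: 4 g / 0.5 g loading infusion: 16/2 g for normal renal function or CRRT,
#: 12/1.5 g for moderate renal impairment, 20/2.5 g for augmented renal
#: clearance.
REGIMEN_BY_CATEGORY = {
    "A": {"piperacillin": 16000.0, "tazobactam": 2000.0},
    "B": {"piperacillin": 16000.0, "tazobactam": 2000.0},
    "C": {"piperacillin": 12000.0, "tazobactam": 1500.0},
    "D": {"piperacillin": 20000.0, "tazobactam": 2500.0},
}

LOADING_MG = {"piperacillin": 4000.0, "tazobactam": 500.0}
LOADING_DURATION_H = 0.5

DATASET_COLUMNS = [
    "ID", "DRUG", "TIME", "EVID", "AMT", "RATE", "DUR", "DV", "MDV",
    "MATRIX", "OCC", "AGE", "WT", "RENAL_CAT", "LLOQ_FLAG",
]


@dataclass(frozen=True)
class CohortDesign:
    """Design of a synthetic cohort mirroring the study population.

    Covariate distributions are normal approximations matched to the
    printed median and interquartile range (sigma ~ IQR/1.349), truncated
    to plausible ranges; the steady-state sampling time T1 is uniform on
    its reported window.
    """

    n_patients: int = 45
    category_probs: tuple = (22 / 45, 12 / 45, 8 / 45, 3 / 45)  # A, B, C, D
    age_median: float = 66.0
    age_iqr: tuple = (57.0, 72.0)
    age_bounds: tuple = (18.0, 95.0)
    weight_median: float = 83.0
    weight_iqr: tuple = (71.0, 92.0)
    weight_bounds: tuple = (40.0, 160.0)
    t1_window: tuple = (48.0, 72.0)
    vac_volume_per_day: tuple = (1.0, 3.0)    # L/day, uniform
    urine_volume_per_day: tuple = (1.0, 4.0)  # L/day, uniform
    lloq: dict = field(
        default_factory=lambda: {"piperacillin": 0.5, "tazobactam": 1.5}
    )
    vac_capture_fraction: float = 1.0
    #: additional plasma / peritoneal sampling times (h) for rich designs
    extra_plasma_times: tuple = ()
    extra_peritoneal_times: tuple = ()
    include_predose_trough: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.category_probs) - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1")
        if not 0 < self.vac_capture_fraction <= 1:
            raise ValueError("vac_capture_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ObservationRecord:
    """One observation or dose event on a subject's timeline."""

    subject_id: int
    drug: str
    time: float
    matrix: str | None  # plasma | peritoneal | vac_fluid | urine (obs rows)
    value: float | None
    occasion: int
    below_lloq: bool = False
    is_dose: bool = False
    amount: float | None = None
    rate: float | None = None
    duration: float | None = None


@dataclass(frozen=True)
class Subject:
    subject_id: int
    covariates: CovariateVector
    effects: dict                      # drug -> RandomEffects
    daily_dose: dict                   # drug -> mg/24 h
    t1: float
    vac_volume: float                  # L collected over [T0, T1]
    urine_volume: float                # L collected over [T0, T1]
    records: tuple = ()


@dataclass(frozen=True)
class Cohort:
    design: CohortDesign
    subjects: tuple
    seed: int

    @property
    def records(self) -> list[ObservationRecord]:
        return [r for s in self.subjects for r in s.records]


def _trunc_normal(rng, median, iqr, bounds, size):
    """Normal approximation to a median [IQR] summary, truncated by redraw."""
    sigma = (iqr[1] - iqr[0]) / 1.349
    out = rng.normal(median, sigma, size=size)
    bad = (out < bounds[0]) | (out > bounds[1])
    while np.any(bad):
        out[bad] = rng.normal(median, sigma, size=int(bad.sum()))
        bad = (out < bounds[0]) | (out > bounds[1])
    return out


def _removal_integral(pop, cov, eta, schedule, t0, t1, which, dt=0.02):
    """Drug amount (mg) removed over [t0, t1] by Cl1 (urine) or Cl2 (VAC).

    Integrates clearance x concentration over a dense grid (trapezoid);
    the clearance tracks the occasion in force at each time.
    """
    n = max(int(math.ceil((t1 - t0) / dt)), 2)
    t = np.linspace(t0, t1, n + 1)
    comps = ["plasma" if which == "urine" else "peritoneal"] * len(t)
    conc = predict_concentrations(pop, cov, eta, schedule, t, comps)
    if which == "urine":
        cl = np.where(
            t < OCCASION_SWITCH_H,
            individual_params(pop, cov, eta, occasion=1).Cl1,
            individual_params(pop, cov, eta, occasion=2).Cl1,
        )
    else:
        cl = individual_params(pop, cov, eta, occasion=1).Cl2
    return float(np.trapezoid(cl * conc, t))


def generate_cohort(
    design: CohortDesign,
    pop_pip: PopulationParams,
    pop_taz: PopulationParams,
    seed: int,
) -> Cohort:
    """Generate a full two-drug cohort under the study design.

    Per subject: draw covariates; assign the regimen from the renal
    category; draw per-drug random effects (two occasions); simulate the
    true profiles; observe plasma at T0 and plasma + peritoneal at T1 with
    proportional noise; summarise VAC-fluid and urine collections over
    [T0, T1].  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = design.n_patients
    ages = _trunc_normal(rng, design.age_median, design.age_iqr, design.age_bounds, n)
    weights = _trunc_normal(
        rng, design.weight_median, design.weight_iqr, design.weight_bounds, n
    )
    cats = rng.choice(list("ABCD"), size=n, p=design.category_probs)
    t1s = rng.uniform(*design.t1_window, size=n)
    vac_rates = rng.uniform(*design.vac_volume_per_day, size=n)
    uri_rates = rng.uniform(*design.urine_volume_per_day, size=n)
    pops = {"piperacillin": pop_pip, "tazobactam": pop_taz}
    effects = {
        drug: sample_random_effects(pop, n, n_occasions=2, rng=rng)
        for drug, pop in pops.items()
    }
    noise = rng  # same stream, after all structural draws

    subjects = []
    for i in range(n):
        cov = CovariateVector(age=float(ages[i]), weight=float(weights[i]),
                              renal_category=str(cats[i]))
        t1 = float(t1s[i])
        interval = t1 - LOADING_DURATION_H
        vac_vol = float(vac_rates[i]) * interval / 24.0
        uri_vol = float(uri_rates[i]) * interval / 24.0
        if vac_vol <= 0 or uri_vol <= 0:
            raise ValueError(f"subject {i + 1}: degenerate fluid collection volume")
        recs: list[ObservationRecord] = []
        sub_effects = {}
        daily = {}
        for drug, pop in pops.items():
            eta = effects[drug][i]
            sub_effects[drug] = eta
            daily_mg = REGIMEN_BY_CATEGORY[cov.renal_category][drug]
            daily[drug] = daily_mg
            sched = DoseSchedule.loading_plus_continuous(
                LOADING_MG[drug], LOADING_DURATION_H, daily_mg, t1
            )
            recs.append(ObservationRecord(
                subject_id=i + 1, drug=drug, time=0.0, matrix=None, value=None,
                occasion=1, is_dose=True, amount=LOADING_MG[drug],
                rate=LOADING_MG[drug] / LOADING_DURATION_H,
                duration=LOADING_DURATION_H,
            ))
            recs.append(ObservationRecord(
                subject_id=i + 1, drug=drug, time=LOADING_DURATION_H, matrix=None,
                value=None, occasion=1, is_dose=True,
                amount=daily[drug] / 24.0 * (t1 - LOADING_DURATION_H),
                rate=daily[drug] / 24.0, duration=t1 - LOADING_DURATION_H,
            ))
            # sampling plan: (time, matrix, occasion)
            plan = [(LOADING_DURATION_H, "plasma", 1),
                    (t1, "plasma", 2), (t1, "peritoneal", 2)]
            for tt in design.extra_plasma_times:
                plan.append((float(tt), "plasma", 1 if tt < OCCASION_SWITCH_H else 2))
            for tt in design.extra_peritoneal_times:
                plan.append((float(tt), "peritoneal",
                             1 if tt < OCCASION_SWITCH_H else 2))
            if design.include_predose_trough:
                plan.insert(0, (0.0, "plasma", 1))
            plan.sort(key=lambda x: (x[0], x[1]))
            times = [p[0] for p in plan]
            comps = [p[1] for p in plan]
            true_conc = predict_concentrations(pop, cov, eta, sched, times, comps)
            lloq = design.lloq[drug]
            for (tt, mat, occ), c in zip(plan, true_conc):
                b = pop.bC1 if mat == "plasma" else pop.bC2
                y = max(c * (1.0 + b * noise.standard_normal()), 0.0)
                recs.append(ObservationRecord(
                    subject_id=i + 1, drug=drug, time=tt, matrix=mat,
                    value=float(y), occasion=occ, below_lloq=bool(y < lloq),
                ))
            # pooled fluid collections over [T0, T1]
            removed_vac = _removal_integral(
                pop, cov, eta, sched, LOADING_DURATION_H, t1, "vac"
            )
            removed_uri = _removal_integral(
                pop, cov, eta, sched, LOADING_DURATION_H, t1, "urine"
            )
            vac_conc = design.vac_capture_fraction * removed_vac / vac_vol
            uri_conc = removed_uri / uri_vol
            for mat, val in (("vac_fluid", vac_conc), ("urine", uri_conc)):
                recs.append(ObservationRecord(
                    subject_id=i + 1, drug=drug, time=t1, matrix=mat,
                    value=float(val), occasion=2, below_lloq=bool(val < lloq),
                ))
        recs.sort(key=lambda r: (r.drug, r.time, not r.is_dose, r.matrix or ""))
        subjects.append(Subject(
            subject_id=i + 1, covariates=cov, effects=sub_effects,
            daily_dose=daily, t1=t1, vac_volume=vac_vol, urine_volume=uri_vol,
            records=tuple(recs),
        ))
    return Cohort(design=design, subjects=tuple(subjects), seed=seed)


def cohort_to_dataset(cohort: Cohort) -> pd.DataFrame:
    """Long-format event table (NONMEM-like dialect), one row per event."""
    rows = []
    for s in cohort.subjects:
        cov = s.covariates
        for r in s.records:
            rows.append({
                "ID": r.subject_id,
                "DRUG": r.drug,
                "TIME": r.time,
                "EVID": 1 if r.is_dose else 0,
                "AMT": r.amount if r.is_dose else np.nan,
                "RATE": r.rate if r.is_dose else np.nan,
                "DUR": r.duration if r.is_dose else np.nan,
                "DV": np.nan if r.is_dose else r.value,
                "MDV": 1 if r.is_dose else 0,
                "MATRIX": "" if r.is_dose else r.matrix,
                "OCC": r.occasion,
                "AGE": cov.age,
                "WT": cov.weight,
                "RENAL_CAT": cov.renal_category,
                "LLOQ_FLAG": int(r.below_lloq),
            })
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write the long-format table as UTF-8 CSV with '.' decimals."""
    df.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a long-format CSV, validating the schema."""
    df = pd.read_csv(path, dtype={"RENAL_CAT": str, "MATRIX": str})
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")
    df["MATRIX"] = df["MATRIX"].fillna("")
    bad = df.index[(df["EVID"] == 0) & (df["DV"] < 0)].tolist()
    if bad:
        raise ValueError(f"negative DV on observation rows: {bad}")
    bad = df.index[~df["RENAL_CAT"].isin(list("ABCD"))].tolist()
    if bad:
        raise ValueError(f"unknown renal category on rows: {bad}")
    return df[DATASET_COLUMNS]
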