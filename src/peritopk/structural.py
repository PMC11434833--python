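"""Deterministic kinetics of the two-compartment plasma-peritoneal model.

The model describes an antibiotic given as a zero-order intravenous
infusion into a central (plasma) compartment of volume ``V1`` that
exchanges with a peritoneal compartment of volume ``V2`` through an
intercompartmental clearance ``Q``.  Drug is eliminated from the central
compartment with clearance ``Cl1`` (renal route, or renal replacement
therapy) and from the peritoneal compartment with clearance ``Cl2``
(fluid drained by the vacuum-assisted wound-closure system):

    dA1/dt = R_inf(t) - (k10 + k12) A1 + k21 A2
    dA2/dt = k12 A1 - (k21 + k20) A2

with first-order constants k10 = Cl1/V1, k12 = Q/V1, k21 = Q/V2 and
k20 = Cl2/V2, and concentrations C1 = A1/V1, C2 = A2/V2.

The system is linear with a piecewise-constant input, so each infusion
segment is solved exactly with the closed-form matrix exponential of the
2x2 rate matrix.  All quantities are in mg, L, h and mg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StructuralParams",
    "DoseSchedule",
    "ConcentrationProfile",
    "rate_constants",
    "simulate_profile",
    "steady_state",
    "propagate_segment",
]


class InvalidParameterError(ValueError):
    """Raised when structural parameters violate their constraints."""


@dataclass(frozen=True)
class StructuralParams:
    """Kinetic parameters of one individual.

    Attributes
    ----------
    V1, V2 : float
        Central and peritoneal volumes of distribution (L).
    Q : float
        Intercompartmental clearance (L/h).
    Cl1 : float
        Central (renal / RRT) clearance (L/h).
    Cl2 : float
        Peritoneal (VAC-route) clearance (L/h); may be zero.
    """

    V1: float
    V2: float
    Q: float
    Cl1: float
    Cl2: float

    def __post_init__(self) -> None:
        for name in ("V1", "V2", "Q", "Cl1"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")
        if not (math.isfinite(self.Cl2) and self.Cl2 >= 0):
            raise InvalidParameterError(f"Cl2 must be finite and >= 0, got {self.Cl2!r}")


@dataclass(frozen=True)
class DoseSchedule:
    """Zero-order infusion events into the central compartment.

    Each event is ``(start, duration, rate)`` in (h, h, mg/h).  Events may
    overlap; overlapping rates add.
    """

    events: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        norm = []
        for ev in self.events:
            start, dur, rate = map(float, ev)
            if dur <= 0:
                raise ValueError(f"infusion duration must be > 0, got {dur}")
            if rate < 0:
                raise ValueError(f"infusion rate must be >= 0, got {rate}")
            if start < 0:
                raise ValueError(f"infusion start must be >= 0, got {start}")
            norm.append((start, dur, rate))
        object.__setattr__(self, "events", tuple(norm))

    @classmethod
    def loading_plus_continuous(
        cls,
        loading_mg: float,
        loading_duration_h: float,
        daily_mg: float,
        infusion_end_h: float,
    ) -> "DoseSchedule":
        """Loading infusion followed immediately by a continuous infusion.

        The continuous infusion runs at ``daily_mg / 24`` mg/h from the end
        of the load until ``infusion_end_h``.
        """
        events = [(0.0, loading_duration_h, loading_mg / loading_duration_h)]
        if infusion_end_h > loading_duration_h:
            events.append(
                (loading_duration_h, infusion_end_h - loading_duration_h, daily_mg / 24.0)
            )
        return cls(tuple(events))

    def breakpoints(self) -> list[float]:
        pts = {0.0}
        for start, dur, _ in self.events:
            pts.add(start)
            pts.add(start + dur)
        return sorted(pts)

    def rate_at(self, t: float) -> float:
        """Total infusion rate on the segment starting at time ``t``."""
        return sum(r for s, d, r in self.events if s <= t < s + d)

    def scaled(self, factor: float) -> "DoseSchedule":
        return DoseSchedule(tuple((s, d, r * factor) for s, d, r in self.events))


@dataclass(frozen=True)
class ConcentrationProfile:
    """Simulated amounts and concentrations on a time grid."""

    times: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    A1: np.ndarray
    A2: np.ndarray


def rate_constants(p: StructuralParams) -> dict[str, float]:
    """First-order rate constants (1/h) of the two-compartment system."""
    return {
        "k10": p.Cl1 / p.V1,
        "k12": p.Q / p.V1,
        "k21": p.Q / p.V2,
        "k20": p.Cl2 / p.V2,
    }


def _expm_coeffs(m11: float, m12: float, m21: float, m22: float, t):
    """Coefficients (a, b) with expm(M t) = a*I + b*M for a 2x2 matrix.

    Uses the eigen-decomposition of M; ``t`` may be a scalar or an array.
    The rate matrix of this model always has two real negative eigenvalues
    (its determinant is positive and trace negative); a tiny floor on the
    eigenvalue gap guards the analytically-possible but measure-zero
    repeated-root case.
    """
    tr = m11 + m22
    det = m11 * m22 - m12 * m21
    disc = tr * tr - 4.0 * det
    s = math.sqrt(max(disc, 0.0))
    if s < 1e-12:
        s = 1e-12
    l1 = 0.5 * (tr + s)
    l2 = 0.5 * (tr - s)
    e1 = np.exp(l1 * t)
    e2 = np.exp(l2 * t)
    b = (e1 - e2) / (l1 - l2)
    a = e1 - l1 * b
    return a, b


def propagate_segment(
    k10: float,
    k12: float,
    k21: float,
    k20: float,
    rate: float,
    a1: float,
    a2: float,
    t,
):
    """Amounts at elapsed time(s) ``t`` within one constant-rate segment.

    Exact solution ``A(t) = A_ss + expm(M t) (A0 - A_ss)`` of the linear
    system with constant input ``rate`` into compartment 1, starting from
    amounts ``(a1, a2)``.  ``t`` may be a scalar or an array.
    """
    m11 = -(k10 + k12)
    m12 = k21
    m21 = k12
    m22 = -(k21 + k20)
    det = m11 * m22 - m12 * m21
    if det == 0.0:
        # no elimination path at all (k10 = k20 = 0, possibly by floating
        # point cancellation): the system has no steady state; nudge the
        # determinant so the segment solution stays defined
        det = 1e-300
    # steady-state amounts for this segment: A_ss = -M^{-1} u, u = (rate, 0)
    ass1 = -m22 * rate / det
    ass2 = m21 * rate / det
    d1 = a1 - ass1
    d2 = a2 - ass2
    ca, cb = _expm_coeffs(m11, m12, m21, m22, t)
    new1 = ass1 + ca * d1 + cb * (m11 * d1 + m12 * d2)
    new2 = ass2 + ca * d2 + cb * (m21 * d1 + m22 * d2)
    return new1, new2


def simulate_profile(
    p: StructuralParams,
    d: DoseSchedule,
    times: Sequence[float] | np.ndarray,
) -> ConcentrationProfile:
    """Simulate amounts/concentrations on ``times`` from a drug-naive start.

    Solves the system exactly (matrix exponential on each constant-rate
    segment).  ``times`` must be sorted and non-negative; the initial
    amounts are zero.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if t.size and t[0] < 0:
        raise ValueError("times must be >= 0")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")

    k = rate_constants(p)
    k10, k12, k21, k20 = k["k10"], k["k12"], k["k21"], k["k20"]

    # segment boundaries: dose breakpoints plus the last requested time
    t_end = float(t[-1]) if t.size else 0.0
    bounds = [b for b in d.breakpoints() if b < t_end] + [t_end]
    bounds = sorted(set([0.0] + bounds))

    a1 = a2 = 0.0
    A1 = np.zeros_like(t)
    A2 = np.zeros_like(t)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        rate = d.rate_at(lo)
        mask = (t > lo) & (t <= hi)
        if np.any(mask):
            A1[mask], A2[mask] = propagate_segment(
                k10, k12, k21, k20, rate, a1, a2, t[mask] - lo
            )
        a1, a2 = propagate_segment(k10, k12, k21, k20, rate, a1, a2, hi - lo)
    # t == 0 entries keep the zero initial condition
    return ConcentrationProfile(times=t, C1=A1 / p.V1, C2=A2 / p.V2, A1=A1, A2=A2)


def steady_state(p: StructuralParams, rate: float) -> tuple[float, float]:
    """Closed-form steady-state concentrations under a constant infusion.

    Under a continuous infusion at ``rate`` mg/h the system settles at

        C1ss = rate / (Cl1 + Q*Cl2 / (Q + Cl2))
        C2ss = C1ss * Q / (Q + Cl2)

    i.e. the peritoneal-to-plasma ratio at steady state depends only on
    the competition between back-transfer (Q) and VAC removal (Cl2).
    """
    if rate < 0:
        raise ValueError("infusion rate must be >= 0")
    effective_cl = p.Cl1 + p.Q * p.Cl2 / (p.Q + p.Cl2)
    c1ss = rate / effective_cl
    c2ss = c1ss * p.Q / (p.Q + p.Cl2)
    return c1ss, c2ss
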