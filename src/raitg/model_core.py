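"""Deterministic forward model of tumor burden and serum thyroglobulin (Tg)
under repeated radioiodine (RAI, ¹³¹I) administrations.

The model couples three compartments:

* ``A(t)`` — effective radioiodine activity (GBq).  Each administration adds
  its activity ``A0`` instantaneously; between administrations the *effect*
  decays as ``dA/dt = -a·ln2·A``.  The rate ``a`` describes the delayed
  biological action of the isotope on tumor cells, not its physical
  half-life.
* ``N(t)`` — metastatic tumor cell count.  Exponential growth with doubling
  time ``Td`` (months) opposed by a log-linear kill term proportional to the
  instantaneous activity: ``dN/dt = (ln2/Td)·N - ρ·A·N``.
* ``Tg(t)`` — serum thyroglobulin concentration (µg/L), produced by tumor
  cells at rate ``λ`` per cell and eliminated at rate ``ke``:
  ``dTg/dt = -ke·Tg + λ·N``.

``A`` and ``N`` admit closed forms (superposition of exponentials, and
``N0·exp(ln2·t/Td - ρ·∫A)`` respectively); ``Tg`` is evaluated by variation
of constants with adaptive quadrature so that no solver error contaminates
downstream likelihoods.

Units throughout: time in months, activity in GBq, Tg in µg/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.integrate import quad

LN2 = math.log(2.0)

__all__ = [
    "LN2",
    "DoseEvent",
    "Regimen",
    "IndividualParameters",
    "Trajectory",
    "SimulatedObservations",
    "activity_at",
    "activity_integral",
    "tumor_at",
    "tg_trajectory",
    "simulate_observations",
]


@dataclass(frozen=True)
class DoseEvent:
    """A single RAI administration: ``activity`` GBq given at ``time`` months."""

    time: float
    activity: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"dose time must be finite and >= 0, got {self.time}")
        if not np.isfinite(self.activity) or self.activity <= 0:
            raise ValueError(f"dose activity must be finite and > 0, got {self.activity}")


@dataclass(frozen=True)
class Regimen:
    """An ordered, strictly increasing sequence of dose events.

    The time origin is the first administration, so ``doses[0].time == 0``.
    """

    doses: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        if len(self.doses) == 0:
            raise ValueError("a regimen must contain at least one dose")
        object.__setattr__(self, "doses", tuple(self.doses))
        times = [d.time for d in self.doses]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")
        if times[0] != 0.0:
            raise ValueError("the first dose defines the time origin and must be at t=0")

    @property
    def times(self) -> np.ndarray:
        return np.array([d.time for d in self.doses], dtype=float)

    @property
    def activities(self) -> np.ndarray:
        return np.array([d.activity for d in self.doses], dtype=float)

    @classmethod
    def single(cls, activity: float) -> "Regimen":
        return cls((DoseEvent(0.0, activity),))

    @classmethod
    def evenly_spaced(cls, n_cycles: int, activity: float, interval: float) -> "Regimen":
        return cls(tuple(DoseEvent(i * interval, activity) for i in range(n_cycles)))

    def truncated(self, t_max: float) -> "Regimen":
        """Doses administered at or before ``t_max`` (at least the first)."""
        kept = tuple(d for d in self.doses if d.time <= t_max)
        return Regimen(kept if kept else self.doses[:1])


@dataclass(frozen=True)
class IndividualParameters:
    """Per-patient kinetic parameters and latent mixture category.

    rho : 1/(GBq·month) — efficiency of RAI on tumor cells.
    a : 1/month — decay rate of the delayed RAI effect.
    lam : µg/(L·month·cell) — Tg production per tumor cell.
    ke : 1/month — Tg elimination rate from blood.
    Td : months — tumor doubling time under treatment.
    N0 : cells — tumor cell count at the start of treatment.
    category : {1, 2} — latent group, 1 = non-responder (short Td).
    """

    rho: float
    a: float
    lam: float
    ke: float
    Td: float
    N0: float
    category: int = 1

    def __post_init__(self) -> None:
        for name in ("rho", "a", "lam", "ke", "Td"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if not np.isfinite(self.N0) or self.N0 < 1:
            raise ValueError(f"N0 must be >= 1 cell, got {self.N0}")
        if self.category not in (1, 2):
            raise ValueError(f"category must be 1 or 2, got {self.category}")

    @property
    def steady_state_tg(self) -> float:
        """Tg level at which production balances elimination for N = N0."""
        return self.lam * self.N0 / self.ke

    def replace(self, **kwargs) -> "IndividualParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Trajectory:
    """Aligned noise-free time courses of the three compartments."""

    times: np.ndarray
    activity: np.ndarray
    tumor: np.ndarray
    tg: np.ndarray


class SimulatedObservations(NamedTuple):
    values: np.ndarray
    truncated: np.ndarray  # True where a negative draw was clipped to 0


def _check_times(t: np.ndarray) -> None:
    if np.any(t < 0):
        raise ValueError("times must be non-negative (t=0 is the first administration)")


def activity_at(t, regimen: Regimen, a: float):
    """Total effective activity at time(s) ``t`` (GBq).

    Linear superposition of the per-dose decay law: each dose contributes
    ``A0·2^(-a·(t - t_dose))`` for ``t >= t_dose`` and nothing before.
    """
    if a <= 0:
        raise ValueError(f"effect decay rate a must be > 0, got {a}")
    t_arr = np.asarray(t, dtype=float)
    _check_times(t_arr)
    dt = t_arr[..., None] - regimen.times
    contrib = np.where(dt >= 0, regimen.activities * np.exp2(-a * np.maximum(dt, 0.0)), 0.0)
    out = contrib.sum(axis=-1)
    return out if t_arr.ndim else float(out)


def activity_integral(t0: float, t1: float, regimen: Regimen, a: float) -> float:
    """Exact ``∫_{t0}^{t1} A(s) ds`` (GBq·month), piecewise analytic.

    Each dose contributes ``A0/(a·ln2) · (2^(-a·max(t0-td,0)) - 2^(-a·max(t1-td,0)))``,
    which is zero for doses given after ``t1``.  Additive over subintervals.
    """
    if t1 < t0:
        raise ValueError(f"need t0 <= t1, got [{t0}, {t1}]")
    if t0 < 0:
        raise ValueError("integration bounds must be non-negative")
    if a <= 0:
        raise ValueError(f"effect decay rate a must be > 0, got {a}")
    td = regimen.times
    lo = np.exp2(-a * np.maximum(t0 - td, 0.0))
    hi = np.exp2(-a * np.maximum(t1 - td, 0.0))
    return float(np.sum(regimen.activities * (lo - hi)) / (a * LN2))


def _cumulative_activity_integral(t: np.ndarray, regimen: Regimen, a: float) -> np.ndarray:
    """Vectorised ``∫_0^{t} A(s) ds`` for an array of times."""
    dt = np.maximum(np.asarray(t, dtype=float)[..., None] - regimen.times, 0.0)
    return np.sum(regimen.activities * (1.0 - np.exp2(-a * dt)), axis=-1) / (a * LN2)


def tumor_at(t, p: IndividualParameters, regimen: Regimen):
    """Tumor cell count at time(s) ``t``.

    Semi-analytic solution ``N(t) = N0·exp((ln2/Td)·t - ρ·∫_0^t A(s) ds)``;
    strictly positive, equals ``N0`` at ``t = 0``.
    """
    t_arr = np.asarray(t, dtype=float)
    _check_times(t_arr)
    integ = _cumulative_activity_integral(t_arr, regimen, p.a)
    out = p.N0 * np.exp(LN2 * t_arr / p.Td - p.rho * integ)
    return out if t_arr.ndim else float(out)


def tg_trajectory(
    times: Sequence[float],
    p: IndividualParameters,
    regimen: Regimen,
    tg0: float,
    epsrel: float = 1e-8,
) -> np.ndarray:
    """Noise-free Tg (µg/L) at the requested times.

    Variation of constants,
    ``Tg(t) = tg0·e^(-ke·t) + λ·∫_0^t e^(-ke·(t-s))·N(s) ds``,
    marched over the knots formed by dose and observation times with adaptive
    quadrature on each smooth segment (the integrand has derivative kinks at
    dose times only).
    """
    t_req = np.asarray(times, dtype=float)
    if t_req.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if t_req.size and np.any(np.diff(t_req) < 0):
        raise ValueError("times must be sorted in increasing order")
    if t_req.size:
        _check_times(t_req)
    if tg0 < 0:
        raise ValueError(f"tg0 must be >= 0, got {tg0}")
    if t_req.size == 0:
        return np.empty(0)

    t_max = float(t_req[-1])
    dose_t = regimen.times
    knots = np.unique(np.concatenate([[0.0], dose_t[dose_t < t_max], t_req]))

    g = LN2 / p.Td

    def integrand(s: float, t_end: float) -> float:
        integ = _cumulative_activity_integral(np.array(s), regimen, p.a)
        return math.exp(-p.ke * (t_end - s) + g * s - p.rho * float(integ))

    tg_at_knot = np.empty(knots.size)
    tg_at_knot[0] = tg0
    for k in range(knots.size - 1):
        u0, u1 = knots[k], knots[k + 1]
        val, _ = quad(integrand, u0, u1, args=(u1,), epsabs=0.0, epsrel=epsrel, limit=200)
        tg_at_knot[k + 1] = tg_at_knot[k] * math.exp(-p.ke * (u1 - u0)) + p.lam * p.N0 * val

    idx = np.searchsorted(knots, t_req)
    return tg_at_knot[idx]


def simulate_observations(
    p: IndividualParameters,
    regimen: Regimen,
    times: Sequence[float],
    b: float,
    rng,
    tg0: float | None = None,
) -> SimulatedObservations:
    """Noisy Tg observations under the proportional residual model.

    ``y = f·(1 + b·ε)`` with ``ε ~ N(0,1)`` i.i.d. across observations;
    ``b = 0`` reproduces the noise-free trajectory exactly.  Negative draws
    (possible because ε is unbounded) are truncated at 0 and flagged; the
    fitting likelihood keeps the untruncated normal model and treats recorded
    zeros as left-censored.

    ``tg0=None`` starts Tg at the individual's steady state λ·N0/ke, which is
    the natural choice when simulating a patient arriving with established
    disease.
    """
    if b < 0:
        raise ValueError(f"proportional error coefficient b must be >= 0, got {b}")
    generator = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if tg0 is None:
        tg0 = p.steady_state_tg
    f = tg_trajectory(times, p, regimen, tg0)
    if b == 0:
        return SimulatedObservations(f.copy(), np.zeros(f.size, dtype=bool))
    eps = generator.standard_normal(f.size)
    y = f * (1.0 + b * eps)
    truncated = y < 0
    return SimulatedObservations(np.where(truncated, 0.0, y), truncated)
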