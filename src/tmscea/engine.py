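"""Deterministic Markov cohort engine.

Propagates state occupancy of a closed cohort through a per-cycle schedule
of 5x5 transition matrices, embeds background mortality, and accumulates
discounted, half-cycle-corrected costs and quality-adjusted life-years
(QALYs) plus the societal quantities (productivity costs, informal-care
hours) attached to each state.

Conventions
-----------
* Cycle length 2 weeks, 39 cycles (~18 months), 26 cycles per year.
* Discounting at 3.5% per annum, applied as ``(1+r)**(-t_years)`` with the
  half-cycle-corrected reward discounted at the cycle midpoint.
* The half-cycle correction is the trapezoidal variant: each cycle's reward
  weight is the mean of the start- and end-of-cycle occupancy.
* Mortality is a per-cycle probability applied uniformly across alive
  states (rate-scaled from an annual probability, elevated by the relative
  risk of all-cause mortality in severe unipolar depression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .states import N_ALIVE, N_STATES, HealthState

__all__ = [
    "ModelSettings",
    "TransitionSchedule",
    "CohortTrace",
    "StateRewards",
    "MortalityInputs",
    "Totals",
    "discount_factor",
    "per_cycle_death_prob",
    "embed_death",
    "run_cohort",
    "accumulate",
]

_ROW_TOL = 1e-10
_TRACE_TOL = 1e-9


@dataclass(frozen=True)
class ModelSettings:
    """Global model settings.

    Defaults encode the base case: 2-week cycles over an 18-month horizon
    (39 cycles, 26 cycles/year), 3.5% annual discounting on both costs and
    outcomes, half-cycle correction on.
    """

    cycle_length_weeks: float = 2.0
    horizon_cycles: int = 39
    annual_discount_rate: float = 0.035
    cycles_per_year: float = 26.0
    half_cycle_correction: bool = True

    def __post_init__(self) -> None:
        if self.cycle_length_weeks <= 0 or self.horizon_cycles <= 0:
            raise ValueError("cycle length and horizon must be positive")
        if self.annual_discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        if self.cycles_per_year <= 0:
            raise ValueError("cycles_per_year must be positive")

    @property
    def horizon_weeks(self) -> float:
        return self.cycle_length_weeks * self.horizon_cycles


def discount_factor(cycle_index: float, settings: ModelSettings) -> float:
    """Discount factor ``(1+r)**(-cycle_index/cycles_per_year)``.

    ``cycle_index`` may be fractional (mid-cycle discounting uses c+0.5).
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be non-negative")
    r = settings.annual_discount_rate
    return float((1.0 + r) ** (-cycle_index / settings.cycles_per_year))


@dataclass(frozen=True)
class MortalityInputs:
    """Background mortality for the cohort.

    ``life_table`` rows give annual all-cause mortality probability ``q``
    by age and sex; the cohort's annual probability is the sex-mix-weighted
    value at ``cohort_age`` (the cohort is not re-aged over the 18-month
    horizon). ``relative_risk`` elevates the general-population rate to the
    all-cause mortality of severe unipolar depression and applies
    identically in every alive state.
    """

    life_table: pd.DataFrame  # columns: age, sex, annual_mortality
    relative_risk: float = 1.58
    cohort_age: float = 45.0
    cohort_female_fraction: float = 0.55

    def __post_init__(self) -> None:
        if self.relative_risk <= 0:
            raise ValueError("relative risk must be positive")
        q = np.asarray(self.life_table["annual_mortality"], dtype=float)
        if np.any(q < 0) or np.any(q >= 1):
            raise ValueError("annual mortality must lie in [0, 1)")

    def annual_probability(self) -> float:
        """Sex-mix-weighted annual mortality at the cohort age."""
        lt = self.life_table
        out = 0.0
        for sex, w in (("female", self.cohort_female_fraction),
                       ("male", 1.0 - self.cohort_female_fraction)):
            sub = lt[lt["sex"] == sex]
            if sub.empty:  # unstratified table
                sub = lt
            i = (sub["age"] - self.cohort_age).abs().idxmin()
            out += w * float(sub.loc[i, "annual_mortality"])
        return out


def per_cycle_death_prob(inputs: MortalityInputs, settings: ModelSettings) -> float:
    """Per-cycle death probability via rate scaling.

    Converts the annual probability ``q`` to a rate ``h = -ln(1-q)``,
    multiplies by the relative risk, and returns
    ``1 - exp(-h * RR / cycles_per_year)``.
    """
    q = inputs.annual_probability()
    if q >= 1.0:
        raise ValueError("annual mortality of 1 implies an infinite rate")
    h = -np.log1p(-q)
    return float(-np.expm1(-h * inputs.relative_risk / settings.cycles_per_year))


def _check_row_stochastic(m: np.ndarray, tol: float = _ROW_TOL) -> None:
    if np.any(m < -tol) or np.any(m > 1 + tol):
        raise ValueError("transition probabilities must lie in [0, 1]")
    if not np.allclose(m.sum(axis=-1), 1.0, atol=max(tol, 1e-9)):
        raise ValueError("transition matrix rows must sum to 1")


def embed_death(alive_matrix: np.ndarray, p_death: float) -> np.ndarray:
    """Embed a uniform per-cycle death probability into a 4x4 alive matrix.

    Each alive row becomes ``(1-p_death) * row`` with ``p_death`` appended
    as the Dead column; the Dead row is the unit vector on Dead.
    """
    alive_matrix = np.asarray(alive_matrix, dtype=float)
    if alive_matrix.shape != (N_ALIVE, N_ALIVE):
        raise ValueError("alive_matrix must be 4x4")
    _check_row_stochastic(alive_matrix)
    if not (0.0 <= p_death <= 1.0):
        raise ValueError("p_death must be a probability")
    full = np.zeros((N_STATES, N_STATES))
    full[:N_ALIVE, :N_ALIVE] = (1.0 - p_death) * alive_matrix
    full[:N_ALIVE, HealthState.DEAD] = p_death
    full[HealthState.DEAD, HealthState.DEAD] = 1.0
    return full


@dataclass(frozen=True)
class TransitionSchedule:
    """Per-cycle 5x5 row-stochastic transition matrices over the horizon."""

    matrices: np.ndarray  # (horizon_cycles, 5, 5)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1:] != (N_STATES, N_STATES):
            raise ValueError("schedule must be a (n_cycles, 5, 5) array")
        _check_row_stochastic(m)
        dead = m[:, HealthState.DEAD, :]
        expected = np.zeros(N_STATES)
        expected[HealthState.DEAD] = 1.0
        if not np.allclose(dead, expected, atol=_ROW_TOL):
            raise ValueError("Dead must be absorbing in every cycle")
        object.__setattr__(self, "matrices", m)

    def __len__(self) -> int:
        return self.matrices.shape[0]

    @classmethod
    def from_alive(
        cls, alive_matrices: np.ndarray, p_death: float
    ) -> "TransitionSchedule":
        """Build a schedule by embedding mortality into 4x4 alive matrices."""
        alive = np.asarray(alive_matrices, dtype=float)
        if alive.ndim != 3 or alive.shape[1:] != (N_ALIVE, N_ALIVE):
            raise ValueError("alive matrices must be (n_cycles, 4, 4)")
        if not (0.0 <= p_death <= 1.0):
            raise ValueError("p_death must be a probability")
        full = np.zeros((alive.shape[0], N_STATES, N_STATES))
        full[:, :N_ALIVE, :N_ALIVE] = (1.0 - p_death) * alive
        full[:, :N_ALIVE, HealthState.DEAD] = p_death
        full[:, HealthState.DEAD, HealthState.DEAD] = 1.0
        return cls(full)


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy by cycle; row 0 is the initial distribution."""

    occupancy: np.ndarray  # (horizon_cycles + 1, 5)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValueError("occupancy must be (n_cycles+1, 5)")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=_TRACE_TOL):
            raise ValueError("occupancy rows must sum to 1")
        if np.any(np.diff(occ[:, HealthState.DEAD]) < -_TRACE_TOL):
            raise ValueError("Dead occupancy must be non-decreasing")
        object.__setattr__(self, "occupancy", occ)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive_composition(self, cycle: int) -> np.ndarray:
        """Alive-state composition (renormalised 4-vector) at a cycle."""
        alive = self.occupancy[cycle, :N_ALIVE]
        total = alive.sum()
        if total <= 0:
            raise ValueError("no alive mass at this cycle")
        return alive / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.occupancy,
            columns=[s.name.lower() for s in HealthState],
        ).rename_axis("cycle")


def run_cohort(
    initial: np.ndarray, schedule: TransitionSchedule, settings: ModelSettings
) -> CohortTrace:
    """Propagate the cohort: ``occupancy[c+1] = occupancy[c] @ matrices[c]``."""
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (N_STATES,) or not np.isclose(initial.sum(), 1.0):
        raise ValueError("initial distribution must be a 5-vector summing to 1")
    if len(schedule) != settings.horizon_cycles:
        raise ValueError(
            f"schedule has {len(schedule)} cycles, settings expect "
            f"{settings.horizon_cycles}"
        )
    occ = np.empty((settings.horizon_cycles + 1, N_STATES))
    occ[0] = initial
    for c in range(settings.horizon_cycles):
        occ[c + 1] = occ[c] @ schedule.matrices[c]
    return CohortTrace(occ)


@dataclass(frozen=True)
class StateRewards:
    """Per-state, per-cycle rewards; index order follows :class:`HealthState`.

    Utilities are annual quality weights in [-0.594, 1] (the EQ-5D-3L
    floor); the engine converts them to per-cycle QALYs. Dead receives zero
    for every quantity.
    """

    cost_per_cycle: np.ndarray
    utility: np.ndarray
    informal_hours_per_cycle: np.ndarray = field(
        default_factory=lambda: np.zeros(N_STATES)
    )
    productivity_cost_per_cycle: np.ndarray = field(
        default_factory=lambda: np.zeros(N_STATES)
    )

    def __post_init__(self) -> None:
        for name in (
            "cost_per_cycle",
            "utility",
            "informal_hours_per_cycle",
            "productivity_cost_per_cycle",
        ):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (N_STATES,):
                raise ValueError(f"{name} must have one entry per state")
            object.__setattr__(self, name, v)
        d = HealthState.DEAD
        if any(
            getattr(self, n)[d] != 0.0
            for n in (
                "cost_per_cycle",
                "utility",
                "informal_hours_per_cycle",
                "productivity_cost_per_cycle",
            )
        ):
            raise ValueError("Dead must carry zero rewards")
        if np.any(self.utility > 1.0) or np.any(self.utility[:N_ALIVE] < -0.594):
            raise ValueError("utilities must lie in [-0.594, 1]")

    @classmethod
    def from_alive(
        cls,
        cost: np.ndarray,
        utility: np.ndarray,
        informal_hours: np.ndarray | None = None,
        productivity_cost: np.ndarray | None = None,
    ) -> "StateRewards":
        """Build rewards from 4-vectors over alive states (Dead gets zero)."""

        def pad(v):
            if v is None:
                return np.zeros(N_STATES)
            return np.concatenate([np.asarray(v, dtype=float), [0.0]])

        return cls(pad(cost), pad(utility), pad(informal_hours), pad(productivity_cost))


@dataclass(frozen=True)
class Totals:
    """Accumulated (discounted) totals for one arm's cohort run."""

    cost: float
    qalys: float
    informal_hours: float
    productivity_cost: float

    def __add__(self, other: "Totals") -> "Totals":
        return Totals(
            self.cost + other.cost,
            self.qalys + other.qalys,
            self.informal_hours + other.informal_hours,
            self.productivity_cost + other.productivity_cost,
        )


def accumulate(
    trace: CohortTrace,
    rewards: StateRewards,
    settings: ModelSettings,
    variant: Literal["half_cycle", "start", "end"] | None = None,
) -> Totals:
    """Accumulate discounted totals over the cohort trace.

    With the half-cycle correction (the default when
    ``settings.half_cycle_correction``), each cycle's reward weights are
    the trapezoidal mean of start- and end-of-cycle occupancy, discounted
    at the cycle midpoint. ``variant`` overrides the correction for bound
    checks: ``"start"``/``"end"`` use the corresponding occupancy endpoint
    (discounted at the same midpoint so only the occupancy convention
    differs).
    """
    if variant is None:
        variant = "half_cycle" if settings.half_cycle_correction else "start"
    occ = trace.occupancy
    if trace.n_cycles != settings.horizon_cycles:
        raise ValueError("trace length does not match settings horizon")
    if variant == "half_cycle":
        weights = 0.5 * (occ[:-1] + occ[1:])
    elif variant == "start":
        weights = occ[:-1]
    elif variant == "end":
        weights = occ[1:]
    else:  # pragma: no cover
        raise ValueError(f"unknown variant {variant!r}")

    cycles = np.arange(settings.horizon_cycles)
    disc = (1.0 + settings.annual_discount_rate) ** (
        -(cycles + 0.5) / settings.cycles_per_year
    )
    qaly_scale = settings.cycle_length_weeks / 52.0

    def total(per_state: np.ndarray, scale: float = 1.0) -> float:
        return float(disc @ (weights @ per_state) * scale)

    return Totals(
        cost=total(rewards.cost_per_cycle),
        qalys=total(rewards.utility, qaly_scale),
        informal_hours=total(rewards.informal_hours_per_cycle),
        productivity_cost=total(rewards.productivity_cost_per_cycle),
    )
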