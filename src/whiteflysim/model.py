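"""Discrete-time predator--prey model of a scaled-down whitefly colony.

The colony is tracked weekly through five compartments:

* ``P`` -- total host-plant leaf surface area (sq.in.), which grows
  multiplicatively and is eroded by insect feeding load,
* ``A`` -- viable adult whiteflies,
* ``N`` -- nymphs, ``E`` -- eggs,
* ``T`` -- total adults ever present (inoculated plus emerged, viable and
  dead); the harvest census counts ``T`` because dead adults are not
  distinguished from live ones at brush-out.

The weekly map (synchronous update, all right-hand sides at week *i*) is::

    P' = P*G_m - beta*P*(A + E/4 + N/2)          (clamped at 0)
    A' = (delta*N + A) / (1 + mu_A)
    T' = T + delta*N
    N' = (gamma*E + (1 - delta)*N) / (1 + mu_N)
    E' = (r*P/(K + P)*A + (1 - gamma)*E) / (1 + mu_E)

The placement of the ``1/(1+mu)`` survival denominators is ambiguous in the
typeset source equations; by default it divides the whole bracketed
numerator (consistently across the adult, nymph and egg equations).  The
alternate reading, where it divides only the carried-over last term, is
available via ``ModelParameters.denominator_scope = "last_term"``.

Dead adults are derived, not stored: ``D = T - A``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

__all__ = [
    "ModelParameters",
    "ParameterBounds",
    "ColonyState",
    "Trajectory",
    "default_parameters",
    "default_bounds",
    "step",
    "simulate",
    "viable_and_dead",
    "calibrate_beta",
    "N_PLANTS_DEFAULT",
    "AREA_PER_PLANT_SQIN",
    "REFERENCE_INITIAL_AREA_SQIN",
    "INOCULUM_DEFAULT",
    "HARVEST_WEEK_DEFAULT",
    "BETA_DEFAULT",
]

#: Standard study condition: 5 host plants of 25 sq.in. leaf area each,
#: inoculated with 100 adults and harvested after 7 weekly steps (47 days).
N_PLANTS_DEFAULT = 5
AREA_PER_PLANT_SQIN = 25.0
REFERENCE_INITIAL_AREA_SQIN = N_PLANTS_DEFAULT * AREA_PER_PLANT_SQIN
INOCULUM_DEFAULT = 100.0
HARVEST_WEEK_DEFAULT = 7

#: Plant-damage coefficient per insect-equivalent per week.  Calibrated once
#: (see :func:`calibrate_beta`) so that the standard run -- 100 adults on
#: 125 sq.in. with the bound-midpoint rates -- ends at 4-fold plant growth
#: after 7 weekly steps, matching the observed harvest-time leaf areas.
#: Regenerate with ``calibrate_beta()``.
BETA_DEFAULT = 1.3167569879442453e-05

_RATE_PARAMS = ("mu_A", "mu_N", "mu_E", "delta", "gamma")


class ConfigurationError(ValueError):
    """Raised for unknown parameter names or invalid configuration values."""


@dataclass(frozen=True)
class ModelParameters:
    """All rate and shape constants of the weekly colony map.

    Rates are per week.  ``K`` shares units with ``P`` (sq.in.).
    """

    G_m: float
    beta: float
    mu_A: float
    mu_N: float
    mu_E: float
    delta: float
    gamma: float
    r: float
    K: float
    denominator_scope: str = "full"

    def __post_init__(self) -> None:
        numeric = {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "denominator_scope"
        }
        for name, value in numeric.items():
            if not math.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value}")
            if value < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {value}")
        if not self.G_m > 0:
            raise ValueError("G_m must be > 0")
        if not self.K > 0:
            raise ValueError("K must be > 0")
        if self.gamma > 1 or self.delta > 1:
            raise ValueError("gamma and delta are weekly fractions and must be <= 1")
        if self.denominator_scope not in ("full", "last_term"):
            raise ValueError(
                "denominator_scope must be 'full' or 'last_term', got "
                f"{self.denominator_scope!r}"
            )

    def within_bounds(self, bounds: "ParameterBounds") -> bool:
        """True iff every bounded parameter lies in its closed interval."""
        return all(
            bounds[name][0] <= getattr(self, name) <= bounds[name][1]
            for name in bounds.names()
        )

    def to_dict(self) -> Dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if f.name != "denominator_scope"
        }

    def replace(self, **overrides: float) -> "ModelParameters":
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
        return replace(self, **overrides)


@dataclass(frozen=True)
class ParameterBounds:
    """Closed per-parameter intervals used for calibration.

    Defaults are the literature-derived bound regions for the death and
    transition rates; ``beta`` gets a wide nonnegative box since no prior
    interval is reported for it.
    """

    intervals: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "mu_A": (0.43, 0.70),
            "delta": (0.43, 0.58),
            "gamma": (0.78, 1.0),
            "mu_N": (0.20, 0.40),
            "mu_E": (0.20, 0.40),
            "beta": (0.0, 1e-3),
        }
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.intervals.items():
            if lo > hi:
                raise ValueError(f"bounds for {name!r} have lo > hi: [{lo}, {hi}]")

    def __getitem__(self, name: str) -> Tuple[float, float]:
        return self.intervals[name]

    def names(self) -> List[str]:
        return list(self.intervals)

    def midpoint(self, name: str) -> float:
        lo, hi = self.intervals[name]
        return 0.5 * (lo + hi)


def default_bounds() -> ParameterBounds:
    return ParameterBounds()


@dataclass(frozen=True)
class ColonyState:
    """The five-compartment weekly state at week index ``week``."""

    week: int
    P: float
    A: float
    N: float
    E: float
    T: float

    def __post_init__(self) -> None:
        if self.week < 0:
            raise ValueError("week index must be >= 0")
        for name in ("P", "A", "N", "E", "T"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"compartment {name} must be finite and >= 0, got {v}")
        if self.T < self.A - 1e-9:
            raise ValueError(f"T ({self.T}) must be >= A ({self.A})")


@dataclass(frozen=True)
class Trajectory:
    """An ordered weekly trajectory with the parameters that produced it."""

    states: Tuple[ColonyState, ...]
    params: ModelParameters
    collapsed: bool = False

    def __post_init__(self) -> None:
        weeks = [s.week for s in self.states]
        if weeks != list(range(weeks[0], weeks[0] + len(weeks))):
            raise ValueError("trajectory weeks must be strictly consecutive")
        if weeks and weeks[0] != 0:
            raise ValueError("trajectory must start at week 0 (the inoculation state)")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @property
    def initial(self) -> ColonyState:
        return self.states[0]

    @property
    def final(self) -> ColonyState:
        return self.states[-1]

    def series(self, compartment: str) -> List[float]:
        return [getattr(s, compartment) for s in self.states]


def inoculation_state(
    inoculum: float = INOCULUM_DEFAULT,
    initial_area: float = REFERENCE_INITIAL_AREA_SQIN,
) -> ColonyState:
    """Week-0 state: counted adults on fresh plants, no eggs or nymphs yet."""
    return ColonyState(week=0, P=initial_area, A=inoculum, N=0.0, E=0.0, T=inoculum)


def default_parameters(
    overrides: Optional[Mapping[str, float]] = None,
    *,
    initial_area: float = REFERENCE_INITIAL_AREA_SQIN,
) -> ModelParameters:
    """The documented default parameter set.

    Death and transition rates sit at the midpoints of their bound regions.
    ``r`` = 25 eggs per adult per week: 109 lifetime eggs over a two-week
    adult life gives ~50 per week, halved because unfertilized (male) eggs
    do not contribute future layers.  ``G_m`` = 4^(1/6): the observed 4-fold
    leaf-area increase over the 6 weeks of insect-free growth.  ``K`` =
    0.25 x the reference initial area, so egg-laying starts at 80% of its
    saturated rate.  ``beta`` is the frozen calibration constant
    :data:`BETA_DEFAULT`.
    """
    b = default_bounds()
    params = ModelParameters(
        G_m=4.0 ** (1.0 / 6.0),
        beta=BETA_DEFAULT,
        mu_A=b.midpoint("mu_A"),
        mu_N=b.midpoint("mu_N"),
        mu_E=b.midpoint("mu_E"),
        delta=b.midpoint("delta"),
        gamma=b.midpoint("gamma"),
        r=25.0,
        K=0.25 * initial_area,
    )
    if overrides:
        params = params.replace(**dict(overrides))
    return params


def step(state: ColonyState, params: ModelParameters) -> ColonyState:
    """Advance the colony one week (synchronous update)."""
    P, A, N, E, T = state.P, state.A, state.N, state.E, state.T
    p = params

    load = A + E / 4.0 + N / 2.0
    P_next = P * p.G_m - p.beta * P * load
    if P_next < 0.0:
        P_next = 0.0

    lay = p.r * P / (p.K + P) * A if P > 0.0 else 0.0

    if p.denominator_scope == "full":
        A_next = (p.delta * N + A) / (1.0 + p.mu_A)
        N_next = (p.gamma * E + (1.0 - p.delta) * N) / (1.0 + p.mu_N)
        E_next = (lay + (1.0 - p.gamma) * E) / (1.0 + p.mu_E)
    else:  # survival factor applied to the carried-over term only
        A_next = p.delta * N + A / (1.0 + p.mu_A)
        N_next = p.gamma * E + (1.0 - p.delta) * N / (1.0 + p.mu_N)
        E_next = lay + (1.0 - p.gamma) * E / (1.0 + p.mu_E)

    T_next = T + p.delta * N
    return ColonyState(
        week=state.week + 1, P=P_next, A=A_next, N=N_next, E=E_next, T=T_next
    )


def simulate(
    initial: ColonyState, params: ModelParameters, n_weeks: int
) -> Trajectory:
    """Iterate :func:`step` ``n_weeks`` times from ``initial``.

    The collapse flag is set if the plant compartment hits zero at any step
    (the damage term is not positivity-preserving at high insect load).
    """
    if n_weeks < 0:
        raise ValueError("n_weeks must be >= 0")
    states = [initial]
    collapsed = initial.P == 0.0
    for _ in range(n_weeks):
        nxt = step(states[-1], params)
        if nxt.P == 0.0:
            collapsed = True
        states.append(nxt)
    return Trajectory(states=tuple(states), params=params, collapsed=collapsed)


def viable_and_dead(state: ColonyState) -> Tuple[float, float]:
    """Split the cumulative adult count into (viable, dead) = (A, T - A)."""
    if state.T < state.A:
        raise ValueError(
            f"invariant violation: T ({state.T}) < A ({state.A}); "
            "dead count would be negative"
        )
    return state.A, state.T - state.A


def calibrate_beta(
    target_fold: float = 4.0,
    inoculum: float = INOCULUM_DEFAULT,
    initial_area: float = REFERENCE_INITIAL_AREA_SQIN,
    n_weeks: int = HARVEST_WEEK_DEFAULT,
    tol: float = 1e-12,
) -> float:
    """Solve for the damage coefficient beta by bisection.

    Finds the beta at which the standard inoculated run ends at
    ``target_fold`` times the initial plant area after ``n_weeks`` weekly
    steps, with every other parameter at its documented default.  The final
    area fold is strictly decreasing in beta, so bisection is exact.
    """

    def fold_at(beta: float) -> float:
        params = default_parameters({"beta": beta}, initial_area=initial_area)
        traj = simulate(inoculation_state(inoculum, initial_area), params, n_weeks)
        return traj.final.P / initial_area

    lo, hi = 0.0, 1e-3
    if fold_at(lo) < target_fold:
        raise ValueError("target fold unreachable even with beta = 0")
    while fold_at(hi) > target_fold:
        hi *= 2.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if fold_at(mid) > target_fold:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
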