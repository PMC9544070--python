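"""Planning tools: one-at-a-time deviation analysis and model inversion.

The deviation analysis perturbs the three controllable inputs of a colony
iteration -- initial leaf area, inoculum size and proliferation duration --
one at a time around the standard condition (5 plants x 25 sq.in., 100
adults, 7 weeks) and reports the ratio of the perturbed final cumulative
adult count to the standard one (no change = 1).  Duration perturbations
are rounded to whole weeks, so a 15% deviation on 7 weeks means +/- 1 week.

Model inversion runs the recurrence backwards in effect: given a harvest
total, bisection on the inoculum A0 finds the initial adult count that the
model maps onto that harvest (final T is monotone increasing in A0 in the
operating regime).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .model import (
    AREA_PER_PLANT_SQIN,
    HARVEST_WEEK_DEFAULT,
    INOCULUM_DEFAULT,
    N_PLANTS_DEFAULT,
    ModelParameters,
    inoculation_state,
    simulate,
)

__all__ = [
    "StandardCondition",
    "DeviationResult",
    "deviation_analysis",
    "back_calculate_inoculum",
    "recommend_inoculum",
    "BISECTION_TOL_ADULTS",
]

#: Bisection tolerance on the recovered inoculum, in adults.  Far below the
#: counting error of the inoculation photographs.
BISECTION_TOL_ADULTS = 0.25

_VARIABLES = ("initial_area", "inoculum", "duration")


@dataclass(frozen=True)
class StandardCondition:
    """The reference colony iteration all deviation ratios are relative to."""

    area_per_plant: float = AREA_PER_PLANT_SQIN
    n_plants: int = N_PLANTS_DEFAULT
    inoculum: float = INOCULUM_DEFAULT
    duration_weeks: int = HARVEST_WEEK_DEFAULT

    def __post_init__(self) -> None:
        if self.area_per_plant <= 0 or self.inoculum <= 0:
            raise ValueError("areas and inoculum must be positive")
        if self.n_plants < 1 or self.duration_weeks < 1:
            raise ValueError("n_plants and duration_weeks must be >= 1")

    @property
    def initial_area(self) -> float:
        return self.area_per_plant * self.n_plants


@dataclass(frozen=True)
class DeviationResult:
    variable: str
    fraction: float
    ratio: float

    def __post_init__(self) -> None:
        if self.variable not in _VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.ratio <= 0:
            raise ValueError("deviation ratio must be > 0")


def _final_T(
    params: ModelParameters, area: float, inoculum: float, weeks: int
) -> float:
    return simulate(inoculation_state(inoculum, area), params, weeks).final.T


def deviation_analysis(
    params: ModelParameters,
    standard: Optional[StandardCondition] = None,
    area_fracs: Sequence[float] = (-0.6, 0.0, 0.6),
    inoc_fracs: Sequence[float] = (-0.6, 0.0, 0.6),
    duration_fracs: Sequence[float] = (-1 / 7, 0.0, 1 / 7),
) -> List[DeviationResult]:
    """One ratio per (variable, signed fraction) against the standard run."""
    standard = standard or StandardCondition()
    base = _final_T(
        params, standard.initial_area, standard.inoculum, standard.duration_weeks
    )
    results: List[DeviationResult] = []
    for frac in area_fracs:
        area = standard.initial_area * (1.0 + frac)
        if area <= 0:
            raise ValueError(f"area perturbation {frac:+.0%} drives area <= 0")
        t = _final_T(params, area, standard.inoculum, standard.duration_weeks)
        results.append(DeviationResult("initial_area", frac, t / base))
    for frac in inoc_fracs:
        inoc = standard.inoculum * (1.0 + frac)
        if inoc <= 0:
            raise ValueError(f"inoculum perturbation {frac:+.0%} drives inoculum <= 0")
        t = _final_T(params, standard.initial_area, inoc, standard.duration_weeks)
        results.append(DeviationResult("inoculum", frac, t / base))
    for frac in duration_fracs:
        weeks = standard.duration_weeks + round(frac * standard.duration_weeks)
        if weeks < 1:
            raise ValueError(
                f"duration perturbation {frac:+.0%} drives duration below 1 week"
            )
        t = _final_T(params, standard.initial_area, standard.inoculum, weeks)
        results.append(DeviationResult("duration", frac, t / base))
    return results


class NoSolutionError(ValueError):
    """Harvest unreachable within the inoculum bracket; carries the range."""

    def __init__(self, msg: str, achievable: Tuple[float, float]):
        super().__init__(msg)
        self.achievable = achievable


def back_calculate_inoculum(
    harvest_total: float,
    params: ModelParameters,
    duration: int = HARVEST_WEEK_DEFAULT,
    bracket: Tuple[float, float] = (1.0, 500.0),
    initial_area: float = AREA_PER_PLANT_SQIN * N_PLANTS_DEFAULT,
    harvest_band: float = 0.25,
    tol: float = BISECTION_TOL_ADULTS,
) -> Tuple[float, Tuple[float, float]]:
    """Invert the model for the inoculum that produced ``harvest_total``.

    Returns ``(point, (lo, hi))`` where the interval back-calculates the
    harvest at ``(1 -/+ harvest_band)`` -- by default the 25% relative
    scatter observed in accumulated whiteflies over two life cycles.
    """
    if harvest_total <= 0:
        raise ValueError("harvest_total must be > 0")
    a_lo, a_hi = bracket
    if a_lo <= 0 or a_hi <= a_lo:
        raise ValueError("bracket must be positive with lo < hi")

    def final_T(a0: float) -> float:
        return _final_T(params, initial_area, a0, duration)

    t_lo, t_hi = final_T(a_lo), final_T(a_hi)

    def solve(target: float) -> float:
        if not t_lo <= target <= t_hi:
            raise NoSolutionError(
                f"harvest {target:.0f} outside achievable range "
                f"[{t_lo:.0f}, {t_hi:.0f}] for inoculum bracket {bracket}",
                (t_lo, t_hi),
            )
        lo, hi = a_lo, a_hi
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if final_T(mid) < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    point = solve(harvest_total)
    band_lo = solve(max(harvest_total * (1.0 - harvest_band), t_lo))
    band_hi = solve(min(harvest_total * (1.0 + harvest_band), t_hi))
    return point, (band_lo, band_hi)


def recommend_inoculum(
    params: ModelParameters,
    standard: Optional[StandardCondition] = None,
    min_final_area_fold: float = 3.0,
    yield_floor: float = 5000.0,
    search: Tuple[float, float] = (10.0, 400.0),
    grid_step: float = 1.0,
) -> Tuple[Optional[Tuple[float, float]], dict]:
    """Largest inoculum interval satisfying both plant-health and yield floors.

    Scans a grid of inoculum sizes; a size is feasible when the simulated run
    keeps final plant area >= ``min_final_area_fold`` x initial AND final
    cumulative adults >= ``yield_floor``.  Purely model-derived; reported
    alongside, not replacing, the empirically chosen 80-110 adult window.
    """
    standard = standard or StandardCondition()
    if min_final_area_fold <= 0:
        raise ValueError("min_final_area_fold must be > 0")
    lo, hi = search
    n = int(round((hi - lo) / grid_step)) + 1
    grid = [lo + i * grid_step for i in range(n)]
    feasible = []
    for a0 in grid:
        traj = simulate(
            inoculation_state(a0, standard.initial_area), params, standard.duration_weeks
        )
        ok_area = traj.final.P >= min_final_area_fold * standard.initial_area
        ok_yield = traj.final.T >= yield_floor
        feasible.append(ok_area and ok_yield)

    best: Optional[Tuple[float, float]] = None
    run_start = None
    for i, ok in enumerate(feasible + [False]):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            cand = (grid[run_start], grid[i - 1])
            if best is None or cand[1] - cand[0] > best[1] - best[0]:
                best = cand
            run_start = None
    diagnostics = {
        "grid": (lo, hi, grid_step),
        "n_feasible": sum(feasible),
        "min_final_area_fold": min_final_area_fold,
        "yield_floor": yield_floor,
    }
    return best, diagnostics
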