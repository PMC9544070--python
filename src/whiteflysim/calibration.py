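"""Bounded least-squares calibration of the colony model and lack-of-fit tests.

Each colony iteration contributes two end-point observations: the harvest
total (compared to the cumulative adult compartment ``T`` at week 7,
because the brush-out census cannot separate dead from viable adults) and
the final total leaf area (compared to ``P``).  Counts and areas live on
different scales, so residuals are normalized by the per-quantity observed
means before squaring.

Model adequacy is assessed with a one-way ANOVA F statistic for model
significance and an F-test on the Left-Out-Terms, the lack-of-fit
component left after subtracting replicate (pure) error from the residual
sum of squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .model import (
    HARVEST_WEEK_DEFAULT,
    ColonyState,
    ModelParameters,
    ParameterBounds,
    default_bounds,
    default_parameters,
    inoculation_state,
    simulate,
)

__all__ = [
    "ObservationRecord",
    "FitResult",
    "LackOfFitReport",
    "fit",
    "predict_record",
    "calibrate_growth",
    "lack_of_fit_test",
    "summarize_fit",
    "FREE_PARAMETERS_ALLOWED",
    "N_MULTISTART",
]

#: Parameters the optimizer may tune; r and G_m stay at their derived
#: defaults (fecundity from the literature, growth from insect-free plants)
#: unless explicitly freed by the caller.
FREE_PARAMETERS_ALLOWED = frozenset(
    {"mu_A", "mu_N", "mu_E", "delta", "gamma", "beta"}
)

#: Number of seeded uniform multistart points added to the midpoint start.
N_MULTISTART = 8


@dataclass(frozen=True)
class ObservationRecord:
    """One colony iteration's measured inputs and end-point outputs."""

    iteration: str
    inoculum: float
    n_plants: int
    initial_area: float
    final_area: float
    harvest_total: float
    harvest_week: int = HARVEST_WEEK_DEFAULT
    weekly_qc: Optional[Mapping[str, Sequence[float]]] = None

    def __post_init__(self) -> None:
        if self.inoculum < 0 or self.harvest_total < 0:
            raise ValueError("counts must be >= 0")
        if self.initial_area <= 0 or self.final_area <= 0:
            raise ValueError("areas must be > 0")
        if self.n_plants <= 0:
            raise ValueError("n_plants must be >= 1")


@dataclass(frozen=True)
class FitResult:
    params: ModelParameters
    objective: float
    residuals: Tuple[Tuple[str, float, float], ...]  # (iteration, harvest, area)
    converged: bool
    bound_active: Dict[str, str] = field(default_factory=dict)  # name -> "lo"/"hi"
    free: Tuple[str, ...] = ()
    start_register: Tuple[Dict[str, float], ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class LackOfFitReport:
    F_model: float
    df_model: Tuple[int, int]
    F_crit_model: float
    F_lot: float
    df_lot: Tuple[int, int]
    F_crit_lot: float
    alpha: float
    ss_residual: float
    ss_pure_error: float
    ss_lot: float
    model_significant: bool
    adequate_fit: bool


def predict_record(record: ObservationRecord, params: ModelParameters) -> Tuple[float, float]:
    """Simulated (harvest T, final area P) for one record's initial condition."""
    init = inoculation_state(record.inoculum, record.initial_area)
    traj = simulate(init, params, record.harvest_week)
    return traj.final.T, traj.final.P


def _objective_residuals(
    theta: np.ndarray,
    free: Sequence[str],
    base: ModelParameters,
    records: Sequence[ObservationRecord],
    mean_harvest: float,
    mean_area: float,
) -> np.ndarray:
    params = base.replace(**dict(zip(free, theta)))
    res = []
    for rec in records:
        t_hat, p_hat = predict_record(rec, params)
        res.append((t_hat - rec.harvest_total) / mean_harvest)
        res.append((p_hat - rec.final_area) / mean_area)
    return np.asarray(res)


def fit(
    records: Sequence[ObservationRecord],
    bounds: Optional[ParameterBounds] = None,
    free: Sequence[str] = ("mu_A", "delta", "beta"),
    seed: int = 0,
    base_params: Optional[ModelParameters] = None,
) -> FitResult:
    """Box-constrained least squares over the free parameters.

    Runs a trust-region-reflective local search from the bound-box midpoint
    plus ``N_MULTISTART`` uniform starts drawn from a seeded generator; the
    best objective wins, ties broken by first-found.  Deterministic given
    identical records, bounds and seed.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to fit")
    unknown = set(free) - FREE_PARAMETERS_ALLOWED
    if unknown:
        raise ValueError(
            f"cannot free {sorted(unknown)}; allowed: {sorted(FREE_PARAMETERS_ALLOWED)}"
        )
    free = tuple(free)
    bounds = bounds or default_bounds()
    base = base_params or default_parameters()

    mean_harvest = float(np.mean([r.harvest_total for r in records]))
    mean_area = float(np.mean([r.final_area for r in records]))
    if mean_harvest == 0 or mean_area == 0:
        raise ValueError("degenerate records: zero mean harvest or area")
    if len({(r.inoculum, r.initial_area) for r in records}) == 1:
        import warnings

        warnings.warn(
            "all records share one design point; the fit may be singular",
            stacklevel=2,
        )

    lo = np.array([bounds[p][0] for p in free])
    hi = np.array([bounds[p][1] for p in free])
    mid = 0.5 * (lo + hi)
    rng = np.random.default_rng(seed)
    starts = [mid] + [rng.uniform(lo, hi) for _ in range(N_MULTISTART)]

    def obj(theta: np.ndarray) -> float:
        return float(
            np.sum(
                _objective_residuals(theta, free, base, records, mean_harvest, mean_area)
                ** 2
            )
        )

    best = None
    fixed = lo == hi  # point intervals are pinned, not optimized
    opt_ix = np.flatnonzero(~fixed)

    def residuals_sub(theta_sub: np.ndarray) -> np.ndarray:
        theta = lo.copy()
        theta[opt_ix] = theta_sub
        return _objective_residuals(theta, free, base, records, mean_harvest, mean_area)

    for x0 in starts:
        if opt_ix.size == 0:
            sol_x, sol_cost, ok = lo.copy(), obj(lo), True
        else:
            sol = optimize.least_squares(
                residuals_sub,
                np.clip(x0[opt_ix], lo[opt_ix], hi[opt_ix]),
                bounds=(lo[opt_ix], hi[opt_ix]),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            sol_x = lo.copy()
            sol_x[opt_ix] = sol.x
            sol_cost, ok = 2.0 * sol.cost, sol.success
        if best is None or sol_cost < best[1]:
            best = (sol_x, sol_cost, ok)

    x, cost, ok = best
    x = np.clip(x, lo, hi)
    fitted = base.replace(**dict(zip(free, x)))
    resids = []
    for rec in records:
        t_hat, p_hat = predict_record(rec, fitted)
        resids.append(
            (
                rec.iteration,
                (t_hat - rec.harvest_total) / mean_harvest,
                (p_hat - rec.final_area) / mean_area,
            )
        )
    tol = 1e-9
    active = {}
    for name, v, l, h in zip(free, x, lo, hi):
        if abs(v - l) <= tol * max(1.0, abs(l)):
            active[name] = "lo"
        elif abs(v - h) <= tol * max(1.0, abs(h)):
            active[name] = "hi"
    return FitResult(
        params=fitted,
        objective=cost,
        residuals=tuple(resids),
        converged=bool(ok),
        bound_active=active,
        free=free,
        start_register=tuple(dict(zip(free, s)) for s in starts),
        seed=seed,
    )


def calibrate_growth(
    initial_areas: Sequence[float], final_areas: Sequence[float], n_weeks: int
) -> float:
    """Weekly growth multiplier from insect-free before/after leaf areas.

    ``G_m`` is the ``n_weeks``-th root of the geometric-mean fold change, so
    compounding it over the observation window reproduces the average fold.
    """
    if len(initial_areas) != len(final_areas) or not initial_areas:
        raise ValueError("initial and final areas must be equal-length, non-empty")
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    a0 = np.asarray(initial_areas, dtype=float)
    a1 = np.asarray(final_areas, dtype=float)
    if (a0 <= 0).any() or (a1 <= 0).any():
        raise ValueError("areas must be positive")
    log_fold = float(np.mean(np.log(a1 / a0)))
    return math.exp(log_fold / n_weeks)


def lack_of_fit_test(
    predicted: Sequence[float],
    observed: Sequence[float],
    replicate_groups: Sequence,
    alpha: float = 0.05,
    n_model_params: int = 1,
) -> LackOfFitReport:
    """Model-significance ANOVA plus the Left-Out-Terms lack-of-fit F-test.

    The residual sum of squares is split into replicate (pure-error)
    variation within groups of replicated observations and the left-out
    terms, LOT = residual - replicate error.  ``F_lot`` compares the LOT
    mean square against the pure-error mean square on
    ``(n_groups - n_model_params, n - n_groups)`` degrees of freedom; the
    fit is adequate when it falls below the upper-``alpha`` F quantile.
    ``F_model`` compares model-explained variation (about the grand mean)
    to residual variation.

    Degrees of freedom depend on the replicate grouping supplied by the
    caller and are always reported alongside the statistics.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    groups = list(replicate_groups)
    if not (len(pred) == len(obs) == len(groups)):
        raise ValueError("predicted, observed and replicate_groups must align")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    labels = sorted(set(groups), key=str)
    idx = {g: [i for i, x in enumerate(groups) if x == g] for g in labels}
    if max(len(v) for v in idx.values()) < 2:
        raise ValueError(
            "no replicated group: pure error is undefined; supply a grouping "
            "with at least one group of >= 2 replicates"
        )

    n = len(obs)
    g = len(labels)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_pe = sum(
        float(np.sum((obs[ix] - obs[ix].mean()) ** 2)) for ix in idx.values()
    )
    ss_lot = max(ss_res - ss_pe, 0.0)
    df_pe = n - g
    df_lot = max(g - n_model_params, 1)

    ms_pe = ss_pe / df_pe if df_pe > 0 else np.nan
    f_lot = (ss_lot / df_lot) / ms_pe if ms_pe > 0 else 0.0
    f_crit_lot = float(stats.f.ppf(1.0 - alpha, df_lot, df_pe))

    grand = obs.mean()
    ss_model = float(np.sum((pred - grand) ** 2))
    df_model_num = max(n_model_params, 1)
    df_model_den = max(n - n_model_params - 1, 1)
    ms_res = ss_res / df_model_den
    f_model = (ss_model / df_model_num) / ms_res if ms_res > 0 else np.inf
    f_crit_model = float(stats.f.ppf(1.0 - alpha, df_model_num, df_model_den))

    return LackOfFitReport(
        F_model=float(f_model),
        df_model=(df_model_num, df_model_den),
        F_crit_model=f_crit_model,
        F_lot=float(f_lot),
        df_lot=(df_lot, df_pe),
        F_crit_lot=f_crit_lot,
        alpha=alpha,
        ss_residual=ss_res,
        ss_pure_error=ss_pe,
        ss_lot=ss_lot,
        model_significant=bool(f_model > f_crit_model),
        adequate_fit=bool(f_lot < f_crit_lot),
    )


def summarize_fit(
    fit_result: FitResult, records: Sequence[ObservationRecord]
) -> Dict[str, object]:
    """Machine-readable fit summary (serialized by :mod:`whiteflysim.io`)."""
    harvests = np.array([r.harvest_total for r in records], dtype=float)
    cv = float(harvests.std(ddof=1) / harvests.mean()) if len(harvests) > 1 else 0.0
    return {
        "parameters": fit_result.params.to_dict(),
        "free": list(fit_result.free),
        "objective": fit_result.objective,
        "converged": fit_result.converged,
        "bound_active": dict(fit_result.bound_active),
        "seed": fit_result.seed,
        "n_records": len(records),
        "harvest_cv": cv,
        "residuals": [
            {"iteration": it, "harvest_resid": rh, "area_resid": ra}
            for it, rh, ra in fit_result.residuals
        ],
    }
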