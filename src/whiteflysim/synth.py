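"""Seeded synthetic data with known ground truth.

Emulates the statistical structure of real colony-iteration logs so the
calibration, planning and QC modules are testable without the deposited
dataset: 5-week-old host plants near 25 sq.in. of leaf each, inocula near
100 adults, 7-week proliferation, harvest totals in the thousands with
roughly +/-25% relative scatter, and plant area growing about 4-fold.

Observation noise is multiplicative lognormal, parameterized to be
mean-unbiased: harvest counts are positive and their reported scatter is
relative, which a lognormal reproduces naturally.  Area measurements were
visibly better controlled than whitefly counts, so the area noise CV is
half the count CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .calibration import ObservationRecord
from .model import (
    AREA_PER_PLANT_SQIN,
    HARVEST_WEEK_DEFAULT,
    ModelParameters,
    Trajectory,
    default_parameters,
    inoculation_state,
    simulate,
)
from .qc import CountImage, ExoskeletonField

__all__ = [
    "SyntheticStudyConfig",
    "SyntheticImageConfig",
    "WeeklyQCObservation",
    "generate_records",
    "generate_harvest_noise",
    "generate_weekly_qc",
    "generate_count_image",
]

#: Default inoculum schedule: six iterations spanning the operating range,
#: including one deliberately doubled (~200-adult) inoculation.
_DEFAULT_INOCULA = (80.0, 100.0, 120.0, 150.0, 180.0, 213.0)


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size=None):
    """Lognormal draws with mean exactly 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=math.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study-level generator settings.  ``seed`` is mandatory."""

    seed: int
    true_params: ModelParameters = field(default_factory=default_parameters)
    n_iterations: int = 6
    inocula: Sequence[float] = _DEFAULT_INOCULA
    n_plants: int = 5
    harvest_week: int = HARVEST_WEEK_DEFAULT
    noise_cv: float = 0.25
    area_jitter: float = 0.10

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if len(self.inocula) < self.n_iterations:
            raise ValueError("need an inoculum count per iteration")
        if any(a <= 0 for a in self.inocula):
            raise ValueError("inoculum counts must be positive")


@dataclass(frozen=True)
class SyntheticImageConfig:
    """Count-image generator settings (emulates a brush-out photograph)."""

    seed: int
    shape: Tuple[int, int] = (512, 512)
    n_blobs: int = 200
    radius_range: Tuple[float, float] = (2.0, 4.0)
    fg_intensity: Tuple[int, int] = (180, 255)
    bg_intensity: Tuple[int, int] = (0, 25)
    overlap_fraction: float = 0.0
    quadrant_frac: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid radius range")
        if 2 * hi >= min(self.shape):
            raise ValueError("blobs do not fit in the raster")
        for band in (self.fg_intensity, self.bg_intensity):
            if not (0 <= band[0] <= band[1] <= 255):
                raise ValueError("intensity bands must lie in [0, 255]")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")


@dataclass(frozen=True)
class WeeklyQCObservation:
    week: int
    sticky_count: int
    exo_field: ExoskeletonField
    exo_intensity: float  # latent exoskeletons per sq.in.


def generate_records(
    cfg: SyntheticStudyConfig,
) -> Tuple[List[ObservationRecord], List[Trajectory]]:
    """Simulate each iteration from the true model, then add observation noise.

    Per-plant initial areas are 25 sq.in. with seeded uniform +/-10% jitter.
    Observed harvest = latent T x LogNormal(mean 1, CV); observed final
    area = latent P x LogNormal(mean 1, CV/2).  Latent trajectories are
    returned alongside as ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    records: List[ObservationRecord] = []
    truths: List[Trajectory] = []
    for i in range(cfg.n_iterations):
        plant_areas = AREA_PER_PLANT_SQIN * (
            1.0 + rng.uniform(-cfg.area_jitter, cfg.area_jitter, size=cfg.n_plants)
        )
        p0 = float(plant_areas.sum())
        inoc = float(cfg.inocula[i])
        traj = simulate(inoculation_state(inoc, p0), cfg.true_params, cfg.harvest_week)
        truths.append(traj)
        harvest = traj.final.T * float(_lognormal_unit_mean(rng, cfg.noise_cv))
        area = traj.final.P * float(_lognormal_unit_mean(rng, cfg.noise_cv / 2.0))
        records.append(
            ObservationRecord(
                iteration=f"I{i + 1:03d}",
                inoculum=inoc,
                n_plants=cfg.n_plants,
                initial_area=p0,
                final_area=area,
                harvest_total=harvest,
                harvest_week=cfg.harvest_week,
            )
        )
    return records, truths


def generate_harvest_noise(
    latent_harvest: float, cv: float, n: int, seed: int
) -> np.ndarray:
    """``n`` replicate noisy observations of one latent harvest total."""
    rng = np.random.default_rng(seed)
    return latent_harvest * _lognormal_unit_mean(rng, cv, size=n)


def generate_weekly_qc(
    trajectory: Trajectory,
    kappa_sticky: float = 0.002,
    kappa_exo: float = 0.005,
    seed: int = 0,
    field_radius: float = 2.0,
) -> List[WeeklyQCObservation]:
    """Weekly sticky-card and exoskeleton observations from a trajectory.

    Sticky counts are Poisson with mean ``kappa_sticky x A_i`` (trap rate
    proportional to flying adults; the default puts counts in the observed
    1-11 range for mid-run adult densities).  Exoskeleton fields are
    homogeneous Poisson point sets with intensity ``kappa_exo x (T_i -
    A_0)`` per sq.in. -- proportional to cumulative emergences, since each
    emergence leaves one exuvia.
    """
    if kappa_sticky <= 0 or kappa_exo <= 0:
        raise ValueError("kappa rates must be > 0")
    rng = np.random.default_rng(seed)
    a0 = trajectory.initial.A
    out: List[WeeklyQCObservation] = []
    for state in trajectory:
        sticky = int(rng.poisson(kappa_sticky * state.A))
        intensity = kappa_exo * max(state.T - a0, 0.0)
        n_pts = int(rng.poisson(intensity * math.pi * field_radius**2))
        # uniform in the disc via sqrt-radius sampling
        rr = field_radius * np.sqrt(rng.uniform(size=n_pts))
        th = rng.uniform(0.0, 2.0 * math.pi, size=n_pts)
        pts = np.column_stack([rr * np.cos(th), rr * np.sin(th)])
        out.append(
            WeeklyQCObservation(
                week=state.week,
                sticky_count=sticky,
                exo_field=ExoskeletonField(points=pts, max_radius=field_radius),
                exo_intensity=intensity,
            )
        )
    return out


def generate_count_image(cfg: SyntheticImageConfig) -> Tuple[CountImage, int, int]:
    """Dark raster with bright elliptical blobs at seeded positions.

    Returns ``(image, true_count, true_quadrant_count)``.  A fraction
    ``overlap_fraction`` of blobs is placed as near-touching pairs (centre
    separation just above the sum of radii), the rest well separated.
    Blobs are kept clear of the manual-count quadrant's internal border so
    the quadrant ground truth is unambiguous.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.shape
    r_lo, r_hi = cfg.radius_range
    qr, qc = int(h * cfg.quadrant_frac), int(w * cfg.quadrant_frac)
    margin = r_hi + 2.0

    img = rng.integers(
        cfg.bg_intensity[0], cfg.bg_intensity[1] + 1, size=(h, w)
    ).astype(np.uint8)

    n_pairs = int(round(cfg.n_blobs * cfg.overlap_fraction / 2.0))
    n_single = cfg.n_blobs - 2 * n_pairs
    min_sep = 2.0 * r_hi + 3.0

    def clear_of_quadrant_border(y: float, x: float) -> bool:
        return abs(y - qr) > margin and abs(x - qc) > margin

    centers: List[Tuple[float, float]] = []

    def place(n_needed: int, paired: bool) -> None:
        attempts = 0
        placed = 0
        while placed < n_needed:
            attempts += 1
            if attempts > 200 * max(n_needed, 1):
                raise ValueError(
                    f"cannot pack {cfg.n_blobs} blobs into {cfg.shape} raster"
                )
            y = rng.uniform(margin, h - margin)
            x = rng.uniform(margin, w - margin)
            if not clear_of_quadrant_border(y, x):
                continue
            pts = [(y, x)]
            if paired:
                ang = rng.uniform(0.0, 2.0 * math.pi)
                sep = 2.0 * r_hi + 1.0  # near-touching, gap ~1 px
                y2, x2 = y + sep * math.sin(ang), x + sep * math.cos(ang)
                if not (
                    margin <= y2 <= h - margin
                    and margin <= x2 <= w - margin
                    and clear_of_quadrant_border(y2, x2)
                ):
                    continue
                pts.append((y2, x2))
            ok = all(
                math.hypot(py - cy, px - cx) >= min_sep
                for cy, cx in centers
                for py, px in pts
            )
            if not ok:
                continue
            centers.extend(pts)
            placed += 1

    place(n_pairs, paired=True)
    place(n_single, paired=False)

    for cy, cx in centers:
        ry = rng.uniform(r_lo, r_hi)
        rx = rng.uniform(r_lo, r_hi)
        ang = rng.uniform(0.0, math.pi)
        ca, sa = math.cos(ang), math.sin(ang)
        # rasterize only a local window around the blob
        pad = int(math.ceil(max(rx, ry))) + 1
        y0, y1 = max(int(cy) - pad, 0), min(int(cy) + pad + 1, h)
        x0, x1 = max(int(cx) - pad, 0), min(int(cx) + pad + 1, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = (ca * dx + sa * dy) / rx
        v = (-sa * dx + ca * dy) / ry
        mask = u * u + v * v <= 1.0
        window = img[y0:y1, x0:x1]
        window[mask] = rng.integers(cfg.fg_intensity[0], cfg.fg_intensity[1] + 1)

    true_quadrant = sum(1 for cy, cx in centers if cy < qr and cx < qc)
    image = CountImage(
        pixels=img,
        quadrant=(0, qr, 0, qc),
        manual_count=true_quadrant,
    )
    return image, len(centers), true_quadrant
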