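"""Quantitative quality-control indices for colony monitoring.

Three nondestructive or end-point indices track colony health between
harvests:

* **Sticky-card index** -- adults trapped on a standardized yellow sticky
  card per sq.in. of card per minute of exposure; a density proxy for the
  flying adult population.
* **Exoskeleton density** -- emerged 4th-instar exoskeletons (exuviae) per
  sq.in. of leaf, measured over concentric circles grown from a standard
  punch-sized area until at least 25 exoskeletons are enclosed, which
  stabilizes the count-based density estimate.
* **Image-based adult count** -- whiteflies brushed onto a dark surface are
  photographed and counted by intensity thresholding plus 8-connected
  component labelling, validated against a manual count of a small quadrant
  of the same image.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from skimage import measure

__all__ = [
    "StickyCardObservation",
    "ExoskeletonField",
    "CountImage",
    "sticky_index",
    "exoskeleton_density",
    "count_whiteflies",
    "calibrate_count",
    "leaf_area_from_mask",
    "InsufficientCountError",
    "CARD_AREA_SQIN_DEFAULT",
    "PUNCH_AREA_SQIN",
    "PUNCH_RADIUS_IN",
]

#: Standard 4 x 4 cm card: 16 cm^2 = 16/6.4516 sq.in.
CARD_AREA_SQIN_DEFAULT = 16.0 / 6.4516

#: Leaf-punch sampling area and its circle-equivalent radius.
PUNCH_AREA_SQIN = 0.78
PUNCH_RADIUS_IN = math.sqrt(PUNCH_AREA_SQIN / math.pi)


@dataclass(frozen=True)
class StickyCardObservation:
    """Adults trapped on a card of known area over a timed exposure."""

    count: int
    card_area_sqin: float = CARD_AREA_SQIN_DEFAULT
    duration_min: float = 15.0

    def __post_init__(self) -> None:
        if self.count < 0 or self.count != int(self.count):
            raise ValueError("count must be a nonnegative integer")
        if self.card_area_sqin <= 0 or self.duration_min <= 0:
            raise ValueError("card area and duration must be > 0")


@dataclass(frozen=True)
class ExoskeletonField:
    """Exoskeleton centres in leaf-local coordinates (inches).

    ``points`` is an (n, 2) array of x, y offsets from ``center``;
    ``max_radius`` bounds the usable concentric-circle growth (leaf edge).
    """

    points: np.ndarray
    center: Tuple[float, float] = (0.0, 0.0)
    max_radius: float = 2.0

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size and pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        object.__setattr__(self, "points", pts.reshape(-1, 2))
        if self.max_radius <= 0:
            raise ValueError("max_radius must be > 0")

    def radii(self) -> np.ndarray:
        if self.points.size == 0:
            return np.empty(0)
        return np.hypot(
            self.points[:, 0] - self.center[0], self.points[:, 1] - self.center[1]
        )


@dataclass(frozen=True)
class CountImage:
    """Single-channel 8-bit raster of brushed-out whiteflies.

    ``quadrant`` is an optional (row0, row1, col0, col1) slice with its
    independent ``manual_count`` for calibration.
    """

    pixels: np.ndarray
    pixel_size_in: float = 1.0 / 300.0
    quadrant: Optional[Tuple[int, int, int, int]] = None
    manual_count: Optional[int] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D single-channel raster")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))
        if self.quadrant is not None:
            r0, r1, c0, c1 = self.quadrant
            h, w = px.shape
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError("quadrant out of image bounds")


class InsufficientCountError(ValueError):
    """Fewer exoskeletons than required; carries the best-available density."""

    def __init__(self, msg: str, best_density: float, best_radius: float):
        super().__init__(msg)
        self.best_density = best_density
        self.best_radius = best_radius


def sticky_index(obs: StickyCardObservation) -> float:
    """Capture rate: whiteflies per sq.in. of card per minute of exposure."""
    return obs.count / (obs.card_area_sqin * obs.duration_min)


def exoskeleton_density(
    field: ExoskeletonField,
    min_count: int = 25,
    radius_step: float = 0.1,
    initial_radius: float = PUNCH_RADIUS_IN,
) -> Tuple[float, float]:
    """Concentric-circle density estimate (radius used, count per sq.in.).

    Grows the sampling circle from the punch-equivalent radius in
    ``radius_step`` increments until at least ``min_count`` exoskeletons are
    enclosed, then divides the enclosed count by the circle area.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    radii = field.radii()
    r = initial_radius
    while r <= field.max_radius + 1e-12:
        enclosed = int(np.sum(radii <= r)) if radii.size else 0
        if enclosed >= min_count:
            return r, enclosed / (math.pi * r * r)
        r += radius_step
    r_best = min(r - radius_step, field.max_radius)
    enclosed = int(np.sum(radii <= r_best)) if radii.size else 0
    raise InsufficientCountError(
        f"only {enclosed} exoskeletons within max radius {field.max_radius:.2f} in "
        f"(need {min_count})",
        best_density=enclosed / (math.pi * r_best * r_best),
        best_radius=r_best,
    )


def count_whiteflies(
    image: CountImage,
    threshold: int,
    min_blob_px: int = 4,
    _region: Optional[Tuple[int, int, int, int]] = None,
) -> int:
    """Count bright blobs (whiteflies) on a dark background.

    Binarizes at ``intensity > threshold``, labels 8-connected components
    and drops those smaller than ``min_blob_px`` pixels.
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    px = image.pixels
    if _region is not None:
        r0, r1, c0, c1 = _region
        px = px[r0:r1, c0:c1]
    mask = px > threshold
    if not mask.any():
        if px.size and (px.max() == px.min()):
            warnings.warn("blank or saturated image: count is 0", stacklevel=2)
        return 0
    if mask.all():
        warnings.warn("saturated image: no background separable, count is 0", stacklevel=2)
        return 0
    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]  # skip background label 0
    return int(np.sum(sizes >= min_blob_px))


def calibrate_count(
    image: CountImage, threshold: int, min_blob_px: int = 4, tolerance: float = 0.05
) -> dict:
    """Validate the automated count against the manual quadrant count.

    Relative error = |automated - manual| / manual within the quadrant;
    flags failure above ``tolerance`` (default 5%).
    """
    if image.quadrant is None or image.manual_count is None:
        raise ValueError("image must carry a manual-count quadrant")
    auto = count_whiteflies(image, threshold, min_blob_px, _region=image.quadrant)
    manual = image.manual_count
    if manual == 0:
        return {
            "automated": auto,
            "manual": 0,
            "relative_error": math.nan,
            "undefined": True,
            "passed": auto == 0,
            "tolerance": tolerance,
        }
    err = abs(auto - manual) / manual
    return {
        "automated": auto,
        "manual": manual,
        "relative_error": err,
        "undefined": False,
        "passed": err <= tolerance,
        "tolerance": tolerance,
    }


def leaf_area_from_mask(mask: np.ndarray, pixel_size_in: float) -> float:
    """Leaf surface area (sq.in.) as foreground pixel count x pixel area.

    The simplest planimetric reading of an overhead photograph; no
    perspective correction.
    """
    if pixel_size_in <= 0:
        raise ValueError("pixel_size_in must be > 0")
    return float(np.count_nonzero(mask)) * pixel_size_in**2
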