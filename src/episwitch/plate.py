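"""Idealized plate scans of sectored colonies and the colony counter.

Colonies are rendered as disks on a GFP-channel scan: fully green colonies as
bright disks, half- and partially-sectored colonies as bright wedges (a half
sector spans 180 degrees) on an otherwise background-level disk, and red
colonies at background GFP level. Total colony counts come from thresholding
a scan where every colony exceeds the threshold (the ``composite`` channel),
binarizing, and counting 8-connected components above a minimum area —
half-sector scoring itself is deliberately left manual, matching how such
scans are analyzed in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from ._rng import ensure_rng
from .errors import ParameterError, PlacementError

__all__ = ["PlateGeometry", "ColonyRecord", "PlateRender", "render_plate", "count_colonies"]

#: green wedge angle (degrees) rendered for each colony class
CLASS_WEDGE_DEG = {"red": 0.0, "half_sector": 180.0, "partial_sector": 60.0, "full_green": 360.0}


@dataclass(frozen=True)
class PlateGeometry:
    shape: tuple[int, int] = (1024, 1024)
    radius_mean: float = 18.0  # px
    radius_sd: float = 2.0
    background: float = 10.0
    brightness: float = 200.0  # GFP level of green regions
    margin: float = 4.0  # min gap between colonies, px
    max_tries: int = 500


@dataclass(frozen=True)
class ColonyRecord:
    center: tuple[float, float]  # (y, x)
    radius: float
    colony_class: str
    wedge_deg: float
    wedge_start_deg: float


@dataclass(frozen=True)
class PlateRender:
    """``gfp`` is the GFP-channel scan (red colonies invisible); ``composite``
    has every colony above background, for total-colony counting."""

    gfp: np.ndarray
    composite: np.ndarray
    colonies: tuple[ColonyRecord, ...] = field(default_factory=tuple)


def render_plate(
    colony_classes,
    seed: int | np.random.Generator,
    geometry: PlateGeometry = PlateGeometry(),
) -> PlateRender:
    """Render non-overlapping colonies of the given fluorescence classes."""
    classes = list(colony_classes)
    for c in classes:
        if c not in CLASS_WEDGE_DEG:
            raise ParameterError(f"unknown colony class {c!r}")
    rng = ensure_rng(seed)
    ny, nx = geometry.shape
    gfp = np.full((ny, nx), geometry.background, dtype=np.float64)
    composite = gfp.copy()
    placed: list[tuple[float, float, float]] = []
    records: list[ColonyRecord] = []
    for c in classes:
        r = max(3.0, rng.normal(geometry.radius_mean, geometry.radius_sd))
        for _ in range(geometry.max_tries):
            cy = rng.uniform(r + 1, ny - r - 1)
            cx = rng.uniform(r + 1, nx - r - 1)
            if all(
                np.hypot(cy - py, cx - px) >= r + pr + geometry.margin for py, px, pr in placed
            ):
                break
        else:
            raise PlacementError(f"could not place colony {len(placed) + 1}/{len(classes)}")
        placed.append((cy, cx, r))
        wedge = CLASS_WEDGE_DEG[c]
        start = float(rng.uniform(0, 360.0))
        y0, y1 = int(cy - r) - 1, int(cy + r) + 2
        x0, x1 = int(cx - r) - 1, int(cx + r) + 2
        yy, xx = np.mgrid[max(0, y0):min(ny, y1), max(0, x0):min(nx, x1)]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        box = np.s_[max(0, y0):min(ny, y1), max(0, x0):min(nx, x1)]
        composite[box][disk] = geometry.brightness
        if wedge >= 360.0:
            gfp[box][disk] = geometry.brightness
        elif wedge > 0:
            ang = (np.degrees(np.arctan2(yy - cy, xx - cx)) - start) % 360.0
            gfp[box][disk & (ang < wedge)] = geometry.brightness
        records.append(
            ColonyRecord(center=(cy, cx), radius=r, colony_class=c, wedge_deg=wedge, wedge_start_deg=start)
        )
    return PlateRender(gfp=gfp, composite=composite, colonies=tuple(records))


def count_colonies(image: np.ndarray, threshold: float, min_area: int = 20) -> int:
    """Threshold -> binary image -> 8-connected components above ``min_area``.

    Counts bright objects only, so pass a channel or composite in which every
    colony of interest exceeds the threshold. Touching colonies merge into one
    component (a known limitation of component counting).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ParameterError("plate scan must be a 2D image")
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    labels = measure.label(image > threshold, connectivity=2)
    if labels.max() == 0:
        return 0
    areas = np.bincount(labels.ravel())[1:]
    return int((areas >= min_area).sum())
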