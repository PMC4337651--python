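"""3D Laplacian-of-Gaussian spot calling and per-cell count statistics.

The detection procedure: a 3D LoG band-pass filter (sign-flipped so bright
diffraction-limited blobs give positive extrema, with per-axis sigmas honoring
the anisotropic voxel spacing), a fixed response threshold reused across all
samples of an experiment, 26-connected component grouping with a size-range
gate, splitting of components that contain multiple well-separated local
maxima (so overlapping transcripts are resolved in three dimensions rather
than in a projection), intensity-weighted centroids, and assignment of each
spot to the cell label under its x-y centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .errors import ParameterError
from .stack import ImageStack

__all__ = [
    "SpotCall",
    "FISHSummary",
    "DetectionScore",
    "log_filter_3d",
    "suggest_threshold",
    "detect_spots",
    "assign_spots_to_cells",
    "summarize_counts",
    "score_detection",
    "spots_to_dataframe",
]


@dataclass(frozen=True)
class SpotCall:
    """One detected spot: intensity-weighted centroid in voxel coordinates
    (origin at the stack corner, z first), component size in voxels, peak
    filtered response, and owning cell label (0 = unassigned)."""

    z: float
    y: float
    x: float
    size: int
    response: float
    cell: int = 0


@dataclass(frozen=True)
class FISHSummary:
    """Per-cell transcript-count statistics in the shape of a results table."""

    mean_spots_per_cell: float
    variance: float | None  # sample (n-1); None for a single cell
    pct_cells_gt0: float
    pct_cells_gt1: float
    n_cells: int

    @property
    def dispersion_index(self) -> float | None:
        """Variance / mean; 1 under Poisson, > 1 indicates overdispersion."""
        if self.variance is None or self.mean_spots_per_cell == 0:
            return None
        return self.variance / self.mean_spots_per_cell


@dataclass(frozen=True)
class DetectionScore:
    precision: float | None  # None when there are no calls
    recall: float | None  # None when there is no truth
    f1: float | None
    n_matched: int
    n_calls: int
    n_truth: int


def log_filter_3d(stack: ImageStack, sigma_xy: float, sigma_z: float, truncate: float = 4.0) -> np.ndarray:
    """Sign-flipped, scale-normalized 3D Laplacian-of-Gaussian response.

    ``sigma_xy`` and ``sigma_z`` are in micrometers and are converted to
    per-axis voxel sigmas from the stack's spacing, so the filter is matched
    to the anisotropic point-spread function. The response is multiplied by
    the lateral voxel sigma squared so peak height tracks blob amplitude
    rather than blob scale.
    """
    if sigma_xy <= 0 or sigma_z <= 0:
        raise ParameterError("sigmas must be > 0")
    sx = sigma_xy / stack.voxel_xy
    sz = sigma_z / stack.z_step
    sigmas = (sz, sx, sx)
    radii = tuple(int(truncate * s + 0.5) for s in sigmas)
    for r, dim in zip(radii, stack.data.shape):
        if 2 * r + 1 > dim:
            raise ParameterError(
                f"LoG kernel extent {2 * r + 1} exceeds stack dimension {dim}"
            )
    smooth, second = [], []
    for s, r in zip(sigmas, radii):
        x = np.arange(-r, r + 1, dtype=np.float64)
        g = np.exp(-(x**2) / (2 * s**2))
        g /= g.sum()
        d2 = g * (x**2 - s**2) / s**4
        d2 -= d2.sum() * g  # zero-sum: a constant image gives exactly zero response
        smooth.append(g)
        second.append(d2)
    data = stack.data.astype(np.float64)
    out = np.zeros_like(data)
    for axis in range(3):
        tmp = data
        for other in range(3):
            if other != axis:
                tmp = ndimage.correlate1d(tmp, smooth[other], axis=other, mode="reflect")
        out += ndimage.correlate1d(tmp, second[axis], axis=axis, mode="reflect")
    return -(sx**2) * out


def suggest_threshold(filtered: np.ndarray, k: float = 8.0) -> float:
    """Propose a detection threshold k median-absolute-deviations above the
    median filtered response. The returned value should be stored and reused
    across all samples of the experiment."""
    med = float(np.median(filtered))
    mad = float(np.median(np.abs(filtered - med)))
    return med + k * mad


def detect_spots(
    filtered: np.ndarray,
    threshold: float,
    size_range: tuple[int, int] = (4, 200),
    min_peak_distance: int = 1,
    peak_prominence: float = 0.3,
) -> list[SpotCall]:
    """Detect spots in a filtered stack at a fixed response threshold.

    Voxels above ``threshold`` are grouped by 26-connectivity; components
    outside ``size_range`` are discarded. A component containing several
    distinct local maxima (``min_peak_distance=1`` keeps maxima at least two
    voxels apart), each above ``peak_prominence`` of the component peak, is
    split by watershed into one call per maximum, resolving overlapping spots
    in three dimensions (fragments below the minimum size are dropped).
    """
    if threshold <= 0:
        raise ParameterError("threshold must be > 0")
    min_size, max_size = size_range
    if not (0 < min_size <= max_size):
        raise ParameterError("size_range must satisfy 0 < min <= max")
    filtered = np.asarray(filtered)
    if filtered.ndim != 3:
        raise ParameterError("filtered stack must be 3D")

    labels, n_comp = ndimage.label(filtered > threshold, structure=np.ones((3, 3, 3), dtype=bool))
    calls: list[SpotCall] = []
    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        inside = labels[sl] == i
        size = int(inside.sum())
        if size < min_size or size > max_size:
            continue
        sub = np.where(inside, filtered[sl], 0.0)
        peak = float(sub.max())
        peaks = peak_local_max(
            sub,
            min_distance=min_peak_distance,
            threshold_abs=peak_prominence * peak,
            exclude_border=False,
        )
        offset = np.array([s.start for s in sl], dtype=float)
        if len(peaks) <= 1:
            calls.append(_make_call(sub, inside, offset))
            continue
        markers = np.zeros_like(inside, dtype=np.int32)
        for j, (pz, py, px) in enumerate(peaks, start=1):
            markers[pz, py, px] = j
        parts = watershed(-sub, markers, mask=inside)
        for j in range(1, len(peaks) + 1):
            region = parts == j
            if int(region.sum()) < min_size:
                continue
            calls.append(_make_call(np.where(region, sub, 0.0), region, offset))
    return calls


def _make_call(weighted: np.ndarray, region: np.ndarray, offset: np.ndarray) -> SpotCall:
    w = weighted[region]
    coords = np.argwhere(region) + offset
    centroid = (coords * w[:, None]).sum(axis=0) / w.sum()
    return SpotCall(
        z=float(centroid[0]),
        y=float(centroid[1]),
        x=float(centroid[2]),
        size=int(region.sum()),
        response=float(w.max()),
        cell=0,
    )


def assign_spots_to_cells(
    spots: Sequence[SpotCall], mask: np.ndarray
) -> tuple[list[SpotCall], pd.Series]:
    """Assign each spot to the cell label at the rounded x-y of its centroid.

    Returns the relabeled spots and per-cell counts over every cell in the
    mask (cells without spots count 0). Spots over background (label 0) stay
    in the spot list but are excluded from per-cell counts.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ParameterError(f"mask must be 2D, got shape {mask.shape}")
    ny, nx = mask.shape
    out: list[SpotCall] = []
    for s in spots:
        yi, xi = int(round(s.y)), int(round(s.x))
        if 0 <= yi < ny and 0 <= xi < nx:
            label = int(mask[yi, xi])
        else:
            raise ParameterError(
                f"spot centroid ({s.y:.1f}, {s.x:.1f}) falls outside the mask extent {mask.shape}"
            )
        out.append(replace(s, cell=label))
    cell_labels = np.unique(mask)
    cell_labels = cell_labels[cell_labels > 0]
    counts = pd.Series(0, index=pd.Index(cell_labels, name="cell"), name="count", dtype=np.int64)
    for s in out:
        if s.cell > 0:
            counts.loc[s.cell] += 1
    return out, counts


def summarize_counts(per_cell_counts) -> FISHSummary:
    """Summary statistics of per-cell transcript counts (sample variance)."""
    counts = np.asarray(per_cell_counts, dtype=float)
    if counts.size == 0:
        raise ParameterError("at least one cell is required")
    variance = float(counts.var(ddof=1)) if counts.size >= 2 else None
    return FISHSummary(
        mean_spots_per_cell=float(counts.mean()),
        variance=variance,
        pct_cells_gt0=float(100.0 * (counts > 0).mean()),
        pct_cells_gt1=float(100.0 * (counts > 1).mean()),
        n_cells=int(counts.size),
    )


def score_detection(
    spots: Sequence[SpotCall],
    truth: pd.DataFrame,
    match_radius: float = 3.0,
) -> DetectionScore:
    """Precision/recall/F1 by one-to-one greedy nearest matching.

    ``truth`` needs columns z, y, x in voxel coordinates. Candidate
    call-truth pairs within ``match_radius`` voxels are accepted closest
    first, each side used at most once; unmatched truth are false negatives
    and unmatched calls false positives.
    """
    n_calls, n_truth = len(spots), len(truth)
    if n_calls and n_truth:
        c = np.array([[s.z, s.y, s.x] for s in spots])
        t = truth[["z", "y", "x"]].to_numpy(dtype=float)
        d = np.sqrt(((c[:, None, :] - t[None, :, :]) ** 2).sum(axis=2))
        pairs = np.argwhere(d <= match_radius)
        order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
        used_c = np.zeros(n_calls, dtype=bool)
        used_t = np.zeros(n_truth, dtype=bool)
        n_matched = 0
        for ci, ti in pairs[order]:
            if not used_c[ci] and not used_t[ti]:
                used_c[ci] = used_t[ti] = True
                n_matched += 1
    else:
        n_matched = 0
    precision = n_matched / n_calls if n_calls else None
    recall = n_matched / n_truth if n_truth else None
    f1 = None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    return DetectionScore(
        precision=precision,
        recall=recall,
        f1=f1,
        n_matched=n_matched,
        n_calls=n_calls,
        n_truth=n_truth,
    )


def spots_to_dataframe(spots: Sequence[SpotCall]) -> pd.DataFrame:
    """Spot table with columns z, y, x, size, response, cell."""
    return pd.DataFrame(
        [(s.z, s.y, s.x, s.size, s.response, s.cell) for s in spots],
        columns=["z", "y", "x", "size", "response", "cell"],
    )
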