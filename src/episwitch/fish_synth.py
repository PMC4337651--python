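"""Synthetic single-molecule RNA FISH data with full ground truth.

Two layers are generated:

* per-cell transcript counts from a stated distribution family — Poisson for a
  constitutively expressed gene, negative binomial (parameterized by mean and
  variance) for an overdispersed one, or a zero/expressing mixture for a
  bistable locus where only a fraction of cells transcribe at all;
* 3D anisotropic image stacks in which each transcript is rendered as a
  diffraction-limited Gaussian spot at a random position inside its cell,
  over a constant background with additive Gaussian or Poisson noise, plus a
  2D cell-label mask.

The true per-cell counts and sub-voxel spot centroids are retained, so spot
callers can be scored for precision and recall against known truth.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import ellipse

from ._rng import ensure_rng
from .errors import ParameterError, PlacementError
from .stack import ImageStack

__all__ = [
    "CountModel",
    "StackSpec",
    "GroundTruth",
    "TwoChannelFixture",
    "sample_counts",
    "place_cells",
    "generate_stack",
    "make_two_channel_fixture",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountModel:
    """Per-cell transcript-count distribution.

    families
    --------
    poisson : ``mean``
    negbin : ``mean`` and ``variance`` (> mean); the minimal two-moment
        overdispersed family. If variance <= mean the sampler falls back to
        Poisson with a logged warning.
    mixture : a non-expressing component (exactly zero counts) with weight
        ``1 - pi_expressed`` and a nested ``expressed_component`` model.
    """

    family: str
    mean: float | None = None
    variance: float | None = None
    pi_expressed: float | None = None
    expressed_component: "CountModel | None" = None

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "negbin", "mixture"):
            raise ParameterError(f"unknown count family {self.family!r}")
        if self.family in ("poisson", "negbin"):
            if self.mean is None or self.mean < 0:
                raise ParameterError(f"{self.family} requires mean >= 0")
        if self.family == "negbin" and self.variance is None:
            raise ParameterError("negbin requires a variance")
        if self.family == "mixture":
            if self.pi_expressed is None or not (0 <= self.pi_expressed <= 1):
                raise ParameterError("mixture requires pi_expressed in [0, 1]")
            if self.expressed_component is None:
                raise ParameterError("mixture requires an expressed_component")

    @classmethod
    def poisson(cls, mean: float) -> "CountModel":
        return cls(family="poisson", mean=mean)

    @classmethod
    def negbin(cls, mean: float, variance: float) -> "CountModel":
        return cls(family="negbin", mean=mean, variance=variance)

    @classmethod
    def mixture(cls, pi_expressed: float, expressed_component: "CountModel") -> "CountModel":
        return cls(family="mixture", pi_expressed=pi_expressed, expressed_component=expressed_component)

    @classmethod
    def from_dict(cls, d: dict) -> "CountModel":
        d = dict(d)
        if "expressed_component" in d and d["expressed_component"] is not None:
            d["expressed_component"] = cls.from_dict(d["expressed_component"])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def sample_counts(model: CountModel, n_cells: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw integer per-cell transcript counts."""
    if n_cells < 0:
        raise ParameterError("n_cells must be >= 0")
    rng = ensure_rng(seed)
    if model.family == "poisson":
        return rng.poisson(model.mean, size=n_cells).astype(np.int64)
    if model.family == "negbin":
        m, v = model.mean, model.variance
        if v <= m:
            logger.warning(
                "negbin variance (%s) <= mean (%s); falling back to Poisson", v, m
            )
            return rng.poisson(m, size=n_cells).astype(np.int64)
        # mean m, variance v  ->  r = m^2/(v-m), numpy success prob p = m/v
        r = m * m / (v - m)
        return rng.negative_binomial(r, m / v, size=n_cells).astype(np.int64)
    # mixture
    counts = np.zeros(n_cells, dtype=np.int64)
    expressed = rng.random(n_cells) < model.pi_expressed
    k = int(expressed.sum())
    if k:
        counts[expressed] = sample_counts(model.expressed_component, k, rng)
    return counts


@dataclass(frozen=True)
class StackSpec:
    """Geometry and optics of a synthetic z-stack.

    Defaults emulate a 60x widefield acquisition: 0.13 um pixels, 0.2 um z
    step, lateral PSF sigma 0.15 um with 2x axial anisotropy, and yeast-sized
    elliptical cells (~4.4 um diameter). ``amplitude / noise_scale`` sets the
    peak signal-to-noise ratio (default 10).
    """

    shape: tuple[int, int, int] = (25, 448, 448)  # (z, y, x) voxels
    voxel_xy: float = 0.13  # um
    z_step: float = 0.2  # um
    amplitude: float = 100.0
    sigma_xy: float = 0.15  # um
    sigma_z: float = 0.30  # um (2x lateral, typical widefield anisotropy)
    background: float = 10.0
    noise: str = "gaussian"  # "gaussian" | "poisson" | "none"
    noise_scale: float = 10.0
    n_cells: int = 30
    cell_radius_um: float = 2.2  # mean semi-axis
    cell_radius_sd_um: float = 0.25
    min_separation: float = 0.0  # voxels, 3D, between rendered spots
    false_spot_rate: float = 0.0  # expected spurious background spots per stack
    z_margin: int = 3  # voxels kept free of spot centers at stack top/bottom
    max_place_tries: int = 500

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ParameterError("shape must be three positive voxel counts (z, y, x)")
        if self.z_step <= 0 or self.voxel_xy <= 0:
            raise ParameterError("voxel sizes must be > 0")
        if self.sigma_xy <= 0 or self.sigma_z <= 0:
            raise ParameterError("PSF sigmas must be > 0")
        if self.noise not in ("gaussian", "poisson", "none"):
            raise ParameterError(f"unknown noise model {self.noise!r}")
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")

    @property
    def sigma_xy_vox(self) -> float:
        return self.sigma_xy / self.voxel_xy

    @property
    def sigma_z_vox(self) -> float:
        return self.sigma_z / self.z_step


@dataclass(frozen=True)
class GroundTruth:
    """True per-cell counts and sub-voxel spot centroids (voxel units).

    ``spots`` has one row per true transcript with columns cell, z, y, x;
    ``false_spots`` records spurious background blobs (no owning cell).
    """

    per_cell_counts: pd.Series  # indexed by cell label
    spots: pd.DataFrame
    false_spots: pd.DataFrame

    def __post_init__(self) -> None:
        if int(self.per_cell_counts.sum()) != len(self.spots):
            raise ParameterError("sum of per-cell counts must equal number of true spots")


def place_cells(spec: StackSpec, rng: np.random.Generator) -> np.ndarray:
    """Place non-overlapping elliptical cells; returns a 2D uint16 label mask.

    Footprints are kept at least ``max(2, min_separation)`` pixels apart so
    spots in different cells automatically respect the spot-separation floor.
    """
    ny, nx = spec.shape[1], spec.shape[2]
    mask = np.zeros((ny, nx), dtype=np.uint16)
    gap = max(2.0, math.ceil(spec.min_separation) + 1.0)
    r_mean = spec.cell_radius_um / spec.voxel_xy
    r_sd = spec.cell_radius_sd_um / spec.voxel_xy
    for label in range(1, spec.n_cells + 1):
        for _ in range(spec.max_place_tries):
            a = max(0.5 * r_mean, rng.normal(r_mean, r_sd))
            b = max(0.5 * r_mean, rng.normal(r_mean, r_sd))
            theta = rng.uniform(0, np.pi)
            rmax = max(a, b) + gap + 1
            if 2 * rmax >= min(ny, nx):
                raise PlacementError("cells too large for the field of view")
            cy = rng.uniform(rmax, ny - rmax)
            cx = rng.uniform(rmax, nx - rmax)
            rr, cc = ellipse(cy, cx, a + gap, b + gap, shape=(ny, nx), rotation=theta)
            if np.any(mask[rr, cc]):
                continue
            rr, cc = ellipse(cy, cx, a, b, shape=(ny, nx), rotation=theta)
            mask[rr, cc] = label
            break
        else:
            raise PlacementError(
                f"could not place cell {label}/{spec.n_cells} after {spec.max_place_tries} tries"
            )
    return mask


def _sample_spot_positions(
    spec: StackSpec,
    footprint: tuple[np.ndarray, np.ndarray],
    n_spots: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform positions inside one cell footprint, honoring min 3D separation."""
    rr, cc = footprint
    zlo, zhi = spec.z_margin, spec.shape[0] - 1 - spec.z_margin
    if zhi < zlo:
        zlo = zhi = (spec.shape[0] - 1) / 2
    aniso = spec.z_step / spec.voxel_xy  # separation measured in xy-voxel units
    for _ in range(20):  # restart the whole cell if packing stalls
        placed: list[tuple[float, float, float]] = []
        ok = True
        for _spot in range(n_spots):
            for _try in range(300):
                j = rng.integers(len(rr))
                y = rr[j] + rng.uniform(-0.5, 0.5)
                x = cc[j] + rng.uniform(-0.5, 0.5)
                z = rng.uniform(zlo, zhi)
                if spec.min_separation > 0 and placed:
                    d2 = [
                        ((z - pz) * aniso) ** 2 + (y - py) ** 2 + (x - px) ** 2
                        for pz, py, px in placed
                    ]
                    if min(d2) < spec.min_separation**2:
                        continue
                placed.append((z, y, x))
                break
            else:
                ok = False
                break
        if ok:
            return np.array(placed).reshape(n_spots, 3)
    raise PlacementError(f"could not place {n_spots} spots with separation {spec.min_separation}")


def _render_spot(data: np.ndarray, spec: StackSpec, z: float, y: float, x: float) -> None:
    sz, sxy = spec.sigma_z_vox, spec.sigma_xy_vox
    nz, ny, nx = data.shape
    ez, exy = int(math.ceil(4 * sz)), int(math.ceil(4 * sxy))
    z0, z1 = max(0, int(z) - ez), min(nz, int(z) + ez + 1)
    y0, y1 = max(0, int(y) - exy), min(ny, int(y) + exy + 1)
    x0, x1 = max(0, int(x) - exy), min(nx, int(x) + exy + 1)
    zz = (np.arange(z0, z1) - z)[:, None, None]
    yy = (np.arange(y0, y1) - y)[None, :, None]
    xx = (np.arange(x0, x1) - x)[None, None, :]
    data[z0:z1, y0:y1, x0:x1] += spec.amplitude * np.exp(
        -(zz**2 / (2 * sz**2) + (yy**2 + xx**2) / (2 * sxy**2))
    )


def _render_channel(
    spec: StackSpec, mask: np.ndarray, counts: np.ndarray, rng: np.random.Generator
) -> tuple[ImageStack, GroundTruth]:
    data = np.zeros(spec.shape, dtype=np.float64)
    rows = []
    for label in range(1, spec.n_cells + 1):
        n_spots = int(counts[label - 1])
        if n_spots == 0:
            continue
        footprint = np.nonzero(mask == label)
        if footprint[0].size == 0:
            raise PlacementError(f"cell {label} has an empty footprint")
        for z, y, x in _sample_spot_positions(spec, footprint, n_spots, rng):
            _render_spot(data, spec, z, y, x)
            rows.append((label, z, y, x))
    spots = pd.DataFrame(rows, columns=["cell", "z", "y", "x"])

    n_false = int(rng.poisson(spec.false_spot_rate)) if spec.false_spot_rate > 0 else 0
    frows = []
    for _ in range(n_false):
        z = rng.uniform(spec.z_margin, spec.shape[0] - 1 - spec.z_margin)
        y = rng.uniform(0, spec.shape[1] - 1)
        x = rng.uniform(0, spec.shape[2] - 1)
        _render_spot(data, spec, z, y, x)
        frows.append((0, z, y, x))
    false_spots = pd.DataFrame(frows, columns=["cell", "z", "y", "x"])

    data += spec.background
    if spec.noise == "gaussian":
        data = data + rng.normal(0.0, spec.noise_scale, size=spec.shape)
    elif spec.noise == "poisson":
        # noise_scale acts as photons per intensity unit
        data = rng.poisson(np.clip(data, 0, None) * spec.noise_scale) / spec.noise_scale
    data = np.clip(data, 0.0, None)

    per_cell = pd.Series(counts, index=pd.RangeIndex(1, spec.n_cells + 1, name="cell"), name="count")
    truth = GroundTruth(per_cell_counts=per_cell, spots=spots, false_spots=false_spots)
    stack = ImageStack(data=data, voxel_xy=spec.voxel_xy, z_step=spec.z_step)
    return stack, truth


def generate_stack(
    spec: StackSpec, counts: np.ndarray, seed: int | np.random.Generator
) -> tuple[ImageStack, np.ndarray, GroundTruth]:
    """Render one channel: stack + 2D cell-label mask + ground truth.

    ``counts`` must hold one per-cell transcript count per cell in the spec.
    """
    counts = np.asarray(counts)
    if len(counts) != spec.n_cells:
        raise ParameterError(f"counts has length {len(counts)}, expected n_cells={spec.n_cells}")
    if np.any(counts < 0):
        raise ParameterError("counts must be non-negative")
    rng = ensure_rng(seed)
    mask = place_cells(spec, rng)
    stack, truth = _render_channel(spec, mask, counts, rng)
    return stack, mask, truth


@dataclass(frozen=True)
class TwoChannelFixture:
    """Two spectrally distinct channels rendered over one shared cell mask."""

    stack_a: ImageStack
    stack_b: ImageStack
    mask: np.ndarray
    truth_a: GroundTruth
    truth_b: GroundTruth


def make_two_channel_fixture(
    model_a: CountModel,
    model_b: CountModel,
    spec: StackSpec,
    seed: int | np.random.Generator,
) -> TwoChannelFixture:
    """Paired stacks with independent per-cell counts over identical cells,
    mirroring dual-probe hybridization of a test gene and an internal control."""
    rng = ensure_rng(seed)
    mask = place_cells(spec, rng)
    counts_a = sample_counts(model_a, spec.n_cells, rng)
    counts_b = sample_counts(model_b, spec.n_cells, rng)
    stack_a, truth_a = _render_channel(spec, mask, counts_a, rng)
    stack_b, truth_b = _render_channel(spec, mask, counts_b, rng)
    return TwoChannelFixture(stack_a=stack_a, stack_b=stack_b, mask=mask, truth_a=truth_a, truth_b=truth_b)
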