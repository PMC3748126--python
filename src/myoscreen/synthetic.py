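"""Synthetic two-channel plate renderer with per-object ground truth.

Emulates a high-content differentiation assay: elongated multinucleated
myotubes (marker channel, e.g. FITC-labelled Troponin T) surrounded by
mononucleated marker-negative cells, with every nucleus visible on the
nuclear channel (DAPI-like).  Myotubes are modelled as 2-D capsules
(rectangle with semicircular caps), the one shape family with closed-form
area, perimeter and Feret diameters, so every rendered object ships with an
analytic ground truth that downstream segmentation and morphometry can be
tested against.

All geometry is carried in micrometres; conversion to pixels happens only at
rasterisation time.  Pixel ``(r, c)`` has its centre at
``((r + 0.5) * pixel_size, (c + 0.5) * pixel_size)`` and ground-truth
centroids are reported in (sub-)pixel coordinates under that convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from scipy import stats

from .io import FieldImage, save_field, validate_well

__all__ = [
    "ConditionPreset",
    "PlateSpec",
    "Capsule",
    "Nucleus",
    "MyotubeSample",
    "FieldSample",
    "GroundTruth",
    "PlacementError",
    "condition_preset",
    "capsule_area",
    "capsule_perimeter",
    "sample_myotube",
    "sample_field",
    "render_field",
    "generate_plate",
    "CONDITION_PRESETS",
]

MAX_PLACEMENT_RETRIES = 400


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place an object (overcrowding)."""


# ---------------------------------------------------------------------------
# presets and specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionPreset:
    """Morphology distribution for one treatment condition.

    Lengths/breadths in µm, areas in µm², intensities in camera units per
    pixel.  Densities are expected object counts per field; they were chosen
    so that the fraction of nuclei residing inside myotubes (the myogenic
    fusion index) lands at the condition's literature value irrespective of
    field size.
    """

    name: str
    mean_length: float
    sd_length: float
    mean_breadth: float
    sd_breadth: float
    mean_nuclei_per_myotube: float
    sd_nuclei: float
    myotube_density: int
    background_cell_density: int
    marker_intensity_mean: float
    marker_intensity_sd: float = 0.0
    myonucleus_area_mean: float = 133.0
    myonucleus_area_sd: float = 3.77
    cell_nucleus_area_mean: float = 140.0
    cell_nucleus_area_sd: float = 7.37

    def __post_init__(self) -> None:
        for attr in (
            "mean_length",
            "mean_breadth",
            "mean_nuclei_per_myotube",
            "marker_intensity_mean",
            "myonucleus_area_mean",
            "cell_nucleus_area_mean",
        ):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        for attr in (
            "sd_length",
            "sd_breadth",
            "sd_nuclei",
            "marker_intensity_sd",
            "myonucleus_area_sd",
            "cell_nucleus_area_sd",
        ):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.mean_breadth >= self.mean_length:
            raise ValueError("mean_length must exceed mean_breadth")
        if self.myotube_density < 0 or self.background_cell_density < 0:
            raise ValueError("densities must be >= 0")


#: Condition presets for the vehicle / ethanol / rapamycin arms of the assay.
#: Length, breadth, nuclei per myotube and nuclear areas follow the published
#: per-condition means (SDs); marker intensities are set so that integrated
#: intensities at the default 0.65 µm/px calibration fall in the published
#: range; densities set the fusion index (≈14.9 / 13.5 / 12.5 %).
CONDITION_PRESETS: dict[str, ConditionPreset] = {
    "vehicle": ConditionPreset(
        name="vehicle",
        mean_length=178.0,
        sd_length=11.3,
        mean_breadth=46.2,
        sd_breadth=5.3,
        mean_nuclei_per_myotube=6.0,
        sd_nuclei=1.0,
        myotube_density=4,
        background_cell_density=137,
        marker_intensity_mean=325.0,
        marker_intensity_sd=32.0,
        myonucleus_area_mean=133.0,
        myonucleus_area_sd=3.77,
        cell_nucleus_area_mean=140.0,
        cell_nucleus_area_sd=7.37,
    ),
    "ethanol": ConditionPreset(
        name="ethanol",
        mean_length=147.0,
        sd_length=13.0,
        mean_breadth=32.1,
        sd_breadth=2.33,
        mean_nuclei_per_myotube=4.0,
        sd_nuclei=1.0,
        myotube_density=4,
        background_cell_density=103,
        marker_intensity_mean=438.0,
        marker_intensity_sd=44.0,
        myonucleus_area_mean=140.0,
        myonucleus_area_sd=3.25,
        cell_nucleus_area_mean=164.0,
        cell_nucleus_area_sd=8.81,
    ),
    "rapamycin": ConditionPreset(
        name="rapamycin",
        mean_length=117.0,
        sd_length=6.86,
        mean_breadth=30.0,
        sd_breadth=3.29,
        mean_nuclei_per_myotube=3.0,
        sd_nuclei=1.0,
        myotube_density=4,
        background_cell_density=84,
        marker_intensity_mean=344.0,
        marker_intensity_sd=34.0,
        myonucleus_area_mean=140.0,
        myonucleus_area_sd=3.42,
        cell_nucleus_area_mean=169.0,
        cell_nucleus_area_sd=9.78,
    ),
}


def condition_preset(name: str, **overrides) -> ConditionPreset:
    """Return a named preset, optionally with fields overridden."""
    try:
        preset = CONDITION_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(CONDITION_PRESETS)}"
        ) from None
    return replace(preset, **overrides) if overrides else preset


@dataclass
class PlateSpec:
    """Acquisition geometry and rendering parameters for one plate.

    ``field_shape`` is (rows, cols) in pixels; the default emulates a 10×
    CCD field of 1392×1040 px at 0.65 µm/px.  ``fields_per_well`` defaults
    to the assay's 36 non-overlapping sites per well.
    """

    wells: list[tuple[str, ConditionPreset]]
    fields_per_well: int = 36
    field_shape: tuple[int, int] = (1040, 1392)
    pixel_size: float = 0.65
    noise_sd: float = 20.0
    blur_sigma: float = 1.0
    rng_seed: int = 0
    plate_id: str = "plate01"
    background_level: float = 100.0
    nuclear_intensity: float = 3000.0
    min_separation: float = 6.0      # µm clearance between myotube surfaces
    interior_only: bool = False      # forbid border-clipped myotubes

    def __post_init__(self) -> None:
        if self.fields_per_well < 1:
            raise ValueError("fields_per_well must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if len(self.field_shape) != 2 or min(self.field_shape) < 8:
            raise ValueError("field_shape must be (rows, cols), each >= 8")
        seen = set()
        for well, _ in self.wells:
            validate_well(well)
            if well in seen:
                raise ValueError(f"duplicate well {well}")
            seen.add(well)

    @property
    def field_extent(self) -> tuple[float, float]:
        """Physical field size (rows µm, cols µm)."""
        return (
            self.field_shape[0] * self.pixel_size,
            self.field_shape[1] * self.pixel_size,
        )


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Capsule:
    """Capsule (stadium) shape: segment of half-length a dilated by radius r.

    ``length`` is end-to-end (tip to tip), ``breadth`` the width, both µm.
    ``center`` is (row, col) in µm, ``orientation`` in radians measured from
    the column (x) axis.
    """

    center: tuple[float, float]
    orientation: float
    length: float
    breadth: float

    @property
    def radius(self) -> float:
        return self.breadth / 2.0

    @property
    def half_axis(self) -> float:
        return (self.length - self.breadth) / 2.0

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        u = np.array([math.sin(self.orientation), math.cos(self.orientation)])
        c = np.asarray(self.center, dtype=float)
        return c - self.half_axis * u, c + self.half_axis * u

    @property
    def area(self) -> float:
        return capsule_area(self.length, self.breadth)

    @property
    def perimeter(self) -> float:
        return capsule_perimeter(self.length, self.breadth)

    def distance_to_axis(self, points: np.ndarray) -> np.ndarray:
        """Distance from (n, 2) points (row, col µm) to the capsule axis."""
        p0, p1 = self.endpoints
        return _point_segment_distance(np.atleast_2d(points), p0, p1)

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """True where points lie within the capsule shrunk by ``margin``."""
        return self.distance_to_axis(points) <= self.radius - margin


@dataclass(frozen=True)
class Nucleus:
    """A rendered nucleus: disc with centre (row, col µm) and area µm²."""

    center: tuple[float, float]
    area: float

    @property
    def radius(self) -> float:
        return math.sqrt(self.area / math.pi)


@dataclass
class MyotubeSample:
    capsule: Capsule
    nuclei: list[Nucleus]
    marker_intensity: float


@dataclass
class FieldSample:
    """All objects of one field: myotubes plus marker-negative cell nuclei."""

    myotubes: list[MyotubeSample]
    cells: list[Nucleus]


def capsule_area(length: float, breadth: float) -> float:
    """Analytic area of a capsule with end-to-end length L and width B."""
    return length * breadth - breadth**2 + math.pi * (breadth / 2.0) ** 2


def capsule_perimeter(length: float, breadth: float) -> float:
    """Analytic perimeter 2(L − B) + πB of a capsule."""
    return 2.0 * (length - breadth) + math.pi * breadth


def _point_segment_distance(
    points: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> np.ndarray:
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0.0:
        return np.linalg.norm(points - p0, axis=1)
    t = np.clip((points - p0) @ d / denom, 0.0, 1.0)
    proj = p0 + t[:, None] * d
    return np.linalg.norm(points - proj, axis=1)


def _segment_segment_distance(
    a0: np.ndarray, a1: np.ndarray, b0: np.ndarray, b1: np.ndarray
) -> float:
    """Minimum distance between two 2-D segments."""
    if _segments_intersect(a0, a1, b0, b1):
        return 0.0
    return min(
        _point_segment_distance(a0[None, :], b0, b1)[0],
        _point_segment_distance(a1[None, :], b0, b1)[0],
        _point_segment_distance(b0[None, :], a0, a1)[0],
        _point_segment_distance(b1[None, :], a0, a1)[0],
    )


def _segments_intersect(a0, a1, b0, b1) -> bool:
    def orient(p, q, r):
        return (q[1] - p[1]) * (r[0] - p[0]) - (q[0] - p[0]) * (r[1] - p[1])

    d1 = orient(b0, b1, a0)
    d2 = orient(b0, b1, a1)
    d3 = orient(a0, a1, b0)
    d4 = orient(a0, a1, b1)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return True
    return False


def capsules_clear(a: Capsule, b: Capsule, gap: float) -> bool:
    """True if the two capsule surfaces are at least ``gap`` apart."""
    a0, a1 = a.endpoints
    b0, b1 = b.endpoints
    return (
        _segment_segment_distance(a0, a1, b0, b1)
        >= a.radius + b.radius + gap
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float
) -> float:
    """One draw from Normal(mean, sd) truncated below at ``lower``.

    Rejection sampling: the truncation point sits far in the lower tail for
    every realistic preset, so acceptance is near-certain; the inverse-CDF
    fallback covers pathological parameterisations.
    """
    if sd == 0.0:
        return float(mean)
    for _ in range(64):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    a = (lower - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def _sample_dims(preset: ConditionPreset, rng: np.random.Generator) -> tuple[float, float]:
    # truncation at 0.1·mean guarantees positivity; resample the pair until
    # breadth < length (essentially immediate for the built-in presets)
    for _ in range(MAX_PLACEMENT_RETRIES):
        length = _truncated_normal(rng, preset.mean_length, preset.sd_length, 0.1 * preset.mean_length)
        breadth = _truncated_normal(rng, preset.mean_breadth, preset.sd_breadth, 0.1 * preset.mean_breadth)
        if breadth < length:
            return length, breadth
    raise PlacementError("could not draw breadth < length; check preset")


def _sample_nuclei_count(preset: ConditionPreset, rng: np.random.Generator) -> int:
    if preset.sd_nuclei == 0.0:
        return max(1, int(round(preset.mean_nuclei_per_myotube)))
    n = int(round(rng.normal(preset.mean_nuclei_per_myotube, preset.sd_nuclei)))
    return max(1, n)


def _sample_nucleus_area(
    rng: np.random.Generator, mean: float, sd: float, pixel_size: float
) -> float:
    # truncate at 4 px² so every nucleus survives rasterisation
    lower = max(0.1 * mean, 4.0 * pixel_size**2)
    return _truncated_normal(rng, mean, sd, lower)


def _place_nuclei_in_capsule(
    capsule: Capsule,
    n: int,
    preset: ConditionPreset,
    rng: np.random.Generator,
    pixel_size: float,
    field_extent: tuple[float, float] | None,
    gap: float = 1.0,
) -> list[Nucleus]:
    """Uniform rejection placement of n non-overlapping nuclei inside a capsule.

    Discs stay fully inside the capsule and, when ``field_extent`` is given,
    fully inside the field.
    """
    p0, p1 = capsule.endpoints
    lo = np.minimum(p0, p1) - capsule.radius
    hi = np.maximum(p0, p1) + capsule.radius
    placed: list[Nucleus] = []
    for _ in range(n):
        area = _sample_nucleus_area(
            rng, preset.myonucleus_area_mean, preset.myonucleus_area_sd, pixel_size
        )
        r = math.sqrt(area / math.pi)
        if r >= capsule.radius:
            raise PlacementError(
                f"nucleus radius {r:.1f} µm does not fit capsule of breadth "
                f"{capsule.breadth:.1f} µm"
            )
        for _attempt in range(MAX_PLACEMENT_RETRIES):
            pt = rng.uniform(lo, hi)
            if not capsule.contains(pt[None, :], margin=r)[0]:
                continue
            if field_extent is not None and not (
                r <= pt[0] <= field_extent[0] - r
                and r <= pt[1] <= field_extent[1] - r
            ):
                continue
            if any(
                np.hypot(pt[0] - q.center[0], pt[1] - q.center[1])
                < r + q.radius + gap
                for q in placed
            ):
                continue
            placed.append(Nucleus(center=(float(pt[0]), float(pt[1])), area=area))
            break
        else:
            raise PlacementError(
                f"failed to place nucleus {len(placed) + 1}/{n} in capsule "
                "after bounded retries (overcrowded capsule)"
            )
    return placed


def sample_myotube(
    preset: ConditionPreset,
    rng: np.random.Generator,
    *,
    center: tuple[float, float] = (0.0, 0.0),
    orientation: float | None = None,
    pixel_size: float = 0.65,
    field_extent: tuple[float, float] | None = None,
) -> MyotubeSample:
    """Draw one myotube: capsule dimensions, orientation and nucleus layout.

    Lengths, breadths and nucleus areas come from truncated normal
    distributions with the preset's mean/SD; the nucleus count is a rounded
    normal draw clipped to ≥ 1.  Nuclei are placed uniformly inside the
    capsule without overlap; a capsule too crowded to hold its nuclei raises
    :class:`PlacementError`.
    """
    last_err: PlacementError | None = None
    for _attempt in range(8):
        length, breadth = _sample_dims(preset, rng)
        theta = (
            float(rng.uniform(0.0, math.pi)) if orientation is None else orientation
        )
        capsule = Capsule(
            center=center, orientation=theta, length=length, breadth=breadth
        )
        n_nuclei = _sample_nuclei_count(preset, rng)
        intensity = _truncated_normal(
            rng, preset.marker_intensity_mean, preset.marker_intensity_sd,
            0.1 * preset.marker_intensity_mean,
        )
        try:
            nuclei = _place_nuclei_in_capsule(
                capsule, n_nuclei, preset, rng, pixel_size, field_extent
            )
        except PlacementError as err:
            # a crowded draw (many nuclei in a narrow capsule) is resampled
            # wholesale a bounded number of times before giving up
            last_err = err
            continue
        return MyotubeSample(capsule=capsule, nuclei=nuclei, marker_intensity=intensity)
    raise PlacementError(str(last_err))


def _capsule_fits_field(capsule: Capsule, extent: tuple[float, float]) -> bool:
    p0, p1 = capsule.endpoints
    r = capsule.radius
    for p in (p0, p1):
        if not (r <= p[0] <= extent[0] - r and r <= p[1] <= extent[1] - r):
            return False
    return True


def sample_field(
    preset: ConditionPreset, spec: PlateSpec, rng: np.random.Generator
) -> FieldSample:
    """Sample all objects of one field under the preset's densities.

    Myotubes are rejection-placed so their surfaces stay ``min_separation``
    apart (merged myotubes would otherwise confound the count-recovery
    oracle); marker-negative cell nuclei are placed outside every capsule
    and away from each other.  A jammed layout is restarted from scratch a
    bounded number of times before :class:`PlacementError` (overcrowding)
    is raised.
    """
    last_err: PlacementError | None = None
    for _restart in range(30):
        try:
            return _sample_field_once(preset, spec, rng)
        except PlacementError as err:
            last_err = err
    raise PlacementError(
        f"field layout failed after repeated restarts: {last_err}"
    )


def _sample_field_once(
    preset: ConditionPreset, spec: PlateSpec, rng: np.random.Generator
) -> FieldSample:
    extent = spec.field_extent
    myotubes: list[MyotubeSample] = []
    for _ in range(preset.myotube_density):
        for _attempt in range(MAX_PLACEMENT_RETRIES):
            center = (
                float(rng.uniform(0.0, extent[0])),
                float(rng.uniform(0.0, extent[1])),
            )
            try:
                cand = sample_myotube(
                    preset,
                    rng,
                    center=center,
                    pixel_size=spec.pixel_size,
                    field_extent=extent,
                )
            except PlacementError:
                continue
            if spec.interior_only and not _capsule_fits_field(cand.capsule, extent):
                continue
            if all(
                capsules_clear(cand.capsule, m.capsule, spec.min_separation)
                for m in myotubes
            ):
                myotubes.append(cand)
                break
        else:
            raise PlacementError(
                "failed to place myotube after bounded retries; reduce "
                "myotube_density or enlarge the field"
            )

    cells: list[Nucleus] = []
    gap = 1.0
    for _ in range(preset.background_cell_density):
        area = _sample_nucleus_area(
            rng, preset.cell_nucleus_area_mean, preset.cell_nucleus_area_sd, spec.pixel_size
        )
        r = math.sqrt(area / math.pi)
        for _attempt in range(MAX_PLACEMENT_RETRIES):
            pt = rng.uniform([r, r], [extent[0] - r, extent[1] - r])
            if any(
                m.capsule.distance_to_axis(pt[None, :])[0]
                < m.capsule.radius + r + gap
                for m in myotubes
            ):
                continue
            if any(
                np.hypot(pt[0] - q.center[0], pt[1] - q.center[1]) < r + q.radius + gap
                for q in cells
            ):
                continue
            cells.append(Nucleus(center=(float(pt[0]), float(pt[1])), area=area))
            break
        else:
            raise PlacementError(
                "failed to place background cell nucleus after bounded "
                "retries; reduce background_cell_density"
            )
    return FieldSample(myotubes=myotubes, cells=cells)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Generator-emitted object and nucleus tables (the testing oracle).

    ``objects`` has one row per rendered object (myotube or marker-negative
    cell) with analytic morphometry; ``nuclei`` one row per nucleus with its
    owning object.  Centroids are in (sub-)pixel coordinates.
    """

    objects: pd.DataFrame
    nuclei: pd.DataFrame

    OBJECT_COLUMNS = [
        "plate", "well", "site", "object_id", "object_class",
        "center_row_px", "center_col_px", "orientation_rad",
        "length_um", "breadth_um", "area_um2", "perimeter_um",
        "n_nuclei", "clipped", "marker_intensity",
    ]
    NUCLEUS_COLUMNS = [
        "plate", "well", "site", "object_id", "nucleus_id",
        "centroid_row_px", "centroid_col_px", "area_um2",
    ]

    @classmethod
    def empty(cls) -> "GroundTruth":
        return cls(
            objects=pd.DataFrame(columns=cls.OBJECT_COLUMNS),
            nuclei=pd.DataFrame(columns=cls.NUCLEUS_COLUMNS),
        )

    @classmethod
    def concat(cls, parts: Sequence["GroundTruth"]) -> "GroundTruth":
        if not parts:
            return cls.empty()
        return cls(
            objects=pd.concat([p.objects for p in parts], ignore_index=True),
            nuclei=pd.concat([p.nuclei for p in parts], ignore_index=True),
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.objects.to_csv(directory / "ground_truth_objects.csv", index=False)
        self.nuclei.to_csv(directory / "ground_truth_nuclei.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "GroundTruth":
        directory = Path(directory)
        return cls(
            objects=pd.read_csv(directory / "ground_truth_objects.csv"),
            nuclei=pd.read_csv(directory / "ground_truth_nuclei.csv"),
        )


def _pixel_centers(spec: PlateSpec) -> tuple[np.ndarray, np.ndarray]:
    rows = (np.arange(spec.field_shape[0]) + 0.5) * spec.pixel_size
    cols = (np.arange(spec.field_shape[1]) + 0.5) * spec.pixel_size
    return rows, cols


def _rasterize_capsule(canvas: np.ndarray, capsule: Capsule, value: float, spec: PlateSpec) -> None:
    ps = spec.pixel_size
    p0, p1 = capsule.endpoints
    r = capsule.radius
    rmin = max(0, int((min(p0[0], p1[0]) - r) / ps) - 1)
    rmax = min(canvas.shape[0], int((max(p0[0], p1[0]) + r) / ps) + 2)
    cmin = max(0, int((min(p0[1], p1[1]) - r) / ps) - 1)
    cmax = min(canvas.shape[1], int((max(p0[1], p1[1]) + r) / ps) + 2)
    if rmin >= rmax or cmin >= cmax:
        return
    rr = (np.arange(rmin, rmax) + 0.5) * ps
    cc = (np.arange(cmin, cmax) + 0.5) * ps
    grid = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1).reshape(-1, 2)
    inside = capsule.contains(grid).reshape(rmax - rmin, cmax - cmin)
    canvas[rmin:rmax, cmin:cmax][inside] += value


def _rasterize_disc(canvas: np.ndarray, nucleus: Nucleus, value: float, spec: PlateSpec) -> None:
    ps = spec.pixel_size
    cy, cx = nucleus.center
    r = nucleus.radius
    rmin = max(0, int((cy - r) / ps) - 1)
    rmax = min(canvas.shape[0], int((cy + r) / ps) + 2)
    cmin = max(0, int((cx - r) / ps) - 1)
    cmax = min(canvas.shape[1], int((cx + r) / ps) + 2)
    if rmin >= rmax or cmin >= cmax:
        return
    rr = (np.arange(rmin, rmax) + 0.5) * ps
    cc = (np.arange(cmin, cmax) + 0.5) * ps
    dist2 = (rr[:, None] - cy) ** 2 + (cc[None, :] - cx) ** 2
    canvas[rmin:rmax, cmin:cmax][dist2 <= r**2] += value


def render_field(
    objects: FieldSample,
    spec: PlateSpec,
    rng: np.random.Generator,
    *,
    well: str = "A01",
    site: int = 1,
) -> tuple[FieldImage, GroundTruth]:
    """Rasterise a field sample into a two-channel image plus ground truth.

    The marker channel carries each capsule at its per-object intensity over
    ``background_level``; the nuclear channel carries every nucleus (myotube
    and marker-negative alike) at ``nuclear_intensity``.  Gaussian blur then
    additive Gaussian noise emulate optics and camera; output is uint16.
    An empty object list yields a valid background-only field.
    """
    shape = spec.field_shape
    marker = np.full(shape, spec.background_level, dtype=float)
    nuclear = np.full(shape, spec.background_level, dtype=float)
    ps = spec.pixel_size
    extent = spec.field_extent

    obj_rows: list[dict] = []
    nuc_rows: list[dict] = []
    next_nucleus = 1
    for i, m in enumerate(objects.myotubes, start=1):
        _rasterize_capsule(marker, m.capsule, m.marker_intensity, spec)
        clipped = not _capsule_fits_field(m.capsule, extent)
        obj_rows.append({
            "plate": spec.plate_id, "well": well, "site": site,
            "object_id": i, "object_class": "myotube",
            "center_row_px": m.capsule.center[0] / ps - 0.5,
            "center_col_px": m.capsule.center[1] / ps - 0.5,
            "orientation_rad": m.capsule.orientation,
            "length_um": m.capsule.length, "breadth_um": m.capsule.breadth,
            "area_um2": m.capsule.area, "perimeter_um": m.capsule.perimeter,
            "n_nuclei": len(m.nuclei), "clipped": clipped,
            "marker_intensity": m.marker_intensity,
        })
        for nuc in m.nuclei:
            _rasterize_disc(nuclear, nuc, spec.nuclear_intensity, spec)
            nuc_rows.append({
                "plate": spec.plate_id, "well": well, "site": site,
                "object_id": i, "nucleus_id": next_nucleus,
                "centroid_row_px": nuc.center[0] / ps - 0.5,
                "centroid_col_px": nuc.center[1] / ps - 0.5,
                "area_um2": nuc.area,
            })
            next_nucleus += 1
    offset = len(objects.myotubes)
    for j, nuc in enumerate(objects.cells, start=1):
        _rasterize_disc(nuclear, nuc, spec.nuclear_intensity, spec)
        d = 2.0 * nuc.radius
        obj_rows.append({
            "plate": spec.plate_id, "well": well, "site": site,
            "object_id": offset + j, "object_class": "cell",
            "center_row_px": nuc.center[0] / ps - 0.5,
            "center_col_px": nuc.center[1] / ps - 0.5,
            "orientation_rad": 0.0,
            "length_um": d, "breadth_um": d,
            "area_um2": nuc.area, "perimeter_um": math.pi * d,
            "n_nuclei": 1, "clipped": False, "marker_intensity": 0.0,
        })
        nuc_rows.append({
            "plate": spec.plate_id, "well": well, "site": site,
            "object_id": offset + j, "nucleus_id": next_nucleus,
            "centroid_row_px": nuc.center[0] / ps - 0.5,
            "centroid_col_px": nuc.center[1] / ps - 0.5,
            "area_um2": nuc.area,
        })
        next_nucleus += 1

    if spec.blur_sigma > 0:
        marker = ndi.gaussian_filter(marker, spec.blur_sigma)
        nuclear = ndi.gaussian_filter(nuclear, spec.blur_sigma)
    if spec.noise_sd > 0:
        marker = marker + rng.normal(0.0, spec.noise_sd, size=shape)
        nuclear = nuclear + rng.normal(0.0, spec.noise_sd, size=shape)
    marker = np.clip(np.rint(marker), 0, 65535).astype(np.uint16)
    nuclear = np.clip(np.rint(nuclear), 0, 65535).astype(np.uint16)

    field_img = FieldImage(
        plate=spec.plate_id, well=well, site=site,
        marker=marker, nuclear=nuclear, pixel_size=ps,
    )
    truth = GroundTruth(
        objects=pd.DataFrame(obj_rows, columns=GroundTruth.OBJECT_COLUMNS),
        nuclei=pd.DataFrame(nuc_rows, columns=GroundTruth.NUCLEUS_COLUMNS),
    )
    return field_img, truth


def simulate_field(
    preset: ConditionPreset,
    spec: PlateSpec,
    rng: np.random.Generator,
    *,
    well: str = "A01",
    site: int = 1,
) -> tuple[FieldImage, GroundTruth]:
    """Sample and render one field in a single call."""
    sample = sample_field(preset, spec, rng)
    return render_field(sample, spec, rng, well=well, site=site)


def generate_plate(
    spec: PlateSpec, outdir: str | Path | None = None
) -> tuple[list[FieldImage], GroundTruth]:
    """Generate every field of a plate; optionally write TIFFs and CSVs.

    One single-channel 16-bit TIFF per field per channel is written, named
    ``{plate}_{well}_s{site:02d}_{marker|nuclear}.tif``, alongside the two
    ground-truth CSVs and a ``plate_spec.yaml`` metadata record.  The same
    ``rng_seed`` reproduces bit-identical images and tables: each field gets
    an independent child stream spawned from the plate seed, so field content
    does not depend on generation order.
    """
    root = np.random.SeedSequence(spec.rng_seed)
    children = root.spawn(len(spec.wells) * spec.fields_per_well)
    fields: list[FieldImage] = []
    truths: list[GroundTruth] = []
    k = 0
    for well, preset in spec.wells:
        for site in range(1, spec.fields_per_well + 1):
            rng = np.random.default_rng(children[k])
            k += 1
            img, truth = simulate_field(preset, spec, rng, well=well, site=site)
            fields.append(img)
            truths.append(truth)
    truth_all = GroundTruth.concat(truths)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for img in fields:
            save_field(img, outdir)
        truth_all.save(outdir)
        meta = {
            "plate_id": spec.plate_id,
            "pixel_size_um": spec.pixel_size,
            "field_shape_px": list(spec.field_shape),
            "fields_per_well": spec.fields_per_well,
            "noise_sd": spec.noise_sd,
            "blur_sigma": spec.blur_sigma,
            "rng_seed": spec.rng_seed,
            "wells": {w: p.name for w, p in spec.wells},
        }
        with open(outdir / "plate_spec.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
    return fields, truth_all
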