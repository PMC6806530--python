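"""Synthetic chamber scenes and sensor fixtures.

Generates parametric plants (flat round leaves vs. elongated twisted
ribbons), labeled point clouds at two sensor fidelities (a coarse
long-range depth camera and a fine short-range profilometer), and
orthographic spectral/thermal fixture images with ground-truth masks.

Units: meters internally; leaf dimensions are accepted in millimeters at
the config boundary.  Right-handed frame, z-up, chamber floor at z = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from phytoprobe.measurements import SpectralCube, ThermalImage

__all__ = [
    "LeafModel",
    "Plant",
    "Pot",
    "ChamberScene",
    "SensorModel",
    "SceneSpec",
    "Pose",
    "LabeledCloud",
    "TOF_COARSE",
    "PROFILOMETER_FINE",
    "build_scene",
    "sample_cloud",
    "render_fixtures",
    "leaf_surface_points",
    "surface_residual",
]

MM = 1e-3


class SceneValidationError(ValueError):
    """Raised when a scene spec violates its invariants."""


# --------------------------------------------------------------------------
# Plant geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LeafModel:
    """A single parametric leaf.

    ``flat_round`` leaves are elliptical planar disks; ``elongated_twisted``
    leaves are ruled ribbons whose cross-section rotates about the major
    axis at ``twist_rate`` degrees per millimeter.
    """

    species_style: str            # "flat_round" | "elongated_twisted"
    length_mm: float
    width_mm: float
    twist_rate: float = 0.0       # deg per mm along the major axis
    attachment: tuple[float, float, float] = (0.0, 0.0, 0.0)   # meters
    azimuth_deg: float = 0.0
    inclination_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.species_style not in ("flat_round", "elongated_twisted"):
            raise SceneValidationError(
                f"unknown species_style {self.species_style!r}"
            )
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise SceneValidationError("leaf length and width must be > 0")
        if self.species_style == "flat_round" and self.twist_rate != 0.0:
            raise SceneValidationError("flat_round leaves must have twist_rate 0")

    @property
    def rotation(self) -> np.ndarray:
        """Local-to-world rotation: yaw by azimuth, pitch by inclination."""
        az = math.radians(self.azimuth_deg)
        inc = math.radians(self.inclination_deg)
        rz = np.array([
            [math.cos(az), -math.sin(az), 0.0],
            [math.sin(az), math.cos(az), 0.0],
            [0.0, 0.0, 1.0],
        ])
        ry = np.array([
            [math.cos(inc), 0.0, math.sin(inc)],
            [0.0, 1.0, 0.0],
            [-math.sin(inc), 0.0, math.cos(inc)],
        ])
        return rz @ ry


def _leaf_local_points(leaf: LeafModel, pitch_mm: float) -> np.ndarray:
    """Regular surface sample grid in the leaf's local frame, in mm."""
    length, width = leaf.length_mm, leaf.width_mm
    nu = max(int(round(length / pitch_mm)) + 1, 2)
    nv = max(int(round(width / pitch_mm)) + 1, 2)
    u = np.linspace(0.0, length, nu)
    v = np.linspace(-width / 2.0, width / 2.0, nv)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    uu, vv = uu.ravel(), vv.ravel()
    if leaf.species_style == "flat_round":
        a, b = length / 2.0, width / 2.0
        inside = ((uu - a) / a) ** 2 + (vv / b) ** 2 <= 1.0 + 1e-12
        uu, vv = uu[inside], vv[inside]
        return np.column_stack([uu, vv, np.zeros_like(uu)])
    theta = np.radians(leaf.twist_rate * uu)
    return np.column_stack([uu, vv * np.cos(theta), vv * np.sin(theta)])


def leaf_surface_points(leaf: LeafModel, pitch_mm: float = 2.0) -> np.ndarray:
    """World-frame surface samples of a leaf on a regular grid (meters)."""
    local = _leaf_local_points(leaf, pitch_mm) * MM
    return np.asarray(leaf.attachment) + local @ leaf.rotation.T


def surface_residual(leaf: LeafModel, points: np.ndarray) -> np.ndarray:
    """Signed distance of points from the leaf's parametric surface (m).

    Exact closed-form inversion: points are mapped back to the local leaf
    frame; the residual is the out-of-surface coordinate.  Points whose
    footprint falls outside the leaf outline get ``inf``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    local = (pts - np.asarray(leaf.attachment)) @ leaf.rotation / MM  # mm
    x, y, z = local.T
    res = np.full(len(pts), np.inf)
    if leaf.species_style == "flat_round":
        a, b = leaf.length_mm / 2.0, leaf.width_mm / 2.0
        on = ((x - a) / a) ** 2 + (y / b) ** 2 <= 1.0 + 1e-9
        res[on] = z[on] * MM
        return res
    theta = np.radians(leaf.twist_rate * x)
    v = y * np.cos(theta) + z * np.sin(theta)
    out = -y * np.sin(theta) + z * np.cos(theta)
    on = (
        (x >= -1e-9)
        & (x <= leaf.length_mm + 1e-9)
        & (np.abs(v) <= leaf.width_mm / 2.0 + 1e-9)
    )
    res[on] = out[on] * MM
    return res


@dataclass(frozen=True)
class Plant:
    stem_height_m: float
    leaves: tuple[LeafModel, ...]

    def __post_init__(self) -> None:
        if self.stem_height_m < 0:
            raise SceneValidationError("stem height must be >= 0")


@dataclass(frozen=True)
class Pot:
    pot_id: int
    position: tuple[float, float]   # floor coordinates, m
    plant: Plant


@dataclass(frozen=True)
class ChamberScene:
    pots: tuple[Pot, ...]
    chamber_extent: tuple[float, float, float] = (1.8, 1.0, 2.2)  # m
    arm_base: tuple[float, float, float] = (0.9, -0.3, 0.5)

    def __post_init__(self) -> None:
        ex, ey, _ = self.chamber_extent
        seen: set[tuple[float, float]] = set()
        for pot in self.pots:
            x, y = pot.position
            if not (0.0 <= x <= ex and 0.0 <= y <= ey):
                raise SceneValidationError(
                    f"pot {pot.pot_id} at {pot.position} outside chamber "
                    f"footprint {ex} x {ey} m"
                )
            if pot.position in seen:
                raise SceneValidationError(
                    f"duplicate pot position {pot.position}"
                )
            seen.add(pot.position)

    @property
    def leaves(self) -> list[tuple[int, LeafModel]]:
        """All leaves with their global 1-based leaf ids, in scene order."""
        out = []
        lid = 1
        for pot in self.pots:
            for leaf in pot.plant.leaves:
                out.append((lid, leaf))
                lid += 1
        return out


# --------------------------------------------------------------------------
# Sensors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorModel:
    kind: str                     # "tof_coarse" | "profilometer_fine"
    noise_sd_mm: float
    min_range_m: float
    max_range_m: float
    fov_h_deg: float
    fov_v_deg: float
    sample_pitch_mm: float

    def __post_init__(self) -> None:
        if self.noise_sd_mm < 0:
            raise SceneValidationError("noise_sd must be >= 0")
        if not self.min_range_m < self.max_range_m:
            raise SceneValidationError("min_range must be < max_range")


TOF_COARSE = SensorModel(
    kind="tof_coarse",
    noise_sd_mm=10.0,
    min_range_m=0.5,
    max_range_m=6.0,
    fov_h_deg=43.0,
    fov_v_deg=33.0,
    sample_pitch_mm=10.0,
)

# Fine-sensor noise is not published for the short-range profilometer;
# 0.2 mm is a documented "highly repeatable" default.
PROFILOMETER_FINE = SensorModel(
    kind="profilometer_fine",
    noise_sd_mm=0.2,
    min_range_m=0.02,
    max_range_m=0.8,
    fov_h_deg=70.0,
    fov_v_deg=70.0,
    sample_pitch_mm=2.0,
)

SENSOR_PRESETS = {s.kind: s for s in (TOF_COARSE, PROFILOMETER_FINE)}


@dataclass(frozen=True)
class Pose:
    """Viewpoint: sensor position and a look-at target, both in meters."""

    position: tuple[float, float, float]
    look_at: tuple[float, float, float]

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (forward, right, up) camera frame."""
        pos = np.asarray(self.position, dtype=float)
        fwd = np.asarray(self.look_at, dtype=float) - pos
        norm = np.linalg.norm(fwd)
        if norm == 0:
            raise SceneValidationError("degenerate viewpoint: look_at == position")
        fwd = fwd / norm
        up_hint = np.array([0.0, 0.0, 1.0])
        if abs(fwd @ up_hint) > 1.0 - 1e-9:
            up_hint = np.array([1.0, 0.0, 0.0])
        right = np.cross(fwd, up_hint)
        right /= np.linalg.norm(right)
        up = np.cross(right, fwd)
        return fwd, right, up


@dataclass(frozen=True)
class LabeledCloud:
    """Point cloud with per-point ground-truth leaf ids (0 = non-leaf)."""

    points: np.ndarray
    labels: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.points) != len(self.labels):
            raise SceneValidationError("labels length must match points")

    def __len__(self) -> int:
        return len(self.points)


# --------------------------------------------------------------------------
# Scene construction
# --------------------------------------------------------------------------

_SPECIES_PRESETS = {
    # length mm, width mm, twist deg/mm
    "flat_round": dict(length_mm=70.0, width_mm=60.0, twist_rate=0.0),
    "elongated_twisted": dict(length_mm=400.0, width_mm=50.0, twist_rate=0.6),
}


@dataclass(frozen=True)
class SceneSpec:
    """Declarative scene description consumed by :func:`build_scene`."""

    pot_positions: tuple[tuple[float, float], ...]
    species_style: str = "flat_round"
    leaves_per_plant: int = 3
    stem_height_m: float = 0.3
    chamber_extent: tuple[float, float, float] = (1.8, 1.0, 2.2)
    arm_base: tuple[float, float, float] = (0.9, -0.3, 0.5)
    leaf_overrides: Mapping[str, float] = field(default_factory=dict)

    @staticmethod
    def grid(n_pots: int, **kwargs) -> "SceneSpec":
        """Pots on a regular grid inside the default chamber footprint."""
        extent = kwargs.get("chamber_extent", (1.8, 1.0, 2.2))
        ncol = int(math.ceil(math.sqrt(n_pots)))
        nrow = int(math.ceil(n_pots / ncol))
        xs = np.linspace(0.2, extent[0] - 0.2, ncol)
        ys = np.linspace(0.2, extent[1] - 0.2, nrow)
        pos = []
        for j in range(nrow):
            for i in range(ncol):
                if len(pos) < n_pots:
                    pos.append((float(xs[i]), float(ys[j])))
        return SceneSpec(pot_positions=tuple(pos), **kwargs)

    @staticmethod
    def from_dict(d: Mapping) -> "SceneSpec":
        d = dict(d)
        if "n_pots" in d and "pot_positions" not in d:
            n = d.pop("n_pots")
            return SceneSpec.grid(n, **_tuplify(d))
        d["pot_positions"] = tuple(tuple(p) for p in d["pot_positions"])
        return SceneSpec(**_tuplify(d))


def _tuplify(d: dict) -> dict:
    for key in ("chamber_extent", "arm_base"):
        if key in d:
            d[key] = tuple(d[key])
    return d


def build_scene(spec: SceneSpec, seed: int) -> ChamberScene:
    """Instantiate a deterministic chamber scene from a spec and seed.

    Plants are generated from per-species leaf presets with seeded random
    azimuths/inclinations so that repeated calls with the same
    ``(spec, seed)`` are bit-identical.
    """
    if len(spec.pot_positions) < 1:
        raise SceneValidationError("scene spec must declare at least one pot")
    rng = np.random.default_rng(seed)
    preset = dict(_SPECIES_PRESETS[spec.species_style])
    preset.update(spec.leaf_overrides)
    pots = []
    for pid, (px, py) in enumerate(spec.pot_positions, start=1):
        leaves = []
        for j in range(spec.leaves_per_plant):
            azimuth = float(rng.uniform(0.0, 360.0))
            inclination = float(rng.uniform(-30.0, 10.0))
            attach_z = spec.stem_height_m * (0.6 + 0.4 * (j + 1) / spec.leaves_per_plant)
            leaves.append(LeafModel(
                species_style=spec.species_style,
                attachment=(px, py, attach_z),
                azimuth_deg=azimuth,
                inclination_deg=inclination,
                **preset,
            ))
        pots.append(Pot(pot_id=pid, position=(px, py),
                        plant=Plant(stem_height_m=spec.stem_height_m,
                                    leaves=tuple(leaves))))
    return ChamberScene(pots=tuple(pots),
                        chamber_extent=spec.chamber_extent,
                        arm_base=spec.arm_base)


# --------------------------------------------------------------------------
# Cloud sampling
# --------------------------------------------------------------------------

def _scene_surface_samples(
    scene: ChamberScene, pitch_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Dense labeled surface samples of all scene geometry."""
    pts_list, lab_list = [], []
    for lid, leaf in scene.leaves:
        pts = leaf_surface_points(leaf, pitch_mm)
        pts_list.append(pts)
        lab_list.append(np.full(len(pts), lid, dtype=int))
    for pot in scene.pots:
        # Stem: vertical line of non-leaf points.
        nz = max(int(pot.plant.stem_height_m / (pitch_mm * MM)), 2)
        z = np.linspace(0.0, pot.plant.stem_height_m, nz)
        stem = np.column_stack([
            np.full(nz, pot.position[0]),
            np.full(nz, pot.position[1]),
            z,
        ])
        pts_list.append(stem)
        lab_list.append(np.zeros(nz, dtype=int))
    if not pts_list:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.vstack(pts_list), np.concatenate(lab_list)


def sample_cloud(
    scene: ChamberScene,
    sensor: SensorModel,
    viewpoint: Pose,
    seed: int,
    occlusion: bool = True,
    occlusion_bin_deg: float = 0.2,
) -> LabeledCloud:
    """Simulate a depth-sensor capture of a scene.

    Surface samples within the sensor's range and field of view are kept,
    hidden points are removed by an angular z-buffer (nearest return per
    angular bin), and survivors are perturbed by isotropic Gaussian noise
    of the sensor's configured standard deviation.  Labels carry the
    ground-truth leaf id of each point; an empty view yields an empty
    cloud.
    """
    rng = np.random.default_rng(seed)
    pts, labels = _scene_surface_samples(scene, sensor.sample_pitch_mm)
    if len(pts) == 0:
        return LabeledCloud(points=pts, labels=labels, source=sensor.kind)

    fwd, right, up = viewpoint.frame()
    rel = pts - np.asarray(viewpoint.position)
    depth = rel @ fwd
    x = rel @ right
    y = rel @ up
    rng_dist = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ang_h = np.degrees(np.arctan2(x, depth))
        ang_v = np.degrees(np.arctan2(y, depth))
    keep = (
        (depth > 0)
        & (rng_dist >= sensor.min_range_m)
        & (rng_dist <= sensor.max_range_m)
        & (np.abs(ang_h) <= sensor.fov_h_deg / 2.0)
        & (np.abs(ang_v) <= sensor.fov_v_deg / 2.0)
    )
    pts, labels = pts[keep], labels[keep]
    rng_dist, ang_h, ang_v = rng_dist[keep], ang_h[keep], ang_v[keep]

    if occlusion and len(pts) > 0:
        bins_h = np.floor(ang_h / occlusion_bin_deg).astype(np.int64)
        bins_v = np.floor(ang_v / occlusion_bin_deg).astype(np.int64)
        key = (bins_h - bins_h.min()) * (bins_v.max() - bins_v.min() + 1) \
            + (bins_v - bins_v.min())
        order = np.lexsort((rng_dist, key))
        key_sorted = key[order]
        first = np.ones(len(key_sorted), dtype=bool)
        first[1:] = key_sorted[1:] != key_sorted[:-1]
        visible = np.sort(order[first])
        pts, labels = pts[visible], labels[visible]

    if sensor.noise_sd_mm > 0 and len(pts) > 0:
        pts = pts + rng.normal(0.0, sensor.noise_sd_mm * MM, size=pts.shape)
    return LabeledCloud(points=pts, labels=labels, source=sensor.kind)


# --------------------------------------------------------------------------
# Spectral / thermal fixtures
# --------------------------------------------------------------------------

DEFAULT_BAND_COUNT = 56
DEFAULT_BAND_RANGE = (400.0, 900.0)


def render_fixtures(
    scene: ChamberScene,
    band_count: int = DEFAULT_BAND_COUNT,
    band_range: tuple[float, float] = DEFAULT_BAND_RANGE,
    leaf_spectra: Mapping[int, Sequence[float]] | None = None,
    leaf_temps: Mapping[int, float] | None = None,
    background_reflectance: float = 0.05,
    background_temp_c: float = 22.0,
    pixel_size_m: float = 0.005,
) -> tuple[SpectralCube, ThermalImage, dict[int, np.ndarray]]:
    """Orthographic top-view spectral cube, thermal image and leaf masks.

    Per-leaf spectra default to a generic vegetation-like spectrum; leaf
    temperatures default to 26 degC.  Background pixels carry a flat
    ``background_reflectance`` spectrum and ``background_temp_c``.
    Pixel (row, col) covers floor cell (y, x) so images align with the
    chamber footprint; taller geometry wins where leaves overlap.
    """
    lo, hi = band_range
    if not (400.0 <= lo < hi <= 900.0):
        raise SceneValidationError("band_range must lie within 400-900 nm")
    bands = np.linspace(lo, hi, band_count)
    leaf_spectra = dict(leaf_spectra or {})
    leaf_temps = dict(leaf_temps or {})

    for lid, spec in leaf_spectra.items():
        if len(np.asarray(spec)) != band_count:
            raise SceneValidationError(
                f"leaf {lid}: spectrum length {len(np.asarray(spec))} "
                f"!= band_count {band_count}"
            )

    ex, ey, _ = scene.chamber_extent
    w = max(int(round(ex / pixel_size_m)), 1)
    h = max(int(round(ey / pixel_size_m)), 1)

    cube = np.full((h, w, band_count), background_reflectance)
    thermal = np.full((h, w), background_temp_c)
    zbuf = np.full((h, w), -np.inf)
    masks: dict[int, np.ndarray] = {}

    default_spectrum = _vegetation_spectrum(bands)
    for lid, leaf in scene.leaves:
        pts = leaf_surface_points(leaf, pitch_mm=pixel_size_m / MM / 2.0)
        cols = np.clip((pts[:, 0] / pixel_size_m).astype(int), 0, w - 1)
        rows = np.clip((pts[:, 1] / pixel_size_m).astype(int), 0, h - 1)
        mask = np.zeros((h, w), dtype=bool)
        spectrum = np.asarray(leaf_spectra.get(lid, default_spectrum), dtype=float)
        temp = float(leaf_temps.get(lid, 26.0))
        for r, c, z in zip(rows, cols, pts[:, 2]):
            if z >= zbuf[r, c]:
                zbuf[r, c] = z
                cube[r, c] = spectrum
                thermal[r, c] = temp
                mask[r, c] = True
        masks[lid] = mask
    # A taller leaf drawn later steals overlapping pixels from earlier masks.
    for lid, leaf_mask in masks.items():
        for other, other_mask in masks.items():
            if other > lid:
                leaf_mask &= ~other_mask
    return (
        SpectralCube(bands=bands, data=cube),
        ThermalImage(data=thermal),
        masks,
    )


def _vegetation_spectrum(bands: np.ndarray) -> np.ndarray:
    """Generic green-leaf reflectance: chlorophyll trough + red-edge step."""
    green_bump = 0.08 * np.exp(-((bands - 550.0) / 40.0) ** 2)
    red_edge = 0.38 / (1.0 + np.exp(-(bands - 715.0) / 8.0))
    return 0.05 + green_bump + red_edge
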