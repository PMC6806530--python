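"""Probe-pose and hyperspectral line-scan planning on leaf segments.

Chooses probing sites on the large flat portions of segmented leaves,
computes probe placements at a configured standoff and incidence angle
relative to the local tangent plane, checks reachability and swept-
cylinder collisions against the workspace, dissects leaves into
fixed-width slices along their major axis, and plans per-slice line-scan
camera poses and the top-view imaging pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from phytoprobe.geometry import NormalField, principal_axes
from phytoprobe.scene import Pose
from phytoprobe.segmentation import Segmentation

__all__ = [
    "ProbePose",
    "ProbeSite",
    "WorkspaceModel",
    "SlicePlan",
    "FeasibilityVerdict",
    "select_probe_sites",
    "compute_probe_pose",
    "check_feasible",
    "slice_leaf",
    "plan_line_scan_poses",
    "plan_topview_pose",
]

MM = 1e-3

# Default probe geometry: hand-held clip places the fiber-optic probe
# ~8 mm from the leaf at 60 deg to the leaf surface; the arm mimics it.
DEFAULT_STANDOFF_MM = 8.0
DEFAULT_INCIDENCE_DEG = 60.0
DEFAULT_SLICE_WIDTH_MM = 5.0
DEFAULT_SCAN_DISTANCE_M = 0.25
DEFAULT_FOOTPRINT_M = 0.5
DEFAULT_REACH_RADIUS_M = 1.3
DEFAULT_CLEARANCE_MM = 15.0
FLATNESS_RMS_MM = 1.0


class PlanningError(ValueError):
    pass


@dataclass(frozen=True)
class ProbePose:
    """A probe placement relative to a leaf site.

    ``axis`` points from the probe tip toward the target; the tip sits
    ``standoff_mm`` back from the target along the axis; ``incidence_deg``
    is the angle between the axis and the leaf tangent plane.
    """

    target: np.ndarray          # m
    axis: np.ndarray            # unit vector
    standoff_mm: float
    incidence_deg: float

    def __post_init__(self) -> None:
        if self.standoff_mm <= 0:
            raise PlanningError("standoff must be > 0")
        if not 0.0 < self.incidence_deg <= 90.0:
            raise PlanningError("incidence must be in (0, 90] degrees")
        axis = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
            raise PlanningError("axis must be a unit vector")
        object.__setattr__(self, "target", np.asarray(self.target, dtype=float))
        object.__setattr__(self, "axis", axis)

    @property
    def tip(self) -> np.ndarray:
        """Probe-tip position in meters."""
        return self.target - self.standoff_mm * MM * self.axis


@dataclass(frozen=True)
class WorkspaceModel:
    arm_base: tuple[float, float, float] = (0.0, 0.0, 0.0)
    reach_radius_m: float = DEFAULT_REACH_RADIUS_M
    probe_clearance_radius_mm: float = DEFAULT_CLEARANCE_MM

    def __post_init__(self) -> None:
        if self.reach_radius_m <= 0:
            raise PlanningError("reach radius must be > 0")


@dataclass(frozen=True)
class FeasibilityVerdict:
    feasible: bool
    reason: str | None = None   # "unreachable" | "collision" | None

    def __bool__(self) -> bool:
        return self.feasible


@dataclass(frozen=True)
class ProbeSite:
    segment_id: int
    point: np.ndarray
    normal: np.ndarray
    score: float                # largest flat-neighborhood radius, m


# --------------------------------------------------------------------------
# Site selection
# --------------------------------------------------------------------------

def _segment_density(pts: np.ndarray) -> float | None:
    """Areal point density (pts / m^2) of a segment's planar projection."""
    from scipy.spatial import ConvexHull, QhullError

    axes = principal_axes(pts)
    proj = (pts - axes.centroid) @ axes.axes[:2].T
    try:
        area = ConvexHull(proj).volume      # 2-D hull "volume" is area
    except QhullError:
        return None
    return len(pts) / area if area > 0 else None


def _flat_radius(
    pts: np.ndarray,
    center_idx: int,
    tol_m: float,
    density: float | None = None,
    coverage: float = 0.7,
) -> float:
    """Largest inscribed flat-neighborhood radius around a point.

    The radius grows while (a) the enclosed points fit a plane within
    ``tol_m`` RMS and (b) the ball stays covered by segment points — the
    enclosed count must reach ``coverage`` of what the segment's areal
    density predicts, which keeps the ball inscribed in the segment
    rather than hanging over its rim.  Prefix covariances over the
    distance-sorted points make each plane fit O(1).
    """
    center = pts[center_idx]
    d = np.linalg.norm(pts - center, axis=1)
    order = np.argsort(d, kind="stable")
    sorted_pts = pts[order]
    d_sorted = d[order]
    csum = np.cumsum(sorted_pts, axis=0)
    csq = np.cumsum(np.einsum("ni,nj->nij", sorted_pts, sorted_pts), axis=0)
    best = 0.0
    for m in range(3, len(pts) + 1):
        mean = csum[m - 1] / m
        cov = csq[m - 1] / m - np.outer(mean, mean)
        lmin = np.linalg.eigvalsh(cov)[0]
        rms = math.sqrt(max(lmin, 0.0))
        if rms > tol_m:
            break
        r = d_sorted[m - 1]
        if density is not None and m >= 12:
            expected = density * math.pi * r * r
            if m < coverage * expected:
                break
        best = r
    return float(best)


def select_probe_sites(
    seg: Segmentation,
    cloud,
    field: NormalField,
    n_sites: int,
    flatness_tol_mm: float = FLATNESS_RMS_MM,
    max_candidates_per_segment: int = 250,
) -> list[ProbeSite]:
    """Rank probing sites by largest locally-flat neighborhood radius.

    At most one site per segment until every segment holds one, then
    additional sites round-robin across segments, separated from already
    chosen sites by at least the chosen site's flat radius.
    """
    pts = np.asarray(getattr(cloud, "points", cloud), dtype=float)
    if n_sites <= 0 or not seg.segments:
        return []
    tol_m = flatness_tol_mm * MM

    per_segment: list[list[ProbeSite]] = []
    for sid, seg_idx in enumerate(seg.segments, start=1):
        seg_pts = pts[seg_idx]
        density = _segment_density(seg_pts)
        stride = max(len(seg_idx) // max_candidates_per_segment, 1)
        cand_local = np.arange(0, len(seg_idx), stride)
        scored = []
        for li in cand_local:
            r = _flat_radius(seg_pts, int(li), tol_m, density=density)
            gi = int(seg_idx[li])
            scored.append(ProbeSite(
                segment_id=sid,
                point=pts[gi],
                normal=field.normals[gi],
                score=r,
            ))
        scored.sort(key=lambda s: -s.score)
        per_segment.append(scored)

    # Round-robin over segments in order of their best candidate's score.
    per_segment.sort(key=lambda lst: -(lst[0].score if lst else -1.0))
    chosen: list[ProbeSite] = []
    cursor = [0] * len(per_segment)
    while len(chosen) < n_sites:
        progressed = False
        for si, cands in enumerate(per_segment):
            if len(chosen) >= n_sites:
                break
            while cursor[si] < len(cands):
                cand = cands[cursor[si]]
                cursor[si] += 1
                min_sep = max(cand.score, 5 * MM)
                taken = [c for c in chosen if c.segment_id == cand.segment_id]
                if all(np.linalg.norm(cand.point - c.point) >= min_sep
                       for c in taken):
                    chosen.append(cand)
                    progressed = True
                    break
        if not progressed:
            break
    return chosen


# --------------------------------------------------------------------------
# Probe poses
# --------------------------------------------------------------------------

def _default_azimuth(normal: np.ndarray) -> np.ndarray:
    """Deterministic tangent direction: global +x projected on the plane."""
    for ref in (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])):
        t = ref - (ref @ normal) * normal
        norm = np.linalg.norm(t)
        if norm > 1e-9:
            return t / norm
    raise PlanningError("cannot construct tangent direction")


def compute_probe_pose(
    site,
    normal,
    standoff_mm: float = DEFAULT_STANDOFF_MM,
    incidence_deg: float = DEFAULT_INCIDENCE_DEG,
    azimuth_dir=None,
) -> ProbePose:
    """Probe pose at a leaf site honoring standoff and incidence.

    The axis tilts away from the surface normal toward ``azimuth_dir``
    (a tangent-plane direction; defaults to the projection of global +x)
    so that it makes ``incidence_deg`` with the tangent plane.  At 90 deg
    the axis coincides with the normal.
    """
    normal = np.asarray(normal, dtype=float)
    if abs(np.linalg.norm(normal) - 1.0) > 1e-6:
        raise PlanningError("normal must be a unit vector")
    normal = normal / np.linalg.norm(normal)
    if not 0.0 < incidence_deg <= 90.0:
        raise PlanningError("incidence must be in (0, 90] degrees")
    if azimuth_dir is None:
        tangent = _default_azimuth(normal)
    else:
        azimuth_dir = np.asarray(azimuth_dir, dtype=float)
        tangent = azimuth_dir - (azimuth_dir @ normal) * normal
        norm = np.linalg.norm(tangent)
        if norm < 1e-12:
            tangent = _default_azimuth(normal)
        else:
            tangent = tangent / norm
    inc = math.radians(incidence_deg)
    axis = math.sin(inc) * normal + math.cos(inc) * tangent
    axis /= np.linalg.norm(axis)
    return ProbePose(
        target=np.asarray(site, dtype=float),
        axis=axis,
        standoff_mm=standoff_mm,
        incidence_deg=incidence_deg,
    )


def check_feasible(
    pose: ProbePose,
    cloud,
    ws: WorkspaceModel,
    exclude_indices=None,
    target_exclusion_radius_mm: float = 20.0,
) -> FeasibilityVerdict:
    """Reachability and straight-approach collision check.

    Infeasible when the probe tip lies beyond the arm's reach radius, or
    when any cloud point (other than excluded indices and points within
    the target's exclusion radius — the leaf patch being probed) falls
    inside the clearance cylinder swept along the approach axis from tip
    to target.
    """
    tip = pose.tip
    base = np.asarray(ws.arm_base, dtype=float)
    if np.linalg.norm(tip - base) > ws.reach_radius_m:
        return FeasibilityVerdict(False, "unreachable")

    pts = np.asarray(getattr(cloud, "points", cloud), dtype=float)
    if len(pts) == 0:
        return FeasibilityVerdict(True)
    mask = np.ones(len(pts), dtype=bool)
    if exclude_indices is not None:
        mask[np.asarray(exclude_indices, dtype=int)] = False
    near_target = np.linalg.norm(pts - pose.target, axis=1) \
        <= target_exclusion_radius_mm * MM
    mask &= ~near_target
    if not mask.any():
        return FeasibilityVerdict(True)
    rel = pts[mask] - tip
    along = rel @ pose.axis
    in_span = (along >= 0.0) & (along <= pose.standoff_mm * MM)
    radial2 = np.einsum("ni,ni->n", rel, rel) - along ** 2
    hit = in_span & (radial2 <= (ws.probe_clearance_radius_mm * MM) ** 2)
    if hit.any():
        return FeasibilityVerdict(False, "collision")
    return FeasibilityVerdict(True)


# --------------------------------------------------------------------------
# Slice plans
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanPose:
    camera: np.ndarray          # m
    view_axis: np.ndarray       # unit, camera -> centroid
    scan_dir: np.ndarray        # unit, in the plane perpendicular to view
    centroid: np.ndarray


@dataclass(frozen=True)
class SlicePlan:
    """Dissection of a leaf segment into fixed-width major-axis slices."""

    points: np.ndarray                       # (M, 3) segment points, m
    slice_indices: tuple[np.ndarray, ...]    # per-slice point indices
    intervals: tuple[tuple[float, float], ...]   # mm along major axis
    slice_width_mm: float
    major_axis: np.ndarray
    origin: np.ndarray                       # point at projection 0
    scan_poses: tuple[ScanPose | None, ...] = ()

    @property
    def n_slices(self) -> int:
        return len(self.slice_indices)

    @property
    def extent_mm(self) -> float:
        return self.intervals[-1][1] if self.intervals else 0.0


def slice_leaf(segment_points, slice_width_mm: float = DEFAULT_SLICE_WIDTH_MM
               ) -> SlicePlan:
    """Bin segment points into contiguous slices along the major axis.

    ``ceil(extent / width)`` bins starting at the minimum projection; all
    interior bins span exactly ``slice_width_mm`` and the last spans the
    remainder.  Empty bins are retained as empty slices; a degenerate
    (zero-extent) segment yields a single slice.
    """
    pts = np.asarray(segment_points, dtype=float)
    if len(pts) < 3:
        raise PlanningError("slice_leaf needs at least 3 points")
    if slice_width_mm <= 0:
        raise PlanningError("slice width must be > 0")
    axes = principal_axes(pts)
    major = axes.axes[0]
    proj_mm = (pts - axes.centroid) @ major / MM
    t = proj_mm - proj_mm.min()
    extent = float(t.max())
    origin = axes.centroid + proj_mm.min() * MM * major
    if extent <= 0.0:
        return SlicePlan(
            points=pts,
            slice_indices=(np.arange(len(pts)),),
            intervals=((0.0, 0.0),),
            slice_width_mm=slice_width_mm,
            major_axis=major,
            origin=origin,
        )
    n = int(math.ceil(extent / slice_width_mm - 1e-9))
    idx = np.minimum((t / slice_width_mm).astype(int), n - 1)
    slices = tuple(np.flatnonzero(idx == i) for i in range(n))
    intervals = tuple(
        (i * slice_width_mm, min((i + 1) * slice_width_mm, extent))
        for i in range(n)
    )
    return SlicePlan(
        points=pts,
        slice_indices=slices,
        intervals=intervals,
        slice_width_mm=slice_width_mm,
        major_axis=major,
        origin=origin,
    )


def plan_line_scan_poses(
    plan: SlicePlan, working_distance_m: float = DEFAULT_SCAN_DISTANCE_M
) -> SlicePlan:
    """Attach a line-scan camera pose to every slice of a plan.

    For each slice with at least 3 points the camera sits at the slice
    centroid plus the working distance along the local surface normal
    (oriented into the upper hemisphere), scanning along the projection
    of the leaf's major direction onto the image plane.  Thin slices
    inherit the pose of the nearest planned slice; empty slices carry no
    pose.
    """
    if plan.n_slices == 0:
        raise PlanningError("plan has no slices")
    if working_distance_m <= 0:
        raise PlanningError("working distance must be > 0")
    poses: list[ScanPose | None] = [None] * plan.n_slices
    planned: list[int] = []
    for i, idx in enumerate(plan.slice_indices):
        if len(idx) < 3:
            continue
        sub = plan.points[idx]
        axes = principal_axes(sub)
        normal = axes.axes[2]
        if normal[2] < 0 or (normal[2] == 0 and _first_nonzero(normal) < 0):
            normal = -normal
        camera = axes.centroid + working_distance_m * normal
        view_axis = -normal
        scan = plan.major_axis - (plan.major_axis @ view_axis) * view_axis
        norm = np.linalg.norm(scan)
        scan = axes.axes[0] if norm < 1e-12 else scan / norm
        poses[i] = ScanPose(camera=camera, view_axis=view_axis,
                            scan_dir=scan, centroid=axes.centroid)
        planned.append(i)
    if not planned:
        raise PlanningError("no slice has enough points to plan a pose")
    for i in range(plan.n_slices):
        if poses[i] is None and len(plan.slice_indices[i]) > 0:
            nearest = min(planned, key=lambda j: abs(j - i))
            poses[i] = poses[nearest]
    return replace(plan, scan_poses=tuple(poses))


def _first_nonzero(v: np.ndarray) -> float:
    for comp in v:
        if comp != 0:
            return float(comp)
    return 0.0


# --------------------------------------------------------------------------
# Top view
# --------------------------------------------------------------------------

def plan_topview_pose(
    plant_height_m: float,
    camera_fov_deg: tuple[float, float] = (43.0, 33.0),
    footprint_side_m: float = DEFAULT_FOOTPRINT_M,
    plant_xy: tuple[float, float] = (0.0, 0.0),
) -> Pose:
    """Overhead camera pose covering a square footprint at plant height.

    The stand-off above the plant is chosen so the narrower field of view
    subtends the full footprint side:
    ``h = footprint / (2 tan(fov_min / 2))``.
    """
    fov_min = min(camera_fov_deg)
    if not 0.0 < fov_min < 180.0:
        raise PlanningError("fov must be in (0, 180) degrees")
    if footprint_side_m < 0:
        raise PlanningError("footprint must be >= 0")
    standoff = footprint_side_m / (2.0 * math.tan(math.radians(fov_min) / 2.0))
    x, y = plant_xy
    return Pose(
        position=(x, y, plant_height_m + standoff),
        look_at=(x, y, plant_height_m),
    )
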