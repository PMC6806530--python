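"""Point-cloud file I/O, workflow configuration, and the per-plant
acquisition pipeline.

Clouds are exchanged as ASCII PLY (with optional integer ``label`` /
``segment`` vertex properties) or ASCII PCD.  ``run_acquisition``
executes the full per-plant sequence: coarse-cloud height estimate,
top-view positioning, fine cloud, segmentation, site selection,
feasibility-gated probe poses and slice scans, fixture measurements, and
export — logging every stage and skip reason along the way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from phytoprobe import chamber, geometry, measurements, planner, scene, segmentation

__all__ = [
    "PointCloud",
    "WorkflowConfig",
    "read_cloud",
    "write_cloud",
    "run_acquisition",
    "CloudFormatError",
]


class CloudFormatError(ValueError):
    """Malformed cloud file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class PointCloud:
    """3D points with optional integer labels and segment ids."""

    points: np.ndarray
    labels: np.ndarray | None = None
    segments: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        for attr in ("labels", "segments"):
            val = getattr(self, attr)
            if val is not None:
                val = np.asarray(val, dtype=int)
                if len(val) != len(self.points):
                    raise CloudFormatError(
                        f"{attr} length {len(val)} != point count "
                        f"{len(self.points)}")
                setattr(self, attr, val)

    def __len__(self) -> int:
        return len(self.points)


# --------------------------------------------------------------------------
# PLY
# --------------------------------------------------------------------------

_FLOAT_TYPES = {"float", "float32", "float64", "double"}
_INT_TYPES = {"char", "uchar", "short", "ushort", "int", "uint",
              "int8", "uint8", "int16", "uint16", "int32", "uint32"}


def write_cloud(cloud, path) -> Path:
    """Write a cloud to ASCII PLY with 6-significant-digit coordinates."""
    path = Path(path)
    pts = np.asarray(getattr(cloud, "points", cloud), dtype=float).reshape(-1, 3)
    labels = getattr(cloud, "labels", None)
    segments = getattr(cloud, "segments", None)
    header = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(pts)}",
        "property float x",
        "property float y",
        "property float z",
    ]
    if labels is not None:
        header.append("property int label")
    if segments is not None:
        header.append("property int segment")
    header.append("end_header")
    lines = header[:]
    for i, p in enumerate(pts):
        row = [np.format_float_positional(v, precision=6, unique=False,
                                          fractional=False) for v in p]
        if labels is not None:
            row.append(str(int(labels[i])))
        if segments is not None:
            row.append(str(int(segments[i])))
        lines.append(" ".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_cloud(path) -> PointCloud:
    """Read an ASCII PLY or PCD point cloud.

    Recognizes per-vertex integer ``label`` and ``segment`` properties in
    PLY.  Malformed headers and truncated bodies raise
    :class:`CloudFormatError` with the offending line number.
    """
    path = Path(path)
    text = path.read_text()
    first = text.lstrip().splitlines()[0].strip() if text.strip() else ""
    if first == "ply":
        return _read_ply(text)
    if path.suffix.lower() == ".pcd" or first.startswith("#") or \
            first.upper().startswith("VERSION"):
        return _read_pcd(text)
    raise CloudFormatError("unrecognized cloud format", line=1)


def _read_ply(text: str) -> PointCloud:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise CloudFormatError("missing 'ply' magic", line=1)
    n_vertex = None
    props: list[tuple[str, str]] = []
    body_start = None
    in_vertex_element = False
    for i, raw in enumerate(lines[1:], start=2):
        tok = raw.strip().split()
        if not tok:
            continue
        if tok[0] == "format":
            if len(tok) < 2 or tok[1] != "ascii":
                raise CloudFormatError("only ASCII PLY is supported", line=i)
        elif tok[0] == "element":
            if len(tok) != 3:
                raise CloudFormatError("malformed element declaration", line=i)
            in_vertex_element = tok[1] == "vertex"
            if in_vertex_element:
                try:
                    n_vertex = int(tok[2])
                except ValueError:
                    raise CloudFormatError("vertex count not an integer",
                                           line=i) from None
        elif tok[0] == "property" and in_vertex_element:
            if len(tok) != 3:
                raise CloudFormatError("malformed property declaration", line=i)
            props.append((tok[1], tok[2]))
        elif tok[0] == "end_header":
            body_start = i
            break
    if body_start is None:
        raise CloudFormatError("missing end_header", line=len(lines))
    if n_vertex is None:
        raise CloudFormatError("missing vertex element", line=body_start)
    names = [name for _, name in props]
    for axis in ("x", "y", "z"):
        if axis not in names:
            raise CloudFormatError(f"missing vertex property {axis!r}",
                                   line=body_start)

    body = [ln for ln in lines[body_start:] if ln.strip()]
    if len(body) < n_vertex:
        raise CloudFormatError(
            f"truncated body: expected {n_vertex} vertices, found {len(body)}",
            line=body_start + len(body) + 1)
    data = np.empty((n_vertex, len(props)))
    for j, ln in enumerate(body[:n_vertex]):
        vals = ln.split()
        if len(vals) != len(props):
            raise CloudFormatError(
                f"expected {len(props)} values, found {len(vals)}",
                line=body_start + j + 1)
        try:
            data[j] = [float(v) for v in vals]
        except ValueError:
            raise CloudFormatError("non-numeric vertex value",
                                   line=body_start + j + 1) from None
    cols = {name: data[:, k] for k, (_, name) in enumerate(props)}
    return PointCloud(
        points=np.column_stack([cols["x"], cols["y"], cols["z"]]),
        labels=cols["label"].astype(int) if "label" in cols else None,
        segments=cols["segment"].astype(int) if "segment" in cols else None,
    )


def _read_pcd(text: str) -> PointCloud:
    lines = text.splitlines()
    fields: list[str] = []
    n_points = None
    data_start = None
    for i, raw in enumerate(lines, start=1):
        tok = raw.strip().split()
        if not tok or tok[0].startswith("#"):
            continue
        key = tok[0].upper()
        if key == "FIELDS":
            fields = [t.lower() for t in tok[1:]]
        elif key == "POINTS":
            try:
                n_points = int(tok[1])
            except (IndexError, ValueError):
                raise CloudFormatError("malformed POINTS line", line=i) from None
        elif key == "DATA":
            if len(tok) < 2 or tok[1] != "ascii":
                raise CloudFormatError("only DATA ascii is supported", line=i)
            data_start = i
            break
    if data_start is None:
        raise CloudFormatError("missing DATA line", line=len(lines))
    if n_points is None:
        raise CloudFormatError("missing POINTS line", line=data_start)
    for axis in ("x", "y", "z"):
        if axis not in fields:
            raise CloudFormatError(f"missing field {axis!r}", line=data_start)
    body = [ln for ln in lines[data_start:] if ln.strip()]
    if len(body) < n_points:
        raise CloudFormatError(
            f"truncated body: expected {n_points} points, found {len(body)}",
            line=data_start + len(body) + 1)
    data = np.empty((n_points, len(fields)))
    for j, ln in enumerate(body[:n_points]):
        vals = ln.split()
        if len(vals) != len(fields):
            raise CloudFormatError(
                f"expected {len(fields)} values, found {len(vals)}",
                line=data_start + j + 1)
        try:
            data[j] = [float(v) for v in vals]
        except ValueError:
            raise CloudFormatError("non-numeric value",
                                   line=data_start + j + 1) from None
    cols = {name: data[:, k] for k, name in enumerate(fields)}
    return PointCloud(
        points=np.column_stack([cols["x"], cols["y"], cols["z"]]),
        labels=cols["label"].astype(int) if "label" in cols else None,
    )


# --------------------------------------------------------------------------
# Workflow configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class WorkflowConfig:
    """All tunable constants of the acquisition workflow."""

    coarse_sensor: str = "tof_coarse"
    fine_sensor: str = "profilometer_fine"
    theta_smooth_deg: float = 10.0
    c_max: float = 0.05
    min_size: int = 100
    k: int = 10
    n_sites: int = 4
    standoff_mm: float = planner.DEFAULT_STANDOFF_MM
    incidence_deg: float = planner.DEFAULT_INCIDENCE_DEG
    slice_width_mm: float = planner.DEFAULT_SLICE_WIDTH_MM
    scan_distance_m: float = planner.DEFAULT_SCAN_DISTANCE_M
    footprint_m: float = planner.DEFAULT_FOOTPRINT_M
    reach_radius_m: float = planner.DEFAULT_REACH_RADIUS_M
    clearance_mm: float = planner.DEFAULT_CLEARANCE_MM
    band_count: int = scene.DEFAULT_BAND_COUNT
    band_range: tuple[float, float] = scene.DEFAULT_BAND_RANGE
    red_edge_window: tuple[float, float] = measurements.DEFAULT_RED_EDGE_WINDOW
    seed: int = 0

    @staticmethod
    def from_file(path) -> "WorkflowConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        for key in ("band_range", "red_edge_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return WorkflowConfig(**raw)

    def to_file(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self)))
        return path

    def segmentation_params(self) -> segmentation.SegmentationParams:
        return segmentation.SegmentationParams(
            theta_smooth_deg=self.theta_smooth_deg,
            c_max=self.c_max,
            min_size=self.min_size,
            k=self.k,
        )


# --------------------------------------------------------------------------
# Acquisition pipeline
# --------------------------------------------------------------------------

@dataclass
class PlantAcquisition:
    pot_id: int
    height_m: float = 0.0
    topview: scene.Pose | None = None
    fine_cloud: scene.LabeledCloud | None = None
    seg: segmentation.Segmentation | None = None
    sites: list = field(default_factory=list)
    probe_poses: list = field(default_factory=list)
    verdicts: list = field(default_factory=list)
    slice_plans: list = field(default_factory=list)
    readings: list = field(default_factory=list)


@dataclass
class AcquisitionBundle:
    plants: dict
    log: list
    spectral: measurements.SpectralCube | None = None
    thermal: measurements.ThermalImage | None = None

    def feasible_sites(self, pot_id: int) -> list:
        plant = self.plants[pot_id]
        return [s for s, v in zip(plant.sites, plant.verdicts) if v.feasible]


def run_acquisition(
    chamber_scene: scene.ChamberScene,
    config: WorkflowConfig | None = None,
    out_dir=None,
) -> AcquisitionBundle:
    """Execute the per-plant acquisition sequence over a chamber scene.

    Stage failures are logged per plant with machine-readable reasons and
    the pipeline continues to the next plant.  Deterministic for fixed
    (scene, config).
    """
    config = config or WorkflowConfig()
    coarse = scene.SENSOR_PRESETS[config.coarse_sensor]
    fine = scene.SENSOR_PRESETS[config.fine_sensor]
    ws_template = planner.WorkspaceModel(
        arm_base=chamber_scene.arm_base,
        reach_radius_m=config.reach_radius_m,
        probe_clearance_radius_mm=config.clearance_mm,
    )
    log: list[dict] = []
    plants: dict[int, PlantAcquisition] = {}
    seeds = np.random.SeedSequence(config.seed).spawn(len(chamber_scene.pots))

    cube, thermal, masks = scene.render_fixtures(
        chamber_scene, band_count=config.band_count,
        band_range=config.band_range)

    site_counter = 0
    for pot, seed_seq in zip(chamber_scene.pots, seeds):
        acq = PlantAcquisition(pot_id=pot.pot_id)
        plants[pot.pot_id] = acq
        plant_seed = int(seed_seq.generate_state(1)[0])
        px, py = pot.position

        def note(stage: str, status: str, **info) -> None:
            log.append({"plant": pot.pot_id, "stage": stage,
                        "status": status, **info})

        # 1. coarse cloud from a prior-height overhead viewpoint
        prior_h = pot.plant.stem_height_m + 0.5
        coarse_view = scene.Pose(position=(px, py, prior_h + 1.0),
                                 look_at=(px, py, 0.0))
        ccloud = scene.sample_cloud(chamber_scene, coarse, coarse_view,
                                    seed=plant_seed)
        near = ccloud.points[
            np.hypot(ccloud.points[:, 0] - px, ccloud.points[:, 1] - py) < 0.3]
        if len(near) == 0:
            note("height_estimate", "skipped", reason="empty_coarse_cloud")
            continue
        # 99th percentile of z: robust to noise spikes
        acq.height_m = float(np.percentile(near[:, 2], 99))
        note("height_estimate", "ok", height_m=acq.height_m)

        # 2. top-view camera positioning
        acq.topview = planner.plan_topview_pose(
            acq.height_m,
            camera_fov_deg=(coarse.fov_h_deg, coarse.fov_v_deg),
            footprint_side_m=config.footprint_m,
            plant_xy=(px, py),
        )
        note("topview_pose", "ok",
             standoff_m=acq.topview.position[2] - acq.height_m)

        # 3. fine cloud from the top-view pose
        fine_view = scene.Pose(
            position=(px, py, acq.height_m + config.scan_distance_m),
            look_at=(px, py, acq.height_m))
        acq.fine_cloud = scene.sample_cloud(chamber_scene, fine, fine_view,
                                            seed=plant_seed + 1)
        if len(acq.fine_cloud) < config.k:
            note("fine_cloud", "skipped", reason="too_few_points",
                 n=len(acq.fine_cloud))
            continue
        note("fine_cloud", "ok", n=len(acq.fine_cloud))

        # 4. segmentation
        fld = geometry.estimate_normals_curvature(
            acq.fine_cloud.points, k=config.k,
            view_origin=fine_view.position)
        acq.seg = segmentation.region_grow(
            acq.fine_cloud.points, fld, config.segmentation_params())
        if not acq.seg.segments:
            note("segmentation", "skipped", reason="no_segments")
            continue
        note("segmentation", "ok", n_segments=len(acq.seg.segments))

        # 5. site selection + feasibility-gated probing
        acq.sites = planner.select_probe_sites(
            acq.seg, acq.fine_cloud.points, fld, config.n_sites)
        if not acq.sites:
            note("site_selection", "skipped", reason="no_sites")
            continue
        note("site_selection", "ok", n_sites=len(acq.sites))
        rng = np.random.default_rng(plant_seed + 2)
        for site in acq.sites:
            pose = planner.compute_probe_pose(
                site.point, site.normal,
                standoff_mm=config.standoff_mm,
                incidence_deg=config.incidence_deg)
            acq.probe_poses.append(pose)
            seg_idx = acq.seg.segments[site.segment_id - 1]
            verdict = planner.check_feasible(
                pose, acq.fine_cloud.points, ws_template,
                exclude_indices=seg_idx)
            acq.verdicts.append(verdict)
            if not verdict.feasible:
                note("probe", "skipped", reason=verdict.reason,
                     site=[float(v) for v in site.point])
                continue
            f_m_prime = float(rng.uniform(0.7, 0.9))
            f = float(rng.uniform(0.2, 0.6)) * f_m_prime
            site_counter += 1
            acq.readings.append(measurements.FluorometerReading(
                F=f, F_M_prime=f_m_prime,
                site=tuple(float(v) for v in site.point),
                site_index=site_counter))
            note("probe", "ok", site_index=site_counter)

        # 6. slice plans for probed segments
        for sid in sorted({s.segment_id for s in acq.sites}):
            seg_pts = acq.fine_cloud.points[acq.seg.segments[sid - 1]]
            try:
                plan = planner.slice_leaf(seg_pts, config.slice_width_mm)
                plan = planner.plan_line_scan_poses(plan, config.scan_distance_m)
                acq.slice_plans.append((sid, plan))
                note("slice_plan", "ok", segment=sid, n_slices=plan.n_slices)
            except planner.PlanningError as exc:
                note("slice_plan", "skipped", segment=sid, reason=str(exc))

    bundle = AcquisitionBundle(plants=plants, log=log,
                               spectral=cube, thermal=thermal)
    if out_dir is not None:
        _export_bundle(bundle, Path(out_dir))
    return bundle


def _export_bundle(bundle: AcquisitionBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    readings = [r for acq in bundle.plants.values() for r in acq.readings]
    if readings:
        measurements.export_records(readings, out_dir / "yii.csv", "csv")
        measurements.export_records(readings, out_dir / "yii.json", "json")
    (out_dir / "acquisition_log.json").write_text(
        json.dumps(bundle.log, indent=1, default=str))
    for pid, acq in bundle.plants.items():
        if acq.fine_cloud is not None and acq.seg is not None:
            cloud = PointCloud(
                points=acq.fine_cloud.points,
                labels=acq.fine_cloud.labels,
                segments=acq.seg.labels(len(acq.fine_cloud)),
            )
            write_cloud(cloud, out_dir / f"plant{pid}_fine.ply")
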