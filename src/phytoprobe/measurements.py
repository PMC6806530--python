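"""Sensor measurement math and region-sampling semantics.

Effective PSII quantum yield from fluorescence pairs, white/dark
reflectance calibration, circle/line region sampling on spectral cubes
and thermal images, red-edge first-derivative features, and record
export to CSV/JSON/PNG.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FluorometerReading",
    "SpectralCube",
    "ThermalImage",
    "RegionShape",
    "compute_yii",
    "calibrate_reflectance",
    "sample_region_spectrum",
    "red_edge_derivative",
    "sample_region_temperature",
    "export_records",
    "DEFAULT_RED_EDGE_WINDOW",
]

#: Red-edge search window (nm): the steep reflectance rise tracking
#: chlorophyll sits around 700-720 nm.
DEFAULT_RED_EDGE_WINDOW = (680.0, 740.0)


class MeasurementError(ValueError):
    pass


@dataclass(frozen=True)
class FluorometerReading:
    """One fluorometer measurement at a probed site."""

    F: float
    F_M_prime: float
    site: tuple[float, float, float]
    site_index: int
    YII: float = field(init=False)
    saturated_ok: bool = field(init=False)

    def __post_init__(self) -> None:
        yii = compute_yii(self.F, self.F_M_prime)
        object.__setattr__(self, "YII", yii)
        object.__setattr__(self, "saturated_ok", self.F <= self.F_M_prime)


@dataclass(frozen=True)
class SpectralCube:
    """H x W x B reflectance cube on a strictly increasing band grid (nm)."""

    bands: np.ndarray
    data: np.ndarray

    def __post_init__(self) -> None:
        bands = np.asarray(self.bands, dtype=float)
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or data.shape[2] != len(bands):
            raise MeasurementError(
                f"cube shape {data.shape} inconsistent with {len(bands)} bands"
            )
        if len(bands) > 1 and not np.all(np.diff(bands) > 0):
            raise MeasurementError("band wavelengths must be strictly increasing")
        object.__setattr__(self, "bands", bands)
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class ThermalImage:
    """H x W image of temperatures in degC."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise MeasurementError("thermal image must be 2-D")
        object.__setattr__(self, "data", data)


@dataclass(frozen=True)
class RegionShape:
    """Circle or thick line drawn on an image, in pixel coordinates.

    Membership is by pixel center: pixel (row, col) belongs to the shape
    iff its integer center lies inside (no partial pixels).
    """

    kind: str                           # "circle" | "line"
    center: tuple[float, float] | None = None      # (row, col)
    radius: float | None = None
    endpoints: tuple[tuple[float, float], tuple[float, float]] | None = None
    thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.kind == "circle":
            if self.center is None or self.radius is None:
                raise MeasurementError("circle needs center and radius")
            if self.radius <= 0:
                raise MeasurementError("circle radius must be > 0")
        elif self.kind == "line":
            if self.endpoints is None:
                raise MeasurementError("line needs two endpoints")
            a, b = self.endpoints
            if tuple(a) == tuple(b):
                raise MeasurementError("line endpoints must be distinct")
            if self.thickness <= 0:
                raise MeasurementError("line thickness must be > 0")
        else:
            raise MeasurementError(f"unknown region kind {self.kind!r}")

    def mask(self, shape_hw: tuple[int, int]) -> np.ndarray:
        h, w = shape_hw
        rr, cc = np.mgrid[0:h, 0:w]
        if self.kind == "circle":
            r0, c0 = self.center
            return (rr - r0) ** 2 + (cc - c0) ** 2 <= self.radius ** 2
        (r1, c1), (r2, c2) = self.endpoints
        a = np.array([r1, c1], dtype=float)
        d = np.array([r2 - r1, c2 - c1], dtype=float)
        length2 = d @ d
        pr = rr - a[0]
        pc = cc - a[1]
        t = np.clip((pr * d[0] + pc * d[1]) / length2, 0.0, 1.0)
        dist2 = (pr - t * d[0]) ** 2 + (pc - t * d[1]) ** 2
        return dist2 <= (self.thickness / 2.0) ** 2


# --------------------------------------------------------------------------
# Fluorometry
# --------------------------------------------------------------------------

def compute_yii(F: float, F_M_prime: float) -> float:
    """Effective PSII quantum yield ``(F'_M - F) / F'_M``.

    ``F`` is the momentary fluorescence of the illuminated sample shortly
    before the saturation pulse; ``F'_M`` the pulse-maximal level.  An
    ``F`` exceeding ``F'_M`` is physically suspect: a warning is emitted
    and the (negative) value still returned.
    """
    if F_M_prime <= 0:
        raise MeasurementError("F_M_prime must be > 0")
    if F < 0:
        raise MeasurementError("F must be >= 0")
    if F > F_M_prime:
        warnings.warn(
            f"F={F} exceeds F_M_prime={F_M_prime}: YII will be negative",
            stacklevel=2,
        )
    return (F_M_prime - F) / F_M_prime


# --------------------------------------------------------------------------
# Reflectance calibration and region sampling
# --------------------------------------------------------------------------

def calibrate_reflectance(
    raw: np.ndarray,
    white: np.ndarray,
    dark: np.ndarray,
    bands: np.ndarray | None = None,
) -> SpectralCube:
    """White/dark reference calibration: ``(raw - dark) / (white - dark)``.

    ``white`` and ``dark`` are per-band reference vectors (or scalars,
    broadcast over bands).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3:
        raise MeasurementError("raw cube must be H x W x B")
    nb = raw.shape[2]
    white = np.broadcast_to(np.asarray(white, dtype=float), (nb,)).copy()
    dark = np.broadcast_to(np.asarray(dark, dtype=float), (nb,)).copy()
    denom = white - dark
    bad = np.flatnonzero(denom <= 0)
    if len(bad):
        raise MeasurementError(
            f"white reference does not exceed dark in band(s) {bad.tolist()}"
        )
    if bands is None:
        bands = np.arange(nb, dtype=float)
    return SpectralCube(bands=np.asarray(bands, dtype=float),
                        data=(raw - dark) / denom)


def sample_region_spectrum(
    cube: SpectralCube, shape: RegionShape
) -> tuple[np.ndarray, int]:
    """Unweighted mean spectrum over pixels inside a drawn region.

    Returns ``(mean spectrum of length B, pixel count)``; an empty
    intersection with the image is an error.
    """
    mask = shape.mask(cube.data.shape[:2])
    n = int(mask.sum())
    if n == 0:
        raise MeasurementError("region does not intersect the image")
    return cube.data[mask].mean(axis=0), n


def sample_region_temperature(
    img: ThermalImage, shape: RegionShape
) -> tuple[float, int]:
    """Mean temperature (degC) over pixels inside a drawn region."""
    mask = shape.mask(img.data.shape)
    n = int(mask.sum())
    if n == 0:
        raise MeasurementError("region does not intersect the image")
    return float(img.data[mask].mean()), n


# --------------------------------------------------------------------------
# Red edge
# --------------------------------------------------------------------------

def red_edge_derivative(
    bands: np.ndarray,
    spectrum: np.ndarray,
    window: tuple[float, float] = DEFAULT_RED_EDGE_WINDOW,
) -> tuple[float, float]:
    """Red-edge wavelength and peak first derivative of a spectrum.

    The first derivative is computed by central finite differences on the
    band grid (one-sided at the grid edges); the result is the wavelength
    of the maximum derivative within ``window`` and that maximum value
    (per nm).  Ties resolve to the lowest wavelength.
    """
    bands = np.asarray(bands, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    if len(bands) != len(spectrum):
        raise MeasurementError("bands and spectrum length mismatch")
    lo, hi = window
    if lo < bands[0] or hi > bands[-1]:
        raise MeasurementError(
            f"window {window} outside band range ({bands[0]}, {bands[-1]})"
        )
    inside = (bands >= lo) & (bands <= hi)
    if inside.sum() < 3:
        raise MeasurementError("need at least 3 bands inside the window")
    deriv = np.gradient(spectrum, bands)
    dwin = deriv[inside]
    bwin = bands[inside]
    i = int(np.argmax(dwin))          # first max -> lowest wavelength on ties
    return float(bwin[i]), float(dwin[i])


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------

_YII_COLUMNS = ["site_index", "x", "y", "z", "YII"]


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(np.format_float_positional(
        x, precision=sig, unique=False, fractional=False))


def readings_frame(readings: Sequence[FluorometerReading]) -> pd.DataFrame:
    rows = [
        {
            "site_index": r.site_index,
            "x": _round_sig(r.site[0]),
            "y": _round_sig(r.site[1]),
            "z": _round_sig(r.site[2]),
            "YII": _round_sig(r.YII),
        }
        for r in readings
    ]
    return pd.DataFrame(rows, columns=_YII_COLUMNS)


def export_records(
    records,
    path,
    format: str = "csv",
    image: np.ndarray | None = None,
    shapes: Sequence[RegionShape] = (),
) -> Path:
    """Export measurement records to CSV, JSON, or an annotated PNG.

    ``records`` is a sequence of :class:`FluorometerReading` or of plain
    dicts.  CSV/JSON round-trip losslessly at 6 significant digits.  PNG
    renders ``image`` with numbered site markers and region overlays.
    """
    path = Path(path)
    if not len(records) and format != "png":
        raise MeasurementError("no records to export")
    if format == "csv":
        _to_frame(records).to_csv(path, index=False)
    elif format == "json":
        payload = {
            "schema_version": 1,
            "records": _to_frame(records).to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
    elif format == "png":
        if image is None:
            raise MeasurementError("png export needs an image")
        _render_png(image, records, shapes, path)
    else:
        raise MeasurementError(f"unknown export format {format!r}")
    return path


def _to_frame(records) -> pd.DataFrame:
    if len(records) and isinstance(records[0], FluorometerReading):
        return readings_frame(records)
    df = pd.DataFrame(list(records))
    return df.map(lambda v: _round_sig(v) if isinstance(v, float) else v)


def import_records(path) -> pd.DataFrame:
    """Re-import a CSV or JSON export produced by :func:`export_records`."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return pd.DataFrame(payload["records"])
    return pd.read_csv(path)


def _render_png(image, records, shapes, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.asarray(image), cmap="viridis")
    for rec in records:
        if isinstance(rec, FluorometerReading):
            r, c = rec.site[1], rec.site[0]
            ax.plot(c, r, "wo", ms=8, mec="k")
            ax.annotate(str(rec.site_index), (c, r), color="white",
                        xytext=(4, 4), textcoords="offset points")
    for shp in shapes:
        if shp.kind == "circle":
            circ = plt.Circle((shp.center[1], shp.center[0]), shp.radius,
                              fill=False, color="white")
            ax.add_patch(circ)
        else:
            (r1, c1), (r2, c2) = shp.endpoints
            ax.plot([c1, c2], [r1, r2], "w-", lw=shp.thickness)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
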