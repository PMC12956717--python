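"""Airway branch: per-cross-section lumen/wall measurement and Pi10.

The wall-measurement operator is full-width-half-maximum (FWHM) ray casting:
from a point inside the lumen, rays are cast in the plane normal to the local
centerline direction; along each ray the inner wall edge is placed at the
half-rise between the lumen HU and the peak wall HU, and the outer edge at
the half-fall between the peak and the parenchymal plateau beyond it.  Radii
are averaged over rays and areas follow the circular model
``LA = π r_l²``, ``WA = π (r_o² − r_l²)``, ``Pi = 2π r_l``.

Pi10 — the standardized airway-remodeling summary — is the predicted √WA at
an internal perimeter of 10 mm, from an ordinary-least-squares fit of √WA on
Pi across measured airways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .core import CTVolume, LabelMask

__all__ = [
    "AirwayMeasurement",
    "AirwayMeasurementError",
    "RayCastConfig",
    "Pi10Result",
    "measure_cross_section",
    "measure_tube_from_masks",
    "measurement_from_radii",
    "pi10_regression",
]


class AirwayMeasurementError(ValueError):
    """A cross-section could not be measured; carries the reason."""


@dataclass
class AirwayMeasurement:
    """Geometry of one airway cross-section under the circular model (mm/mm²)."""

    lumen_radius: float
    outer_radius: float
    lumen_diameter: float
    wall_thickness: float
    lumen_area: float          # LA
    wall_area: float           # WA
    internal_perimeter: float  # Pi
    wa_percent: float          # 100·WA/(WA+LA)
    wa_la_ratio: float         # WA/LA


def measurement_from_radii(lumen_radius: float, outer_radius: float) -> AirwayMeasurement:
    """Build a measurement from lumen and outer wall radii (mm)."""
    if not 0 < lumen_radius < outer_radius:
        raise AirwayMeasurementError(
            f"need 0 < lumen radius < outer radius, got {lumen_radius}, {outer_radius}")
    la = math.pi * lumen_radius ** 2
    wa = math.pi * (outer_radius ** 2 - lumen_radius ** 2)
    return AirwayMeasurement(
        lumen_radius=lumen_radius,
        outer_radius=outer_radius,
        lumen_diameter=2 * lumen_radius,
        wall_thickness=outer_radius - lumen_radius,
        lumen_area=la,
        wall_area=wa,
        internal_perimeter=2 * math.pi * lumen_radius,
        wa_percent=100.0 * wa / (wa + la),
        wa_la_ratio=wa / la,
    )


@dataclass
class RayCastConfig:
    """FWHM ray-casting parameters.

    ``n_rays`` equiangular rays, sampled every ``step_mm`` out to
    ``max_radius_mm``, with trilinear interpolation of HU along each ray.
    A ray fails when no wall peak at least ``min_contrast_hu`` above the
    lumen HU is found, or the profile never falls back to the half level;
    the measurement is rejected when more than ``max_failed_fraction`` of
    rays fail.
    """

    n_rays: int = 64
    step_mm: float = 0.1
    max_radius_mm: float = 10.0
    min_contrast_hu: float = 100.0
    max_failed_fraction: float = 0.25


def _plane_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise AirwayMeasurementError("axis direction must be non-zero")
    axis = axis / norm
    helper = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def _half_crossing(radii: np.ndarray, profile: np.ndarray, level: float,
                   start: int, stop: int, rising: bool) -> float | None:
    """Linear-interpolated radius where the profile crosses ``level``."""
    for i in range(start, stop):
        a, b = profile[i], profile[i + 1]
        if (rising and a < level <= b) or (not rising and a > level >= b):
            t = (level - a) / (b - a) if b != a else 0.0
            return float(radii[i] + t * (radii[i + 1] - radii[i]))
    return None


def measure_cross_section(volume: CTVolume, center: Sequence[float],
                          axis: Sequence[float],
                          cfg: RayCastConfig | None = None) -> AirwayMeasurement:
    """Measure one airway cross-section by FWHM ray casting.

    Parameters
    ----------
    center : (z, y, x) voxel coordinates (float) of a point inside the lumen.
    axis : (z, y, x) direction of the local centerline (need not be unit).
    """
    cfg = cfg or RayCastConfig()
    center = np.asarray(center, dtype=float)
    spacing = np.asarray(volume.spacing, dtype=float)
    u, v = _plane_basis(np.asarray(axis, dtype=float) * spacing)  # physical-space plane

    radii = np.arange(0.0, cfg.max_radius_mm + cfg.step_mm, cfg.step_mm)
    center_mm = center * spacing

    inner, outer = [], []
    n_failed = 0
    for k in range(cfg.n_rays):
        theta = 2 * math.pi * k / cfg.n_rays
        direction = math.cos(theta) * u + math.sin(theta) * v  # unit, mm
        pts_mm = center_mm[None, :] + radii[:, None] * direction[None, :]
        coords = (pts_mm / spacing).T  # voxel coordinates for map_coordinates
        profile = ndimage.map_coordinates(volume.data.astype(np.float64), coords,
                                          order=1, mode="nearest")
        lumen_hu = profile[0]
        peak_idx = int(np.argmax(profile))
        peak_hu = profile[peak_idx]
        if peak_idx == 0 or peak_hu - lumen_hu < cfg.min_contrast_hu:
            n_failed += 1
            continue
        half_rise = 0.5 * (lumen_hu + peak_hu)
        r_in = _half_crossing(radii, profile, half_rise, 0, peak_idx, rising=True)
        # Parenchymal plateau: the far end of the profile beyond the peak.
        tail = profile[peak_idx:]
        parenchyma_hu = float(np.min(tail)) if tail.size > 1 else lumen_hu
        half_fall = 0.5 * (peak_hu + parenchyma_hu)
        r_out = _half_crossing(radii, profile, half_fall, peak_idx,
                               len(profile) - 1, rising=False)
        if r_in is None or r_out is None or not r_in < r_out:
            n_failed += 1
            continue
        inner.append(r_in)
        outer.append(r_out)

    if n_failed > cfg.max_failed_fraction * cfg.n_rays or not inner:
        raise AirwayMeasurementError(
            f"measurement rejected: {n_failed}/{cfg.n_rays} rays found no wall "
            "(center outside a closed lumen, or insufficient wall contrast)")
    return measurement_from_radii(float(np.mean(inner)), float(np.mean(outer)))


def measure_tube_from_masks(lumen: LabelMask, wall: LabelMask,
                            axis: int = 0) -> AirwayMeasurement:
    """Mask-based measurement of an axis-aligned airway segment.

    Cross-sectional areas are mean per-slice voxel counts (along ``axis``,
    default z) times the in-plane pixel area; radii follow from the circular
    model ``r = sqrt(A/π)``.  This is the voxel-counting oracle against which
    the FWHM HU-based path is validated.
    """
    if lumen.shape != wall.shape:
        raise ValueError("lumen and wall masks must share a shape")
    lum = lumen.binary()
    wal = wall.binary()
    if not lum.any():
        raise AirwayMeasurementError("empty lumen mask")
    sum_axes = tuple(i for i in range(3) if i != axis)
    per_slice_lumen = lum.sum(axis=sum_axes)
    per_slice_wall = wal.sum(axis=sum_axes)
    occupied = per_slice_lumen > 0
    in_plane = [s for i, s in enumerate(lumen.spacing) if i != axis]
    pixel_area = float(in_plane[0] * in_plane[1])
    la = float(per_slice_lumen[occupied].mean()) * pixel_area
    wa = float(per_slice_wall[occupied].mean()) * pixel_area
    r_l = math.sqrt(la / math.pi)
    r_o = math.sqrt((la + wa) / math.pi)
    m = measurement_from_radii(r_l, r_o)
    # keep the exact voxel-count areas rather than the circular re-derivation
    m.lumen_area = la
    m.wall_area = wa
    m.wa_percent = 100.0 * wa / (wa + la)
    m.wa_la_ratio = wa / la
    return m


@dataclass
class Pi10Result:
    pi10: float
    slope: float
    intercept: float
    n_airways: int
    r_squared: float


def pi10_regression(measurements: Iterable[AirwayMeasurement],
                    at_perimeter: float = 10.0) -> Pi10Result:
    """OLS of √WA on internal perimeter; Pi10 = fitted √WA at Pi = 10 mm.

    Requires at least two measurements with distinct perimeters; a degenerate
    (all-equal-Pi) set raises instead of returning NaN.
    """
    ms = list(measurements)
    if len(ms) < 2:
        raise ValueError(f"insufficient airways for Pi10 regression: {len(ms)} < 2")
    pi = np.array([m.internal_perimeter for m in ms], dtype=float)
    sqrt_wa = np.array([math.sqrt(m.wall_area) for m in ms], dtype=float)
    if np.ptp(pi) == 0:
        raise ValueError("degenerate Pi10 fit: all internal perimeters identical")
    slope, intercept = np.polyfit(pi, sqrt_wa, 1)
    fitted = intercept + slope * pi
    ss_res = float(np.sum((sqrt_wa - fitted) ** 2))
    ss_tot = float(np.sum((sqrt_wa - sqrt_wa.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return Pi10Result(
        pi10=float(intercept + slope * at_perimeter),
        slope=float(slope),
        intercept=float(intercept),
        n_airways=len(ms),
        r_squared=r2,
    )
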