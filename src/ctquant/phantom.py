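"""Seeded synthetic thorax phantom with analytically known ground truth.

The phantom emulates the content of an inspiratory chest CT at the level a
quantification toolkit needs: aerated lung (≈ −850 HU) with low-attenuation
emphysema pockets (≈ −980 HU) occupying a target fraction of the lung,
soft-tissue background (≈ 40 HU), tubular airways with distinct lumen and
wall densities, a set of vessel cylinders (optionally a recursive branching
tree) of known radii, a two-phase left-ventricular blood pool with a
myocardial shell, and calcified plaques (≥ 130 HU) of known area and peak
density.  Optional Gaussian noise is seeded.

Ground-truth metric values are defined on the *voxelized* geometry — voxel
counts, not the continuous solids — so mask-based recovery can be asserted
exactly.  Airway walls are painted with a one-voxel linear partial-volume
ramp at both boundaries (a crude point-spread-function stand-in) so that
half-maximum edge localization recovers the true radii; the lung truth mask
excludes a one-voxel margin around every airway and the vessel and cardiac
voxels, keeping the lung HU distribution an exact two-point mixture.

Generation is pure: (spec, seed) fully determines the output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import CTVolume, LabelMask

__all__ = [
    "AirwaySpec",
    "VesselCylinder",
    "LVSpec",
    "PlaqueSpec",
    "LungSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "degrade",
    "default_spec",
    "branching_vessel_tree",
]


class StructureFitError(ValueError):
    """A requested structure does not fit inside the phantom grid."""


@dataclass
class LungSpec:
    """One lung as an axis-aligned ellipsoid (voxel center, voxel semi-axes)."""
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]


@dataclass
class AirwaySpec:
    """A straight airway tube: lumen cylinder plus concentric wall annulus."""
    center: tuple[float, float, float]       # (z, y, x) voxels
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    length_mm: float = 40.0
    lumen_radius_mm: float = 2.0
    wall_thickness_mm: float = 1.0
    wall_hu: float = 0.0
    lumen_hu: float = -1000.0


@dataclass
class VesselCylinder:
    center: tuple[float, float, float]
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    length_mm: float = 40.0
    radius_mm: float = 1.0
    hu: float = 150.0


@dataclass
class LVSpec:
    """Two-phase left ventricle: concentric spherical blood pools + shell."""
    center: tuple[float, float, float]
    edv_target_ml: float = 120.0
    esv_target_ml: float = 48.0
    myo_thickness_mm: float = 6.0
    blood_hu: float = 45.0
    myo_hu: float = 55.0


@dataclass
class PlaqueSpec:
    """A calcified lesion painted on one axial slice."""
    slice_index: int
    center_yx: tuple[int, int]
    area_mm2: float = 4.0
    peak_hu: float = 250.0


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (104, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lung_hu: float = -850.0
    emphysema_hu: float = -980.0
    emphysema_fraction: float = 0.25
    soft_tissue_hu: float = 40.0
    lungs: list[LungSpec] = field(default_factory=list)
    airways: list[AirwaySpec] = field(default_factory=list)
    vessels: list[VesselCylinder] = field(default_factory=list)
    lv: LVSpec | None = None
    plaques: list[PlaqueSpec] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.emphysema_fraction <= 1:
            raise ValueError("emphysema_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.emphysema_hu >= self.lung_hu:
            raise ValueError("emphysema must be lower attenuation than lung")
        for a in self.airways:
            if a.lumen_radius_mm <= 0 or a.wall_thickness_mm <= 0:
                raise ValueError("airway radii/thicknesses must be > 0")
        for v in self.vessels:
            if v.radius_mm <= 0:
                raise ValueError("vessel radii must be > 0")
        if self.lv is not None and not self.lv.esv_target_ml < self.lv.edv_target_ml:
            raise ValueError("esv_target must be < edv_target")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["lungs"] = [LungSpec(**x) for x in d.get("lungs", [])]
        d["airways"] = [AirwaySpec(**x) for x in d.get("airways", [])]
        d["vessels"] = [VesselCylinder(**x) for x in d.get("vessels", [])]
        if d.get("lv") is not None:
            d["lv"] = LVSpec(**d["lv"])
        d["plaques"] = [PlaqueSpec(**x) for x in d.get("plaques", [])]
        for key in ("shape", "spacing"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Ground-truth masks, expected metric values, and the generating spec."""
    masks: dict[str, LabelMask]
    expected: dict
    spec: PhantomSpec

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "expected": self.expected,
            "spec": self.spec.to_dict(),
            "mask_voxel_counts": {k: int(m.binary().sum()) for k, m in sorted(self.masks.items())},
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path


# ---------------------------------------------------------------------------
# geometry helpers (all in physical mm on the voxel-center grid)
# ---------------------------------------------------------------------------

def _grids_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _check_box_fits(lo, hi, shape, desc: str) -> None:
    if any(l < 0 for l in lo) or any(h > n for h, n in zip(hi, shape)):
        raise StructureFitError(
            f"structure does not fit the grid: {desc} needs voxels "
            f"{tuple(lo)}..{tuple(hi)} in a grid of shape {tuple(shape)}")


def _cylinder_geometry(shape, spacing, center, axis, length_mm, max_radius_mm, desc):
    """Bounding-box slices plus radial/axial distance fields for a cylinder."""
    spacing = np.asarray(spacing, float)
    center_mm = np.asarray(center, float) * spacing
    u = np.asarray(axis, float) * spacing  # direction in physical space
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError(f"{desc}: axis must be non-zero")
    u = u / norm

    half = length_mm / 2.0
    extent_mm = np.abs(u) * half + max_radius_mm
    lo = np.floor((center_mm - extent_mm) / spacing).astype(int)
    hi = np.ceil((center_mm + extent_mm) / spacing).astype(int) + 1
    _check_box_fits(lo, hi, shape, desc)
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

    coords = [ (np.arange(s.start, s.stop) * sp) for s, sp in zip(box, spacing) ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    rel = np.stack([zz - center_mm[0], yy - center_mm[1], xx - center_mm[2]])
    axial = rel[0] * u[0] + rel[1] * u[1] + rel[2] * u[2]
    radial = np.sqrt(np.maximum(np.sum(rel ** 2, axis=0) - axial ** 2, 0.0))
    return box, radial, np.abs(axial) <= half


def _sphere_mask_and_dist(shape, spacing, center, radius_mm, desc):
    spacing = np.asarray(spacing, float)
    center_mm = np.asarray(center, float) * spacing
    lo = np.floor((center_mm - radius_mm) / spacing).astype(int)
    hi = np.ceil((center_mm + radius_mm) / spacing).astype(int) + 1
    _check_box_fits(lo, hi, shape, desc)
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    coords = [(np.arange(s.start, s.stop) * sp) for s, sp in zip(box, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    dist = np.sqrt((zz - center_mm[0]) ** 2 + (yy - center_mm[1]) ** 2
                   + (xx - center_mm[2]) ** 2)
    return box, dist


def _voxelized_ball_count(spacing, radius_mm) -> int:
    """Voxel count of a digital ball of the given radius (centered on a voxel)."""
    n = [int(math.ceil(radius_mm / s)) for s in spacing]
    axes = [np.arange(-k, k + 1) * s for k, s in zip(n, spacing)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return int(np.count_nonzero(zz ** 2 + yy ** 2 + xx ** 2 <= radius_mm ** 2))


def _calibrated_ball(shape, spacing, center, target_ml, desc):
    """Digital ball whose voxel count is trimmed to exactly the target volume.

    The radius is chosen so the digital count meets or exceeds the target,
    then the outermost voxels (largest center distance, ties broken by flat
    index) are removed until the count matches exactly.
    """
    voxel_mm3 = float(np.prod(spacing))
    target_vox = int(round(target_ml * 1000.0 / voxel_mm3))
    if target_vox < 1:
        raise ValueError(f"{desc}: target volume below one voxel")
    r = (3.0 * target_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    while _voxelized_ball_count(spacing, r) < target_vox:
        r += 0.25 * min(spacing)
    box, dist = _sphere_mask_and_dist(shape, spacing, center, r, desc)
    inside = dist <= r
    n = int(inside.sum())
    if n < target_vox:
        raise StructureFitError(f"structure does not fit the grid: {desc}")
    excess = n - target_vox
    mask = inside.copy()
    if excess:
        flat = np.flatnonzero(inside.ravel())
        order = np.lexsort((flat, dist.ravel()[flat]))  # by distance, then index
        drop = flat[order[-excess:]]
        mask.ravel()[drop] = False
    return box, mask, r


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Voxelize the phantom and compute its ground truth.

    Returns the HU volume (noise applied last, if requested) and a
    :class:`PhantomTruth` whose masks are consistent with the painted
    regions and whose expected metric values are computed from voxel counts
    at generation time.
    """
    shape = tuple(int(n) for n in spec.shape)
    spacing = tuple(float(s) for s in spec.spacing)
    voxel_mm3 = float(np.prod(spacing))
    voxel_ml = voxel_mm3 / 1000.0
    rng = np.random.default_rng(spec.seed)

    vol = np.full(shape, spec.soft_tissue_hu, dtype=np.float64)
    masks: dict[str, np.ndarray] = {}
    expected: dict = {}

    # --- lungs -------------------------------------------------------------
    lung_region = np.zeros(shape, dtype=bool)
    zz, yy, xx = _grids_mm(shape, spacing)
    for i, lung in enumerate(spec.lungs):
        c = np.asarray(lung.center, float) * np.asarray(spacing)
        a = np.asarray(lung.semi_axes, float) * np.asarray(spacing)
        lo = [lung.center[k] - lung.semi_axes[k] for k in range(3)]
        hi = [lung.center[k] + lung.semi_axes[k] + 1 for k in range(3)]
        _check_box_fits([int(math.floor(v)) for v in lo],
                        [int(math.ceil(v)) for v in hi], shape, f"lung {i}")
        inside = (((zz - c[0]) / a[0]) ** 2 + ((yy - c[1]) / a[1]) ** 2
                  + ((xx - c[2]) / a[2]) ** 2) <= 1.0
        lung_region |= inside
    vol[lung_region] = spec.lung_hu

    # --- airways (partial-volume ramped walls) ------------------------------
    airway_lumen = np.zeros(shape, dtype=np.int16)
    airway_wall = np.zeros(shape, dtype=np.int16)
    airway_excl = np.zeros(shape, dtype=bool)
    margin = max(spacing)
    h = 0.5 * min(spacing[1:])  # half-voxel ramp width, in-plane
    airway_truth = []
    for i, aw in enumerate(spec.airways):
        if aw.wall_thickness_mm < 2 * h:
            raise ValueError(f"airway {i}: wall thickness {aw.wall_thickness_mm} mm "
                             f"below the voxel-grid resolvable minimum {2 * h} mm")
        r_l = aw.lumen_radius_mm
        r_o = r_l + aw.wall_thickness_mm
        box, radial, in_len = _cylinder_geometry(
            shape, spacing, aw.center, aw.axis, aw.length_mm, r_o + margin,
            f"airway {i}")
        paint = in_len & (radial <= r_o + h)
        profile = np.interp(radial, [r_l - h, r_l + h, r_o - h, r_o + h],
                            [aw.lumen_hu, aw.wall_hu, aw.wall_hu, spec.lung_hu])
        vol[box][paint] = profile[paint]
        airway_lumen[box][in_len & (radial <= r_l)] = i + 1
        airway_wall[box][in_len & (radial > r_l) & (radial <= r_o)] = i + 1
        airway_excl[box] |= in_len & (radial <= r_o + margin)

        la = math.pi * r_l ** 2
        wa = math.pi * (r_o ** 2 - r_l ** 2)
        airway_truth.append({
            "lumen_radius_mm": r_l,
            "outer_radius_mm": r_o,
            "la_mm2": la,
            "wa_mm2": wa,
            "wa_percent": 100.0 * wa / (wa + la),
            "wa_la_ratio": wa / la,
            "internal_perimeter_mm": 2 * math.pi * r_l,
        })

    # --- vessels -------------------------------------------------------------
    vessel_labels = np.zeros(shape, dtype=np.int16)
    vessel_truth = []
    for i, vs in enumerate(spec.vessels):
        box, radial, in_len = _cylinder_geometry(
            shape, spacing, vs.center, vs.axis, vs.length_mm, vs.radius_mm,
            f"vessel {i}")
        m = in_len & (radial <= vs.radius_mm)
        vol[box][m] = vs.hu
        vessel_labels[box][m] = i + 1
    for i, vs in enumerate(spec.vessels):
        n_vox = int(np.count_nonzero(vessel_labels == i + 1))
        vessel_truth.append({
            "radius_mm": vs.radius_mm,
            "csa_mm2": math.pi * vs.radius_mm ** 2,
            "n_voxels": n_vox,
        })
    vessel_mask = vessel_labels > 0

    # --- heart --------------------------------------------------------------
    blood_ed = np.zeros(shape, dtype=bool)
    blood_es = np.zeros(shape, dtype=bool)
    myocardium = np.zeros(shape, dtype=bool)
    heart_excl = np.zeros(shape, dtype=bool)
    if spec.lv is not None:
        lv = spec.lv
        box_ed, ball_ed, r_ed = _calibrated_ball(shape, spacing, lv.center,
                                                 lv.edv_target_ml, "LV blood pool (ED)")
        box_es, ball_es, _ = _calibrated_ball(shape, spacing, lv.center,
                                              lv.esv_target_ml, "LV blood pool (ES)")
        blood_ed[box_ed] = ball_ed
        blood_es[box_es] = ball_es
        r_out = r_ed + lv.myo_thickness_mm
        box_m, dist_m = _sphere_mask_and_dist(shape, spacing, lv.center, r_out,
                                              "LV myocardium")
        shell = (dist_m > r_ed) & (dist_m <= r_out)
        myocardium[box_m] = shell
        heart_excl[box_m] = dist_m <= r_out + margin
        vol[box_m][dist_m <= r_ed] = lv.blood_hu
        vol[box_m][shell] = lv.myo_hu

        edv = int(blood_ed.sum()) * voxel_ml
        esv = int(blood_es.sum()) * voxel_ml
        expected.update({
            "edv_ml": edv, "esv_ml": esv, "sv_ml": edv - esv,
            "ef_percent": 100.0 * (edv - esv) / edv,
            "lvm_g": int(myocardium.sum()) * voxel_ml * 1.05,
        })

    # --- final lung mask and emphysema ---------------------------------------
    lung_mask = lung_region & ~airway_excl & ~vessel_mask & ~heart_excl
    n_lung = int(lung_mask.sum())
    emphysema = np.zeros(shape, dtype=bool)
    if spec.emphysema_fraction > 0 and n_lung:
        target = int(round(spec.emphysema_fraction * n_lung))
        eligible_flat = np.flatnonzero(lung_mask.ravel())
        count = 0
        guard = 0
        while count < target and guard < 100000:
            guard += 1
            idx = int(rng.choice(eligible_flat))
            cz, cy, cx = np.unravel_index(idx, shape)
            r = int(rng.integers(2, 5))
            lo = [max(0, c - r) for c in (cz, cy, cx)]
            hi = [min(n, c + r + 1) for c, n in zip((cz, cy, cx), shape)]
            box = tuple(slice(a, b) for a, b in zip(lo, hi))
            bz, by, bx = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)],
                                     indexing="ij")
            ball = ((bz - cz) ** 2 + (by - cy) ** 2 + (bx - cx) ** 2) <= r ** 2
            new = ball & lung_mask[box] & ~emphysema[box]
            n_new = int(new.sum())
            if count + n_new > target:  # trim the final sphere to land exactly
                flat_new = np.flatnonzero(new.ravel())
                keep = flat_new[: target - count]
                trimmed = np.zeros(new.size, dtype=bool)
                trimmed[keep] = True
                new = trimmed.reshape(new.shape)
                n_new = target - count
            emphysema[box] |= new
            count += n_new
        vol[emphysema] = spec.emphysema_hu

    n_emph = int(emphysema.sum())
    if n_lung:
        lav = 100.0 * n_emph / n_lung
        mld = (n_emph * spec.emphysema_hu + (n_lung - n_emph) * spec.lung_hu) / n_lung
        k = max(1, math.ceil(0.15 * n_lung))
        perc15 = spec.emphysema_hu if k <= n_emph else spec.lung_hu
        expected.update({
            "lav_percent": lav, "mld_hu": mld, "perc15_hu": perc15,
            "n_lung_voxels": n_lung, "n_emphysema_voxels": n_emph,
        })

    # --- plaques -------------------------------------------------------------
    calcium = np.zeros(shape, dtype=bool)
    pixel_area = spacing[1] * spacing[2]
    lesions = []
    for i, pl in enumerate(spec.plaques):
        n_vox = max(1, int(round(pl.area_mm2 / pixel_area)))
        side = int(math.ceil(math.sqrt(n_vox)))
        z = int(pl.slice_index)
        y0, x0 = int(pl.center_yx[0]), int(pl.center_yx[1])
        if not (0 <= z < shape[0]):
            raise StructureFitError(f"structure does not fit the grid: plaque {i} slice {z}")
        offsets = [(dy, dx) for dy in range(side) for dx in range(side)][:n_vox]
        for dy, dx in offsets:
            y, x = y0 + dy, x0 + dx
            if not (0 <= y < shape[1] and 0 <= x < shape[2]):
                raise StructureFitError(f"structure does not fit the grid: plaque {i}")
            if lung_region[z, y, x] or blood_ed[z, y, x] or myocardium[z, y, x]:
                raise StructureFitError(
                    f"plaque {i} overlaps lung/cardiac structures at {(z, y, x)}")
            vol[z, y, x] = pl.peak_hu
            calcium[z, y, x] = True
        area = n_vox * pixel_area
        if pl.peak_hu >= 130 and area >= 1.0:
            if pl.peak_hu < 200:
                w = 1
            elif pl.peak_hu < 300:
                w = 2
            elif pl.peak_hu < 400:
                w = 3
            else:
                w = 4
            lesions.append({"slice_index": z, "area_mm2": area,
                            "peak_hu": pl.peak_hu, "weight": w,
                            "score": area * w * spacing[0] / 3.0})
    expected["cacs"] = float(sum(l["score"] for l in lesions))
    expected["lesions"] = lesions

    # coronary search region: the plaques dilated by two voxels
    roi = np.zeros(shape, dtype=bool)
    if calcium.any():
        roi = ndimage.binary_dilation(calcium, iterations=2)

    # --- vessel summary ------------------------------------------------------
    if spec.vessels:
        total_vox = sum(v["n_voxels"] for v in vessel_truth)
        below = sum(v["n_voxels"] for v in vessel_truth if v["csa_mm2"] < 5.0)
        expected["bv5_percent"] = 100.0 * below / total_vox if total_vox else None
        expected["total_vessel_volume_ml"] = total_vox * voxel_ml
    expected["airways"] = airway_truth
    expected["vessel_components"] = vessel_truth

    # --- noise ---------------------------------------------------------------
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=shape)

    def _mask(arr, name=None):
        data = arr.astype(np.int16) if arr.dtype == bool else arr
        labels = {name: 1} if name else {}
        return LabelMask(data, spacing, labels)

    masks = {
        "lung": _mask(lung_mask, "lung"),
        "emphysema": _mask(emphysema, "emphysema"),
        "airway_lumen": LabelMask(airway_lumen, spacing,
                                  {f"airway_{i+1}": i + 1 for i in range(len(spec.airways))}),
        "airway_wall": LabelMask(airway_wall, spacing,
                                 {f"airway_{i+1}": i + 1 for i in range(len(spec.airways))}),
        "vessels": LabelMask(vessel_labels, spacing,
                             {f"vessel_{i+1}": i + 1 for i in range(len(spec.vessels))}),
        "lv_blood_ed": _mask(blood_ed, "lv_blood_ed"),
        "lv_blood_es": _mask(blood_es, "lv_blood_es"),
        "myocardium": _mask(myocardium, "myocardium"),
        "calcium": _mask(calcium, "calcium"),
        "coronary_roi": _mask(roi, "coronary_roi"),
    }
    volume = CTVolume(vol, spacing)
    return volume, PhantomTruth(masks=masks, expected=expected, spec=spec)


def degrade(volume: CTVolume, noise_sd: float, seed: int) -> CTVolume:
    """Add seeded Gaussian noise (HU); ``noise_sd=0`` is the identity."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return volume.copy()
    rng = np.random.default_rng(seed)
    return CTVolume(volume.data + rng.normal(0.0, noise_sd, size=volume.shape),
                    volume.spacing, volume.origin)


def branching_vessel_tree(root_center: Sequence[float],
                          root_axis: Sequence[float] = (1.0, 0.0, 0.0),
                          root_radius_mm: float = 3.0,
                          root_length_mm: float = 30.0,
                          depth: int = 3,
                          taper: float = 0.7,
                          length_ratio: float = 0.75,
                          spread: float = 0.5,
                          hu: float = 150.0) -> list[VesselCylinder]:
    """Recursive bifurcating tree as a flat list of vessel cylinders.

    Each branch spawns two children rotated by ±``spread`` radians in
    alternating planes, with radius scaled by ``taper`` and length by
    ``length_ratio``.  Deeper trees are more space-filling, which is what the
    fractal-dimension trend tests exercise.
    """
    cylinders: list[VesselCylinder] = []

    def recurse(center, axis, radius, length, level):
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        cylinders.append(VesselCylinder(center=tuple(float(c) for c in center),
                                        axis=tuple(float(a) for a in axis),
                                        length_mm=length, radius_mm=radius, hu=hu))
        if level >= depth:
            return
        tip = np.asarray(center, float) + axis * (length / 2.0)
        perp = np.array([0.0, 1.0, 0.0]) if level % 2 == 0 else np.array([0.0, 0.0, 1.0])
        if abs(np.dot(perp, axis)) > 0.9:
            perp = np.array([1.0, 0.0, 0.0])
        perp = perp - np.dot(perp, axis) * axis
        perp /= np.linalg.norm(perp)
        for sign in (+1, -1):
            child_axis = axis * math.cos(spread) + sign * perp * math.sin(spread)
            child_len = length * length_ratio
            child_center = tip + child_axis * (child_len / 2.0)
            recurse(child_center, child_axis, radius * taper, child_len, level + 1)

    recurse(np.asarray(root_center, float), root_axis, root_radius_mm,
            root_length_mm, 1)
    return cylinders


def default_spec(seed: int = 0, noise_sd: float = 0.0,
                 emphysema_fraction: float = 0.25) -> PhantomSpec:
    """A representative thorax phantom exercising every biomarker branch.

    104×128×128 voxels at 1 mm isotropic spacing: two ellipsoidal lungs,
    three airways of distinct caliber (so the Pi10 regression has distinct
    perimeters), a mixed population of small (< 5 mm² CSA) and large vessel
    cylinders, a 120/48 mL two-phase left ventricle, and two calcified
    plaques spanning two density weight classes.
    """
    shape = (104, 128, 128)
    return PhantomSpec(
        shape=shape,
        spacing=(1.0, 1.0, 1.0),
        emphysema_fraction=emphysema_fraction,
        lungs=[
            LungSpec(center=(40.0, 64.0, 34.0), semi_axes=(36.0, 44.0, 26.0)),
            LungSpec(center=(40.0, 64.0, 94.0), semi_axes=(36.0, 44.0, 26.0)),
        ],
        airways=[
            AirwaySpec(center=(30.0, 56.0, 30.0), length_mm=32.0,
                       lumen_radius_mm=2.0, wall_thickness_mm=1.0),
            AirwaySpec(center=(30.0, 72.0, 30.0), length_mm=32.0,
                       lumen_radius_mm=3.0, wall_thickness_mm=1.2),
            AirwaySpec(center=(26.0, 64.0, 44.0), length_mm=18.0,
                       lumen_radius_mm=1.5, wall_thickness_mm=1.0),
        ],
        vessels=[
            VesselCylinder(center=(32.0, 52.0, 88.0), length_mm=44.0, radius_mm=1.0),
            VesselCylinder(center=(32.0, 64.0, 104.0), length_mm=20.0, radius_mm=2.0),
            VesselCylinder(center=(32.0, 56.0, 100.0), length_mm=36.0, radius_mm=1.0),
        ],
        lv=LVSpec(center=(60.0, 84.0, 64.0)),
        plaques=[
            PlaqueSpec(slice_index=20, center_yx=(12, 60), area_mm2=4.0, peak_hu=250.0),
            PlaqueSpec(slice_index=24, center_yx=(12, 72), area_mm2=9.0, peak_hu=450.0),
        ],
        noise_sd=noise_sd,
        seed=seed,
    )
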