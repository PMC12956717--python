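"""CT volume / label mask data model, NIfTI I/O, preprocessing, and reports.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)`` with voxel spacing ``(dz, dy, dx)`` in mm,
  all coordinates 0-based;
* volumes carry raw Hounsfield units (HU).  :func:`preprocess` produces a
  *separate* truncated/normalized copy intended as model input — every
  quantification branch reads raw HU, because truncating at 400 HU would
  destroy the ≥400 HU Agatston density class.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage


__all__ = [
    "CTVolume",
    "LabelMask",
    "PreprocessConfig",
    "BiomarkerReport",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "preprocess",
    "write_report",
    "read_report",
]


@dataclass
class CTVolume:
    """A 3D scalar grid in Hounsfield units with anisotropic voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        HU values; must be finite.
    spacing : tuple of float
        ``(dz, dy, dx)`` in mm, strictly positive.
    origin : tuple of float
        mm offset of voxel (0, 0, 0); informational.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "zyx"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def copy(self) -> "CTVolume":
        return CTVolume(self.data.copy(), self.spacing, self.origin, self.axis_order)


@dataclass
class LabelMask:
    """Integer label grid aligned to a :class:`CTVolume`.

    ``labels`` maps structure names to integer codes; 0 is background and
    need not be declared.  For binary masks the convention is a single label
    mapping to 1.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    labels: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer) and self.data.dtype != bool:
            raise ValueError("mask data must be integer or boolean")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.labels:
            declared = set(int(v) for v in self.labels.values()) | {0}
            present = set(int(v) for v in np.unique(self.data))
            extra = present - declared
            if extra:
                raise ValueError(f"mask contains undeclared labels {sorted(extra)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def binary(self, name: str | None = None) -> np.ndarray:
        """Boolean array for one named label, or foreground if ``name`` is None."""
        if name is None:
            return self.data.astype(bool)
        if name not in self.labels:
            raise KeyError(f"unknown label {name!r}; declared: {sorted(self.labels)}")
        return self.data == int(self.labels[name])

    def check_aligned(self, volume: CTVolume) -> None:
        if self.shape != volume.shape:
            raise ValueError(f"mask shape {self.shape} != volume shape {volume.shape}")
        if not np.allclose(self.spacing, volume.spacing):
            raise ValueError(f"mask spacing {self.spacing} != volume spacing {volume.spacing}")


@dataclass
class PreprocessConfig:
    """Model-input preprocessing: Gaussian denoising, HU truncation, [0,1] scaling.

    ``gaussian_sigma`` defaults to 1.0 — the low end of the conventional 1–1.5
    denoising range — to minimally blur thin airway walls.  Sigma is
    interpreted in voxel units unless ``sigma_units`` is ``"mm"``.
    """

    gaussian_sigma: float = 1.0
    sigma_units: str = "voxel"  # "voxel" or "mm"
    hu_window: tuple[float, float] = (-1000.0, 400.0)
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.sigma_units not in ("voxel", "mm"):
            raise ValueError("sigma_units must be 'voxel' or 'mm'")
        low, high = self.hu_window
        if not low < high:
            raise ValueError(f"hu_window low must be < high, got {self.hu_window}")


def preprocess(volume: CTVolume, cfg: PreprocessConfig | None = None) -> CTVolume:
    """Gaussian-denoise, truncate to the HU window, optionally map to [0, 1].

    Returns a new volume; the input (raw HU) is never modified.  With
    ``sigma == 0`` and ``normalize == False`` this is the identity on volumes
    already inside the window.
    """
    cfg = cfg or PreprocessConfig()
    data = volume.data.astype(np.float64, copy=True)
    if cfg.gaussian_sigma > 0:
        if cfg.sigma_units == "mm":
            sigma = tuple(cfg.gaussian_sigma / s for s in volume.spacing)
        else:
            sigma = cfg.gaussian_sigma
        data = ndimage.gaussian_filter(data, sigma=sigma)
    low, high = cfg.hu_window
    data = np.clip(data, low, high)
    if cfg.normalize:
        data = (data - low) / (high - low)
    return CTVolume(data, volume.spacing, volume.origin, volume.axis_order)


# ---------------------------------------------------------------------------
# NIfTI I/O.  nibabel stores arrays (x, y, z); we transpose to (z, y, x).
# ---------------------------------------------------------------------------

def _affine_from_spacing(spacing: tuple[float, float, float],
                         origin: tuple[float, float, float]) -> np.ndarray:
    dz, dy, dx = spacing
    oz, oy, ox = origin
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = [ox, oy, oz]
    return affine


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a CTVolume as NIfTI; integer dtypes round-trip bit-exactly."""
    path = Path(path)
    img = nib.Nifti1Image(np.asanyarray(volume.data).T, _affine_from_spacing(volume.spacing, volume.origin))
    img.header.set_zooms((volume.spacing[2], volume.spacing[1], volume.spacing[0]))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> CTVolume:
    """Read a 3D NIfTI file into a CTVolume (spacing from the header)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing {spacing} in {path}")
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return CTVolume(data.T, spacing, origin)


def write_mask(mask: LabelMask, path: str | Path) -> Path:
    path = Path(path)
    vol = CTVolume(np.zeros(mask.shape), mask.spacing)  # spacing validation only
    img = nib.Nifti1Image(mask.data.astype(np.int16).T, _affine_from_spacing(mask.spacing, (0, 0, 0)))
    img.header.set_zooms((vol.spacing[2], vol.spacing[1], vol.spacing[0]))
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, labels: Mapping[str, int] | None = None) -> LabelMask:
    vol = read_volume(path)
    return LabelMask(vol.data.astype(np.int16), vol.spacing, labels or {})


# ---------------------------------------------------------------------------
# Biomarker report
# ---------------------------------------------------------------------------

#: Stable report keys, one per quantified index, with units.
REPORT_FIELDS = (
    ("lav_percent", "%"),
    ("perc15_hu", "HU"),
    ("mld_hu", "HU"),
    ("wa_percent", "%"),
    ("pi10_mm", "mm"),
    ("bv5_percent", "%"),
    ("fractal_dimension", ""),
    ("cacs", "AU"),
    ("lvm_g", "g"),
    ("edv_ml", "mL"),
    ("esv_ml", "mL"),
    ("sv_ml", "mL"),
    ("ef_percent", "%"),
)


@dataclass
class BiomarkerReport:
    """The quantified imaging indices of one subject/phantom.

    Unpopulated metrics are ``None`` ("explicitly marked absent"), never 0.
    """

    lav_percent: float | None = None
    perc15_hu: float | None = None
    mld_hu: float | None = None
    wa_percent: float | None = None
    pi10_mm: float | None = None
    bv5_percent: float | None = None
    fractal_dimension: float | None = None
    cacs: float | None = None
    lvm_g: float | None = None
    edv_ml: float | None = None
    esv_ml: float | None = None
    sv_ml: float | None = None
    ef_percent: float | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in list(d.items()):
            if isinstance(v, float) and math.isnan(v):
                d[k] = None
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "BiomarkerReport":
        known = {k for k, _ in REPORT_FIELDS} | {"provenance"}
        return cls(**{k: v for k, v in d.items() if k in known})


def write_report(report: BiomarkerReport, path: str | Path) -> tuple[Path, Path]:
    """Emit a report as JSON (machine) and CSV (tabular).

    ``path`` may carry either suffix or none; both files are written next to
    each other with ``.json`` and ``.csv`` suffixes.
    """
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".json", ".csv") else path
    json_path = base.with_suffix(".json")
    csv_path = base.with_suffix(".csv")
    d = report.to_dict()
    json_path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["metric", "value", "unit"])
        for key, unit in REPORT_FIELDS:
            w.writerow([key, "" if d[key] is None else d[key], unit])
    return json_path, csv_path


def read_report(path: str | Path) -> BiomarkerReport:
    return BiomarkerReport.from_dict(json.loads(Path(path).read_text()))
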