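"""Cardiac branch: Agatston calcium score, LV mass, ejection fraction, stroke volume.

The Agatston score follows the classic protocol: per axial slice,
8-connected components of voxels ≥ 130 HU inside the coronary search region;
lesions below 1 mm² of in-plane area are dropped; each lesion contributes
``area (mm²) × density weight × (slice spacing / 3 mm)`` where the weight is
1/2/3/4 for a peak HU of 130–199/200–299/300–399/≥400.  The spacing factor
normalizes to the original 3 mm-slice protocol and is configurable.

Scoring must run on the raw HU volume: a model-input copy truncated at
400 HU makes the weight-4 class unreachable, which triggers a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CTVolume, LabelMask

__all__ = [
    "AgatstonConfig",
    "LesionRecord",
    "CardiacMetrics",
    "agatston_score",
    "agatston_weight",
    "lv_mass",
    "lv_function",
]

MYOCARDIAL_DENSITY_G_PER_ML = 1.05


@dataclass
class AgatstonConfig:
    threshold_hu: float = 130.0
    min_area_mm2: float = 1.0
    normalize_slice_spacing: bool = True
    reference_slice_mm: float = 3.0


@dataclass
class LesionRecord:
    slice_index: int
    area_mm2: float
    peak_hu: float
    weight: int
    score: float


@dataclass
class CardiacMetrics:
    cacs: float | None = None
    lvm_g: float | None = None
    edv_ml: float | None = None
    esv_ml: float | None = None
    sv_ml: float | None = None
    ef_percent: float | None = None
    lesion_table: list[LesionRecord] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def agatston_weight(peak_hu: float) -> int:
    """Peak-density weight class of the classic protocol."""
    if peak_hu < 130:
        raise ValueError(f"peak {peak_hu} HU below the 130 HU calcium threshold")
    if peak_hu < 200:
        return 1
    if peak_hu < 300:
        return 2
    if peak_hu < 400:
        return 3
    return 4


_STRUCTURE_8CONN = np.ones((3, 3), dtype=int)


def agatston_score(volume: CTVolume, roi: LabelMask,
                   cfg: AgatstonConfig | None = None,
                   ) -> tuple[float, list[LesionRecord]]:
    """Classic per-slice Agatston score inside a coronary search region.

    Returns the total score and the per-lesion table.  Warns when the input
    looks truncated at 400 HU (the ≥400 HU weight class would then be
    unreachable — quantification must read raw HU).
    """
    cfg = cfg or AgatstonConfig()
    roi.check_aligned(volume)
    data = volume.data
    roi_sel = roi.binary()

    if roi_sel.any():
        vmax = float(data[roi_sel].max())
        if vmax == 400.0 and np.count_nonzero(data[roi_sel] == 400.0) > 1:
            warnings.warn(
                "volume appears truncated at 400 HU; peak-density class 4 is "
                "unreachable — Agatston scoring should use the raw HU volume",
                UserWarning, stacklevel=2)

    dz, dy, dx = volume.spacing
    pixel_area = dy * dx
    spacing_factor = dz / cfg.reference_slice_mm if cfg.normalize_slice_spacing else 1.0

    lesions: list[LesionRecord] = []
    candidate = (data >= cfg.threshold_hu) & roi_sel
    for z in range(volume.shape[0]):
        plane = candidate[z]
        if not plane.any():
            continue
        labeled, n = ndimage.label(plane, structure=_STRUCTURE_8CONN)
        for lab in range(1, n + 1):
            sel = labeled == lab
            area = float(sel.sum()) * pixel_area
            if area < cfg.min_area_mm2:
                continue
            peak = float(data[z][sel].max())
            w = agatston_weight(peak)
            lesions.append(LesionRecord(
                slice_index=z, area_mm2=area, peak_hu=peak, weight=w,
                score=area * w * spacing_factor))
    return float(sum(l.score for l in lesions)), lesions


def lv_mass(myocardium: LabelMask,
            density_g_per_ml: float = MYOCARDIAL_DENSITY_G_PER_ML,
            ) -> tuple[float, list[str]]:
    """Left-ventricular mass: myocardial volume × tissue density (1.05 g/mL)."""
    n = int(myocardium.binary().sum())
    voxel_ml = float(np.prod(myocardium.spacing)) / 1000.0
    flags = [] if n else ["empty myocardium mask"]
    return n * voxel_ml * density_g_per_ml, flags


def lv_function(blood_ed: LabelMask, blood_es: LabelMask) -> CardiacMetrics:
    """EDV, ESV, SV and EF from the two-phase blood-pool masks.

    Volumes are voxel summations; ``sv = edv − esv`` and
    ``ef = 100·sv/edv``.  Inconsistent phases (ESV ≥ EDV) raise.
    """
    n_ed = int(blood_ed.binary().sum())
    n_es = int(blood_es.binary().sum())
    if n_ed == 0 or n_es == 0:
        raise ValueError("blood-pool masks must be non-empty")
    if not np.allclose(blood_ed.spacing, blood_es.spacing):
        raise ValueError("ED/ES masks must share voxel spacing")
    voxel_ml = float(np.prod(blood_ed.spacing)) / 1000.0
    edv = n_ed * voxel_ml
    esv = n_es * voxel_ml
    if esv >= edv:
        raise ValueError(f"inconsistent phases: ESV {esv:.1f} mL >= EDV {edv:.1f} mL")
    sv = edv - esv
    return CardiacMetrics(edv_ml=edv, esv_ml=esv, sv_ml=sv,
                          ef_percent=100.0 * sv / edv)
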