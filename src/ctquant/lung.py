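"""Lung parenchyma branch: LAV%, Perc15 and mean lung density from raw HU.

LAV% is the percentage of lung voxels below a low-attenuation threshold
(default −950 HU, the field-standard cutoff for inspiratory HRCT emphysema
quantification).  Perc15 is the HU value at the 15th percentile of the
lung-voxel density histogram; MLD is the mean HU over the lung mask.  All
three are computed on the raw HU volume restricted to the lung mask, with
voxel-count weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import CTVolume, LabelMask

__all__ = ["LungMetrics", "lung_metrics", "percentile_lower"]

#: Default low-attenuation threshold (HU) for inspiratory CT.
DEFAULT_LAA_THRESHOLD = -950.0


@dataclass
class LungMetrics:
    lav_percent: float | None
    perc15: float | None
    mld: float | None
    laa_threshold: float
    n_lung_voxels: int
    defined: bool = True


def percentile_lower(values: np.ndarray, q: float) -> float:
    """Order statistic at rank ``ceil(q·n)`` (1-based) of the sorted sample.

    This "lower-value" convention is fixed so that tests are exact: for a
    sample with at least a fraction ``q`` of its mass at the minimum value,
    the percentile sits inside that block.
    """
    values = np.asarray(values).ravel()
    n = values.size
    if n == 0:
        raise ValueError("empty sample")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    k = max(1, math.ceil(q * n))
    return float(np.partition(values, k - 1)[k - 1])


def lung_metrics(volume: CTVolume, lung: LabelMask,
                 laa_threshold: float = DEFAULT_LAA_THRESHOLD,
                 label: str | None = None) -> LungMetrics:
    """Compute LAV%, Perc15 and MLD over the lung mask.

    Parameters
    ----------
    volume : CTVolume
        Raw HU volume (not the truncated/normalized model-input copy).
    lung : LabelMask
        Lung mask aligned to ``volume``; ``label`` selects a named label,
        otherwise any foreground voxel counts as lung.
    laa_threshold : float
        Low-attenuation cutoff in HU; a voxel is "low attenuation" iff
        ``HU < laa_threshold``.

    An empty mask yields flagged-absent metrics (``defined=False``), not
    zeros.
    """
    lung.check_aligned(volume)
    sel = lung.binary(label)
    n = int(sel.sum())
    if n == 0:
        return LungMetrics(None, None, None, float(laa_threshold), 0, defined=False)
    hu = volume.data[sel].astype(np.float64)
    lav = 100.0 * float(np.count_nonzero(hu < laa_threshold)) / n
    return LungMetrics(
        lav_percent=lav,
        perc15=percentile_lower(hu, 0.15),
        mld=float(hu.mean()),
        laa_threshold=float(laa_threshold),
        n_lung_voxels=n,
    )
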