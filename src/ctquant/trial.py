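"""Trial-design statistics: two-sample-means sample size, GOLD grading,
stratified 1:1 randomization, Benjamini–Hochberg adjustment, and the
biomarker–function correlation matrix.

The sample-size formula is the standard two-sample comparison of means,

    n = 2 σ² (Z₁₋α/₂ + Z₁₋β)² / δ²   per group,

with σ the outcome standard deviation and δ the between-group difference;
the returned n is the ceiling of the raw value.  GOLD grades partition FEV₁
percent-predicted: I ≥ 80, II 50–80, III 30–50, IV < 30 (or respiratory
failure, which forces grade IV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SampleSizeSpec",
    "SampleSizeResult",
    "EnrollmentPlan",
    "sample_size_per_group",
    "inflate_for_design",
    "gold_grade",
    "stratified_randomize",
    "bh_adjust",
    "correlation_matrix",
]


@dataclass
class SampleSizeSpec:
    """Inputs to the two-sample-means sample-size formula.

    ``z_alpha``/``z_beta`` may be supplied directly (e.g. the rounded 1.96
    and 0.84) or left ``None`` to be derived exactly from ``alpha`` (two
    sided) and ``power``.
    """

    sigma: float
    delta: float
    alpha: float = 0.05
    power: float = 0.8
    z_alpha: float | None = None
    z_beta: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0 (a zero difference leaves n undefined)")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")

    def quantiles(self) -> tuple[float, float]:
        za = self.z_alpha if self.z_alpha is not None else float(stats.norm.ppf(1 - self.alpha / 2))
        zb = self.z_beta if self.z_beta is not None else float(stats.norm.ppf(self.power))
        return za, zb


@dataclass
class SampleSizeResult:
    n: int
    n_raw: float
    z_alpha: float
    z_beta: float


def sample_size_per_group(spec: SampleSizeSpec) -> SampleSizeResult:
    """Per-group n for a two-sample comparison of means (ceiling of the raw value)."""
    za, zb = spec.quantiles()
    n_raw = 2.0 * spec.sigma ** 2 * (za + zb) ** 2 / spec.delta ** 2
    return SampleSizeResult(n=max(1, math.ceil(n_raw)), n_raw=n_raw,
                            z_alpha=za, z_beta=zb)


@dataclass
class EnrollmentPlan:
    n_per_group: int
    dropout_rate: float
    inflated_n_per_group: int
    per_stratum_target: int | None = None
    strata: int | None = None
    arms: int | None = None
    total: int | None = None


def inflate_for_design(n_per_group: int, dropout_rate: float = 0.15,
                       strata: int | None = None,
                       per_stratum_target: int | None = None,
                       arms: int = 2) -> EnrollmentPlan:
    """Dropout-inflated per-group n and, optionally, a fixed-target total.

    The inflation formula is ``ceil(n / (1 − dropout))``.  When a fixed
    per-stratum target is supplied (a design input, e.g. 50 per subgroup),
    ``total = target × strata × arms``; the inflation-formula value is still
    reported — a design may round it to a convenient target, which is a
    choice of the design, not of this function.
    """
    if not 0 <= dropout_rate < 1:
        raise ValueError("dropout_rate must lie in [0, 1)")
    inflated = math.ceil(n_per_group / (1.0 - dropout_rate))
    total = None
    if per_stratum_target is not None:
        if strata is None:
            raise ValueError("strata count required with a per-stratum target")
        total = per_stratum_target * strata * arms
    return EnrollmentPlan(n_per_group=n_per_group, dropout_rate=dropout_rate,
                          inflated_n_per_group=inflated,
                          per_stratum_target=per_stratum_target,
                          strata=strata, arms=arms, total=total)


GOLD_GRADES = ("I", "II", "III", "IV")


def gold_grade(fev1_percent_predicted: float,
               respiratory_failure: bool = False) -> str:
    """COPD severity grade from FEV₁ percent predicted.

    I: ≥ 80; II: 50–80; III: 30–50; IV: < 30 or respiratory failure.
    Boundaries are inclusive on the lower grade side (80.0 → I, 50.0 → II,
    30.0 → III).
    """
    f = float(fev1_percent_predicted)
    if not 0 < f < 200:
        raise ValueError(f"FEV1 %predicted {f} outside the plausible (0, 200) range")
    if respiratory_failure or f < 30:
        return "IV"
    if f < 50:
        return "III"
    if f < 80:
        return "II"
    return "I"


def stratified_randomize(subjects: Sequence[Hashable],
                         strata: Sequence[Hashable],
                         seed: int,
                         arms: tuple[str, str] = ("EG", "CG"),
                         ) -> tuple[dict, list]:
    """Seeded 1:1 allocation within each stratum.

    Returns ``(assignment, imbalanced_strata)``: a subject→arm mapping and
    the list of odd-sized strata where an exact 1:1 split is impossible
    (those get a ±1 imbalance, flagged rather than erroring).
    """
    subjects = list(subjects)
    if not subjects:
        raise ValueError("no subjects to randomize")
    if len(strata) != len(subjects):
        raise ValueError("strata must align with subjects")
    groups: dict[Hashable, list] = {}
    for s, g in zip(subjects, strata):
        groups.setdefault(g, []).append(s)

    rng = np.random.default_rng(seed)
    assignment: dict = {}
    imbalanced = []
    for key in sorted(groups, key=repr):
        members = groups[key]
        n = len(members)
        if n % 2:
            imbalanced.append(key)
        order = rng.permutation(n)
        half = n // 2 + int(rng.integers(0, 2)) * (n % 2)  # odd: extra goes to a random arm
        for rank, idx in enumerate(order):
            assignment[members[idx]] = arms[0] if rank < half else arms[1]
    return assignment, imbalanced


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_matrix(imaging: pd.DataFrame, function: pd.DataFrame,
                       method: str = "pearson",
                       min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise imaging-biomarker × clinical-function correlations.

    Missing data are handled pairwise-complete; cells with fewer than
    ``min_pairs`` complete pairs or a constant column are flagged undefined
    (NaN r/p) and excluded from the BH adjustment, which runs across all
    defined cells.  Returns a long-format frame with columns
    ``imaging, function, n, r, p, q, defined``.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if len(imaging) != len(function):
        raise ValueError("imaging and function tables must have aligned rows")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr

    rows = []
    for icol in imaging.columns:
        for fcol in function.columns:
            x = pd.to_numeric(imaging[icol], errors="coerce")
            y = pd.to_numeric(function[fcol], errors="coerce")
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if n < min_pairs or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                rows.append((icol, fcol, n, np.nan, np.nan, False))
                continue
            res = corr(x[ok].to_numpy(), y[ok].to_numpy())
            rows.append((icol, fcol, n, float(res.statistic), float(res.pvalue), True))
    out = pd.DataFrame(rows, columns=["imaging", "function", "n", "r", "p", "defined"])
    out["q"] = np.nan
    mask = out["defined"]
    if mask.any():
        out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out
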