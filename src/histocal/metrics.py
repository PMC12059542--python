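"""Quantitative analysis metrics: visibility, duration-normalised intensity,
mean residual error (MRE), mean absolute deviation (MAD) and Pearson r.

These are the effect metrics of the phantom experiments.  The surrounding
hypothesis-test battery (Shapiro-Wilk, Levene, Kruskal-Wallis, Dunn,
Mann-Whitney, t-test) is deliberately left to scipy.stats / pingouin and is
not re-implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .localization import AlgoParams, difference_image
from .volume_io import Volume


@dataclass(frozen=True)
class IntensityRecord:
    """Mean |difference| intensity in one treatment zone.

    ``position_flag`` is 0 if the treatment was placed between barium
    layers and 1 if on a layer.
    """

    intensity: float
    trial: int
    duration_s: float
    position_flag: int

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.position_flag not in (0, 1):
            raise ValueError("position_flag must be 0 (between layers) or 1 (on a layer)")


@dataclass(frozen=True)
class TranslationMeasurement:
    """One measured vs. planned translation (mm) along one axis."""

    measured_mm: float
    planned_mm: float
    axis: str = "X"
    trial: int = 0


def visibility(
    pre_registered: Volume,
    post: Volume,
    ellipse_center_mm: Sequence[float],
    params: AlgoParams | None = None,
    radii_mm: Sequence[float] = (2.0, 2.0, 4.0),
) -> float:
    """Mean filtered |post − pre| inside the nominal 4 x 4 x 8 mm ellipsoid.

    The pair must already be registered onto a common grid.  Ellipsoid
    membership is by voxel-center inclusion.
    """
    params = params or AlgoParams()
    diff = difference_image(pre_registered, post, params)
    c = np.asarray(ellipse_center_mm, float)
    r = np.asarray(radii_mm, float)
    lo, hi = diff.extent
    if np.any(c - r < lo) or np.any(c + r > hi):
        raise ValueError("visibility ellipsoid extends outside the volume")
    w = [diff.origin[a] + np.arange(diff.shape[a]) * diff.spacing[a] for a in range(3)]
    nx = (w[0] - c[0]) / r[0]
    ny = (w[1] - c[1]) / r[1]
    nz = (w[2] - c[2]) / r[2]
    inside = (
        nx[:, None, None] ** 2 + ny[None, :, None] ** 2 + nz[None, None, :] ** 2
    ) <= 1.0
    return float(diff.data[inside].mean())


def normalize_visibility(records: Iterable[IntensityRecord]) -> list[float]:
    """Remove the duration effect: subtract each duration group's pooled
    (both positions) mean intensity from every record in that group.

    Requires the design to be balanced: within each duration group, the
    same number of trials at each position.  Returns the normalised values
    in the input order.
    """
    records = list(records)
    groups: dict[float, list[IntensityRecord]] = {}
    for rec in records:
        groups.setdefault(rec.duration_s, []).append(rec)
    means: dict[float, float] = {}
    for j, recs in groups.items():
        n0 = sum(1 for r in recs if r.position_flag == 0)
        n1 = len(recs) - n0
        if n0 != n1 or n0 == 0:
            raise ValueError(
                f"duration group {j}: unbalanced positions (n0={n0}, n1={n1}); "
                "the normalisation assumes equal n per position"
            )
        means[j] = float(np.mean([r.intensity for r in recs]))
    return [r.intensity - means[r.duration_s] for r in records]


def mean_residual_error(
    measurements: Iterable[TranslationMeasurement],
) -> tuple[float, float, dict[float, float]]:
    """Signed mean of (measured − planned) translation distances.

    Pooled over all planned distances and trials; requires the same number
    of trials per planned distance (the 1/(Jn) averaging assumes a balanced
    design).  Returns (MRE, sample SD of the residuals, per-distance mean
    residual).
    """
    ms = list(measurements)
    if not ms:
        raise ValueError("no measurements")
    groups: dict[float, list[float]] = {}
    for m in ms:
        groups.setdefault(m.planned_mm, []).append(m.measured_mm - m.planned_mm)
    sizes = {len(v) for v in groups.values()}
    if len(sizes) != 1:
        raise ValueError(f"unbalanced planned-distance groups: sizes {sorted(sizes)}")
    residuals = np.array([m.measured_mm - m.planned_mm for m in ms])
    per_group = {j: float(np.mean(v)) for j, v in sorted(groups.items())}
    sd = float(np.std(residuals, ddof=1)) if residuals.size > 1 else 0.0
    return float(residuals.mean()), sd, per_group


def mean_absolute_deviation(samples: Sequence[float]) -> float:
    """Mean absolute deviation about the arithmetic mean: (1/n) Σ |x_i − m(x)|."""
    x = np.asarray(samples, float)
    if x.size < 2:
        raise ValueError("MAD requires at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("MAD requires finite samples")
    return float(np.mean(np.abs(x - x.mean())))


def pearson_r(x_list: Sequence[float], y_list: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x_list, float)
    y = np.asarray(y_list, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r requires equal-length inputs of size >= 3")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)
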