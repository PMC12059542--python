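"""Multi-bubble-cloud calibration: joint localization of a fixed 4-cloud
pattern and the robot-to-bubble-cloud 3D offset.

A single bubble cloud's Z estimate is noisy when the cloud straddles or
misses barium layers, so the calibration treatment prescribes four clouds
at fixed spacings (10 mm apart in Y, 1 mm apart in Z) that sample distinct
layer phases.  Localizing all four jointly — the ROIs move rigidly as a
group, so the cost pools the evidence of all four treatment zones — and
averaging drives down the per-axis variability of the measured offset.

The reported offset is (average measured centroid) − (average planned
centroid), signed per axis, in the pre-scan (plan) world frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .localization import (
    AlgoParams,
    CuboidROI,
    LocalizationResult,
    difference_image,
    localize_in_difference,
    locate_z,
    observed_seed,
    roi_mean_cost,
    z_profile,
)
from .registration import RigidTransform, register_rigid, resample
from .volume_io import Volume

#: Fixed inter-cloud step of the calibration pattern (mm): 10 mm in Y,
#: 1 mm along the layer normal.
PATTERN_STEP_MM = np.array([0.0, 10.0, 1.0])


@dataclass
class CalibrationPattern:
    """The planned 4-cloud pattern: p_k = p0 + k * (0, 10, 1) mm, k = 0..3."""

    p0_mm: tuple[float, float, float]
    n_clouds: int = 4
    step_mm: tuple[float, float, float] = tuple(PATTERN_STEP_MM)

    @property
    def targets_mm(self) -> np.ndarray:
        p0 = np.asarray(self.p0_mm, float)
        step = np.asarray(self.step_mm, float)
        return np.array([p0 + k * step for k in range(self.n_clouds)])

    @property
    def mean_target_mm(self) -> np.ndarray:
        return self.targets_mm.mean(axis=0)


@dataclass
class OffsetResult:
    """Measured − planned average centroid, with per-cloud diagnostics."""

    offset_mm: np.ndarray
    avg_measured_mm: np.ndarray
    avg_planned_mm: np.ndarray
    per_cloud: list[LocalizationResult] = field(default_factory=list)
    euclidean_mm: float = 0.0
    warning: str | None = None
    convention: str = "measured - planned, plan frame, mm"

    def __post_init__(self) -> None:
        self.offset_mm = np.asarray(self.offset_mm, float)
        self.avg_measured_mm = np.asarray(self.avg_measured_mm, float)
        self.avg_planned_mm = np.asarray(self.avg_planned_mm, float)
        self.euclidean_mm = float(np.linalg.norm(self.offset_mm))


def compute_offset(
    measured_centroids: Sequence[Sequence[float]], pattern: CalibrationPattern
) -> OffsetResult:
    """Offset from already-localized centroids: mean(measured) − mean(planned)."""
    measured = np.asarray(measured_centroids, float)
    targets = pattern.targets_mm
    if measured.shape != targets.shape:
        raise ValueError(
            f"expected {targets.shape[0]} measured centroids, got {measured.shape[0]}"
        )
    avg_measured = measured.mean(axis=0)
    avg_planned = targets.mean(axis=0)
    return OffsetResult(avg_measured - avg_planned, avg_measured, avg_planned)


def localize_pattern(
    pre: Volume,
    post: Volume,
    pattern: CalibrationPattern,
    params: AlgoParams | None = None,
    transform: RigidTransform | None = None,
    snap_seed_radius_mm: float | None = None,
) -> OffsetResult:
    """Jointly localize the 4-cloud pattern and return the shared offset.

    Stage 1: each cloud is localized independently, seeded at its target
    (or, with ``snap_seed_radius_mm`` set, at the brightest difference
    voxel within that radius of the target — emulating the manually placed
    "observed center" seed of the reference workflow, which keeps stage 1
    on the correct cloud for transducer offsets of several mm); the mean
    measured-minus-planned displacement initialises the shared offset.  Stage 2: Nelder-Mead over a single shared in-plane offset
    (x, y) maximising the mean ROI cost of the four rigidly co-moving
    cuboids.  Stage 3: the four Z profiles, aligned by the known 1 mm Z
    stagger, are averaged and the single-cloud Z rule applied to the
    averaged profile, giving the shared Z offset.
    """
    params = params or AlgoParams()
    if transform is None:
        transform = register_rigid(post, pre)
    pre_reg = resample(pre, transform, post)
    diff = difference_image(pre_reg, post, params)
    t_inv = transform.inverse()
    targets_plan = pattern.targets_mm
    targets_post = np.array([t_inv.apply_point(p) for p in targets_plan])

    # --- Stage 1: independent per-cloud localization ------------------------
    warning = None
    per_cloud: list[LocalizationResult] = []
    try:
        for p in targets_post:
            seed = (
                observed_seed(diff, p, (snap_seed_radius_mm,) * 3)
                if snap_seed_radius_mm is not None
                else p
            )
            per_cloud.append(localize_in_difference(diff, seed, params))
        measured_post = np.array([r.centroid_mm for r in per_cloud])
        t0 = measured_post.mean(axis=0) - targets_post.mean(axis=0)
    except ValueError as exc:
        warning = f"stage-1 localization failed ({exc}); seeding joint stage at zero offset"
        per_cloud = []
        t0 = np.zeros(3)

    # --- Stage 2: shared in-plane offset, ROIs rigidly co-moving ------------
    dims = tuple(np.asarray(params.roi_dims_mm, float))
    z_ks = targets_post[:, 2] + t0[2]

    def neg_joint_cost(txy: np.ndarray) -> float:
        costs = [
            roi_mean_cost(
                diff,
                CuboidROI((p[0] + txy[0], p[1] + txy[1], zk), dims),
            )
            for p, zk in zip(targets_post, z_ks)
        ]
        return -float(np.mean(costs))

    edge = float(np.mean(diff.spacing))
    x0 = t0[:2].copy()
    simplex = np.array([x0, x0 + [edge, 0.0], x0 + [0.0, edge]])
    f0 = neg_joint_cost(x0)
    res = minimize(
        neg_joint_cost,
        x0,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "xatol": params.nm_xatol_mm,
            "fatol": params.nm_frtol * max(abs(f0), 1e-12),
            "maxfev": params.nm_maxfev,
        },
    )
    from .localization import _center_on_plateau

    txy, joint_cost = _center_on_plateau(neg_joint_cost, np.asarray(res.x, float), edge)

    # --- Stage 3: shared Z from the stagger-aligned averaged profile --------
    # The 1 mm Z stagger is not a multiple of the voxel pitch, so the four
    # aligned profiles sample Z at four distinct sub-pitch phases; averaging
    # them on a 4x finer grid keeps that dither and gives the joint Z rule
    # sub-voxel resolution (the point of staggering the pattern).
    step = np.asarray(pattern.step_mm, float)
    aligned_axes, profiles = [], []
    for k, (p, zk) in enumerate(zip(targets_post, z_ks)):
        center = np.array([p[0] + txy[0], p[1] + txy[1], zk])
        z_pos, prof = z_profile(diff, center, params)
        aligned_axes.append(z_pos - k * step[2])  # cloud 0's Z frame
        profiles.append(prof)
    z_lo = max(a[0] for a in aligned_axes)
    z_hi = min(a[-1] for a in aligned_axes)
    fine_pitch = float(diff.spacing[2]) / 4.0
    z_fine = np.arange(z_lo, z_hi + fine_pitch / 2, fine_pitch)
    avg_profile = np.mean(
        [np.interp(z_fine, a, prof) for a, prof in zip(aligned_axes, profiles)], axis=0
    )
    z_center0, z_extent, z_method = locate_z(z_fine, avg_profile, params)
    tz = z_center0 - targets_post[0, 2]

    # --- assemble in the plan frame -----------------------------------------
    t_post = np.array([txy[0], txy[1], tz])
    measured_post_final = targets_post + t_post
    measured_plan = np.array([transform.apply_point(p) for p in measured_post_final])
    for r in per_cloud:  # report per-cloud centroids in the plan frame too
        r.centroid_mm = transform.apply_point(r.centroid_mm)
        r.transform = transform
    avg_measured = measured_plan.mean(axis=0)
    avg_planned = targets_plan.mean(axis=0)
    out = OffsetResult(
        avg_measured - avg_planned,
        avg_measured,
        avg_planned,
        per_cloud=per_cloud,
        warning=warning,
    )
    out.joint_cost = joint_cost  # type: ignore[attr-defined]
    out.z_method = z_method  # type: ignore[attr-defined]
    out.z_extent_mm = z_extent  # type: ignore[attr-defined]
    out.measured_mm = measured_plan  # type: ignore[attr-defined]
    out.measured_post_mm = measured_post_final  # type: ignore[attr-defined]
    out.targets_post_mm = targets_post  # type: ignore[attr-defined]
    out.stage1_offset_mm = t0  # type: ignore[attr-defined]
    return out
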