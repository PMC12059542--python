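"""Rigid pre-to-post registration by mean-squared-error minimisation.

The first stage of the localization pipeline: the pre-treatment scan is
rigidly registered to the post-treatment scan to undo the minor physical
shift of the phantom in the water bath between scans.  The metric is plain
MSE, the optimiser regular-step gradient descent on a 3-level multiresolution
pyramid, and interpolation is trilinear throughout (backed by SimpleITK's
registration framework).

Convention: :func:`register_rigid` returns the transform ``T`` mapping
points of the *fixed* volume's world frame to the *moving* volume's frame
(the resampling convention), as XYZ Euler angles about the fixed volume's
center plus a translation.  For the pipeline, fixed = post and
moving = pre, so downstream centroids found on the post grid map back into
the pre (plan) frame via ``T.apply_point``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .volume_io import Volume, from_sitk, to_sitk


@dataclass
class RigidTransform:
    """Rigid map y = R(x - c) + c + t (XYZ Euler, degrees, about center c)."""

    translation: np.ndarray
    rotation_deg: np.ndarray
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    converged: bool = True
    final_metric: float = float("nan")

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float)
        self.center_mm = np.asarray(self.center_mm, dtype=float)

    def rotation_matrix(self) -> np.ndarray:
        ax, ay, az = np.deg2rad(self.rotation_deg)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry @ rx

    def apply_point(self, point_mm: np.ndarray) -> np.ndarray:
        """Map a world point through the transform."""
        p = np.asarray(point_mm, dtype=float)
        return self.rotation_matrix() @ (p - self.center_mm) + self.center_mm + self.translation

    def inverse(self) -> "RigidTransform":
        """Exact inverse about the same center."""
        r = self.rotation_matrix()
        ax, ay, az = _euler_xyz_from_matrix(r.T)
        t_inv = -(r.T @ self.translation)
        return RigidTransform(t_inv, np.rad2deg([ax, ay, az]), self.center_mm.copy())

    def to_sitk(self) -> sitk.Euler3DTransform:
        tf = sitk.Euler3DTransform()
        tf.SetComputeZYX(True)  # Rz(az) @ Ry(ay) @ Rx(ax), matching rotation_matrix()
        tf.SetCenter(tuple(self.center_mm))
        ax, ay, az = np.deg2rad(self.rotation_deg)
        tf.SetRotation(float(ax), float(ay), float(az))
        tf.SetTranslation(tuple(self.translation))
        return tf

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "translation_mm": self.translation.tolist(),
                "rotation_deg": self.rotation_deg.tolist(),
                "center_mm": self.center_mm.tolist(),
                "convention": "xyz-euler-about-center, y = R(x-c)+c+t, fixed->moving",
                "converged": bool(self.converged),
                "final_metric": None if np.isnan(self.final_metric) else float(self.final_metric),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "RigidTransform":
        p = Path(text_or_path) if not str(text_or_path).lstrip().startswith("{") else None
        obj = json.loads(p.read_text() if p is not None else str(text_or_path))
        return cls(obj["translation_mm"], obj["rotation_deg"], obj["center_mm"])

    @classmethod
    def identity(cls, center_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3), np.asarray(center_mm, float))


def _euler_xyz_from_matrix(r: np.ndarray) -> tuple[float, float, float]:
    """XYZ Euler angles (radians) with R = Rz(az) @ Ry(ay) @ Rx(ax)."""
    ay = np.arcsin(np.clip(-r[2, 0], -1.0, 1.0))
    if np.abs(np.cos(ay)) > 1e-8:
        ax = np.arctan2(r[2, 1], r[2, 2])
        az = np.arctan2(r[1, 0], r[0, 0])
    else:  # gimbal lock; irrelevant in the small-angle regime
        ax = np.arctan2(-r[1, 2], r[1, 1])
        az = 0.0
    return ax, ay, az


def register_rigid(
    fixed: Volume,
    moving: Volume,
    init: RigidTransform | None = None,
    background: float = 0.0,
) -> RigidTransform:
    """Estimate the rigid transform minimising the MSE between volumes.

    Multi-start-free local descent: MeanSquares metric, regular-step
    gradient descent over a 3-level shrink pyramid (4x, 2x, 1x), evaluated
    on a deterministic 2% random voxel sample for speed.  Suited to the
    small motions ("minor physical shifts") the simulator and the
    water-bath setup produce; capture range is a few mm / a few degrees.
    """
    f_img = to_sitk(fixed)
    m_img = to_sitk(moving)

    center = fixed.center_mm()
    tf = sitk.Euler3DTransform()
    tf.SetComputeZYX(True)
    tf.SetCenter(tuple(center))
    if init is not None:
        ax, ay, az = np.deg2rad(init.rotation_deg)
        tf.SetRotation(float(ax), float(ay), float(az))
        tf.SetTranslation(tuple(init.translation))

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=0.2,
        minStep=5e-4,
        numberOfIterations=60,
        relaxationFactor=0.5,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(0.02, 1234)  # fixed seed: deterministic
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(tf, inPlace=True)

    try:
        out = reg.Execute(f_img, m_img)
    except RuntimeError as exc:
        raise ValueError(f"registration failed (degenerate overlap?): {exc}") from exc

    euler = sitk.Euler3DTransform(out)
    angles = np.rad2deg([euler.GetAngleX(), euler.GetAngleY(), euler.GetAngleZ()])
    stop = reg.GetOptimizerStopConditionDescription()
    converged = "maximum number of iterations" not in stop.lower()
    return RigidTransform(
        np.array(euler.GetTranslation()),
        angles,
        np.array(euler.GetCenter()),
        converged=converged,
        final_metric=float(reg.GetMetricValue()),
    )


def resample(
    volume: Volume,
    transform: RigidTransform,
    reference: Volume,
    background: float = 0.0,
) -> Volume:
    """Map ``volume`` onto ``reference``'s grid through ``transform``.

    ``transform`` maps reference-frame points into ``volume``'s frame
    (the convention returned by :func:`register_rigid` with
    fixed=reference).  Trilinear interpolation; out-of-bounds filled with
    ``background``.
    """
    out = sitk.Resample(
        to_sitk(volume),
        to_sitk(reference),
        transform.to_sitk(),
        sitk.sitkLinear,
        float(background),
        sitk.sitkFloat32,
    )
    res = from_sitk(out)
    res.meta = dict(volume.meta)
    return res
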