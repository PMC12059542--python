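"""Single bubble-cloud localization from a registered pre/post pair.

Pipeline (run by :func:`localize_single`):

1. rigidly register the pre scan to the post scan (MSE, gradient descent);
2. take the Gaussian-filtered absolute difference of the registered pair;
3. place a 4 x 4 x 30 mm cuboid ROI at a seed point and maximise its mean
   difference intensity over the in-plane (X, Y) position with Nelder-Mead,
   restarted from 7 perturbed seeds to dodge local maxima;
4. average the central third of the cuboid footprint into a 1D Z profile
   and locate the cloud top/bottom by threshold crossings; if the detected
   extent reaches the expected 8 mm cloud height the Z centroid is the
   midpoint of top and bottom, otherwise (cloud sitting between two barium
   layers, extent unreliable) the intensity-weighted centroid of the
   profile.

The tall, uniformly weighted ROI makes the X/Y estimate insensitive to the
exact Z and robust to extra cavitation along the beam path.  All positions
are world mm; the returned centroid is reported in the pre-scan (plan)
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import minimize

from .registration import RigidTransform, register_rigid, resample
from .volume_io import Volume, sample


@dataclass
class AlgoParams:
    """Tunables of the localization algorithm (voxel-denominated constants
    assume the 0.47 mm reconstruction pitch but scale with the actual grid)."""

    gauss_kernel_vox: int = 5
    gauss_sigma_vox: float = 1.0
    roi_dims_mm: tuple[float, float, float] = (4.0, 4.0, 30.0)
    n_seeds: int = 7
    seed_perturb_vox: tuple[float, float, float] = (2.0, 2.0, 4.0)
    z_threshold_mm: float = 8.0
    expected_cloud_mm: tuple[float, float, float] = (4.0, 4.0, 8.0)
    nm_xatol_mm: float = 0.01
    nm_frtol: float = 1e-6
    nm_maxfev: int = 200

    def __post_init__(self) -> None:
        if self.gauss_kernel_vox < 1 or self.gauss_sigma_vox <= 0:
            raise ValueError("Gaussian kernel/sigma must be positive")
        if np.any(np.asarray(self.roi_dims_mm) <= 0) or self.z_threshold_mm <= 0:
            raise ValueError("ROI dims and z threshold must be positive")


@dataclass(frozen=True)
class CuboidROI:
    """Axis-aligned cuboid (center + dims, mm) for the mean-intensity cost."""

    center_mm: tuple[float, float, float]
    dims_mm: tuple[float, float, float] = (4.0, 4.0, 30.0)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.dims_mm) <= 0):
            raise ValueError("ROI dims must be positive")


@dataclass
class SeedRun:
    """Diagnostics of one Nelder-Mead start."""

    start_mm: np.ndarray
    xy_mm: np.ndarray
    z_mm: float
    cost: float
    n_evals: int
    improved: bool


@dataclass
class LocalizationResult:
    centroid_mm: np.ndarray
    cost: float
    z_extent_mm: float
    z_method: str  # "boundary_midpoint" | "weighted_centroid"
    seed_runs: list[SeedRun] = field(default_factory=list)
    transform: RigidTransform | None = None
    warning: str | None = None


def difference_image(pre_registered: Volume, post: Volume, params: AlgoParams | None = None) -> Volume:
    """Gaussian-filtered absolute difference of a registered pair.

    Kernel size 5 voxels (radius 2), sigma 1 voxel by default.
    """
    params = params or AlgoParams()
    if pre_registered.shape != post.shape or not (
        np.allclose(pre_registered.spacing, post.spacing)
        and np.allclose(pre_registered.origin, post.origin)
    ):
        raise ValueError("difference_image requires both volumes on the same grid")
    diff = np.abs(post.data - pre_registered.data)
    radius = (params.gauss_kernel_vox - 1) // 2
    diff = gaussian_filter(diff, sigma=params.gauss_sigma_vox, radius=radius)
    return Volume(diff, post.spacing.copy(), post.origin.copy())


def _roi_lattice(roi_dims: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Sampling offsets (n, 3) spanning the ROI, pitch = voxel spacing,
    symmetric about the ROI center (cost stays continuous in the center)."""
    axes = []
    for dim, pitch in zip(roi_dims, spacing):
        n = max(int(np.floor(dim / pitch)) + 1, 2)
        axes.append((np.arange(n) - (n - 1) / 2.0) * pitch)
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)


def roi_mean_cost(diff: Volume, roi: CuboidROI) -> float:
    """Mean of trilinear samples of the difference image over the cuboid.

    Samples outside the volume contribute the background value 0, so ROIs
    poking past a cropped edge degrade gracefully.
    """
    offsets = _roi_lattice(np.asarray(roi.dims_mm, float), diff.spacing)
    pts = np.asarray(roi.center_mm, float) + offsets
    return float(np.mean(sample(diff, pts)))


def _seed_starts(seed_mm: np.ndarray, spacing: np.ndarray, params: AlgoParams) -> list[np.ndarray]:
    """The 7 Nelder-Mead starts: the seed, ±2 voxels in X, ±2 in Y and ±4
    (an extra perturbation perpendicular to the layers) in Z."""
    px, py, pz = params.seed_perturb_vox
    deltas = [
        np.zeros(3),
        np.array([+px * spacing[0], 0, 0]),
        np.array([-px * spacing[0], 0, 0]),
        np.array([0, +py * spacing[1], 0]),
        np.array([0, -py * spacing[1], 0]),
        np.array([0, 0, +pz * spacing[2]]),
        np.array([0, 0, -pz * spacing[2]]),
    ]
    return [seed_mm + d for d in deltas[: params.n_seeds]]


def _center_on_plateau(neg_cost, xy: np.ndarray, pitch: float, rel_tol: float = 1e-9):
    """Center a converged in-plane position within its cost plateau.

    With the sampling lattice commensurate with the voxel grid the cost is
    affine within each voxel cell, so a symmetric signal has an exactly
    flat, one-pitch-wide optimum on which the simplex stops arbitrarily
    (typically at an edge, half a voxel off center).  Scanning one pitch
    along each axis and taking the midpoint of the contiguous tied-optimal
    run removes that half-voxel indeterminacy deterministically.
    """
    xy = xy.copy()
    f0 = neg_cost(xy)
    tol = abs(f0) * rel_tol + 1e-15
    for axis in range(2):
        offsets = np.linspace(-pitch / 2.0, pitch / 2.0, 21)
        vals = np.empty_like(offsets)
        for i, d in enumerate(offsets):
            probe = xy.copy()
            probe[axis] += d
            vals[i] = neg_cost(probe)
        tied = vals <= vals.min() + tol
        i0 = int(np.argmin(np.abs(offsets)))  # run containing the current point
        if not tied[i0]:
            continue
        lo = i0
        while lo > 0 and tied[lo - 1]:
            lo -= 1
        hi = i0
        while hi < len(offsets) - 1 and tied[hi + 1]:
            hi += 1
        xy[axis] += 0.5 * (offsets[lo] + offsets[hi])
    return xy, -neg_cost(xy)


def optimize_xy(
    diff: Volume, seed_mm: Sequence[float], params: AlgoParams | None = None
) -> tuple[np.ndarray, float, list[SeedRun]]:
    """Maximise the cuboid's mean difference intensity over (x, y).

    Z is held fixed per start (the 30 mm cuboid makes the cost weakly
    Z-sensitive; the ±4-voxel Z perturbations across starts cover it).
    Returns the (x, y) of the best run; ties break toward the run whose
    result lies nearest the unperturbed seed.
    """
    params = params or AlgoParams()
    seed = np.asarray(seed_mm, float)
    dims = np.asarray(params.roi_dims_mm, float)
    edge = float(np.mean(diff.spacing))  # initial simplex edge: 1 voxel

    runs: list[SeedRun] = []
    for start in _seed_starts(seed, diff.spacing, params):
        z = float(start[2])

        def neg_cost(xy: np.ndarray) -> float:
            roi = CuboidROI((float(xy[0]), float(xy[1]), z), tuple(dims))
            return -roi_mean_cost(diff, roi)

        x0 = start[:2]
        simplex = np.array([x0, x0 + [edge, 0.0], x0 + [0.0, edge]])
        f0 = neg_cost(x0)
        res = minimize(
            neg_cost,
            x0,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "xatol": params.nm_xatol_mm,
                "fatol": params.nm_frtol * max(abs(f0), 1e-12),
                "maxfev": params.nm_maxfev,
            },
        )
        runs.append(
            SeedRun(
                start_mm=start.copy(),
                xy_mm=np.asarray(res.x, float),
                z_mm=z,
                cost=-float(res.fun),
                n_evals=int(res.nfev),
                improved=bool(-res.fun > -f0),
            )
        )

    best = max(
        runs,
        key=lambda r: (r.cost, -float(np.linalg.norm(np.append(r.xy_mm, r.z_mm) - seed))),
    )

    z_best = best.z_mm

    def neg_cost_best(xy: np.ndarray) -> float:
        return -roi_mean_cost(diff, CuboidROI((float(xy[0]), float(xy[1]), z_best), tuple(dims)))

    xy_centered, cost_centered = _center_on_plateau(neg_cost_best, best.xy_mm, edge)
    return xy_centered, cost_centered, runs


def z_profile(
    diff: Volume, center_mm: Sequence[float], params: AlgoParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Average the central third of the ROI footprint into a Z profile.

    The central ~1.33 x 1.33 mm column of the 4 x 4 mm footprint is averaged
    in X and Y at each Z sample over the cuboid's full 30 mm extent (pitch =
    Z spacing).  Returns (z_positions_mm, values).
    """
    params = params or AlgoParams()
    c = np.asarray(center_mm, float)
    dims = np.asarray(params.roi_dims_mm, float)
    foot = dims[:2] / 3.0

    ax = []
    for dim, pitch in zip(foot, diff.spacing[:2]):
        n = max(int(np.floor(dim / pitch)) + 1, 2)
        ax.append((np.arange(n) - (n - 1) / 2.0) * pitch)
    n_z = max(int(np.round(dims[2] / diff.spacing[2])), 2)
    z_off = (np.arange(n_z) - (n_z - 1) / 2.0) * diff.spacing[2]

    gx, gy, gz = np.meshgrid(ax[0], ax[1], z_off, indexing="ij")
    pts = c + np.stack([gx, gy, gz], axis=-1)
    vals = sample(diff, pts)  # (nx, ny, nz)
    return c[2] + z_off, vals.mean(axis=(0, 1))


def locate_z(
    z_positions_mm: np.ndarray, profile: np.ndarray, params: AlgoParams | None = None
) -> tuple[float, float, str]:
    """Find the cloud's Z center from the averaged column profile.

    Threshold = mean of the profile.  Scanning down from the top and up
    from the bottom, the first supra-threshold samples mark the cloud top
    and bottom.  If the extent reaches the expected cloud height (8 mm) the
    center is their midpoint; otherwise the intensity-weighted centroid
    (first image moment) of the full profile is used.
    """
    params = params or AlgoParams()
    z = np.asarray(z_positions_mm, float)
    p = np.asarray(profile, float)
    if z.size == 0 or p.size != z.size:
        raise ValueError("profile and z positions must be equal-length and nonempty")
    if np.allclose(p, p[0]):
        raise ValueError("degenerate difference image: constant Z profile")
    thr = float(p.mean())
    above = np.nonzero(p > thr)[0]
    if above.size == 0:
        raise ValueError("degenerate difference image: no supra-threshold sample")
    z_bot = float(z[above[0]])   # scanning up from the bottom
    z_top = float(z[above[-1]])  # scanning down from the top
    # Each supra-threshold sample supports half a pitch on either side; the
    # sample-center difference alone underestimates a 10 mm boxcar by one
    # pitch, so the extent counts the end half-samples.
    pitch = float(z[1] - z[0]) if z.size > 1 else 0.0
    extent = z_top - z_bot + pitch
    if extent >= params.z_threshold_mm:
        return 0.5 * (z_top + z_bot), extent, "boundary_midpoint"
    total = float(p.sum())
    return float(np.dot(z, p) / total), extent, "weighted_centroid"


def observed_seed(
    diff: Volume, near_mm: Sequence[float], radius_mm: Sequence[float] = (5.0, 5.0, 5.0)
) -> np.ndarray:
    """Emulate the manual seed: the brightest difference-image voxel near a
    nominal position.

    The reference workflow places the seed by eye at the observed center of
    the treatment zone on the post image; this returns the world position
    of the maximum filtered |difference| within ``near_mm`` ± ``radius_mm``
    (the radius is kept below half the calibration-pattern spacing so the
    seed cannot jump to a neighboring cloud).
    """
    near = np.asarray(near_mm, float)
    r = np.asarray(radius_mm, float)
    lo = np.maximum(np.ceil(diff.world_to_index(near - r)).astype(int), 0)
    hi = np.minimum(np.floor(diff.world_to_index(near + r)).astype(int), np.array(diff.shape) - 1)
    if np.any(hi < lo):
        raise ValueError("seed search window lies outside the volume")
    sl = tuple(slice(a, b + 1) for a, b in zip(lo, hi))
    local = diff.data[sl]
    idx = np.array(np.unravel_index(np.argmax(local), local.shape)) + lo
    return diff.index_to_world(idx)


def localize_in_difference(
    diff: Volume, seed_mm: Sequence[float], params: AlgoParams | None = None
) -> LocalizationResult:
    """Run the XY optimisation + Z analysis on a precomputed difference image.

    Coordinates stay in the difference image's (post-scan) frame; used
    directly by the calibration and experiment drivers, which register once
    per scan pair.
    """
    params = params or AlgoParams()
    seed = np.asarray(seed_mm, float)
    xy, cost, runs = optimize_xy(diff, seed, params)
    best = max(
        runs,
        key=lambda r: (r.cost, -float(np.linalg.norm(np.append(r.xy_mm, r.z_mm) - seed))),
    )
    center = np.array([xy[0], xy[1], best.z_mm])
    z_pos, prof = z_profile(diff, center, params)
    z_center, z_extent, z_method = locate_z(z_pos, prof, params)
    warning = None if any(r.improved for r in runs) else "no Nelder-Mead start improved on its seed"
    return LocalizationResult(
        centroid_mm=np.array([xy[0], xy[1], z_center]),
        cost=cost,
        z_extent_mm=z_extent,
        z_method=z_method,
        seed_runs=runs,
        warning=warning,
    )


def localize_single(
    pre: Volume,
    post: Volume,
    seed_mm: Sequence[float],
    params: AlgoParams | None = None,
    transform: RigidTransform | None = None,
) -> LocalizationResult:
    """Full single-cloud pipeline; seed and returned centroid in the pre
    (plan) world frame.

    ``transform`` may carry a precomputed post->pre registration to skip
    the registration stage (e.g. when localizing several clouds in one scan
    pair).
    """
    params = params or AlgoParams()
    if transform is None:
        transform = register_rigid(post, pre)  # maps post-frame points to pre frame
    pre_reg = resample(pre, transform, post)
    diff = difference_image(pre_reg, post, params)
    seed_post = transform.inverse().apply_point(np.asarray(seed_mm, float))
    result = localize_in_difference(diff, seed_post, params)
    result.centroid_mm = transform.apply_point(result.centroid_mm)
    result.transform = transform
    return result
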