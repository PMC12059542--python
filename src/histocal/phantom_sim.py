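"""Synthetic layered-phantom CBCT simulator.

Generates pre-/post-treatment volume pairs of an agar phantom with 11
alternating high/low x-ray-attenuation layers, emulating what the
localization algorithm sees on reconstructed cone-beam CT: a bubble-cloud
treatment homogenises ("mixes") the layers inside an ellipsoidal zone whose
contrast saturates with treatment duration, the post scan is rigidly
shifted a little relative to the pre scan (phantom settling in the water
bath), and both scans carry reconstruction blur and additive noise.

Ground truth (treatment centers, layer boundaries, specs, seeds) travels in
``Volume.meta`` and in the JSON sidecar written next to simulated volumes.
All simulation is in the reconstructed-volume domain; there is no acoustics
or projection physics here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.ndimage import affine_transform, gaussian_filter

from .volume_io import Volume

#: Reference reconstruction pitch (mm/voxel) of the clinical C-arm volumes.
DEFAULT_SPACING_MM = 0.47

#: Default simulation field of view (mm): phantom plus a water margin.
DEFAULT_FIELD_MM = (60.0, 60.0, 35.0)


@dataclass
class PhantomSpec:
    """Parametric description of the layered agar phantom.

    The physical phantom is a 50 x 50 x 25 mm block of 11 layers along Z:
    six plain agar layers (~3-4 mm) alternating with five thin barium
    sulfate layers (~1-1.5 mm), in a low-intensity water background.
    """

    size_mm: tuple[float, float, float] = (50.0, 50.0, 25.0)
    n_layers: int = 11
    layer_thickness_mm: Sequence[float] | None = None  # drawn if None
    intensity_plain: float = 60.0
    intensity_barium: float = 400.0
    intensity_water: float = 0.0
    layer_jitter_mm: float = 0.15

    def __post_init__(self) -> None:
        if self.n_layers % 2 == 0 or self.n_layers < 3:
            raise ValueError("n_layers must be odd and >= 3 (plain/barium alternation ends plain)")
        if self.layer_thickness_mm is not None:
            t = list(self.layer_thickness_mm)
            if len(t) != self.n_layers:
                raise ValueError(f"need {self.n_layers} thicknesses, got {len(t)}")
            if sum(t) > self.size_mm[2] + 1e-9:
                raise ValueError("layer thicknesses exceed phantom depth")

    def draw_thicknesses(self, rng: np.random.Generator) -> np.ndarray:
        """Layer thicknesses (mm), plain layers first/last, alternating.

        Plain layers are drawn U[3, 4] mm and barium layers U[1, 1.5] mm,
        jittered by ``layer_jitter_mm``; if the drawn stack is deeper than
        the phantom it is rescaled proportionally to fit.
        """
        if self.layer_thickness_mm is not None:
            t = np.asarray(self.layer_thickness_mm, dtype=float)
        else:
            t = np.empty(self.n_layers)
            for i in range(self.n_layers):
                t[i] = rng.uniform(3.0, 4.0) if i % 2 == 0 else rng.uniform(1.0, 1.5)
        t = t + rng.normal(0.0, self.layer_jitter_mm, size=t.shape)
        t = np.clip(t, 0.3, None)
        total = t.sum()
        if total > self.size_mm[2]:
            t *= (self.size_mm[2] - 1e-6) / total
        return t


@dataclass
class TreatmentSpec:
    """One simulated bubble-cloud treatment (ground truth attached).

    The nominal bubble cloud is a 4 x 4 x 8 mm ellipsoid (radii 2, 2, 4 mm)
    centered at ``center_mm``; ``duration_s`` controls mixing contrast via
    :func:`mixing_strength`.  For long treatments (>= 20 s) extra cavitation
    along the beam path extends the zone toward the transducer (-Z) over a
    thin cylinder of length ``tail_length_mm``.
    """

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float] = (2.0, 2.0, 4.0)
    duration_s: float = 20.0
    tail_length_mm: float = 0.0
    mix_noise_sigma: float | None = None  # None -> 0.15 * barium-plain contrast

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.radii_mm) <= 0):
            raise ValueError("treatment radii must be positive")
        if self.tail_length_mm < 0:
            raise ValueError("tail_length_mm must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass
class ScanNoiseSpec:
    """Per-scan degradations: blur, noise and post-scan rigid motion.

    ``shift_mm``/``rotation_deg`` give the rigid motion of the post scan
    relative to the pre scan; ``None`` draws them uniformly from ±1 mm and
    ±0.5° per axis (the "minor physical shifts" regime).
    """

    noise_sigma: float = 10.0
    shift_mm: tuple[float, float, float] | None = None
    rotation_deg: tuple[float, float, float] | None = None
    psf_sigma_mm: float = 0.4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.rotation_deg is not None and np.any(np.abs(self.rotation_deg) > 5):
            raise ValueError("|rotation_deg| must be <= 5")

    def realized_motion(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        shift = (
            np.asarray(self.shift_mm, float)
            if self.shift_mm is not None
            else rng.uniform(-1.0, 1.0, size=3)
        )
        rot = (
            np.asarray(self.rotation_deg, float)
            if self.rotation_deg is not None
            else rng.uniform(-0.5, 0.5, size=3)
        )
        return shift, rot


#: Mixing-heterogeneity noise, as a fraction of the barium-plain contrast.
MIX_NOISE_FRACTION = 0.15

#: Z-radius dilation applied when a treatment intersects a barium layer
#: (barium sulfate seeds cavitation, blurring the cloud top/bottom).
BARIUM_Z_DILATION = 1.25

#: Extra mixing completeness for foci between barium layers: a focus placed
#: directly on a barium layer seeds cavitation prematurely at the layer,
#: which shields the focal zone and leaves the mixing less thorough, while
#: a focus between layers cavitates in clean agar with seed bubbles fed
#: from both adjacent layers.  Scales the between-layers vs. on-layer
#: visibility asymmetry; 0 disables it.
BARIUM_SEED_BOOST = 0.15

#: Saturation time constant (s) of mixing contrast vs. treatment duration.
MIXING_TAU_S = 11.5


def mixing_strength(duration_s: float, m_max: float = 1.0, tau_s: float = MIXING_TAU_S) -> float:
    """Saturating mixing contrast m(t) = m_max * (1 - exp(-t / tau)).

    Defaults reproduce the observed visibility saturation: contrast rises
    steeply from 5 s and plateaus from ~20 s, with m(20)/m(5) ~ 2.34.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    return m_max * (1.0 - np.exp(-duration_s / tau_s))


def _grid_world(shape: tuple[int, int, int], spacing: np.ndarray, origin: np.ndarray):
    """Open world-coordinate grids (wx, wy, wz) along each axis."""
    return [origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)]


def build_phantom_clean(
    spec: PhantomSpec,
    spacing_mm: float | Sequence[float] = DEFAULT_SPACING_MM,
    rng_seed: int = 0,
    field_mm: Sequence[float] = DEFAULT_FIELD_MM,
) -> Volume:
    """Noiseless, unblurred piecewise-constant phantom volume.

    The phantom block is centered in a water field of ``field_mm``; the
    world origin is placed so the field center is at (0, 0, 0) mm.  Layer
    boundaries (world Z, mm) and layer kinds are recorded in ``meta``.
    """
    spacing = np.asarray(spacing_mm, dtype=float) * np.ones(3)
    field = np.asarray(field_mm, dtype=float)
    if np.any(spec.size_mm > field):
        raise ValueError("phantom does not fit in the simulation field with a water margin")
    rng = np.random.default_rng(rng_seed)
    thick = spec.draw_thicknesses(rng)

    shape = tuple(int(np.round(f / s)) for f, s in zip(field, spacing))
    origin = -(np.array(shape) - 1) * spacing / 2.0
    wx, wy, wz = _grid_world(shape, spacing, origin)

    # Layer stack centered in Z within the phantom block.
    stack_h = float(thick.sum())
    z0 = -stack_h / 2.0
    bounds = z0 + np.concatenate([[0.0], np.cumsum(thick)])
    kinds = ["plain" if i % 2 == 0 else "barium" for i in range(spec.n_layers)]

    zvals = np.full(len(wz), spec.intensity_water)
    for i in range(spec.n_layers):
        inside = (wz >= bounds[i]) & (wz < bounds[i + 1])
        zvals[inside] = spec.intensity_plain if kinds[i] == "plain" else spec.intensity_barium

    half = np.asarray(spec.size_mm, float) / 2.0
    in_x = np.abs(wx) <= half[0]
    in_y = np.abs(wy) <= half[1]
    data = np.where(
        in_x[:, None, None] & in_y[None, :, None],
        zvals[None, None, :],
        spec.intensity_water,
    ).astype(np.float64)

    meta = {
        "phantom_spec": asdict(spec) | {"layer_thickness_mm": thick.tolist()},
        "layer_bounds_mm": bounds.tolist(),
        "layer_kinds": kinds,
        "rng_seed": int(rng_seed),
    }
    return Volume(data, spacing, origin, meta)


def _degrade(volume: Volume, noise: ScanNoiseSpec, rng: np.random.Generator) -> Volume:
    """Apply reconstruction blur and additive Gaussian noise (no motion)."""
    data = volume.data
    if noise.psf_sigma_mm > 0:
        data = gaussian_filter(data, sigma=noise.psf_sigma_mm / volume.spacing)
    if noise.noise_sigma > 0:
        data = data + rng.normal(0.0, noise.noise_sigma, size=data.shape)
    else:
        data = data.copy()
    return Volume(data, volume.spacing.copy(), volume.origin.copy(), dict(volume.meta))


def build_phantom(
    spec: PhantomSpec,
    spacing_mm: float | Sequence[float] = DEFAULT_SPACING_MM,
    rng_seed: int = 0,
    noise: ScanNoiseSpec | None = None,
    field_mm: Sequence[float] = DEFAULT_FIELD_MM,
) -> Volume:
    """Simulated pre-treatment scan: layered phantom + blur + noise."""
    noise = noise if noise is not None else ScanNoiseSpec()
    clean = build_phantom_clean(spec, spacing_mm, rng_seed, field_mm)
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 1]))
    return _degrade(clean, noise, rng)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _treatment_weight(
    volume: Volume, treatment: TreatmentSpec, radii: np.ndarray
) -> np.ndarray:
    """Spatial mixing weight s(x): 1 inside 80% of the radii, ->0 at the boundary.

    If the treatment has a beam-path tail, a 2 mm-radius cylinder extending
    toward the transducer (-Z) from the ellipsoid carries half weight.
    """
    wx, wy, wz = _grid_world(volume.shape, volume.spacing, volume.origin)
    c = np.asarray(treatment.center_mm, float)
    nx = (wx - c[0]) / radii[0]
    ny = (wy - c[1]) / radii[1]
    nz = (wz - c[2]) / radii[2]
    rho = np.sqrt(nx[:, None, None] ** 2 + ny[None, :, None] ** 2 + nz[None, None, :] ** 2)
    s = _smoothstep((1.0 - rho) / 0.2)  # rho<=0.8 -> 1, rho>=1 -> 0

    tail_active = treatment.tail_length_mm > 0 and treatment.duration_s >= 20
    if tail_active:
        r_xy = np.sqrt(
            ((wx - c[0]) ** 2)[:, None, None] + ((wy - c[1]) ** 2)[None, :, None]
        )
        z_lo = c[2] - radii[2] - treatment.tail_length_mm
        z_hi = c[2] - radii[2] * 0.5
        in_tail = (r_xy <= 2.0) & ((wz >= z_lo) & (wz <= z_hi))[None, None, :]
        s = np.maximum(s, 0.5 * in_tail)
    return s


def _barium_centers(volume: Volume) -> np.ndarray | None:
    bounds = volume.meta.get("layer_bounds_mm")
    kinds = volume.meta.get("layer_kinds")
    if bounds is None or kinds is None:
        return None
    return np.array(
        [0.5 * (bounds[i] + bounds[i + 1]) for i, k in enumerate(kinds) if k == "barium"]
    )


def _barium_dilated_radii(treatment: TreatmentSpec, volume: Volume) -> np.ndarray:
    """Dilate the Z radius when the ellipsoid intersects a barium layer."""
    radii = np.asarray(treatment.radii_mm, float).copy()
    bounds = volume.meta.get("layer_bounds_mm")
    kinds = volume.meta.get("layer_kinds")
    if bounds is None or kinds is None:
        return radii
    cz = treatment.center_mm[2]
    z_lo, z_hi = cz - radii[2], cz + radii[2]
    for i, kind in enumerate(kinds):
        if kind == "barium" and bounds[i] <= z_hi and bounds[i + 1] >= z_lo:
            radii[2] *= BARIUM_Z_DILATION
            break
    return radii


def _seed_boost(treatment: TreatmentSpec, volume: Volume) -> float:
    """Mixing-completeness factor from the focus position between layers.

    Grows linearly from 1 at a barium layer center to 1 + BARIUM_SEED_BOOST
    midway between two layers.
    """
    centers = _barium_centers(volume)
    if centers is None or centers.size == 0:
        return 1.0
    d = float(np.min(np.abs(centers - treatment.center_mm[2])))
    half_gap = float(np.mean(np.diff(np.sort(centers)))) / 2.0 if centers.size > 1 else d
    if half_gap <= 0:
        return 1.0
    return 1.0 + BARIUM_SEED_BOOST * min(d / half_gap, 1.0)


def apply_treatment(
    pre: Volume,
    treatment: TreatmentSpec,
    rng_seed: int = 0,
    mix_noise_sigma: float | None = None,
) -> Volume:
    """Mix the layers inside one treatment ellipsoid.

    post(x) = (1 - w(x)) pre(x) + w(x) (homog + eta(x)), with
    w(x) = m(duration) * s(x); ``homog`` is the mean of ``pre`` over a 10 mm
    Z window of the 4 mm ROI column at the treatment XY location (the fully
    mixed value) and ``eta`` is zero-mean Gaussian mixing heterogeneity.
    """
    c = np.asarray(treatment.center_mm, float)
    radii = _barium_dilated_radii(treatment, pre)
    lo, hi = pre.extent
    if np.any(c - radii < lo) or np.any(c + radii > hi):
        raise ValueError("treatment ellipsoid (incl. dilation) extends outside the volume")

    if mix_noise_sigma is None:
        spec = pre.meta.get("phantom_spec", {})
        contrast = spec.get("intensity_barium", 400.0) - spec.get("intensity_plain", 60.0)
        mix_noise_sigma = MIX_NOISE_FRACTION * contrast

    # Homogenised mixed value: mean over a 4x4 mm column, 10 mm Z window.
    idx_c = pre.world_to_index(c)
    half_xy = np.maximum(np.round(2.0 / pre.spacing[:2]).astype(int), 1)
    half_z = max(int(np.round(5.0 / pre.spacing[2])), 1)
    sl = tuple(
        slice(max(int(round(idx_c[a])) - h, 0), int(round(idx_c[a])) + h + 1)
        for a, h in zip(range(3), [half_xy[0], half_xy[1], half_z])
    )
    homog = float(pre.data[sl].mean())

    m = min(mixing_strength(treatment.duration_s) * _seed_boost(treatment, pre), 1.0)
    s = _treatment_weight(pre, treatment, radii)
    w = m * s
    rng = np.random.default_rng(rng_seed)
    data = pre.data.copy()
    support = w > 0
    if np.any(support):
        eta = rng.normal(0.0, mix_noise_sigma, size=int(support.sum())) if mix_noise_sigma > 0 else 0.0
        mixed = homog + eta
        data[support] = (1.0 - w[support]) * pre.data[support] + w[support] * mixed
    out = Volume(data, pre.spacing.copy(), pre.origin.copy(), dict(pre.meta))
    out.meta["treatments"] = list(pre.meta.get("treatments", [])) + [
        asdict(treatment) | {"applied_radii_mm": radii.tolist(), "homog_value": homog}
    ]
    return out


def rigid_shift(
    volume: Volume, shift_mm: np.ndarray, rotation_deg: np.ndarray, background: float = 0.0
) -> Volume:
    """Apply a small rigid motion (rotation about the volume center, then
    translation) and resample onto the same grid with trilinear interpolation.

    The returned volume satisfies out(x) ~= in(R^-1 (x - c) + c - t): features
    move *by* ``shift_mm`` in world space.
    """
    shift = np.asarray(shift_mm, float)
    rot = np.deg2rad(np.asarray(rotation_deg, float))
    cx, cy, cz = np.cos(rot)
    sx, sy, sz = np.sin(rot)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    r = rz @ ry @ rx
    center = volume.center_mm()
    # affine_transform: in_index = A @ out_index + offset, in index space.
    a = np.diag(1.0 / volume.spacing) @ r.T @ np.diag(volume.spacing)
    offset = (
        np.diag(1.0 / volume.spacing)
        @ (r.T @ (volume.origin - center - shift) + center - volume.origin)
    )
    data = affine_transform(
        volume.data, a, offset=offset, order=1, mode="constant", cval=background
    )
    return Volume(data, volume.spacing.copy(), volume.origin.copy(), dict(volume.meta))


def _check_disjoint(treatments: Sequence[TreatmentSpec], spacing: np.ndarray) -> None:
    for i in range(len(treatments)):
        for j in range(i + 1, len(treatments)):
            ci = np.asarray(treatments[i].center_mm, float)
            cj = np.asarray(treatments[j].center_mm, float)
            d = np.abs(cj - ci)
            ri = np.asarray(treatments[i].radii_mm, float)
            rj = np.asarray(treatments[j].radii_mm, float)
            # disjoint if separated along at least one axis by the summed
            # radii plus one voxel; conservative for axis-aligned ellipsoids
            if np.all(d < ri + rj + spacing):
                raise ValueError(f"treatments {i} and {j} overlap (centers {ci} / {cj})")


def layer_centers_mm(volume: Volume, kind: str) -> np.ndarray:
    """World-Z centers (mm) of the phantom's layers of the given kind
    ("barium" or "plain"), from the simulator metadata."""
    bounds = np.asarray(volume.meta["layer_bounds_mm"], float)
    kinds = volume.meta["layer_kinds"]
    return np.array(
        [0.5 * (bounds[i] + bounds[i + 1]) for i, k in enumerate(kinds) if k == kind]
    )


def moved_point(point_mm: np.ndarray, shift_mm, rotation_deg, center_mm) -> np.ndarray:
    """Where a clean-phantom world point lands after the post-scan motion."""
    rot = np.deg2rad(np.asarray(rotation_deg, float))
    cx, cy, cz = np.cos(rot)
    sx, sy, sz = np.sin(rot)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    r = rz @ ry @ rx
    c = np.asarray(center_mm, float)
    return r @ (np.asarray(point_mm, float) - c) + c + np.asarray(shift_mm, float)


def simulate_scans(
    clean: Volume,
    treatments: Sequence[TreatmentSpec],
    scan_noise: ScanNoiseSpec | None = None,
) -> tuple[Volume, Volume, list[np.ndarray]]:
    """Turn a clean phantom into a degraded pre/post scan pair.

    Treatments are applied to the post scan, which is then rigidly moved
    per ``scan_noise`` and both scans receive blur and *independent* noise.
    Returns (pre, post, truth) with truth = treatment centers in the pre
    (plan) world frame.
    """
    noise = scan_noise if scan_noise is not None else ScanNoiseSpec()
    master = np.random.SeedSequence(int(noise.rng_seed))
    seed_pre, seed_post, seed_motion, *seed_mix = master.spawn(3 + len(treatments))

    _check_disjoint(treatments, clean.spacing)
    water = clean.meta.get("phantom_spec", {}).get("intensity_water", 0.0)

    treated = clean
    for t, ss in zip(treatments, seed_mix):
        treated = apply_treatment(
            treated,
            t,
            rng_seed=int(ss.generate_state(1)[0] % (2**31)),
            mix_noise_sigma=t.mix_noise_sigma,
        )

    shift, rot = noise.realized_motion(np.random.default_rng(seed_motion))
    moved = rigid_shift(treated, shift, rot, background=water)
    moved.meta["applied_shift_mm"] = shift.tolist()
    moved.meta["applied_rotation_deg"] = rot.tolist()

    pre = _degrade(clean, noise, np.random.default_rng(seed_pre))
    post = _degrade(moved, noise, np.random.default_rng(seed_post))
    truth = [np.asarray(t.center_mm, float) for t in treatments]
    pre.meta["truth_centers_mm"] = [c.tolist() for c in truth]
    post.meta["truth_centers_mm"] = [c.tolist() for c in truth]
    return pre, post, truth


def generate_pair(
    phantom_spec: PhantomSpec,
    treatments: Sequence[TreatmentSpec],
    scan_noise: ScanNoiseSpec | None = None,
    spacing_mm: float | Sequence[float] = DEFAULT_SPACING_MM,
    field_mm: Sequence[float] = DEFAULT_FIELD_MM,
) -> tuple[Volume, Volume, list[np.ndarray]]:
    """Simulate a pre-/post-treatment scan pair with ground truth.

    Convenience wrapper: builds the clean phantom (its layer draw seeded
    from the scan-noise seed) and runs :func:`simulate_scans`.
    """
    noise = scan_noise if scan_noise is not None else ScanNoiseSpec()
    phantom_seed = int(
        np.random.SeedSequence([int(noise.rng_seed), 97]).generate_state(1)[0] % (2**31)
    )
    clean = build_phantom_clean(phantom_spec, spacing_mm, phantom_seed, field_mm)
    return simulate_scans(clean, treatments, noise)
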