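"""Shared fixtures: all test volumes are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from histocal import (
    PhantomSpec,
    ScanNoiseSpec,
    TreatmentSpec,
    Volume,
    build_phantom_clean,
    layer_centers_mm,
    simulate_scans,
)


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def clean_phantom(phantom_spec) -> Volume:
    return build_phantom_clean(phantom_spec, rng_seed=42)


@pytest.fixture(scope="session")
def single_cloud_case(phantom_spec):
    """Default-noise pre/post pair with one 20 s cloud on a barium layer."""
    clean = build_phantom_clean(phantom_spec, rng_seed=314)
    zb = layer_centers_mm(clean, "barium")
    z = float(zb[np.argmin(np.abs(zb))])
    center = np.array([0.0, 0.0, z])
    pre, post, truth = simulate_scans(
        clean, [TreatmentSpec(tuple(center), duration_s=20.0)], ScanNoiseSpec(rng_seed=271)
    )
    return {"pre": pre, "post": post, "truth": truth[0], "clean": clean}


@pytest.fixture(scope="session")
def noiseless_cloud_case(phantom_spec):
    """Zero-noise, zero-motion pair with one 20 s cloud (plus clean phantom)."""
    clean = build_phantom_clean(phantom_spec, rng_seed=99)
    zb = layer_centers_mm(clean, "barium")
    z = float(zb[np.argmin(np.abs(zb))])
    center = np.array([0.0, 0.0, z])
    noise = ScanNoiseSpec(
        noise_sigma=0.0, shift_mm=(0.0, 0.0, 0.0), rotation_deg=(0.0, 0.0, 0.0), rng_seed=7
    )
    pre, post, truth = simulate_scans(
        clean, [TreatmentSpec(tuple(center), duration_s=20.0)], noise
    )
    return {"pre": pre, "post": post, "truth": truth[0], "clean": clean}


def make_volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> Volume:
    return Volume(np.asarray(data, dtype=float), np.asarray(spacing), np.asarray(origin))


@pytest.fixture()
def linear_field_volume() -> Volume:
    """f(x, y, z) = 2x - 3y + 0.5z + 7 sampled on an 11^3 unit grid."""
    n = 11
    idx = np.indices((n, n, n)).astype(float)
    data = 2.0 * idx[0] - 3.0 * idx[1] + 0.5 * idx[2] + 7.0
    return make_volume(data)
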