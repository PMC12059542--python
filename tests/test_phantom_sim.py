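"""Synthetic layered-phantom simulator: layer structure, mixing model,
treatment application and pre/post pair generation."""

import numpy as np
import pytest
from scipy import ndimage

from histocal import (
    PhantomSpec,
    ScanNoiseSpec,
    TreatmentSpec,
    apply_treatment,
    build_phantom_clean,
    generate_pair,
    layer_centers_mm,
    mixing_strength,
    rigid_shift,
    simulate_scans,
)
from histocal.phantom_sim import MIXING_TAU_S


class TestBuildPhantom:
    def test_layer_profile_has_five_barium_plateaus(self):
        # fixed 11-layer stack summing to 25 mm
        thick = [3.4, 1.2, 3.4, 1.2, 3.4, 1.2, 3.4, 1.2, 3.4, 1.2, 2.0]
        spec = PhantomSpec(layer_thickness_mm=thick, layer_jitter_mm=0.0)
        vol = build_phantom_clean(spec, rng_seed=0)
        half_in = np.abs(vol.origin[0] + np.arange(vol.shape[0]) * vol.spacing[0]) <= 20
        profile = vol.data[np.ix_(half_in, half_in)].mean(axis=(0, 1))
        thr = 0.5 * (spec.intensity_plain + spec.intensity_barium)
        crossings = np.diff((profile > thr).astype(int))
        assert (crossings == 1).sum() == 5  # five barium plateaus

    def test_clean_phantom_takes_exactly_three_values(self, clean_phantom, phantom_spec):
        values = np.unique(clean_phantom.data)
        expected = {
            phantom_spec.intensity_water,
            phantom_spec.intensity_plain,
            phantom_spec.intensity_barium,
        }
        assert set(values) == expected

    def test_same_seed_reproduces_volume(self, phantom_spec):
        a = build_phantom_clean(phantom_spec, rng_seed=8)
        b = build_phantom_clean(phantom_spec, rng_seed=8)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.meta["layer_bounds_mm"] == b.meta["layer_bounds_mm"]

    def test_layers_deeper_than_phantom_raise(self):
        with pytest.raises(ValueError, match="exceed"):
            PhantomSpec(layer_thickness_mm=[4.0, 2.0] * 5 + [4.0])

    def test_alternation_metadata(self, clean_phantom):
        kinds = clean_phantom.meta["layer_kinds"]
        assert kinds[0] == kinds[-1] == "plain"
        assert all(k == ("plain" if i % 2 == 0 else "barium") for i, k in enumerate(kinds))


class TestMixingStrength:
    def test_saturates_at_m_max(self):
        assert mixing_strength(1e9) == pytest.approx(1.0)
        assert mixing_strength(1e9, m_max=0.7) == pytest.approx(0.7)

    def test_20s_to_5s_contrast_ratio(self):
        # closed form (1 - exp(-20/tau)) / (1 - exp(-5/tau)) at the default tau
        expected = (1 - np.exp(-20 / MIXING_TAU_S)) / (1 - np.exp(-5 / MIXING_TAU_S))
        assert mixing_strength(20.0) / mixing_strength(5.0) == pytest.approx(expected)
        assert expected == pytest.approx(2.34, abs=0.01)

    def test_strictly_increasing(self):
        t = np.linspace(0.5, 60, 100)
        m = np.array([mixing_strength(v) for v in t])
        assert np.all(np.diff(m) > 0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            mixing_strength(0.0)


class TestApplyTreatment:
    def test_vanishing_duration_is_noop(self, clean_phantom):
        treat = TreatmentSpec((0.0, 0.0, 0.0), duration_s=1e-9)
        post = apply_treatment(clean_phantom, treat, rng_seed=0, mix_noise_sigma=0.0)
        np.testing.assert_allclose(post.data, clean_phantom.data, atol=1e-5)

    def test_full_mixing_center_equals_homogenized_value(self, clean_phantom):
        treat = TreatmentSpec((0.0, 0.0, 0.0), duration_s=1e9)  # m -> 1
        post = apply_treatment(clean_phantom, treat, rng_seed=0, mix_noise_sigma=0.0)
        homog = post.meta["treatments"][-1]["homog_value"]
        center_idx = np.round(post.world_to_index(np.zeros(3))).astype(int)
        assert post.data[tuple(center_idx)] == pytest.approx(homog, rel=1e-12)

    def test_mean_change_increases_with_duration(self, clean_phantom):
        center = np.zeros(3)
        radii = np.array([2.0, 2.0, 4.0])
        w = [clean_phantom.origin[a] + np.arange(clean_phantom.shape[a]) * clean_phantom.spacing[a] for a in range(3)]
        nx, ny, nz = [(w[a] - center[a]) / radii[a] for a in range(3)]
        inside = nx[:, None, None] ** 2 + ny[None, :, None] ** 2 + nz[None, None, :] ** 2 <= 1
        means = []
        for dur in (5.0, 10.0, 15.0, 20.0):
            post = apply_treatment(
                clean_phantom, TreatmentSpec(tuple(center), duration_s=dur), rng_seed=4
            )
            means.append(np.abs(post.data - clean_phantom.data)[inside].mean())
        assert np.all(np.diff(means) > 0)

    def test_voxels_outside_support_untouched(self, clean_phantom):
        treat = TreatmentSpec((5.0, 5.0, 0.0), duration_s=20.0)
        post = apply_treatment(clean_phantom, treat, rng_seed=1)
        changed = np.argwhere(post.data != clean_phantom.data)
        w = clean_phantom.index_to_world(changed)
        # all changed voxels lie within the (dilated) ellipsoid bounding box
        radii = np.array(post.meta["treatments"][-1]["applied_radii_mm"])
        assert np.all(np.abs(w - np.array([5.0, 5.0, 0.0])) <= radii + 1e-9)

    def test_ellipsoid_outside_phantom_raises(self, clean_phantom):
        with pytest.raises(ValueError, match="outside"):
            apply_treatment(clean_phantom, TreatmentSpec((0.0, 0.0, 40.0)))


class TestGeneratePair:
    def test_argmax_of_difference_inside_ellipsoid(self, noiseless_cloud_case):
        pre, post, truth = (
            noiseless_cloud_case["pre"],
            noiseless_cloud_case["post"],
            noiseless_cloud_case["truth"],
        )
        diff = np.abs(post.data - pre.data)
        idx = np.array(np.unravel_index(np.argmax(diff), diff.shape))
        w = pre.index_to_world(idx)
        assert np.all(np.abs(w - truth) <= np.array([2.0, 2.0, 5.0]) + pre.spacing)

    def test_same_seeds_give_bit_identical_pair(self, phantom_spec):
        treats = [TreatmentSpec((0.0, 0.0, 0.0), duration_s=20.0)]
        a = generate_pair(phantom_spec, treats, ScanNoiseSpec(rng_seed=17))
        b = generate_pair(phantom_spec, treats, ScanNoiseSpec(rng_seed=17))
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].data, b[1].data)

    def test_pre_and_post_noise_streams_differ(self, phantom_spec):
        pre, post, _ = generate_pair(phantom_spec, [], ScanNoiseSpec(rng_seed=23, shift_mm=(0, 0, 0), rotation_deg=(0, 0, 0)))
        assert not np.array_equal(pre.data, post.data)

    def test_calibration_pattern_gives_four_components(self, phantom_spec):
        p0 = np.array([0.0, -15.0, -1.0])
        treats = [
            TreatmentSpec(tuple(p0 + k * np.array([0.0, 10.0, 1.0])), duration_s=20.0)
            for k in range(4)
        ]
        noise = ScanNoiseSpec(noise_sigma=0.0, shift_mm=(0, 0, 0), rotation_deg=(0, 0, 0), rng_seed=2)
        pre, post, _ = generate_pair(phantom_spec, treats, noise)
        from histocal import difference_image

        d = difference_image(pre, post)
        # within a zone the plain-layer gaps dip below half-max (layered
        # contrast); at quarter-max each treatment is one connected zone
        labels, n = ndimage.label(d.data > 0.25 * d.data.max())
        assert n == 4
        centroids = ndimage.center_of_mass(d.data, labels, range(1, 5))
        worlds = sorted(d.index_to_world(np.array(c))[1] for c in centroids)
        np.testing.assert_allclose(worlds, [t.center_mm[1] for t in treats], atol=1.0)

    def test_overlapping_treatments_rejected(self, phantom_spec):
        treats = [
            TreatmentSpec((0.0, 0.0, 0.0), duration_s=20.0),
            TreatmentSpec((1.0, 1.0, 0.0), duration_s=20.0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            generate_pair(phantom_spec, treats)


def test_rigid_shift_by_one_voxel_moves_indices(clean_phantom):
    pitch = clean_phantom.spacing.copy()
    out = rigid_shift(clean_phantom, pitch, (0.0, 0.0, 0.0))
    np.testing.assert_allclose(
        out.data[1:, 1:, 1:], clean_phantom.data[:-1, :-1, :-1], atol=1e-9
    )


def test_layer_centers_lookup(clean_phantom):
    zb = layer_centers_mm(clean_phantom, "barium")
    zp = layer_centers_mm(clean_phantom, "plain")
    assert len(zb) == 5 and len(zp) == 6
    assert np.all(np.diff(np.sort(np.concatenate([zb, zp]))) > 0)
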