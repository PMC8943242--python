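"""Phantom generation, lesion shapes, insertion, compression, downsampling."""

import numpy as np
import pytest

from usdot.phantom import (
    LabelVolume,
    LesionSpec,
    PhantomConfig,
    PhantomError,
    TISSUE_INDEX,
    compress,
    downsample_labels,
    equivalent_radius,
    generate_lesion_shape,
    generate_phantom,
    insert_lesion,
)


def test_generation_is_deterministic_and_matches_fat_fraction(small_phantom_config,
                                                              small_phantom):
    again = generate_phantom(small_phantom_config, rng_seed=1)
    assert np.array_equal(small_phantom.labels, again.labels)
    lab = small_phantom.labels
    soft = (lab != TISSUE_INDEX["air"]) & (lab != TISSUE_INDEX["skin"])
    adipose_frac = (lab == TISSUE_INDEX["adipose"]).sum() / soft.sum()
    assert 0.5 <= adipose_frac <= 0.7


def test_pure_fat_degenerate_composition():
    cfg = PhantomConfig(fat_fraction=1.0, fine_spacing=1.0, coarse_spacing=4.0,
                        enable_structures=False)
    vol = generate_phantom(cfg, rng_seed=0)
    lab = vol.labels
    interior = (lab != TISSUE_INDEX["air"]) & (lab != TISSUE_INDEX["skin"])
    assert np.all(lab[interior] == TISSUE_INDEX["adipose"])


def test_domain_too_thin_for_skin_raises():
    cfg = PhantomConfig(domain_size=(20.0, 20.0, 3.0), fine_spacing=1.0, coarse_spacing=2.0)
    with pytest.raises(PhantomError):
        generate_phantom(cfg, rng_seed=0)


def test_sphere_limit_volume_and_radius():
    mask = generate_lesion_shape(LesionSpec(mean_radius=6.0, irregularity=0.0), spacing=0.5)
    vol = mask.sum() * 0.5**3
    assert abs(vol - 4.0 / 3.0 * np.pi * 6.0**3) / (4.0 / 3.0 * np.pi * 6.0**3) < 0.05
    assert 5.1 <= equivalent_radius(mask, 0.5) <= 6.9


def test_irregular_shape_reproducible_single_component_rougher():
    from scipy import ndimage

    spec = LesionSpec(mean_radius=8.0, irregularity=0.5, rng_seed=11)
    m1 = generate_lesion_shape(spec, 0.5)
    m2 = generate_lesion_shape(spec, 0.5)
    assert np.array_equal(m1, m2)
    _, n = ndimage.label(m1)
    assert n == 1
    assert abs(equivalent_radius(m1, 0.5) - 8.0) / 8.0 < 0.15

    def surface_to_volume(m):
        surf = 0
        for ax in range(3):
            surf += np.count_nonzero(np.diff(m.astype(int), axis=ax) != 0)
        return surf / m.sum()

    sphere = generate_lesion_shape(LesionSpec(mean_radius=8.0, irregularity=0.0), 0.5)
    assert surface_to_volume(m1) >= surface_to_volume(sphere) * 0.999


def test_radius_below_resolvable_raises():
    with pytest.raises(PhantomError):
        generate_lesion_shape(LesionSpec(mean_radius=2.5), spacing=2.0)


def test_insert_locality_and_imaging_plane_constraint(small_phantom, lesion_mask_8mm):
    vol = insert_lesion(small_phantom, lesion_mask_8mm, rng_seed=4)
    changed = vol.labels != small_phantom.labels
    assert np.all(vol.labels[changed] == TISSUE_INDEX["lesion"])
    assert changed.sum() <= lesion_mask_8mm.sum()
    # |y_com| <= 0.3 l where l is the mask's maximum y extent
    les = np.argwhere(vol.labels == TISSUE_INDEX["lesion"])
    ycen = vol.voxel_centers(1)
    y_com = ycen[les[:, 1]].mean()
    l_mm = lesion_mask_8mm.shape[1] * vol.spacing
    assert abs(y_com) <= 0.3 * l_mm


def test_insert_placement_constraint_across_many_seeds(small_phantom, lesion_mask_8mm):
    l_mm = lesion_mask_8mm.shape[1] * small_phantom.spacing
    ycen = small_phantom.voxel_centers(1)
    for seed in range(100):
        vol = insert_lesion(small_phantom, lesion_mask_8mm, rng_seed=seed)
        les = np.argwhere(vol.labels == TISSUE_INDEX["lesion"])
        assert abs(ycen[les[:, 1]].mean()) <= 0.3 * l_mm


def test_insert_into_all_skin_volume_raises():
    labels = np.full((30, 30, 30), TISSUE_INDEX["skin"], dtype=np.int16)
    vol = LabelVolume(labels, 1.0, origin=np.array([-15.0, -15.0, 0.0]))
    mask = np.ones((5, 5, 5), dtype=bool)
    with pytest.raises(PhantomError):
        insert_lesion(vol, mask, rng_seed=0)


def test_compress_extent_volume_and_identity(small_phantom):
    target = 45.0
    out = compress(small_phantom, target)
    breast = out.breast_mask()
    z = np.nonzero(breast.any(axis=(0, 1)))[0]
    extent = (z[-1] - z[0] + 1) * out.spacing
    assert abs(extent - target) <= out.spacing
    v_ratio = breast.sum() / small_phantom.breast_mask().sum()
    assert abs(v_ratio - 1.0) <= 0.10
    assert set(np.unique(out.labels)) <= set(np.unique(small_phantom.labels))
    # compressing to the current thickness is the identity
    same = compress(out, target)
    assert np.array_equal(same.labels, out.labels)


def test_downsample_majority_air_rule_and_roundtrip(small_phantom):
    uniform = LabelVolume(
        np.full((8, 8, 8), TISSUE_INDEX["glandular"], dtype=np.int16), 0.5
    )
    coarse = downsample_labels(uniform, 4)
    assert coarse.labels.shape == (2, 2, 2)
    assert np.all(coarse.labels == TISSUE_INDEX["glandular"])
    assert coarse.spacing == 2.0

    # an air-majority corner in an adipose-dominated volume becomes adipose
    lab = np.full((4, 4, 4), TISSUE_INDEX["adipose"], dtype=np.int16)
    lab[:3, :3, :3] = TISSUE_INDEX["air"]
    filled = downsample_labels(LabelVolume(lab, 1.0), 4)
    assert filled.labels.reshape(-1)[0] == TISSUE_INDEX["adipose"]

    # down/up-sampling keeps most labels on a smooth phantom
    coarse = downsample_labels(small_phantom, 5)
    up = np.repeat(np.repeat(np.repeat(coarse.labels, 5, 0), 5, 1), 5, 2)
    up = up[: small_phantom.labels.shape[0], : small_phantom.labels.shape[1],
            : small_phantom.labels.shape[2]]
    nonair = small_phantom.labels != TISSUE_INDEX["air"]
    agreement = (up[nonair] == small_phantom.labels[nonair]).mean()
    assert agreement >= 0.70


def test_depth_band_constrains_lesion(small_phantom, lesion_mask_8mm):
    vol = insert_lesion(compress(small_phantom, 45.0), lesion_mask_8mm, rng_seed=2,
                        z_range=(2.0, 29.0))
    les = np.argwhere(vol.labels == TISSUE_INDEX["lesion"])
    zmax = (les[:, 2].max() + 1) * vol.spacing
    assert zmax <= 29.0 + 1e-9
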