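"""Topographic rendering, frame stacking and the super-pixel feature mask."""

import numpy as np
import pytest

from cfsimage.cfs import CFSMatrix
from cfsimage.imaging import (CFSImageSequence, build_feature_mask,
                              group_topoplots, in_hull_mask, interpolate_at,
                              render_layer, stack_frames)

TRIPLET = (("Theta", "Gamma"), ("Alpha", "Beta"), ("Beta", "Gamma"))


def test_constant_field_is_reproduced_everywhere(projected, grid):
    img = render_layer(np.full(31, 0.7), projected, grid=grid)
    hull = in_hull_mask(projected, grid)
    np.testing.assert_allclose(img[hull], 0.7, atol=1e-9)
    assert np.all(img[~hull] == 0.0)


def test_affine_field_exact_at_electrode_sites(projected):
    values = 0.3 + 0.2 * projected.coords[:, 0] - 0.1 * projected.coords[:, 1]
    at_sites = interpolate_at(values, projected, projected.coords)
    np.testing.assert_allclose(at_sites, values, atol=1e-9)


def test_affine_field_reproduced_on_interior_pixels(projected, grid):
    values = 0.5 + 0.1 * projected.coords[:, 0] + 0.2 * projected.coords[:, 1]
    img = render_layer(values, projected, grid=grid)
    hull = in_hull_mask(projected, grid)
    xx, yy = np.meshgrid(grid.x, grid.y)
    expected = 0.5 + 0.1 * xx + 0.2 * yy
    np.testing.assert_allclose(img[hull], expected[hull], atol=1e-7)


def test_one_hot_field_peaks_at_its_electrode(projected, grid):
    idx = list(projected.names).index("Pz")
    values = np.zeros(31)
    values[idx] = 1.0
    img = render_layer(values, projected, grid=grid)
    peak = np.unravel_index(np.argmax(img), img.shape)
    px, py = grid.x[peak[1]], grid.y[peak[0]]
    target = projected.coord("Pz")
    pitch = grid.x[1] - grid.x[0]
    assert np.hypot(px - target[0], py - target[1]) <= 1.5 * pitch


def test_mesh_size_contract(projected):
    assert render_layer(np.zeros(31), projected, mesh=32).shape == (32, 32)
    assert render_layer(np.zeros(31), projected, mesh=16).shape == (16, 16)


def test_nan_value_rejected(projected):
    values = np.zeros(31)
    values[3] = np.nan
    with pytest.raises(ValueError, match="finite"):
        render_layer(values, projected)


# -- frame stacking ---------------------------------------------------------

def _matrix(rng, n_seg=4):
    values = rng.uniform(0, 1, (31, 3, n_seg))
    return CFSMatrix(values, TRIPLET,
                     tuple(f"e{i}" for i in range(31)))


def test_stack_frames_geometry(rng, projected):
    mat = _matrix(rng)
    mat = CFSMatrix(mat.values, TRIPLET, projected.names, subject_id="s1",
                    label="control")
    seq = stack_frames(mat, TRIPLET, projected)
    assert seq.frames.shape == (4, 32, 32, 3)
    assert seq.n_frames == 4
    assert seq.band_pairs == TRIPLET
    in_hull = seq.frames[:, seq.hull, :]
    assert in_hull.min() >= -1e-9 and in_hull.max() <= 1 + 1e-9


def test_zero_cfs_renders_black_and_unit_renders_white(projected):
    zeros = CFSMatrix(np.zeros((31, 3, 1)), TRIPLET, projected.names)
    seq = stack_frames(zeros, TRIPLET, projected)
    np.testing.assert_array_equal(seq.frames, 0.0)
    ones = CFSMatrix(np.ones((31, 3, 1)), TRIPLET, projected.names)
    white = stack_frames(ones, TRIPLET, projected)
    np.testing.assert_allclose(white.frames[0][white.hull], 1.0, atol=1e-9)


def test_triplet_arity_enforced(rng, projected):
    mat = CFSMatrix(rng.uniform(0, 1, (31, 3, 2)), TRIPLET, projected.names)
    with pytest.raises(ValueError, match="3 band pairs"):
        stack_frames(mat, TRIPLET[:2], projected)


def test_sequence_container_round_trip(rng, projected, tmp_path):
    mat = CFSMatrix(rng.uniform(0, 1, (31, 3, 2)), TRIPLET, projected.names,
                    subject_id="s", label="dyslexic")
    seq = stack_frames(mat, TRIPLET, projected)
    seq.save(tmp_path / "seq.npz")
    back = CFSImageSequence.load(tmp_path / "seq.npz")
    np.testing.assert_array_equal(back.frames, seq.frames)
    assert back.label == "dyslexic"


# -- feature mask -----------------------------------------------------------

def test_mask_has_31_superpixels_partitioning_the_hull(feature_mask, projected,
                                                       grid):
    labels = feature_mask.labels
    hull = in_hull_mask(projected, grid)
    assert feature_mask.n_superpixels == 31
    assert set(np.unique(labels[hull])) == set(range(1, 32))
    # out-of-hull pixels are unlabelled, except the snapped nearest pixels
    # of hull-vertex electrodes
    assert np.sum(labels[~hull] > 0) <= len(projected)
    # partition: every labelled pixel carries exactly one label
    sizes = [feature_mask.pixels_of(e).sum() for e in projected.names]
    assert sum(sizes) == np.sum(labels > 0)
    assert min(sizes) >= 1


def test_each_electrode_claims_its_own_pixel(feature_mask, projected, grid):
    for name in projected.names:
        x, y = projected.coord(name)
        j = int(np.argmin(np.abs(grid.x - x)))
        i = int(np.argmin(np.abs(grid.y - y)))
        label = feature_mask.labels[i, j]
        assert label == list(projected.names).index(name) + 1


def test_mask_consistent_with_one_hot_rendering(feature_mask, projected, grid):
    """The electrode whose one-hot layer dominates a pixel at an electrode's
    projected coordinate is the electrode the mask assigns there."""
    for name in ("FC5", "TP9", "Oz"):
        idx = list(projected.names).index(name)
        values = np.zeros(31)
        values[idx] = 1.0
        img = render_layer(values, projected, grid=grid)
        region = feature_mask.pixels_of(name)
        assert img[region].max() == pytest.approx(img.max(), abs=1e-9)


def test_duplicate_coordinates_rejected(projected):
    import dataclasses

    broken = dataclasses.replace(projected)
    broken.coords = projected.coords.copy()
    broken.coords[1] = broken.coords[0]
    with pytest.raises(ValueError, match="duplicate"):
        build_feature_mask(broken)


# -- group topographies -----------------------------------------------------

def test_single_subject_group_average_is_identity(rng, projected):
    mat = CFSMatrix(rng.uniform(0, 1, (31, 3, 2)), TRIPLET, projected.names)
    images, means = group_topoplots([mat], ["control"], ("Alpha", "Beta"),
                                    projected=projected)
    np.testing.assert_array_equal(means["control"], mat.pair(("Alpha", "Beta")))
    direct = render_layer(mat.pair(("Alpha", "Beta"))[:, 0], projected)
    np.testing.assert_allclose(images[("control", 0)], direct, atol=1e-12)


def test_identical_groups_give_identical_panels(rng, projected):
    mat = CFSMatrix(rng.uniform(0, 1, (31, 3, 1)), TRIPLET, projected.names)
    images, _ = group_topoplots([mat, mat], ["a", "b"], ("Alpha", "Beta"),
                                projected=projected)
    np.testing.assert_array_equal(images[("a", 0)], images[("b", 0)])


def test_group_difference_map_peaks_at_differing_electrode(rng, projected):
    """A dyslexic-only coupling raised at TP9 makes the DX-CN difference
    topography maximal at TP9's projected location."""
    base = rng.uniform(0.0, 0.05, (31, 3, 1))
    cn = CFSMatrix(base, TRIPLET, projected.names)
    raised = base.copy()
    raised[list(projected.names).index("TP9"), :, :] += 0.8
    dx = CFSMatrix(raised, TRIPLET, projected.names)
    images, _ = group_topoplots([cn, dx], ["CN", "DX"], ("Theta", "Gamma"),
                                projected=projected)
    diff = images[("DX", 0)] - images[("CN", 0)]
    mask = build_feature_mask(projected)
    peak_label = mask.labels[np.unravel_index(np.argmax(diff), diff.shape)]
    assert mask.electrode_names[peak_label - 1] == "TP9"


def test_empty_group_rejected(rng, projected):
    mat = CFSMatrix(rng.uniform(0, 1, (31, 3, 1)), TRIPLET, projected.names)
    with pytest.raises(ValueError, match="one group label"):
        group_topoplots([mat], [], ("Alpha", "Beta"), projected=projected)
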