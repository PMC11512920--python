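"""Feature-mask LIME: perturbation, kernel, surrogate and aggregation."""

import numpy as np
import pytest

from cfsimage.explain import (DEFAULT_N_SAMPLES, ExplanationMap,
                              explain_frame, explain_sequence, kernel_weight,
                              perturb_frame, render_relevance,
                              top_superpixels)


class PlantedModel:
    """Oracle model whose positive-class probability is a known linear
    function of one super-pixel's mean pixel value."""

    def __init__(self, mask, electrode):
        self.region = mask.pixels_of(electrode)

    def predict_proba(self, sequences):
        sequences = np.asarray(sequences)
        if sequences.ndim == 4:
            sequences = sequences[None]
        level = sequences[:, 0][:, self.region].mean(axis=1)
        p = 0.1 + 0.8 * np.clip(level, 0, 1)
        return np.column_stack([1 - p, p])


class ConstantModel:
    def predict_proba(self, sequences):
        sequences = np.asarray(sequences)
        n = 1 if sequences.ndim == 4 else sequences.shape[0]
        return np.tile([0.3, 0.7], (n, 1))


def planted_sequence(mask, rng, frames=3):
    seq = rng.uniform(0.0, 0.1, (frames,) + mask.labels.shape + (3,))
    seq[:, mask.labels > 0, :] += 0.1
    return seq


# -- perturbation -----------------------------------------------------------

def test_all_ones_design_reproduces_original(feature_mask, rng):
    seq = planted_sequence(feature_mask, rng)
    pset = perturb_frame(seq, 1, feature_mask, n_samples=16, seed=0)
    assert np.all(pset.designs[0] == 1)
    np.testing.assert_array_equal(pset.frames[0], seq[1])
    np.testing.assert_array_equal(pset.sequence(0), seq)


def test_perturbation_touches_only_chosen_frame(feature_mask, rng):
    seq = planted_sequence(feature_mask, rng)
    pset = perturb_frame(seq, 1, feature_mask, n_samples=64, seed=0)
    i = int(np.argmin(pset.designs.sum(axis=1)))  # most super-pixels off
    rebuilt = pset.sequence(i)
    np.testing.assert_array_equal(rebuilt[0], seq[0])
    np.testing.assert_array_equal(rebuilt[2], seq[2])
    off = np.flatnonzero(pset.designs[i] == 0)
    off_region = np.isin(feature_mask.labels, off + 1)
    assert np.all(rebuilt[1][off_region] == 0.0)


def test_off_superpixels_are_zeroed_exactly(feature_mask, rng):
    seq = planted_sequence(feature_mask, rng)
    pset = perturb_frame(seq, 0, feature_mask, n_samples=32, seed=1)
    i = 7
    off = np.flatnonzero(pset.designs[i] == 0)
    for j in off:
        region = feature_mask.labels == j + 1
        assert np.all(pset.frames[i][region] == 0.0)
    on = np.flatnonzero(pset.designs[i] == 1)
    for j in on[:3]:
        region = feature_mask.labels == j + 1
        np.testing.assert_array_equal(pset.frames[i][region], seq[0][region])


def test_default_sample_count_is_ten_thousand():
    assert DEFAULT_N_SAMPLES == 10_000


def test_perturbation_bounds(feature_mask, rng):
    seq = planted_sequence(feature_mask, rng)
    with pytest.raises(IndexError):
        perturb_frame(seq, 99, feature_mask, n_samples=4)
    with pytest.raises(ValueError, match="at least 2"):
        perturb_frame(seq, 0, feature_mask, n_samples=1)


# -- kernel -----------------------------------------------------------------

def test_kernel_weight_examples(rng):
    x = rng.random((8, 8, 3))
    assert kernel_weight(x, x, width=1.0) == pytest.approx(1.0)
    z = x.copy()
    z[0, 0, 0] += 0.5
    d = np.linalg.norm(x - z)
    assert kernel_weight(x, z, width=d) == pytest.approx(np.exp(-1.0))


def test_kernel_weight_monotone_in_distance(rng):
    x = np.zeros((4, 4, 3))
    previous = 1.0
    for step in (0.1, 0.2, 0.4, 0.8):
        z = np.full_like(x, step)
        w = kernel_weight(x, z, width=1.0)
        assert w < previous
        previous = w


def test_kernel_width_validation(rng):
    x = np.zeros((2, 2, 3))
    with pytest.raises(ValueError, match="width"):
        kernel_weight(x, x, width=0.0)


# -- surrogate fitting ------------------------------------------------------

def test_constant_model_yields_zero_coefficients(feature_mask, rng):
    seq = planted_sequence(feature_mask, rng)
    coef, _ = explain_frame(ConstantModel(), seq, 0, feature_mask,
                            n_samples=200, seed=0, explained_class=1)
    np.testing.assert_allclose(coef, 0.0, atol=1e-9)


def test_planted_superpixel_dominates_explanation(feature_mask, rng):
    model = PlantedModel(feature_mask, "FC5")
    seq = planted_sequence(feature_mask, rng)
    seq[0][feature_mask.pixels_of("FC5")] = 0.9
    coef, fidelity = explain_frame(model, seq, 0, feature_mask,
                                   n_samples=800, seed=0, explained_class=1,
                                   lasso_penalty=1e-4)
    idx = feature_mask.electrode_names.index("FC5")
    others = np.delete(np.abs(coef), idx)
    assert abs(coef[idx]) > 5 * others.max()
    assert fidelity >= 0.99


def test_fixed_seed_reproducible(feature_mask, rng):
    model = PlantedModel(feature_mask, "Pz")
    seq = planted_sequence(feature_mask, rng)
    a, _ = explain_frame(model, seq, 1, feature_mask, n_samples=300, seed=9,
                         explained_class=1)
    b, _ = explain_frame(model, seq, 1, feature_mask, n_samples=300, seed=9,
                         explained_class=1)
    np.testing.assert_array_equal(a, b)


def test_zero_penalty_limit_matches_weighted_least_squares(feature_mask, rng):
    """Shrinking the lasso penalty converges to the closed-form weighted
    least-squares solution on the same design."""
    from cfsimage.explain import _fit_surrogate, _surrogate_scores

    model = PlantedModel(feature_mask, "Oz")
    seq = planted_sequence(feature_mask, rng)
    pset = perturb_frame(seq, 0, feature_mask, n_samples=400, seed=2)
    scores = _surrogate_scores(model, pset, 1)
    d2 = np.sum((pset.frames - seq[0]) ** 2, axis=(1, 2, 3))
    weights = np.exp(-d2 / (2 * np.median(d2[1:])))

    X = np.column_stack([np.ones(len(scores)), pset.designs.astype(float)])
    sw = np.sqrt(weights)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], scores * sw, rcond=None)

    gaps = []
    for alpha in (1e-3, 1e-6, 1e-9):
        coef, _ = _fit_surrogate(pset.designs, scores, weights, alpha)
        gaps.append(np.max(np.abs(coef - beta[1:])))
    assert gaps[-1] <= gaps[0]
    assert gaps[-1] < 1e-6


# -- sequence maps and aggregation ------------------------------------------

def test_sequence_map_shape_and_zero_rows(feature_mask, rng):
    model = PlantedModel(feature_mask, "Pz")  # reads frame 0 only
    seq = planted_sequence(feature_mask, rng, frames=3)
    emap = explain_sequence(model, seq, feature_mask, n_samples=200, seed=0,
                            explained_class=1)
    assert emap.coefficients.shape == (3, 31)
    # frames the model ignores explain to (near) zero rows
    np.testing.assert_allclose(emap.coefficients[2], 0.0, atol=1e-6)
    frame = emap.to_dataframe()
    assert len(frame) == 3 * 31
    assert frame.frame.min() == 1  # 1-based in reports


def test_top_superpixels_ranking_and_order_invariance(feature_mask):
    t, d = 2, 31
    a = ExplanationMap(np.zeros((t, d)), 1, np.ones(t),
                       feature_mask.electrode_names, "a")
    b = ExplanationMap(np.zeros((t, d)), 1, np.ones(t),
                       feature_mask.electrode_names, "b")
    a.coefficients[0, 3] = 0.9
    b.coefficients[0, 3] = 0.5
    a.coefficients[0, 7] = -0.6
    b.coefficients[0, 7] = -0.8
    mean_ab, rank_ab = top_superpixels([a, b], k=2)
    mean_ba, rank_ba = top_superpixels([b, a], k=2)
    np.testing.assert_array_equal(mean_ab, mean_ba)
    assert rank_ab == rank_ba
    assert rank_ab[0] == [feature_mask.electrode_names[3],
                          feature_mask.electrode_names[7]]


def test_opposite_coefficients_cancel(feature_mask):
    t, d = 1, 31
    a = ExplanationMap(np.zeros((t, d)), 1, np.ones(t),
                       feature_mask.electrode_names)
    b = ExplanationMap(np.zeros((t, d)), 1, np.ones(t),
                       feature_mask.electrode_names)
    a.coefficients[0, 5] = 0.7
    b.coefficients[0, 5] = -0.7
    mean_map, _ = top_superpixels([a, b], k=5)
    assert mean_map[0, 5] == pytest.approx(0.0, abs=1e-15)


def test_single_subject_ranking_is_sorted_magnitudes(feature_mask, rng):
    coefs = rng.normal(size=(1, 31))
    emap = ExplanationMap(coefs, 0, np.ones(1), feature_mask.electrode_names)
    _, ranking = top_superpixels([emap], k=31)
    mags = [abs(coefs[0, feature_mask.electrode_names.index(e)])
            for e in ranking[0]]
    assert mags == sorted(mags, reverse=True)


def test_relevance_rendering_signs(feature_mask):
    values = np.zeros(31)
    values[0], values[1] = 0.8, -0.4
    img = render_relevance(feature_mask, values, top_k=5)
    pos = feature_mask.pixels_of(feature_mask.electrode_names[0])
    neg = feature_mask.pixels_of(feature_mask.electrode_names[1])
    assert np.all(img[pos][:, 1] > 0) and np.all(img[pos][:, 0] == 0)
    assert np.all(img[neg][:, 0] > 0) and np.all(img[neg][:, 1] == 0)


def test_empty_aggregation_rejected():
    with pytest.raises(ValueError, match="no explanation maps"):
        top_superpixels([])
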