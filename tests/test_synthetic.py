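"""Synthetic EEG generation: calibration, determinism, export."""

import numpy as np
import pytest
from scipy.special import i0e, i1e

import mne

from cfsimage.bands import extract_phases
from cfsimage.cfs import SegmentationSpec, cfs_matrix, cfs_value
from cfsimage.montage import MontageError
from cfsimage.synthetic import (ClassTemplate, CouplingSpec,
                                coupling_to_concentration, default_templates,
                                difference_electrodes, generate_subject,
                                make_cohort, pink_noise, read_matrix,
                                write_edf, write_manifest, write_matrix)


def bessel_ratio(kappa):
    return i1e(kappa) / i0e(kappa)


# -- von Mises calibration --------------------------------------------------

def test_zero_coupling_is_uniform_noise():
    assert coupling_to_concentration(0.0) == 0.0


def test_full_coupling_returns_degenerate_sentinel():
    assert np.isinf(coupling_to_concentration(1.0))


@pytest.mark.parametrize("bad", [-0.1, 1.0001])
def test_out_of_range_target_rejected(bad):
    with pytest.raises(ValueError):
        coupling_to_concentration(bad)


@pytest.mark.parametrize("target", [0.1, 0.3, 0.5, 0.7, 0.9])
def test_concentration_inverts_bessel_ratio(target):
    kappa = coupling_to_concentration(target)
    assert bessel_ratio(kappa) == pytest.approx(target, abs=1e-7)


def test_monte_carlo_resultant_of_high_concentration(rng):
    # 1e6 draws at the kappa for 0.9: empirical resultant within 5e-3
    kappa = coupling_to_concentration(0.9)
    draws = rng.vonmises(0.0, kappa, 1_000_000)
    assert np.abs(np.mean(np.exp(1j * draws))) == pytest.approx(0.9, abs=5e-3)


def test_end_to_end_phase_pair_recovery(rng):
    # jittering one phase series by von Mises noise at the calibrated kappa
    # yields the target synchronisation through the estimator
    kappa = coupling_to_concentration(0.5)
    phi = rng.uniform(-np.pi, np.pi, 100_000)
    jittered = phi + rng.vonmises(0.0, kappa, phi.size)
    assert cfs_value(jittered, phi) == pytest.approx(0.5, abs=0.01)


@pytest.mark.parametrize("target", [0.1, 0.3, 0.5, 0.7, 0.9])
def test_estimator_recovers_targets_within_monte_carlo_error(rng, target):
    # n = 2500 phase pairs; tolerance three Monte-Carlo standard errors of
    # the von Mises resultant estimate
    n = 2500
    kappa = coupling_to_concentration(target)
    phi = rng.uniform(-np.pi, np.pi, n)
    est = cfs_value(phi + rng.vonmises(0.0, kappa, n), phi)
    se = np.sqrt((1 - target ** 2) / (2 * n)) + 1 / np.sqrt(n)
    assert est == pytest.approx(target, abs=3 * se)


# -- spectral background ----------------------------------------------------

def test_pink_noise_spectrum_slope(rng):
    x = pink_noise(2 ** 16, 1.0, rng)
    freqs = np.fft.rfftfreq(x.size, 1 / 500.0)
    power = np.abs(np.fft.rfft(x)) ** 2
    lo = (freqs > 1) & (freqs < 10)
    hi = (freqs > 20) & (freqs < 200)
    ratio = power[lo].mean() / power[hi].mean()
    # 1/f: mean-per-bin power ratio between decades roughly 10-ish
    assert 5 < ratio < 40
    assert x.std() == pytest.approx(1.0, abs=1e-9)


# -- subject generation -----------------------------------------------------

def test_generation_is_deterministic_and_correct_size():
    template, _ = default_templates()
    a = generate_subject(template, duration_s=150.0, sfreq=500.0, seed=11)
    b = generate_subject(template, duration_s=150.0, sfreq=500.0, seed=11)
    assert a.data.shape == (31, 75_000)
    np.testing.assert_array_equal(a.data, b.data)
    assert generate_subject(template, seed=12).data[0, 0] != a.data[0, 0]


def test_channels_are_standardised_and_finite():
    template, _ = default_templates()
    rec = generate_subject(template, duration_s=20.0, seed=0)
    assert np.all(np.isfinite(rec.data))
    np.testing.assert_allclose(rec.data.mean(axis=1), 0.0, atol=1e-12)
    np.testing.assert_allclose(rec.data.std(axis=1), 1.0, atol=1e-12)


def test_unknown_electrode_rejected():
    template = ClassTemplate("x", (CouplingSpec("XX9", ("Alpha", "Beta"), 0.5),))
    with pytest.raises(MontageError):
        generate_subject(template, duration_s=10.0, seed=0)


def test_disjoint_pair_coupling_warns():
    template = ClassTemplate("x", (CouplingSpec("FC5", ("Theta", "Gamma"), 0.5),))
    with pytest.warns(RuntimeWarning, match="no filter edge"):
        generate_subject(template, duration_s=10.0, seed=0)


def test_coupling_spec_validation():
    with pytest.raises(ValueError, match="distinct"):
        CouplingSpec("Pz", ("Alpha", "Alpha"), 0.5)
    with pytest.raises(ValueError, match="onset"):
        CouplingSpec("Pz", ("Alpha", "Beta"), 0.5, onset_segment=5,
                     offset_segment=2)


def test_injected_coupling_recovered_through_pipeline():
    """The headline generator contract: a strong Alpha-Beta coupling at FC5
    shows up at FC5 through filtering, phase extraction and the
    synchronisation estimator, while all other electrodes stay at the
    uncoupled baseline."""
    template = ClassTemplate(
        "x", (CouplingSpec("FC5", ("Alpha", "Beta"), 0.95),))
    rec = generate_subject(template, duration_s=150.0, seed=4)
    mat = cfs_matrix(extract_phases(rec), (("Alpha", "Beta"),),
                     SegmentationSpec())
    values = mat.pair(("Alpha", "Beta"))
    idx = mat.electrode_names.index("FC5")
    assert values[idx].mean() >= 0.9
    others = np.delete(values, idx, axis=0)
    assert others.mean(axis=1).max() < 0.2


def test_segment_gated_coupling_covers_only_requested_segments():
    template = ClassTemplate(
        "x", (CouplingSpec("Pz", ("Alpha", "Beta"), 0.9,
                           onset_segment=1, offset_segment=3),))
    rec = generate_subject(template, duration_s=30.0, seed=2)
    mat = cfs_matrix(extract_phases(rec), (("Alpha", "Beta"),),
                     SegmentationSpec())
    series = mat.pair(("Alpha", "Beta"))[mat.electrode_names.index("Pz")]
    assert series[2].mean() > 0.7          # inside the covered span
    assert series[5] < 0.3                 # outside


# -- cohorts ----------------------------------------------------------------

def test_default_cohort_counts_and_labels():
    cohort = make_cohort(seed=0, duration_s=5.0)
    assert len(cohort) == 48
    assert sum(r.label == "control" for r in cohort) == 33
    assert sum(r.label == "dyslexic" for r in cohort) == 15


def test_two_subject_cohort_has_distinct_seeds():
    a, b = make_cohort(1, 1, seed=5, duration_s=5.0)
    assert a.label == "control" and b.label == "dyslexic"
    assert a.subject_id != b.subject_id
    control, _ = default_templates()
    same_template = make_cohort(2, 1, seed=5, duration_s=5.0)
    assert not np.array_equal(same_template[0].data, same_template[1].data)


def test_difference_electrodes_of_default_templates():
    assert difference_electrodes(*default_templates()) == {"FC5", "TP9", "PO9"}


def test_templates_require_couplings():
    with pytest.raises(ValueError):
        ClassTemplate("empty", ())


# -- export -----------------------------------------------------------------

def test_matrix_round_trip(tmp_path):
    template, _ = default_templates()
    rec = generate_subject(template, duration_s=5.0, seed=3)
    write_matrix(rec, tmp_path / "sub")
    back = read_matrix(tmp_path / "sub")
    np.testing.assert_allclose(back.data, rec.data, atol=1e-5)
    assert back.sfreq == rec.sfreq
    assert back.channel_names == rec.channel_names
    assert back.label == rec.label


def test_matrix_without_sidecar_rejected(tmp_path):
    np.savetxt(tmp_path / "orphan.tsv", np.zeros((2, 10)), delimiter="\t")
    with pytest.raises(FileNotFoundError, match="sidecar"):
        read_matrix(tmp_path / "orphan")


def test_edf_round_trip_against_mne(tmp_path):
    template, _ = default_templates()
    rec = generate_subject(template, duration_s=5.0, seed=3)
    path = tmp_path / "sub.edf"
    write_edf(rec, path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    assert raw.info["sfreq"] == rec.sfreq
    assert tuple(raw.ch_names) == rec.channel_names
    # mne rescales microvolt channels to volts; quantisation is 16-bit
    np.testing.assert_allclose(raw.get_data() * 1e6, rec.data, atol=1e-3)


def test_manifest(tmp_path):
    import pandas as pd

    cohort = make_cohort(2, 1, seed=0, duration_s=5.0)
    write_manifest(cohort, tmp_path / "manifest.csv")
    table = pd.read_csv(tmp_path / "manifest.csv")
    assert list(table.columns) == ["subject_id", "label"]
    assert list(table.label) == ["control", "control", "dyslexic"]
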