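"""Band-pass decomposition and instantaneous phase.

EEG rhythms are isolated with linear-phase Hamming-windowed FIR band-pass
filters.  Linear phase matters because the whole pipeline is built on phase
relations: an FIR filter delays every passband component by the same constant
``(L - 1) / 2`` samples, which is removed by shifting, so phase structure is
preserved exactly.  The instantaneous phase of each band-limited signal is the
angle of its analytic signal (the signal plus ``j`` times its Hilbert
transform), computed on the full-length filtered signal before any
segmentation.

Filter lengths follow the windowed-design rule ``L = ceil(3.3 / df * fs)``
rounded up to odd, with transition bandwidth
``df = min(max(0.25 * f_low, 2 Hz), f_low)``.  At 500 Hz this yields
3301 / 825 / 825 / 551 / 221 samples for the five canonical bands; explicit
lengths can be given to override the rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import firwin, hilbert, oaconvolve

from .recording import Recording


class FilterDesignError(ValueError):
    pass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with optional explicit FIR length (odd)."""

    name: str
    f_low: float
    f_high: float
    filter_length: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise FilterDesignError(f"invalid band edges for {self.name}")
        if self.filter_length is not None and self.filter_length % 2 == 0:
            raise FilterDesignError("filter_length must be odd")


#: The five canonical EEG bands.  Lengths are derived from the design rule
#: (they equal the conventional printed values at 500 Hz).
CANONICAL_BANDS = (
    BandDefinition("Delta", 0.5, 4.0),
    BandDefinition("Theta", 4.0, 8.0),
    BandDefinition("Alpha", 8.0, 12.0),
    BandDefinition("Beta", 12.0, 30.0),
    BandDefinition("Gamma", 30.0, 80.0),
)


def band_by_name(name: str, bands=CANONICAL_BANDS) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")


def transition_bandwidth(f_low: float) -> float:
    """Transition bandwidth of the windowed design rule, in Hz."""
    return min(max(0.25 * f_low, 2.0), f_low)


def derive_filter_length(band: BandDefinition, sfreq: float) -> int:
    """FIR length in samples: ``ceil(3.3 / df * fs)`` rounded up to odd."""
    if band.filter_length is not None:
        return band.filter_length
    df = transition_bandwidth(band.f_low)
    length = int(np.ceil(3.3 / df * sfreq))
    return length + 1 if length % 2 == 0 else length


def design_fir(band: BandDefinition, sfreq: float) -> tuple[np.ndarray, int]:
    """Hamming-windowed linear-phase band-pass FIR for ``band`` at ``sfreq``.

    Returns
    -------
    (coefficients, group_delay)
        ``coefficients`` has the band's (derived or explicit) length;
        ``group_delay`` is ``(length - 1) // 2`` samples.
    """
    if band.f_high >= sfreq / 2:
        raise FilterDesignError(
            f"{band.name}: upper edge {band.f_high} Hz reaches Nyquist ({sfreq / 2} Hz)"
        )
    length = derive_filter_length(band, sfreq)
    coeffs = firwin(length, [band.f_low, band.f_high], pass_zero=False,
                    window="hamming", fs=sfreq)
    return coeffs, (length - 1) // 2


def filter_data(data: np.ndarray, band: BandDefinition, sfreq: float) -> np.ndarray:
    """Zero-phase-equivalent band-pass along the last axis.

    The linear-phase FIR output is shifted back by the constant group delay so
    in-band components align with the input at lag zero; the first and last
    ``(L - 1) // 2`` output samples involve zero-padded edges.
    """
    data = np.asarray(data)
    n = data.shape[-1]
    coeffs, delay = design_fir(band, sfreq)
    if n <= coeffs.size:
        raise FilterDesignError(
            f"signal of {n} samples shorter than {band.name} filter ({coeffs.size})"
        )
    full = oaconvolve(data, coeffs[(np.newaxis,) * (data.ndim - 1)], axes=-1)
    return full[..., delay:delay + n]


def bandpass(recording: Recording, band: BandDefinition) -> Recording:
    """Band-limited copy of a recording (delay-compensated, same length)."""
    return replace(recording, data=filter_data(recording.data, band, recording.sfreq))


def analytic_phase(x: np.ndarray, unwrap: bool = False) -> np.ndarray:
    """Instantaneous phase (radians) of the analytic signal, along last axis.

    Wrapped phase lies in ``(-pi, pi]``; pass ``unwrap=True`` for the
    cumulative phase.  Phase-difference synchronisation measures are invariant
    to the choice.  An all-zero signal has undefined phase; zeros are returned
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("need at least two samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    if np.all(x == 0):
        warnings.warn("all-zero signal: instantaneous phase undefined, returning zeros",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(x)
    phase = np.angle(hilbert(x, axis=-1))
    return np.unwrap(phase, axis=-1) if unwrap else phase


@dataclass
class PhaseTensor:
    """Instantaneous phase per channel, band and sample (radians).

    ``edge_samples`` maps band name to the number of leading/trailing samples
    affected by filter edge padding (kept in the tensor so the sample count is
    identical across bands, but flagged for downstream interpretation).
    """

    phase: np.ndarray  # (channels, bands, samples)
    sfreq: float
    band_names: tuple[str, ...]
    channel_names: tuple[str, ...]
    edge_samples: dict[str, int]
    subject_id: str | None = None
    label: str | None = None

    def band(self, name: str) -> np.ndarray:
        try:
            return self.phase[:, self.band_names.index(name), :]
        except ValueError:
            raise KeyError(f"band {name!r} not in tensor") from None


def extract_phases(recording: Recording,
                   bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
                   unwrap: bool = False) -> PhaseTensor:
    """Band-pass each channel into every band and take the analytic phase."""
    n_ch, n = recording.data.shape
    phase = np.empty((n_ch, len(bands), n), dtype=float)
    edges: dict[str, int] = {}
    for j, band in enumerate(bands):
        filtered = filter_data(recording.data, band, recording.sfreq)
        phase[:, j, :] = analytic_phase(filtered, unwrap=unwrap)
        edges[band.name] = (derive_filter_length(band, recording.sfreq) - 1) // 2
    return PhaseTensor(
        phase=phase,
        sfreq=recording.sfreq,
        band_names=tuple(b.name for b in bands),
        channel_names=tuple(recording.channel_names),
        edge_samples=edges,
        subject_id=recording.subject_id,
        label=recording.label,
    )


def export_filter_coefficients(bands, sfreq: float, path) -> None:
    """Write designed coefficients to CSV (one column per band) for audit."""
    import pandas as pd

    cols = {}
    for band in bands:
        coeffs, _ = design_fir(band, sfreq)
        cols[band.name] = pd.Series(coeffs)
    pd.DataFrame(cols).to_csv(path, index_label="tap")
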