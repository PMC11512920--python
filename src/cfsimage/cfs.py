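"""Cross-frequency phase synchronisation (CFS).

The CFS between two frequency bands at one electrode is the resultant length
of the time-averaged unit phasors of their instantaneous-phase differences
over a temporal segment::

    S_CF = | (1/n) * sum_t exp(i * (phi_A(t) - phi_B(t))) |

It is 1 when the phase difference is constant over the segment and tends to 0
for independent phases (for ``n`` independent uniform differences the expected
resultant is the Rayleigh value ``sqrt(pi / (4 n))``).  The measure is the
intra-electrode, cross-band variant of intersite phase clustering.  Phase
differences are taken 1:1 by default; an ``(n, m)`` generalisation
(``n * phi_A - m * phi_B``) is available for conventional n:m locking studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import PhaseTensor


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class SegmentationSpec:
    """Rectangular windowing of the phase series.

    ``window_s`` seconds per segment (default 5), ``overlap_s`` seconds of
    overlap between consecutive segments (default 0: non-overlapping).
    Trailing samples that do not fill a window are discarded.
    """

    window_s: float = 5.0
    overlap_s: float = 0.0

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise SegmentationError("window_s must be positive")
        if not 0 <= self.overlap_s < self.window_s:
            raise SegmentationError("overlap_s must lie in [0, window_s)")

    def n_segments(self, n_samples: int, sfreq: float) -> int:
        win = int(round(self.window_s * sfreq))
        hop = int(round((self.window_s - self.overlap_s) * sfreq))
        if n_samples < win:
            return 0
        return (n_samples - win) // hop + 1

    def bounds(self, n_samples: int, sfreq: float) -> list[tuple[int, int]]:
        win = int(round(self.window_s * sfreq))
        hop = int(round((self.window_s - self.overlap_s) * sfreq))
        return [(s, s + win) for s in range(0, n_samples - win + 1, hop)]


def segment_phase(phase: np.ndarray, spec: SegmentationSpec,
                  sfreq: float) -> list[np.ndarray]:
    """Split a phase series (last axis = time) into windowed segments."""
    phase = np.asarray(phase)
    bounds = spec.bounds(phase.shape[-1], sfreq)
    if not bounds:
        raise SegmentationError(
            f"{phase.shape[-1] / sfreq:.2f} s of data is shorter than one "
            f"{spec.window_s} s window"
        )
    return [phase[..., a:b] for a, b in bounds]


def cfs_value(phi_a: np.ndarray, phi_b: np.ndarray,
              ratio: tuple[int, int] = (1, 1)) -> float:
    """Resultant length of the mean unit phasor of phase differences.

    ``ratio=(n, m)`` computes ``|mean exp(i (n phi_a - m phi_b))|``; the
    default (1, 1) is the plain phase difference.
    """
    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    if phi_a.shape != phi_b.shape:
        raise ValueError(f"shape mismatch: {phi_a.shape} vs {phi_b.shape}")
    if phi_a.size == 0:
        raise ValueError("empty phase segment")
    n, m = ratio
    return float(np.abs(np.mean(np.exp(1j * (n * phi_a - m * phi_b)))))


@dataclass
class CFSMatrix:
    """CFS values per electrode, band pair and temporal segment, in [0, 1]."""

    values: np.ndarray  # (electrodes, band_pairs, segments)
    band_pairs: tuple[tuple[str, str], ...]
    electrode_names: tuple[str, ...]
    subject_id: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.band_pairs = tuple(tuple(p) for p in self.band_pairs)
        self.electrode_names = tuple(self.electrode_names)
        e, p, s = self.values.shape
        if e != len(self.electrode_names) or p != len(self.band_pairs):
            raise ValueError("values shape inconsistent with labels")

    @property
    def segment_count(self) -> int:
        return self.values.shape[2]

    def pair(self, pair: tuple[str, str]) -> np.ndarray:
        """(electrodes, segments) slice for one band pair."""
        try:
            return self.values[:, self.band_pairs.index(tuple(pair)), :]
        except ValueError:
            raise KeyError(f"band pair {pair} not present") from None

    def to_dataframe(self):
        import pandas as pd

        e, p, s = self.values.shape
        idx = np.indices((e, p, s)).reshape(3, -1)
        return pd.DataFrame({
            "subject": self.subject_id,
            "electrode": np.array(self.electrode_names)[idx[0]],
            "pair": ["-".join(self.band_pairs[k]) for k in idx[1]],
            "segment": idx[2],
            "value": self.values.reshape(-1),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def save(self, path) -> None:
        np.savez_compressed(
            path, values=self.values,
            band_pairs=np.array(["-".join(p) for p in self.band_pairs]),
            electrode_names=np.array(self.electrode_names),
            subject_id=str(self.subject_id), label=str(self.label),
        )

    @classmethod
    def load(cls, path) -> "CFSMatrix":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                values=z["values"],
                band_pairs=tuple(tuple(p.split("-")) for p in z["band_pairs"]),
                electrode_names=tuple(z["electrode_names"]),
                subject_id=str(z["subject_id"]), label=str(z["label"]),
            )


#: Default band-pair triplet used for the three image layers.
DEFAULT_PAIRS = (("Theta", "Gamma"), ("Alpha", "Beta"), ("Beta", "Gamma"))


def cfs_matrix(phases: PhaseTensor,
               pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
               spec: SegmentationSpec = SegmentationSpec(),
               ratio: tuple[int, int] = (1, 1)) -> CFSMatrix:
    """One CFS value per (electrode, band pair, segment).

    Vectorised over electrodes and segments; equivalent to calling
    :func:`cfs_value` on every individual segment.
    """
    for a, b in pairs:
        phases.band(a), phases.band(b)  # raise KeyError early
    bounds = spec.bounds(phases.phase.shape[-1], phases.sfreq)
    if not bounds:
        raise SegmentationError("recording shorter than one segment window")
    n, m = ratio
    n_el = phases.phase.shape[0]
    values = np.empty((n_el, len(pairs), len(bounds)))
    for j, (a, b) in enumerate(pairs):
        diff = n * phases.band(a) - m * phases.band(b)
        phasor = np.exp(1j * diff)
        for s, (lo, hi) in enumerate(bounds):
            values[:, j, s] = np.abs(phasor[:, lo:hi].mean(axis=1))
    return CFSMatrix(values, pairs, phases.channel_names,
                     subject_id=phases.subject_id, label=phases.label)
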