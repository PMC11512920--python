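"""Electrode-level LIME for CFS image-sequence classifiers.

The interpretable representation of a frame is a binary vector with one bit
per electrode super-pixel (the feature-mask regions).  To explain one frame
of a subject's sequence, the frame is perturbed: random subsets of
super-pixels are switched off (their pixels set to 0, the out-of-hull /
zero-synchronisation value) while the remaining frames stay untouched.  The
classifier's score for the explained class on each perturbed sequence (its
log-odds -- see :func:`_surrogate_scores`), weighted by an exponential kernel
on the Euclidean distance between original and perturbed frame, trains a
lasso surrogate whose coefficients are the per-electrode relevances.  Applying this to all frames yields a
frames x electrodes explanation map; maps are averaged over (correctly
classified) subjects and the top-k super-pixels per frame are reported with
signed relevance.

Perturbing a single frame leaves the other frames' convolutional features
unchanged, so the implementation caches per-frame CNN features and
re-evaluates only the perturbed frame and the recurrent head; this is a pure
optimisation with results identical to evaluating full sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso, LinearRegression

from .imaging import FeatureMask

__all__ = [
    "PerturbationSet", "ExplanationMap", "perturb_frame", "kernel_weight",
    "explain_frame", "explain_sequence", "top_superpixels",
    "render_relevance", "plot_relevance_frames",
]

#: Perturbation-set size used for reported explanations.
DEFAULT_N_SAMPLES = 10_000

#: Default lasso penalty; a fixed value (chosen once on surrogate fidelity)
#: rather than per-frame tuning, so explanations are deterministic.
DEFAULT_LASSO_PENALTY = 1e-3


def default_kernel_width(n_superpixels: int) -> float:
    """Kernel width 0.25 * sqrt(d'), the usual LIME scaling for distances
    measured on the binary design (number of switched-off super-pixels).

    Distances here are measured in pixel space, whose scale depends on the
    image content, so the default behaviour of :func:`explain_frame` is
    instead scale-adaptive (see there); this constant is kept for callers
    who weight on the binary scale.
    """
    return 0.25 * np.sqrt(n_superpixels)


@dataclass
class PerturbationSet:
    """N perturbed versions of one frame plus their binary designs.

    ``designs[i]`` has one bit per super-pixel (1 = kept); ``designs[0]`` is
    all ones, reproducing the original frame.  ``frames[i]`` is the perturbed
    frame; other frames of the parent sequence are unchanged and can be
    materialised with :meth:`sequence`.
    """

    designs: np.ndarray  # (N, d') uint8
    frames: np.ndarray  # (N, mesh, mesh, layers)
    frame_idx: int
    base_sequence: np.ndarray  # (T, mesh, mesh, layers)

    def sequence(self, i: int) -> np.ndarray:
        seq = self.base_sequence.copy()
        seq[self.frame_idx] = self.frames[i]
        return seq


def _superpixel_stack(mask: FeatureMask) -> np.ndarray:
    """(d', mesh, mesh) boolean stack of super-pixel regions."""
    d = mask.n_superpixels
    if not np.any(mask.labels > 0):
        raise ValueError("feature mask has no labelled pixels")
    return np.stack([mask.labels == j + 1 for j in range(d)])


def perturb_frame(sequence: np.ndarray, frame_idx: int, mask: FeatureMask,
                  n_samples: int = DEFAULT_N_SAMPLES, seed: int = 0,
                  off_value: float = 0.0) -> PerturbationSet:
    """Draw perturbations of one frame by switching super-pixels off.

    Bits are independent fair coin flips; switched-off super-pixels have
    their pixels replaced by ``off_value`` (default 0, matching the imaging
    module's zero-fill semantics; a band-pair-wise in-hull mean can be passed
    for mean-fill perturbation).
    """
    sequence = np.asarray(sequence)
    if not 0 <= frame_idx < sequence.shape[0]:
        raise IndexError(f"frame {frame_idx} outside sequence of "
                         f"{sequence.shape[0]} frames")
    if n_samples < 2:
        raise ValueError("need at least 2 perturbation samples")
    regions = _superpixel_stack(mask)
    d = regions.shape[0]
    rng = np.random.default_rng(seed)
    designs = (rng.random((n_samples, d)) < 0.5).astype(np.uint8)
    designs[0] = 1
    base = sequence[frame_idx]
    # off_weight[i, x, y] = 1 where any switched-off super-pixel covers (x, y)
    off = np.einsum("nd,dxy->nxy", (1 - designs).astype(np.float64),
                    regions.astype(np.float64))
    keep = (off == 0)[..., None]
    frames = np.where(keep, base[None], off_value)
    return PerturbationSet(designs=designs, frames=frames,
                           frame_idx=frame_idx, base_sequence=sequence)


def kernel_weight(x_frame: np.ndarray, z_frame: np.ndarray,
                  width: float) -> float:
    """Exponential kernel on the Euclidean frame distance: exp(-D^2 / w^2)."""
    if width <= 0:
        raise ValueError("kernel width must be positive")
    x_frame, z_frame = np.asarray(x_frame), np.asarray(z_frame)
    if x_frame.shape != z_frame.shape:
        raise ValueError("frame shapes differ")
    d2 = float(np.sum((x_frame - z_frame) ** 2))
    return float(np.exp(-d2 / width ** 2))


def _surrogate_scores(model, pset: PerturbationSet, explained_class: int,
                      chunk: int = 1000) -> np.ndarray:
    """Explained-class log-odds for every perturbed sequence.

    The surrogate target is the class log-odds (the logit margin of a
    two-class softmax) rather than the probability itself: a well-separated
    classifier saturates its probabilities, and single-frame perturbations
    would otherwise leave the target numerically constant.
    """
    n = pset.designs.shape[0]
    base_seq = pset.base_sequence
    if hasattr(model, "frame_features") and hasattr(model, "head_logits_variants"):
        base_feats = model.frame_features(base_seq)  # (T, F)
        out = np.empty(n)
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            pf = model.frame_features(pset.frames[lo:hi])
            logits = model.head_logits_variants(base_feats, pset.frame_idx, pf)
            out[lo:hi] = (logits[:, explained_class]
                          - logits[:, 1 - explained_class])
        return out
    # generic fall-back: materialise full sequences chunk-wise
    out = np.empty(n)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        seqs = np.broadcast_to(base_seq, (hi - lo,) + base_seq.shape).copy()
        seqs[:, pset.frame_idx] = pset.frames[lo:hi]
        p = np.clip(model.predict_proba(seqs)[:, explained_class],
                    1e-12, 1 - 1e-12)
        out[lo:hi] = np.log(p) - np.log1p(-p)
    return out


def _fit_surrogate(designs: np.ndarray, scores: np.ndarray,
                   weights: np.ndarray, penalty: float):
    """Weighted lasso (or weighted least squares at zero penalty)."""
    X = designs.astype(np.float64)
    if penalty > 0:
        reg = Lasso(alpha=penalty, fit_intercept=True, max_iter=50_000,
                    tol=1e-8)
    else:
        reg = LinearRegression()
    reg.fit(X, scores, sample_weight=weights)
    pred = reg.predict(X)
    resid = np.average((scores - pred) ** 2, weights=weights)
    total = np.average((scores - np.average(scores, weights=weights)) ** 2,
                       weights=weights)
    r2 = 1.0 if total == 0 else 1.0 - resid / total
    return reg.coef_, float(r2)


def explain_frame(model, sequence: np.ndarray, frame_idx: int,
                  mask: FeatureMask, n_samples: int = DEFAULT_N_SAMPLES,
                  lasso_penalty: float = DEFAULT_LASSO_PENALTY, seed: int = 0,
                  kernel_width: float | None = None,
                  explained_class: int | None = None,
                  off_value: float = 0.0) -> tuple[np.ndarray, float]:
    """Lasso-surrogate coefficients (one per super-pixel) for one frame.

    Returns ``(coefficients, fidelity)`` where fidelity is the surrogate's
    kernel-weighted R^2 on the perturbation set.  ``explained_class``
    defaults to the model's predicted class for the unperturbed sequence.
    """
    pset = perturb_frame(sequence, frame_idx, mask, n_samples, seed,
                         off_value=off_value)
    if explained_class is None:
        if hasattr(model, "frame_features"):
            feats = model.frame_features(np.asarray(sequence))
            explained_class = int(np.argmax(model.head_proba(feats[None])[0]))
        else:
            explained_class = int(np.argmax(
                model.predict_proba(np.asarray(sequence)[None])[0]))
    base = pset.base_sequence[frame_idx]
    d2 = np.sum((pset.frames - base[None]) ** 2, axis=(1, 2, 3))
    if kernel_width is None:
        # scale-adaptive width: the median perturbation gets weight e^-0.5,
        # so locality weighting is meaningful at any CFS image contrast
        med = float(np.median(d2[1:]))
        width = np.sqrt(2.0 * med) if med > 0 else default_kernel_width(
            mask.n_superpixels)
    else:
        width = kernel_width
    weights = np.exp(-d2 / width ** 2)
    if np.all(pset.designs == pset.designs[0]):
        import warnings

        warnings.warn("degenerate perturbation design (all samples identical)",
                      RuntimeWarning, stacklevel=2)
    scores = _surrogate_scores(model, pset, explained_class)
    coef, r2 = _fit_surrogate(pset.designs, scores, weights, lasso_penalty)
    return coef, r2


@dataclass
class ExplanationMap:
    """Per-frame, per-super-pixel surrogate coefficients for one subject."""

    coefficients: np.ndarray  # (frames, d')
    explained_class: int
    fidelity: np.ndarray  # (frames,) weighted surrogate R^2
    electrode_names: tuple[str, ...]
    subject_id: str | None = None

    def to_dataframe(self):
        import pandas as pd

        t, d = self.coefficients.shape
        idx = np.indices((t, d)).reshape(2, -1)
        return pd.DataFrame({
            "subject": self.subject_id,
            "frame": idx[0] + 1,  # 1-based in reports
            "electrode": np.array(self.electrode_names)[idx[1]],
            "coefficient": self.coefficients.reshape(-1),
            "explained_class": self.explained_class,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def explain_sequence(model, sequence: np.ndarray, mask: FeatureMask,
                     n_samples: int = DEFAULT_N_SAMPLES,
                     lasso_penalty: float = DEFAULT_LASSO_PENALTY,
                     seed: int = 0, explained_class: int | None = None,
                     kernel_width: float | None = None,
                     subject_id: str | None = None) -> ExplanationMap:
    """Apply frame-wise LIME to every frame of a sequence (30 x 31 map)."""
    sequence = np.asarray(sequence)
    if explained_class is None:
        if hasattr(model, "frame_features"):
            feats = model.frame_features(sequence)
            explained_class = int(np.argmax(model.head_proba(feats[None])[0]))
        else:
            explained_class = int(np.argmax(
                model.predict_proba(sequence[None])[0]))
    n_frames = sequence.shape[0]
    coefs = np.empty((n_frames, mask.n_superpixels))
    fid = np.empty(n_frames)
    for t in range(n_frames):
        coefs[t], fid[t] = explain_frame(
            model, sequence, t, mask, n_samples, lasso_penalty,
            seed=seed + t, kernel_width=kernel_width,
            explained_class=explained_class)
    return ExplanationMap(coefficients=coefs, explained_class=explained_class,
                          fidelity=fid,
                          electrode_names=tuple(mask.electrode_names),
                          subject_id=subject_id)


def top_superpixels(maps: list[ExplanationMap], k: int = 5
                    ) -> tuple[np.ndarray, list[list[str]]]:
    """Average explanation maps over subjects and rank super-pixels per frame.

    Returns ``(mean_map, rankings)``: the (frames, d') subject-average
    coefficients and, per frame, the ``k`` electrode names with largest
    absolute average relevance (descending).  Averaging is symmetric in the
    subjects, so the result does not depend on their order.  Callers select
    which subjects to pool (e.g. only correctly classified ones, or one
    class's explanations).
    """
    if not maps:
        raise ValueError("no explanation maps to aggregate")
    names = maps[0].electrode_names
    if any(m.electrode_names != names for m in maps):
        raise ValueError("explanation maps disagree on electrode order")
    mean_map = np.mean([m.coefficients for m in maps], axis=0)
    rankings = []
    for t in range(mean_map.shape[0]):
        order = np.argsort(-np.abs(mean_map[t]))[:k]
        rankings.append([names[j] for j in order])
    return mean_map, rankings


def render_relevance(mask: FeatureMask, values: np.ndarray,
                     top_k: int | None = None) -> np.ndarray:
    """Signed relevance image on the mask geometry.

    Positive relevance renders green, negative red (alpha-free RGB); pixels
    outside the hull, and super-pixels outside the top-k when ``top_k`` is
    given, stay black.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (mask.n_superpixels,):
        raise ValueError("one relevance value per super-pixel required")
    shown = np.arange(values.size)
    if top_k is not None:
        shown = np.argsort(-np.abs(values))[:top_k]
    peak = np.max(np.abs(values[shown])) or 1.0
    img = np.zeros(mask.labels.shape + (3,))
    for j in shown:
        region = mask.labels == j + 1
        mag = abs(values[j]) / peak
        img[region, 1 if values[j] >= 0 else 0] = mag
    return img


def plot_relevance_frames(mask: FeatureMask, mean_map: np.ndarray,
                          frames, k: int = 5, path=None):
    """Panel figure of top-k signed relevance for selected frames."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    frames = list(frames)
    fig, axes = plt.subplots(1, len(frames), figsize=(2 * len(frames), 2.2),
                             squeeze=False)
    for ax, t in zip(axes[0], frames):
        ax.imshow(render_relevance(mask, mean_map[t], top_k=k), origin="lower")
        ax.set_title(f"frame {t + 1}")
        ax.set_xticks([]), ax.set_yticks([])
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
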