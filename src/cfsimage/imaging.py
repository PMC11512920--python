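"""Topographic imaging of CFS values.

Per-segment electrode values are interpolated onto a 32 x 32 pixel mesh with
the piecewise-cubic C1 Clough-Tocher scheme on the Delaunay triangulation of
the azimuthally projected electrode positions.  Three band-pair layers are
stacked into an RGB frame per temporal segment; the frames of one subject form
a CFS image sequence.  A companion feature mask partitions the in-hull pixels
into 31 super-pixels, one per electrode (nearest projected electrode), used as
interpretable features by the explanation module.

The mesh bounding box is square, covers the projected electrode cloud plus a
5% margin, and is identical for every layer, frame and the mask, so pixels are
geometrically aligned across the whole pipeline.  Pixels outside the convex
hull of the electrodes take the fill value 0 (zero synchronisation renders
black).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator
from scipy.spatial import Delaunay, cKDTree

from .cfs import CFSMatrix
from .montage import (Montage, ProjectedMontage, default_montage,
                      project_montage)

__all__ = [
    "ImageGrid", "CFSImageSequence", "FeatureMask",
    "make_grid", "render_layer", "stack_frames", "build_feature_mask",
    "group_topoplots", "plot_topoplot_grid",
]


@dataclass(frozen=True)
class ImageGrid:
    """Square pixel mesh shared by all layers, frames and the feature mask."""

    x: np.ndarray  # (mesh,) pixel-centre coordinates
    y: np.ndarray  # (mesh,)
    mesh: int

    @property
    def points(self) -> np.ndarray:
        """(mesh*mesh, 2) pixel-centre coordinates, row-major (y outer)."""
        xx, yy = np.meshgrid(self.x, self.y)
        return np.column_stack([xx.ravel(), yy.ravel()])


def make_grid(projected: ProjectedMontage, mesh: int = 32,
              margin: float = 0.05) -> ImageGrid:
    """Square bounding box of the projected cloud plus a fractional margin."""
    lo, hi = projected.coords.min(), projected.coords.max()
    half = 0.5 * (hi - lo) * (1 + 2 * margin)
    cx = 0.5 * (projected.coords[:, 0].min() + projected.coords[:, 0].max())
    cy = 0.5 * (projected.coords[:, 1].min() + projected.coords[:, 1].max())
    return ImageGrid(x=np.linspace(cx - half, cx + half, mesh),
                     y=np.linspace(cy - half, cy + half, mesh), mesh=mesh)


def in_hull_mask(projected: ProjectedMontage, grid: ImageGrid) -> np.ndarray:
    """Boolean (mesh, mesh) mask of pixels inside the electrode convex hull."""
    tri = Delaunay(projected.coords)
    inside = tri.find_simplex(grid.points) >= 0
    return inside.reshape(grid.mesh, grid.mesh)


def render_layer(values: np.ndarray, projected: ProjectedMontage,
                 mesh: int = 32, grid: ImageGrid | None = None,
                 fill: float = 0.0) -> np.ndarray:
    """Interpolate one value per electrode onto the pixel mesh.

    Clough-Tocher interpolation is exact at the electrode sites, reproduces
    constant and affine fields, and is C1 inside the convex hull; out-of-hull
    pixels are set to ``fill``.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(projected),):
        raise ValueError(f"expected {len(projected)} electrode values")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite electrode value")
    grid = grid or make_grid(projected, mesh)
    interp = CloughTocher2DInterpolator(projected.coords, values)
    img = interp(grid.points).reshape(grid.mesh, grid.mesh)
    img[~np.isfinite(img)] = fill
    return img


def interpolate_at(values: np.ndarray, projected: ProjectedMontage,
                   points: np.ndarray) -> np.ndarray:
    """Evaluate the same Clough-Tocher interpolant at arbitrary points."""
    interp = CloughTocher2DInterpolator(projected.coords, np.asarray(values, float))
    return interp(np.atleast_2d(points))


@dataclass
class CFSImageSequence:
    """Stack of 32 x 32 x 3 CFS frames for one subject.

    ``frames[t, i, j, k]`` is the CFS of band pair ``band_pairs[k]`` in
    temporal segment ``t`` at pixel ``(i, j)``; raw values in [0, 1], no
    per-frame rescaling.  ``hull`` flags in-hull pixels.
    """

    frames: np.ndarray  # (segments, mesh, mesh, 3)
    band_pairs: tuple[tuple[str, str], ...]
    hull: np.ndarray  # (mesh, mesh) bool
    subject_id: str | None = None
    label: str | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def save(self, path) -> None:
        np.savez_compressed(
            path, frames=self.frames, hull=self.hull,
            band_pairs=np.array(["-".join(p) for p in self.band_pairs]),
            subject_id=str(self.subject_id), label=str(self.label))

    @classmethod
    def load(cls, path) -> "CFSImageSequence":
        with np.load(path, allow_pickle=False) as z:
            return cls(frames=z["frames"], hull=z["hull"],
                       band_pairs=tuple(tuple(p.split("-"))
                                        for p in z["band_pairs"]),
                       subject_id=str(z["subject_id"]), label=str(z["label"]))

    def write_pngs(self, directory, normalise: bool = True) -> None:
        """Optional per-frame RGB previews (normalisation is display-only)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        peak = self.frames.max() if normalise and self.frames.max() > 0 else 1.0
        for t in range(self.n_frames):
            rgb = np.clip(self.frames[t] / peak, 0, 1)
            plt.imsave(directory / f"frame-{t + 1:02d}.png", rgb, origin="lower")


def stack_frames(cfs: CFSMatrix, triplet=None,
                 projected: ProjectedMontage | None = None,
                 mesh: int = 32) -> CFSImageSequence:
    """Render three band-pair layers per segment and stack them as RGB frames."""
    triplet = tuple(tuple(p) for p in (triplet or cfs.band_pairs))
    if len(triplet) != 3:
        raise ValueError(f"need exactly 3 band pairs, got {len(triplet)}")
    projected = projected or project_montage(default_montage())
    if tuple(projected.names) != tuple(cfs.electrode_names):
        raise ValueError("projected montage channels do not match CFS electrodes")
    grid = make_grid(projected, mesh)
    hull = in_hull_mask(projected, grid)
    n_seg = cfs.segment_count
    frames = np.zeros((n_seg, mesh, mesh, 3))
    for k, pair in enumerate(triplet):
        layer_values = cfs.pair(pair)  # (electrodes, segments)
        for t in range(n_seg):
            frames[t, :, :, k] = render_layer(layer_values[:, t], projected,
                                              grid=grid)
    # piecewise-cubic interpolation can overshoot; synchronisation values are
    # physically confined to [0, 1]
    np.clip(frames, 0.0, 1.0, out=frames)
    return CFSImageSequence(frames=frames, band_pairs=triplet, hull=hull,
                            subject_id=cfs.subject_id, label=cfs.label)


@dataclass
class FeatureMask:
    """Integer label grid assigning each in-hull pixel to an electrode.

    Labels run 1..n_electrodes (order of ``electrode_names``); 0 marks
    out-of-hull pixels.  Super-pixels partition the in-hull pixel set by
    nearest projected electrode (planar Euclidean distance).
    """

    labels: np.ndarray  # (mesh, mesh) int
    electrode_names: tuple[str, ...]

    @property
    def n_superpixels(self) -> int:
        return len(self.electrode_names)

    def pixels_of(self, electrode: str) -> np.ndarray:
        """Boolean mask of the super-pixel for one electrode."""
        idx = self.electrode_names.index(electrode) + 1
        return self.labels == idx


def build_feature_mask(projected: ProjectedMontage, mesh: int = 32,
                       grid: ImageGrid | None = None) -> FeatureMask:
    """Label every in-hull pixel with its nearest projected electrode."""
    coords = projected.coords
    uniq = np.unique(np.round(coords, 9), axis=0)
    if uniq.shape[0] != coords.shape[0]:
        raise ValueError("duplicate projected electrode coordinates")
    grid = grid or make_grid(projected, mesh)
    hull = in_hull_mask(projected, grid)
    _, nearest = cKDTree(coords).query(grid.points)
    labels = (nearest + 1).reshape(grid.mesh, grid.mesh)
    labels[~hull] = 0
    # hull-vertex electrodes may sit nearer an out-of-hull pixel centre than
    # any in-hull one; every electrode still owns its nearest pixel
    for j, xy in enumerate(coords):
        flat = np.argmin(np.sum((grid.points - xy) ** 2, axis=1))
        labels[np.unravel_index(flat, labels.shape)] = j + 1
    return FeatureMask(labels=labels, electrode_names=tuple(projected.names))


def group_topoplots(matrices: list[CFSMatrix], groups: list[str],
                    pair: tuple[str, str], segments=None,
                    projected: ProjectedMontage | None = None,
                    mesh: int = 32):
    """Electrode-wise group-mean CFS, rendered per (group, segment).

    Returns ``(images, means)`` where ``images[(group, segment)]`` is the
    rendered topography and ``means[group]`` the (electrodes, segments)
    group-average matrix.
    """
    if len(matrices) != len(groups):
        raise ValueError("one group label per CFS matrix required")
    if not matrices:
        raise ValueError("empty cohort")
    projected = projected or project_montage(default_montage())
    grid = make_grid(projected, mesh)
    segments = (range(matrices[0].segment_count)
                if segments is None else list(segments))
    images, means = {}, {}
    for group in dict.fromkeys(groups):
        layer = [m.pair(pair) for m, g in zip(matrices, groups) if g == group]
        if not layer:
            raise ValueError(f"group {group!r} is empty")
        mean = np.mean(layer, axis=0)
        means[group] = mean
        for t in segments:
            images[(group, t)] = render_layer(mean[:, t], projected, grid=grid)
    return images, means


def plot_topoplot_grid(images: dict, groups, segments, path=None):
    """Figure with one row per group and one column per segment."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    groups, segments = list(groups), list(segments)
    fig, axes = plt.subplots(len(groups), len(segments),
                             figsize=(2 * len(segments), 2 * len(groups)),
                             squeeze=False)
    vmax = max(img.max() for img in images.values()) or 1.0
    for i, g in enumerate(groups):
        for j, t in enumerate(segments):
            ax = axes[i][j]
            ax.imshow(images[(g, t)], origin="lower", vmin=0, vmax=vmax)
            ax.set_xticks([]), ax.set_yticks([])
            if i == 0:
                ax.set_title(f"segment {t + 1}")
        axes[i][0].set_ylabel(g)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
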