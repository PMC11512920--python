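"""Electrode montages on the sphere.

The default montage is an idealised spherical 10-20/10-10 layout of the 32
electrodes used by a standard 32-channel auditory-EEG cap (Cz-referenced,
leaving 31 signal channels).  Positions are constructed geometrically from the
arc-fraction rules of the 10-20 system -- electrodes sit on great circles of a
unit sphere at 10%/20% arc fractions -- so the layout is exactly spherical and
exactly mirror-symmetric between hemispheres, which digitised head models are
not.  Arbitrary montages can be loaded from ``.sfp``-style text files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 32 electrode labels of the default cap (10-20 plus 10-10 extensions).
DEFAULT_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)


class MontageError(ValueError):
    """Raised for unknown electrodes or malformed montage definitions."""


def _sph(polar_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector from polar angle (from vertex) and azimuth (0 = nasion,
    positive towards the right ear).  Axes: +x right, +y anterior, +z up."""
    c = np.deg2rad(polar_deg)
    a = np.deg2rad(azimuth_deg)
    return np.array([np.sin(c) * np.sin(a), np.sin(c) * np.cos(a), np.cos(c)])


def _slerp(p: np.ndarray, q: np.ndarray, t: float) -> np.ndarray:
    """Point at arc fraction ``t`` along the great circle from ``p`` to ``q``."""
    omega = np.arccos(np.clip(p @ q, -1.0, 1.0))
    if omega < 1e-12:
        return p.copy()
    return (np.sin((1 - t) * omega) * p + np.sin(t * omega) * q) / np.sin(omega)


def _below(p: np.ndarray, extra_deg: float) -> np.ndarray:
    """Push a point further from the vertex along its own meridian."""
    z = np.array([0.0, 0.0, 1.0])
    c = np.arccos(np.clip(p @ z, -1.0, 1.0))
    meridian = p - np.cos(c) * z
    meridian /= np.linalg.norm(meridian)
    c2 = c + np.deg2rad(extra_deg)
    return np.cos(c2) * z + np.sin(c2) * meridian


def _ideal_positions() -> dict[str, np.ndarray]:
    pos: dict[str, np.ndarray] = {}
    pos["Cz"] = _sph(0, 0)
    pos["Fz"] = _sph(36, 0)
    pos["Pz"] = _sph(36, 180)
    pos["Oz"] = _sph(72, 180)
    # circumferential ring at 72 deg polar, 18 deg (5% of 360) azimuth steps
    ring = {"Fp1": -18, "Fp2": 18, "F7": -54, "F8": 54, "T7": -90, "T8": 90,
            "P7": -126, "P8": 126, "O1": -162, "O2": 162}
    for name, az in ring.items():
        pos[name] = _sph(72, az)
    pos["C3"] = _sph(36, -90)
    pos["C4"] = _sph(36, 90)
    # 10-20 intermediate rows: midway along the arcs joining midline and ring
    pos["F3"] = _slerp(pos["Fz"], pos["F7"], 0.5)
    pos["F4"] = _slerp(pos["Fz"], pos["F8"], 0.5)
    pos["P3"] = _slerp(pos["Pz"], pos["P7"], 0.5)
    pos["P4"] = _slerp(pos["Pz"], pos["P8"], 0.5)
    # 10-10 rows: FC between F and C, CP between C and P
    fcz = _slerp(pos["Fz"], pos["Cz"], 0.5)
    cpz = _slerp(pos["Cz"], pos["Pz"], 0.5)
    fc3 = _slerp(pos["F3"], pos["C3"], 0.5)
    fc4 = _slerp(pos["F4"], pos["C4"], 0.5)
    cp3 = _slerp(pos["C3"], pos["P3"], 0.5)
    cp4 = _slerp(pos["C4"], pos["P4"], 0.5)
    ft7 = _slerp(pos["F7"], pos["T7"], 0.5)
    ft8 = _slerp(pos["F8"], pos["T8"], 0.5)
    tp7 = _slerp(pos["T7"], pos["P7"], 0.5)
    tp8 = _slerp(pos["T8"], pos["P8"], 0.5)
    pos["FC1"] = _slerp(fcz, fc3, 0.5)
    pos["FC2"] = _slerp(fcz, fc4, 0.5)
    pos["FC5"] = _slerp(fc3, ft7, 0.5)
    pos["FC6"] = _slerp(fc4, ft8, 0.5)
    pos["CP1"] = _slerp(cpz, cp3, 0.5)
    pos["CP2"] = _slerp(cpz, cp4, 0.5)
    pos["CP5"] = _slerp(cp3, tp7, 0.5)
    pos["CP6"] = _slerp(cp4, tp8, 0.5)
    # inferior 10-10 electrodes: 10% (18 deg) below their superior neighbours
    pos["TP9"] = _below(tp7, 18)
    pos["TP10"] = _below(tp8, 18)
    pos["PO9"] = _below(_slerp(pos["P7"], pos["O1"], 0.5), 18)
    pos["PO10"] = _below(_slerp(pos["P8"], pos["O2"], 0.5), 18)
    return pos


@dataclass
class Montage:
    """Electrode labels with 3-D coordinates on (or normalisable to) a sphere.

    Parameters
    ----------
    names
        Ordered electrode labels, including the reference.
    positions
        ``(n, 3)`` coordinates.  They are normalised to a common sphere of
        radius ``radius`` centred on the origin.
    reference
        Label of the reference electrode (projection centre), default ``Cz``.
    """

    names: tuple[str, ...]
    positions: np.ndarray
    reference: str = "Cz"
    radius: float = 1.0

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.names), 3):
            raise MontageError(
                f"positions shape {pos.shape} does not match {len(self.names)} labels"
            )
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0):
            raise MontageError("electrode at sphere centre cannot be normalised")
        self.positions = self.radius * pos / norms[:, None]
        if self.reference not in self.names:
            raise MontageError(f"reference electrode {self.reference!r} not in montage")

    @property
    def channels(self) -> tuple[str, ...]:
        """Signal-channel labels: every electrode except the reference."""
        return tuple(n for n in self.names if n != self.reference)

    def position(self, name: str) -> np.ndarray:
        try:
            return self.positions[self.names.index(name)]
        except ValueError:
            raise MontageError(f"unknown electrode {name!r}") from None

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class ProjectedMontage:
    """2-D electrode coordinates from the azimuthal equidistant projection.

    Holds the non-reference channels; the reference itself maps to the origin
    by construction (zero angular distance).
    """

    names: tuple[str, ...]
    coords: np.ndarray  # (n_channels, 2)
    reference: str = "Cz"

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.names), 2):
            raise MontageError("coordinate shape does not match labels")

    def coord(self, name: str) -> np.ndarray:
        try:
            return self.coords[self.names.index(name)]
        except ValueError:
            raise MontageError(f"unknown electrode {name!r}") from None

    def __len__(self) -> int:
        return len(self.names)


def default_montage() -> Montage:
    """The idealised spherical 32-electrode 10-20/10-10 montage (Cz reference)."""
    pos = _ideal_positions()
    return Montage(DEFAULT_LABELS, np.array([pos[n] for n in DEFAULT_LABELS]))


def azimuthal_equidistant(points: np.ndarray, centre: np.ndarray,
                          radius: float = 1.0) -> np.ndarray:
    """Project points on a sphere to the plane, preserving distance and
    direction from the centre point.

    Each point maps to polar coordinates ``(theta, rho)`` with ``rho = R * c``
    (``c`` the angular distance from the centre) and Cartesian coordinates
    ``x = rho * sin(theta)``, ``y = -rho * cos(theta)``.  The azimuth ``theta``
    is measured from the anterior direction, positive towards the right.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centre = np.asarray(centre, dtype=float)
    zhat = centre / np.linalg.norm(centre)
    # anterior reference direction in the tangent plane at the centre
    anterior = np.array([0.0, 1.0, 0.0])
    if abs(anterior @ zhat) > 1 - 1e-9:  # centre at nasion: fall back to +z
        anterior = np.array([0.0, 0.0, 1.0])
    yhat = anterior - (anterior @ zhat) * zhat
    yhat /= np.linalg.norm(yhat)
    xhat = np.cross(yhat, zhat)

    unit = points / np.linalg.norm(points, axis=1)[:, None]
    cosc = np.clip(unit @ zhat, -1.0, 1.0)
    if np.any(cosc <= -1 + 1e-12):
        raise MontageError("electrode antipodal to projection centre")
    c = np.arccos(cosc)
    theta = np.arctan2(unit @ xhat, unit @ yhat)
    rho = radius * c
    return np.column_stack([rho * np.sin(theta), -rho * np.cos(theta)])


def project_montage(montage: Montage) -> ProjectedMontage:
    """Azimuthal equidistant projection of all non-reference electrodes."""
    centre = montage.position(montage.reference)
    chans = montage.channels
    pts = np.array([montage.position(n) for n in chans])
    xy = azimuthal_equidistant(pts, centre, radius=montage.radius)
    return ProjectedMontage(chans, xy, reference=montage.reference)


def read_sfp(path) -> Montage:
    """Read an ``.sfp``-style montage file: ``label x y z`` per line."""
    names, pts = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise MontageError(f"malformed montage line: {line!r}")
            names.append(parts[0])
            pts.append([float(v) for v in parts[1:]])
    if not names:
        raise MontageError(f"no electrodes found in {path}")
    ref = "Cz" if "Cz" in names else names[0]
    return Montage(tuple(names), np.array(pts), reference=ref)


def write_sfp(montage: Montage, path) -> None:
    with open(path, "w") as fh:
        for name, p in zip(montage.names, montage.positions):
            fh.write(f"{name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
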