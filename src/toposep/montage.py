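"""Electrode montages on the unit sphere.

Spherical convention
--------------------
``theta`` is the polar angle in degrees measured from the vertex (+z), and
``phi`` the azimuth in degrees measured from the right preauricular axis
(+x) towards the nose (+y):

    x = sin(theta) cos(phi)      (+x = right)
    y = sin(theta) sin(phi)      (+y = anterior / nose)
    z = cos(theta)               (+z = vertex)

so ``phi = 90`` is the anterior midline and ``phi = -90`` the posterior
midline.  EEG packages disagree on this convention; it is fixed here because
it places the virtual channel FzFCz (theta 34, phi 90) anteriorly and CzCPz
(theta 11, phi -90) posteriorly, consistent with their scalp positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Montage",
    "to_cartesian",
    "to_spherical",
    "standard_montage",
    "STANDARD_64_LABELS",
]

#: Labels of a standard 64-channel cap laid out on the extended 10-20
#: (10-10) system.  Positions are resolved against the idealized-head
#: coordinates shipped with MNE and projected onto a best-fit sphere.
STANDARD_64_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
)


def to_cartesian(theta, phi):
    """Convert spherical angles in degrees to unit vectors.

    Accepts scalars or arrays; returns an array with a trailing axis of
    length 3.  ``(0, anything)`` maps to the vertex ``(0, 0, 1)``.
    """
    th = np.deg2rad(np.asarray(theta, dtype=float))
    ph = np.deg2rad(np.asarray(phi, dtype=float))
    st = np.sin(th)
    out = np.stack([st * np.cos(ph), st * np.sin(ph), np.cos(th)], axis=-1)
    return out


def to_spherical(xyz):
    """Convert unit vectors to ``(theta, phi)`` in degrees.

    ``theta`` in [0, 180]; ``phi`` in (-180, 180].  At the poles phi is 0.
    """
    v = np.asarray(xyz, dtype=float)
    theta = np.degrees(np.arccos(np.clip(v[..., 2], -1.0, 1.0)))
    phi = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    return theta, phi


@dataclass(frozen=True)
class Montage:
    """An ordered set of named electrode positions on the unit sphere."""

    labels: tuple[str, ...]
    theta: np.ndarray  # degrees, polar from vertex
    phi: np.ndarray    # degrees, azimuth (+90 anterior)
    radius: float = 1.0
    cartesian: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        if len(labels) < 2:
            raise ValueError("a montage needs at least 2 channels")
        if len(set(labels)) != len(labels):
            raise ValueError("montage labels must be unique")
        if not (len(labels) == theta.size == phi.size):
            raise ValueError("labels, theta and phi must have equal length")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "phi", phi)
        cart = to_cartesian(theta, phi)
        object.__setattr__(self, "cartesian", cart)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def subset(self, labels) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(tuple(labels), self.theta[idx], self.phi[idx])

    def extended(self, defs) -> "Montage":
        """Return a montage with ``(label, theta, phi)`` channels appended."""
        new_labels = [d[0] for d in defs]
        for l in new_labels:
            if l in self.labels:
                raise ValueError(f"channel {l!r} already in montage")
        return Montage(
            self.labels + tuple(new_labels),
            np.concatenate([self.theta, [float(d[1]) for d in defs]]),
            np.concatenate([self.phi, [float(d[2]) for d in defs]]),
        )

    # ---------------------------------------------------------------- I/O
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\ttheta\tphi\n")
            for l, t, p in zip(self.labels, self.theta, self.phi):
                fh.write(f"{l}\t{t:.10g}\t{p:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "Montage":
        labels, theta, phi = [], [], []
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header[:3] != ["label", "theta", "phi"]:
                raise ValueError(f"unrecognized montage TSV header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                l, t, p = line.strip().split("\t")[:3]
                labels.append(l)
                theta.append(float(t))
                phi.append(float(p))
        return cls(tuple(labels), np.array(theta), np.array(phi))


def _mne_1005_positions():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import mne

        try:
            mon = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # renamed in newer MNE releases
            mon = mne.channels.make_standard_montage("colin27_1005")
    return mon.get_positions()["ch_pos"]


def standard_montage(labels=STANDARD_64_LABELS) -> Montage:
    """Build a spherical montage for standard 10-10 channel labels.

    Positions come from the idealized-head electrode table shipped with MNE
    (head frame: +x right, +y nasion, +z up, matching this package's
    convention), projected onto the unit sphere about the best-fit sphere
    center of the requested channel set.
    """
    pos = _mne_1005_positions()
    missing = [l for l in labels if l not in pos]
    if missing:
        raise KeyError(f"labels not in the standard 10-10 table: {missing}")
    X = np.array([pos[l] for l in labels], dtype=float)
    # least-squares sphere fit: |x - c|^2 = r^2
    A = np.hstack([2 * X, np.ones((len(X), 1))])
    b = (X ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    U = X - center
    U /= np.linalg.norm(U, axis=1, keepdims=True)
    theta, phi = to_spherical(U)
    return Montage(tuple(labels), theta, phi)
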