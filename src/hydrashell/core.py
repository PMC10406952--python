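"""Domain types and periodic geometry for ion hydration-shell analysis.

Unit system used throughout the package: lengths in Angstrom, times in ps,
energies in kJ/mol, charges in units of the elementary charge e.  The Coulomb
prefactor in these units is ``KE_COULOMB`` = 1/(4 pi eps0) = 1389.35458
kJ Angstrom / (mol e^2).

Waters follow the rigid four-site TIP4P/2005 geometry: O-H 0.9572 A, H-O-H
104.52 deg, and a massless charge site M on the bisector 0.1546 A from the
oxygen (charges +0.5564 e on each H, -1.1128 e on M).  The resulting molecular
dipole is 0.4795 e*A ~ 2.30 D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

KE_COULOMB = 1389.35458  # kJ * Angstrom / (mol * e^2)
KB = 8.314462618e-3      # kJ / (mol * K)

# Rigid water geometry (TIP4P/2005)
OH_BOND = 0.9572         # Angstrom
HOH_ANGLE = 104.52       # degrees
OM_DIST = 0.1546         # Angstrom, M site on the H-O-H bisector
Q_H = 0.5564             # e
Q_M = -2.0 * Q_H         # e
WATER_MOLAR_MASS = 18.015268  # g/mol


class HydrashellError(Exception):
    """Base class for package errors."""


class FormatError(HydrashellError):
    """Malformed trajectory file or unsupported dialect."""


class AnalysisError(HydrashellError):
    """An analysis precondition failed (degenerate profile, empty shell ...)."""


@dataclass(frozen=True)
class Box:
    """Periodic cubic simulation box."""

    edge_length: float
    periodic: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.edge_length) or self.edge_length <= 0:
            raise ValueError(f"box edge must be positive, got {self.edge_length}")

    @property
    def volume(self) -> float:
        return float(self.edge_length) ** 3

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Map positions into [0, L) componentwise."""
        pos = np.asarray(positions, dtype=float)
        if not self.periodic:
            return pos
        return np.mod(pos, self.edge_length)


def min_image_displacement(a, b, box: Box) -> np.ndarray:
    """Minimum-image displacement b - a in a cubic periodic box.

    Every component of the result lies in [-L/2, L/2).  ``b`` may be an
    (N, 3) array; the displacement is broadcast over the leading axis.
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if box is not None and box.periodic:
        L = box.edge_length
        d = d - L * np.floor(d / L + 0.5)
    return d


def min_image_distance(a, b, box: Box) -> np.ndarray:
    return np.linalg.norm(min_image_displacement(a, b, box), axis=-1)


@dataclass
class Site:
    """A point interaction site: position (Angstrom), charge (e), label."""

    position: np.ndarray
    charge: float = 0.0
    species: str = "X"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("site coordinates must be finite")


@dataclass
class WaterRecord:
    """A rigid water molecule: oxygen, two hydrogens, optional M site."""

    oxygen: Site
    hydrogens: Sequence[Site]
    msite: Site | None = None

    def __post_init__(self) -> None:
        if len(self.hydrogens) != 2:
            raise ValueError("a water needs exactly two hydrogen sites")

    def sites(self) -> list[Site]:
        out = [self.oxygen, *self.hydrogens]
        if self.msite is not None:
            out.append(self.msite)
        return out

    @property
    def dipole(self) -> np.ndarray:
        """Charge-weighted first moment about the oxygen (e * Angstrom)."""
        return water_dipole(self)

    def check_rigid(self, box: Box | None = None, tol: float = 1e-6) -> None:
        """Verify O-H bond lengths and the H-O-H angle against the rigid model."""
        o = self.oxygen.position
        vh = [min_image_displacement(o, h.position, box) for h in self.hydrogens]
        for v in vh:
            if abs(np.linalg.norm(v) - OH_BOND) > tol:
                raise AnalysisError("O-H bond deviates from the rigid geometry")
        cosang = np.dot(vh[0], vh[1]) / (np.linalg.norm(vh[0]) * np.linalg.norm(vh[1]))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if abs(ang - HOH_ANGLE) > 1e-3:
            raise AnalysisError("H-O-H angle deviates from the rigid geometry")


def water_dipole(w: WaterRecord, box: Box | None = None) -> np.ndarray:
    """Dipole moment of one water about its oxygen, in e*Angstrom.

    Sum of q_i * (r_i - r_O) over all charged sites; for symmetric hydrogen
    charges the vector lies along the H-O-H bisector.  Site separations are
    taken minimum-image when a box is supplied, so wrapped frames are safe.
    """
    if w.hydrogens is None or len(w.hydrogens) != 2:
        raise ValueError("water lacks hydrogen sites")
    o = w.oxygen.position
    mu = np.zeros(3)
    for s in w.sites():
        mu += s.charge * min_image_displacement(o, s.position, box)
    return mu


def canonical_water() -> WaterRecord:
    """Rigid water at the origin with its dipole (bisector) along +z."""
    half = np.radians(HOH_ANGLE / 2.0)
    h1 = OH_BOND * np.array([np.sin(half), 0.0, np.cos(half)])
    h2 = OH_BOND * np.array([-np.sin(half), 0.0, np.cos(half)])
    m = np.array([0.0, 0.0, OM_DIST])
    return WaterRecord(
        oxygen=Site(np.zeros(3), 0.0, "OW"),
        hydrogens=[Site(h1, Q_H, "HW1"), Site(h2, Q_H, "HW2")],
        msite=Site(m, Q_M, "MW"),
    )


def build_water(center, rotation: np.ndarray | None = None) -> WaterRecord:
    """Place a rigid water with its oxygen at ``center``.

    ``rotation`` is a 3x3 rotation matrix applied to the canonical
    (+z-bisector) orientation before translation.
    """
    w = canonical_water()
    center = np.asarray(center, dtype=float)
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    for s in w.sites():
        s.position = R @ s.position + center
    return w


@dataclass
class Frame:
    """One configuration: ions, waters, box, and a time stamp (ps)."""

    time: float
    ions: list[Site]
    waters: list[WaterRecord]
    box: Box | None = None
    wrap: bool = True

    def __post_init__(self) -> None:
        if self.box is not None and self.box.periodic and self.wrap:
            for s in self.all_sites():
                s.position = self.box.wrap(s.position)

    def all_sites(self) -> Iterator[Site]:
        for ion in self.ions:
            yield ion
        for w in self.waters:
            yield from w.sites()

    def oxygen_positions(self) -> np.ndarray:
        if not self.waters:
            return np.zeros((0, 3))
        return np.array([w.oxygen.position for w in self.waters])

    def ion_positions(self) -> np.ndarray:
        if not self.ions:
            return np.zeros((0, 3))
        return np.array([s.position for s in self.ions])

    def water_dipoles(self) -> np.ndarray:
        return np.array([water_dipole(w, self.box) for w in self.waters])


@dataclass
class Trajectory:
    """An ordered, uniformly spaced sequence of frames."""

    frames: list[Frame]

    def __post_init__(self) -> None:
        times = np.array([f.time for f in self.frames], dtype=float)
        if len(times) > 1:
            dts = np.diff(times)
            if np.any(dts <= 0):
                raise ValueError("frame times must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ValueError("frame spacing must be uniform")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    @property
    def dt(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return self.frames[1].time - self.frames[0].time

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def oxygen_positions(self) -> np.ndarray:
        """(n_frames, n_waters, 3) oxygen coordinates."""
        return np.array([f.oxygen_positions() for f in self.frames])

    def ion_positions(self) -> np.ndarray:
        return np.array([f.ion_positions() for f in self.frames])
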