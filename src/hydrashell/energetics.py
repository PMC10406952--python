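"""Pairwise energetics: Lennard-Jones + Coulomb site sums and the derived
hydration-shell energy scales.

Sign convention everywhere: attraction negative, repulsion positive.  The
relevant scalars are

* ``E_w-w``      mean interaction energy between two neighbouring waters in
                 the same hydration shell (negative while H-bonding dominates,
                 positive once radial dipole alignment makes the pair repel);
* ``dE_ion_water``  magnitude of the mean ion - (single shell water)
                 interaction energy;
* ``E_hbond``    mean pair energy over hydrogen-bonded pairs in neat water,
                 with a +-1 sd thermal band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AnalysisError,
    Box,
    Frame,
    KE_COULOMB,
    Site,
    Trajectory,
    WaterRecord,
    min_image_displacement,
)
from .hbond import detect_hbonds
from .shell import ShellAssignment


@dataclass(frozen=True)
class PairParams:
    """Lennard-Jones well depth/diameter and an optional whole-box cutoff."""

    epsilon: float  # kJ/mol
    sigma: float    # Angstrom
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.epsilon < 0 or self.sigma <= 0:
            raise ValueError("need epsilon >= 0 and sigma > 0")


# TIP4P/2005 oxygen-oxygen LJ parameters
TIP4P2005_OO = PairParams(epsilon=0.7749, sigma=3.1589)


def lj_energy(r: float, epsilon: float, sigma: float) -> float:
    """4 eps [ (sigma/r)^12 - (sigma/r)^6 ]."""
    if r <= 0:
        raise ValueError("zero separation in LJ energy")
    x6 = (sigma / r) ** 6
    return 4.0 * epsilon * (x6 * x6 - x6)


def coulomb_energy(q1: float, q2: float, r: float) -> float:
    if r <= 0:
        raise ValueError("zero separation in Coulomb energy")
    return KE_COULOMB * q1 * q2 / r


def charge_dipole_energy(q: float, dipole: np.ndarray, r_vec: np.ndarray) -> float:
    """Energy of a point dipole in the field of a charge at displacement r_vec.

    ``r_vec`` points from the charge to the dipole; U = -k_e q (p . rhat)/r^2.
    A dipole pointing radially away from a cation is bound (negative energy).
    """
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec)
    if r <= 0:
        raise ValueError("zero separation in charge-dipole energy")
    return -KE_COULOMB * q * float(np.dot(dipole, r_vec)) / r**3


def dipole_dipole_energy(p1: np.ndarray, p2: np.ndarray, r_vec: np.ndarray) -> float:
    """Point dipole-dipole energy; r_vec joins the two dipole positions."""
    r_vec = np.asarray(r_vec, dtype=float)
    r = np.linalg.norm(r_vec)
    if r <= 0:
        raise ValueError("zero separation in dipole-dipole energy")
    rhat = r_vec / r
    return KE_COULOMB * (np.dot(p1, p2) - 3.0 * np.dot(p1, rhat) * np.dot(p2, rhat)) / r**3


def pair_potential(
    sites_a: list[Site],
    sites_b: list[Site],
    params: PairParams,
    box: Box | None = None,
    lj_pair: tuple[int, int] | None = (0, 0),
) -> float:
    """LJ + Coulomb interaction energy between two disjoint site groups.

    The LJ term acts between one designated site of each group (``lj_pair``
    indices, conventionally the oxygens / the ion); Coulomb runs over every
    charged site pair with minimum-image separations.  No cutoff truncation is
    applied here - a cutoff only matters when scanning whole boxes.
    """
    e = 0.0
    if lj_pair is not None and params.epsilon > 0:
        ra = sites_a[lj_pair[0]].position
        rb = sites_b[lj_pair[1]].position
        r = float(np.linalg.norm(min_image_displacement(ra, rb, box)))
        e += lj_energy(r, params.epsilon, params.sigma)
    for sa in sites_a:
        if sa.charge == 0.0:
            continue
        for sb in sites_b:
            if sb.charge == 0.0:
                continue
            r = float(np.linalg.norm(
                min_image_displacement(sa.position, sb.position, box)))
            e += coulomb_energy(sa.charge, sb.charge, r)
    return e


@dataclass
class PairEnergyResult:
    """Mean/spread of a population of pair energies (kJ/mol)."""

    mean: float
    sd: float
    energies: np.ndarray
    n_pairs: int


def _frames(obj) -> list[Frame]:
    if isinstance(obj, Trajectory):
        return list(obj.frames)
    if isinstance(obj, Frame):
        return [obj]
    return list(obj)


def shell_pair_energy(
    traj,
    shell: ShellAssignment,
    params: PairParams = TIP4P2005_OO,
    neighbour_gate: float = 3.5,
) -> PairEnergyResult:
    """E_w-w: mean energy of neighbouring water pairs inside the same shell.

    Neighbouring means O-O below ``neighbour_gate`` (default the H-bond
    distance gate, a stand-in for the first minimum of the water-water RDF).
    The full pair-energy distribution is returned for unimodality checks.
    """
    energies = []
    for fi, frame in enumerate(_frames(traj)):
        members = shell.membership[min(fi, len(shell.membership) - 1)]
        for ion_members in members:
            idx = list(ion_members)
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    wa, wb = frame.waters[idx[a]], frame.waters[idx[b]]
                    d = np.linalg.norm(min_image_displacement(
                        wa.oxygen.position, wb.oxygen.position, frame.box))
                    if d < neighbour_gate:
                        energies.append(pair_potential(
                            wa.sites(), wb.sites(), params, frame.box))
    if not energies:
        raise AnalysisError("no qualifying shell water pairs")
    arr = np.asarray(energies)
    return PairEnergyResult(float(arr.mean()), float(arr.std()), arr, len(arr))


def ion_water_energy(
    traj,
    shell: ShellAssignment,
    params: PairParams,
) -> PairEnergyResult:
    """dE_ion_water: |mean ion - shell-water interaction| over members and frames.

    Each sample is the full LJ(ion-O) + Coulomb(ion vs water sites) energy of
    one ion/shell-water pair; the returned ``mean`` is its magnitude (the
    signed mean sits in the distribution).
    """
    energies = []
    for fi, frame in enumerate(_frames(traj)):
        members = shell.membership[min(fi, len(shell.membership) - 1)]
        for ion, ion_members in zip(frame.ions, members):
            for wi in ion_members:
                w = frame.waters[wi]
                energies.append(pair_potential(
                    [ion], w.sites(), params, frame.box, lj_pair=(0, 0)))
    if not energies:
        raise AnalysisError("empty shell")
    arr = np.asarray(energies)
    return PairEnergyResult(float(abs(arr.mean())), float(arr.std()), arr, len(arr))


def hbond_energy_bulk(
    frames,
    params: PairParams = TIP4P2005_OO,
) -> PairEnergyResult:
    """E_hbond and its thermal band from neat-water frames.

    Mean pair energy over (unordered) hydrogen-bonded pairs; the band is one
    population standard deviation.
    """
    energies = []
    for frame in _frames(frames):
        bonds = detect_hbonds(frame)
        seen = set()
        for b in bonds:
            key = (min(b.donor, b.acceptor), max(b.donor, b.acceptor))
            if key in seen:
                continue
            seen.add(key)
            wa, wb = frame.waters[key[0]], frame.waters[key[1]]
            energies.append(pair_potential(wa.sites(), wb.sites(), params, frame.box))
    if not energies:
        raise AnalysisError("no hydrogen bonds detected")
    arr = np.asarray(energies)
    return PairEnergyResult(float(arr.mean()), float(arr.std()), arr, len(arr))
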