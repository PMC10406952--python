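"""Hydrogen-bond detection and shell-resolved H-bond statistics.

The Luzar-Chandler geometric criterion is used throughout: two waters are
H-bonded when their (minimum-image) O-O distance is below 3.5 Angstrom and the
angle between the donor's O-H bond vector and the donor-O -> acceptor-O vector
is below 30 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AnalysisError, Frame, Trajectory, min_image_displacement
from .shell import ShellAssignment

OO_CUTOFF = 3.5     # Angstrom
ANGLE_CUTOFF = 30.0  # degrees


@dataclass(frozen=True)
class HBond:
    donor: int          # water index of the donor (its O-H points at the acceptor)
    acceptor: int
    distance: float     # O-O, Angstrom
    angle: float        # H-O...O, degrees


def detect_hbonds(
    frame: Frame,
    oo_cutoff: float = OO_CUTOFF,
    angle_cutoff: float = ANGLE_CUTOFF,
) -> list[HBond]:
    """All ordered donor -> acceptor H-bonded water pairs in a frame."""
    waters = frame.waters
    n = len(waters)
    if n == 0:
        return []
    for w in waters:
        if len(w.hydrogens) != 2:
            raise AnalysisError("waters lack hydrogen sites")
    box = frame.box
    opos = frame.oxygen_positions()
    bonds: list[HBond] = []
    for i in range(n):
        doo = min_image_displacement(opos[i], opos, box)      # (n, 3)
        dist = np.linalg.norm(doo, axis=1)
        # O-H bond vectors of the donor (minimum-image, wrapped frames safe)
        ohs = [min_image_displacement(opos[i], h.position, box)
               for h in waters[i].hydrogens]
        for j in np.nonzero((dist < oo_cutoff) & (dist > 0))[0]:
            if j == i:
                continue
            udoo = doo[j] / dist[j]
            best = 180.0
            for oh in ohs:
                c = float(np.dot(oh, udoo)) / np.linalg.norm(oh)
                ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
                best = min(best, ang)
            if best < angle_cutoff:
                bonds.append(HBond(i, int(j), float(dist[j]), best))
    return bonds


@dataclass
class ShellHBondStats:
    """Shell-resolved H-bond statistics.

    ``n_hw_hw``         mean H-bonds per hydrated water with partners in the
                        same shell (both donated and accepted bonds count);
    ``bridging_per_ion``  mean count per ion of bridging waters - non-shell
                        waters between r1 and ``second_limit`` H-bonded to at
                        least two distinct first-shell waters;
    ``bridging_per_shell_water``  the same count normalised per shell water.
    """

    n_hw_hw: float
    bridging_per_ion: float
    bridging_per_shell_water: float


def shell_hbond_stats(
    traj,
    shell: ShellAssignment,
    second_limit: float | None = None,
    oo_cutoff: float = OO_CUTOFF,
    angle_cutoff: float = ANGLE_CUTOFF,
) -> ShellHBondStats:
    """Fig-1-style shell H-bond statistics averaged over frames and ions."""
    if second_limit is None:
        second_limit = shell.second_limit()
    frames = list(traj.frames) if isinstance(traj, Trajectory) else [traj]
    per_water_counts: list[float] = []
    bridging_counts: list[float] = []
    shell_sizes: list[int] = []
    for fi, frame in enumerate(frames):
        bonds = detect_hbonds(frame, oo_cutoff, angle_cutoff)
        # undirected partner sets per water
        partners: dict[int, set[int]] = {}
        for b in bonds:
            partners.setdefault(b.donor, set()).add(b.acceptor)
            partners.setdefault(b.acceptor, set()).add(b.donor)
        members = shell.membership[min(fi, len(shell.membership) - 1)]
        opos = frame.oxygen_positions()
        for ion, ion_members in zip(frame.ions, members):
            mset = set(int(m) for m in ion_members)
            if not mset:
                raise AnalysisError("empty shell")
            for m in mset:
                per_water_counts.append(
                    len(partners.get(m, set()) & (mset - {m})))
            # bridging waters: outside the shell but inside second_limit,
            # H-bonded to >= 2 distinct first-shell waters
            r = np.linalg.norm(
                min_image_displacement(ion.position, opos, frame.box), axis=1)
            nbridge = 0
            for w in range(len(frame.waters)):
                if w in mset or not (shell.r1 < r[w] <= second_limit):
                    continue
                if len(partners.get(w, set()) & mset) >= 2:
                    nbridge += 1
            bridging_counts.append(nbridge)
            shell_sizes.append(len(mset))
    n_hw_hw = float(np.mean(per_water_counts))
    per_ion = float(np.mean(bridging_counts))
    per_sw = float(np.sum(bridging_counts) / np.sum(shell_sizes))
    return ShellHBondStats(n_hw_hw, per_ion, per_sw)
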