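"""Shared fixture builders: oriented waters, dimers, random water frames."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from hydrashell.core import (
    Box,
    Frame,
    HOH_ANGLE,
    OH_BOND,
    Site,
    build_water,
    canonical_water,
)


def canonical_oh_directions() -> tuple[np.ndarray, np.ndarray]:
    half = np.radians(HOH_ANGLE / 2.0)
    d1 = np.array([np.sin(half), 0.0, np.cos(half)])
    d2 = np.array([-np.sin(half), 0.0, np.cos(half)])
    return d1, d2


def water_with_oh_toward(center, target):
    """Rigid water at ``center`` whose first O-H bond points at ``target``."""
    center = np.asarray(center, dtype=float)
    direction = np.asarray(target, dtype=float) - center
    direction = direction / np.linalg.norm(direction)
    d1, _ = canonical_oh_directions()
    rot, _ = Rotation.align_vectors([direction], [d1])
    return build_water(center, rot.as_matrix())


def water_with_oh_directions(center, dir1, dir2):
    """Rigid water at ``center`` with its two O-H bonds along dir1/dir2.

    The two directions must subtend the rigid H-O-H angle; the rotation is
    then exact.
    """
    dir1 = np.asarray(dir1, float) / np.linalg.norm(dir1)
    dir2 = np.asarray(dir2, float) / np.linalg.norm(dir2)
    d1, d2 = canonical_oh_directions()
    rot, rssd = Rotation.align_vectors([dir1, dir2], [d1, d2])
    assert rssd < 1e-6, "target directions incompatible with the rigid angle"
    return build_water(center, rot.as_matrix())


def random_water_frame(n_waters, L, seed, ion_at_center=True, time=0.0):
    """Waters at uniform random positions/orientations (no packing floor)."""
    rng = np.random.default_rng(seed)
    waters = []
    for _ in range(n_waters):
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        waters.append(build_water(rng.uniform(0, L, 3),
                                  Rotation.from_quat(q).as_matrix()))
    ions = [Site(np.full(3, L / 2.0), 1.0, "ION")] if ion_at_center else []
    return Frame(time=time, ions=ions, waters=waters, box=Box(L), wrap=False)


def attractive_dimer(origin, d_oo=2.8):
    """A genuinely attractive H-bonded water dimer along +x.

    Donor O-H points straight at the acceptor oxygen; the acceptor's bisector
    is tilted ~50 deg off the O-O axis, near the minimum-energy orientation of
    the rigid four-site pair at this separation.
    """
    o1 = np.asarray(origin, dtype=float)
    o2 = o1 + np.array([d_oo, 0.0, 0.0])
    theta = np.radians(HOH_ANGLE)
    d1 = np.array([1.0, 0.0, 0.0])
    d2 = np.cos(theta) * d1 + np.sin(theta) * np.array([0.0, 0.0, 1.0])
    donor = water_with_oh_directions(o1, d1, d2)
    tilt = np.radians(50.0)
    bis = np.array([np.cos(tilt), 0.0, -np.sin(tilt)])
    rot, _ = Rotation.align_vectors([bis], [[0.0, 0.0, 1.0]])
    acceptor = build_water(o2, rot.as_matrix())
    return donor, acceptor


def brute_force_min_distance(a, b, L):
    """Minimum distance between a and b over all 27 periodic images."""
    best = np.inf
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            for iz in (-1, 0, 1):
                shift = np.array([ix, iy, iz], float) * L
                best = min(best, float(np.linalg.norm(
                    np.asarray(b) + shift - np.asarray(a))))
    return best
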