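"""Radial structure of the first hydration shell.

Implements the ion-oxygen RDF g(r) with its running coordination number, the
location of the first shell (peak position d, first minimum r1, coordination
number n), the translational order parameter

    t = (1/xi_c) * int_0^{xi_c} |g(xi) - 1| dxi,   xi = r * rho^(1/3),

with the one-component order-map cutoff xi_c = 2.843, and the radial profile
of the dipolar order parameter <cos theta>.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import AnalysisError, Frame, Trajectory, min_image_displacement

XI_C = 2.843  # dimensionless cutoff of the translational order integral


@dataclass
class RadialProfile:
    """Binned ion-oxygen g(r) with running coordination number."""

    r: np.ndarray            # bin centres, Angstrom
    g: np.ndarray
    running_n: np.ndarray    # direct count within r, per ion per frame
    rho: float               # partner number density, 1/Angstrom^3
    bin_width: float

    def running_n_integral(self) -> np.ndarray:
        """Coordination number as the integral 4 pi rho int g r^2 dr."""
        integrand = 4.0 * np.pi * self.rho * self.g * self.r**2
        return np.concatenate([[0.0], np.cumsum(
            0.5 * (integrand[1:] + integrand[:-1]) * np.diff(self.r))])


def _ion_oxygen_distances(frame: Frame, ion_indices) -> np.ndarray:
    opos = frame.oxygen_positions()
    rows = []
    for k in ion_indices:
        d = min_image_displacement(frame.ions[k].position, opos, frame.box)
        rows.append(np.linalg.norm(d, axis=1))
    return np.array(rows)  # (n_ions, n_waters)


def compute_rdf(
    traj,
    bin_width: float = 0.02,
    r_max: float | None = None,
    ion_indices=None,
) -> RadialProfile:
    """Shell-volume-normalised ion-oxygen pair histogram, frame-averaged."""
    frames = list(traj.frames) if isinstance(traj, Trajectory) else [traj]
    if not frames:
        raise AnalysisError("empty trajectory")
    L = min(f.box.edge_length for f in frames)
    if r_max is None:
        r_max = L / 2.0
    if r_max > L / 2.0 + 1e-9:
        raise AnalysisError(f"r_max {r_max} exceeds half the box {L / 2}")
    if ion_indices is None:
        ion_indices = range(len(frames[0].ions))
    ion_indices = list(ion_indices)
    if not ion_indices or not frames[0].waters:
        raise AnalysisError("empty ion or oxygen selection")

    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    rho_acc = 0.0
    for frame in frames:
        d = _ion_oxygen_distances(frame, ion_indices).ravel()
        counts += np.histogram(d, bins=edges)[0]
        rho_acc += len(frame.waters) / frame.box.volume
    n_samples = len(frames) * len(ion_indices)
    rho = rho_acc / len(frames)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (n_samples * rho * shell_vol)
    # midpoint-consistent running count: at a bin centre, half that bin
    running = (np.cumsum(counts) - 0.5 * counts) / n_samples
    centres = 0.5 * (edges[1:] + edges[:-1])
    return RadialProfile(centres, g, running, rho, bin_width)


@dataclass
class ShellAssignment:
    """First-shell geometry and per-frame membership.

    ``membership[frame][ion]`` is an integer array of water indices inside r1.
    """

    d: float    # first-peak position, Angstrom
    r1: float   # first-minimum position, Angstrom
    n: float    # frame-averaged direct count within r1
    membership: list = field(default_factory=list)
    r2: float | None = None  # second-minimum position if resolvable

    def __post_init__(self) -> None:
        if not (0 < self.d < self.r1):
            raise ValueError("need 0 < d < r1")

    def second_limit(self) -> float:
        """Outer gate for bridging waters: second minimum, or r1 + 1.5 A."""
        return self.r2 if self.r2 is not None else self.r1 + 1.5


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-bin extremum via a 3-point parabola through (x[i-1..i+1], y)."""
    if i <= 0 or i >= len(x) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    h = x[i + 1] - x[i]
    return float(x[i] + delta * h), float(y1 - 0.25 * (y0 - y2) * delta)


def locate_shell(
    profile: RadialProfile,
    traj=None,
    ion_indices=None,
    min_depth: float | None = None,
) -> ShellAssignment:
    """Locate the first shell (d, r1) and record per-frame membership.

    The first interior maximum of g gives d; the first interior minimum after
    it whose depth exceeds ``min_depth`` (default: one standard deviation of
    the noise, estimated from the profile tail) gives r1.  Sub-bin positions
    come from a 3-point parabola.  ``n`` is the frame-averaged direct count
    within r1 when a trajectory is supplied, else the running-count estimate.
    """
    g, r = profile.g, profile.r
    if min_depth is None:
        tail = g[int(0.8 * len(g)):]
        min_depth = float(np.std(tail)) if len(tail) > 3 else 0.0
    peaks, _ = find_peaks(g, prominence=max(min_depth, 1e-12))
    if len(peaks) == 0:
        raise AnalysisError("no interior peak in g(r): flat or monotone profile")
    ipk = int(peaks[0])
    d, _ = _parabolic_refine(r, g, ipk)

    minima, props = find_peaks(-g[ipk:], prominence=max(min_depth, 1e-12))
    if len(minima) > 0:
        imin = ipk + int(minima[0])
    else:
        # isolated shell: g falls to a flat floor with no rise afterwards;
        # take the first post-peak point attaining the post-peak minimum
        post = g[ipk + 1:]
        if len(post) == 0 or post.min() >= g[ipk] - max(min_depth, 1e-12):
            raise AnalysisError("no interior minimum after the first peak")
        imin = ipk + 1 + int(np.argmax(post <= post.min() + 1e-12))
    r1, _ = _parabolic_refine(r, g, imin)
    r2 = None
    minima2, _ = find_peaks(-g[imin + 1:], prominence=max(min_depth, 1e-12))
    peaks2, _ = find_peaks(g[imin:], prominence=max(min_depth, 1e-12))
    if len(peaks2) > 0 and len(minima2) > 0:
        cand = imin + 1 + int(minima2[0])
        if cand > imin + int(peaks2[0]):
            r2, _ = _parabolic_refine(r, g, cand)

    membership: list = []
    if traj is not None:
        frames = list(traj.frames) if isinstance(traj, Trajectory) else [traj]
        if ion_indices is None:
            ion_indices = range(len(frames[0].ions))
        ion_indices = list(ion_indices)
        counts = []
        for frame in frames:
            dist = _ion_oxygen_distances(frame, ion_indices)
            per_ion = [np.nonzero(dist[i] <= r1)[0] for i in range(len(ion_indices))]
            membership.append(per_ion)
            counts.extend(len(m) for m in per_ion)
        n = float(np.mean(counts))
    else:
        n = float(np.interp(r1, profile.r, profile.running_n))
    return ShellAssignment(d=d, r1=r1, n=n, membership=membership, r2=r2)


def translational_order(profile: RadialProfile, xi_c: float = XI_C) -> float:
    """Translational order parameter t on the density-scaled abscissa."""
    scale = profile.rho ** (1.0 / 3.0)
    xi = profile.r * scale
    if xi[-1] < xi_c:
        raise AnalysisError(
            f"profile truncated at xi={xi[-1]:.3f} before xi_c={xi_c}")
    dev = np.abs(profile.g - 1.0)
    # integrate on [0, xi_c]; extend flat to xi=0 from the first bin centre
    grid = np.linspace(0.0, xi_c, 4096)
    vals = np.interp(grid, xi, dev, left=dev[0])
    return float(np.trapezoid(vals, grid) / xi_c)


@dataclass
class DipolarProfile:
    """<cos theta> binned by ion-oxygen distance."""

    r: np.ndarray
    cos_theta: np.ndarray  # NaN where a bin is unoccupied
    counts: np.ndarray


def dipolar_profile(
    traj,
    bin_width: float = 0.1,
    r_max: float | None = None,
    ion_indices=None,
) -> DipolarProfile:
    """Radial profile of the dipolar order parameter.

    theta is the angle between the water dipole and the ion -> oxygen vector;
    +1 means the dipole points radially away from the ion (the bound
    orientation around a cation).
    """
    frames = list(traj.frames) if isinstance(traj, Trajectory) else [traj]
    L = min(f.box.edge_length for f in frames)
    if r_max is None:
        r_max = L / 2.0
    if ion_indices is None:
        ion_indices = range(len(frames[0].ions))
    ion_indices = list(ion_indices)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1)
    for frame in frames:
        mu = frame.water_dipoles()
        norms = np.linalg.norm(mu, axis=1)
        if np.any(norms <= 0):
            raise AnalysisError("zero water dipole magnitude")
        mu = mu / norms[:, None]
        opos = frame.oxygen_positions()
        for k in ion_indices:
            dvec = min_image_displacement(frame.ions[k].position, opos, frame.box)
            dist = np.linalg.norm(dvec, axis=1)
            cos = np.einsum("ij,ij->i", mu, dvec) / np.where(dist > 0, dist, 1.0)
            sel = (dist > 0) & (dist < r_max)
            idx = np.minimum((dist[sel] / bin_width).astype(int), len(sums) - 1)
            np.add.at(sums, idx, cos[sel])
            np.add.at(counts, idx, 1.0)
    centres = 0.5 * (edges[1:] + edges[:-1])
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DipolarProfile(centres, mean, counts)
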