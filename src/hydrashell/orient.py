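"""Angular order of a hydration shell on the sphere.

A shell of n waters at mean radius R around an ion is treated as a point set
on a sphere.  The geodesic RDF g(phi) is the distribution of oxygen-ion-oxygen
pair angles phi, normalised by the uniform-sphere expectation (pair-angle
density sin(phi)/2) so that a structureless shell gives g = 1.  Its
bond-orientational entropy (in units of k_B, per particle)

    s_phi = -(n/4) * int_0^pi [ g ln g - g + 1 ] sin(phi) dphi

vanishes for uniform coverage and grows more negative with angular order; it
equals -pi rho_s R^2 * int with the surface density rho_s = n/(4 pi R^2).
A ``literal`` switch evaluates the variant with rho = n/(pi R^2) and no area
factor, for cross-reading against tabulations that use that convention.

The Thomson problem (minimal Coulomb energy of n unit charges on the unit
sphere) supplies the reference angles phi_T that ordered shells lock onto.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize

from .core import AnalysisError


@dataclass
class AngularProfile:
    """Kernel-smoothed geodesic pair distribution of a shell."""

    phi_deg: np.ndarray   # bin centres, degrees, on (0, 180)
    g: np.ndarray         # uniform-normalised geodesic RDF
    p: np.ndarray         # normalised pair-angle density, per radian
    n: float              # mean shell occupancy
    radius: float         # mean shell radius, Angstrom
    kernel_width: float   # degrees

    @property
    def phi(self) -> np.ndarray:
        return np.radians(self.phi_deg)

    @property
    def geodesic_l(self) -> np.ndarray:
        """Geodesic distances l = R * phi (Angstrom)."""
        return self.radius * self.phi


def _as_config_list(configs) -> list[np.ndarray]:
    if isinstance(configs, np.ndarray) and configs.ndim == 2:
        return [configs]
    return [np.asarray(c, dtype=float) for c in configs]


def pair_angles(points: np.ndarray) -> np.ndarray:
    """All pair angles (radians) subtended at the origin by a point set."""
    u = points / np.linalg.norm(points, axis=1)[:, None]
    c = np.clip(u @ u.T, -1.0, 1.0)
    iu = np.triu_indices(len(u), k=1)
    return np.arccos(c[iu])


def geodesic_rdf(
    configs,
    kernel_width: float = 5.0,
    n_bins: int = 720,
) -> AngularProfile:
    """Geodesic RDF g(phi) of one or more shell configurations.

    ``configs``: a (n, 3) point set or a sequence of them, positions relative
    to the shell centre (need not sit exactly on one radius).  Pair angles are
    histogrammed on (0, pi), smoothed with a Gaussian kernel of
    ``kernel_width`` degrees (reflecting at both boundaries, which conserves
    probability mass), and divided by the uniform expectation sin(phi)/2.
    """
    frames = _as_config_list(configs)
    angles = []
    occupancies = []
    radii = []
    for pts in frames:
        if len(pts) >= 2:
            angles.append(pair_angles(pts))
            occupancies.append(len(pts))
            radii.append(np.mean(np.linalg.norm(pts, axis=1)))
    if not angles:
        raise AnalysisError("fewer than 2 shell members in every frame")
    allang = np.concatenate(angles)
    edges = np.linspace(0.0, np.pi, n_bins + 1)
    width = edges[1] - edges[0]
    hist = np.histogram(allang, bins=edges)[0].astype(float)
    centres = 0.5 * (edges[1:] + edges[:-1])
    ref = 0.5 * np.sin(centres)               # uniform-sphere pair-angle density
    sigma_bins = np.radians(kernel_width) / width
    if sigma_bins > 0:
        hist = gaussian_filter1d(hist, sigma_bins, mode="reflect")
        # smooth the uniform reference identically so the ratio is unbiased
        # at the phi = 0 and phi = pi boundaries
        ref = gaussian_filter1d(ref, sigma_bins, mode="reflect")
    p = hist / (len(allang) * width)          # density per radian, integrates to 1
    g = p / ref
    return AngularProfile(
        phi_deg=np.degrees(centres),
        g=g,
        p=p,
        n=float(np.mean(occupancies)),
        radius=float(np.mean(radii)),
        kernel_width=kernel_width,
    )


def entropy_integrand(g: np.ndarray) -> np.ndarray:
    """g ln g - g + 1, with the 0 ln 0 = 0 convention; >= 0 for g >= 0."""
    g = np.asarray(g, dtype=float)
    if np.any(g < -1e-12):
        raise AnalysisError("negative g values in entropy integrand")
    g = np.clip(g, 0.0, None)
    out = np.where(g > 0, g * np.log(np.where(g > 0, g, 1.0)) - g + 1.0, 1.0)
    return out


def bond_orientational_entropy(profile: AngularProfile, literal: bool = False) -> float:
    """s_phi of a shell profile (k_B units); 0 for uniform, negative if ordered."""
    phi = profile.phi
    integrand = entropy_integrand(profile.g) * np.sin(phi)
    integral = float(np.trapezoid(integrand, phi))
    if literal:
        return -(profile.n / profile.radius**2) * integral
    return -(profile.n / 4.0) * integral


def characteristic_angle(profile: AngularProfile, min_contrast: float = 0.2) -> float:
    """phi_ion: location (degrees) of the primary peak of P(phi).

    The peak must carry real angular structure: g at the peak has to exceed
    1 + ``min_contrast``, otherwise the shell is flagged as structureless
    (a uniform shell's P(phi) peaks at 90 deg through the sin(phi) measure
    alone, which is not a characteristic angle).
    """
    p = profile.p
    interior = slice(1, len(p) - 1)
    i = 1 + int(np.argmax(p[interior]))
    if profile.g[i] < 1.0 + min_contrast:
        raise AnalysisError("no interior peak above the uniform background")
    # 3-point parabolic refinement
    y0, y1, y2 = p[i - 1], p[i], p[i + 1]
    denom = y0 - 2.0 * y1 + y2
    delta = 0.0 if denom == 0 else float(np.clip(0.5 * (y0 - y2) / denom, -1, 1))
    h = profile.phi_deg[i + 1] - profile.phi_deg[i]
    return float(profile.phi_deg[i] + delta * h)


# ----------------------------------------------------------- Thomson problem

@dataclass
class ThomsonSolution:
    n: int
    coordinates: np.ndarray   # (n, 3) unit-sphere points
    energy: float             # sum over pairs of 1/r, unit charges/radius
    phi_t: float              # primary nearest-neighbour angle, degrees
    grad_norm: float
    restarts: int


def _coulomb_energy_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
    n = len(x)
    diff = x[:, None, :] - x[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    iu = np.triu_indices(n, k=1)
    e = float(np.sum(1.0 / r[iu]))
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(r > 0, 1.0 / r**3, 0.0)
    grad = -(w[:, :, None] * diff).sum(axis=1)
    return e, grad


def thomson_solve(n: int, restarts: int = 20, seed: int = 0) -> ThomsonSolution:
    """Best-of-restarts minimisation of the Coulomb energy on the unit sphere.

    Free ambient coordinates are radially normalised inside the objective, so
    the energy is scale-invariant per particle and the gradient is projected
    onto the sphere's tangent space; L-BFGS-B then converges quadratically.
    No global-optimality guarantee for large n.
    """
    if n < 2:
        raise ValueError("need at least 2 charges")
    rng = np.random.default_rng(seed)

    def objective(y_flat: np.ndarray) -> tuple[float, np.ndarray]:
        y = y_flat.reshape(n, 3)
        norms = np.linalg.norm(y, axis=1)
        x = y / norms[:, None]
        e, g = _coulomb_energy_grad(x)
        # chain rule through the normalisation: (I - x x^T) / |y|
        gproj = (g - (np.einsum("ij,ij->i", g, x))[:, None] * x) / norms[:, None]
        return e, gproj.ravel()

    best = None
    for _ in range(restarts):
        y0 = rng.standard_normal((n, 3))
        y0 /= np.linalg.norm(y0, axis=1)[:, None]
        res = minimize(objective, y0.ravel(), jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    x = best.x.reshape(n, 3)
    x /= np.linalg.norm(x, axis=1)[:, None]
    energy, grad = _coulomb_energy_grad(x)
    tangent = grad - (np.einsum("ij,ij->i", grad, x))[:, None] * x
    phi_t = _primary_neighbour_angle(x)
    return ThomsonSolution(n=n, coordinates=x, energy=energy, phi_t=phi_t,
                           grad_norm=float(np.linalg.norm(tangent)),
                           restarts=restarts)


def _primary_neighbour_angle(x: np.ndarray) -> float:
    """Median over particles of the nearest-neighbour pair angle (degrees)."""
    c = np.clip(x @ x.T, -1.0, 1.0)
    np.fill_diagonal(c, -2.0)
    nearest = np.degrees(np.arccos(np.clip(c.max(axis=1), -1.0, 1.0)))
    return float(np.median(nearest))
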