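"""Kinetics of the hydration shell: residence correlation, stretched-
exponential fits, conditioned MSD / local diffusion, and the Rosenfeld-like
and Jones-Dole regressions.

The heavy operations work on plain arrays - an occupancy mask
(n_frames, n_ions, n_waters) and a position stack (n_frames, n_particles, 3) -
with helpers to extract these from a molecular Trajectory, so that synthetic
point-particle fixtures (Brownian walks, Markov occupancy chains) are
first-class inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import AnalysisError, Trajectory, min_image_displacement


@dataclass
class CorrelationSeries:
    """Intermittent shell-occupancy correlation P(t)."""

    t: np.ndarray
    p: np.ndarray
    origins: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)


def shell_occupancy(traj: Trajectory, r1: float, ion_indices=None) -> np.ndarray:
    """Boolean (n_frames, n_ions, n_waters) occupancy under the r <= r1 rule."""
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    frames = traj.frames
    if ion_indices is None:
        ion_indices = range(len(frames[0].ions))
    ion_indices = list(ion_indices)
    occ = np.zeros((len(frames), len(ion_indices), len(frames[0].waters)), dtype=bool)
    for fi, frame in enumerate(frames):
        opos = frame.oxygen_positions()
        for ii, k in enumerate(ion_indices):
            d = np.linalg.norm(
                min_image_displacement(frame.ions[k].position, opos, frame.box),
                axis=1)
            occ[fi, ii] = d <= r1
    return occ


def residence_correlation(
    occupancy: np.ndarray,
    times: np.ndarray,
    origin_stride: int = 1,
    max_lag: int | None = None,
) -> CorrelationSeries:
    """P(t) = <p(t0+t) p(t0)> / <p(t0)> over waters, ions, and time origins.

    The indicator is intermittent: a water that leaves and re-enters the shell
    counts as present again.  ``occupancy`` may be (frames, waters) or
    (frames, ions, waters).
    """
    occ = np.asarray(occupancy, dtype=bool)
    if occ.ndim == 2:
        occ = occ[:, None, :]
    nf = occ.shape[0]
    if nf < 2:
        raise AnalysisError("need at least two frames")
    if not occ.any():
        raise AnalysisError("no water ever inside the shell")
    if max_lag is None:
        max_lag = nf // 2
    max_lag = min(max_lag, nf - 1)
    occf = occ.reshape(nf, -1).astype(float)
    p = np.empty(max_lag + 1)
    n_origins = 0
    for lag in range(max_lag + 1):
        o0 = occf[0:nf - lag:origin_stride]
        olag = occf[lag:nf:origin_stride][:len(o0)]
        denom = o0.sum()
        p[lag] = (o0 * olag).sum() / denom if denom > 0 else np.nan
        if lag == 0:
            n_origins = len(o0)
    times = np.asarray(times, dtype=float)
    t = times[:max_lag + 1] - times[0]
    return CorrelationSeries(t=t, p=p, origins=n_origins)


@dataclass
class StretchedExpFit:
    """P(t) = P0 exp[-(t/tau)^beta] least-squares fit."""

    p0: float
    tau: float     # ps
    beta: float
    residual_norm: float
    n_points: int

    def __post_init__(self) -> None:
        if self.tau <= 0 or not (0 < self.beta <= 2):
            raise ValueError("fit outside the physical domain")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.p0 * np.exp(-np.power(t / self.tau, self.beta))


def fit_stretched_exp(series: CorrelationSeries, floor: float = 0.01) -> StretchedExpFit:
    """Nonlinear least squares on points with P > floor.

    Initial guesses: tau from the 1/e crossing, beta = 1, P0 = 1.
    """
    mask = np.isfinite(series.p) & (series.p > floor)
    t, p = series.t[mask], series.p[mask]
    if len(t) < 4:
        raise AnalysisError("fewer than 4 points above the fit floor")
    below = np.nonzero(p <= np.exp(-1.0))[0]
    tau0 = t[below[0]] if len(below) else max(t[-1], 1e-6)
    tau0 = max(float(tau0), 1e-6)

    def model(t, p0, tau, beta):
        return p0 * np.exp(-np.power(np.maximum(t, 0.0) / tau, beta))

    try:
        popt, _ = curve_fit(
            model, t, p, p0=[1.0, tau0, 1.0],
            bounds=([1e-8, 1e-8, 1e-3], [1.5, np.inf, 2.0]), maxfev=20000)
    except RuntimeError as exc:
        raise AnalysisError(f"stretched-exponential fit did not converge: {exc}")
    resid = float(np.linalg.norm(model(t, *popt) - p))
    return StretchedExpFit(p0=float(popt[0]), tau=float(popt[1]),
                           beta=float(popt[2]), residual_norm=resid,
                           n_points=len(t))


@dataclass
class MsdSeries:
    """Mean-squared displacement conditioned on shell membership at t = 0."""

    t: np.ndarray
    msd: np.ndarray   # Angstrom^2
    n_samples: np.ndarray


def unwrap_positions(positions: np.ndarray, box=None) -> np.ndarray:
    """Undo periodic wrapping by accumulating minimum-image increments."""
    pos = np.asarray(positions, dtype=float)
    if box is None:
        return pos
    out = np.empty_like(pos)
    out[0] = pos[0]
    for i in range(1, len(pos)):
        out[i] = out[i - 1] + min_image_displacement(pos[i - 1], pos[i], box)
    return out


def conditioned_msd(
    positions: np.ndarray,
    times: np.ndarray,
    membership: np.ndarray | None = None,
    box=None,
    origin_stride: int = 1,
    max_lag: int | None = None,
) -> MsdSeries:
    """MSD over particles inside the shell at each time origin.

    ``membership`` is a boolean (n_frames, n_particles) mask (``None`` means
    unconditioned).  Displacements are taken on minimum-image-unwrapped
    coordinates; multiple origins with the given stride.
    """
    pos = unwrap_positions(np.asarray(positions, dtype=float), box)
    nf, npart = pos.shape[0], pos.shape[1]
    if membership is None:
        membership = np.ones((nf, npart), dtype=bool)
    membership = np.asarray(membership, dtype=bool)
    if max_lag is None:
        max_lag = nf // 2
    max_lag = min(max_lag, nf - 1)
    origins = np.arange(0, nf - 1, origin_stride)
    if not membership[origins].any():
        raise AnalysisError("no conditioned origins")
    msd = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    for lag in range(1, max_lag + 1):
        valid = origins[origins + lag < nf]
        if len(valid) == 0:
            break
        disp = pos[valid + lag] - pos[valid]          # (n_orig, npart, 3)
        sq = np.einsum("opk,opk->op", disp, disp)
        m = membership[valid]
        msd[lag] = sq[m].sum()
        counts[lag] = m.sum()
    counts[0] = membership[origins].sum()
    with np.errstate(invalid="ignore"):
        msd = np.where(counts > 0, msd / np.maximum(counts, 1), np.nan)
    times = np.asarray(times, dtype=float)
    return MsdSeries(t=times[:max_lag + 1] - times[0], msd=msd, n_samples=counts)


def local_diffusion(msd: MsdSeries, lower: float = 8.0, upper: float = 16.0) -> float:
    """D_1 from the Einstein relation, MSD = 6 D t, fitted on the window
    lower <= MSD <= upper (Angstrom^2).

    The lower bound keeps the fit in the diffusive (linear) regime, the upper
    bound keeps the displacement local to the shell.
    """
    mask = np.isfinite(msd.msd) & (msd.msd >= lower) & (msd.msd <= upper)
    if mask.sum() < 2:
        raise AnalysisError(
            f"MSD window [{lower}, {upper}] A^2 contains fewer than 2 points")
    slope = np.polyfit(msd.t[mask], msd.msd[mask], 1)[0]
    return float(slope / 6.0)


@dataclass
class RosenfeldFit:
    """tau_res = tau0 exp(alpha s_phi); alpha is expected negative."""

    tau0: float
    alpha: float


def rosenfeld_fit(s_phi, tau) -> RosenfeldFit:
    """Linear regression of ln(tau) on s_phi."""
    s = np.asarray(s_phi, dtype=float)
    t = np.asarray(tau, dtype=float)
    if len(s) < 2:
        raise AnalysisError("need at least 2 points")
    if np.any(t <= 0):
        raise AnalysisError("residence times must be positive")
    slope, intercept = np.polyfit(s, np.log(t), 1)
    return RosenfeldFit(tau0=float(np.exp(intercept)), alpha=float(slope))


@dataclass
class JonesDoleFit:
    """eta(c)/eta0 = 1 + A sqrt(c) + B c."""

    a: float  # (mol/dm^3)^(-1/2)
    b: float  # dm^3/mol

    def __call__(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return 1.0 + self.a * np.sqrt(c) + self.b * c


def jones_dole_fit(concentrations, eta_rel) -> JonesDoleFit:
    """Least squares of (eta/eta0 - 1) on the design [sqrt(c), c]."""
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(eta_rel, dtype=float) - 1.0
    if np.any(c <= 0):
        raise AnalysisError("concentrations must be positive")
    if len(np.unique(c)) < 2:
        raise AnalysisError("need at least 2 distinct concentrations")
    design = np.column_stack([np.sqrt(c), c])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 2:
        raise AnalysisError("degenerate design")
    return JonesDoleFit(a=float(coef[0]), b=float(coef[1]))
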