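"""Machinery for the (q, d) plane: scan grids with charge neutrality, the
susceptibility chi = dn/dd, the structural transformation line (maximal
dn/dq), the H-bond length lambda_HB(q), and generic crossover contours.

A scan point is one model salt solution: cations of charge q = k * delta_q
with the cation-oxygen VDW diameter shifted by k * delta_sigma from the
reference, and the smallest integral anion count that makes the box exactly
neutral.  The plane is plotted against the measured shell radius d, which the
analysis fills in per point; sigma is only the control knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import find_contours

from .core import AnalysisError, WATER_MOLAR_MASS


@dataclass
class ScanPoint:
    """One (charge level, VDW level) system of the scan."""

    q: float                 # cation charge, e
    sigma_cation_o: float    # Angstrom
    n_cations: int
    n_anions: int
    anion_charge: float      # magnitude, e
    molality: float          # mol salt / kg water
    k_q: int
    k_sigma: int
    d: float | None = None   # measured shell radius, filled after analysis

    def __post_init__(self) -> None:
        if abs(self.n_cations * self.q - self.n_anions * self.anion_charge) > 1e-9:
            raise ValueError("scan point is not charge-neutral")


def molality(n_waters: int, n_salt_units: int) -> float:
    """Moles of salt per kilogram of water."""
    kg_water = n_waters * WATER_MOLAR_MASS / 1000.0  # g -> kg
    return n_salt_units / kg_water


def build_scan_grid(
    sigma_ref: float,
    delta_sigma: float = 0.04,
    k_sigma_range=range(0, 1),
    delta_q: float = 0.17,
    k_q_range=range(1, 21),
    n_cations: int = 10,
    anion_charge: float = 0.85,
    n_waters: int = 3456,
) -> list[ScanPoint]:
    """Cartesian (charge level) x (VDW level) scan with exact neutrality.

    Per point the smallest anion count achieving exact neutrality with the
    given anion charge magnitude is used; a charge combination that admits no
    integral neutral count raises.
    """
    if delta_q <= 0 or delta_sigma <= 0:
        raise ValueError("delta_q and delta_sigma must be positive")
    points: list[ScanPoint] = []
    molal = molality(n_waters, n_cations)
    for kq in k_q_range:
        q = kq * delta_q
        total = n_cations * q
        n_an = total / anion_charge
        if abs(n_an - round(n_an)) > 1e-9:
            raise AnalysisError(
                f"no integral anion count neutralises q={q:.4f} e "
                f"with anion charge {anion_charge} e")
        n_an = int(round(n_an))
        for ks in k_sigma_range:
            points.append(ScanPoint(
                q=q, sigma_cation_o=sigma_ref + ks * delta_sigma,
                n_cations=n_cations, n_anions=n_an,
                anion_charge=anion_charge, molality=molal,
                k_q=kq, k_sigma=ks))
    return points


def fractional_charge_grid(
    sigma_cation_o: float = 2.73,
    delta_q: float = 0.05,
    n_levels: int = 25,
    n_ion_pairs: int = 10,
    n_waters: int = 3456,
) -> list[ScanPoint]:
    """Small-fractional-charge refinement preset: anion charge equals the
    cation charge, equal counts, q = 0 .. (n_levels-1) * delta_q."""
    molal = molality(n_waters, n_ion_pairs)
    return [ScanPoint(q=k * delta_q, sigma_cation_o=sigma_cation_o,
                      n_cations=n_ion_pairs, n_anions=n_ion_pairs,
                      anion_charge=k * delta_q, molality=molal,
                      k_q=k, k_sigma=0)
            for k in range(n_levels)]


@dataclass
class PhaseGrid:
    """An observable tabulated on the (q, d) lattice.

    ``values[i, j]`` is the observable at q = q_values[i], d = d_values[j];
    ``mask`` marks valid cells.
    """

    q_values: np.ndarray
    d_values: np.ndarray
    values: np.ndarray
    name: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q_values = np.asarray(self.q_values, dtype=float)
        self.d_values = np.asarray(self.d_values, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.q_values) <= 0) or np.any(np.diff(self.d_values) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if self.values.shape != (len(self.q_values), len(self.d_values)):
            raise ValueError("value matrix shape does not match the axes")
        if self.mask is None:
            self.mask = np.isfinite(self.values)


@dataclass
class CrossoverLine:
    """An ordered (q, d) polyline with the condition that defines it."""

    q: np.ndarray
    d: np.ndarray
    condition: str = ""
    segments: list = field(default_factory=list)  # disconnected pieces, if any


def susceptibility_chi(grid: PhaseGrid) -> PhaseGrid:
    """chi = dn/dd by central finite differences along d (one-sided at the
    boundaries), per charge level."""
    if len(grid.d_values) < 3:
        raise AnalysisError("need at least 3 d-levels")
    chi = np.gradient(grid.values, grid.d_values, axis=1)
    return PhaseGrid(grid.q_values, grid.d_values, chi,
                     name=f"chi({grid.name})", mask=grid.mask)


def _refine_max(x: np.ndarray, y: np.ndarray) -> float | None:
    """Parabolically refined argmax of y; None when no interior maximum."""
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return None
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    delta = 0.0 if denom == 0 else float(np.clip(0.5 * (y0 - y2) / denom, -1, 1))
    return float(x[i] + delta * (x[i + 1] - x[i]))


def transformation_line(grid: PhaseGrid, smooth: bool = True) -> CrossoverLine:
    """Structural transformation: per d, the charge q_c of maximal |dn/dq|.

    A flat derivative (no interior maximum, e.g. linear n(q)) leaves a gap at
    that d.
    """
    if len(grid.q_values) < 3:
        raise AnalysisError("need at least 3 q-levels")
    qs, ds = [], []
    for j, d in enumerate(grid.d_values):
        col = grid.values[:, j]
        if not np.all(np.isfinite(col)):
            continue
        deriv = np.abs(np.gradient(col, grid.q_values))
        if np.ptp(deriv) <= 1e-12 * max(1.0, np.abs(deriv).max()):
            continue  # flat derivative: flagged gap at this d
        if smooth and len(deriv) >= 3:
            deriv = np.convolve(deriv, np.ones(3) / 3.0, mode="same")
        qc = _refine_max(grid.q_values, deriv)
        if qc is None:
            continue
        qs.append(qc)
        ds.append(d)
    if not qs:
        raise AnalysisError("derivative flat everywhere: no transformation line")
    return CrossoverLine(q=np.asarray(qs), d=np.asarray(ds),
                         condition="argmax |dn/dq|")


def lambda_hb(
    de_grid: PhaseGrid,
    e_hbond: float,
    band: float = 0.0,
) -> tuple[CrossoverLine, CrossoverLine | None, CrossoverLine | None]:
    """lambda_HB(q): per q, the d at which dE_ion-water(d) crosses E_hbond.

    Energies enter as magnitudes.  The root is found by monotone linear
    interpolation in d; band edges come from e_hbond +- band.  A charge level
    with no bracketing sign change is left out of the line (a per-q gap).
    Returns (line, lower-band line, upper-band line).
    """
    def level_line(level: float, tag: str) -> CrossoverLine | None:
        qs, ds = [], []
        for i, q in enumerate(de_grid.q_values):
            row = de_grid.values[i]
            ok = np.isfinite(row)
            d_ax, vals = de_grid.d_values[ok], row[ok]
            if len(vals) < 2:
                continue
            diff = vals - level
            sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
            if len(sign_change) == 0:
                continue
            k = sign_change[0]
            frac = diff[k] / (diff[k] - diff[k + 1])
            qs.append(q)
            ds.append(float(d_ax[k] + frac * (d_ax[k + 1] - d_ax[k])))
        if not qs:
            return None
        return CrossoverLine(q=np.asarray(qs), d=np.asarray(ds), condition=tag)

    line = level_line(e_hbond, "dE_ion-water = E_hbond")
    if line is None:
        raise AnalysisError("E_hbond never bracketed by dE_ion-water in range")
    lo = level_line(e_hbond - band, "lower band") if band > 0 else None
    hi = level_line(e_hbond + band, "upper band") if band > 0 else None
    return line, lo, hi


def crossover_contour(
    grid_a: PhaseGrid,
    grid_b: PhaseGrid | float = 1.0,
    level: float = 1.0,
) -> CrossoverLine:
    """Level set of grid_a / grid_b (or grid_a - level for scalar grid_b = 1
    and level != 1) on the (q, d) lattice, by marching squares with linear
    interpolation.  An empty contour (no sign change) is a valid result.
    """
    if isinstance(grid_b, PhaseGrid):
        if (len(grid_a.q_values) != len(grid_b.q_values)
                or len(grid_a.d_values) != len(grid_b.d_values)):
            raise AnalysisError("grids must share axes")
        surface = grid_a.values / grid_b.values - level
    else:
        surface = grid_a.values / float(grid_b) - level
    segments = []
    for contour in find_contours(surface, 0.0):
        qi, di = contour[:, 0], contour[:, 1]
        qseg = np.interp(qi, np.arange(len(grid_a.q_values)), grid_a.q_values)
        dseg = np.interp(di, np.arange(len(grid_a.d_values)), grid_a.d_values)
        segments.append(np.column_stack([qseg, dseg]))
    if segments:
        all_pts = np.vstack(segments)
        q, d = all_pts[:, 0], all_pts[:, 1]
    else:
        q = d = np.array([])
    return CrossoverLine(q=q, d=d, condition=f"ratio = {level}",
                         segments=segments)
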