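"""Synthetic inputs for the pipeline, at desk scale.

The centrepiece is a toy Metropolis simulator of a single hydration shell:
``n_shell`` point-dipole particles radially attracted to a central charge q,
interacting through charge-dipole, dipole-dipole, and ion-particle
Lennard-Jones terms (plus an optional harmonic radial tether emulating the
thin single-layer shell).  It reproduces the physics the analyses probe -
dipolar order growing with q, angular order maximal at composite occupancy -
without any pretence of being an all-atom water model.  Explicit-site
hydrogen-bond fixtures come instead from ``toy_water_box``.

Every generator here is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Box, Frame, KB, build_water, min_image_displacement
from .dynamics import CorrelationSeries
from .energetics import charge_dipole_energy, dipole_dipole_energy, lj_energy


# ----------------------------------------------------------------- fixtures

def sample_uniform_sphere(n: int, radius: float = 1.0, seed: int = 0) -> np.ndarray:
    """n points i.i.d. uniform on a sphere surface (Gaussian projection)."""
    if n < 1:
        raise ValueError("need n >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    return radius * v / np.linalg.norm(v, axis=1)[:, None]


_PHI = (1.0 + np.sqrt(5.0)) / 2.0


def _platonic_vertices(n: int) -> np.ndarray:
    if n == 4:
        v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    elif n == 6:
        v = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                      [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
    elif n == 8:
        v = np.array([[sx, sy, sz] for sx in (-1, 1)
                      for sy in (-1, 1) for sz in (-1, 1)], float)
    elif n == 12:
        v = []
        for a in (-1.0, 1.0):
            for b in (-_PHI, _PHI):
                v += [[0, a, b], [a, b, 0], [b, 0, a]]
        v = np.array(v)
    elif n == 20:
        v = [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        for a in (-1.0 / _PHI, 1.0 / _PHI):
            for b in (-_PHI, _PHI):
                v += [[0, a, b], [a, b, 0], [b, 0, a]]
        v = np.array(v)
    else:
        raise ValueError(f"no Platonic solid with {n} vertices (use 4/6/8/12/20)")
    return v / np.linalg.norm(v, axis=1)[:, None]


def platonic_shell(n: int, radius: float = 1.0) -> np.ndarray:
    """Exact vertices of the regular polyhedron with n vertices, scaled."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return radius * _platonic_vertices(n)


# ------------------------------------------------------------ random walks

@dataclass
class PointTrajectory:
    """Bare point-particle trajectory: times (ps) and (F, N, 3) positions."""

    times: np.ndarray
    positions: np.ndarray
    box: Box | None = None


def brownian_walk(
    D: float,
    dt: float,
    n_steps: int,
    n_particles: int,
    seed: int = 0,
) -> PointTrajectory:
    """Independent Gaussian walks with per-dimension increment variance 2 D dt."""
    if D < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_steps, n_particles, 3)) * np.sqrt(2.0 * D * dt)
    pos = np.zeros((n_steps + 1, n_particles, 3))
    np.cumsum(steps, axis=0, out=pos[1:])
    times = dt * np.arange(n_steps + 1)
    return PointTrajectory(times=times, positions=pos)


def stretched_occupancy(
    tau: float,
    beta: float,
    t_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CorrelationSeries:
    """P(t) = exp[-(t/tau)^beta] plus clipped Gaussian noise; P(0) stays 1."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if not (0 < beta <= 2):
        raise ValueError("beta must lie in (0, 2]")
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    p = np.exp(-np.power(t / tau, beta))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p = np.clip(p + rng.normal(0.0, noise_sd, size=p.shape), 0.0, 1.0)
    p[t == 0] = 1.0
    return CorrelationSeries(t=t, p=p, origins=1)


# ------------------------------------------------------------- water boxes

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalised random quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def toy_water_box(
    n_water: int,
    box: Box,
    seed: int = 0,
    motifs: list | None = None,
    min_oo: float = 2.2,
    max_attempts_per_water: int = 500,
) -> Frame:
    """Random rigid waters in a periodic box, optional verbatim motifs.

    ``motifs`` is a list of WaterRecord objects inserted unchanged (their
    coordinates are trusted); the remaining waters are placed at random
    positions/orientations subject to a minimum-image O-O distance floor.
    """
    rng = np.random.default_rng(seed)
    waters = list(motifs) if motifs else []
    placed = [w.oxygen.position for w in waters]
    n_random = n_water - len(waters)
    if n_random < 0:
        raise ValueError("more motif waters than n_water")
    budget = max_attempts_per_water * max(n_random, 1)
    while n_random > 0:
        if budget <= 0:
            raise RuntimeError("packing failure: attempt budget exhausted")
        budget -= 1
        pos = rng.uniform(0.0, box.edge_length, size=3)
        if placed:
            d = np.linalg.norm(
                min_image_displacement(pos, np.array(placed), box), axis=1)
            if d.min() < min_oo:
                continue
        waters.append(build_water(pos, _random_rotation(rng)))
        placed.append(pos)
        n_random -= 1
    return Frame(time=0.0, ions=[], waters=waters, box=box, wrap=False)


def hbond_dimer(origin, d_oo: float = 2.8, tilt_deg: float = 50.0):
    """An attractive hydrogen-bonded rigid water dimer along +x.

    The donor's O-H points straight at the acceptor oxygen; the acceptor's
    bisector is tilted ``tilt_deg`` off the O-O axis, near the minimum-energy
    orientation of the rigid four-site pair.  Returns (donor, acceptor).
    """
    o1 = np.asarray(origin, dtype=float)
    o2 = o1 + np.array([d_oo, 0.0, 0.0])
    from .core import HOH_ANGLE, OH_BOND  # local import keeps header tidy
    half = np.radians(HOH_ANGLE / 2.0)
    # donor: rotate the canonical frame so H1 lies along +x, H plane = xz
    c1 = np.array([np.sin(half), 0.0, np.cos(half)])   # canonical H1 direction
    t1 = np.array([1.0, 0.0, 0.0])
    theta = np.radians(HOH_ANGLE)
    c2 = np.array([-np.sin(half), 0.0, np.cos(half)])
    t2 = np.cos(theta) * t1 + np.sin(theta) * np.array([0.0, 0.0, 1.0])
    donor = build_water(o1, _rotation_between_pairs(c1, c2, t1, t2))
    tilt = np.radians(tilt_deg)
    bis = np.array([np.cos(tilt), 0.0, -np.sin(tilt)])
    acceptor = build_water(o2, _rotation_to_axis(bis))
    return donor, acceptor


def _rotation_to_axis(target: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to ``target`` (unit), by axis-angle."""
    z = np.array([0.0, 0.0, 1.0])
    t = np.asarray(target, dtype=float)
    t = t / np.linalg.norm(t)
    v = np.cross(z, t)
    s, c = np.linalg.norm(v), float(np.dot(z, t))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _rotation_between_pairs(a1, a2, b1, b2) -> np.ndarray:
    """Exact rotation taking the orthonormalised frame of (a1, a2) to (b1, b2)."""
    def frame(u, v):
        e1 = u / np.linalg.norm(u)
        w = v - np.dot(v, e1) * e1
        e2 = w / np.linalg.norm(w)
        return np.column_stack([e1, e2, np.cross(e1, e2)])

    return frame(b1, b2) @ frame(a1, a2).T


# --------------------------------------------------- Metropolis shell model

@dataclass
class McParams:
    """Parameters of the toy dipolar-shell Metropolis simulator."""

    n_shell: int = 6
    ion_charge: float = 1.0        # e
    dipole_moment: float = 0.48    # e*Angstrom (rigid-water bulk value)
    lj_sigma: float = 2.5          # Angstrom, ion-particle
    lj_epsilon: float = 0.79       # kJ/mol, ion-particle
    temperature: float = 300.0     # K
    shell_spring: float | None = None   # kJ/mol/A^2 radial tether
    shell_radius: float | None = None   # tether centre; default LJ minimum
    n_steps: int = 4000            # production sweeps (1 sweep = n_shell moves)
    n_equil: int = 1000            # equilibration sweeps (move-scale tuning)
    sample_every: int = 10         # sweeps between samples
    seed: int = 0
    translation_scale: float = 0.15  # Angstrom
    rotation_scale: float = 0.4      # rad
    hard_core: float = 2.0           # Angstrom; inter-particle overlap exclusion

    def __post_init__(self) -> None:
        if self.n_shell < 1:
            raise ValueError("need n_shell >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.translation_scale <= 0 or self.rotation_scale <= 0:
            raise ValueError("move scales must be positive")

    @property
    def r0(self) -> float:
        return self.shell_radius if self.shell_radius is not None \
            else self.lj_sigma * 2.0 ** (1.0 / 6.0)


@dataclass
class ShellTrajectory:
    """Sampled states of the dipolar-shell chain.

    positions/axes: (n_samples, n_shell, 3); axes are unit dipole directions.
    """

    params: McParams
    steps: np.ndarray
    positions: np.ndarray
    axes: np.ndarray
    energies: np.ndarray
    acceptance_rate: float
    final_energy_tracked: float
    final_energy_recomputed: float

    def cos_theta(self) -> np.ndarray:
        """(n_samples, n_shell) radial dipole projections u . rhat."""
        r = np.linalg.norm(self.positions, axis=2)
        return np.einsum("spk,spk->sp", self.axes, self.positions) / r

    def mean_cos_theta(self) -> float:
        return float(self.cos_theta().mean())

    def configs(self) -> list[np.ndarray]:
        """Per-sample point sets, ready for the orientational analyses."""
        return [self.positions[i] for i in range(len(self.positions))]


class _ShellSystem:
    """Energy bookkeeping for the dipolar shell (ion fixed at the origin)."""

    def __init__(self, p: McParams):
        self.p = p
        self.kp2 = p.dipole_moment ** 2

    def particle_energy(self, i: int, pos: np.ndarray, axes: np.ndarray) -> float:
        p = self.p
        ri_vec = pos[i]
        ri = float(np.linalg.norm(ri_vec))
        d = np.linalg.norm(pos - ri_vec, axis=1)
        d[i] = np.inf
        if d.min() < p.hard_core:
            return np.inf  # hard-core exclusion; a point dipole pair would collapse
        e = lj_energy(ri, p.lj_epsilon, p.lj_sigma)
        mu_i = p.dipole_moment * axes[i]
        if p.ion_charge != 0.0:
            e += charge_dipole_energy(p.ion_charge, mu_i, ri_vec)
        if p.shell_spring is not None:
            e += 0.5 * p.shell_spring * (ri - p.r0) ** 2
        for j in range(len(pos)):
            if j == i:
                continue
            e += dipole_dipole_energy(
                mu_i, p.dipole_moment * axes[j], pos[j] - ri_vec)
        return e

    def total_energy(self, pos: np.ndarray, axes: np.ndarray) -> float:
        p = self.p
        if len(pos) > 1:
            diff = pos[:, None, :] - pos[None, :, :]
            dd = np.linalg.norm(diff, axis=2)
            iu = np.triu_indices(len(pos), k=1)
            if dd[iu].min() < p.hard_core:
                return np.inf
        r = np.linalg.norm(pos, axis=1)
        e = sum(lj_energy(ri, p.lj_epsilon, p.lj_sigma) for ri in r)
        mu = p.dipole_moment * axes
        if p.ion_charge != 0.0:
            for i in range(len(pos)):
                e += charge_dipole_energy(p.ion_charge, mu[i], pos[i])
        if p.shell_spring is not None:
            e += 0.5 * p.shell_spring * float(np.sum((r - p.r0) ** 2))
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                e += dipole_dipole_energy(mu[i], mu[j], pos[j] - pos[i])
        return float(e)


def _initial_shell(p: McParams, rng: np.random.Generator):
    for _ in range(500):
        pos = sample_uniform_sphere(p.n_shell, p.r0, seed=int(rng.integers(2**31)))
        if p.n_shell == 1:
            break
        iu = np.triu_indices(p.n_shell, k=1)
        diff = pos[:, None, :] - pos[None, :, :]
        if np.linalg.norm(diff, axis=2)[iu].min() >= p.hard_core:
            break
    else:
        raise ValueError("could not place the shell without hard-core overlap")
    axes = pos / np.linalg.norm(pos, axis=1)[:, None]  # radial-out start
    return pos, axes.copy()


def _run_chain(
    system: _ShellSystem,
    pos: np.ndarray,
    axes: np.ndarray,
    rng: np.random.Generator,
    n_sweeps: int,
    trans_scale: float,
    rot_scale: float,
    tune: bool,
    kt: float,
    record_every: int | None = None,
    recorder=None,
):
    """Metropolis sweeps; returns (pos, axes, scales, accepted, attempted, dE_sum)."""
    n = len(pos)
    accepted = attempted = 0
    block_acc = block_att = 0
    de_sum = 0.0
    for sweep in range(n_sweeps):
        for _ in range(n):
            i = int(rng.integers(n))
            translate = rng.random() < 0.5
            e_old = system.particle_energy(i, pos, axes)
            if translate:
                old = pos[i].copy()
                pos[i] = old + rng.normal(0.0, trans_scale, 3)
            else:
                old = axes[i].copy()
                cand = old + rng.normal(0.0, rot_scale, 3)
                axes[i] = cand / np.linalg.norm(cand)
            e_new = system.particle_energy(i, pos, axes)
            de = e_new - e_old
            attempted += 1
            block_att += 1
            if de <= 0 or rng.random() < np.exp(-de / kt):
                accepted += 1
                block_acc += 1
                de_sum += de
            else:
                if translate:
                    pos[i] = old
                else:
                    axes[i] = old
        if tune and block_att >= 100:
            acc = block_acc / block_att
            factor = float(np.clip(acc / 0.4, 0.5, 2.0))
            trans_scale = float(np.clip(trans_scale * factor, 1e-3, 2.0))
            rot_scale = float(np.clip(rot_scale * factor, 1e-3, np.pi))
            block_acc = block_att = 0
        if record_every and (sweep + 1) % record_every == 0:
            recorder(sweep + 1, pos, axes, de_sum)
    return pos, axes, trans_scale, rot_scale, accepted, attempted, de_sum


def shell_mc_simulate(p: McParams) -> ShellTrajectory:
    """Metropolis chain over translation/rotation moves of the dipolar shell.

    Move scales are auto-tuned toward ~40% acceptance during the ``n_equil``
    equilibration sweeps, then frozen for production.  The energy is tracked
    incrementally and cross-checked against a full recomputation at the end.
    """
    rng = np.random.default_rng(p.seed)
    system = _ShellSystem(p)
    pos, axes = _initial_shell(p, rng)
    e0 = system.total_energy(pos, axes)
    if not np.isfinite(e0):
        raise ValueError("non-finite starting energy (overlapping particles)")
    kt = KB * p.temperature

    pos, axes, ts, rs, *_ = _run_chain(
        system, pos, axes, rng, p.n_equil,
        p.translation_scale, p.rotation_scale, tune=True, kt=kt)

    e_start = system.total_energy(pos, axes)
    samples_pos, samples_axes, samples_e, samples_step = [], [], [], []

    def recorder(step, cpos, caxes, de_sum):
        samples_step.append(step)
        samples_pos.append(cpos.copy())
        samples_axes.append(caxes.copy())
        samples_e.append(e_start + de_sum)

    pos, axes, _, _, acc, att, de_sum = _run_chain(
        system, pos, axes, rng, p.n_steps, ts, rs, tune=False, kt=kt,
        record_every=p.sample_every, recorder=recorder)

    tracked = e_start + de_sum
    recomputed = system.total_energy(pos, axes)
    return ShellTrajectory(
        params=p,
        steps=np.asarray(samples_step),
        positions=np.asarray(samples_pos),
        axes=np.asarray(samples_axes),
        energies=np.asarray(samples_e),
        acceptance_rate=acc / max(att, 1),
        final_energy_tracked=tracked,
        final_energy_recomputed=recomputed,
    )


@dataclass
class ChargeJumpResult:
    """Ensemble-averaged relaxation after an instantaneous charge jump.

    cos_theta / pair_energy are (n_replicas, n_samples); the time axis is in
    production sweeps after the jump.
    """

    steps: np.ndarray
    cos_theta: np.ndarray
    pair_energy: np.ndarray
    q_before: float
    q_after: float

    @property
    def n_replicas(self) -> int:
        return self.cos_theta.shape[0]

    def mean_cos_theta(self) -> np.ndarray:
        return self.cos_theta.mean(axis=0)

    def mean_pair_energy(self) -> np.ndarray:
        return self.pair_energy.mean(axis=0)


def _neighbour_pair_energy(pos: np.ndarray, axes: np.ndarray, p: McParams) -> float:
    """Mean nearest-neighbour dipole-dipole energy of the shell."""
    mu = p.dipole_moment * axes
    n = len(pos)
    vals = []
    for i in range(n):
        d = np.linalg.norm(pos - pos[i], axis=1)
        d[i] = np.inf
        j = int(np.argmin(d))
        vals.append(dipole_dipole_energy(mu[i], mu[j], pos[j] - pos[i]))
    return float(np.mean(vals))


def charge_jump_protocol(
    p: McParams,
    q_before: float,
    q_after: float,
    n_replicas: int = 50,
    equil_steps: int = 1000,
    require_change: bool = False,
) -> ChargeJumpResult:
    """Equilibrate each replica at q_before, jump to q_after, record relaxation.

    Mirrors the charge-jump protocol shape (independent replicas equilibrated
    in the initial state, instantaneous charge switch at time zero, ensemble
    averaging) at toy-model cost.
    """
    if n_replicas < 1:
        raise ValueError("need n_replicas >= 1")
    if require_change and q_before == q_after:
        raise ValueError("relaxation requested but q_before == q_after")
    cos_rows, en_rows, steps = [], [], None
    for r in range(n_replicas):
        seed = (p.seed + 7919 * (r + 1)) % (2**31)
        pb = replace(p, ion_charge=q_before, seed=seed)
        rng = np.random.default_rng(seed)
        sys_b = _ShellSystem(pb)
        pos, axes = _initial_shell(pb, rng)
        kt = KB * pb.temperature
        pos, axes, ts, rs, *_ = _run_chain(
            sys_b, pos, axes, rng, equil_steps,
            pb.translation_scale, pb.rotation_scale, tune=True, kt=kt)
        # the jump: same configuration, new charge
        pa = replace(p, ion_charge=q_after, seed=seed)
        sys_a = _ShellSystem(pa)
        cs, es, ss = [], [], []

        def recorder(step, cpos, caxes, de_sum):
            r_ = np.linalg.norm(cpos, axis=1)
            cs.append(float(np.mean(
                np.einsum("pk,pk->p", caxes, cpos) / r_)))
            es.append(_neighbour_pair_energy(cpos, caxes, pa))
            ss.append(step)

        _run_chain(sys_a, pos, axes, rng, pa.n_steps, ts, rs, tune=False,
                   kt=kt, record_every=pa.sample_every, recorder=recorder)
        cos_rows.append(cs)
        en_rows.append(es)
        steps = np.asarray(ss)
    return ChargeJumpResult(
        steps=steps,
        cos_theta=np.asarray(cos_rows),
        pair_energy=np.asarray(en_rows),
        q_before=q_before,
        q_after=q_after,
    )
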