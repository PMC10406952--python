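"""Trajectory readers/writers for the GRO and multi-frame XYZ dialects.

Both dialects are multi-frame by concatenation.  GRO follows the standard
fixed-column layout (coordinates in nm; written here with 4 decimal places so
a round trip preserves Angstrom coordinates to 1e-3).  The XYZ dialect stores
coordinates in Angstrom and carries ``box=<L> t=<time>`` key-value pairs on
the per-frame comment line.

Waters are recognised by residue name ``SOL`` with atoms OW/HW1/HW2 and an
optional MW site (GRO), or by an ``O H H [M]`` atom run (XYZ).  Any other atom
is read back as an ion site.  Charges are not part of either format: water
sites get the rigid-model charges on read, ions get ``ion_charge``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import (
    Box,
    FormatError,
    Frame,
    Q_H,
    Q_M,
    Site,
    Trajectory,
    WaterRecord,
)

_WATER_SITE_NAMES = ("OW", "HW1", "HW2", "MW")
_XYZ_WATER_LABELS = ("O", "H", "H", "M")


def trajectory_io(path, mode: str, dialect: str, traj: Trajectory | None = None, **kw):
    """Read or write a trajectory.  Thin dispatcher over the dialect functions."""
    if dialect not in ("gro", "xyz"):
        raise FormatError(f"unknown dialect {dialect!r}")
    if mode == "read":
        return read_trajectory(path, dialect, **kw)
    if mode == "write":
        if traj is None:
            raise ValueError("write mode needs a trajectory")
        write_trajectory(traj, path, dialect, **kw)
        return traj
    raise ValueError(f"mode must be 'read' or 'write', got {mode!r}")


def read_trajectory(path, dialect: str | None = None, ion_charge: float = 0.0) -> Trajectory:
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    if dialect == "gro":
        return _read_gro(path, ion_charge)
    if dialect == "xyz":
        return _read_xyz(path, ion_charge)
    raise FormatError(f"unknown dialect {dialect!r}")


def write_trajectory(traj: Trajectory, path, dialect: str | None = None, decimals: int = 4) -> None:
    path = Path(path)
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    if dialect == "gro":
        path.write_text(_format_gro(traj, decimals))
    elif dialect == "xyz":
        path.write_text(_format_xyz(traj))
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------- GRO dialect

def _format_gro(traj: Trajectory, decimals: int = 4) -> str:
    width = decimals + 5
    lines: list[str] = []
    for frame in traj.frames:
        if frame.box is None:
            raise FormatError("GRO frames need a box")
        natoms = len(frame.ions) + sum(len(w.sites()) for w in frame.waters)
        lines.append(f"hydrashell t= {frame.time:.6f}")
        lines.append(f"{natoms:5d}")
        atom_id = 0
        res_id = 0
        for ion in frame.ions:
            atom_id += 1
            res_id += 1
            lines.append(_gro_atom(res_id, "ION", ion.species[:5], atom_id,
                                   ion.position, width, decimals))
        for w in frame.waters:
            res_id += 1
            for name, s in zip(_WATER_SITE_NAMES, w.sites()):
                atom_id += 1
                lines.append(_gro_atom(res_id, "SOL", name, atom_id,
                                       s.position, width, decimals))
        L = frame.box.edge_length / 10.0  # Angstrom -> nm
        lines.append(f"{L:10.5f}{L:10.5f}{L:10.5f}")
    return "\n".join(lines) + "\n"


def _gro_atom(res_id, resname, name, atom_id, pos, width, decimals) -> str:
    x, y, z = np.asarray(pos, dtype=float) / 10.0  # Angstrom -> nm
    return (f"{res_id % 100000:5d}{resname:<5s}{name:>5s}{atom_id % 100000:5d}"
            f"{x:{width}.{decimals}f}{y:{width}.{decimals}f}{z:{width}.{decimals}f}")


def _read_gro(path: Path, ion_charge: float) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"unparsable time in title {title!r}") from exc
        try:
            natoms = int(lines[i + 1])
        except (IndexError, ValueError) as exc:
            raise FormatError("missing or malformed atom-count line") from exc
        atom_lines = lines[i + 2:i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise FormatError(f"frame declares {natoms} atoms but file ends early")
        box_idx = i + 2 + natoms
        if box_idx >= len(lines):
            raise FormatError("missing box line")
        box = _parse_gro_box(lines[box_idx])
        frames.append(_assemble_gro_frame(time, atom_lines, box, ion_charge))
        i = box_idx + 1
    if not frames:
        raise FormatError("no frames found")
    return Trajectory(frames)


def _parse_gro_box(line: str) -> Box:
    parts = line.split()
    if len(parts) < 3:
        # a line that fails to parse as a box usually means a truncated frame
        raise FormatError(f"malformed box line {line!r}")
    vals = [float(p) for p in parts]
    if len(vals) > 3 and any(abs(v) > 1e-12 for v in vals[3:]):
        raise FormatError("non-cubic (triclinic) box is not supported")
    lx, ly, lz = vals[:3]
    if not (abs(lx - ly) < 1e-9 and abs(lx - lz) < 1e-9):
        raise FormatError("non-cubic box is not supported")
    return Box(edge_length=lx * 10.0)  # nm -> Angstrom


def _assemble_gro_frame(time, atom_lines, box, ion_charge) -> Frame:
    ions: list[Site] = []
    waters: list[WaterRecord] = []
    pending: dict[str, Site] = {}

    def flush_water():
        if not pending:
            return
        if "OW" not in pending or "HW1" not in pending or "HW2" not in pending:
            raise FormatError("incomplete water residue (need OW, HW1, HW2)")
        msite = pending.get("MW")
        o = pending["OW"]
        if msite is None:
            o.charge = Q_M  # 3-site water: put the negative charge on O
        waters.append(WaterRecord(oxygen=o,
                                  hydrogens=[pending["HW1"], pending["HW2"]],
                                  msite=msite))
        pending.clear()

    prev_res = None
    for line in atom_lines:
        if len(line) < 44:
            raise FormatError(f"atom line too short: {line!r}")
        res_id = line[0:5].strip()
        resname = line[5:10].strip()
        name = line[10:15].strip()
        rest = line[20:].rstrip()
        dots = [k for k, ch in enumerate(rest) if ch == "."]
        if len(dots) < 3:
            raise FormatError(f"unparsable coordinates: {line!r}")
        fw = dots[1] - dots[0]  # field width from decimal-point spacing
        try:
            pos = np.array([float(rest[k * fw:(k + 1) * fw])
                            for k in range(3)]) * 10.0  # nm -> Angstrom
        except ValueError as exc:
            raise FormatError(f"unparsable coordinates: {line!r}") from exc
        key = (res_id, resname)
        if key != prev_res:
            flush_water()
            prev_res = key
        if resname == "SOL":
            charge = {"OW": 0.0, "HW1": Q_H, "HW2": Q_H, "MW": Q_M}.get(name)
            if charge is None:
                raise FormatError(f"unknown water site name {name!r}")
            pending[name] = Site(pos, charge, name)
        else:
            flush_water()
            ions.append(Site(pos, ion_charge, name))
    flush_water()
    return Frame(time=time, ions=ions, waters=waters, box=box)


# ---------------------------------------------------------------- XYZ dialect

def _format_xyz(traj: Trajectory) -> str:
    lines: list[str] = []
    for frame in traj.frames:
        natoms = len(frame.ions) + sum(len(w.sites()) for w in frame.waters)
        lines.append(f"{natoms}")
        comment = f"t={frame.time:.6f}"
        if frame.box is not None:
            comment = f"box={frame.box.edge_length:.6f} " + comment
        lines.append(comment)
        for ion in frame.ions:
            lines.append(_xyz_atom(ion.species or "X", ion.position))
        for w in frame.waters:
            for label, s in zip(_XYZ_WATER_LABELS, w.sites()):
                lines.append(_xyz_atom(label, s.position))
    return "\n".join(lines) + "\n"


def _xyz_atom(label, pos) -> str:
    x, y, z = np.asarray(pos, dtype=float)
    return f"{label:<4s} {x:14.6f} {y:14.6f} {z:14.6f}"


def _read_xyz(path: Path, ion_charge: float) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"expected atom count, got {lines[i]!r}") from exc
        if i + 1 >= len(lines):
            raise FormatError("missing comment line")
        box, time = _parse_xyz_comment(lines[i + 1])
        atom_lines = lines[i + 2:i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise FormatError(f"frame declares {natoms} atoms but file ends early")
        frames.append(_assemble_xyz_frame(time, atom_lines, box, ion_charge))
        i += 2 + natoms
    if not frames:
        raise FormatError("no frames found")
    return Trajectory(frames)


def _parse_xyz_comment(line: str) -> tuple[Box | None, float]:
    box = None
    time = 0.0
    for token in line.split():
        if token.startswith("box="):
            box = Box(edge_length=float(token[4:]))
        elif token.startswith("t="):
            time = float(token[2:])
    return box, time


def _assemble_xyz_frame(time, atom_lines, box, ion_charge) -> Frame:
    ions: list[Site] = []
    waters: list[WaterRecord] = []
    j = 0
    parsed = []
    for line in atom_lines:
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"malformed atom line {line!r}")
        parsed.append((parts[0], np.array([float(p) for p in parts[1:4]])))
    n = len(parsed)
    while j < n:
        label, pos = parsed[j]
        if label == "O":
            if j + 2 >= n or parsed[j + 1][0] != "H" or parsed[j + 2][0] != "H":
                raise FormatError("water 'O' not followed by two 'H' atoms")
            o = Site(pos, 0.0, "OW")
            h1 = Site(parsed[j + 1][1], Q_H, "HW1")
            h2 = Site(parsed[j + 2][1], Q_H, "HW2")
            j += 3
            msite = None
            if j < n and parsed[j][0] == "M":
                msite = Site(parsed[j][1], Q_M, "MW")
                j += 1
            else:
                o.charge = Q_M
            waters.append(WaterRecord(oxygen=o, hydrogens=[h1, h2], msite=msite))
        elif label in ("H", "M"):
            raise FormatError(f"stray {label!r} atom outside a water run")
        else:
            ions.append(Site(pos, ion_charge, label))
            j += 1
    return Frame(time=time, ions=ions, waters=waters, box=box)
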