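"""Coordinate I/O, periodic geometry and leaflet assignment.

Configurations are held in :class:`Frame` objects: flat numpy arrays of
residue indices/names, atom names and positions (nm) plus an orthorhombic
:class:`Box`.  GRO and PDB files are supported, including multi-frame
concatenations (repeated GRO blocks, PDB MODEL/ENDMDL records).  Multi-frame
GRO is the native trajectory format of the synthetic generator.

All coordinates are stored in nanometres; PDB angstroms are converted on
read.  Only orthorhombic boxes are accepted — every analysis in this package
separates along z, and triclinic wrapping is deliberately out of scope.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .topology import LipidTopology

__all__ = [
    "Atom",
    "Box",
    "Frame",
    "LeafletAssignment",
    "read_configuration",
    "read_trajectory",
    "write_configuration",
    "write_trajectory",
    "assign_leaflets",
    "minimum_image_distance",
    "minimum_image_displacement",
]

_ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class Atom:
    """One atom record: residue identity, atom name and position in nm."""

    residue_index: int
    residue_name: str
    atom_name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        if not self.residue_name:
            raise ValueError("residue_name must be non-empty")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box, edge lengths in nm."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        if lengths.shape != (3,) or not np.all(lengths > 0):
            raise ValueError("box lengths must be three positive numbers")
        object.__setattr__(self, "lengths", lengths)

    @property
    def cross_section(self) -> float:
        """Lateral (xy) area in nm^2."""
        return float(self.lengths[0] * self.lengths[1])

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))


@dataclass
class Frame:
    """One configuration: parallel atom arrays plus the periodic box."""

    residue_index: np.ndarray
    residue_name: np.ndarray
    atom_name: np.ndarray
    positions: np.ndarray
    box: Box
    time: float = 0.0

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        self.residue_name = np.asarray(self.residue_name, dtype="U8")
        self.atom_name = np.asarray(self.atom_name, dtype="U8")
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.residue_index)
        if not (len(self.residue_name) == len(self.atom_name) == n
                and self.positions.shape == (n, 3)):
            raise ValueError("atom arrays must have matching lengths")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.residue_index)

    @property
    def atoms(self) -> Iterator[Atom]:
        """Iterate atoms as individual records (convenience view)."""
        for i in range(self.n_atoms):
            yield Atom(int(self.residue_index[i]), str(self.residue_name[i]),
                       str(self.atom_name[i]), self.positions[i].copy())

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom], box: Box, time: float = 0.0) -> "Frame":
        return cls(
            residue_index=[a.residue_index for a in atoms],
            residue_name=[a.residue_name for a in atoms],
            atom_name=[a.atom_name for a in atoms],
            positions=np.array([a.position for a in atoms], dtype=float).reshape(-1, 3),
            box=box,
            time=time,
        )

    def select(self, residue_name: str | None = None,
               atom_name: str | None = None) -> np.ndarray:
        """Boolean mask of atoms matching exact residue/atom names."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residue_name is not None:
            mask &= self.residue_name == residue_name
        if atom_name is not None:
            mask &= self.atom_name == atom_name
        return mask


@dataclass(frozen=True)
class LeafletAssignment:
    """Map from lipid residue index to leaflet, plus the bilayer mid-plane."""

    leaflet_of: Mapping[int, str]  # residue_index -> "upper" | "lower"
    bilayer_center_z: float

    def residues(self, leaflet: str) -> list[int]:
        return [r for r, l in self.leaflet_of.items() if l == leaflet]


# ---------------------------------------------------------------------------
# parsing


class ParseError(ValueError):
    """Malformed coordinate file; message names the offending line."""


def _parse_gro_block(lines: list[str], lineno0: int) -> Frame:
    if len(lines) < 3:
        raise ParseError(f"line {lineno0 + 1}: truncated GRO block")
    title = lines[0]
    time = 0.0
    if "t=" in title:
        try:
            time = float(title.rsplit("t=", 1)[1].split()[0])
        except (ValueError, IndexError):
            time = 0.0
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise ParseError(f"line {lineno0 + 2}: bad atom count {lines[1]!r}") from exc
    if len(lines) != n_atoms + 3:
        raise ParseError(f"line {lineno0 + 2}: GRO block declares {n_atoms} atoms "
                         f"but holds {len(lines) - 3}")
    res_idx = np.empty(n_atoms, dtype=np.int64)
    res_name = np.empty(n_atoms, dtype="U8")
    atm_name = np.empty(n_atoms, dtype="U8")
    pos = np.empty((n_atoms, 3), dtype=float)
    for i in range(n_atoms):
        line = lines[2 + i]
        try:
            res_idx[i] = int(line[0:5])
            res_name[i] = line[5:10].strip()
            atm_name[i] = line[10:15].strip()
            pos[i, 0] = float(line[20:28])
            pos[i, 1] = float(line[28:36])
            pos[i, 2] = float(line[36:44])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"line {lineno0 + 3 + i}: malformed GRO atom record "
                             f"{line!r}") from exc
    box_fields = lines[-1].split()
    if len(box_fields) < 3:
        raise ParseError(f"line {lineno0 + len(lines)}: malformed GRO box line")
    vals = [float(v) for v in box_fields]
    if len(vals) > 3 and any(abs(v) > 1e-12 for v in vals[3:]):
        raise ParseError(f"line {lineno0 + len(lines)}: triclinic box not supported")
    return Frame(res_idx, res_name, atm_name, pos, Box(np.array(vals[:3])), time=time)


def _iter_gro_frames(path) -> Iterator[Frame]:
    with open(path) as fh:
        all_lines = fh.read().splitlines()
    i = 0
    while i < len(all_lines):
        if not all_lines[i].strip() and i == len(all_lines) - 1:
            break
        try:
            n_atoms = int(all_lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise ParseError(f"line {i + 2}: expected GRO atom count") from exc
        block = all_lines[i:i + n_atoms + 3]
        yield _parse_gro_block(block, i)
        i += n_atoms + 3


def _iter_pdb_frames(path) -> Iterator[Frame]:
    box: Box | None = None
    atoms: list[tuple[int, str, str, float, float, float]] = []
    seen_model = False

    def build() -> Frame:
        if box is None:
            raise ParseError("PDB file lacks a CRYST1 box record (box required)")
        arr = np.array([[a[3], a[4], a[5]] for a in atoms], dtype=float).reshape(-1, 3)
        return Frame(
            residue_index=[a[0] for a in atoms],
            residue_name=[a[1] for a in atoms],
            atom_name=[a[2] for a in atoms],
            positions=arr / _ANGSTROM_PER_NM,
            box=box,
        )

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                    alpha = float(line[33:40])
                    beta = float(line[40:47])
                    gamma = float(line[47:54])
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"line {lineno}: malformed CRYST1 record") from exc
                if any(abs(ang - 90.0) > 1e-6 for ang in (alpha, beta, gamma)):
                    raise ParseError(f"line {lineno}: triclinic box not supported")
                box = Box(np.array([a, b, c]) / _ANGSTROM_PER_NM)
            elif rec in ("ATOM", "HETATM"):
                try:
                    atoms.append((
                        int(line[22:26]),
                        line[17:21].strip(),
                        line[12:16].strip(),
                        float(line[30:38]),
                        float(line[38:46]),
                        float(line[46:54]),
                    ))
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"line {lineno}: malformed {rec} record") from exc
            elif rec == "MODEL":
                seen_model = True
            elif rec == "ENDMDL":
                yield build()
                atoms = []
    if atoms or not seen_model:
        if not atoms:
            raise ParseError("no ATOM/HETATM records found")
        yield build()


def _detect_format(path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = str(path).rsplit(".", 1)[-1].lower()
    if fmt not in ("gro", "pdb"):
        raise ValueError(f"unsupported coordinate format {fmt!r} (use gro or pdb)")
    return fmt


def read_configuration(path, format: str | None = None) -> Frame:
    """Read the first (or only) frame of a GRO or PDB file."""
    fmt = _detect_format(path, format)
    it = _iter_gro_frames(path) if fmt == "gro" else _iter_pdb_frames(path)
    try:
        return next(it)
    except StopIteration:
        raise ParseError(f"{path}: no frames found") from None


def read_trajectory(path, topology_frame: Frame | None = None,
                    format: str | None = None, burn_in: int = 0) -> list[Frame]:
    """Read all frames of a multi-frame GRO/PDB file, dropping ``burn_in``.

    If ``topology_frame`` is given, every frame must match its atom count.
    """
    fmt = _detect_format(path, format)
    it = _iter_gro_frames(path) if fmt == "gro" else _iter_pdb_frames(path)
    frames: list[Frame] = []
    for idx, frame in enumerate(it):
        if topology_frame is not None and frame.n_atoms != topology_frame.n_atoms:
            raise ParseError(
                f"frame {idx}: atom count {frame.n_atoms} does not match "
                f"topology ({topology_frame.n_atoms})")
        frames.append(frame)
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    return frames[burn_in:]


def write_configuration(frame: Frame, path, format: str | None = None,
                        append: bool = False) -> None:
    """Write one frame as GRO or PDB (nm written as-is for GRO, Å for PDB)."""
    fmt = _detect_format(path, format)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if fmt == "gro":
            fh.write(f"lamella frame t= {frame.time:.3f}\n{frame.n_atoms}\n")
            for i in range(frame.n_atoms):
                x, y, z = frame.positions[i]
                fh.write(f"{int(frame.residue_index[i]) % 100000:5d}"
                         f"{frame.residue_name[i]:<5.5s}{frame.atom_name[i]:>5.5s}"
                         f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n")
            lx, ly, lz = frame.box.lengths
            fh.write(f"{lx:10.5f}{ly:10.5f}{lz:10.5f}\n")
        else:
            a, b, c = frame.box.lengths * _ANGSTROM_PER_NM
            fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}"
                     f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
            fh.write("MODEL     1\n")
            for i in range(frame.n_atoms):
                x, y, z = frame.positions[i] * _ANGSTROM_PER_NM
                fh.write(f"ATOM  {(i + 1) % 100000:5d} {frame.atom_name[i]:<4.4s}"
                         f"{frame.residue_name[i]:<4.4s} "
                         f"{int(frame.residue_index[i]) % 10000:4d}    "
                         f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n")
            fh.write("ENDMDL\n")


def write_trajectory(frames: Iterable[Frame], path, format: str | None = None) -> None:
    """Write a frame sequence as a multi-frame GRO (or multi-MODEL PDB)."""
    first = True
    for frame in frames:
        write_configuration(frame, path, format=format, append=not first)
        first = False


# ---------------------------------------------------------------------------
# periodic geometry


def minimum_image_displacement(a, b, box: Box) -> np.ndarray:
    """Displacement a - b wrapped to the nearest periodic image (vectorized)."""
    delta = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    lengths = box.lengths
    return delta - lengths * np.round(delta / lengths)


def minimum_image_distance(a, b, box: Box) -> float | np.ndarray:
    """Euclidean distance under the minimum-image convention."""
    delta = minimum_image_displacement(a, b, box)
    return np.linalg.norm(delta, axis=-1)


def brute_force_min_image_distance(a, b, box: Box) -> float:
    """Reference implementation: minimum over all 27 neighbour images."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = np.inf
    for shift in itertools.product((-1, 0, 1), repeat=3):
        d = np.linalg.norm(a - (b + np.asarray(shift) * box.lengths))
        best = min(best, float(d))
    return best


# ---------------------------------------------------------------------------
# leaflets


def assign_leaflets(frame: Frame,
                    topologies: Mapping[str, LipidTopology]) -> LeafletAssignment:
    """Assign each lipid to the upper or lower leaflet by its phosphorus z.

    The bilayer centre is the mean z of all lipid phosphorus atoms; a lipid
    is "upper" iff its phosphorus lies above the centre.  Assignment is
    per-frame; flip-flop is not tracked.
    """
    masks = []
    for species, topo in topologies.items():
        masks.append(frame.select(species, topo.phosphorus_atom))
    if not masks:
        raise ValueError("no lipid topologies supplied")
    p_mask = np.logical_or.reduce(masks)
    if not p_mask.any():
        raise ValueError("no lipid phosphorus atoms found in frame")
    p_z = frame.positions[p_mask, 2]
    residues = frame.residue_index[p_mask]
    if len(residues) < 2:
        raise ValueError("need at least two lipids to define a bilayer")
    center = float(p_z.mean())
    if np.ptp(p_z) < 1e-9:
        raise ValueError("degenerate bilayer: all phosphorus atoms at identical z")
    leaflet_of = {int(r): ("upper" if z > center else "lower")
                  for r, z in zip(residues, p_z)}
    return LeafletAssignment(leaflet_of=leaflet_of, bilayer_center_z=center)
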