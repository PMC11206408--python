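"""Readers/writers for the external representations the pipeline touches.

Formats: fixed-width PDB (MODEL/ENDMDL multi-frame), multi-frame XYZ,
two-column whitespace time series, and WHAM-style umbrella metadata files.
All coordinates are Å, times ps, energies kcal mol⁻¹.

Boxes are orthorhombic; distance helpers here apply the minimum-image
convention in each Cartesian direction independently.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


class StructureError(ValueError):
    """Frames of one trajectory are mutually inconsistent."""


class OrderingError(ValueError):
    """Time values are not strictly increasing."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class SelectionError(KeyError):
    """A named atom selection cannot be resolved."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """Identity and metadata of one atom; positions live on the Trajectory."""

    atom_name: str
    element: str
    residue_name: str
    residue_id: int
    chain_tag: str = "A"

    def __post_init__(self):
        if self.residue_id < 1:
            raise ValidationError(f"residue_id must be >= 1, got {self.residue_id}")


@dataclass
class Frame:
    """A single snapshot: atom metadata plus an (N, 3) coordinate array."""

    atoms: list
    coords: np.ndarray
    box: np.ndarray
    time: float = 0.0


class Trajectory:
    """Ordered frames with identical atom content and named index selections.

    Coordinates are stored as one (n_frames, n_atoms, 3) array; the atom
    metadata list is shared by every frame.
    """

    def __init__(self, atoms, coords, box, times=None, selections=None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise ValidationError("a trajectory needs at least one frame")
        if coords.shape[1] != len(atoms):
            raise StructureError(
                f"coords hold {coords.shape[1]} atoms but {len(atoms)} records given")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite coordinate encountered")
        box = np.asarray(box, dtype=float)
        if box.shape != (3,) or np.any(box <= 0):
            raise ValidationError("box must be a positive 3-vector (orthorhombic)")
        self.atoms = list(atoms)
        self.coords = coords
        self.box = box
        self.times = (np.arange(coords.shape[0], dtype=float)
                      if times is None else np.asarray(times, dtype=float))
        self.selections: dict[str, np.ndarray] = {}
        for name, idx in (selections or {}).items():
            self.add_selection(name, idx)

    # -- basic shape ----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(self.atoms, self.coords[i], self.box, float(self.times[i]))

    # -- selections -----------------------------------------------------
    def add_selection(self, name: str, indices) -> None:
        idx = np.asarray(indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
            raise SelectionError(f"selection {name!r} has out-of-range indices")
        self.selections[name] = idx

    def selection(self, name: str) -> np.ndarray:
        if name not in self.selections:
            raise SelectionError(f"unknown selection {name!r}")
        return self.selections[name]

    def select(self, atom_name=None, residue_id=None, residue_name=None,
               chain_tag=None, element=None) -> np.ndarray:
        """Indices of atoms matching every given (chain, residue, name) field."""
        out = []
        for i, a in enumerate(self.atoms):
            if atom_name is not None and a.atom_name != atom_name:
                continue
            if residue_id is not None and a.residue_id != residue_id:
                continue
            if residue_name is not None and a.residue_name != residue_name:
                continue
            if chain_tag is not None and a.chain_tag != chain_tag:
                continue
            if element is not None and a.element != element:
                continue
            out.append(i)
        return np.asarray(out, dtype=int)

    def residue_ids(self) -> list:
        seen = []
        for a in self.atoms:
            if a.residue_id not in seen:
                seen.append(a.residue_id)
        return seen

    def residue_indices(self, residue_id: int) -> np.ndarray:
        idx = self.select(residue_id=residue_id)
        if idx.size == 0:
            raise SelectionError(f"residue {residue_id} has zero atoms")
        return idx


@dataclass
class TimeSeries:
    """Named scalar series on a strictly increasing time grid (ps)."""

    name: str
    times: np.ndarray
    values: np.ndarray
    unit: str = "A"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise OrderingError(f"times of series {self.name!r} not strictly increasing")

    def __len__(self):
        return self.times.size


@dataclass
class UmbrellaMetadata:
    """Window inventory: (data_path, bias_center Å, force constant kcal/mol/Å²)."""

    entries: list = field(default_factory=list)

    def __post_init__(self):
        paths = [e[0] for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ValidationError("duplicate data_path in umbrella metadata")
        for path, center, k in self.entries:
            if k <= 0:
                raise ValidationError(
                    f"force_constant must be > 0 (entry {path!r} has {k})")

    def __len__(self):
        return len(self.entries)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def minimum_image(delta, box):
    """Wrap Cartesian displacement(s) into the central orthorhombic cell."""
    delta = np.asarray(delta, dtype=float)
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def mi_distance(a, b, box):
    """Minimum-image distance(s) between position arrays broadcastable to (..., 3)."""
    d = minimum_image(np.asarray(a) - np.asarray(b), box)
    return np.sqrt(np.sum(d * d, axis=-1))


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_PDB_DEFAULT_BOX = np.array([500.0, 500.0, 500.0])


def _pdb_element(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return "X"
    # two-letter elements (Ca, Cl, Na...) start in column 13 of a 4-char name
    if len(stripped) >= 2 and stripped[:2].capitalize() in (
            "Ca", "Cl", "Na", "Mg", "Zn", "Fe", "Br"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def read_pdb(path) -> Trajectory:
    """Parse a fixed-width (wwPDB) file, honouring MODEL/ENDMDL multi-frame blocks."""
    atoms: list[AtomRecord] = []
    frames: list[list] = []
    current: list = []
    box = None
    first_frame_done = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                try:
                    box = np.array([float(line[6:15]), float(line[15:24]),
                                    float(line[24:33])])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: malformed CRYST1 record")
            elif rec in ("ATOM  ", "HETATM"):
                try:
                    name = line[12:16].strip()
                    resname = line[17:20].strip() or "UNK"
                    chain = line[21].strip() or "A"
                    resid = int(line[22:26])
                    xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    elem = line[76:78].strip() if len(line) >= 78 else ""
                except (ValueError, IndexError):
                    raise ParseError(f"{path}:{lineno}: malformed ATOM/HETATM record")
                if not first_frame_done:
                    atoms.append(AtomRecord(name, elem or _pdb_element(name),
                                            resname, resid, chain))
                current.append(xyz)
            elif rec.startswith("ENDMDL") or rec.startswith("END "):
                if current:
                    frames.append(current)
                    current = []
                    first_frame_done = True
    if current:
        frames.append(current)
    if not frames:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    n0 = len(frames[0])
    for i, f in enumerate(frames):
        if len(f) != n0:
            raise StructureError(
                f"{path}: frame {i + 1} has {len(f)} atoms, frame 1 has {n0}")
    coords = np.array(frames, dtype=float)
    return Trajectory(atoms, coords, _PDB_DEFAULT_BOX if box is None else box)


def write_pdb(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        b = traj.box
        fh.write(f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                 f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
        for fi in range(traj.n_frames):
            fh.write(f"MODEL     {fi + 1:4d}\n")
            for ai, a in enumerate(traj.atoms):
                x, y, z = traj.coords[fi, ai]
                name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
                fh.write(
                    f"ATOM  {ai + 1 if ai < 99999 else 99999:5d} {name:4s} "
                    f"{a.residue_name:<3s} {a.chain_tag[:1]}{a.residue_id:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{a.element:>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def read_xyz(path) -> Trajectory:
    """Parse multi-frame XYZ. The comment line may carry a residue directive
    ``residues=NAME:ID,NAME:ID,...`` (one entry per atom); otherwise residue
    metadata defaults to UNK/1. A ``box=Lx,Ly,Lz`` directive sets the box."""
    frames = []
    atoms: list[AtomRecord] = []
    box = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 0
    first = True
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].split()[0])
        except ValueError:
            raise ParseError(f"{path}:{i + 1}: expected atom count, got {lines[i]!r}")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        residues = None
        for tok in comment.split():
            if tok.startswith("box="):
                box = np.array([float(v) for v in tok[4:].split(",")])
            if tok.startswith("residues="):
                residues = [t.split(":") for t in tok[9:].split(",")]
        frame = []
        for j in range(natoms):
            lineno = i + 2 + j
            if lineno >= len(lines):
                raise StructureError(f"{path}: truncated frame at line {lineno + 1}")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno + 1}: malformed atom line")
            try:
                xyz = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise ParseError(f"{path}:{lineno + 1}: non-numeric coordinate")
            if first:
                if residues is not None and j < len(residues):
                    rname, rid = residues[j][0], int(residues[j][1])
                else:
                    rname, rid = "UNK", 1
                atoms.append(AtomRecord(parts[0], parts[0], rname, rid))
            frame.append(xyz)
        if not first and natoms != len(atoms):
            raise StructureError(
                f"{path}: frame has {natoms} atoms, first frame has {len(atoms)}")
        frames.append(frame)
        first = False
        i = lineno + 1
    if not frames:
        raise ParseError(f"{path}: empty XYZ file")
    return Trajectory(atoms, np.array(frames, dtype=float),
                      _PDB_DEFAULT_BOX if box is None else box)


def write_xyz(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        b = traj.box
        res = ",".join(f"{a.residue_name}:{a.residue_id}" for a in traj.atoms)
        for fi in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame={fi} box={b[0]:.6f},{b[1]:.6f},{b[2]:.6f} residues={res}\n")
            for ai, a in enumerate(traj.atoms):
                x, y, z = traj.coords[fi, ai]
                fh.write(f"{a.atom_name:<6s} {x:.9f} {y:.9f} {z:.9f}\n")


def read_structure(path, fmt=None) -> Trajectory:
    """Dispatch on format name or file extension ({pdb|xyz})."""
    if fmt is None:
        fmt = os.path.splitext(str(path))[1].lstrip(".").lower()
    if fmt == "pdb":
        return read_pdb(path)
    if fmt == "xyz":
        return read_xyz(path)
    raise ValidationError(f"unknown structure format {fmt!r}")


# ---------------------------------------------------------------------------
# time series & umbrella metadata
# ---------------------------------------------------------------------------

def read_timeseries(path, name=None) -> TimeSeries:
    """Two whitespace columns (time ps, value); '#' lines are comments."""
    times, values = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected two columns")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric token")
    ts = np.asarray(times)
    if ts.size > 1 and not np.all(np.diff(ts) > 0):
        raise OrderingError(f"{path}: times not strictly increasing")
    return TimeSeries(name or os.path.basename(str(path)), ts, np.asarray(values))


def write_timeseries(series: TimeSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# t_ps {series.name}\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.9g} {v:.9g}\n")


def read_umbrella_metadata(path) -> UmbrellaMetadata:
    """WHAM-convention metadata: one window per line: path center force_constant."""
    entries = []
    base = os.path.dirname(os.path.abspath(str(path)))
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 'path center k'")
            try:
                center, k = float(parts[1]), float(parts[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric center or k")
            p = parts[0]
            if not os.path.isabs(p):
                p = os.path.join(base, p)
            entries.append((p, center, k))
    return UmbrellaMetadata(entries)
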