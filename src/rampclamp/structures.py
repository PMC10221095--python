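"""Structures, trajectories, force traces, and their file formats.

The data model is deliberately small: an :class:`Atom` table wrapped by
:class:`Structure`, a :class:`Trajectory` that shares one atom table across
frames, and a :class:`ForceTrace` for pulling experiments.  Readers cover
the ATOM/HETATM/MODEL/ENDMDL/TER subset of the PDB format, multi-frame XYZ,
and force traces as headed CSV.  A VMD-flavoured selection language
(``"name CA and chain A"``) resolves to ordered atom indices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .errors import (
    EmptyInputError,
    ParseError,
    RampClampError,
    SelectionError,
    ShapeError,
)

# standard atomic masses (amu) for the elements that occur in protein models
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "NA": 22.990,
    "CL": 35.45, "MG": 24.305, "CA": 40.078, "K": 39.098,
}

# element-keyed van der Waals radii (Å), Bondi-style, used as SASA defaults
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "FE": 1.50, "ZN": 1.39, "NA": 2.27,
    "CL": 1.75, "MG": 1.73, "CA": 2.31, "K": 2.75,
}


@dataclass
class Atom:
    """One atom: identity, residue membership, and coordinates in Å."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coord: np.ndarray
    mass: Optional[float] = None
    charge: Optional[float] = None
    vdw_radius: Optional[float] = None

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ShapeError(f"atom {self.serial}: coord must be a finite 3-vector")
        if self.mass is None:
            self.mass = ATOMIC_MASSES.get(self.element.upper(), 12.011)
        if self.mass <= 0:
            raise RampClampError(f"atom {self.serial}: mass must be positive")
        if self.vdw_radius is None:
            self.vdw_radius = VDW_RADII.get(self.element.upper())
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise RampClampError(f"atom {self.serial}: vdw_radius must be positive")

    @property
    def residue_key(self) -> tuple:
        return (self.chain_id, self.res_name, self.res_seq)


class Structure:
    """An ordered atom table with convenience arrays and selections."""

    def __init__(self, atoms: Sequence[Atom]):
        if len(atoms) == 0:
            raise EmptyInputError("a Structure needs at least one atom")
        self.atoms = list(atoms)
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.res_seq, a.name)
            if key in seen:
                raise RampClampError(f"duplicate atom identity {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @coords.setter
    def coords(self, value):
        value = np.asarray(value, dtype=float)
        if value.shape != (len(self.atoms), 3):
            raise ShapeError("coordinate array shape mismatch")
        for a, c in zip(self.atoms, value):
            a.coord = c.copy()

    @property
    def chains(self) -> set:
        return {a.chain_id for a in self.atoms}

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array(
            [a.vdw_radius if a.vdw_radius is not None else 1.7 for a in self.atoms],
            dtype=float,
        )

    def select(self, expression: str) -> np.ndarray:
        """Resolve a selection expression to ordered atom indices."""
        return select(self, expression)

    def subset(self, indices: Iterable[int]) -> "Structure":
        return Structure([self.atoms[i] for i in indices])

    def copy(self) -> "Structure":
        return Structure(
            [
                Atom(a.serial, a.name, a.element, a.res_name, a.res_seq,
                     a.chain_id, a.coord.copy(), a.mass, a.charge, a.vdw_radius)
                for a in self.atoms
            ]
        )


class Trajectory:
    """Ordered frames of coordinates over one shared atom table.

    Parameters
    ----------
    structure : Structure
        Topology; its own coordinates are ignored once frames exist.
    coords : ndarray, shape (n_frames, n_atoms, 3), Å
    times : ndarray, ns, strictly increasing
    """

    def __init__(self, structure: Structure, coords, times=None):
        self.structure = structure
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[1] != structure.n_atoms or coords.shape[2] != 3:
            raise ShapeError(
                f"trajectory coords must be (n_frames, {structure.n_atoms}, 3); "
                f"got {coords.shape}"
            )
        self.coords = coords
        if times is None:
            times = np.arange(coords.shape[0], dtype=float)
        times = np.asarray(times, dtype=float)
        if times.shape != (coords.shape[0],):
            raise ShapeError("times length must equal number of frames")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise RampClampError("frame times must be strictly increasing")
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Structure:
        s = self.structure.copy()
        s.coords = self.coords[i]
        return s


@dataclass
class ForceTrace:
    """A pulling-experiment time series.

    ``force`` is the signed projection of the spring (or clamp) force on
    the pulling direction, in pN; ``dummy_pos`` and ``steered_pos`` are
    positions along the pulling axis in Å; ``phase`` labels each sample
    ``"ramp"`` or ``"clamp"`` and may switch at most once, ramp→clamp.
    """

    times: np.ndarray
    force: np.ndarray
    dummy_pos: np.ndarray
    steered_pos: np.ndarray
    phase: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.dummy_pos = np.asarray(self.dummy_pos, dtype=float)
        self.steered_pos = np.asarray(self.steered_pos, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        n = len(self.times)
        if n == 0:
            raise EmptyInputError("force trace is empty")
        for arr, nm in [(self.force, "force"), (self.dummy_pos, "dummy_pos"),
                        (self.steered_pos, "steered_pos"), (self.phase, "phase")]:
            if len(arr) != n:
                raise ShapeError(f"{nm} length != times length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise RampClampError("trace times must be strictly increasing")
        bad = set(self.phase) - {"ramp", "clamp"}
        if bad:
            raise RampClampError(f"unknown phase labels: {bad}")
        switches = int(np.sum(self.phase[1:] != self.phase[:-1]))
        if switches > 1:
            raise RampClampError("phase may change at most once")
        if switches == 1 and self.phase[0] != "ramp":
            raise RampClampError("phase change must be ramp→clamp")

    def __len__(self):
        return len(self.times)

    @property
    def ramp_mask(self) -> np.ndarray:
        return self.phase == "ramp"

    @property
    def clamp_mask(self) -> np.ndarray:
        return self.phase == "clamp"


# ----------------------------------------------------------------- PDB IO

def _infer_element(name: str, res_name: str) -> str:
    """Infer the element from PDB atom-name columns."""
    stripped = name.strip()
    if not stripped:
        return "C"
    # two-letter elements occurring in proteins/ions
    up = stripped.upper()
    for two in ("SE", "FE", "ZN", "MG", "CL", "NA"):
        if up.startswith(two) and res_name.strip().upper() not in ("",):
            # only treat as two-letter when the name is exactly the ion
            if up == two or (len(name) >= 2 and name[0] != " " and up[:2] == two):
                return two
    # hydrogen names may start with a digit (e.g. 1HB2)
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_pdb(path, model_policy: str = "all", altloc_policy: str = "first",
             frame_dt: float = 1.0) -> Union[Structure, Trajectory]:
    """Read a PDB file into a Structure (single model) or Trajectory.

    Parameters
    ----------
    model_policy : {"all", "first"}
        ``"all"`` turns a multi-MODEL file into a Trajectory; ``"first"``
        keeps only the first model.
    altloc_policy : {"first", "all"}
        ``"first"`` keeps altloc ``'A'`` or blank records only.
    frame_dt : float
        Time spacing (ns) assigned to models of a multi-MODEL file.

    Notes
    -----
    Coordinates are in Å.  The modified residue PCA (pyroglutamate) is
    parsed exactly like a standard residue.  Elements are inferred from
    the atom-name columns when the element field is blank.
    """
    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    n_atom_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if current:
                    models.append(current)
                current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
            elif rec in ("ATOM", "HETATM"):
                n_atom_records += 1
                try:
                    altloc = line[16]
                    if altloc_policy == "first" and altloc not in (" ", "A"):
                        continue
                    serial = int(line[6:11])
                    name = line[12:16]
                    res_name = line[17:20].strip()
                    chain_id = line[21].strip() or "A"
                    res_seq = int(line[22:26])
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                    element = line[76:78].strip() if len(line) >= 78 else ""
                    if not element:
                        element = _infer_element(name, res_name)
                    current.append(
                        Atom(serial, name.strip(), element.upper(), res_name,
                             res_seq, chain_id, np.array([x, y, z]))
                    )
                except (ValueError, IndexError) as exc:
                    raise ParseError(
                        f"{path}: malformed PDB record at line {lineno}: {exc}"
                    ) from exc
    if current:
        models.append(current)
    models = [m for m in models if m]
    if n_atom_records == 0 or not models:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    first = Structure(models[0])
    if len(models) == 1 or model_policy == "first":
        return first
    for i, m in enumerate(models[1:], start=2):
        if len(m) != first.n_atoms:
            raise ShapeError(
                f"{path}: MODEL {i} has {len(m)} atoms, expected {first.n_atoms}"
            )
    coords = np.array([[a.coord for a in m] for m in models])
    times = np.arange(len(models), dtype=float) * frame_dt
    return Trajectory(first, coords, times)


def _format_atom_line(a: Atom, serial: int) -> str:
    for v in a.coord:
        if not (-999.999 <= v <= 9999.999):
            raise RampClampError(
                f"coordinate {v:.3f} not representable in PDB fixed width"
            )
    name = a.name
    # PDB convention: 1-3 char names start in column 14
    if len(name) < 4:
        name = f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {name:<4s} {a.res_name:<3s} {a.chain_id:1s}"
        f"{a.res_seq:4d}    {a.coord[0]:8.3f}{a.coord[1]:8.3f}{a.coord[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
    )


def write_pdb(obj: Union[Structure, Trajectory], path) -> None:
    """Write a Structure (single block) or Trajectory (MODEL/ENDMDL blocks)."""
    with open(path, "w") as fh:
        if isinstance(obj, Trajectory):
            for f in range(obj.n_frames):
                fh.write(f"MODEL     {f + 1:4d}\n")
                for i, a in enumerate(obj.structure.atoms, start=1):
                    a2 = Atom(a.serial, a.name, a.element, a.res_name, a.res_seq,
                              a.chain_id, obj.coords[f, i - 1], a.mass,
                              a.charge, a.vdw_radius)
                    fh.write(_format_atom_line(a2, i))
                fh.write("ENDMDL\n")
        else:
            for i, a in enumerate(obj.atoms, start=1):
                fh.write(_format_atom_line(a, i))
            fh.write("TER\n")
        fh.write("END\n")


# ----------------------------------------------------------------- XYZ IO

def read_xyz_traj(path, atom_table: Structure, frame_dt: float = 1.0) -> Trajectory:
    """Read a multi-frame XYZ file against a known atom table."""
    frames = []
    times = []
    with open(path) as fh:
        lines = fh.readlines()
    if not any(ln.strip() for ln in lines):
        raise EmptyInputError(f"{path}: empty XYZ file")
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: bad atom-count line {i + 1}") from exc
        if n != atom_table.n_atoms:
            raise ShapeError(
                f"{path}: frame at line {i + 1} has {n} atoms, "
                f"atom table has {atom_table.n_atoms}"
            )
        comment = lines[i + 1].strip()
        t = None
        if "time=" in comment:
            try:
                t = float(comment.split("time=")[1].split()[0])
            except (ValueError, IndexError):
                t = None
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ParseError(f"{path}: truncated frame at line {i + 1}")
        coords = np.empty((n, 3))
        for j, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: bad atom line {i + 3 + j}")
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        times.append(t)
        i += 2 + n
    if any(t is None for t in times):
        times = np.arange(len(frames), dtype=float) * frame_dt
    return Trajectory(atom_table, np.array(frames), np.asarray(times, dtype=float))


def write_xyz_traj(traj: Trajectory, path) -> None:
    """Write a Trajectory as multi-frame XYZ (6-decimal precision)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {f} time={traj.times[f]:.9g} ns\n")
            for a, c in zip(traj.structure.atoms, traj.coords[f]):
                fh.write(f"{a.element:<2s} {c[0]:.6f} {c[1]:.6f} {c[2]:.6f}\n")


# ----------------------------------------------------- force-trace CSV IO

FORCE_TRACE_HEADER = "time_ns,force_pN,dummy_A,steered_A,phase"


def write_force_trace(trace: ForceTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(FORCE_TRACE_HEADER + "\n")
        for t, f, d, s, p in zip(trace.times, trace.force, trace.dummy_pos,
                                 trace.steered_pos, trace.phase):
            fh.write(f"{t:.9g},{f:.9g},{d:.9g},{s:.9g},{p}\n")


def read_force_trace(path) -> ForceTrace:
    times, force, dummy, steered, phase = [], [], [], [], []
    with open(path) as fh:
        header = fh.readline().strip()
        if header.replace(" ", "") != FORCE_TRACE_HEADER:
            raise ParseError(f"{path}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.strip().split(",")
            if len(parts) != 5:
                raise ParseError(f"{path}: bad row at line {lineno}")
            times.append(float(parts[0]))
            force.append(float(parts[1]))
            dummy.append(float(parts[2]))
            steered.append(float(parts[3]))
            phase.append(parts[4])
    if not times:
        raise EmptyInputError(f"{path}: no force-trace rows")
    return ForceTrace(np.array(times), np.array(force), np.array(dummy),
                      np.array(steered), np.array(phase, dtype=object))


# ------------------------------------------------------------- selections

_KEYWORDS = {"name", "chain", "resname", "resseq", "element"}
_OPERATORS = {"and", "or", "not", "(", ")", "all", "none"}


def _tokenize(expression: str) -> list:
    out = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _SelParser:
    """Recursive-descent parser for the tiny selection grammar."""

    def __init__(self, tokens: list, structure: Structure):
        self.tokens = tokens
        self.pos = 0
        self.s = structure
        self.names = np.array([a.name for a in structure.atoms])
        self.chains = np.array([a.chain_id for a in structure.atoms])
        self.resnames = np.array([a.res_name for a in structure.atoms])
        self.resseqs = np.array([a.res_seq for a in structure.atoms])
        self.elements = np.array([a.element for a in structure.atoms])

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.pos != len(self.tokens):
            raise SelectionError(f"trailing tokens at {self.tokens[self.pos:]}")
        return mask

    def expr(self):
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self):
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self):
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression")
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        if tok == "all":
            self.next()
            return np.ones(len(self.s), dtype=bool)
        if tok == "none":
            self.next()
            return np.zeros(len(self.s), dtype=bool)
        if tok in _KEYWORDS:
            return self.primitive()
        raise SelectionError(f"unexpected token {tok!r}")

    def _values(self) -> list:
        vals = []
        while self.peek() is not None and self.peek() not in _OPERATORS \
                and self.peek() not in _KEYWORDS:
            vals.append(self.next())
        if not vals:
            raise SelectionError("keyword without values")
        return vals

    def primitive(self):
        kw = self.next()
        vals = self._values()
        mask = np.zeros(len(self.s), dtype=bool)
        if kw == "name":
            for v in vals:
                mask |= self.names == v
        elif kw == "element":
            for v in vals:
                mask |= self.elements == v.upper()
        elif kw == "chain":
            known = set(self.chains)
            for v in vals:
                if v not in known:
                    raise SelectionError(f"unknown chain {v!r}")
                mask |= self.chains == v
        elif kw == "resname":
            known = set(self.resnames)
            for v in vals:
                if v not in known:
                    raise SelectionError(f"unknown residue name {v!r}")
                mask |= self.resnames == v
        elif kw == "resseq":
            for v in vals:
                if "-" in v[1:]:
                    a, b = v.split("-", 1) if not v.startswith("-") else (None, None)
                    if a is None:
                        raise SelectionError(f"bad resseq range {v!r}")
                    lo, hi = int(a), int(b)
                    mask |= (self.resseqs >= lo) & (self.resseqs <= hi)
                else:
                    mask |= self.resseqs == int(v)
        return mask


def select(structure: Structure, expression: str) -> np.ndarray:
    """Resolve a selection expression to an ordered array of atom indices.

    The order is file order (ascending index); the same expression on the
    same structure always yields the same indices.  An empty selection is
    allowed but warned about.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _SelParser(tokens, structure).parse()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return idx
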