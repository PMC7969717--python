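"""Domain types and file I/O for structures, trajectories and parameter sidecars.

Conventions used throughout the package:

* coordinates are in Angstrom, energies in kcal/mol, charges in elementary
  charge units (e), electrostatic potentials in kT/e at the stated temperature;
* residue numbering is 1-based as written in PDB files, internal atom indices
  are 0-based;
* the atom order of a :class:`Structure` defines the coordinate-vector order
  for every downstream calculation (lambda, fluctuation matrices, modes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class Atom:
    """A named atom with coordinates and optional nonbonded parameters.

    ``charge`` [e], ``lj_sigma`` [A], ``lj_epsilon`` [kcal/mol] and ``radius``
    [A] are optional: geometry-only workflows never touch them, and energetics
    operations raise when an atom they need is unparameterized.
    """

    name: str
    element: str
    residue_id: int
    residue_name: str
    chain: str
    position: np.ndarray
    charge: float | None = None
    lj_sigma: float | None = None
    lj_epsilon: float | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if self.radius is not None and self.radius <= 0:
            raise ValueError(f"atom {self.name}: radius must be > 0")
        if self.lj_epsilon is not None and self.lj_epsilon < 0:
            raise ValueError(f"atom {self.name}: lj_epsilon must be >= 0")

    def key(self) -> tuple[str, int, str]:
        """(chain, residue_id, atom name) — the parameter-table key."""
        return (self.chain, self.residue_id, self.name)


class Structure:
    """An ordered list of atoms; the unit of all geometry."""

    def __init__(self, atoms: Sequence[Atom], metadata: dict | None = None):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("a Structure needs at least one atom")
        self.atoms = atoms
        self.metadata = dict(metadata or {})
        self._check_residue_order()

    def _check_residue_order(self) -> None:
        last: dict[str, int] = {}
        for a in self.atoms:
            prev = last.get(a.chain)
            if prev is not None and a.residue_id < prev:
                raise ValueError(
                    f"residue ids must be non-decreasing within chain {a.chain!r}"
                )
            last[a.chain] = a.residue_id

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in atom order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A new Structure with the same atom identities but new positions."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return Structure(atoms, self.metadata)

    def copy(self) -> "Structure":
        return self.with_coords(self.coords)

    def atom_identity(self) -> list[tuple[str, int, str, str]]:
        return [(a.chain, a.residue_id, a.residue_name, a.name) for a in self.atoms]

    def total_charge(self) -> float:
        return float(sum(a.charge or 0.0 for a in self.atoms))


class Trajectory:
    """Ordered frames over a fixed atom set."""

    def __init__(self, frames: Sequence[Structure]):
        frames = list(frames)
        if not frames:
            raise ValueError("a Trajectory needs at least one frame")
        ident = frames[0].atom_identity()
        for i, f in enumerate(frames[1:], start=1):
            if f.atom_identity() != ident:
                raise ValueError(
                    f"frame {i} does not share the atom list of frame 0 "
                    f"({len(f)} vs {len(frames[0])} atoms or differing identities)"
                )
        self.frames = frames

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0])

    @property
    def coords(self) -> np.ndarray:
        """(n_frames, N, 3) coordinate array."""
        return np.stack([f.coords for f in self.frames])


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection resolved against a Structure.

    Modes: ``all``; ``calpha`` (atoms named CA with element C, one per amino
    acid residue); ``residue_range`` (inclusive 1-based ``start``..``stop``);
    ``name_list`` (atom names in ``names``).
    """

    mode: str = "calpha"
    start: int | None = None
    stop: int | None = None
    names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.mode not in {"all", "calpha", "residue_range", "name_list"}:
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.mode == "residue_range" and (self.start is None or self.stop is None):
            raise ValueError("residue_range selection needs start and stop")
        if self.mode == "name_list" and not self.names:
            raise ValueError("name_list selection needs at least one name")

    def resolve(self, s: Structure) -> np.ndarray:
        """Strictly increasing 0-based atom indices selected on ``s``."""
        if self.mode == "all":
            idx = np.arange(len(s))
        elif self.mode == "calpha":
            idx = np.array(
                [i for i, a in enumerate(s.atoms)
                 if a.name == "CA" and a.element.upper() == "C"],
                dtype=int,
            )
        elif self.mode == "residue_range":
            idx = np.array(
                [i for i, a in enumerate(s.atoms)
                 if self.start <= a.residue_id <= self.stop],
                dtype=int,
            )
        else:  # name_list
            wanted = set(self.names)
            idx = np.array([i for i, a in enumerate(s.atoms) if a.name in wanted],
                           dtype=int)
        if idx.size == 0:
            raise ValueError(f"selection {self} resolves to no atoms")
        return idx


def apply_selection(s: Structure, sel: SelectionSpec) -> np.ndarray:
    """Resolve ``sel`` on ``s`` (thin alias for :meth:`SelectionSpec.resolve`)."""
    return sel.resolve(s)


# --------------------------------------------------------------------------
# PDB and XYZ readers / writers
# --------------------------------------------------------------------------

def _infer_dialect(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    ext = Path(path).suffix.lower()
    if ext in {".pdb", ".ent"}:
        return "pdb"
    if ext == ".xyz":
        return "xyz"
    raise ValueError(f"cannot infer dialect from extension {ext!r}; pass dialect=")


def _prescan_pdb(path: Path) -> None:
    """Cheap validation pass so malformed records fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in {"ATOM", "HETATM"}:
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"{path}: line {lineno}: truncated {rec} record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: malformed {rec} record ({exc})"
                ) from None
            if line[26] != " ":
                raise ParseError(
                    f"{path}: line {lineno}: insertion code {line[26]!r} not supported"
                )


def _structures_from_atom_array(arr: struc.AtomArray) -> Structure:
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(Atom(
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]).capitalize(),
            residue_id=int(arr.res_id[i]),
            residue_name=str(arr.res_name[i]),
            chain=str(arr.chain_id[i]) or "A",
            position=np.asarray(arr.coord[i], dtype=float),
        ))
    return Structure(atoms)


def _read_pdb_models(path: Path) -> list[Structure]:
    _prescan_pdb(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise ParseError(f"{path}: no ATOM records found")
    frames = []
    template = None
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m, altloc="first")
        s = _structures_from_atom_array(arr)
        if template is None:
            template = s.atom_identity()
        elif s.atom_identity() != template:
            raise ParseError(
                f"{path}: frame {m - 1} (MODEL {m}) does not match the atom "
                f"list of the first model"
            )
        frames.append(s)
    return frames


def _read_xyz_frames(path: Path) -> list[Structure]:
    """Plain (possibly concatenated) XYZ: count line, comment line, atom lines."""
    frames: list[Structure] = []
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    lineno = 0
    while pos < len(lines):
        if not lines[pos].strip():           # trailing blank lines
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError:
            raise ParseError(
                f"{path}: line {pos + 1}: expected an atom count"
            ) from None
        if count <= 0:
            raise ParseError(f"{path}: line {pos + 1}: atom count must be positive")
        if pos + 1 + count >= len(lines) + 1 and pos + 2 + count > len(lines):
            raise ParseError(
                f"{path}: frame starting at line {pos + 1} is truncated"
            )
        atoms = []
        for j in range(count):
            lineno = pos + 2 + j
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno + 1}: malformed atom line")
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno + 1}: malformed coordinate ({exc})"
                ) from None
            element = parts[0]
            atoms.append(Atom(
                name=element, element=element.capitalize(), residue_id=1,
                residue_name="UNK", chain="A", position=np.array(xyz),
            ))
        frames.append(Structure(atoms))
        pos += 2 + count
    if not frames:
        raise ParseError(f"{path}: empty file")
    return frames


def read_structure(path: str | Path, dialect: str | None = None) -> Structure:
    """Read a single structure from a PDB or XYZ file.

    For multi-model files the first model is returned; use
    :func:`read_trajectory` to keep all frames.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    d = _infer_dialect(path, dialect)
    frames = _read_pdb_models(path) if d == "pdb" else _read_xyz_frames(path)
    return frames[0]


def read_trajectory(path: str | Path, dialect: str | None = None) -> Trajectory:
    """Read a multi-model PDB or concatenated XYZ file as a Trajectory."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    d = _infer_dialect(path, dialect)
    frames = _read_pdb_models(path) if d == "pdb" else _read_xyz_frames(path)
    try:
        return Trajectory(frames)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def _atom_array_from_structure(s: Structure) -> struc.AtomArray:
    n = len(s)
    arr = struc.AtomArray(n)
    arr.coord = s.coords.astype(np.float32)
    arr.atom_name = np.array([a.name for a in s.atoms])
    arr.element = np.array([a.element.upper() for a in s.atoms])
    arr.res_id = np.array([a.residue_id for a in s.atoms])
    arr.res_name = np.array([a.residue_name for a in s.atoms])
    arr.chain_id = np.array([a.chain for a in s.atoms])
    arr.hetero = np.array([a.residue_name not in _AMINO_ACIDS for a in s.atoms])
    return arr


_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def write_structure(s: Structure, path: str | Path, dialect: str | None = None) -> None:
    write_trajectory(Trajectory([s]), path, dialect)


def write_trajectory(traj: Trajectory, path: str | Path,
                     dialect: str | None = None) -> None:
    """Write frames as a multi-model PDB or concatenated XYZ file."""
    path = Path(path)
    d = _infer_dialect(path, dialect)
    if d == "pdb":
        if len(traj) == 1:
            obj = _atom_array_from_structure(traj.frames[0])
        else:
            arrays = [_atom_array_from_structure(f) for f in traj.frames]
            obj = struc.stack(arrays)
        pdb = PDBFile()
        pdb.set_structure(obj)
        pdb.write(str(path))
    else:
        with open(path, "w") as fh:
            for k, frame in enumerate(traj.frames):
                fh.write(f"{len(frame)}\n")
                fh.write(f"frame {k}\n")
                for a in frame.atoms:
                    x, y, z = a.position
                    fh.write(f"{a.element:<3s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


# --------------------------------------------------------------------------
# Parameter sidecar
# --------------------------------------------------------------------------

PARAM_COLUMNS = ["chain", "resid", "atom", "charge", "sigma", "epsilon", "radius"]


class ParameterTable:
    """Per-atom nonbonded parameters keyed by (chain, residue_id, atom name)."""

    def __init__(self, rows: pd.DataFrame):
        missing = [c for c in PARAM_COLUMNS if c not in rows.columns]
        if missing:
            raise ValueError(f"parameter table missing required columns: {missing}")
        keys = list(zip(rows["chain"], rows["resid"], rows["atom"]))
        dupes = pd.Series(keys).duplicated()
        if dupes.any():
            first = keys[int(np.flatnonzero(dupes.to_numpy())[0])]
            raise ValueError(f"duplicate parameter key {first}")
        self.rows = rows.reset_index(drop=True)
        self._index = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self.rows)

    def get(self, key: tuple[str, int, str]) -> pd.Series | None:
        i = self._index.get((str(key[0]), int(key[1]), str(key[2])))
        return None if i is None else self.rows.iloc[i]

    def attach(self, s: Structure) -> int:
        """Attach parameters to matching atoms in place.

        Returns the number of atoms with no matching row; those atoms keep
        unset parameters (an error only if energetics later touches them).
        """
        unmatched = 0
        for a in s.atoms:
            row = self.get(a.key())
            if row is None:
                unmatched += 1
                continue
            a.charge = float(row["charge"])
            a.lj_sigma = float(row["sigma"])
            a.lj_epsilon = float(row["epsilon"])
            a.radius = float(row["radius"])
        return unmatched

    @classmethod
    def from_structure(cls, s: Structure) -> "ParameterTable":
        rows = pd.DataFrame(
            [
                {"chain": a.chain, "resid": a.residue_id, "atom": a.name,
                 "charge": a.charge, "sigma": a.lj_sigma,
                 "epsilon": a.lj_epsilon, "radius": a.radius}
                for a in s.atoms
            ]
        )
        return cls(rows)


def read_parameters(path: str | Path) -> ParameterTable:
    """Read a tab-separated parameter sidecar (header: chain resid atom
    charge sigma epsilon radius; charges in e, sigma/radius in A, epsilon in
    kcal/mol)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"chain": str, "atom": str})
    if "resid" in df.columns:
        df["resid"] = df["resid"].astype(int)
    return ParameterTable(df)


def write_parameters(table: ParameterTable, path: str | Path,
                     header_comments: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        table.rows.to_csv(fh, sep="\t", index=False)


# --------------------------------------------------------------------------
# Labeled-matrix and report output
# --------------------------------------------------------------------------

def write_matrix(matrix: np.ndarray, labels: Sequence[str], path: str | Path,
                 header_comments: Iterable[str] = ()) -> None:
    """Emit a square matrix as labeled TSV (row/column labels included)."""
    df = pd.DataFrame(np.asarray(matrix), index=list(labels), columns=list(labels))
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label="atom")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_report(df: pd.DataFrame, path: str | Path,
                 header_comments: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
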