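"""Structure/trajectory IO and atom selections.

Multi-model PDB files carry the trajectory snapshots; hetero residues
(FAD, FMN, NAP/NDP, HEM) are first-class citizens because the cofactor
geometry is the object of study.  Parsing and writing are delegated to
biotite; this module adds the data model the analysis works on (shared
topology with per-atom masses), the named-selection machinery for
domains and cofactor rings, and the boost-energy (ΔV) log formats.

Masses are standard atomic masses by element; hydrogen-free structures
are allowed, in which case centers of mass are over heavy atoms (the
convention is recorded in output metadata by the pipeline).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.info as struc_info
import biotite.structure.io.pdb as pdb
from biotite import InvalidFileError

from .exceptions import (
    PDBParseError,
    SelectionError,
    TopologyError,
    ValidationError,
)

__all__ = [
    "ALLOXAZINE_RING_ATOMS",
    "Topology",
    "Structure",
    "Trajectory",
    "SelectionSpec",
    "read_pdb",
    "write_pdb",
    "resolve_selection",
    "center_of_mass",
    "read_deltav_log",
    "write_deltav_log",
    "read_amd_log",
]

#: The 15 fused-ring atoms of the flavin (iso)alloxazine ring, in PDB
#: chemical-component naming, excluding methyls and the ribityl chain.
#: This is the default ring selection for FMN/FAD residues; it is
#: configurable because different deposition dialects exist.
ALLOXAZINE_RING_ATOMS: tuple[str, ...] = (
    "N1", "C2", "O2", "N3", "C4", "O4", "C4A", "N5",
    "C5A", "C6", "C7", "C8", "C9", "C9A", "N10",
)


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Topology:
    """Per-atom annotations shared by all frames of a trajectory.

    Residue ids follow the as-deposited (author) PDB numbering.
    """

    atom_name: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    element: np.ndarray
    mass: np.ndarray

    def __post_init__(self):
        n = len(self.atom_name)
        for f_ in ("res_name", "res_id", "chain_id", "element", "mass"):
            if len(getattr(self, f_)) != n:
                raise ValidationError(f"topology field '{f_}' length mismatch")
        if n and not np.all(self.mass > 0):
            raise ValidationError("every atom must have positive mass")
        keys = list(zip(self.chain_id, self.res_id, self.atom_name))
        if len(set(keys)) != n:
            raise ValidationError(
                "(chain_id, residue_id, atom_name) must be unique within a model"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def subset(self, indices: np.ndarray) -> "Topology":
        idx = np.asarray(indices)
        return Topology(
            atom_name=self.atom_name[idx],
            res_name=self.res_name[idx],
            res_id=self.res_id[idx],
            chain_id=self.chain_id[idx],
            element=self.element[idx],
            mass=self.mass[idx],
        )


@dataclass(frozen=True)
class Structure:
    """A single snapshot: topology plus coordinates in Å."""

    topology: Topology
    coord: np.ndarray  # (n_atoms, 3)

    def __post_init__(self):
        coord = np.asarray(self.coord, dtype=float)
        object.__setattr__(self, "coord", coord)
        if coord.shape != (self.topology.n_atoms, 3):
            raise ValidationError(
                f"coordinate shape {coord.shape} does not match "
                f"{self.topology.n_atoms} atoms"
            )
        if coord.size and not np.all(np.isfinite(coord)):
            raise ValidationError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with ``x -> R x + t`` applied to every atom."""
        return replace(self, coord=self.coord @ np.asarray(rotation).T + translation)


@dataclass(frozen=True)
class Trajectory:
    """Ordered snapshots sharing one topology.

    times are in ns and strictly increasing; ``delta_v`` is the optional
    per-frame boost energy ΔV in kcal/mol (non-negative by definition of
    the boost), aligned to frames.
    """

    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,) ns
    delta_v: Optional[np.ndarray] = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "times", times)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValidationError(f"coords must be (frames, atoms, 3), got {coords.shape}")
        if coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"frames have {coords.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        if len(times) != coords.shape[0]:
            raise ValidationError("times length must equal frame count")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError("times must be strictly increasing")
        if self.delta_v is not None:
            dv = np.asarray(self.delta_v, dtype=float)
            object.__setattr__(self, "delta_v", dv)
            if len(dv) != coords.shape[0]:
                raise ValidationError("delta_v length must equal frame count")
            if np.any(dv < 0) or not np.all(np.isfinite(dv)):
                raise ValidationError("delta_v values must be finite and >= 0")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        return Structure(self.topology, self.coords[i])

    def with_delta_v(self, delta_v: np.ndarray) -> "Trajectory":
        return replace(self, delta_v=np.asarray(delta_v, dtype=float))

    def subset(self, frame_indices: np.ndarray) -> "Trajectory":
        idx = np.asarray(frame_indices)
        return Trajectory(
            self.topology,
            self.coords[idx],
            self.times[idx],
            None if self.delta_v is None else self.delta_v[idx],
        )


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionSpec:
    """Declarative atom selection: residue ranges/names, atom names, chain.

    Criteria combine conjunctively; an unspecified criterion matches all.
    ``residue_ranges`` are inclusive (first_id, last_id) pairs in author
    numbering and must not overlap.
    """

    name: str
    residue_ranges: tuple[tuple[int, int], ...] = ()
    residue_names: Optional[frozenset[str]] = None
    atom_names: Optional[frozenset[str]] = None
    chain_id: Optional[str] = None

    def __post_init__(self):
        ranges = tuple(tuple(map(int, r)) for r in self.residue_ranges)
        object.__setattr__(self, "residue_ranges", ranges)
        if self.residue_names is not None:
            object.__setattr__(self, "residue_names", frozenset(self.residue_names))
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))
        for first, last in ranges:
            if last < first:
                raise SelectionError(f"selection '{self.name}': range {first}..{last} reversed")
        spans = sorted(ranges)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 <= a1:
                raise SelectionError(
                    f"selection '{self.name}': overlapping residue ranges "
                    f"{a0}..{a1} and {b0}..{b1}"
                )

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "SelectionSpec":
        return cls(
            name=name,
            residue_ranges=tuple(tuple(r) for r in d.get("residue_ranges", ())),
            residue_names=(frozenset(d["residue_names"]) if d.get("residue_names") else None),
            atom_names=(frozenset(d["atom_names"]) if d.get("atom_names") else None),
            chain_id=d.get("chain_id"),
        )


def resolve_selection(
    structure: Union[Structure, Trajectory, Topology], spec: SelectionSpec
) -> np.ndarray:
    """Resolve a selection to a deterministic, order-preserving index array.

    Raises :class:`SelectionError` naming the spec when nothing matches.
    """
    top = structure if isinstance(structure, Topology) else structure.topology
    mask = np.ones(top.n_atoms, dtype=bool)
    if spec.chain_id is not None:
        mask &= top.chain_id == spec.chain_id
    if spec.residue_ranges:
        in_range = np.zeros(top.n_atoms, dtype=bool)
        for first, last in spec.residue_ranges:
            in_range |= (top.res_id >= first) & (top.res_id <= last)
        mask &= in_range
    if spec.residue_names is not None:
        mask &= np.isin(top.res_name, sorted(spec.residue_names))
    if spec.atom_names is not None:
        mask &= np.isin(top.atom_name, sorted(spec.atom_names))
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError(f"selection '{spec.name}' matches no atoms")
    return idx


def center_of_mass(
    structure: Structure, selection: Optional[np.ndarray] = None
) -> np.ndarray:
    """Mass-weighted center Σ mᵢxᵢ / Σ mᵢ of the selected atoms, in Å."""
    if selection is None:
        selection = np.arange(structure.n_atoms)
    selection = np.asarray(selection)
    if selection.size == 0:
        raise SelectionError("center_of_mass of an empty selection")
    m = structure.topology.mass[selection]
    total = m.sum()
    if total <= 0:
        raise ValidationError("zero total mass in center_of_mass")
    return (m[:, None] * structure.coord[selection]).sum(axis=0) / total


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _element_masses(elements: np.ndarray, atom_names: np.ndarray) -> np.ndarray:
    masses = np.empty(len(elements), dtype=float)
    for i, (el, an) in enumerate(zip(elements, atom_names)):
        el = (el or "").strip()
        if not el:  # infer from the atom name when the element column is blank
            el = struc.infer_elements([an])[0]
        m = struc_info.mass(el.capitalize() if len(el) > 1 else el)
        if m is None or m <= 0:
            raise ValidationError(f"no atomic mass for element '{el}' (atom '{an}')")
        masses[i] = m
    return masses


def _locate_bad_pdb_line(path: Path) -> Optional[str]:
    """Best-effort scan for the first unparsable ATOM/HETATM record."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38]), float(line[38:46]), float(line[46:54])
                    except (ValueError, IndexError):
                        return f"line {lineno}: {line.rstrip()}"
    except OSError:
        pass
    return None


def _filter_first_icode(array, path):
    ins = array.ins_code
    if not np.any(ins != ""):
        return array
    warnings.warn(f"{path}: insertion codes present; keeping first icode per residue")
    keep = np.ones(array.array_length(), dtype=bool)
    first: dict[tuple, str] = {}
    for i in range(array.array_length()):
        key = (array.chain_id[i], array.res_id[i])
        first.setdefault(key, ins[i])
        keep[i] = ins[i] == first[key]
    return array[..., keep]


def _topology_from_biotite(array, path) -> Topology:
    return Topology(
        atom_name=np.asarray(array.atom_name),
        res_name=np.asarray(array.res_name),
        res_id=np.asarray(array.res_id, dtype=int),
        chain_id=np.asarray(array.chain_id),
        element=np.asarray(array.element),
        mass=_element_masses(array.element, array.atom_name),
    )


def read_pdb(path) -> Union[Structure, Trajectory]:
    """Read a PDB file; multi-MODEL files become a :class:`Trajectory`.

    Hetero residues (FAD, FMN, NAP, HEM, ...) are retained.  Altloc
    policy: keep altloc 'A'/blank; insertion codes: keep the first per
    residue (with a warning).  Trajectory time stamps default to the
    model index in ns (replace via run metadata when known).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    try:
        pdb_file = pdb.PDBFile.read(path)
        n_models = pdb_file.get_model_count()
        array = pdb_file.get_structure(altloc="first")
    except InvalidFileError as exc:
        if "atoms" in str(exc) and "must be equal" in str(exc):
            raise TopologyError(f"{path}: {exc}") from exc
        raise PDBParseError(f"{path}: {exc}") from exc
    except ValueError as exc:
        loc = _locate_bad_pdb_line(path)
        detail = f" ({loc})" if loc else ""
        raise PDBParseError(f"{path}: malformed ATOM/HETATM record{detail}: {exc}") from exc
    array = _filter_first_icode(array, path)
    if n_models == 1:
        single = array if isinstance(array, struc.AtomArray) else array[0]
        return Structure(_topology_from_biotite(single, path), np.asarray(single.coord, dtype=float))
    top = _topology_from_biotite(array[0], path)
    coords = np.asarray(array.coord, dtype=float)
    return Trajectory(top, coords, times=np.arange(n_models, dtype=float))


def _to_biotite(obj: Union[Structure, Trajectory]):
    top = obj.topology
    n = top.n_atoms
    if isinstance(obj, Trajectory):
        arr = struc.AtomArrayStack(obj.n_frames, n)
        arr.coord = np.asarray(obj.coords, dtype=np.float32)
    else:
        arr = struc.AtomArray(n)
        arr.coord = np.asarray(obj.coord, dtype=np.float32)
    arr.atom_name = top.atom_name.astype("U6")
    arr.res_name = top.res_name.astype("U5")
    arr.res_id = top.res_id
    arr.chain_id = top.chain_id.astype("U4")
    arr.element = np.char.upper(top.element.astype("U2"))
    arr.hetero = ~struc.filter_amino_acids(arr)
    return arr


def write_pdb(path, obj: Union[Structure, Trajectory]) -> None:
    """Write a Structure (single model) or Trajectory (multi-MODEL) PDB."""
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(_to_biotite(obj))
    pdb_file.write(Path(path))


# ---------------------------------------------------------------------------
# boost-energy logs
# ---------------------------------------------------------------------------

def read_deltav_log(path) -> pd.Series:
    """Read a per-frame ΔV log (kcal/mol).

    Format: whitespace-separated columns ``frame_index deltav_total
    [deltav_dihedral ...]`` with '#' comments.  When several boost
    columns are present (dual dihedral + total boost) the total boost
    used downstream is their elementwise sum, matching the additive
    composition of the boosted potential.
    """
    path = Path(path)
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise ValidationError(f"{path}: unparsable ΔV log: {exc}") from exc
    if data.size == 0 or data.shape[1] < 2:
        raise ValidationError(f"{path}: ΔV log needs frame_index and >=1 boost column")
    frames = data[:, 0]
    if not np.allclose(frames, np.round(frames)):
        raise ValidationError(f"{path}: non-integer frame indices")
    frames = frames.astype(int)
    if len(np.unique(frames)) != len(frames):
        raise ValidationError(f"{path}: duplicate frame index in ΔV log")
    boosts = data[:, 1:]
    if np.any(boosts < 0):
        raise ValidationError(f"{path}: negative ΔV value")
    series = pd.Series(boosts.sum(axis=1), index=frames, name="delta_v")
    return series.sort_index()


def write_deltav_log(path, delta_v: Sequence[float], frame_indices=None) -> None:
    """Write a ΔV log in the columnar text format read_deltav_log accepts."""
    dv = np.asarray(delta_v, dtype=float)
    if frame_indices is None:
        frame_indices = np.arange(len(dv))
    with open(path, "w") as fh:
        fh.write("# frame_index deltav_total (kcal/mol)\n")
        for i, v in zip(frame_indices, dv):
            fh.write(f"{int(i)} {v:.10g}\n")


def read_amd_log(
    path,
    step_col: int = 1,
    boost_cols: Iterable[int] = (4, 5),
) -> pd.Series:
    """Shim for the 6-column AMBER-style amd.log dialect.

    Default mapping (0-based): column 1 is the MD step, columns 4 and 5
    carry the total-potential and dihedral boost energies; their sum is
    returned per snapshot, indexed 0..n-1 in file order.  Override the
    column mapping to match other dialects.
    """
    data = np.loadtxt(Path(path), comments="#", ndmin=2)
    cols = list(boost_cols)
    needed = max([step_col] + cols)
    if data.shape[1] <= needed:
        raise ValidationError(
            f"{path}: amd.log has {data.shape[1]} columns, mapping needs {needed + 1}"
        )
    boosts = data[:, cols]
    if np.any(boosts < 0):
        raise ValidationError(f"{path}: negative boost energy in amd.log")
    return pd.Series(boosts.sum(axis=1), index=np.arange(len(data)), name="delta_v")
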