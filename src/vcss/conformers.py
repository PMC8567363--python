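"""Structure I/O and geometric kernels.

A :class:`Conformer` is one structural snapshot of a molecule — atom names,
residue numbering and Cartesian coordinates — and a :class:`Trajectory` is an
ordered stack of conformers sharing one atom roster.  All coordinates are kept
in nanometres internally; the PDB reader/writer converts from/to the Angstrom
convention of the file format at the boundary.

The two geometric kernels every downstream stage relies on are
:func:`interatomic_distance` and :func:`omega_dihedral` (the peptide-bond
dihedral CA(i-1)-C(i-1)-N(i)-CA(i) that distinguishes cis from trans
prolines).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .exceptions import GeometryError, PDBParseError, RosterError, SelectionError

__all__ = [
    "Conformer",
    "Trajectory",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "interatomic_distance",
    "omega_dihedral",
    "parse_selection",
]

ANGSTROM_PER_NM = 10.0

#: Default snapshot spacing (ps) assumed when a file carries no time metadata.
DEFAULT_FRAME_INTERVAL_PS = 10.0


def _normalize_hydrogen_name(name: str) -> str:
    """Map digit-first hydrogen variants (``1HH1``) to PDB v3 (``HH11``)."""
    if name and name[0].isdigit() and len(name) > 1 and name[1] == "H":
        return name[1:] + name[0]
    return name


@dataclass
class Conformer:
    """One structural snapshot.

    Parameters
    ----------
    id : int
        0-based frame identifier within its trajectory.
    time : float
        Picoseconds since trajectory start.
    atom_names, res_ids, res_names : ndarray
        Per-atom name, 1-based residue index and 3-letter residue code.
    coords : ndarray, shape (n_atoms, 3)
        Cartesian coordinates in nm.
    """

    id: int
    time: float
    atom_names: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype="U3")
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in conformer %d" % self.id)
        keys = list(zip(self.res_ids.tolist(), self.atom_names.tolist()))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (residue_index, atom_name) pairs")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_index(self, res_id: int, atom_name: str) -> int:
        """Resolve a (residue_index, atom_name) selection to one atom index."""
        name = _normalize_hydrogen_name(atom_name)
        mask = (self.res_ids == res_id) & (self.atom_names == name)
        hits = np.flatnonzero(mask)
        if len(hits) != 1:
            candidates = sorted(
                f"{r}:{a}" for r, a in zip(self.res_ids[self.res_ids == res_id],
                                           self.atom_names[self.res_ids == res_id])
            )
            raise SelectionError(
                f"selection {res_id}:{atom_name} resolved to {len(hits)} atoms; "
                f"atoms of residue {res_id}: {candidates or 'none'}"
            )
        return int(hits[0])

    def position(self, res_id: int, atom_name: str) -> np.ndarray:
        return self.coords[self.atom_index(res_id, atom_name)]

    def roster(self) -> tuple:
        return tuple(zip(self.res_ids.tolist(), self.atom_names.tolist()))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        """Return a copy with coordinates rigidly transformed (about the centroid)."""
        center = self.coords.mean(axis=0)
        new = (self.coords - center) @ np.asarray(rotation).T + center + np.asarray(translation)
        return Conformer(self.id, self.time, self.atom_names.copy(),
                         self.res_ids.copy(), self.res_names.copy(), new)


@dataclass
class Trajectory:
    """Ordered stack of conformers with a shared atom roster."""

    conformers: list[Conformer]
    isomer_hint: str | None = None      # optional {"cis", "trans"} provenance tag
    replica_id: int = 0
    frame_interval: float = DEFAULT_FRAME_INTERVAL_PS

    def __post_init__(self):
        if self.conformers:
            ref = self.conformers[0].roster()
            for c in self.conformers[1:]:
                if c.roster() != ref:
                    raise RosterError(
                        f"conformer {c.id} roster differs from conformer "
                        f"{self.conformers[0].id}"
                    )
            times = [c.time for c in self.conformers]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError("conformer times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i) -> Conformer:
        return self.conformers[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([c.time for c in self.conformers])


def parse_selection(spec: str) -> tuple[int, str]:
    """Parse a ``"RES:ATOM"`` selection string, e.g. ``"2:OH"`` -> ``(2, "OH")``."""
    try:
        res, atom = spec.split(":")
        return int(res), atom.strip()
    except ValueError as exc:
        raise SelectionError(f"cannot parse selection {spec!r}; expected RES:ATOM") from exc


def _scan_for_malformed_atom_lines(path: str) -> None:
    # Best-effort pre-scan so parse errors can name a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"truncated ATOM record at line {lineno} of {path}")
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError:
                    raise PDBParseError(
                        f"unparseable coordinates in ATOM record at line {lineno} of {path}"
                    ) from None


def read_multimodel_pdb(path: str, frame_interval: float = DEFAULT_FRAME_INTERVAL_PS,
                        isomer_hint: str | None = None, replica_id: int = 0) -> Trajectory:
    """Read a (multi-)MODEL PDB file into a :class:`Trajectory`.

    Each MODEL block becomes one :class:`Conformer`; a single-structure file
    yields a one-frame trajectory.  File coordinates (A) are converted to nm.
    Frame times are assigned as ``i * frame_interval`` since PDB carries no
    time metadata.

    Raises
    ------
    PDBParseError
        If an ATOM record is malformed (names the line number).
    RosterError
        If the models do not share one atom roster.
    """
    _scan_for_malformed_atom_lines(path)
    try:
        pdb = PDBFile.read(path)
        stack = pdb.get_structure(model=None)  # AtomArrayStack, all models
    except Exception as exc:
        msg = str(exc)
        if "model" in msg.lower() and "atom" in msg.lower():
            raise RosterError(f"inconsistent atom rosters across models in {path}: {msg}") from exc
        raise PDBParseError(f"failed to parse {path}: {msg}") from exc
    if stack.array_length() == 0:
        raise PDBParseError(f"no ATOM records found in {path}")

    names = np.array([_normalize_hydrogen_name(n) for n in stack.atom_name], dtype="U6")
    conformers = []
    for i in range(stack.stack_depth()):
        conformers.append(Conformer(
            id=i,
            time=i * frame_interval,
            atom_names=names,
            res_ids=stack.res_id,
            res_names=stack.res_name,
            coords=stack.coord[i] / ANGSTROM_PER_NM,
        ))
    return Trajectory(conformers, isomer_hint=isomer_hint, replica_id=replica_id,
                      frame_interval=frame_interval)


def write_multimodel_pdb(trajectory: Trajectory, path: str) -> None:
    """Write a trajectory as a multi-model PDB file (nm converted back to A)."""
    ref = trajectory[0]
    n = ref.n_atoms
    atoms = struc.AtomArray(n)
    atoms.atom_name = ref.atom_names
    atoms.res_id = ref.res_ids
    atoms.res_name = ref.res_names
    atoms.chain_id = np.full(n, "A")
    atoms.element = np.array([nm[:1] for nm in ref.atom_names])
    stack = struc.stack([atoms] * len(trajectory))
    stack.coord = np.array([c.coords for c in trajectory]) * ANGSTROM_PER_NM
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def interatomic_distance(conformer: Conformer, sel_a: tuple[int, str],
                         sel_b: tuple[int, str]) -> float:
    """Euclidean distance (nm) between two uniquely selected atoms."""
    pa = conformer.position(*sel_a)
    pb = conformer.position(*sel_b)
    return float(np.linalg.norm(pa - pb))


def _dihedral(p1, p2, p3, p4) -> float:
    # Signed dihedral via the atan2 formulation; range (-180, 180].
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = -np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def omega_dihedral(conformer: Conformer, residue_index: int) -> float:
    """Peptide-bond omega dihedral (degrees) preceding ``residue_index``.

    Defined over CA(i-1), C(i-1), N(i), CA(i) by the IUPAC convention:
    ~180 deg for a trans peptide bond, ~0 deg for cis.  Range (-180, 180].
    """
    if residue_index < 2:
        raise GeometryError("omega requires residue_index >= 2 (needs the preceding residue)")
    atoms = [(residue_index - 1, "CA"), (residue_index - 1, "C"),
             (residue_index, "N"), (residue_index, "CA")]
    positions = []
    for res, name in atoms:
        try:
            positions.append(conformer.position(res, name))
        except SelectionError as exc:
            raise GeometryError(
                f"missing backbone atom {res}:{name} for omega of residue {residue_index}"
            ) from exc
    return _dihedral(*positions)
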