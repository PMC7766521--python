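"""Structure/trajectory data model, PDB/XYZ readers and writers, and exact
geometric measurements.

Coordinates are Cartesian and always in Å; angles are always in degrees.
Atom indices are 0-based internally and 1-based in PDB serial numbers.
Dihedral angles follow the IUPAC sign convention (cis = 0°, positive =
clockwise when viewed from the second toward the third atom); the sign
matches ``biotite.structure.dihedral`` and MDAnalysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import biotite.structure as bstruc
from biotite.structure.io.pdb import PDBFile


class ParseError(ValueError):
    """A file did not parse under the named format."""


class GeometryError(ValueError):
    """Degenerate geometry (zero-length bond, collinear torsion axis)."""


#: Element symbols accepted on read/write (capitalised form).
ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Mn Fe Co Ni Cu Zn "
    "Se Br Kr I Xe D".split()
)

#: Standard amino-acid residue names, used to tell receptor residues from
#: ligands when a cluster is extracted.
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL".split()
)

WATER_NAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})


def _normalize_element(sym: str) -> str:
    sym = sym.strip().capitalize()
    if sym not in ELEMENTS:
        raise ParseError(f"unknown element symbol {sym!r}")
    return sym


@dataclass(frozen=True)
class Atom:
    """Metadata for one atom; coordinates live on the parent Structure."""

    element: str
    name: str
    res_name: str
    res_number: int
    chain: str = "A"


@dataclass
class Structure:
    """A molecular structure: per-atom metadata plus an (n, 3) coordinate
    array in Å.

    Invariants enforced at construction: the coordinate array matches the
    atom list in length and contains only finite values.  Residue numbers
    need not be contiguous.
    """

    atoms: list[Atom]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.atoms) != self.coords.shape[0]:
            raise ValueError(
                f"atom count {len(self.atoms)} != coordinate count "
                f"{self.coords.shape[0]}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms])

    @property
    def res_numbers(self) -> np.ndarray:
        return np.array([a.res_number for a in self.atoms])

    @property
    def res_names(self) -> np.ndarray:
        return np.array([a.res_name for a in self.atoms])

    def copy(self) -> "Structure":
        return Structure(list(self.atoms), self.coords.copy())

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def heavy_indices(self) -> np.ndarray:
        return np.flatnonzero(self.elements != "H")

    def subset(self, indices: Sequence[int]) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure([self.atoms[i] for i in idx], self.coords[idx])

    def residues(self) -> Iterator[tuple[int, str, np.ndarray]]:
        """Yield (res_number, res_name, atom indices) in first-seen order."""
        seen: dict[tuple[int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            seen.setdefault((a.res_number, a.res_name), []).append(i)
        for (num, name), idx in seen.items():
            yield num, name, np.asarray(idx, dtype=int)

    def index_of(self, atom_name: str, res_number: int | None = None) -> int:
        """Index of the unique atom with this name (optionally within a
        residue).  Raises KeyError if absent or ambiguous."""
        hits = [
            i
            for i, a in enumerate(self.atoms)
            if a.name == atom_name
            and (res_number is None or a.res_number == res_number)
        ]
        if not hits:
            raise KeyError(f"no atom named {atom_name!r}"
                           + (f" in residue {res_number}" if res_number else ""))
        if len(hits) > 1:
            raise KeyError(f"atom name {atom_name!r} is ambiguous")
        return hits[0]

    def select(self, selection: "Selection") -> np.ndarray:
        return selection.resolve(self)


@dataclass(frozen=True)
class Selection:
    """Predicate over atom name / residue name / residue-number range /
    element / chain.  Resolving yields a stable, sorted 0-based index array."""

    atom_name: str | frozenset | None = None
    res_name: str | frozenset | None = None
    res_range: tuple[int, int] | None = None
    element: str | None = None
    chain: str | None = None

    @staticmethod
    def _match(value: str, crit: str | frozenset | Iterable) -> bool:
        if isinstance(crit, str):
            return value == crit
        return value in crit

    def resolve(self, structure: Structure) -> np.ndarray:
        out = []
        for i, a in enumerate(structure.atoms):
            if self.atom_name is not None and not self._match(a.name, self.atom_name):
                continue
            if self.res_name is not None and not self._match(a.res_name, self.res_name):
                continue
            if self.res_range is not None:
                lo, hi = self.res_range
                if not (lo <= a.res_number <= hi):
                    continue
            if self.element is not None and a.element != self.element:
                continue
            if self.chain is not None and a.chain != self.chain:
                continue
            out.append(i)
        return np.asarray(sorted(out), dtype=int)


@dataclass
class Trajectory:
    """Ordered frames sharing one topology.  ``frames`` has shape
    (n_frames, n_atoms, 3) in Å; frame indices are 0-based."""

    topology: Structure
    frames: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame_structure(self, i: int) -> Structure:
        return Structure(list(self.topology.atoms), self.frames[i].copy())


# ---------------------------------------------------------------------------
# biotite conversion


def _to_atom_array(s: Structure) -> bstruc.AtomArray:
    arr = bstruc.AtomArray(s.n_atoms)
    arr.coord = s.coords.astype(np.float32)
    arr.chain_id = np.array([a.chain for a in s.atoms])
    arr.res_id = np.array([a.res_number for a in s.atoms])
    arr.res_name = np.array([a.res_name for a in s.atoms])
    arr.atom_name = np.array([a.name for a in s.atoms])
    arr.element = np.array([a.element.upper() for a in s.atoms])
    arr.hetero = np.array(
        [a.res_name not in AMINO_ACIDS for a in s.atoms]
    )
    arr.set_annotation("occupancy", np.ones(s.n_atoms, dtype=np.float32))
    arr.set_annotation("b_factor", np.zeros(s.n_atoms, dtype=np.float32))
    return arr


def _atoms_from_array(arr: bstruc.AtomArray) -> list[Atom]:
    atoms = []
    for i in range(arr.array_length()):
        el = str(arr.element[i]).strip()
        if not el:
            # fall back on the first alphabetic character of the atom name
            name = str(arr.atom_name[i])
            el = next((c for c in name if c.isalpha()), "")
        atoms.append(
            Atom(
                element=_normalize_element(el),
                name=str(arr.atom_name[i]),
                res_name=str(arr.res_name[i]),
                res_number=int(arr.res_id[i]),
                chain=str(arr.chain_id[i]) or "A",
            )
        )
    return atoms


# ---------------------------------------------------------------------------
# format detection and validation


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in {"pdb", "xyz"}:
            raise ValueError(f"unsupported format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in {"pdb", "ent"}:
        return "pdb"
    if suffix == "xyz":
        return "xyz"
    raise ValueError(f"cannot infer format from {path!r}; pass format=")


def _validate_pdb_lines(lines: list[str]) -> None:
    """Cheap structural validation so parse errors carry a line number."""
    for ln, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec in {"ATOM", "HETATM"}:
            if len(line.rstrip("\n")) < 54:
                raise ParseError(f"line {ln}: truncated {rec} record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise ParseError(
                    f"line {ln}: malformed coordinate fields in {rec} record"
                ) from None


# ---------------------------------------------------------------------------
# XYZ (plain element + 3 floats; concatenated blocks for trajectories)


def _parse_xyz_blocks(lines: list[str]) -> list[tuple[list[str], np.ndarray]]:
    blocks = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected atom count") from None
        if i + 1 + n + 1 > n_lines + 1:
            raise ParseError(f"line {i + 1}: block shorter than declared count")
        elements, coords = [], []
        for j in range(n):
            ln = i + 2 + j
            if ln >= n_lines:
                raise ParseError(f"line {ln + 1}: unexpected end of file")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"line {ln + 1}: expected 'element x y z'")
            elements.append(_normalize_element(parts[0]))
            try:
                coords.append([float(v) for v in parts[1:4]])
            except ValueError:
                raise ParseError(f"line {ln + 1}: malformed coordinate") from None
        blocks.append((elements, np.asarray(coords)))
        i += 2 + n
    if not blocks:
        raise ParseError("empty XYZ file")
    return blocks


def _xyz_block_structure(elements: list[str], coords: np.ndarray) -> Structure:
    atoms = [
        Atom(element=el, name=f"{el}{k + 1}", res_name="MOL", res_number=1)
        for k, el in enumerate(elements)
    ]
    return Structure(atoms, coords)


def _format_xyz_block(s: Structure, comment: str) -> str:
    lines = [str(s.n_atoms), comment]
    for a, xyz in zip(s.atoms, s.coords):
        lines.append(
            f"{a.element:<2s} {xyz[0]:14.6f} {xyz[1]:14.6f} {xyz[2]:14.6f}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# public I/O


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a single structure from a PDB or XYZ file.

    For a multi-model PDB the first model is returned.  XYZ input yields a
    single synthetic residue (MOL 1) with atom names like "C1", "N2".
    """
    fmt = _infer_format(path, format)
    text = Path(path).read_text()
    if fmt == "xyz":
        elements, coords = _parse_xyz_blocks(text.splitlines())[0]
        return _xyz_block_structure(elements, coords)
    _validate_pdb_lines(text.splitlines())
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    return Structure(_atoms_from_array(arr), np.asarray(arr.coord, dtype=float))


def write_structure(s: Structure, path: str | Path, format: str | None = None) -> None:
    """Write a structure.  PDB uses wwPDB v3.3 fixed columns with 3-decimal
    coordinates, occupancy 1.00 and B-factor 0.00; XYZ writes element plus
    three floats.  Zero-atom structures are refused."""
    if s.n_atoms == 0:
        raise ValueError("refusing to write a zero-atom structure")
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        Path(path).write_text(_format_xyz_block(s, "deutbind structure"))
        return
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(s))
    pdb.write(str(path))


def read_trajectory(path: str | Path, format: str | None = None) -> Trajectory:
    """Read a multi-model PDB or concatenated multi-frame XYZ trajectory.

    All frames must share the topology atom count; a mismatch raises a
    ParseError naming the offending 0-based frame index.
    """
    fmt = _infer_format(path, format)
    text = Path(path).read_text()
    lines = text.splitlines()
    if fmt == "xyz":
        blocks = _parse_xyz_blocks(lines)
        topo = _xyz_block_structure(*blocks[0])
        for i, (els, coords) in enumerate(blocks):
            if len(els) != topo.n_atoms:
                raise ParseError(
                    f"frame {i}: atom count {len(els)} != {topo.n_atoms}"
                )
        frames = np.stack([c for _, c in blocks])
        return Trajectory(topo, frames)
    _validate_pdb_lines(lines)
    # verify per-model atom counts before handing to biotite, so the error
    # can name the frame
    counts: list[int] = []
    current: int | None = None
    for line in lines:
        rec = line[:6].strip()
        if rec == "MODEL":
            current = 0
        elif rec in {"ATOM", "HETATM"}:
            if current is None:  # file without MODEL records: one frame
                current = 0
            current += 1
        elif rec == "ENDMDL":
            counts.append(current or 0)
            current = None
    if current:
        counts.append(current)
    if len(counts) > 1:
        for i, c in enumerate(counts):
            if c != counts[0]:
                raise ParseError(f"frame {i}: atom count {c} != {counts[0]}")
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack over all models
    first = stack[0]
    topo = Structure(_atoms_from_array(first), np.asarray(first.coord, dtype=float))
    return Trajectory(topo, np.asarray(stack.coord, dtype=float))


def write_trajectory(traj: Trajectory, path: str | Path, format: str | None = None) -> None:
    """Write a trajectory as multi-model PDB (MODEL/ENDMDL blocks) or
    concatenated XYZ frames."""
    if traj.topology.n_atoms == 0:
        raise ValueError("refusing to write a zero-atom trajectory")
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        blocks = [
            _format_xyz_block(traj.frame_structure(i), f"frame {i}")
            for i in range(traj.n_frames)
        ]
        Path(path).write_text("".join(blocks))
        return
    arr = _to_atom_array(traj.topology)
    stack = bstruc.stack([arr] * traj.n_frames)
    stack.coord = traj.frames.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# geometric measurements

_EPS = 1e-10


def _coords_of(obj) -> np.ndarray:
    if isinstance(obj, Structure):
        return obj.coords
    return np.asarray(obj, dtype=float)


def distance(coords, i: int, j: int) -> float:
    c = _coords_of(coords)
    return float(np.linalg.norm(c[j] - c[i]))


def angle(coords, i: int, j: int, k: int) -> float:
    """Angle at j in degrees, in [0, 180]."""
    c = _coords_of(coords)
    u = c[i] - c[j]
    v = c[k] - c[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise GeometryError("zero-length vector in angle")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(coords, i: int, j: int, k: int, l: int) -> float:
    """Signed torsion i-j-k-l in degrees, IUPAC convention, in (-180, 180].

    Raises GeometryError when either atom triple is collinear (the torsion
    is undefined rather than NaN).
    """
    c = _coords_of(coords)
    b1 = c[j] - c[i]
    b2 = c[k] - c[j]
    b3 = c[l] - c[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < _EPS:
        raise GeometryError("zero-length central bond in dihedral")
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise GeometryError("collinear atoms make the torsion undefined")
    m = np.cross(b2 / nb2, n1)
    phi = math.degrees(math.atan2(np.dot(m, n2), np.dot(n1, n2)))
    if phi <= -180.0:
        phi += 360.0
    return phi


def measure(coords, kind: str, indices: Sequence[int]) -> float:
    """Measure a distance (Å), angle or dihedral (degrees) between atoms.

    ``coords`` may be a Structure or an (n, 3) array.  Indices must be
    distinct and number 2, 3 or 4 for distance, angle, dihedral.
    """
    idx = list(indices)
    if len(set(idx)) != len(idx):
        raise ValueError("atom indices must be distinct")
    expected = {"distance": 2, "angle": 3, "dihedral": 4}
    if kind not in expected:
        raise ValueError(f"unknown measurement kind {kind!r}")
    if len(idx) != expected[kind]:
        raise ValueError(f"{kind} needs {expected[kind]} indices, got {len(idx)}")
    if kind == "distance":
        return distance(coords, *idx)
    if kind == "angle":
        return angle(coords, *idx)
    return dihedral(coords, *idx)


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place a new atom D from internal coordinates: |C-D| = bond,
    angle(B,C,D) = angle_deg and dihedral(A,B,C,D) = dihedral_deg under the
    same sign convention as :func:`dihedral`."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < _EPS:
        raise GeometryError("coincident reference atoms")
    bc = bc / nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        raise GeometryError("collinear reference atoms")
    n = n / nn
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(dih), math.sin(ang) * math.sin(dih)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def covalent_hydrogen_pairs(
    s: Structure, max_bond: float = 1.4
) -> list[tuple[int, int]]:
    """(heavy index, H index) pairs for every hydrogen within ``max_bond`` Å
    of its nearest heavy atom.  The 1.4 Å default covers N-H (≈1.0 Å),
    O-H (≈0.96 Å) and the longer S-H (≈1.34 Å) bonds."""
    heavy = s.heavy_indices()
    h_idx = np.flatnonzero(s.elements == "H")
    pairs = []
    if len(heavy) == 0 or len(h_idx) == 0:
        return pairs
    d = np.linalg.norm(
        s.coords[h_idx][:, None, :] - s.coords[heavy][None, :, :], axis=2
    )
    for row, h in enumerate(h_idx):
        j = int(np.argmin(d[row]))
        if d[row, j] <= max_bond:
            pairs.append((int(heavy[j]), int(h)))
    return pairs
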