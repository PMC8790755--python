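"""Structure input/output: PDB proteins, SDF ligands, Gaussian cube volumes.

Atom records carry the eight pharmacophore-style property flags used by the
voxelizer (hydrophobic, aromatic, H-bond donor, H-bond acceptor, positive
ionizable, negative ionizable, metal, heavy/occupancy).  Only heavy atoms and
polar hydrogens are retained from input structures; hydrogens contribute
solely to donor flagging of their heavy parent and never to occupancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

PROPERTY_NAMES = (
    "hydrophobic",
    "aromatic",
    "donor",
    "acceptor",
    "positive_ionizable",
    "negative_ionizable",
    "metal",
    "heavy",
)

#: Bondi-style van der Waals radii, Å.
VDW_RADII = {
    "H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
METALS = {"Zn", "Mg", "Mn", "Ca", "Fe", "Ni", "Cu", "Co", "Na", "K"}
DEFAULT_VDW = 1.5
METAL_VDW = 2.0

MAX_LIGANDS_PER_JOB = 100

ANGSTROM_TO_BOHR = 1.8897259886

ATOMIC_NUMBERS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "Na": 11, "Mg": 12, "P": 15,
    "S": 16, "Cl": 17, "K": 19, "Ca": 20, "Mn": 25, "Fe": 26, "Co": 27,
    "Ni": 28, "Cu": 29, "Zn": 30, "Br": 35, "I": 53,
}


class StructureError(ValueError):
    """Unreadable or empty input structure."""


class LigandLimitError(StructureError):
    """More ligand records than a single job accepts."""


def vdw_radius(element: str) -> float:
    if element in METALS:
        return METAL_VDW
    return VDW_RADII.get(element, DEFAULT_VDW)


@dataclass
class AtomRecord:
    """One atom with position, vdW radius and pharmacophore property flags."""

    element: str
    position: np.ndarray  # (3,) Å
    source: str  # "protein" | "ligand"
    vdw_radius: float
    hydrophobic: bool = False
    aromatic: bool = False
    donor: bool = False
    acceptor: bool = False
    positive_ionizable: bool = False
    negative_ionizable: bool = False
    metal: bool = False
    heavy: bool = True
    name: str = ""
    resname: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")
        if not self.vdw_radius > 0:
            raise ValueError("vdw_radius must be positive")
        if self.metal and (self.donor or self.acceptor or self.aromatic):
            raise ValueError("metal atoms cannot be donor/acceptor/aromatic")
        if self.source not in ("protein", "ligand"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def flags(self) -> tuple[bool, ...]:
        return tuple(getattr(self, p) for p in PROPERTY_NAMES)

    def moved(self, position: np.ndarray) -> "AtomRecord":
        return replace(self, position=np.asarray(position, dtype=float))


@dataclass
class ComplexStructure:
    """A protein pocket plus one ligand pose."""

    protein_atoms: list[AtomRecord]
    ligand_atoms: list[AtomRecord]
    id: str = ""

    def __post_init__(self) -> None:
        if not self.ligand_atoms:
            raise ValueError("ligand_atoms must be non-empty")
        if any(a.source != "protein" for a in self.protein_atoms):
            raise ValueError("protein_atoms contains non-protein records")
        if any(a.source != "ligand" for a in self.ligand_atoms):
            raise ValueError("ligand_atoms contains non-ligand records")

    def with_ligand_coords(self, coords: np.ndarray, id: str | None = None) -> "ComplexStructure":
        """Same complex with the ligand atoms moved to ``coords`` (n, 3)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.ligand_atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        ligand = [a.moved(c) for a, c in zip(self.ligand_atoms, coords)]
        return ComplexStructure(self.protein_atoms, ligand, id if id is not None else self.id)


def atom_coords(atoms: Sequence[AtomRecord], heavy_only: bool = False) -> np.ndarray:
    sel = [a for a in atoms if a.heavy] if heavy_only else list(atoms)
    if not sel:
        return np.zeros((0, 3))
    return np.array([a.position for a in sel], dtype=float)


def flag_matrix(atoms: Sequence[AtomRecord]) -> np.ndarray:
    """(n_atoms, 8) boolean matrix in the canonical property order."""
    return np.array([a.flags for a in atoms], dtype=bool).reshape(len(atoms), 8)


# ---------------------------------------------------------------------------
# PDB protein reading

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


def read_protein(path: str | Path) -> list[AtomRecord]:
    """Read a protonated protein from a PDB file.

    Keeps standard amino-acid residues (first model, first altloc) and any
    coordinated metal ions; drops waters and other heteroatoms.  Nonpolar
    hydrogens are discarded; polar hydrogens (bound to N/O/S) are retained as
    flagless records and mark their heavy parent as an H-bond donor.
    """
    import gemmi

    path = Path(path)
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(structure) == 0:
        raise StructureError(f"no models in {path}")
    structure.setup_entities()

    raw: list[tuple[str, str, str, np.ndarray]] = []  # element, name, resname, pos
    model = structure[0]
    for chain in model:
        for residue in chain:
            info = gemmi.find_tabulated_residue(residue.name)
            is_aa = info is not None and info.is_amino_acid()
            is_metal_res = residue.name.strip().capitalize() in METALS
            if residue.name in _WATER_NAMES or not (is_aa or is_metal_res):
                continue
            for atom in residue:
                if atom.altloc not in ("\0", "", "A"):
                    continue
                element = atom.element.name
                if not element or element == "X":
                    element = _element_from_name(atom.name)
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                raw.append((element.capitalize(), atom.name, residue.name, pos))

    if not raw:
        raise StructureError(f"no protein atoms retained from {path}")

    heavies = [(e, n, rn, p) for e, n, rn, p in raw if e != "H"]
    hydrogens = [(e, n, rn, p) for e, n, rn, p in raw if e == "H"]
    if not heavies:
        raise StructureError(f"no heavy protein atoms retained from {path}")

    heavy_pos = np.array([p for _, _, _, p in heavies])
    records = [
        AtomRecord(element=e, position=p, source="protein",
                   vdw_radius=vdw_radius(e), heavy=True, name=n, resname=rn,
                   metal=(e in METALS))
        for e, n, rn, p in heavies
    ]
    # polar hydrogens: keep, flag the nearest N/O/S within bonding distance
    for e, n, rn, p in hydrogens:
        d = np.linalg.norm(heavy_pos - p, axis=1)
        j = int(np.argmin(d))
        if d[j] < 1.3 and records[j].element in ("N", "O", "S"):
            records[j].donor = True
            records.append(AtomRecord(
                element="H", position=p, source="protein", vdw_radius=vdw_radius("H"),
                heavy=False, name=n, resname=rn))

    from .voxelizer import assign_pharmacophore_flags

    assign_pharmacophore_flags(records)
    return records


def _element_from_name(name: str) -> str:
    name = name.strip()
    for two in ("Cl", "Br", "Zn", "Mg", "Mn", "Ca", "Fe", "Ni", "Cu", "Co", "Na"):
        if name[:2].capitalize() == two:
            return two
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


# ---------------------------------------------------------------------------
# SDF ligand reading

def read_ligands(path: str | Path) -> list[list[AtomRecord]]:
    """Read ligand poses from a (possibly multi-record) SDF file.

    Returns one atom list per record, file order preserved.  At most
    ``MAX_LIGANDS_PER_JOB`` records are accepted.  Records that fail to parse
    are skipped with a warning; an error is raised only if every record fails.
    """
    from rdkit import Chem

    from .voxelizer import assign_pharmacophore_flags, ligand_flags_from_mol

    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    n_records = len(supplier)
    if n_records == 0:
        raise StructureError(f"no molecule records in {path}")
    if n_records > MAX_LIGANDS_PER_JOB:
        raise LigandLimitError(
            f"{n_records} records in {path}; only {MAX_LIGANDS_PER_JOB} ligands are allowed per job")

    out: list[list[AtomRecord]] = []
    n_failed = 0
    for i in range(n_records):
        mol = supplier[i]
        if mol is None:
            # retry unsanitized so that odd valences still yield coordinates
            mol = _read_record_unsanitized(path, i)
        if mol is None:
            n_failed += 1
            log.warning("skipping unreadable SDF record %d in %s", i, path)
            continue
        atoms = _mol_to_atoms(mol)
        if mol.GetNumBonds() > 0 or _is_sanitized(mol):
            ligand_flags_from_mol(mol, atoms)
        else:
            assign_pharmacophore_flags(atoms)
        out.append(atoms)
    if not out:
        raise StructureError(f"all {n_records} records in {path} failed to parse")
    if n_failed:
        log.warning("%d of %d SDF records skipped in %s", n_failed, n_records, path)
    return out


def _read_record_unsanitized(path: Path, index: int):
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    try:
        mol = supplier[index]
    except Exception:  # pragma: no cover - rdkit raises many exception types
        return None
    return mol


def _is_sanitized(mol) -> bool:
    from rdkit import Chem

    return not Chem.DetectChemistryProblems(mol)


def _mol_to_atoms(mol) -> list[AtomRecord]:
    conf = mol.GetConformer()
    atoms: list[AtomRecord] = []
    for atom in mol.GetAtoms():
        element = atom.GetSymbol()
        pos = conf.GetAtomPosition(atom.GetIdx())
        heavy = element != "H"
        if not heavy:
            # hydrogens handled through rdkit H counts; keep polar ones only
            nb = [n.GetSymbol() for n in atom.GetNeighbors()]
            if not any(s in ("N", "O", "S") for s in nb):
                continue
        atoms.append(AtomRecord(
            element=element, position=np.array([pos.x, pos.y, pos.z]),
            source="ligand", vdw_radius=vdw_radius(element), heavy=heavy,
            metal=(element in METALS) and heavy))
    if not atoms:
        raise StructureError("SDF record contains no atoms")
    return atoms


# ---------------------------------------------------------------------------
# Synthetic-structure writers (PDB / SDF fixtures for the demo CLI)

def write_protein_pdb(atoms: Sequence[AtomRecord], path: str | Path) -> None:
    """Write protein atoms as a minimal PDB file (pseudo-residues: one atom each)."""
    lines = []
    for i, a in enumerate(atoms, start=1):
        resname = (a.resname or "UNK")[:3]
        name = (a.name or a.element)[:4]
        x, y, z = a.position
        lines.append(
            f"ATOM  {i:5d} {name:<4s}{resname:>4s} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element:>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ligands_sdf(poses: Iterable[Sequence[AtomRecord]],
                      bonds_per_pose: Iterable[Sequence[tuple[int, int]]],
                      path: str | Path) -> None:
    """Write ligand poses as a multi-record V2000 SDF (single bonds only)."""
    blocks = []
    for pose, bonds in zip(poses, bonds_per_pose):
        n, m = len(pose), len(bonds)
        lines = ["synthetic ligand", "  voxattrib", "",
                 f"{n:3d}{m:3d}  0  0  0  0  0  0  0  0999 V2000"]
        for a in pose:
            x, y, z = a.position
            lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
        for i, j in bonds:
            lines.append(f"{i + 1:3d}{j + 1:3d}  1  0")
        lines.append("M  END")
        lines.append("$$$$")
        blocks.append("\n".join(lines))
    Path(path).write_text("\n".join(blocks) + "\n")


# ---------------------------------------------------------------------------
# Gaussian cube export

def write_cube(attr, channel: int, path: str | Path,
               complex_structure: ComplexStructure | None = None,
               comment: str = "") -> None:
    """Write one channel of an attribution (or feature) grid as a Gaussian cube.

    Lengths are written in Bohr, voxel values in the standard z-fastest
    nesting.  The atom block holds the ligand plus any protein atoms inside
    the grid box; with no complex given, a single dummy atom at the origin is
    emitted (the format requires >= 1 atom).
    """
    values = np.asarray(attr.values)
    if not (0 <= channel < values.shape[0]):
        raise IndexError(f"channel {channel} out of range 0..{values.shape[0] - 1}")
    n = values.shape[1:]
    origin = np.asarray(attr.origin, dtype=float)
    spacing = float(attr.spacing)

    atoms: list[tuple[int, np.ndarray]] = []
    if complex_structure is not None:
        lo = origin - 0.5 * spacing
        hi = origin + spacing * (np.array(n) - 0.5)
        for a in complex_structure.ligand_atoms:
            atoms.append((ATOMIC_NUMBERS.get(a.element, 6), a.position))
        for a in complex_structure.protein_atoms:
            if np.all(a.position >= lo) and np.all(a.position <= hi):
                atoms.append((ATOMIC_NUMBERS.get(a.element, 6), a.position))
    if not atoms:
        atoms = [(1, origin)]

    b = ANGSTROM_TO_BOHR
    lines = [comment or "voxattrib volumetric data",
             f"channel {channel}"]
    ox, oy, oz = origin * b
    lines.append(f"{len(atoms):5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}")
    lines.append(f"{n[0]:5d}{spacing * b:12.6f}{0.0:12.6f}{0.0:12.6f}")
    lines.append(f"{n[1]:5d}{0.0:12.6f}{spacing * b:12.6f}{0.0:12.6f}")
    lines.append(f"{n[2]:5d}{0.0:12.6f}{0.0:12.6f}{spacing * b:12.6f}")
    for z_num, pos in atoms:
        px, py, pz = np.asarray(pos, dtype=float) * b
        lines.append(f"{z_num:5d}{float(z_num):12.6f}{px:12.6f}{py:12.6f}{pz:12.6f}")

    vol = values[channel]
    for i in range(n[0]):
        for j in range(n[1]):
            row = vol[i, j]
            for k0 in range(0, n[2], 6):
                lines.append("".join(f"{v: .6E} " for v in row[k0:k0 + 6]).rstrip())
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write cube file {path}: {exc}") from exc


def read_cube(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Parse a cube file written by :func:`write_cube`.

    Returns ``(values, origin_angstrom, spacing_angstrom)`` with values shaped
    (nx, ny, nz).  Only axis-aligned cubes with isotropic spacing are handled.
    """
    lines = Path(path).read_text().splitlines()
    natoms_line = lines[2].split()
    natoms = int(natoms_line[0])
    origin = np.array([float(v) for v in natoms_line[1:4]]) / ANGSTROM_TO_BOHR
    shape = []
    spacings = []
    for ax, line in enumerate(lines[3:6]):
        parts = line.split()
        shape.append(int(parts[0]))
        vec = [float(v) for v in parts[1:4]]
        spacings.append(vec[ax])
    spacing = spacings[0] / ANGSTROM_TO_BOHR
    data_lines = lines[6 + natoms:]
    flat = np.array([float(v) for line in data_lines for v in line.split()])
    return flat.reshape(shape), origin, spacing
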