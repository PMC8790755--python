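"""Voxelization of protein-ligand complexes onto 16-channel property grids.

Eight pharmacophore-style properties (hydrophobic, aromatic, H-bond donor,
H-bond acceptor, positive ionizable, negative ionizable, metal, occupancy)
are rasterized separately for protein and ligand atoms, giving 16 channels.
Each flagged atom deposits the distance-decaying van der Waals kernel

    n(r) = 1 - exp(-(r_vdw / r)^12)

onto every voxel within a cutoff, aggregated per voxel by maximum, so all
grid values stay in [0, 1].  The cubic box is centered at the ligand's
geometric center and follows it under translation.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .structio import (
    METALS,
    PROPERTY_NAMES,
    AtomRecord,
    ComplexStructure,
    atom_coords,
)

log = logging.getLogger(__name__)

DEFAULT_GRID_SIZE = 24
DEFAULT_SPACING = 1.0  # Å per voxel
DEFAULT_CUTOFF = 5.0  # Å, kernel support radius

ENTITIES = ("protein", "ligand")


class ChannelScheme:
    """Fixed ordering of the 16 (entity, property) grid channels.

    Protein block first (8 properties in canonical order), then the ligand
    block.  The fingerprint ties trained models to the scheme they saw.
    """

    def __init__(self) -> None:
        self.descriptors: tuple[tuple[str, str], ...] = tuple(
            (entity, prop) for entity in ENTITIES for prop in PROPERTY_NAMES)

    def __len__(self) -> int:
        return len(self.descriptors)

    def index(self, entity: str, prop: str) -> int:
        return self.descriptors.index((entity, prop))

    @property
    def fingerprint(self) -> str:
        text = ";".join(f"{e}:{p}" for e, p in self.descriptors)
        return hashlib.sha1(text.encode()).hexdigest()[:16]


def default_scheme() -> ChannelScheme:
    return ChannelScheme()


@dataclass
class VoxelGrid:
    """16 x N x N x N feature grid with world-coordinate mapping.

    ``origin`` is the world position of the *center* of voxel (0, 0, 0);
    voxel (i, j, k) is centered at ``origin + spacing * (i, j, k)``.
    """

    values: np.ndarray
    origin: np.ndarray
    spacing: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def voxel_center(self, index: Sequence[int]) -> np.ndarray:
        index = np.asarray(index)
        if np.any(index < 0) or np.any(index >= self.values.shape[1:]):
            raise IndexError(f"voxel index {tuple(index)} outside grid")
        return self.origin + self.spacing * index

    def nearest_voxel(self, point: Sequence[float]) -> tuple[int, int, int]:
        point = np.asarray(point, dtype=float)
        idx = np.rint((point - self.origin) / self.spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.values.shape[1:]):
            raise ValueError(f"point {tuple(point)} outside the grid box")
        return tuple(int(v) for v in idx)


# ---------------------------------------------------------------------------
# Pharmacophore typing

_AROMATIC_RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}
_POSITIVE_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
}
_NEGATIVE_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
_DONOR_ATOMS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "TRP": {"NE1"},
    "HIS": {"ND1", "NE2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
}
_ACCEPTOR_ATOMS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": set(),
}
_KNOWN_ELEMENTS = set("H C N O S P F I".split()) | {"Cl", "Br"} | METALS

_BOND_CUTOFF = 1.85  # Å, heavy-heavy covalent bond heuristic
_H_BOND_CUTOFF = 1.3  # Å, X-H covalent bond heuristic


def assign_pharmacophore_flags(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Set property flags in place from elements, geometry and residue names.

    Connectivity is inferred from interatomic distances; aromaticity, charge
    and donor/acceptor roles additionally use standard residue templates when
    residue names are available.  Pre-set flags are kept (unioned), so the
    synthetic generator and explicit-hydrogen donor detection compose with
    these rules.  Unknown elements keep only the heavy flag.
    """
    heavy = [a for a in atoms if a.element != "H"]
    pos = atom_coords(heavy)
    n = len(heavy)
    if n:
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        bonded = (d < _BOND_CUTOFF) & ~np.eye(n, dtype=bool)
    h_pos = atom_coords([a for a in atoms if a.element == "H"])
    has_explicit_h = len(h_pos) > 0

    for i, a in enumerate(heavy):
        a.heavy = True
        if a.element not in _KNOWN_ELEMENTS:
            log.warning("unknown element %r: occupancy flag only", a.element)
            continue
        if a.element in METALS:
            a.metal = True
            a.donor = a.acceptor = a.aromatic = False
            a.hydrophobic = a.positive_ionizable = a.negative_ionizable = False
            continue
        resname, name = a.resname, a.name
        a.aromatic = a.aromatic or name in _AROMATIC_RING_ATOMS.get(resname, ())
        a.positive_ionizable = (a.positive_ionizable
                                or name in _POSITIVE_ATOMS.get(resname, ()))
        a.negative_ionizable = (a.negative_ionizable
                                or name in _NEGATIVE_ATOMS.get(resname, ())
                                or name == "OXT")
        if a.element in ("N", "O", "S"):
            if has_explicit_h and len(h_pos):
                if np.any(np.linalg.norm(h_pos - a.position, axis=1) < _H_BOND_CUTOFF):
                    a.donor = True
            elif resname:
                a.donor = (a.donor or name in _DONOR_ATOMS.get(resname, ())
                           or (name == "N" and resname != "PRO"))
        if a.element in ("N", "O") and not a.positive_ionizable:
            if resname:
                a.acceptor = (a.acceptor or name in _ACCEPTOR_ATOMS.get(resname, ())
                              or name in ("O", "OXT"))
            else:
                a.acceptor = True
        if a.element in ("C", "S"):
            nb_no = bonded[i] & np.array([b.element in ("N", "O") for b in heavy])
            ionizable = a.positive_ionizable or a.negative_ionizable
            a.hydrophobic = a.hydrophobic or (not np.any(nb_no) and not ionizable)
    return atoms


def ligand_flags_from_mol(mol, atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Flag ligand atom records using RDKit connectivity and substructures.

    ``atoms`` must be in the order produced by the SDF reader (heavy atoms and
    polar hydrogens, nonpolar hydrogens skipped).
    """
    from rdkit import Chem

    pos_idx: set[int] = set()
    neg_idx: set[int] = set()
    no_lp_n: set[int] = set()
    for smarts, collect in (
            ("[+;!$([N+][O-])]", pos_idx),
            ("[NX3;H2,H1;!$(NC=[O,S,N]);!$(N[a]);!$(N*=*)]", pos_idx),
            ("[NX3][CX3](=[NX2,NX3+])[NX3]", pos_idx),
    ):
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            collect.update(i for i in match
                           if mol.GetAtomWithIdx(i).GetSymbol() == "N"
                           or smarts.startswith("[+"))
    for smarts in ("[CX3](=[OX1])[OX2H1,OX1-]",
                   "[PX4](=[OX1])([OX2H1,OX1-])",
                   "[SX4](=[OX1])(=[OX1])"):
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            neg_idx.update(i for i in match
                           if mol.GetAtomWithIdx(i).GetSymbol() == "O")
    for smarts in ("[NX3][CX3](=[OX1])", "[n;H1]"):  # amide / pyrrole N: no free lone pair
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            no_lp_n.update(i for i in match
                           if mol.GetAtomWithIdx(i).GetSymbol() == "N")

    it = iter(atoms)
    for atom in mol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol == "H" and not any(
                n.GetSymbol() in ("N", "O", "S") for n in atom.GetNeighbors()):
            continue
        rec = next(it)
        if symbol == "H":
            rec.heavy = False
            continue
        i = atom.GetIdx()
        rec.heavy = True
        if symbol in METALS:
            rec.metal = True
            continue
        rec.aromatic = atom.GetIsAromatic()
        rec.positive_ionizable = i in pos_idx or atom.GetFormalCharge() > 0
        rec.negative_ionizable = i in neg_idx or (
            symbol == "O" and atom.GetFormalCharge() < 0)
        if symbol in ("N", "O", "S"):
            rec.donor = atom.GetTotalNumHs(includeNeighbors=True) > 0
        if symbol in ("N", "O"):
            rec.acceptor = (atom.GetFormalCharge() <= 0
                            and not rec.positive_ionizable
                            and i not in no_lp_n)
        if symbol in ("C", "S"):
            nb = {n.GetSymbol() for n in atom.GetNeighbors()}
            rec.hydrophobic = (not ({"N", "O"} & nb)
                               and not rec.positive_ionizable
                               and not rec.negative_ionizable)
    return atoms


# ---------------------------------------------------------------------------
# Voxelization

def occupancy_kernel(r: np.ndarray, r_vdw: float) -> np.ndarray:
    """n(r) = 1 - exp(-(r_vdw/r)^12); the r -> 0 limit is 1."""
    r = np.asarray(r, dtype=float)
    out = np.ones_like(r)
    nz = r > 1e-12
    out[nz] = 1.0 - np.exp(-((r_vdw / r[nz]) ** 12))
    return out


def voxelize(complex_structure: ComplexStructure,
             scheme: ChannelScheme | None = None,
             size: int = DEFAULT_GRID_SIZE,
             spacing: float = DEFAULT_SPACING,
             cutoff: float = DEFAULT_CUTOFF,
             dtype=np.float32) -> VoxelGrid:
    """Rasterize a complex onto the 16-channel grid the scorers consume."""
    scheme = scheme or default_scheme()
    if len(scheme) != 16:
        raise ValueError("channel scheme must define 16 channels")

    lig_heavy = atom_coords(complex_structure.ligand_atoms, heavy_only=True)
    if lig_heavy.size == 0:
        raise ValueError("ligand has no heavy atoms")
    center = lig_heavy.mean(axis=0)
    origin = center - spacing * (size - 1) / 2.0

    values = np.zeros((16, size, size, size), dtype=dtype)
    half_box = spacing * (size - 1) / 2.0
    if np.any(np.abs(lig_heavy - center) > half_box + 0.5 * spacing):
        log.warning("ligand atoms of %s extend beyond the grid box (clipped)",
                    complex_structure.id)

    axis = np.arange(size)
    for entity, atoms in (("protein", complex_structure.protein_atoms),
                          ("ligand", complex_structure.ligand_atoms)):
        for atom in atoms:
            if not atom.heavy:
                continue
            channels = [scheme.index(entity, prop)
                        for prop, on in zip(PROPERTY_NAMES, atom.flags) if on]
            if not channels:
                continue
            rel = (atom.position - origin) / spacing
            lo = np.maximum(np.ceil(rel - cutoff / spacing), 0).astype(int)
            hi = np.minimum(np.floor(rel + cutoff / spacing), size - 1).astype(int)
            if np.any(lo > hi):
                continue
            dx = (axis[lo[0]:hi[0] + 1] - rel[0]) * spacing
            dy = (axis[lo[1]:hi[1] + 1] - rel[1]) * spacing
            dz = (axis[lo[2]:hi[2] + 1] - rel[2]) * spacing
            r = np.sqrt(dx[:, None, None] ** 2 + dy[None, :, None] ** 2
                        + dz[None, None, :] ** 2)
            contrib = occupancy_kernel(r, atom.vdw_radius)
            contrib[r > cutoff] = 0.0
            window = (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1),
                      slice(lo[2], hi[2] + 1))
            for ch in channels:
                np.maximum(values[ch][window], contrib.astype(dtype),
                           out=values[ch][window])

    return VoxelGrid(values=values, origin=origin, spacing=spacing,
                     source_id=complex_structure.id)


def voxelize_many(complexes: Sequence[ComplexStructure], **kwargs) -> list[VoxelGrid]:
    return [voxelize(c, **kwargs) for c in complexes]
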