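"""Synthetic protein-ligand complexes, clashed poses and RMSD-controlled decoys.

The generator builds a spherical pseudo-pocket (a shell of pseudo-residue
atoms around a cavity) holding a connected random-walk ligand.  A configurable
fraction of flagged ligand atoms receives a pharmacophore-complementary
protein partner at hydrogen-bond/contact range (2.6-3.4 Å), so trained
scorers have chemically meaningful signal to find.  Crystal-like poses keep
every protein-ligand heavy-atom distance >= 2.4 Å, while clashed poses drive
the ligand into the pocket wall until the minimum contact drops below 1.5 Å;
the two classes are disjoint by construction.

All randomness flows from explicit integer seeds through numpy Generators;
no global state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import AtomRecord, ComplexStructure, atom_coords, vdw_radius

CLASH_THRESHOLD = 1.5  # Å, min heavy-atom contact below which a pose clashes
MIN_SEPARATION = 2.4  # Å, min contact of crystal-like poses
GOOD_RMSD = 2.0  # Å, docking-success convention
BAD_RMSD = 4.0  # Å; (2, 4) is excluded as ambiguous
CONTACT_RANGE = (2.6, 3.4)  # Å, complementary-pair placement distance

#: property -> complementary partner property
COMPLEMENT = {
    "donor": "acceptor",
    "acceptor": "donor",
    "aromatic": "aromatic",
    "hydrophobic": "hydrophobic",
}


class GenerationError(RuntimeError):
    """Requested synthetic structure cannot be built."""


@dataclass
class PoseLabel:
    """Class label of a generated pose with its defining geometry."""

    kind: str | None  # crystal_like | good_pose | bad_pose | clashed | None
    rmsd_to_reference: float
    min_contact: float

    def __post_init__(self) -> None:
        if self.kind == "clashed" and not self.min_contact < CLASH_THRESHOLD:
            raise ValueError("clashed pose must have min_contact below threshold")
        if self.kind == "good_pose" and not self.rmsd_to_reference <= GOOD_RMSD:
            raise ValueError("good pose must have RMSD within the good cutoff")
        if self.kind == "bad_pose" and not self.rmsd_to_reference >= BAD_RMSD:
            raise ValueError("bad pose must have RMSD beyond the bad cutoff")


@dataclass
class GeneratorParams:
    """Geometry and composition of the synthetic pockets.

    Defaults give a ~8 Å-radius cavity holding a 12-heavy-atom ligand (offset
    up to 1.2 Å from the pocket center) whose flagged atoms are 60% paired to
    complementary pocket atoms — a desk-scale stand-in for a druggable
    binding site.
    """

    pocket_radius: float = 8.0
    pocket_radius_jitter: float = 0.75
    shell_jitter: float = 0.6
    n_shell_atoms: int = 80
    ligand_size: int = 12
    bond_length: float = 1.5
    ligand_extent: float = 3.0
    ligand_offset: float = 1.2
    pairing_fraction: float = 0.6
    aromatic_patch_size: int = 3
    max_clash_shift: float = 4.0


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return _unit(v)


def _ligand_atom(element: str, position: np.ndarray, **flags) -> AtomRecord:
    return AtomRecord(element=element, position=position, source="ligand",
                      vdw_radius=vdw_radius(element), **flags)


def _protein_atom(element: str, position: np.ndarray, **flags) -> AtomRecord:
    return AtomRecord(element=element, position=position, source="protein",
                      vdw_radius=vdw_radius(element), **flags)


def generate_complex(seed: int, params: GeneratorParams | None = None,
                     id_prefix: str = "synth") -> ComplexStructure:
    """Build one crystal-like synthetic complex, deterministic given ``seed``."""
    params = params or GeneratorParams()
    if params.ligand_size < 4:
        raise GenerationError("ligand must have at least 4 atoms")
    min_radius = params.pocket_radius - params.pocket_radius_jitter
    if params.ligand_extent + MIN_SEPARATION >= min_radius - params.shell_jitter:
        raise GenerationError("ligand does not fit inside the cavity")
    rng = np.random.default_rng(seed)
    radius = params.pocket_radius + rng.uniform(-params.pocket_radius_jitter,
                                                params.pocket_radius_jitter)
    # the ligand sits off-center inside the cavity, as real ligands do
    offset = params.ligand_offset * rng.random() ** (1 / 3) * _random_direction(rng)

    ligand = _grow_ligand(rng, params, offset)
    lig_pos = atom_coords(ligand)

    protein: list[AtomRecord] = []
    # complementary partners for a fraction of the flagged ligand atoms
    flagged = [i for i, a in enumerate(ligand)
               if a.donor or a.acceptor or a.aromatic or a.hydrophobic]
    n_pair = int(round(params.pairing_fraction * len(flagged)))
    paired = list(rng.choice(flagged, size=n_pair, replace=False)) if n_pair else []
    for i in paired:
        partner = _place_partner(rng, ligand[i], lig_pos, protein, params)
        protein.append(partner)

    # pocket wall: pseudo-residue shell atoms around the cavity
    for _ in range(params.n_shell_atoms):
        for _attempt in range(60):
            direction = _random_direction(rng)
            r = radius + rng.uniform(-params.shell_jitter, params.shell_jitter)
            pos = direction * r
            if _min_dist(pos, lig_pos) < MIN_SEPARATION:
                continue
            if protein and _min_dist(pos, atom_coords(protein)) < 1.8:
                continue
            protein.append(_shell_atom(rng, pos))
            break

    complex_structure = ComplexStructure(protein, ligand, f"{id_prefix}-{seed}")
    if min_contact(complex_structure) < MIN_SEPARATION:
        raise GenerationError("generated pocket violates the contact floor")
    return complex_structure


def _grow_ligand(rng: np.random.Generator, params: GeneratorParams,
                 anchor: np.ndarray | None = None) -> list[AtomRecord]:
    """Connected random-walk heavy-atom cluster anchored inside the cavity."""
    anchor = np.zeros(3) if anchor is None else np.asarray(anchor, dtype=float)
    positions = [anchor.copy()]
    parents = [-1]
    degree = [0]
    while len(positions) < params.ligand_size:
        for _attempt in range(200):
            j = int(rng.integers(len(positions)))
            if degree[j] >= 3:
                continue
            cand = positions[j] + params.bond_length * _random_direction(rng)
            if np.linalg.norm(cand - anchor) > params.ligand_extent:
                continue
            if _min_dist(cand, np.array(positions)) < 1.2:
                continue
            positions.append(cand)
            parents.append(j)
            degree.append(1)
            degree[j] += 1
            break
        else:
            raise GenerationError("random-walk ligand growth failed")
    center = np.mean(positions, axis=0)
    positions = [p - center + anchor for p in positions]

    elements = rng.choice(["C", "N", "O"], size=len(positions), p=[0.6, 0.2, 0.2])
    atoms: list[AtomRecord] = []
    for el, pos in zip(elements, positions):
        flags = dict(heavy=True)
        if el == "N":
            flags["donor"] = True
            flags["positive_ionizable"] = bool(rng.random() < 0.3)
        elif el == "O":
            flags["acceptor"] = True
            flags["negative_ionizable"] = bool(rng.random() < 0.3)
        atoms.append(_ligand_atom(el, pos, **flags))
    # hydrophobic = carbon with no bonded N/O (walk adjacency defines bonds)
    for i, a in enumerate(atoms):
        if a.element != "C":
            continue
        neighbors = [j for j, pj in enumerate(parents) if pj == i]
        if parents[i] >= 0:
            neighbors.append(parents[i])
        a.hydrophobic = not any(atoms[j].element in ("N", "O") for j in neighbors)
    carbons = [i for i, a in enumerate(atoms) if a.element == "C"]
    if len(carbons) >= params.aromatic_patch_size:
        patch = rng.choice(carbons, size=params.aromatic_patch_size, replace=False)
        for i in patch:
            atoms[i].aromatic = True
    for a, parent in zip(atoms, parents):
        a.parent_index = parent  # type: ignore[attr-defined]
    return atoms


def ligand_bonds(ligand: Sequence[AtomRecord]) -> list[tuple[int, int]]:
    """Random-walk bond list (for SDF fixture export)."""
    bonds = []
    for i, a in enumerate(ligand):
        parent = getattr(a, "parent_index", -1)
        if parent >= 0:
            bonds.append((parent, i))
    return bonds


def _place_partner(rng, lig_atom: AtomRecord, lig_pos: np.ndarray,
                   protein: list[AtomRecord], params: GeneratorParams) -> AtomRecord:
    prop = next(p for p in ("donor", "acceptor", "aromatic", "hydrophobic")
                if getattr(lig_atom, p))
    partner_prop = COMPLEMENT[prop]
    element = {"donor": "N", "acceptor": "O",
               "aromatic": "C", "hydrophobic": "C"}[partner_prop]
    centroid = lig_pos.mean(axis=0)
    outward = lig_atom.position - centroid
    for _attempt in range(300):
        direction = _unit(_unit(outward) + 0.6 * rng.standard_normal(3))
        dist = rng.uniform(*CONTACT_RANGE)
        pos = lig_atom.position + direction * dist
        if _min_dist(pos, lig_pos) < MIN_SEPARATION:
            continue
        if protein and _min_dist(pos, atom_coords(protein)) < 1.8:
            continue
        flags = {partner_prop: True, "heavy": True}
        if partner_prop == "aromatic":
            flags["hydrophobic"] = True
        return _protein_atom(element, pos, **flags)
    raise GenerationError("cannot place a complementary partner atom")


def _shell_atom(rng: np.random.Generator, pos: np.ndarray) -> AtomRecord:
    u = rng.random()
    if u < 0.70:
        flags = dict(hydrophobic=True, heavy=True)
        flags["aromatic"] = bool(rng.random() < 0.2)
        return _protein_atom("C", pos, **flags)
    if u < 0.85:
        return _protein_atom("N", pos, donor=True,
                             positive_ionizable=bool(rng.random() < 0.2), heavy=True)
    if u < 0.98:
        return _protein_atom("O", pos, acceptor=True,
                             negative_ionizable=bool(rng.random() < 0.2), heavy=True)
    return _protein_atom("Zn", pos, metal=True, heavy=True)


# ---------------------------------------------------------------------------
# geometry helpers

def _min_dist(point: np.ndarray, coords: np.ndarray) -> float:
    if coords.size == 0:
        return math.inf
    return float(np.min(np.linalg.norm(coords - point, axis=1)))


def min_contact(complex_structure: ComplexStructure) -> float:
    """Minimum protein-ligand heavy-atom distance, Å."""
    p = atom_coords(complex_structure.protein_atoms, heavy_only=True)
    l = atom_coords(complex_structure.ligand_atoms, heavy_only=True)
    if p.size == 0 or l.size == 0:
        return math.inf
    d = np.linalg.norm(p[:, None, :] - l[None, :, :], axis=-1)
    return float(d.min())


def rmsd(pose_a, pose_b) -> float:
    """Heavy-atom RMSD between matched poses, no re-superposition.

    Accepts ComplexStructures, atom lists, or (n, 3) coordinate arrays.
    """
    a = _pose_coords(pose_a)
    b = _pose_coords(pose_b)
    if a.shape != b.shape:
        raise ValueError(f"atom count mismatch: {a.shape[0]} vs {b.shape[0]}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _pose_coords(pose) -> np.ndarray:
    if isinstance(pose, ComplexStructure):
        return atom_coords(pose.ligand_atoms, heavy_only=True)
    if isinstance(pose, (list, tuple)) and pose and isinstance(pose[0], AtomRecord):
        return atom_coords(pose, heavy_only=True)
    return np.asarray(pose, dtype=float).reshape(-1, 3)


# ---------------------------------------------------------------------------
# pose variants

def make_clashed_pose(complex_structure: ComplexStructure, seed: int,
                      max_shift: float = 4.0
                      ) -> tuple[ComplexStructure, PoseLabel]:
    """Translate the ligand rigidly into the pocket wall until it clashes.

    Directions are drawn at random; one that does not reach the wall within
    ``max_shift`` Å (e.g. threading a gap between wall atoms) is redrawn, so
    clashed poses stay docking-like rather than grossly displaced.
    """
    rng = np.random.default_rng(seed)
    ref = atom_coords(complex_structure.ligand_atoms)
    heavy_mask = np.array([a.heavy for a in complex_structure.ligand_atoms])
    prot = atom_coords(complex_structure.protein_atoms, heavy_only=True)
    step = 0.1
    for _attempt in range(40):
        direction = _random_direction(rng)
        shift = 0.0
        while shift <= max_shift:
            shift += step
            coords = ref + shift * direction
            contact = float(np.min(np.linalg.norm(
                prot[:, None, :] - coords[heavy_mask][None, :, :], axis=-1)))
            if contact < CLASH_THRESHOLD:
                posed = complex_structure.with_ligand_coords(
                    coords, id=f"{complex_structure.id}-clash")
                label = PoseLabel(kind="clashed",
                                  rmsd_to_reference=rmsd(ref[heavy_mask],
                                                         coords[heavy_mask]),
                                  min_contact=contact)
                return posed, label
    raise GenerationError("could not reach a clash within search bounds")


def make_perturbed_pose(complex_structure: ComplexStructure, target_rmsd: float,
                        seed: int, max_steps: int = 60
                        ) -> tuple[ComplexStructure, PoseLabel]:
    """Rigid rotation+translation of the ligand tuned by bisection to a target RMSD.

    The achieved RMSD is within 5% of the target (0.05 Å absolute for small
    targets).  Poses in the ambiguous (2, 4) Å band get ``kind=None``.
    """
    if target_rmsd < 0:
        raise ValueError("target_rmsd must be non-negative")
    ref = atom_coords(complex_structure.ligand_atoms)
    heavy_mask = np.array([a.heavy for a in complex_structure.ligand_atoms])
    center = ref[heavy_mask].mean(axis=0)
    if target_rmsd == 0:
        label = PoseLabel(kind="crystal_like", rmsd_to_reference=0.0,
                          min_contact=min_contact(complex_structure))
        return complex_structure.with_ligand_coords(ref), label

    rng = np.random.default_rng(seed)
    axis = _random_direction(rng)
    trans_dir = _random_direction(rng)
    max_angle = math.pi
    max_shift = max(10.0, 2.0 * target_rmsd)

    def apply(m: float) -> np.ndarray:
        rot = Rotation.from_rotvec(axis * m * max_angle)
        return (ref - center) @ rot.as_matrix().T + center + m * max_shift * trans_dir

    tol = max(0.05 * target_rmsd, 0.05)
    lo, hi = 0.0, 1.0
    if rmsd(ref[heavy_mask], apply(1.0)[heavy_mask]) < target_rmsd - tol:
        raise GenerationError("target RMSD unreachable within motion bounds")
    coords = None
    for _ in range(max_steps):
        mid = 0.5 * (lo + hi)
        coords = apply(mid)
        achieved = rmsd(ref[heavy_mask], coords[heavy_mask])
        if abs(achieved - target_rmsd) <= tol:
            break
        if achieved < target_rmsd:
            lo = mid
        else:
            hi = mid
    else:
        raise GenerationError("RMSD bisection did not converge")

    posed = complex_structure.with_ligand_coords(
        coords, id=f"{complex_structure.id}-rmsd{target_rmsd:.2f}")
    achieved = rmsd(ref[heavy_mask], coords[heavy_mask])
    if achieved <= GOOD_RMSD:
        kind = "good_pose"
    elif achieved >= BAD_RMSD:
        kind = "bad_pose"
    else:
        kind = None
    label = PoseLabel(kind=kind, rmsd_to_reference=achieved,
                      min_contact=min_contact(posed))
    return posed, label


def random_rotation(complex_structure: ComplexStructure,
                    seed: int) -> ComplexStructure:
    """Uniform random rotation of protein+ligand about the ligand center."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    center = atom_coords(complex_structure.ligand_atoms,
                         heavy_only=True).mean(axis=0)

    def transform(atoms: list[AtomRecord]) -> list[AtomRecord]:
        return [a.moved((a.position - center) @ rot.T + center) for a in atoms]

    return ComplexStructure(transform(complex_structure.protein_atoms),
                            transform(complex_structure.ligand_atoms),
                            f"{complex_structure.id}-rot")


# ---------------------------------------------------------------------------
# labelled datasets

def make_clash_dataset(n_complexes: int, seed: int,
                       params: GeneratorParams | None = None
                       ) -> list[tuple[ComplexStructure, PoseLabel]]:
    """n crystal-like complexes plus one clashed variant each (labels 0/1)."""
    out = []
    for i in range(n_complexes):
        c = generate_complex(seed + i, params)
        out.append((c, PoseLabel(kind="crystal_like", rmsd_to_reference=0.0,
                                 min_contact=min_contact(c))))
        out.append(make_clashed_pose(c, seed + 500_000 + i))
    return out


def make_pose_dataset(n_complexes: int, seed: int,
                      params: GeneratorParams | None = None,
                      good_range: tuple[float, float] = (0.5, 1.9),
                      bad_range: tuple[float, float] = (4.3, 6.0)
                      ) -> list[tuple[ComplexStructure, PoseLabel]]:
    """n complexes, each with one good (low-RMSD) and one bad (high-RMSD) decoy."""
    rng = np.random.default_rng(seed + 900_000)
    out = []
    for i in range(n_complexes):
        c = generate_complex(seed + i, params)
        good_target = rng.uniform(*good_range)
        bad_target = rng.uniform(*bad_range)
        out.append(make_perturbed_pose(c, good_target, seed + 600_000 + i))
        out.append(make_perturbed_pose(c, bad_target, seed + 700_000 + i))
    return out


def make_clashed_set(n_complexes: int, seed: int,
                     params: GeneratorParams | None = None
                     ) -> list[ComplexStructure]:
    """n fresh complexes, each returned in its clashed pose (for attribution studies)."""
    out = []
    for i in range(n_complexes):
        c = generate_complex(seed + i, params)
        posed, _ = make_clashed_pose(c, seed + 500_000 + i)
        out.append(posed)
    return out


def contact_affinity_label(complex_structure: ComplexStructure) -> float:
    """Synthetic pKd-like regression label in [2, 12].

    Counts ligand atoms with a pharmacophore-complementary protein partner
    within contact range and maps the count linearly onto the 2-12 pKd range
    typical of public binding-affinity databases.
    """
    count = 0
    prot = complex_structure.protein_atoms
    for la in complex_structure.ligand_atoms:
        if not la.heavy:
            continue
        for prop, partner_prop in COMPLEMENT.items():
            if not getattr(la, prop):
                continue
            for pa in prot:
                if getattr(pa, partner_prop) and (
                        np.linalg.norm(pa.position - la.position)
                        <= CONTACT_RANGE[1]):
                    count += 1
                    break
            break
    n = max(1, sum(a.heavy for a in complex_structure.ligand_atoms))
    return 2.0 + 10.0 * min(1.0, count / n)
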