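"""Reciprocity analysis of attributions in complementary channel pairs.

If a scorer has learned protein-ligand interactions, the top-attributed
voxels of complementary channels (protein donor vs ligand acceptor, the two
occupancy channels, ...) should sit close together in space.  This module
measures those top-voxel distances per complex, compares the distribution
against a random baseline drawn from well-occupied voxels (feature value
> 0.75, guaranteeing an atom nearby), tests the difference with a two-sided
Mann-Whitney U test, and correlates attribution magnitude with distance.
It also quantifies how consistently the same atom is highlighted across
rotated or slightly perturbed input variants.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .igattrib import AttributionGrid, atom_attribution, integrated_gradients
from .structio import ComplexStructure
from .synthcomplex import make_perturbed_pose, random_rotation
from .voxelizer import ChannelScheme, VoxelGrid, default_scheme, voxelize

log = logging.getLogger(__name__)

OCCUPANCY_BASELINE_THRESHOLD = 0.75


@dataclass(frozen=True)
class ChannelPair:
    protein_channel: int
    ligand_channel: int
    name: str


def complementary_pairs(scheme: ChannelScheme | None = None) -> list[ChannelPair]:
    """The five complementary (protein, ligand) channel pairs under study."""
    scheme = scheme or default_scheme()
    pair_defs = [("hydrophobic", "hydrophobic", "hydrophobic"),
                 ("aromatic", "aromatic", "pi_stacking"),
                 ("acceptor", "donor", "hbond_prot_acceptor"),
                 ("donor", "acceptor", "hbond_prot_donor"),
                 ("heavy", "heavy", "occupancy")]
    return [ChannelPair(scheme.index("protein", p), scheme.index("ligand", l), name)
            for p, l, name in pair_defs]


def occupancy_pair(scheme: ChannelScheme | None = None) -> ChannelPair:
    return complementary_pairs(scheme)[-1]


def _channel_argmax(values: np.ndarray) -> tuple[np.ndarray, float]:
    """(i, j, k) of the first max-|value| voxel and its |value|."""
    flat = np.abs(values).ravel()
    lin = int(np.argmax(flat))
    return np.array(np.unravel_index(lin, values.shape)), float(flat[lin])


def pair_distance(attr: AttributionGrid, pair: ChannelPair) -> float | None:
    """Distance (Å) between the top-|attribution| voxels of a channel pair.

    Returns None when either channel is identically zero (complex excluded
    from that pair's distribution).
    """
    values = np.asarray(attr.values)
    va, vb = values[pair.protein_channel], values[pair.ligand_channel]
    if not np.any(va) or not np.any(vb):
        log.info("pair %s undefined for %s: empty channel", pair.name, attr.source_id)
        return None
    ia, _ = _channel_argmax(va)
    ib, _ = _channel_argmax(vb)
    return float(np.linalg.norm((ia - ib) * attr.spacing))


def pair_magnitude(attr: AttributionGrid, pair: ChannelPair) -> float | None:
    """Summed |attribution| of the two top voxels of the pair."""
    values = np.asarray(attr.values)
    va, vb = values[pair.protein_channel], values[pair.ligand_channel]
    if not np.any(va) or not np.any(vb):
        return None
    _, ma = _channel_argmax(va)
    _, mb = _channel_argmax(vb)
    return ma + mb


def baseline_pair_distance(grid: VoxelGrid, pair: ChannelPair,
                           seed: int | np.random.Generator) -> float | None:
    """Distance between two random well-occupied voxels of the pair's channels.

    Candidate voxels must have feature value > 0.75 in their own channel of
    the *feature* grid, ensuring an atom is nearby.  Deterministic given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.asarray(grid.values)
    picks = []
    for ch in (pair.protein_channel, pair.ligand_channel):
        qualifying = np.argwhere(values[ch] > OCCUPANCY_BASELINE_THRESHOLD)
        if len(qualifying) == 0:
            log.info("baseline undefined for %s channel %d of %s",
                     pair.name, ch, grid.source_id)
            return None
        picks.append(qualifying[rng.integers(len(qualifying))])
    return float(np.linalg.norm((picks[0] - picks[1]) * grid.spacing))


# ---------------------------------------------------------------------------
# Mann-Whitney U

def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   exact_limit: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Small samples (min(n, m) <= ``exact_limit``) are tested by exact
    enumeration of all group assignments with midrank tie handling; larger
    samples use the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    u = _u_statistic(x, y)
    if min(n, m) <= exact_limit:
        p = _exact_two_sided_p(x, y, u)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
    return u, min(1.0, max(p, np.finfo(float).tiny))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # midranks
    r1 = ranks[:len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact permutation distribution of U over all group assignments."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n, total = len(x), len(combined)
    offset = n * (n + 1) / 2.0
    center = n * len(y) / 2.0
    stat_obs = abs(u_obs - center)
    count = 0
    n_comb = 0
    for assignment in itertools.combinations(range(total), n):
        u = ranks[list(assignment)].sum() - offset
        if abs(u - center) >= stat_obs - 1e-9:
            count += 1
        n_comb += 1
    return count / n_comb


def magnitude_distance_correlation(magnitudes: Sequence[float],
                                   distances: Sequence[float]) -> float | None:
    """Pearson r between summed top-two |attribution| and top-voxel distance."""
    magnitudes = np.asarray(magnitudes, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if len(magnitudes) < 3:
        raise ValueError("need at least 3 records")
    if np.std(magnitudes) == 0 or np.std(distances) == 0:
        return None
    return float(stats.pearsonr(magnitudes, distances).statistic)


# ---------------------------------------------------------------------------
# study drivers

@dataclass
class PairStats:
    pair: ChannelPair
    u_statistic: float
    p_value: float
    pearson_r: float | None
    n: int


@dataclass
class DistanceStudyResult:
    """Tidy per-complex records plus per-pair test statistics."""

    records: pd.DataFrame
    pair_stats: dict[str, PairStats]

    def stats_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            dict(pair=name, U=s.u_statistic, p_value=s.p_value,
                 pearson_r=s.pearson_r, n=s.n)
            for name, s in self.pair_stats.items()])


def distance_study(complexes: Sequence[ComplexStructure], scorer,
                   pairs: Sequence[ChannelPair] | None = None,
                   seed: int = 0, steps: int = 100,
                   scheme: ChannelScheme | None = None,
                   grid_kwargs: dict | None = None) -> DistanceStudyResult:
    """Top-voxel pair distances vs the random occupancy baseline.

    Voxelizes and attributes every complex, records per (complex, pair) the
    attribution top-voxel distance, one random baseline distance and the
    summed top-two |attribution|, then computes per-pair Mann-Whitney U/p and
    the magnitude-distance Pearson r.
    """
    scheme = scheme or default_scheme()
    pairs = list(pairs) if pairs is not None else complementary_pairs(scheme)
    grid_kwargs = grid_kwargs or {}
    rng = np.random.default_rng(seed)

    rows = []
    for c in complexes:
        grid = voxelize(c, scheme=scheme, **grid_kwargs)
        attr = integrated_gradients(scorer, grid, steps=steps)
        for pair in pairs:
            rows.append(dict(
                complex_id=c.id, pair=pair.name,
                distance=pair_distance(attr, pair),
                baseline_distance=baseline_pair_distance(grid, pair, rng),
                magnitude=pair_magnitude(attr, pair)))
    records = pd.DataFrame(rows)

    pair_stats: dict[str, PairStats] = {}
    for pair in pairs:
        sub = records[records["pair"] == pair.name]
        d = sub["distance"].dropna().to_numpy(dtype=float)
        b = sub["baseline_distance"].dropna().to_numpy(dtype=float)
        both = sub.dropna(subset=["distance", "magnitude"])
        if len(d) == 0 or len(b) == 0:
            log.warning("pair %s has no defined distances; skipped", pair.name)
            continue
        u, p = mann_whitney_u(d, b)
        if len(both) >= 3:
            try:
                r = magnitude_distance_correlation(
                    both["magnitude"].to_numpy(), both["distance"].to_numpy())
            except ValueError:
                r = None
        else:
            r = None
        pair_stats[pair.name] = PairStats(pair=pair, u_statistic=u, p_value=p,
                                          pearson_r=r, n=len(d))
    return DistanceStudyResult(records=records, pair_stats=pair_stats)


# ---------------------------------------------------------------------------
# consistency under input variation

@dataclass
class ConsistencyResult:
    protein_repeat_count: int
    ligand_repeat_count: int
    baseline_expected_repeat: float
    n_variants_used: int


def consistency_study(complex_structure: ComplexStructure, scorer,
                      n_variants: int = 10, mode: str = "rotation",
                      seed: int = 0, steps: int = 50,
                      perturbation_rmsd: float = 0.5,
                      scheme: ChannelScheme | None = None,
                      grid_kwargs: dict | None = None,
                      baseline_draws: int = 200) -> ConsistencyResult:
    """How often the same atom tops the attribution across input variants.

    Generates ``n_variants`` rotated (or 0.5 Å-perturbed) copies, attributes
    each, and counts the modal top atom per entity.  The random baseline is
    the expected modal count when top atoms are drawn uniformly, estimated by
    simulation from the same seed stream.
    """
    if n_variants < 2:
        raise ValueError("need at least 2 variants")
    if mode not in ("rotation", "pose_perturbation"):
        raise ValueError(f"unknown mode {mode!r}")
    scheme = scheme or default_scheme()
    grid_kwargs = grid_kwargs or {}
    rng = np.random.default_rng(seed)

    top_protein: list[int] = []
    top_ligand: list[int] = []
    n_failed = 0
    for v in range(n_variants):
        sub_seed = int(rng.integers(2 ** 31))
        try:
            if mode == "rotation":
                variant = random_rotation(complex_structure, sub_seed)
            else:
                variant, _ = make_perturbed_pose(
                    complex_structure, perturbation_rmsd, sub_seed)
            grid = voxelize(variant, scheme=scheme, **grid_kwargs)
            attr = integrated_gradients(scorer, grid, steps=steps)
            atoms = atom_attribution(attr, variant, scheme=scheme)
        except Exception as exc:  # noqa: BLE001 - variant-level containment
            n_failed += 1
            log.warning("variant %d failed: %s", v, exc)
            continue
        if atoms.top_protein_atom is not None:
            top_protein.append(atoms.top_protein_atom)
        if atoms.top_ligand_atom is not None:
            top_ligand.append(atoms.top_ligand_atom)
    if n_failed > n_variants // 2:
        raise RuntimeError(f"{n_failed} of {n_variants} variants failed")

    def modal_count(picks: list[int]) -> int:
        if not picks:
            return 0
        return int(np.max(np.bincount(picks)))

    n_atoms = (len(complex_structure.protein_atoms)
               + len(complex_structure.ligand_atoms))
    n_used = max(len(top_protein), len(top_ligand))
    baseline = _expected_modal_count(rng, n_atoms, max(n_used, 2), baseline_draws)
    return ConsistencyResult(protein_repeat_count=modal_count(top_protein),
                             ligand_repeat_count=modal_count(top_ligand),
                             baseline_expected_repeat=baseline,
                             n_variants_used=n_used)


def _expected_modal_count(rng: np.random.Generator, n_atoms: int,
                          n_variants: int, n_draws: int) -> float:
    counts = []
    for _ in range(n_draws):
        picks = rng.integers(n_atoms, size=n_variants)
        counts.append(np.max(np.bincount(picks)))
    return float(np.mean(counts))
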