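"""Post-search filters: solvent accessibility and ligand-affinity scoring.

Hits from the similarity search are kept only if (i) the matched residues
are solvent-exposed — their Shrake-Rupley SASA must exceed a configurable
fraction (default 75%) of the query motif's SASA — and (ii) re-docking the
query ligand at the matched site scores no worse than the query complex's
own docking score inflated by a tolerance fraction (default 10%):

    SASA_hit  >  SASA_query * sasa_threshold          (strict)
    DSCORE_hit <  mean(DSCORE_query) + |mean(DSCORE_query)| * dscore_threshold

Docking uses a deterministic surrogate scorer (soft-clash penalty, contact
reward, polar-interaction bonus) behind a pluggable backend contract; both
sides of the docking criterion are evaluated with the same backend, which
preserves the criterion's semantics independent of the absolute score scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .interactions import GeometricCriteria, LigandChemistry, detect_interactions
from .residue_data import VDW_RADII
from .structure_io import Residue, Structure

__all__ = [
    "SASAResult",
    "DockingResult",
    "FilterConfig",
    "ScoreWeights",
    "sasa",
    "sasa_filter",
    "score_pose",
    "dock_ligand",
    "docking_filter",
]


@dataclass(frozen=True)
class FilterConfig:
    sasa_threshold: float = 0.75
    dscore_threshold: float = 0.10
    probe_radius: float = 0.14  # nm
    sasa_points: int = 960
    n_poses: int = 200

    def __post_init__(self) -> None:
        if self.sasa_threshold < 0 or self.dscore_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.probe_radius <= 0:
            raise ValueError("probe radius must be positive")


@dataclass
class SASAResult:
    structure_id: str
    residue_ids: tuple
    sasa: float  # nm^2
    probe_radius: float  # nm
    n_points: int


@dataclass
class DockingResult:
    structure_id: str
    site_center: np.ndarray
    score: float
    backend: str
    seed: int
    pose: np.ndarray  # ligand heavy-atom coordinates
    clash_only: bool = False


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic, seedless unit-sphere point set (golden-section spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radius(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise ValueError(f"no van der Waals radius for element {element!r}") from None


def sasa(
    structure: Structure,
    residue_ids: Iterable[tuple[str, int, str]] | None = None,
    probe_radius: float = 0.14,
    n_points: int = 960,
) -> SASAResult:
    """Shrake-Rupley SASA of the selected residues, in full-structure context.

    ``probe_radius`` is in nm; atom radii come from a fixed element table.
    Surface points are a deterministic golden-section spiral, so results are
    bit-reproducible.  The returned area is in nm².
    """
    if n_points < 60:
        raise ValueError("n_points must be >= 60 for a usable point density")
    probe_a = probe_radius * 10.0  # Å

    heavy = [(r, a) for r in structure.residues for a in r.atoms if a.is_heavy]
    if not heavy:
        raise ValueError(f"{structure.id}: no heavy atoms")
    coords = np.array([a.coords for _, a in heavy])
    radii = np.array([_radius(a.element) for _, a in heavy]) + probe_a

    if residue_ids is None:
        selected = np.ones(len(heavy), dtype=bool)
        sel_ids: tuple = tuple(sorted({r.id for r, _ in heavy}))
    else:
        wanted = set(residue_ids)
        selected = np.array([r.id in wanted for r, _ in heavy])
        sel_ids = tuple(sorted(wanted))
        if not selected.any():
            raise KeyError(f"{structure.id}: none of the requested residues found")

    sphere = _golden_spiral(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    total = 0.0
    for i in np.flatnonzero(selected):
        pts = coords[i] + radii[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], radii[i] + max_r):
            if j == i:
                continue
            exposed &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
            if not exposed.any():
                break
        frac = exposed.sum() / n_points
        total += frac * 4.0 * math.pi * radii[i] ** 2
    return SASAResult(
        structure_id=structure.id,
        residue_ids=sel_ids,
        sasa=total / 100.0,  # Å² -> nm²
        probe_radius=probe_radius,
        n_points=n_points,
    )


def sasa_filter(hit_sasa: float, query_sasa: float, threshold: float = 0.75) -> bool:
    """Accessibility criterion: SASA_hit > SASA_query * threshold (strict)."""
    if query_sasa <= 0:
        raise ValueError("query motif SASA is zero: the query site is unexposed")
    return hit_sasa > query_sasa * threshold


@dataclass(frozen=True)
class ScoreWeights:
    """Surrogate scoring-function weights (dimensionless; lower = better)."""

    clash: float = 10.0
    contact: float = 0.2
    polar: float = 2.0
    clash_factor: float = 0.8  # clash when d < clash_factor * (r_i + r_j)
    contact_max: float = 4.5  # Å
    #: per-ligand-atom cap on rewarded contacts; saturation keeps dense
    #: crevices from outscoring a designed polar-anchored site
    contact_cap: int = 8


class _ScoreContext:
    """Receptor-side precomputation for repeated pose scoring."""

    def __init__(self, receptor: Structure, ligand: Residue,
                 weights: ScoreWeights | None = None,
                 criteria: GeometricCriteria | None = None,
                 ligand_chemistry: LigandChemistry | None = None) -> None:
        from .residue_data import (ANIONIC_GROUPS, CATIONIC_GROUPS,
                                   HBOND_ACCEPTORS, HBOND_DONORS)

        self.w = weights or ScoreWeights()
        self.criteria = criteria or GeometricCriteria()
        chem = ligand_chemistry or LigandChemistry()

        rec_heavy = [a for r in receptor.residues for a in r.atoms if a.is_heavy]
        self.rc = np.array([a.coords for a in rec_heavy]).reshape(-1, 3)
        self.rr = np.array([_radius(a.element) for a in rec_heavy])
        self.tree = cKDTree(self.rc) if len(rec_heavy) else None

        # receptor polar atoms: backbone N/O + side-chain donor/acceptor table
        polar_idx = []
        i = 0
        for r in receptor.residues:
            names = {"N", "O"} | set(HBOND_DONORS.get(r.resname, ())) \
                | set(HBOND_ACCEPTORS.get(r.resname, ()))
            for a in r.atoms:
                if a.is_heavy:
                    if a.name in names:
                        polar_idx.append(i)
                    i += 1
        self.polar_tree = cKDTree(self.rc[polar_idx]) if polar_idx else None

        # receptor charged-group centroids
        cat, ani = [], []
        for r in receptor.residues:
            g = CATIONIC_GROUPS.get(r.resname)
            if g and all(r.has_atom(n) for n in g):
                cat.append(np.mean([r.atom(n).coords for n in g], axis=0))
            g = ANIONIC_GROUPS.get(r.resname)
            if g and all(r.has_atom(n) for n in g):
                ani.append(np.mean([r.atom(n).coords for n in g], axis=0))
        self.rec_cations = np.array(cat).reshape(-1, 3)
        self.rec_anions = np.array(ani).reshape(-1, 3)

        # ligand-side templates, as indices into the heavy-atom array
        heavy = ligand.heavy_atoms()
        name_to_i = {a.name: i for i, a in enumerate(heavy)}
        self.lig_radii = np.array([_radius(a.element) for a in heavy])
        self.lig_polar = np.array([i for i, a in enumerate(heavy)
                                   if a.element.upper() in ("N", "O")], dtype=int)
        self.lig_cation_groups = [
            np.array([name_to_i[n] for n in grp if n in name_to_i], dtype=int)
            for grp in chem.cation_groups
        ]
        self.lig_anion_groups = [
            np.array([name_to_i[n] for n in grp if n in name_to_i], dtype=int)
            for grp in chem.anion_groups
        ]

    def score(self, coords: np.ndarray) -> float:
        if self.tree is None:
            return 0.0
        w = self.w
        clash = 0.0
        contacts = 0
        neighbor_lists = self.tree.query_ball_point(coords, w.contact_max)
        for i, js in enumerate(neighbor_lists):
            if not js:
                continue
            js = np.asarray(js, dtype=int)
            d = np.linalg.norm(self.rc[js] - coords[i], axis=1)
            contacts += min(len(js), w.contact_cap)
            cut = w.clash_factor * (self.lig_radii[i] + self.rr[js])
            over = cut > d
            if over.any():
                clash += float((((cut[over] - d[over]) / cut[over]) ** 2).sum())

        polar = 0
        if contacts and self.polar_tree is not None and len(self.lig_polar):
            polar += sum(len(js) for js in self.polar_tree.query_ball_point(
                coords[self.lig_polar], self.criteria.hbond_da_max))
        if contacts:
            for grp in self.lig_cation_groups:
                if len(grp) and len(self.rec_anions):
                    c = coords[grp].mean(axis=0)
                    polar += int((np.linalg.norm(self.rec_anions - c, axis=1)
                                  <= self.criteria.saltbridge_max).sum())
            for grp in self.lig_anion_groups:
                if len(grp) and len(self.rec_cations):
                    c = coords[grp].mean(axis=0)
                    polar += int((np.linalg.norm(self.rec_cations - c, axis=1)
                                  <= self.criteria.saltbridge_max).sum())
        return w.clash * clash - w.contact * contacts - w.polar * polar

    def hard_clash(self, coords: np.ndarray) -> bool:
        if self.tree is None:
            return False
        for i, js in enumerate(self.tree.query_ball_point(coords, 2.0)):
            for j in js:
                d = float(np.linalg.norm(coords[i] - self.rc[j]))
                if d < 0.5 * (self.lig_radii[i] + self.rr[j]):
                    return True
        return False


def score_pose(
    receptor: Structure,
    ligand_pose: Residue,
    weights: ScoreWeights | None = None,
    criteria: GeometricCriteria | None = None,
    ligand_chemistry: LigandChemistry | None = None,
) -> float:
    """Deterministic surrogate affinity score of a rigid ligand pose.

    score = soft-clash penalty - contact reward - polar bonus (hydrogen-bond
    and salt-bridge geometry from the interaction criteria); a ligand far
    from the receptor scores exactly 0 and lower is better.
    """
    heavy = ligand_pose.heavy_atoms()
    if not heavy:
        raise ValueError("ligand pose has no heavy atoms")
    ctx = _ScoreContext(receptor, ligand_pose, weights, criteria, ligand_chemistry)
    return float(ctx.score(np.array([a.coords for a in heavy])))


def _pose_residue(ligand: Residue, coords: np.ndarray) -> Residue:
    heavy = ligand.heavy_atoms()
    atoms = [replace(a, coords=c.copy()) for a, c in zip(heavy, coords)]
    return Residue(ligand.chain, ligand.resseq, ligand.icode, ligand.resname, atoms)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def _rotation_from_rng(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def dock_ligand(
    receptor: Structure,
    site_center: np.ndarray,
    ligand: Residue,
    seed: int = 0,
    n_poses: int = 200,
    search_radius: float | None = None,
    weights: ScoreWeights | None = None,
    criteria: GeometricCriteria | None = None,
    ligand_chemistry: LigandChemistry | None = None,
    backend: str = "surrogate",
    initial_poses: Sequence[np.ndarray] | None = None,
) -> DockingResult:
    """Rigid-ligand pose search around ``site_center`` with the surrogate scorer.

    ``n_poses`` random orientations/translations inside a sphere (default
    radius: half the ligand diameter + 3 Å) are each refined by fixed-step
    rigid-body coordinate descent (translations and rotations); the
    best-scoring pose is returned.  ``initial_poses`` (full heavy-atom
    coordinate arrays) are refined ahead of the random draws — e.g. a
    ligand placement inferred from a motif correspondence — without
    consuming random numbers.  Deterministic for a fixed seed, and the best
    score is monotone non-worsening in ``n_poses`` because poses are drawn
    sequentially from one seeded generator.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    site_center = np.asarray(site_center, dtype=float)
    heavy = ligand.heavy_atoms()
    if not heavy:
        raise ValueError("ligand has no heavy atoms")
    lig0 = np.array([a.coords for a in heavy])
    lig0 -= lig0.mean(axis=0)
    if search_radius is None:
        diam = float(np.linalg.norm(lig0[:, None] - lig0[None, :], axis=-1).max())
        search_radius = diam / 2.0 + 3.0

    rng = np.random.default_rng(seed)
    ctx = _ScoreContext(receptor, ligand, weights, criteria, ligand_chemistry)

    best_score = math.inf
    best_pose: np.ndarray | None = None
    all_clash = True
    # translation steps (Å) paired with rotation steps (rad) for the
    # rigid-body coordinate descent
    steps = ((1.0, 0.5), (0.5, 0.25), (0.25, 0.125))
    axes = np.vstack([np.eye(3), -np.eye(3)])

    def refine(coords: np.ndarray) -> tuple[np.ndarray, float]:
        s = ctx.score(coords)
        for t_step, r_step in steps:
            improved = True
            rounds = 0
            while improved and rounds < 20:
                improved = False
                rounds += 1
                for ax in axes:
                    cand = coords + t_step * ax
                    sc = ctx.score(cand)
                    if sc < s - 1e-9:
                        coords, s = cand, sc
                        improved = True
                center = coords.mean(axis=0)
                for ax in axes:
                    Rm = _rotation_about(ax, r_step)
                    cand = (coords - center) @ Rm.T + center
                    sc = ctx.score(cand)
                    if sc < s - 1e-9:
                        coords, s = cand, sc
                        improved = True
        return coords, s

    starts: list[np.ndarray] = [np.asarray(p, dtype=float)
                                for p in (initial_poses or [])]
    for coords in starts:
        if coords.shape != lig0.shape:
            raise ValueError("initial pose shape does not match the ligand")
        coords, s = refine(coords)
        if not ctx.hard_clash(coords):
            all_clash = False
        if s < best_score:
            best_score, best_pose = s, coords

    for _ in range(n_poses):
        R = _rotation_from_rng(rng)
        # uniform point in the sphere
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        offset = u * search_radius * rng.random() ** (1.0 / 3.0)
        coords, s = refine(lig0 @ R.T + site_center + offset)
        if not ctx.hard_clash(coords):
            all_clash = False
        if s < best_score:
            best_score, best_pose = s, coords

    assert best_pose is not None
    return DockingResult(
        structure_id=receptor.id,
        site_center=site_center,
        score=float(best_score),
        backend=backend,
        seed=seed,
        pose=best_pose,
        clash_only=all_clash,
    )


def docking_filter(
    hit_score: float,
    query_scores: Sequence[float],
    threshold: float = 0.10,
) -> bool:
    """Affinity criterion (strict <) against the mean query docking score."""
    if len(query_scores) == 0:
        raise ValueError("query_scores must be non-empty")
    mean_q = float(np.mean(query_scores))
    return hit_score < mean_q + abs(mean_q) * threshold
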