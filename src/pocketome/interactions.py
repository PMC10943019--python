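"""Geometric detection of non-covalent receptor-ligand interactions.

The detector reproduces the contact classes a protein-ligand interaction
profiler reports — hydrophobic contacts, hydrogen bonds, salt bridges,
pi-stacking, pi-cation and halogen bonds — from explicit distance/angle
criteria.  Water bridges and metal complexes are out of scope (curation
removes HETATM water and ions from screened targets).

Ligand chemistry is inferred from the input coordinates: covalent bonds by
a distance criterion, apolar carbons as carbons bonded only to C/H, rings
by cycle detection plus a planarity test.  Formal charges cannot be
inferred from heavy atoms alone, so cationic/anionic ligand groups are
taken from explicit hints (carboxylates are auto-detected).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .residue_data import (
    ANIONIC_GROUPS,
    AROMATIC_RINGS,
    CATIONIC_GROUPS,
    HBOND_ACCEPTORS,
    HBOND_DONORS,
    HIS_CATION_GROUP,
    STANDARD_AA,
)
from .structure_io import Residue, Structure, TrajectoryEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "GeometricCriteria",
    "InteractionRecord",
    "InteractionProbabilityTable",
    "LigandChemistry",
    "detect_interactions",
    "interaction_probability",
]

_BOND_CUTOFF = 1.85  # Å, heavy-atom covalent bond inference
_HALOGENS = {"F", "CL", "BR", "I"}


@dataclass(frozen=True)
class GeometricCriteria:
    """Distance/angle thresholds for each interaction class (Å, degrees)."""

    hydrophobic_max: float = 4.0
    hbond_da_max: float = 4.1
    hbond_angle_min: float = 100.0
    saltbridge_max: float = 5.5
    pistack_max: float = 5.5
    pistack_angle_tol: float = 30.0
    pication_max: float = 6.0
    halogen_max: float = 4.0

    def __post_init__(self) -> None:
        for f in ("hydrophobic_max", "hbond_da_max", "saltbridge_max",
                  "pistack_max", "pication_max", "halogen_max"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        for f in ("hbond_angle_min", "pistack_angle_tol"):
            if not (0.0 < getattr(self, f) <= 180.0):
                raise ValueError(f"{f} must lie in (0, 180]")

    def max_for(self, kind: str) -> float:
        return {
            "hydrophobic": self.hydrophobic_max,
            "hbond": self.hbond_da_max,
            "saltbridge": self.saltbridge_max,
            "pistack": self.pistack_max,
            "pication": self.pication_max,
            "halogen": self.halogen_max,
        }[kind]


@dataclass(frozen=True)
class InteractionRecord:
    kind: str
    residue_id: tuple[str, int, str, str]  # chain, resseq, icode, resname
    ligand_atoms: tuple[str, ...]
    receptor_atoms: tuple[str, ...]
    distance: float
    angle: float | None = None


@dataclass
class InteractionProbabilityTable:
    entries: dict[tuple[tuple[str, int, str, str], str], float]
    frame_count: int


@dataclass
class LigandChemistry:
    """Explicit protonation/charge hints for a ligand residue.

    ``cation_groups``/``anion_groups`` are tuples of atom names whose
    centroid carries the formal charge.  ``donor_atoms`` marks N/O heavy
    atoms allowed to donate a hydrogen bond even without explicit H.
    """

    cation_groups: tuple[tuple[str, ...], ...] = ()
    anion_groups: tuple[tuple[str, ...], ...] = ()
    donor_atoms: tuple[str, ...] = ()


def _ligand_bond_graph(atoms) -> nx.Graph:
    g = nx.Graph()
    coords = np.array([a.coords for a in atoms])
    g.add_nodes_from(range(len(atoms)))
    if len(atoms) > 1:
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(_BOND_CUTOFF):
            g.add_edge(int(i), int(j))
    return g


def _apolar_carbons(atoms, bonds: nx.Graph) -> list[int]:
    out = []
    for i, a in enumerate(atoms):
        if a.element.upper() != "C":
            continue
        if all(atoms[j].element.upper() in ("C", "H") for j in bonds.neighbors(i)):
            out.append(i)
    return out


def _residue_bonds(residue: Residue) -> nx.Graph:
    return _ligand_bond_graph(residue.heavy_atoms())


def _ligand_rings(atoms, bonds: nx.Graph, max_planarity: float = 0.10) -> list[list[int]]:
    rings = []
    for cycle in nx.minimum_cycle_basis(bonds):
        if len(cycle) not in (5, 6):
            continue
        pts = np.array([atoms[i].coords for i in cycle])
        c = pts.mean(axis=0)
        sv = np.linalg.svd(pts - c, compute_uv=False)
        if sv[-1] / math.sqrt(len(cycle)) <= max_planarity:
            rings.append(list(cycle))
    return rings


def _plane_normal(pts: np.ndarray) -> np.ndarray:
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    return vt[-1]


def _angle_between_planes(n1: np.ndarray, n2: np.ndarray) -> float:
    cosv = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return math.degrees(math.acos(min(1.0, cosv)))


def detect_interactions(
    receptor: Structure,
    ligand: Residue | Sequence[Residue],
    criteria: GeometricCriteria | None = None,
    ligand_chemistry: LigandChemistry | None = None,
    protonated_his: Iterable[tuple[str, int, str]] = (),
) -> list[InteractionRecord]:
    """Detect receptor-ligand contacts; one record per (residue, kind).

    Where several atom pairs of the same class link a residue to the ligand
    only the minimal-distance pair is reported, which stabilises motif
    membership across frames.
    """
    criteria = criteria or GeometricCriteria()
    chem = ligand_chemistry or LigandChemistry()
    lig_residues = [ligand] if isinstance(ligand, Residue) else list(ligand)
    lig_atoms = [a for r in lig_residues for a in r.atoms]
    lig_heavy = [a for a in lig_atoms if a.is_heavy]
    if not lig_heavy:
        raise ValueError("ligand has no heavy atoms")
    protonated_his = set(protonated_his)

    lig_bonds = _ligand_bond_graph(lig_heavy)
    lig_coords = np.array([a.coords for a in lig_heavy])
    lig_tree = cKDTree(lig_coords)
    lig_apolar = set(_apolar_carbons(lig_heavy, lig_bonds))
    lig_name = {a.name: i for i, a in enumerate(lig_heavy)}

    # ligand hydrogens for donor-angle evaluation
    lig_h = [a for a in lig_atoms if not a.is_heavy]

    # ligand donor/acceptor roles: O is always an acceptor; N is an acceptor
    # unless it carries explicit hydrogens or a positive charge (an N-H or
    # N+ group donates, a bare N accepts)
    cation_atoms = {n for grp in chem.cation_groups for n in grp}

    def _has_h(a) -> bool:
        return any(np.linalg.norm(h.coords - a.coords) < 1.3 for h in lig_h)

    lig_acceptors = [
        i for i, a in enumerate(lig_heavy)
        if a.element.upper() == "O"
        or (a.element.upper() == "N" and a.name not in cation_atoms
            and not _has_h(a))
    ]
    lig_donors = [
        i for i, a in enumerate(lig_heavy)
        if a.name in chem.donor_atoms
        or (a.element.upper() in ("N", "O") and _has_h(a))
    ]

    # ligand charged groups: hints + carboxylate auto-detection
    def centroid(names: tuple[str, ...]) -> np.ndarray | None:
        try:
            return np.mean([lig_coords[lig_name[n]] for n in names], axis=0)
        except KeyError:
            return None

    lig_cations = [(grp, centroid(grp)) for grp in chem.cation_groups]
    lig_anions = [(grp, centroid(grp)) for grp in chem.anion_groups]
    for i, a in enumerate(lig_heavy):
        if a.element.upper() != "C":
            continue
        terminal_o = [j for j in lig_bonds.neighbors(i)
                      if lig_heavy[j].element.upper() == "O"
                      and lig_bonds.degree(j) == 1]
        if len(terminal_o) == 2:
            grp = tuple(lig_heavy[j].name for j in terminal_o)
            if not any(set(grp) == set(g) for g, _ in lig_anions):
                lig_anions.append((grp, lig_coords[terminal_o].mean(axis=0)))

    lig_rings = [(tuple(lig_heavy[i].name for i in cyc),
                  np.array([lig_heavy[i].coords for i in cyc]))
                 for cyc in _ligand_rings(lig_heavy, lig_bonds)]

    # halogen donors: ligand C-X
    lig_halogens = [
        i for i, a in enumerate(lig_heavy)
        if a.element.upper() in _HALOGENS
        and any(lig_heavy[j].element.upper() == "C" for j in lig_bonds.neighbors(i))
    ]

    reach = max(criteria.saltbridge_max, criteria.pication_max,
                criteria.pistack_max, criteria.hbond_da_max,
                criteria.hydrophobic_max, criteria.halogen_max) + 8.0

    best: dict[tuple, InteractionRecord] = {}

    def record(kind: str, res: Residue, dist: float, lig_names: tuple[str, ...],
               rec_names: tuple[str, ...], angle: float | None = None) -> None:
        rid = (res.chain, res.resseq, res.icode, res.resname)
        key = (rid, kind)
        prev = best.get(key)
        if prev is None or dist < prev.distance:
            best[key] = InteractionRecord(kind, rid, lig_names, rec_names,
                                          float(dist), angle)

    for res in receptor.residues:
        if res.resname not in STANDARD_AA:
            logger.warning("skipping unknown residue %s %s", res.resname, res.id)
            continue
        heavy = res.heavy_atoms()
        if not heavy:
            continue
        rcoords = np.array([a.coords for a in heavy])
        # cheap reach test
        dmin = lig_tree.query(rcoords, k=1)[0].min()
        if dmin > reach:
            continue

        rbonds = _ligand_bond_graph(heavy)
        # --- hydrophobic ---
        for i in _apolar_carbons(heavy, rbonds):
            for j in lig_tree.query_ball_point(heavy[i].coords, criteria.hydrophobic_max):
                if j in lig_apolar:
                    d = float(np.linalg.norm(heavy[i].coords - lig_coords[j]))
                    record("hydrophobic", res, d,
                           (lig_heavy[j].name,), (heavy[i].name,))

        # --- hydrogen bonds (both directions) ---
        donors = [a for a in heavy if a.name == "N"]
        donors += [a for a in heavy if a.name in HBOND_DONORS.get(res.resname, ())]
        acceptors = [a for a in heavy if a.name == "O"]
        acceptors += [a for a in heavy if a.name in HBOND_ACCEPTORS.get(res.resname, ())]
        res_h = [a for a in res.atoms if not a.is_heavy]

        def hbond_angle(donor, acceptor, hs) -> float | None:
            cand = [h for h in hs if np.linalg.norm(h.coords - donor.coords) < 1.3]
            if not cand:
                return None
            angles = []
            for h in cand:
                v1 = donor.coords - h.coords
                v2 = acceptor.coords - h.coords
                c = float(np.dot(v1, v2) /
                          (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12))
                angles.append(math.degrees(math.acos(max(-1.0, min(1.0, c)))))
            return max(angles)

        for d_at in donors:  # receptor donor -> ligand acceptor
            for j in lig_acceptors:
                dist = float(np.linalg.norm(d_at.coords - lig_coords[j]))
                if dist <= criteria.hbond_da_max:
                    ang = hbond_angle(d_at, lig_heavy[j], res_h)
                    if ang is None or ang >= criteria.hbond_angle_min:
                        record("hbond", res, dist, (lig_heavy[j].name,),
                               (d_at.name,), ang)
        for a_at in acceptors:  # ligand donor -> receptor acceptor
            for j in lig_donors:
                dist = float(np.linalg.norm(a_at.coords - lig_coords[j]))
                if dist <= criteria.hbond_da_max:
                    ang = hbond_angle(lig_heavy[j], a_at, lig_h)
                    if ang is None or ang >= criteria.hbond_angle_min:
                        record("hbond", res, dist, (lig_heavy[j].name,),
                               (a_at.name,), ang)

        # --- salt bridges ---
        def group_centroid(names: tuple[str, ...]) -> np.ndarray | None:
            if all(res.has_atom(n) for n in names):
                return np.mean([res.atom(n).coords for n in names], axis=0)
            return None

        res_cations: list[tuple[tuple[str, ...], np.ndarray]] = []
        res_anions: list[tuple[tuple[str, ...], np.ndarray]] = []
        grp = CATIONIC_GROUPS.get(res.resname)
        if grp is not None:
            c = group_centroid(grp)
            if c is not None:
                res_cations.append((grp, c))
        if res.resname == "HIS" and res.id in protonated_his:
            c = group_centroid(HIS_CATION_GROUP)
            if c is not None:
                res_cations.append((HIS_CATION_GROUP, c))
        grp = ANIONIC_GROUPS.get(res.resname)
        if grp is not None:
            c = group_centroid(grp)
            if c is not None:
                res_anions.append((grp, c))

        for rg, rc in res_cations:
            for lg, lc in lig_anions:
                if lc is None:
                    continue
                d = float(np.linalg.norm(rc - lc))
                if d <= criteria.saltbridge_max:
                    record("saltbridge", res, d, lg, rg)
        for rg, rc in res_anions:
            for lg, lc in lig_cations:
                if lc is None:
                    continue
                d = float(np.linalg.norm(rc - lc))
                if d <= criteria.saltbridge_max:
                    record("saltbridge", res, d, lg, rg)

        # --- pi-stacking & pi-cation ---
        res_rings = []
        for ring in AROMATIC_RINGS.get(res.resname, ()):
            if all(res.has_atom(n) for n in ring):
                res_rings.append((ring, np.array([res.atom(n).coords for n in ring])))
        for rnames, rpts in res_rings:
            rc = rpts.mean(axis=0)
            rn = _plane_normal(rpts)
            for lnames, lpts in lig_rings:
                d = float(np.linalg.norm(rc - lpts.mean(axis=0)))
                if d > criteria.pistack_max:
                    continue
                ang = _angle_between_planes(rn, _plane_normal(lpts))
                if ang <= criteria.pistack_angle_tol or \
                        abs(ang - 90.0) <= criteria.pistack_angle_tol:
                    record("pistack", res, d, lnames, rnames, ang)
            for lg, lc in lig_cations:  # receptor ring vs ligand cation
                if lc is None:
                    continue
                d = float(np.linalg.norm(rc - lc))
                if d <= criteria.pication_max:
                    record("pication", res, d, lg, rnames)
        for rg, rc in res_cations:  # ligand ring vs receptor cation
            for lnames, lpts in lig_rings:
                d = float(np.linalg.norm(rc - lpts.mean(axis=0)))
                if d <= criteria.pication_max:
                    record("pication", res, d, lnames, rg)

        # --- halogen bonds ---
        for a_at in acceptors:
            for j in lig_halogens:
                d = float(np.linalg.norm(a_at.coords - lig_coords[j]))
                if d <= criteria.halogen_max:
                    record("halogen", res, d, (lig_heavy[j].name,), (a_at.name,))

    records = sorted(best.values(),
                     key=lambda r: (r.residue_id[:3], r.kind, r.distance))
    return records


def interaction_probability(
    frames: TrajectoryEnsemble,
    receptor: Structure,
    ligand: Residue | Sequence[Residue],
    criteria: GeometricCriteria | None = None,
    ligand_chemistry: LigandChemistry | None = None,
) -> InteractionProbabilityTable:
    """Fraction of frames in which each (residue, kind) contact occurs.

    The receptor/ligand arguments identify the atom subsets inside the
    ensemble's topology; coordinates are taken from each frame.
    """
    topo = frames.topology
    idx = topo.atom_index_map()
    lig_residues = [ligand] if isinstance(ligand, Residue) else list(ligand)

    counts: dict[tuple, int] = {}
    n = frames.frame_count
    for f in range(n):
        xyz = frames.frames[f]
        rec_f = _with_frame_coords(receptor, idx, xyz)
        lig_f = [_residue_with_coords(r, idx, xyz) for r in lig_residues]
        for rec in detect_interactions(rec_f, lig_f, criteria, ligand_chemistry):
            key = (rec.residue_id, rec.kind)
            counts[key] = counts.get(key, 0) + 1
    entries = {k: v / n for k, v in counts.items()}
    return InteractionProbabilityTable(entries=entries, frame_count=n)


def _residue_with_coords(r: Residue, idx, xyz) -> Residue:
    from dataclasses import replace
    atoms = [replace(a, coords=xyz[idx[(r.chain, r.resseq, r.icode, a.name)]].copy())
             for a in r.atoms]
    return Residue(r.chain, r.resseq, r.icode, r.resname, atoms, r.model)


def _with_frame_coords(s: Structure, idx, xyz) -> Structure:
    return Structure(
        id=s.id,
        residues=[_residue_with_coords(r, idx, xyz) for r in s.residues],
        models=1,
    )


def interactions_to_rows(records: Iterable[InteractionRecord]) -> list[dict]:
    """Flatten records for TSV export."""
    return [
        {
            "kind": r.kind,
            "chain": r.residue_id[0],
            "resseq": r.residue_id[1],
            "icode": r.residue_id[2],
            "resname": r.residue_id[3],
            "distance": round(r.distance, 3),
            "angle": round(r.angle, 1) if r.angle is not None else "",
            "ligand_atoms": ",".join(r.ligand_atoms),
            "receptor_atoms": ",".join(r.receptor_atoms),
        }
        for r in records
    ]
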