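"""Seeded synthetic fixtures: pseudo-protein complexes, decoy databases
with planted motifs, clustered trajectories and annotation universes.

The generators are pure functions of their parameters, so every pipeline
stage is testable offline with known ground truth.  Pseudo-proteins are
built from idealized side-chain templates oriented toward designed contact
points; a small rigid ligand is placed so that salt-bridge, hydrophobic and
hydrogen-bond contacts exist at 90% of their detection thresholds.  Decoy
structures embed rigid (optionally mirrored, jittered) copies of a query
motif among filler residues whose types never occur in the motif, so the
planted correspondences are the only full-size matches possible under
identity type equivalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationTable
from .interactions import LigandChemistry
from .motif_builder import Motif
from .residue_data import FUNCTIONAL_ATOMS, TEMPLATES, atom_element
from .structure_io import Atom, Residue, Structure, TrajectoryEnsemble, combine

__all__ = [
    "FixtureSpec",
    "ComplexFixture",
    "make_complex",
    "make_trajectory",
    "make_decoy_db",
    "make_annotations",
    "write_decoy_db",
]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_decoys: int = 50
    planted_fraction: float = 0.5
    jitter_sigma: float = 0.3
    mirror_fraction: float = 0.0
    # trajectory parameters
    k_true: int = 3
    frames_per_cluster: int = 20
    cluster_displacement: float = 6.0
    noise_sigma: float = 0.3
    # annotation parameters
    annotation_N: int = 1000
    annotation_terms: int = 100
    enriched_term_K: int = 50
    enrichment_factor: float = 8.0
    hit_list_size: int = 50

    def __post_init__(self) -> None:
        if not (0.0 <= self.planted_fraction <= 1.0
                and 0.0 <= self.mirror_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_decoys, self.k_true, self.frames_per_cluster) < 0:
            raise ValueError("counts must be non-negative")


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        return np.eye(3)
    x, y, z = axis / n
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def _align_x_to(d: np.ndarray, roll: float = 0.0) -> np.ndarray:
    """Rotation mapping the +x axis to unit vector d, then rolled about d."""
    d = np.asarray(d, dtype=float)
    d = d / np.linalg.norm(d)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, d)
    c = float(np.dot(x, d))
    if np.linalg.norm(v) < 1e-12:
        base = np.eye(3) if c > 0 else _rotation([0.0, 0.0, 1.0], math.pi)
    else:
        base = _rotation(v, math.acos(max(-1.0, min(1.0, c))))
    return _rotation(d, roll) @ base


def place_residue(
    resname: str,
    chain: str,
    resseq: int,
    target_point: np.ndarray,
    direction: np.ndarray,
    roll: float = 0.0,
) -> Residue:
    """Build a template residue with its functional centroid at a point.

    ``direction`` is the side-chain axis, pointing from CA toward the
    functional centroid (i.e. toward the ligand for a pocket residue).
    """
    t = TEMPLATES[resname]
    f_local = np.mean([t[n] for n in FUNCTIONAL_ATOMS[resname]], axis=0)
    R = _align_x_to(direction, roll)
    atoms = []
    for i, (name, local) in enumerate(t.items()):
        pos = R @ (local - f_local) + np.asarray(target_point, dtype=float)
        atoms.append(Atom(serial=i + 1, name=name, element=atom_element(name),
                          altloc="", occupancy=1.0, coords=pos))
    return Residue(chain, resseq, "", resname, atoms)


def place_residue_at_ca(
    resname: str,
    chain: str,
    resseq: int,
    ca_point: np.ndarray,
    direction: np.ndarray,
    roll: float = 0.0,
) -> Residue:
    """Build a template residue with CA at a point, side chain along ``direction``."""
    t = TEMPLATES[resname]
    R = _align_x_to(direction, roll)
    atoms = []
    for i, (name, local) in enumerate(t.items()):
        pos = R @ local + np.asarray(ca_point, dtype=float)
        atoms.append(Atom(serial=i + 1, name=name, element=atom_element(name),
                          altloc="", occupancy=1.0, coords=pos))
    return Residue(chain, resseq, "", resname, atoms)


def _make_ligand() -> tuple[Residue, LigandChemistry]:
    """Small rigid cationic ligand: tertiary ammonium, apolar tail, one O."""
    pos = {
        "N1": (0.00, 0.00, 0.00),
        "C1": (1.47, 0.00, 0.00),
        "C2": (-0.74, 1.27, 0.00),
        "C3": (-0.74, -1.27, 0.00),
        "C4": (2.21, 1.27, 0.00),
        "C5": (3.68, 1.27, 0.00),
        "O1": (-1.46, -2.51, 0.00),
    }
    atoms = [Atom(serial=i + 1, name=n, element=n[0], altloc="", occupancy=1.0,
                  coords=np.array(p)) for i, (n, p) in enumerate(pos.items())]
    lig = Residue("L", 1, "", "LIG", atoms)
    chem = LigandChemistry(cation_groups=(("N1",),))
    return lig, chem


# pocket design: (resname, resseq, ligand anchor atom, outward direction,
# distance from anchor to the residue's functional centroid)
_POCKET_PLAN = (
    ("GLU", 10, "N1", (0.0, 0.0, 1.0), 4.95),      # salt bridge, 0.9 x 5.5
    ("PHE", 20, "C5", (1.0, 0.0, 0.0), 4.99),      # hydrophobic via ring apex
    ("VAL", 30, "C4", (0.0, 1.0, 0.0), 3.40),      # hydrophobic via CG1/CG2
    ("SER", 40, "O1", (-0.5, -0.85, 0.0), 3.69),   # hbond donor OG, 0.9 x 4.1
    ("TRP", 50, "C5", (0.35, 0.0, -1.0), 5.10),    # hydrophobic via ring
)

_FILLER_TYPES = ("ALA", "GLY", "THR", "LYS", "ASN", "LEU")


@dataclass
class ComplexFixture:
    receptor: Structure
    ligand: Residue
    chemistry: LigandChemistry
    complex: Structure
    pocket_ids: tuple[tuple[str, int, str], ...]


def make_complex(seed: int = 0, n_fillers: int = 18) -> ComplexFixture:
    """Compact pseudo-protein + rigid ligand with designed contacts.

    Contacts are constructed at 90% of the default detection thresholds:
    one salt bridge (Glu carboxylate vs the ligand ammonium), hydrophobic
    contacts (Phe/Trp ring carbons and Val methyls vs the ligand's apolar
    tail) and one hydrogen bond (Ser OG donor vs the ligand oxygen).
    Filler residues sit on a shell >= 14 Å from the ligand.
    """
    rng = np.random.default_rng(seed)
    ligand, chem = _make_ligand()
    anchor = {a.name: a.coords for a in ligand.atoms}

    residues: list[Residue] = []
    for resname, resseq, anchor_name, outward, dist in _POCKET_PLAN:
        outward = np.asarray(outward, dtype=float)
        outward = outward / np.linalg.norm(outward)
        target = anchor[anchor_name] + dist * outward
        roll = float(rng.uniform(0.0, 2.0 * math.pi))
        residues.append(place_residue(resname, "A", resseq, target, -outward, roll))

    # filler shell on a golden spiral, side chains pointing outward
    center = np.array([1.0, 0.0, 0.0])
    for i in range(n_fillers):
        phi = math.pi * (3.0 - math.sqrt(5.0)) * (i + 0.5)
        z = 1.0 - 2.0 * (i + 0.5) / n_fillers
        r = math.sqrt(max(0.0, 1.0 - z * z))
        d = np.array([r * math.cos(phi), r * math.sin(phi), z])
        radius = 20.0 + float(rng.uniform(0.0, 2.0))
        resname = _FILLER_TYPES[i % len(_FILLER_TYPES)]
        residues.append(
            place_residue_at_ca(resname, "A", 100 + i, center + radius * d, d,
                                roll=float(rng.uniform(0.0, 2.0 * math.pi)))
        )

    receptor = Structure(id=f"fixture_complex_{seed}", residues=residues)
    cx = combine(receptor, [ligand], id=f"fixture_complex_{seed}")
    return ComplexFixture(
        receptor=receptor,
        ligand=ligand,
        chemistry=chem,
        complex=cx,
        pocket_ids=tuple(("A", rs, "") for _, rs, *_ in _POCKET_PLAN),
    )


def make_trajectory(
    spec: FixtureSpec,
    fixture: ComplexFixture | None = None,
) -> tuple[TrajectoryEnsemble, np.ndarray, ComplexFixture]:
    """Ensemble with ``k_true`` ligand placements plus Gaussian noise.

    Cluster c displaces the ligand along a distinct axis by
    ``cluster_displacement`` Å (cluster 0 keeps the bound placement); every
    frame then receives i.i.d. Gaussian coordinate noise of ``noise_sigma``.
    Returns (ensemble, true frame labels, underlying complex fixture).
    """
    if spec.k_true < 1:
        raise ValueError("k_true must be >= 1")
    fixture = fixture or make_complex(spec.seed)
    rng = np.random.default_rng(spec.seed + 1)
    topo = fixture.complex
    base = topo.coords()
    idx = topo.atom_index_map()
    lig_idx = [idx[(fixture.ligand.chain, fixture.ligand.resseq, "", a.name)]
               for a in fixture.ligand.atoms]

    dirs = np.array([
        [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, -1],
        [-1, 0, 0], [0, -1, 0], [1, 1, 0], [1, -1, 0],
        [1, 0, 1], [0, 1, 1], [-1, 1, 0], [1, 1, 1],
    ], dtype=float)
    dirs[1:] /= np.linalg.norm(dirs[1:], axis=1, keepdims=True)
    if spec.k_true > len(dirs):
        raise ValueError(f"k_true capped at {len(dirs)}")

    frames = []
    labels = []
    for c in range(spec.k_true):
        conf = base.copy()
        conf[lig_idx] += dirs[c] * spec.cluster_displacement
        for _ in range(spec.frames_per_cluster):
            frames.append(conf + rng.normal(0.0, spec.noise_sigma, size=conf.shape))
            labels.append(c)
    ens = TrajectoryEnsemble(topology=topo, frames=np.array(frames))
    return ens, np.array(labels), fixture


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _transform_residue(r: Residue, fn, chain: str, resseq: int) -> Residue:
    atoms = [Atom(serial=a.serial, name=a.name, element=a.element, altloc="",
                  occupancy=1.0, coords=fn(a.coords)) for a in r.atoms]
    return Residue(chain, resseq, "", r.resname, atoms)


@dataclass
class DecoyDatabase:
    structures: list[Structure]
    truth: pd.DataFrame  # target_id, planted, mirrored
    correspondences: dict[str, dict[tuple, tuple]]  # target_id -> query->target ids


def make_decoy_db(spec: FixtureSpec, motif: Motif) -> DecoyDatabase:
    """Decoy structures, a fraction carrying a planted copy of the motif.

    Planted decoys embed a rigidly rotated/translated (``mirror_fraction``
    of them mirrored) copy of the motif with per-coordinate Gaussian jitter
    ``jitter_sigma``; the rest carry a type-shuffled copy whose residue
    types are drawn from outside the motif, so they can never produce a
    full-size match under identity type equivalence.  Filler residues also
    avoid motif types.  The truth table records planted files and the
    planted query->target correspondences.
    """
    if not motif.matchable:
        raise ValueError("motif must be matchable (>= 3 residues)")
    rng = np.random.default_rng(spec.seed + 2)
    motif_types = {r.resname for r in motif.residues}
    filler_pool = [t for t in sorted(TEMPLATES) if t not in motif_types]

    n_planted = int(round(spec.n_decoys * spec.planted_fraction))
    planted_flags = np.zeros(spec.n_decoys, dtype=bool)
    planted_flags[:n_planted] = True
    rng.shuffle(planted_flags)
    n_mirror = int(round(n_planted * spec.mirror_fraction))
    mirror_pool = [i for i in range(spec.n_decoys) if planted_flags[i]]
    mirror_flags = np.zeros(spec.n_decoys, dtype=bool)
    for i in mirror_pool[:n_mirror]:
        mirror_flags[i] = True

    structures: list[Structure] = []
    rows = []
    correspondences: dict[str, dict[tuple, tuple]] = {}
    mcenter = motif.center()

    for d in range(spec.n_decoys):
        target_id = f"decoy_{d:04d}"
        residues: list[Residue] = []

        # filler coil: outward-pointing residues on a jittered shell
        n_fill = int(rng.integers(16, 25))
        for i in range(n_fill):
            phi = math.pi * (3.0 - math.sqrt(5.0)) * (i + 0.5)
            z = 1.0 - 2.0 * (i + 0.5) / n_fill
            r = math.sqrt(max(0.0, 1.0 - z * z))
            dvec = np.array([r * math.cos(phi), r * math.sin(phi), z])
            radius = 8.0 + float(rng.uniform(0.0, 3.0))
            resname = filler_pool[int(rng.integers(len(filler_pool)))]
            residues.append(
                place_residue_at_ca(resname, "A", 100 + i, radius * dvec, dvec,
                                    roll=float(rng.uniform(0.0, 2.0 * math.pi)))
            )

        # embedded copy of the motif, exposed well outside the filler shell
        R = _random_rotation(rng)
        mirror = bool(mirror_flags[d])
        M = np.diag([-1.0, 1.0, 1.0]) if mirror else np.eye(3)
        shift = np.array([38.0, 0.0, 0.0]) + rng.uniform(-2.0, 2.0, size=3)

        corr: dict[tuple, tuple] = {}
        for j, qres in enumerate(motif.residues):
            resseq = 500 + j
            if planted_flags[d]:
                def fn(c, R=R, M=M, shift=shift):
                    return R @ (M @ (c - mcenter)) + shift + \
                        rng.normal(0.0, spec.jitter_sigma, size=3)
                residues.append(_transform_residue(qres, fn, "A", resseq))
                corr[qres.id] = ("A", resseq, "")
            else:
                # geometry preserved, type replaced by a non-motif type
                newtype = filler_pool[int(rng.integers(len(filler_pool)))]
                vec = np.mean([qres.atom(n).coords
                               for n in FUNCTIONAL_ATOMS[qres.resname]], axis=0)
                target = R @ (M @ (vec - mcenter)) + shift
                ca = qres.atom("CA").coords
                dvec = R @ (M @ (vec - ca))
                nrm = np.linalg.norm(dvec)
                dvec = dvec / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
                residues.append(
                    place_residue(newtype, "A", resseq, target, dvec,
                                  roll=float(rng.uniform(0.0, 2.0 * math.pi)))
                )

        structures.append(Structure(id=target_id, residues=residues))
        rows.append({"target_id": target_id, "planted": bool(planted_flags[d]),
                     "mirrored": mirror})
        if planted_flags[d]:
            correspondences[target_id] = corr

    return DecoyDatabase(
        structures=structures,
        truth=pd.DataFrame(rows),
        correspondences=correspondences,
    )


def write_decoy_db(db: DecoyDatabase, out_dir: str | Path) -> Path:
    """Write one PDB per decoy plus ``truth.tsv`` into a folder."""
    from .structure_io import write_structure

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in db.structures:
        write_structure(s, out_dir / f"{s.id}.pdb")
    db.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return out_dir


def make_annotations(
    spec: FixtureSpec,
    hit_accessions: Sequence[str] | None = None,
) -> tuple[AnnotationTable, list[str], str]:
    """Annotation universe with one designed over-represented term.

    Returns (table, hit list, enriched term).  When ``hit_accessions`` is
    given the designated term is built around it; otherwise a hit list of
    ``hit_list_size`` accessions is drawn with the enriched term's members
    over-represented by ``enrichment_factor`` relative to chance.
    """
    rng = np.random.default_rng(spec.seed + 3)
    N = spec.annotation_N
    universe = [f"ACC{i:05d}" for i in range(N)]
    if hit_accessions is not None:
        # external accessions join the background universe
        universe = sorted(set(universe) | set(hit_accessions))
        N = len(universe)
    uni_arr = np.array(universe)

    term_members: dict[str, frozenset] = {}
    term_ns: dict[str, str] = {}
    namespaces = ("BP", "MF", "CC")
    for t in range(spec.annotation_terms):
        name = f"T{t:04d}"
        K = int(rng.integers(20, 80))
        members = rng.choice(N, size=K, replace=False)
        term_members[name] = frozenset(uni_arr[members])
        term_ns[name] = namespaces[t % len(namespaces)]

    enriched = "T_ENRICHED"
    if hit_accessions is not None:
        hits = list(dict.fromkeys(hit_accessions))
        extra = spec.enriched_term_K - len(hits)
        others = [a for a in universe if a not in set(hits)]
        pad = list(rng.choice(len(others), size=max(extra, 0), replace=False))
        term_members[enriched] = frozenset(hits) | {others[i] for i in pad}
        term_ns[enriched] = "BP"
    else:
        K = spec.enriched_term_K
        members = uni_arr[rng.choice(N, size=K, replace=False)]
        term_members[enriched] = frozenset(members)
        term_ns[enriched] = "BP"
        n = spec.hit_list_size
        base_rate = K / N
        k = min(K, n, int(round(spec.enrichment_factor * base_rate * n)))
        hit_members = list(rng.choice(sorted(term_members[enriched]), size=k,
                                      replace=False))
        rest_pool = sorted(set(universe) - term_members[enriched])
        rest = list(np.array(rest_pool)[rng.choice(len(rest_pool), size=n - k,
                                                   replace=False)])
        hits = hit_members + rest

    table = AnnotationTable(
        universe=frozenset(universe),
        term_members=term_members,
        term_namespace=term_ns,
    )
    return table, list(hits), enriched
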