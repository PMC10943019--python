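"""Pseudo-atom vector graphs and clique-based amino-acid pattern matching.

Each residue is summarised by a directed segment: start S at CB (CA for
glycine), end E at the centroid of the side chain's functional atoms, and
midpoint M.  A residue pattern becomes a complete graph whose edges carry
the five inter-vector distances SS, SE, ES, EE and MM.  Matching a query
pattern against a target structure builds the association (correspondence)
graph — vertices are type-compatible (query, target) residue pairs, edges
connect pairs whose selected distance components agree within a tolerance —
and enumerates its maximal cliques with the Bron-Kerbosch algorithm.  A
full-size clique is a geometric match; its quality is the RMSD of the
paired (S, E) pseudo-atoms after least-squares superposition, computed for
both proper and mirror-image fits because pure distance matching cannot see
chirality.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .residue_data import FUNCTIONAL_ATOMS, STANDARD_AA
from .structure_io import Residue, Structure

__all__ = [
    "PseudoAtomVector",
    "SiteGraph",
    "MatchParams",
    "MatchHit",
    "NodeConstructionError",
    "ComplexityGuardError",
    "node_vectors",
    "build_graph",
    "association_graph",
    "find_cliques",
    "superpose",
    "match_sites",
]

ALL_COMPONENTS = ("SS", "SE", "ES", "EE", "MM")


class NodeConstructionError(ValueError):
    """A residue lacks the atoms needed for its pseudo-atom vector."""


class ComplexityGuardError(RuntimeError):
    """Association graph exceeded the configured vertex cap."""


@dataclass(frozen=True)
class PseudoAtomVector:
    S: np.ndarray
    E: np.ndarray
    M: np.ndarray
    residue_id: tuple[str, int, str]
    restype: str

    def point(self, which: str) -> np.ndarray:
        return {"S": self.S, "E": self.E, "M": self.M}[which]


@dataclass
class SiteGraph:
    nodes: list[PseudoAtomVector]

    def distance(self, component: str, i: int, j: int) -> float:
        a, b = component[0], component[1]
        return float(np.linalg.norm(self.nodes[i].point(a) - self.nodes[j].point(b)))

    def edge(self, i: int, j: int) -> tuple[float, float, float, float, float]:
        return tuple(self.distance(c, i, j) for c in ALL_COMPONENTS)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def diameter(self) -> float:
        pts = np.concatenate([[n.S, n.E] for n in self.nodes])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return float(d.max())


@dataclass(frozen=True)
class MatchParams:
    tol: float = 1.5
    components: tuple[str, ...] = ALL_COMPONENTS
    equivalence: Mapping[str, frozenset[str]] | None = None
    min_nodes: int = 3
    min_match_fraction: float = 1.0
    allow_reflection: bool = True
    max_vertices: int = 20000
    prune: bool = True

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not self.components or any(c not in ALL_COMPONENTS for c in self.components):
            raise ValueError(f"components must be a non-empty subset of {ALL_COMPONENTS}")

    def compatible(self, qtype: str, ttype: str) -> bool:
        if self.equivalence is None:
            return qtype == ttype
        return ttype in self.equivalence.get(qtype, frozenset({qtype}))


@dataclass
class MatchHit:
    target_id: str
    motif_index: int
    correspondence: dict[tuple[str, int, str], tuple[str, int, str]]
    rmsd: float
    reflected: bool
    target_residues: tuple[tuple[str, int, str], ...]


def node_vectors(residue: Residue) -> PseudoAtomVector:
    """Pseudo-atom vector of one standard residue.

    S = CB (CA for glycine); E = centroid of the residue's functional-atom
    set; M = (S + E) / 2.  Glycine's degenerate S = E = M = CA is allowed.
    """
    if residue.resname not in STANDARD_AA:
        raise NodeConstructionError(
            f"residue {residue.resname} {residue.id} is not a standard amino acid"
        )
    start_name = "CA" if residue.resname == "GLY" else "CB"
    try:
        S = residue.atom(start_name).coords.astype(float)
        func = FUNCTIONAL_ATOMS[residue.resname]
        E = np.mean([residue.atom(n).coords for n in func], axis=0)
    except KeyError as exc:
        raise NodeConstructionError(
            f"residue {residue.resname} {residue.id}: {exc.args[0]}"
        ) from None
    return PseudoAtomVector(S=S, E=E.astype(float), M=(S + E) / 2.0,
                            residue_id=residue.id, restype=residue.resname)


def build_graph(residues: Sequence[Residue]) -> SiteGraph:
    """Complete pseudo-atom vector graph over the given residues."""
    if len(residues) < 2:
        raise ValueError("a site graph needs at least 2 residues")
    return SiteGraph(nodes=[node_vectors(r) for r in residues])


@dataclass
class AssociationGraph:
    """Correspondence graph between a query and a target site graph."""

    vertices: list[tuple[int, int]]  # (query node, target node)
    adjacency: list[set[int]]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


def association_graph(
    Q: SiteGraph,
    T: SiteGraph,
    tol: float = 1.5,
    components: Sequence[str] = ALL_COMPONENTS,
    equivalence: Mapping[str, frozenset[str]] | None = None,
    max_vertices: int | None = None,
) -> AssociationGraph:
    """Vertices: type-compatible (q, t) pairs; edges: consistent geometry.

    Two vertices (q1, t1), (q2, t2) are joined iff q1 != q2, t1 != t2 and
    |d_c(q1, q2) - d_c(t1, t2)| <= tol for every selected component c, with
    SE/ES compared respecting pair orientation.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    components = tuple(components)
    params = MatchParams(tol=tol, components=components, equivalence=equivalence)

    vertices = [
        (q, t)
        for q in range(Q.n_nodes)
        for t in range(T.n_nodes)
        if params.compatible(Q.nodes[q].restype, T.nodes[t].restype)
    ]
    if max_vertices is not None and len(vertices) > max_vertices:
        raise ComplexityGuardError(
            f"association graph has {len(vertices)} vertices (cap {max_vertices}); "
            "reduce the tolerance or restrict the residue-equivalence map"
        )
    nv = len(vertices)
    adjacency: list[set[int]] = [set() for _ in range(nv)]
    for i in range(nv):
        q1, t1 = vertices[i]
        for j in range(i + 1, nv):
            q2, t2 = vertices[j]
            if q1 == q2 or t1 == t2:
                continue
            ok = True
            for c in components:
                if abs(Q.distance(c, q1, q2) - T.distance(c, t1, t2)) > tol:
                    ok = False
                    break
            if ok:
                adjacency[i].add(j)
                adjacency[j].add(i)
    return AssociationGraph(vertices=vertices, adjacency=adjacency)


def _bron_kerbosch(adj: list[set[int]], R: set[int], P: set[int], X: set[int],
                   out: list[frozenset[int]]) -> None:
    if not P and not X:
        out.append(frozenset(R))
        return
    # pivot with the most neighbours in P (smallest index on ties)
    pivot = max(sorted(P | X), key=lambda u: len(adj[u] & P))
    for v in sorted(P - adj[pivot]):
        _bron_kerbosch(adj, R | {v}, P & adj[v], X & adj[v], out)
        P = P - {v}
        X = X | {v}


def find_cliques(graph: AssociationGraph, min_size: int = 3,
                 max_vertices: int | None = 20000) -> list[tuple[int, ...]]:
    """All maximal cliques of size >= min_size via Bron-Kerbosch with pivot.

    Output is deterministic: sorted by size (descending) then
    lexicographically by vertex indices.
    """
    if min_size < 3:
        raise ValueError("min_size must be >= 3")
    nv = graph.n_vertices
    if max_vertices is not None and nv > max_vertices:
        raise ComplexityGuardError(
            f"association graph has {nv} vertices (cap {max_vertices}); "
            "reduce the matching tolerance"
        )
    if nv == 0:
        return []
    out: list[frozenset[int]] = []
    _bron_kerbosch(graph.adjacency, set(), set(range(nv)), set(), out)
    cliques = [tuple(sorted(c)) for c in out if len(c) >= min_size]
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def _kcore_reduce(graph: AssociationGraph, min_size: int) -> AssociationGraph:
    """Remove vertices of degree < min_size - 1 iteratively.

    Every clique of size >= min_size lies inside the (min_size-1)-core, so
    the reduction is exact for full-size matches.
    """
    alive = set(range(graph.n_vertices))
    changed = True
    while changed:
        changed = False
        for v in sorted(alive):
            if len(graph.adjacency[v] & alive) < min_size - 1:
                alive.discard(v)
                changed = True
    keep = sorted(alive)
    remap = {v: i for i, v in enumerate(keep)}
    return AssociationGraph(
        vertices=[graph.vertices[v] for v in keep],
        adjacency=[{remap[u] for u in graph.adjacency[v] if u in alive} for v in keep],
    )


def superpose(P: np.ndarray, Q: np.ndarray,
              allow_reflection: bool = False) -> tuple[float, bool]:
    """Least-squares rigid superposition RMSD of paired points.

    Uses the Kabsch algorithm with determinant correction to a proper
    rotation.  With ``allow_reflection`` the improper (mirror) fit is also
    evaluated and the better RMSD is reported with ``reflected=True`` when
    the mirror fit wins.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("at least 3 point pairs are required")

    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, sv, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt)) or 1.0
    norm2 = (P0 ** 2).sum() + (Q0 ** 2).sum()
    n = P.shape[0]

    def rmsd_for(det_sign: float) -> float:
        s = sv.copy()
        s[-1] *= det_sign
        e = max(norm2 - 2.0 * s.sum(), 0.0)
        return float(np.sqrt(e / n))

    proper = rmsd_for(d if d != 0 else 1.0)
    if not allow_reflection:
        return proper, False
    improper = rmsd_for(-d)
    if improper < proper - 1e-12:
        return improper, True
    return proper, False


def superpose_transform(
    P: np.ndarray, Q: np.ndarray, allow_reflection: bool = False
) -> tuple[float, bool, np.ndarray, np.ndarray]:
    """Superposition returning the optimal map x -> (x - mean(P)) @ R + mean(Q).

    Returns (rmsd, reflected, R, t) with t chosen so that ``P @ R + t``
    best fits Q; R is a proper rotation unless ``allow_reflection`` selects
    the better improper (mirror) fit.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    rmsd, reflected = superpose(P, Q, allow_reflection=allow_reflection)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt)) or 1.0
    sign = -d if reflected else d
    R = U @ np.diag([1.0, 1.0, sign]) @ Vt
    return rmsd, reflected, R, qc - pc @ R


def match_sites(
    motifs: Sequence["object"],
    target: Structure,
    params: MatchParams | None = None,
) -> list[MatchHit]:
    """Match each motif's pseudo-atom graph against a target structure.

    Only full-size cliques (every query node matched, or the configured
    fraction) become hits; per (target, motif) the lowest-RMSD hit is kept.
    Hits are sorted by RMSD.
    """
    from .motif_builder import Motif  # local import to avoid a cycle

    params = params or MatchParams()
    target_res = []
    for r in target.residues:
        if r.resname not in STANDARD_AA:
            continue
        try:
            node_vectors(r)
        except NodeConstructionError:
            continue
        target_res.append(r)
    if len(target_res) < 2:
        return []
    T = build_graph(target_res)

    hits: list[MatchHit] = []
    for m_idx, motif in enumerate(motifs):
        residues = motif.as_residues() if isinstance(motif, Motif) else list(motif)
        if len(residues) < params.min_nodes:
            continue
        Q = build_graph(residues)
        need = max(params.min_nodes,
                   int(np.ceil(params.min_match_fraction * Q.n_nodes)))
        ag = association_graph(Q, T, tol=params.tol, components=params.components,
                               equivalence=params.equivalence,
                               max_vertices=params.max_vertices)
        if params.prune:
            ag = _kcore_reduce(ag, need)
        cliques = find_cliques(ag, min_size=max(3, need),
                               max_vertices=params.max_vertices)
        best: MatchHit | None = None
        for clique in cliques:
            pairs = [ag.vertices[v] for v in clique]
            qs = [q for q, _ in pairs]
            if len(set(qs)) < need:
                continue
            P_pts, T_pts = [], []
            for q, t in pairs:
                P_pts.extend([Q.nodes[q].S, Q.nodes[q].E])
                T_pts.extend([T.nodes[t].S, T.nodes[t].E])
            rmsd, reflected = superpose(np.array(P_pts), np.array(T_pts),
                                        allow_reflection=params.allow_reflection)
            corr = {Q.nodes[q].residue_id: T.nodes[t].residue_id for q, t in pairs}
            hit = MatchHit(
                target_id=target.id,
                motif_index=m_idx,
                correspondence=corr,
                rmsd=rmsd,
                reflected=reflected,
                target_residues=tuple(sorted(T.nodes[t].residue_id for _, t in pairs)),
            )
            if best is None or hit.rmsd < best.rmsd:
                best = hit
        if best is not None:
            hits.append(best)
    hits.sort(key=lambda h: (h.rmsd, h.motif_index))
    return hits
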