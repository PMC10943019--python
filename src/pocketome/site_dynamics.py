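"""Binding-site definition and conformational clustering of an ensemble.

The binding site is the union over frames of receptor residues with any
heavy atom within a distance cutoff (default 10 Å) of any ligand heavy
atom.  Each frame is rigid-body superposed onto the first frame on the
site's backbone atoms, the ligand+site heavy-atom coordinates are flattened
into a feature row, and frames are clustered with seeded k-means.  The
number of clusters is chosen by the mean silhouette coefficient
s = (b - a) / max(a, b), scanned from 2 to 12 clusters; the frame nearest
each cluster mean is kept as that cluster's centroid conformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .residue_data import BACKBONE_ATOMS
from .structure_io import Residue, Structure, TrajectoryEnsemble

__all__ = [
    "BindingSiteSelection",
    "FeatureMatrix",
    "ClusterModel",
    "EmptySiteError",
    "extract_binding_site",
    "featurize",
    "kmeans",
    "silhouette",
    "select_k",
    "centroid_frames",
]


class EmptySiteError(ValueError):
    """No residue falls within the cutoff of the ligand."""


@dataclass
class BindingSiteSelection:
    residue_ids: frozenset  # of (chain, resseq, icode)
    cutoff: float

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    def sorted_ids(self) -> list[tuple[str, int, str]]:
        return sorted(self.residue_ids)


@dataclass
class FeatureMatrix:
    X: np.ndarray  # (n_frames, n_features)
    frame_index: list[int]
    atom_labels: list[tuple]  # provenance of each coordinate triple

    @property
    def n_frames(self) -> int:
        return int(self.X.shape[0])


@dataclass
class ClusterModel:
    k: int
    labels: np.ndarray
    means: np.ndarray
    inertia: float
    silhouette: float
    seed: int


def _heavy_indices(topology: Structure, residues, idx) -> list[int]:
    out = []
    for r in residues:
        for a in r.atoms:
            if a.is_heavy:
                out.append(idx[(r.chain, r.resseq, r.icode, a.name)])
    return out


def extract_binding_site(
    frames: TrajectoryEnsemble,
    receptor: Structure,
    ligand: Residue | list[Residue],
    cutoff: float = 10.0,
) -> BindingSiteSelection:
    """Residues with a heavy atom within ``cutoff`` of the ligand in >=1 frame."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_residues = [ligand] if isinstance(ligand, Residue) else list(ligand)
    idx = frames.topology.atom_index_map()
    lig_idx = _heavy_indices(frames.topology, lig_residues, idx)
    if not lig_idx:
        raise ValueError("ligand has no heavy atoms")

    res_idx = {r.id: _heavy_indices(frames.topology, [r], idx)
               for r in receptor.residues}

    included: set[tuple] = set()
    for f in range(frames.frame_count):
        xyz = frames.frames[f]
        tree = cKDTree(xyz[lig_idx])
        for rid, ai in res_idx.items():
            if rid in included or not ai:
                continue
            d, _ = tree.query(xyz[ai], k=1)
            if float(np.min(d)) <= cutoff:
                included.add(rid)
    if not included:
        raise EmptySiteError(
            f"no receptor residue within {cutoff} Å of the ligand in any frame; "
            "consider a larger cutoff"
        )
    return BindingSiteSelection(residue_ids=frozenset(included), cutoff=cutoff)


def _kabsch_transform(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimising |P@R + t - Q|."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return R, qc - pc @ R


def featurize(
    frames: TrajectoryEnsemble,
    sel: BindingSiteSelection,
    ligand: Residue | list[Residue],
) -> FeatureMatrix:
    """Superposed, flattened heavy-atom coordinates of ligand + site.

    Every frame is superposed onto frame 0 using the site residues'
    backbone (N, CA, C, O) atoms, then the ligand heavy atoms followed by
    the site residues' heavy atoms (residues in (chain, resseq, icode)
    order, atoms in topology order) are concatenated into one row.
    """
    topo = frames.topology
    idx = topo.atom_index_map()
    lig_residues = [ligand] if isinstance(ligand, Residue) else list(ligand)

    site_res = sorted(
        (r for r in topo.residues if r.id in sel.residue_ids),
        key=lambda r: r.id,
    )
    if not site_res:
        raise EmptySiteError("binding-site selection matches no topology residue")

    bb_idx = [idx[(r.chain, r.resseq, r.icode, n)]
              for r in site_res for n in BACKBONE_ATOMS if r.has_atom(n)]
    feat_idx = _heavy_indices(topo, lig_residues, idx) + \
        _heavy_indices(topo, site_res, idx)
    labels = []
    for r in lig_residues + site_res:
        for a in r.atoms:
            if a.is_heavy:
                labels.append((r.chain, r.resseq, r.icode, a.name))

    ref_bb = frames.frames[0][bb_idx]
    rows = np.empty((frames.frame_count, len(feat_idx) * 3))
    for f in range(frames.frame_count):
        xyz = frames.frames[f]
        if bb_idx:
            R, t = _kabsch_transform(xyz[bb_idx], ref_bb)
            moved = xyz[feat_idx] @ R + t
        else:
            moved = xyz[feat_idx]
        rows[f] = moved.reshape(-1)
    return FeatureMatrix(X=rows, frame_index=list(range(frames.frame_count)),
                         atom_labels=labels)


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def _farthest_point(X: np.ndarray, means: np.ndarray) -> int:
    d = cdist(X, means).min(axis=1)
    return int(np.argmax(d))  # argmax takes the lowest index on ties


def kmeans(X, k: int, seed: int = 0, max_iter: int = 300) -> ClusterModel:
    """Seeded Lloyd iterations from k-means++ starts.

    Deterministic for fixed (X, k, seed).  An empty cluster is re-seeded at
    the point farthest from all current means (lowest index on ties).
    """
    X = _as_array(X)
    n = X.shape[0]
    if not (1 < k <= n):
        raise ValueError(f"k={k} must satisfy 1 < k <= n_frames={n}")
    rng = np.random.default_rng(seed)

    # k-means++ initialisation
    means = np.empty((k, X.shape[1]))
    means[0] = X[rng.integers(n)]
    closest = ((X - means[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = closest.sum()
        if total <= 0:
            means[j] = X[int(rng.integers(n))]
        else:
            means[j] = X[rng.choice(n, p=closest / total)]
        closest = np.minimum(closest, ((X - means[j]) ** 2).sum(axis=1))

    labels = np.full(n, -1, dtype=int)
    for _ in range(max_iter):
        d2 = cdist(X, means, metric="sqeuclidean")
        new_labels = d2.argmin(axis=1)
        for j in range(k):
            members = X[new_labels == j]
            if len(members) == 0:
                fp = _farthest_point(X, means)
                means[j] = X[fp]
                new_labels[fp] = j
            else:
                means[j] = members.mean(axis=0)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels

    inertia = float(((X - means[labels]) ** 2).sum())
    sil = silhouette(X, labels) if len(set(labels.tolist())) > 1 else 0.0
    return ClusterModel(k=k, labels=labels, means=means, inertia=inertia,
                        silhouette=sil, seed=seed)


def silhouette(X, labels) -> float:
    """Mean silhouette coefficient s = (b - a) / max(a, b) over samples.

    Samples in singleton clusters score 0; if a == b == 0 the sample also
    scores 0.
    """
    X = _as_array(X)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    D = cdist(X, X)
    n = X.shape[0]
    s = np.zeros(n)
    for i in range(n):
        same = labels == labels[i]
        n_same = int(same.sum())
        if n_same <= 1:
            s[i] = 0.0
            continue
        a = D[i][same].sum() / (n_same - 1)
        b = min(D[i][labels == c].mean() for c in uniq if c != labels[i])
        m = max(a, b)
        s[i] = 0.0 if m == 0 else (b - a) / m
    return float(s.mean())


def select_k(X, kmin: int = 2, kmax: int = 12, seed: int = 0,
             max_iter: int = 300) -> tuple[int, ClusterModel]:
    """Scan k in [kmin, min(kmax, n)] and keep the best mean silhouette.

    Ties go to the smallest k.
    """
    X = _as_array(X)
    n = X.shape[0]
    if n < kmin:
        raise ValueError(f"need at least kmin={kmin} frames, got {n}")
    best: tuple[int, ClusterModel] | None = None
    for k in range(kmin, min(kmax, n) + 1):
        model = kmeans(X, k, seed=seed, max_iter=max_iter)
        if best is None or model.silhouette > best[1].silhouette + 1e-12:
            best = (k, model)
    assert best is not None
    return best


def centroid_frames(X, model: ClusterModel) -> list[int]:
    """Per cluster, the frame nearest its mean (lowest index on ties)."""
    X = _as_array(X)
    out = []
    for j in range(model.k):
        members = np.flatnonzero(model.labels == j)
        d = np.linalg.norm(X[members] - model.means[j], axis=1)
        out.append(int(members[int(np.argmin(d))]))
    return out
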