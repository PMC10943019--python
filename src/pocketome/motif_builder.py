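"""Assembly of binding-site motifs from centroid-frame interactions.

A motif is the subset of binding-site residues that carry at least one
detected non-covalent interaction in one representative (centroid) frame,
with coordinates taken from that frame.  Motifs with fewer than three
residues are kept but flagged unmatchable: a two-node pattern does not
constrain a 3D correspondence search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .interactions import (
    GeometricCriteria,
    InteractionRecord,
    LigandChemistry,
    detect_interactions,
    _residue_with_coords,
    _with_frame_coords,
)
from .structure_io import Residue, Structure, TrajectoryEnsemble, read_structure, write_structure

logger = logging.getLogger(__name__)

__all__ = ["Motif", "MIN_MATCHABLE_RESIDUES", "build_motifs", "write_motif"]

MIN_MATCHABLE_RESIDUES = 3


@dataclass
class Motif:
    centroid_index: int
    residues: list[Residue]
    interactions: list[InteractionRecord]
    label: str = ""

    @property
    def matchable(self) -> bool:
        return len(self.residues) >= MIN_MATCHABLE_RESIDUES

    @property
    def residue_ids(self) -> tuple[tuple[str, int, str], ...]:
        return tuple(r.id for r in self.residues)

    def as_residues(self) -> list[Residue]:
        return self.residues

    def center(self) -> np.ndarray:
        pts = np.concatenate([r.heavy_coords() for r in self.residues])
        return pts.mean(axis=0)

    def diameter(self) -> float:
        pts = np.concatenate([r.heavy_coords() for r in self.residues])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        return float(d.max())


def build_motifs(
    centroids: Sequence[int],
    frames: TrajectoryEnsemble,
    receptor: Structure,
    ligand: Residue | Sequence[Residue],
    criteria: GeometricCriteria | None = None,
    ligand_chemistry: LigandChemistry | None = None,
    site_ids: frozenset | None = None,
) -> list[Motif]:
    """One motif per centroid frame from that frame's interacting residues.

    ``site_ids`` optionally restricts motif residues to a binding-site
    selection.  Empty or sub-minimal motifs are flagged and logged but kept,
    so the pipeline can continue with the remaining motifs.
    """
    if len(centroids) == 0:
        raise ValueError("at least one centroid frame is required")
    idx = frames.topology.atom_index_map()
    lig_residues = [ligand] if isinstance(ligand, Residue) else list(ligand)

    motifs: list[Motif] = []
    for ci in centroids:
        xyz = frames.frames[ci]
        rec_f = _with_frame_coords(receptor, idx, xyz)
        lig_f = [_residue_with_coords(r, idx, xyz) for r in lig_residues]
        records = detect_interactions(rec_f, lig_f, criteria, ligand_chemistry)
        if site_ids is not None:
            records = [r for r in records if r.residue_id[:3] in site_ids]
        wanted = {r.residue_id[:3] for r in records}
        residues = sorted(
            (r for r in rec_f.residues if r.id in wanted),
            key=lambda r: (r.chain, r.resseq, r.icode),
        )
        motif = Motif(
            centroid_index=int(ci),
            residues=residues,
            interactions=records,
            label=f"motif_{len(motifs)}",
        )
        if not motif.matchable:
            logger.warning(
                "motif from centroid frame %d has %d residue(s); "
                "flagged unmatchable", ci, len(residues),
            )
        motifs.append(motif)
    return motifs


def write_motif(m: Motif, path: str | Path) -> Path:
    """Export the motif residues' heavy atoms as a PDB fragment."""
    if not m.residues:
        raise ValueError("cannot export an empty motif")
    frag = Structure(
        id=m.label or "motif",
        residues=[
            Residue(r.chain, r.resseq, r.icode, r.resname, r.heavy_atoms())
            for r in sorted(m.residues, key=lambda r: (r.chain, r.resseq, r.icode))
        ],
    )
    return write_structure(frag, path)


def write_motif_manifest(motifs: Sequence[Motif], path: str | Path) -> Path:
    """TSV manifest: centroid frame, residues and interaction kinds per motif."""
    lines = ["motif\tcentroid_frame\tmatchable\tresidues\tinteraction_kinds"]
    for i, m in enumerate(motifs):
        res = ",".join(f"{c}:{s}{ic}:{rn}" for (c, s, ic), rn in
                       ((r.id, r.resname) for r in m.residues))
        kinds = ",".join(sorted({r.kind for r in m.interactions}))
        lines.append(f"{i}\t{m.centroid_index}\t{int(m.matchable)}\t{res}\t{kinds}")
    p = Path(path)
    p.write_text("\n".join(lines) + "\n")
    return p
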