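"""End-to-end orchestration: motifs -> similarity search -> filters -> enrichment.

The pipeline mirrors a four-step screening workflow: (1) binding-site motif
creation from a complex (and optionally a conformational ensemble), (2)
pseudo-atom graph matching of each motif against every structure in a local
database folder, (3) solvent-accessibility and docking-score filtering of
the hits, and (4) term-enrichment analysis of the surviving unique protein
accessions.  Every stage count is recorded as a screening funnel, and runs
are deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import enrichment as enr
from .filters import (DockingResult, FilterConfig, ScoreWeights, dock_ligand,
                      docking_filter, sasa, sasa_filter)
from .graph_match import (MatchHit, MatchParams, match_sites, node_vectors,
                          superpose_transform)
from .interactions import (GeometricCriteria, LigandChemistry,
                           _residue_with_coords, _with_frame_coords,
                           detect_interactions)
from .motif_builder import Motif, build_motifs, write_motif, write_motif_manifest
from .site_dynamics import (centroid_frames, extract_binding_site, featurize,
                            kmeans, select_k)
from .structure_io import (Structure, TrajectoryEnsemble, clean_structure,
                           read_structure, read_trajectory, split_complex)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "ReportRow", "run_pipeline", "write_report"]

REPORT_COLUMNS = (
    "target_id", "motif_index", "shared_residues", "rmsd", "reflected",
    "sasa_hit", "sasa_query", "sasa_pass", "dscore_hit", "dscore_query_mean",
    "dock_pass", "accession",
)


@dataclass
class PipelineConfig:
    complex_pdb: str | Path
    receptor_chains: str
    ligand_chain: str
    db_dir: str | Path
    trajectory: str | Path | None = None
    mapping_table: str | Path | None = None
    annotation_table: str | Path | None = None
    out_dir: str | Path | None = None
    cutoff: float = 10.0
    k: int | str = "auto"
    kmin: int = 2
    kmax: int = 12
    criteria: GeometricCriteria = field(default_factory=GeometricCriteria)
    ligand_chemistry: LigandChemistry = field(default_factory=LigandChemistry)
    match: MatchParams = field(default_factory=MatchParams)
    filters: FilterConfig = field(default_factory=FilterConfig)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    q_threshold: float = 0.1
    seed: int = 42

    def to_dict(self) -> dict:
        def conv(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: conv(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, Path):
                return str(v)
            if isinstance(v, (tuple, frozenset)):
                return sorted(v) if isinstance(v, frozenset) else list(v)
            return v
        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


@dataclass
class ReportRow:
    target_id: str
    motif_index: int
    shared_residues: str
    rmsd: float
    reflected: bool
    sasa_hit: float
    sasa_query: float
    sasa_pass: bool
    dscore_hit: float
    dscore_query_mean: float
    dock_pass: bool
    accession: str

    @property
    def passed(self) -> bool:
        return self.sasa_pass and self.dock_pass


@dataclass
class PipelineResult:
    rows: list[ReportRow]
    stage_counts: dict[str, int]
    motifs: list[Motif]
    enrichment_rows: list
    accessions: set[str]
    config: PipelineConfig


def _target_seed(base_seed: int, target_id: str) -> int:
    return (base_seed * 1000003 + zlib.crc32(target_id.encode())) % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full screening workflow; see the module docstring."""
    cx = read_structure(config.complex_pdb)
    receptor, ligand = split_complex(cx, config.receptor_chains, config.ligand_chain)

    if config.trajectory is not None:
        ensemble = read_trajectory(cx, config.trajectory)
    else:
        ensemble = TrajectoryEnsemble(topology=cx, frames=cx.coords()[None, :, :])

    site = extract_binding_site(ensemble, receptor, ligand, cutoff=config.cutoff)
    if ensemble.frame_count > 1:
        X = featurize(ensemble, site, ligand)
        if config.k == "auto":
            _, model = select_k(X, kmin=config.kmin, kmax=config.kmax,
                                seed=config.seed)
        else:
            model = kmeans(X, int(config.k), seed=config.seed)
        centroids = centroid_frames(X, model)
        logger.info("clustering: k=%d silhouette=%.3f centroids=%s",
                    model.k, model.silhouette, centroids)
    else:
        centroids = [0]

    motifs = build_motifs(centroids, ensemble, receptor, ligand,
                          config.criteria, config.ligand_chemistry,
                          site_ids=site.residue_ids)
    matchable = [m for m in motifs if m.matchable]
    if not matchable:
        raise RuntimeError(
            "motif creation produced no matchable motif (>= 3 interacting "
            "residues); cannot run the similarity search"
        )

    db_dir = Path(config.db_dir)
    db_files = sorted(p for p in db_dir.glob("*.pdb"))
    if not db_files:
        raise FileNotFoundError(f"database folder {db_dir} contains no .pdb files")

    idx = ensemble.topology.atom_index_map()

    # per-motif query baselines, computed on that motif's centroid frame
    query_sasa: list[float] = []
    query_scores: list[float] = []
    query_lig_coords: list[np.ndarray] = []
    for m_i, m in enumerate(matchable):
        xyz = ensemble.frames[m.centroid_index]
        rec_f = _with_frame_coords(receptor, idx, xyz)
        lig_f = [_residue_with_coords(r, idx, xyz) for r in
                 ([ligand] if not isinstance(ligand, list) else ligand)]
        qs = sasa(rec_f, [r.id for r in m.residues],
                  probe_radius=config.filters.probe_radius,
                  n_points=config.filters.sasa_points)
        query_sasa.append(qs.sasa)
        lig_coords = lig_f[0].heavy_coords()
        query_lig_coords.append(lig_coords)
        # the bound placement itself seeds the query baseline search
        dock = dock_ligand(
            rec_f, m.center(), lig_f[0],
            seed=_target_seed(config.seed, f"query_{m_i}"),
            n_poses=config.filters.n_poses,
            search_radius=m.diameter() / 2.0 + 3.0,
            weights=config.weights, criteria=config.criteria,
            ligand_chemistry=config.ligand_chemistry,
            initial_poses=[lig_coords],
        )
        query_scores.append(dock.score)
    dscore_query_mean = float(np.mean(query_scores))

    mapping = (enr.read_mapping_table(config.mapping_table)
               if config.mapping_table else {})

    rows: list[ReportRow] = []
    search_targets: set[str] = set()
    sasa_targets: set[str] = set()
    dock_targets: set[str] = set()

    lig_template = ligand[0] if isinstance(ligand, list) else ligand
    for f in db_files:
        target = clean_structure(read_structure(f))
        target.id = f.stem
        hits = match_sites(matchable, target, config.match)
        if not hits:
            continue
        search_targets.add(target.id)
        for hit in hits:
            m = matchable[hit.motif_index]
            hs = sasa(target, hit.target_residues,
                      probe_radius=config.filters.probe_radius,
                      n_points=config.filters.sasa_points)
            s_pass = sasa_filter(hs.sasa, query_sasa[hit.motif_index],
                                 config.filters.sasa_threshold)
            d_score = float("nan")
            d_pass = False
            if s_pass:
                pts = np.concatenate([
                    target.residue(*rid).heavy_coords()
                    for rid in hit.target_residues
                ])
                # seed the search with the query ligand mapped through the
                # motif -> hit superposition
                xyz = ensemble.frames[m.centroid_index]
                P, T = [], []
                for q_id, t_id in sorted(hit.correspondence.items()):
                    q_res = next(r for r in m.residues if r.id == q_id)
                    qv = node_vectors(q_res)
                    tv = node_vectors(target.residue(*t_id))
                    P.extend([qv.S, qv.E])
                    T.extend([tv.S, tv.E])
                _, _, R, t = superpose_transform(
                    np.array(P), np.array(T),
                    allow_reflection=config.match.allow_reflection)
                aligned = query_lig_coords[hit.motif_index] @ R + t
                dock = dock_ligand(
                    target, pts.mean(axis=0), lig_template,
                    seed=_target_seed(config.seed, target.id),
                    n_poses=config.filters.n_poses,
                    search_radius=m.diameter() / 2.0 + 3.0,
                    weights=config.weights, criteria=config.criteria,
                    ligand_chemistry=config.ligand_chemistry,
                    initial_poses=[aligned],
                )
                d_score = dock.score
                d_pass = docking_filter(d_score, query_scores,
                                        config.filters.dscore_threshold)
            if s_pass:
                sasa_targets.add(target.id)
            if s_pass and d_pass:
                dock_targets.add(target.id)
            shared = ";".join(
                f"{q[0]}{q[1]}{q[2]}->{t[0]}{t[1]}{t[2]}"
                for q, t in sorted(hit.correspondence.items())
            )
            rows.append(ReportRow(
                target_id=target.id,
                motif_index=hit.motif_index,
                shared_residues=shared,
                rmsd=float(hit.rmsd),
                reflected=bool(hit.reflected),
                sasa_hit=float(hs.sasa),
                sasa_query=float(query_sasa[hit.motif_index]),
                sasa_pass=bool(s_pass),
                dscore_hit=float(d_score),
                dscore_query_mean=float(dscore_query_mean),
                dock_pass=bool(d_pass),
                accession=mapping.get(target.id, ""),
            ))

    passing = [r for r in rows if r.passed]
    accessions = enr.map_ids([r.target_id for r in passing], mapping) \
        if mapping else set()

    enrichment_rows: list = []
    if config.annotation_table and accessions:
        table = enr.read_annotation_table(config.annotation_table)
        enrichment_rows, _ = enr.enrich(accessions, table,
                                        q_threshold=config.q_threshold)

    stage_counts = {
        "database": len(db_files),
        "search_hits": len(search_targets),
        "post_sasa": len(sasa_targets),
        "post_docking": len(dock_targets),
        "unique_accessions": len(accessions),
    }
    logger.info("funnel: %s", stage_counts)

    result = PipelineResult(
        rows=sorted(rows, key=lambda r: (r.target_id, r.motif_index)),
        stage_counts=stage_counts,
        motifs=motifs,
        enrichment_rows=enrichment_rows,
        accessions=accessions,
        config=config,
    )
    if config.out_dir is not None:
        write_report(result, config.out_dir)
    return result


def _fmt(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return "nan" if v != v else f"{v:.4f}"
    return str(v)


def write_report(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write Results.txt (passing hits), the full report, a JSON sidecar,
    the unique-accession list and the funnel counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    header = "\t".join(REPORT_COLUMNS)

    def row_line(r: ReportRow) -> str:
        return "\t".join(_fmt(getattr(r, c)) for c in REPORT_COLUMNS)

    passing = [r for r in result.rows if r.passed]
    (out / "Results.txt").write_text(
        "\n".join([header] + [row_line(r) for r in passing]) + "\n"
    )
    if not passing:
        logger.info("0 hits passed all filters")
    (out / "report_full.tsv").write_text(
        "\n".join([header] + [row_line(r) for r in result.rows]) + "\n"
    )
    (out / "accessions.txt").write_text(
        "\n".join(sorted(result.accessions)) + ("\n" if result.accessions else "")
    )
    funnel_lines = ["stage\tcount"] + [
        f"{k}\t{v}" for k, v in result.stage_counts.items()
    ]
    (out / "funnel.tsv").write_text("\n".join(funnel_lines) + "\n")

    sidecar = {
        "config": result.config.to_dict(),
        "stage_counts": result.stage_counts,
        "n_motifs": len(result.motifs),
        "matchable_motifs": sum(m.matchable for m in result.motifs),
        "passing_hits": [dataclasses.asdict(r) for r in passing],
        "enrichment": [
            {"term": e.term, "namespace": e.namespace, "k": e.k, "n": e.n,
             "K": e.K, "N": e.N, "p": e.p, "q": e.q,
             "significant": e.significant}
            for e in result.enrichment_rows
        ],
    }
    def _json_default(o):
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, (np.floating, np.ndarray)):
            return float(o) if np.ndim(o) == 0 else np.asarray(o).tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    (out / "results.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True, default=_json_default)
    )

    for i, m in enumerate(result.motifs):
        if m.residues:
            write_motif(m, out / f"motif_{i}.pdb")
    write_motif_manifest(result.motifs, out / "motifs.tsv")
    return out
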