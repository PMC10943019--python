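# Methods

This note documents the models and procedures implemented in `pocketome`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic fixtures do and do not establish
about behaviour on real structures.

## Structure handling and database curation

Structures are read from fixed-column PDB v3.3 coordinate records by a small
in-package reader so that occupancies, altloc codes and model boundaries are
preserved exactly; writing quantizes coordinates to the format's 3 decimal
places, so a read→write→read round trip is lossless after the first pass.
Database entries are normalised by four curation rules: (i) chains whose
organism does not match the requested one are removed — organism labels come
from `SOURCE` header records when present, else from a user-supplied
chain→organism TSV; chains with no resolvable organism are kept with a
warning by default (configurable to an error); (ii) only the first model of
a multi-model file is kept; (iii) HETATM content is dropped (ANISOU records
never survive parsing); (iv) within each altloc group only the
highest-occupancy conformer is kept, ties resolved to the lexicographically
smallest altloc code, and the altloc field is blanked. Cleaning is
idempotent and never moves an atom. Hydrogens are retained on read, but all
geometric operations downstream use heavy atoms unless a rule explicitly
involves hydrogen (the D–H···A angle). Insertion codes are part of residue
identity throughout. Conformational ensembles are multi-model PDB files
congruent with the complex topology; binary trajectory dialects are out of
scope for the core but the `TrajectoryEnsemble` contract (topology + frame
array) is the adapter point.

## Binding-site definition and ensemble clustering

A residue belongs to the binding site iff at least one of its heavy atoms
lies within the cutoff (default 10 Å, closed boundary) of any ligand heavy
atom in at least one frame — the union over frames, which guarantees every
frame yields a congruent feature vector. Each frame is rigid-body superposed
onto frame 0 (Kabsch, proper rotation) on the site residues' backbone N, CA,
C, O atoms; the feature row is the flattened heavy-atom coordinates of
ligand followed by site residues in (chain, resseq, icode) order. This
embedding is declared, not inferred: it is the simplest metric-compatible
choice and is invariant to global rigid motion of the ensemble.

k-means is Lloyd's algorithm from a seeded k-means++ initialisation, one
restart, iterated to an assignment fixpoint (inertia is non-increasing). An
empty cluster is re-seeded at the point farthest from all current means,
lowest index on ties — a deterministic rule, so fixed (data, k, seed) gives
identical output. The cluster count is selected by the mean silhouette
coefficient s = (b − a)/max(a, b), scanned over k from 2 to 12 (capped at
the frame count), smallest k on ties; samples in singleton clusters score 0
(convention), as does a sample with a = b = 0. Each cluster is represented
by the frame nearest its mean (lowest index on ties).

## Interaction detection

The detector reports six contact classes with explicit geometric criteria
(defaults in Å/degrees): hydrophobic — apolar-carbon pairs ≤ 4.0; hydrogen
bond — donor–acceptor heavy-atom distance ≤ 4.1 with D–H···A angle ≥ 100°
when an explicit hydrogen is present (distance-only otherwise, since
protein templates and most PDB files lack hydrogens); salt bridge —
charged-group centroid distance ≤ 5.5; π-stacking — ring-centroid distance
≤ 5.5 with inter-plane angle within 30° of parallel or perpendicular;
π–cation ≤ 6.0; halogen ≤ 4.0. These defaults follow published
interaction-profiler conventions and are all configurable. Water bridges
and metal complexes are not implemented: curation removes HETATM water and
ions from screened targets.

Protein-side roles come from fixed per-residue tables (donor/acceptor
atoms, charged groups, aromatic rings). Ligand chemistry is inferred from
geometry: covalent bonds by a 1.85 Å heavy-atom distance criterion, apolar
carbons as carbons bonded only to C/H, rings as planar 5/6-cycles of the
bond graph. Formal charges cannot be inferred from heavy atoms, so
cationic/anionic ligand groups are explicit hints (`LigandChemistry`);
carboxylates are auto-detected. A ligand N bearing explicit hydrogens (or a
positive-charge hint) donates and does not accept. Only the
minimal-distance contact per (residue, kind) is recorded, which stabilises
motif membership across frames. Interaction probability over an ensemble is
the fraction of frames in which a (residue, kind) contact occurs.

## Motifs

One motif per centroid frame: the binding-site residues carrying ≥ 1
interaction record in that frame, with that frame's coordinates. A single
PDB input yields a single motif. Motifs with fewer than 3 residues are kept
but flagged unmatchable — a 2-node pattern under-constrains a 3-D
correspondence search. Ligand atoms are not part of the exported motif
fragment (the query pattern is protein residues only). Fragments are
written as PDB with residues in ascending (chain, resseq) order.

## Graph matching

Each residue is a pseudo-atom vector: S = CB (CA for glycine), E = centroid
of a fixed 20-entry functional-atom table (Lys NZ; Arg NE/NH1/NH2; Asp/Glu
carboxylate oxygens; aromatic rings for Phe/Tyr/Trp/His; hydroxyl/thiol
oxygens and sulfurs; terminal carbons for aliphatics; CA for glycine,
giving a permitted degenerate vector), M = (S+E)/2. The table preserves the
"functional portion of the side chain" intent and is declared in code
rather than inherited from any external tool. A residue set becomes a
complete graph whose edges carry the five distances SS, SE, ES, EE, MM
(SE/ES respect pair orientation).

Matching builds the association graph: vertices are type-compatible
(query, target) residue pairs (identity equivalence by default; a
user-supplied equivalence map relaxes it), and two vertices are adjacent
iff their query-side and target-side distances agree within a per-component
tolerance (default 1.5 Å on all five components; both the subset and the
tolerance are configurable). Maximal cliques are enumerated with
Bron–Kerbosch with pivoting, output deterministically ordered (size
descending, then lexicographic). By default a hit must match every query
node (a full-size clique); a minimum-match fraction option exists. A
(min_size−1)-core reduction prunes the association graph first — every
clique of size ≥ min_size survives it, and tests assert pruned and unpruned
results are identical. Association graphs above 20,000 vertices abort with
guidance to tighten the tolerance.

Distance-only matching is chirality-blind, so handedness is resolved at the
scoring stage: the paired (S, E) pseudo-atoms are superposed by Kabsch with
determinant correction, and the improper (mirror) fit is evaluated
alongside the proper one; the hit records the better RMSD and a `reflected`
flag. Per (target, motif) only the lowest-RMSD hit is kept, and no RMSD
threshold is applied at this stage — thresholding is the filter stage's
job.

## Filters

**Solvent accessibility.** Shrake–Rupley SASA with a deterministic
golden-section-spiral point set (960 points by default), a fixed
element→radius table (C 1.70, N 1.55, O 1.52, S/P 1.80, halogens per
element, in Å) and probe radius 0.14 nm; areas are reported in nm². SASA is
computed in the context of the whole structure — a site buried in the
protein scores low even if its residues are intrinsically large — matching
the rationale that a buried cleft is inaccessible to solvent and ligand.
The hit side sums over the matched target residues; the query baseline is
the same motif's residues in its centroid frame. The criterion is the
strict inequality `SASA_hit > SASA_query × threshold` with threshold 0.75
by default. The point set is seedless and fixed, so values are
bit-reproducible; rotation invariance holds to the discretization error
(≈0.4% at 960 points, shrinking with density), translation invariance is
exact.

**Docking.** The external docking engine is replaced by a surrogate behind
a pluggable backend contract (receptor, site centre, ligand → score,
pose). The surrogate score is `clash − contacts − polar`: a soft quadratic
penalty for heavy-atom pairs closer than 0.8× the radii sum, a 0.2-point
reward per receptor atom within 4.5 Å of a ligand atom capped at 8
neighbours per ligand atom (saturation, as in empirical scoring functions —
without it, dense crevices outscore designed polar-anchored sites), and a
2-point bonus per hydrogen-bond-range polar pair and per salt-bridge-range
charged-group pair (distances from the interaction criteria). Lower is
better and a ligand far from the receptor scores exactly 0. The pose search
draws n_poses random rigid placements inside a sphere around the site
centre (radius: half the motif diameter + 3 Å) from one seeded generator —
so the best score is monotone non-worsening in n_poses — and refines each
by fixed-step rigid-body coordinate descent over translations and
rotations. The pipeline additionally seeds the search with an informed
pose: the query ligand mapped through the motif→hit superposition (and the
bound placement itself for the query baseline), which is what a practitioner
re-docking into a matched site would do and removes most search-luck
variance from the criterion. The criterion is the strict inequality
`DSCORE_hit < mean(DSCORE_query) + |mean(DSCORE_query)| × threshold`
(threshold 0.10), with the query mean taken over the per-centroid baseline
scores. Absolute surrogate scores are not comparable to any external
engine's; both sides of the criterion use the same backend, which preserves
its meaning.

## Enrichment

Hits are mapped to accessions via a user-supplied TSV (unmapped IDs are
logged and dropped; duplicates collapse). Each term with overlap k ≥ 1 gets
the hypergeometric upper tail p = P(X ≥ k) (scipy); an EASE-style variant
(tail at k − 1) is available since annotation servers differ on this
statistic. Benjamini–Hochberg correction is applied within each namespace
(BP/MF/CC/pathway) separately, mirroring per-category reporting; q < 0.1
flags significance. The background universe is the annotation table's
accession set unless a custom background is supplied. GO-hierarchy
propagation (level slicing) is out of scope. Bar-plot data are the top 5
terms per namespace.

## Synthetic fixtures: what they emulate and what they do not

`make_complex` builds a pseudo-protein from idealized side-chain templates
(standard covalent bond lengths, exactly planar rings, no dihedral realism)
oriented so that designed contacts sit at 90% of their detection
thresholds: one Glu–ammonium salt bridge, hydrophobic contacts from
Phe/Trp/Val, and a Ser–O hydrogen bond, with filler residues on a shell
≥ 14 Å from the ligand. `make_decoy_db` embeds rigidly transformed
(optionally mirrored) copies of a motif with per-coordinate Gaussian jitter
among filler residues whose types never occur in the motif — so under
identity type equivalence the planted correspondences are provably the only
full-size matches, and recall/precision can be scored exactly.
`make_trajectory` displaces the ligand along distinct axes per cluster and
adds coordinate noise; with displacement/noise = 20 the generating cluster
count is recoverable by silhouette. `make_annotations` plants one
over-represented term in an otherwise random annotation universe. All
generators are pure functions of their parameters.

Passing these tests shows the machinery is correct — parsing, geometry,
clique enumeration, formulas, determinism — under conditions where ground
truth is known. It does not show that real binding sites are recovered at
these rates: real side chains have conformational freedom the templates
lack, real databases contain homologous near-matches rather than
type-disjoint fillers, and the surrogate scorer is not a validated affinity
model. With jitter σ = 0.3 Å and tolerance 1.5 Å, a planted 5-residue motif
is occasionally (a few percent of random seeds) missed because one of the
~50 compared distances exceeds the tolerance — the expected tail behaviour
of distance-threshold matching, visible in the acceptance report when an
unlucky seed is chosen.

## Numerical choices and problem sizes

Tolerances and tie-breaks are fixed and documented next to the code:
k-means ties and empty clusters as above; silhouette ties to smallest k;
centroid ties to lowest frame index; altloc ties to smallest code; clique
output sorted (size desc, lexicographic); strict inequalities in both
filter criteria exactly as their formulas state. The test suite and the
acceptance script run on fixture-scale problems — 12–50 decoy structures of
20–30 residues, 30-frame ensembles, 100–200 docking poses, 200 null
replicates — sizes chosen so the full suite completes in about a minute
while every stage is still exercised end to end; all scale linearly with
database size in the screening loop.

## Known limitations

- Side-chain pseudo-atom definitions are this package's own fixed table;
  other tools choose different functional atoms and will rank borderline
  hits differently.
- Ligand protonation/charge is taken as given (hints), not predicted.
- The surrogate docking score is a geometric plausibility filter, not a
  binding-affinity predictor; use the backend hook to plug in a real
  engine.
- Aromatic ring detection on ligands is a planarity test on 5/6-cycles;
  fused exotic ring systems may be partially detected.
- mmCIF, homology modelling of missing residues, and bulk structure
  retrieval are out of scope.
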