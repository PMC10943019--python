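"""Reading, cleaning, splitting and writing PDB-format structures.

The screening database is a folder of single-model, protein-only PDB files.
Raw entries are normalised by :func:`clean_structure`, which applies four
curation rules: (i) drop chains not belonging to the requested organism,
(ii) keep only the first model, (iii) drop ANISOU and HETATM content, and
(iv) collapse alternative locations to the highest-occupancy conformer.

Coordinate records are handled at the fixed-column record level (PDB v3.3)
so that occupancies, altloc codes and model boundaries survive a round trip
to the 3-decimal precision the format allows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "TrajectoryEnsemble",
    "PDBParseError",
    "EmptyStructureError",
    "ChainLookupError",
    "CongruenceError",
    "read_structure",
    "write_structure",
    "clean_structure",
    "split_complex",
    "combine",
    "read_trajectory",
    "read_chain_organisms",
]


class PDBParseError(ValueError):
    """Malformed fixed-column coordinate record (strict mode)."""


class EmptyStructureError(ValueError):
    """File or selection contains no coordinate records."""


class ChainLookupError(KeyError):
    """A requested chain is absent from the structure."""


class CongruenceError(ValueError):
    """Trajectory frame incompatible with its topology."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    altloc: str
    occupancy: float
    coords: np.ndarray
    record_kind: str = "ATOM"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: empty element symbol")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    chain: str
    resseq: int
    icode: str
    resname: str
    atoms: list[Atom] = field(default_factory=list)
    model: int = 1

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.resname} {self.id}: no atom named {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms()], dtype=float).reshape(-1, 3)


@dataclass
class Structure:
    id: str
    residues: list[Residue] = field(default_factory=list)
    models: int = 1
    source_organisms: dict[str, str] | None = None

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()], dtype=float).reshape(-1, 3)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise CongruenceError(
                f"coordinate array shape {xyz.shape} does not match {self.n_atoms} atoms"
            )
        for atom, row in zip(self.atoms(), xyz):
            atom.coords = row.copy()

    def atom_index_map(self) -> dict[tuple[str, int, str, str], int]:
        """Map (chain, resseq, icode, atom name) -> flat atom index."""
        out: dict[tuple[str, int, str, str], int] = {}
        i = 0
        for r in self.residues:
            for a in r.atoms:
                out[(r.chain, r.resseq, r.icode, a.name)] = i
                i += 1
        return out

    def residue(self, chain: str, resseq: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.id == (chain, resseq, icode):
                return r
        raise KeyError(f"{self.id}: no residue {(chain, resseq, icode)}")

    def copy(self) -> "Structure":
        return Structure(
            id=self.id,
            residues=[
                Residue(r.chain, r.resseq, r.icode, r.resname,
                        [replace(a, coords=a.coords.copy()) for a in r.atoms], r.model)
                for r in self.residues
            ],
            models=self.models,
            source_organisms=dict(self.source_organisms) if self.source_organisms else None,
        )


@dataclass
class TrajectoryEnsemble:
    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise CongruenceError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise CongruenceError("ensemble needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise CongruenceError(
                f"frames carry {self.frames.shape[1]} atoms, topology has {self.topology.n_atoms}"
            )

    @property
    def frame_count(self) -> int:
        return int(self.frames.shape[0])

    def frame_structure(self, index: int) -> Structure:
        s = self.topology.copy()
        s.set_coords(self.frames[index])
        return s


_COORD_RE = re.compile(r"^(ATOM|HETATM)")

# ORGANISM_SCIENTIFIC in SOURCE records, keyed to the current MOL_ID's chains
_SOURCE_CHAIN_RE = re.compile(r"CHAIN:\s*([A-Za-z0-9,\s]+);?")
_SOURCE_ORG_RE = re.compile(r"ORGANISM_SCIENTIFIC:\s*([^;]+);?")


def _parse_coord_line(line: str, lineno: int, permissive: bool):
    line = line.rstrip("\n")
    padded = line.ljust(80)
    try:
        serial = int(padded[6:11])
        name = padded[12:16].strip()
        altloc = padded[16].strip()
        resname = padded[17:20].strip()
        chain = padded[21].strip()
        resseq = int(padded[22:26])
        icode = padded[26].strip()
        x = float(padded[30:38])
        y = float(padded[38:46])
        z = float(padded[46:54])
        occ_field = padded[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = padded[76:78].strip()
    except ValueError as exc:
        if permissive:
            return None
        raise PDBParseError(f"line {lineno}: malformed coordinate record: {exc}") from None
    if not element:
        # fall back to the atom-name convention: first alphabetic character
        for ch in name:
            if ch.isalpha():
                element = ch.upper()
                break
        if name[:1].isdigit() and len(name) > 1:
            element = "H" if "H" in name.upper() else element
    if not name or not element:
        if permissive:
            return None
        raise PDBParseError(f"line {lineno}: coordinate record without atom name/element")
    occupancy = min(max(occupancy, 0.0), 1.0)
    atom = Atom(serial, name, element, altloc, occupancy, np.array([x, y, z]),
                record_kind=padded[0:6].strip())
    return (chain, resseq, icode, resname), atom


def read_structure(path: str | Path, permissive: bool = True) -> Structure:
    """Parse a (possibly multi-model) PDB file into a :class:`Structure`.

    All models' coordinate records are read; residues of later models carry
    the same identifiers as the first and are appended in file order.  The
    model count is recorded in ``Structure.models``.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise OSError(f"cannot read PDB file {path}: {exc}") from exc

    residues: list[Residue] = []
    index: dict[tuple, Residue] = {}
    organisms: dict[str, str] = {}
    pending_chains: list[str] = []
    models = 0
    in_model = False
    current_model = 0

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            models += 1
            in_model = True
            current_model = models
        elif rec == "ENDMDL":
            in_model = False
        elif rec == "SOURCE":
            m = _SOURCE_CHAIN_RE.search(line)
            if m:
                pending_chains = [c.strip() for c in m.group(1).split(",") if c.strip()]
            m = _SOURCE_ORG_RE.search(line)
            if m:
                org = m.group(1).strip().lower()
                for c in pending_chains:
                    organisms[c] = org
        elif _COORD_RE.match(line):
            parsed = _parse_coord_line(line, lineno, permissive)
            if parsed is None:
                continue
            (chain, resseq, icode, resname), atom = parsed
            key = (current_model, chain, resseq, icode, resname)
            res = index.get(key)
            if res is None:
                res = Residue(chain, resseq, icode, resname, model=max(current_model, 1))
                index[key] = res
                residues.append(res)
            res.atoms.append(atom)

    if not residues:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records found")
    return Structure(
        id=path.stem,
        residues=residues,
        models=max(models, 1),
        source_organisms=organisms or None,
    )


def write_structure(s: Structure, path: str | Path) -> Path:
    """Write a single-model PDB file (fixed-column v3.3 coordinate records)."""
    path = Path(path)
    lines = []
    serial = 0
    for r in s.residues:
        for a in r.atoms:
            serial += 1
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"{a.record_kind:<6s}{serial:>5d} {name:<4s}{a.altloc or ' ':1s}"
                f"{r.resname:>3s} {r.chain:1s}{r.resseq:>4d}{r.icode or ' ':1s}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_chain_organisms(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping chain ID -> organism label."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"chain-organism table: expected 2 columns, got {line!r}")
        out[parts[0].strip()] = parts[1].strip().lower()
    return out


def _first_model_residues(s: Structure) -> list[Residue]:
    if s.models <= 1:
        return s.residues
    first = min(r.model for r in s.residues)
    return [r for r in s.residues if r.model == first]


def clean_structure(
    s: Structure,
    allowed_organism: str | None = None,
    chain_organisms: Mapping[str, str] | None = None,
    on_unknown_organism: str = "keep",
) -> Structure:
    """Apply the four database-curation rules.

    (i) chains whose organism does not match ``allowed_organism`` are removed
    (skipped when ``allowed_organism`` is None); (ii) only the first model is
    kept; (iii) HETATM records are dropped (ANISOU records never survive
    parsing); (iv) within each altloc group only the highest-occupancy
    conformer is kept — ties resolved to the lexicographically smallest
    altloc code — and the altloc field is blanked.

    ``on_unknown_organism`` controls chains with no resolvable organism when
    a filter is requested: ``"keep"`` retains them with a warning, ``"error"``
    raises.
    """
    import warnings

    organisms: dict[str, str] = {}
    if s.source_organisms:
        organisms.update(s.source_organisms)
    if chain_organisms:
        organisms.update({k: v.lower() for k, v in chain_organisms.items()})

    out_residues: list[Residue] = []
    for r in _first_model_residues(s):
        if allowed_organism is not None:
            org = organisms.get(r.chain)
            if org is None:
                if on_unknown_organism == "error":
                    raise ValueError(
                        f"{s.id}: organism filter requested but chain {r.chain!r} "
                        "has no organism annotation"
                    )
                warnings.warn(
                    f"{s.id}: chain {r.chain!r} has no organism annotation; keeping it",
                    stacklevel=2,
                )
            elif org != allowed_organism.lower():
                continue
        atoms = [a for a in r.atoms if a.record_kind == "ATOM"]
        if not atoms:
            continue
        # rule (iv): per atom name, keep the highest-occupancy altloc
        by_name: dict[str, Atom] = {}
        for a in atoms:
            prev = by_name.get(a.name)
            if prev is None or a.occupancy > prev.occupancy or (
                a.occupancy == prev.occupancy and a.altloc < prev.altloc
            ):
                by_name[a.name] = a
        kept = [
            replace(a, altloc="", coords=a.coords.copy())
            for a in atoms
            if by_name[a.name] is a
        ]
        out_residues.append(Residue(r.chain, r.resseq, r.icode, r.resname, kept))

    return Structure(id=s.id, residues=out_residues, models=1,
                     source_organisms=dict(organisms) or None)


def split_complex(
    s: Structure, receptor_chains: Sequence[str] | str, ligand_chain: str
) -> tuple[Structure, list[Residue]]:
    """Split a complex into its receptor chains and the ligand residues."""
    if isinstance(receptor_chains, str):
        receptor_chains = [c.strip() for c in receptor_chains.split(",") if c.strip()]
    rec_set = set(receptor_chains)
    if ligand_chain in rec_set:
        raise ValueError(
            f"ligand chain {ligand_chain!r} overlaps the receptor chains {sorted(rec_set)}"
        )
    available = set(s.chains())
    missing = (rec_set | {ligand_chain}) - available
    if missing:
        raise ChainLookupError(
            f"{s.id}: chain(s) {sorted(missing)} not found; available chains: "
            f"{sorted(available)}"
        )
    receptor = Structure(
        id=f"{s.id}:receptor",
        residues=[r for r in s.residues if r.chain in rec_set],
        models=1,
    )
    ligand = [r for r in s.residues if r.chain == ligand_chain]
    if not receptor.residues:
        raise EmptyStructureError(f"{s.id}: receptor selection is empty")
    if not ligand:
        raise EmptyStructureError(f"{s.id}: ligand selection is empty")
    return receptor, ligand


def combine(receptor: Structure, ligand: Iterable[Residue], id: str = "complex") -> Structure:
    """Join receptor residues and ligand residues into one Structure."""
    return Structure(id=id, residues=list(receptor.residues) + list(ligand), models=1)


def read_trajectory(topology: Structure, path: str | Path) -> TrajectoryEnsemble:
    """Read a multi-model PDB as an ensemble congruent with ``topology``.

    Every model must carry exactly the topology's atom count, in the same
    atom order.
    """
    raw = read_structure(path, permissive=True)
    n_top = topology.n_atoms
    all_coords = raw.coords()
    n_models = max(raw.models, 1)
    if all_coords.shape[0] != n_models * n_top:
        # locate the first incongruent model for the error message
        counts: list[int] = []
        per_model: dict[int, int] = {}
        # re-walk the file to count atoms per model
        i = 0
        model = 1
        for line in Path(path).read_text().splitlines():
            rec = line[:6].strip()
            if rec == "MODEL":
                model = len(counts) + 1
            elif rec == "ENDMDL":
                counts.append(per_model.get(model, 0))
                per_model.pop(model, None)
                model += 1
            elif rec in ("ATOM", "HETATM"):
                per_model[model] = per_model.get(model, 0) + 1
        if per_model:
            counts.append(sum(per_model.values()))
        for idx, c in enumerate(counts, start=1):
            if c != n_top:
                raise CongruenceError(
                    f"{path}: model {idx} has {c} atoms, topology has {n_top}"
                )
        raise CongruenceError(f"{path}: atom count incongruent with topology")
    frames = all_coords.reshape(n_models, n_top, 3)
    return TrajectoryEnsemble(topology=topology, frames=frames)
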