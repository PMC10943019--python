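"""Chemical reference tables for the twenty standard amino acids.

Templates are idealized heavy-atom geometries built in a local frame (CA at
the origin, side chain extending along +x, ring planes in the xz plane).
Bond lengths follow standard covalent values; dihedral realism is not
attempted because every downstream operation is distance-threshold based.
"""

from __future__ import annotations

import math

import numpy as np

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: van der Waals radii (Å) used by the Shrake-Rupley surface and the
#: surrogate docking scorer.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "H": 1.20,
}

#: Functional-atom sets defining the end (E) pseudo-atom of each side-chain
#: vector; the start (S) is CB (CA for glycine).
FUNCTIONAL_ATOMS = {
    "GLY": ("CA",),
    "ALA": ("CB",),
    "SER": ("OG",),
    "CYS": ("SG",),
    "THR": ("OG1",),
    "VAL": ("CG1", "CG2"),
    "LEU": ("CD1", "CD2"),
    "ILE": ("CD1",),
    "PRO": ("CG",),
    "MET": ("SD", "CE"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"),
    "HIS": ("CG", "ND1", "CE1", "NE2", "CD2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1", "ND2"),
    "GLN": ("OE1", "NE2"),
}

#: Aromatic ring atom sets per residue (TRP carries two fused rings).
AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "TYR": [("CG", "CD1", "CE1", "CZ", "CE2", "CD2")],
    "HIS": [("CG", "ND1", "CE1", "NE2", "CD2")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
}

#: Hydrogen-bond donor heavy atoms per residue (side chains; backbone N is a
#: donor for every residue) and acceptor heavy atoms.
HBOND_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "TRP": ("NE1",),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"),
    "ASN": ("ND2",), "GLN": ("NE2",),
}
HBOND_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "SER": ("OG",),
    "THR": ("OG1",), "TYR": ("OH",), "ASN": ("OD1",), "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
}

#: Charged-group atom sets: group centroid is used for salt bridges.
CATIONIC_GROUPS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}
#: HIS counts as cationic only when flagged protonated.
HIS_CATION_GROUP = ("ND1", "NE2", "CE1", "CD2", "CG")
ANIONIC_GROUPS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# --- template construction -------------------------------------------------

_U = np.array([1.0, 0.0, 0.0])  # side-chain axis
_Z = np.array([0.0, 0.0, 1.0])

# tetrahedral branch directions about the side-chain axis
_T1 = math.cos(math.radians(54.75)) * _U + math.sin(math.radians(54.75)) * _Z
_T2 = math.cos(math.radians(54.75)) * _U - math.sin(math.radians(54.75)) * _Z


def _hexagon(attach: np.ndarray, names: tuple[str, ...], bond: float = 1.39):
    """Planar 6-ring in the xz plane; names[0] sits at ``attach``.

    A regular hexagon's circumradius equals its bond length, so the center
    lies one bond along +x from the attachment vertex; names are ordered
    around the ring.
    """
    center = attach.copy()
    center[0] += bond
    out = {}
    for k, nm in enumerate(names):
        ang = math.pi + k * math.pi / 3.0  # attachment vertex faces -x
        out[nm] = center + bond * (math.cos(ang) * _U + math.sin(ang) * _Z)
    return out


def _pentagon(attach: np.ndarray, names: tuple[str, ...], bond: float = 1.39):
    r5 = bond / (2.0 * math.sin(math.pi / 5.0))
    center = attach.copy()
    center[0] += r5
    out = {}
    for k, nm in enumerate(names):
        ang = math.pi + k * 2.0 * math.pi / 5.0
        out[nm] = center + r5 * (math.cos(ang) * _U + math.sin(ang) * _Z)
    return out


def _build_templates() -> dict[str, dict[str, np.ndarray]]:
    N = np.array([-1.45, 0.0, 0.0])
    CA = np.array([0.0, 0.0, 0.0])
    C = np.array([0.55, 1.40, 0.0])
    O = np.array([1.75, 1.55, 0.0])
    # CB placed off the backbone plane so the side chain runs along +x
    CB = np.array([0.85, -1.25, 0.0])

    def chainx(start: np.ndarray, *steps: float) -> list[np.ndarray]:
        pts, p = [], start.copy()
        for s in steps:
            p = p + s * _U
            pts.append(p.copy())
        return pts

    t: dict[str, dict[str, np.ndarray]] = {}
    bb = {"N": N, "CA": CA, "C": C, "O": O}

    def make(resname: str, side: dict[str, np.ndarray]) -> None:
        t[resname] = {**{k: v.copy() for k, v in bb.items()},
                      **{k: np.asarray(v, dtype=float) for k, v in side.items()}}

    make("GLY", {})
    make("ALA", {"CB": CB})
    (cg,) = chainx(CB, 1.52)
    make("SER", {"CB": CB, "OG": CB + 1.43 * _U})
    make("CYS", {"CB": CB, "SG": CB + 1.81 * _U})
    make("THR", {"CB": CB, "OG1": CB + 1.43 * _T1, "CG2": CB + 1.52 * _T2})
    make("VAL", {"CB": CB, "CG1": CB + 1.52 * _T1, "CG2": CB + 1.52 * _T2})
    make("LEU", {"CB": CB, "CG": cg, "CD1": cg + 1.52 * _T1, "CD2": cg + 1.52 * _T2})
    make("ILE", {"CB": CB, "CG1": CB + 1.52 * _T1, "CG2": CB + 1.52 * _T2,
                 "CD1": CB + 1.52 * _T1 + 1.52 * _U})
    make("PRO", {"CB": CB, "CG": cg, "CD": cg + 1.52 * _T1})
    cg2, sd, ce = CB + 1.52 * _U, CB + 1.52 * _U + 1.81 * _U, None
    make("MET", {"CB": CB, "CG": cg2, "SD": sd, "CE": sd + 1.79 * _T1})
    cgl = chainx(CB, 1.52, 1.52)
    make("LYS", {"CB": CB, "CG": cgl[0], "CD": cgl[1],
                 "CE": cgl[1] + 1.52 * _T1, "NZ": cgl[1] + 1.52 * _T1 + 1.47 * _U})
    ne = cgl[1] + 1.46 * _T1
    cz = ne + 1.33 * _U
    make("ARG", {"CB": CB, "CG": cgl[0], "CD": cgl[1], "NE": ne, "CZ": cz,
                 "NH1": cz + 1.33 * _T1, "NH2": cz + 1.33 * _T2})
    make("ASP", {"CB": CB, "CG": cg, "OD1": cg + 1.25 * _T1, "OD2": cg + 1.25 * _T2})
    make("ASN", {"CB": CB, "CG": cg, "OD1": cg + 1.23 * _T1, "ND2": cg + 1.32 * _T2})
    cd = cg + 1.52 * _U
    make("GLU", {"CB": CB, "CG": cg, "CD": cd, "OE1": cd + 1.25 * _T1,
                 "OE2": cd + 1.25 * _T2})
    make("GLN", {"CB": CB, "CG": cg, "CD": cd, "OE1": cd + 1.23 * _T1,
                 "NE2": cd + 1.32 * _T2})

    hexn = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    ring = _hexagon(cg - 0.0 * _U, hexn)  # CG bonded to CB via ring placement
    # shift ring so CG lands exactly at the chain position cg
    delta = cg - ring["CG"]
    ring = {k: v + delta for k, v in ring.items()}
    make("PHE", {"CB": CB, **ring})
    oh = ring["CZ"] + 1.36 * _U
    make("TYR", {"CB": CB, **ring, "OH": oh})

    pent = _pentagon(cg, ("CG", "ND1", "CE1", "NE2", "CD2"))
    delta = cg - pent["CG"]
    pent = {k: v + delta for k, v in pent.items()}
    make("HIS", {"CB": CB, **pent})

    # tryptophan: pentagon fused with a hexagon on the CD2-CE2 edge
    pent_w = _pentagon(cg, ("CG", "CD1", "NE1", "CE2", "CD2"))
    delta = cg - pent_w["CG"]
    pent_w = {k: v + delta for k, v in pent_w.items()}
    cd2, ce2 = pent_w["CD2"], pent_w["CE2"]
    mid = 0.5 * (cd2 + ce2)
    pc = sum(pent_w.values()) / 5.0
    away = mid - pc
    away /= np.linalg.norm(away)
    hex_center = mid + (1.39 * math.sqrt(3.0) / 2.0) * away
    # walk the hexagon from CD2 away from CE2
    def hex_vertex(base: np.ndarray, k: int) -> np.ndarray:
        v = base - hex_center
        ang = math.atan2(v[2], v[0])
        a = ang + k * math.pi / 3.0
        return hex_center + 1.39 * (math.cos(a) * _U + math.sin(a) * _Z)
    # choose rotation sign so the first step moves away from CE2
    step = hex_vertex(cd2, 1)
    sign = 1 if np.linalg.norm(step - ce2) > 1.5 else -1
    trp_extra = {
        "CE3": hex_vertex(cd2, sign * 1),
        "CZ3": hex_vertex(cd2, sign * 2),
        "CH2": hex_vertex(cd2, sign * 3),
        "CZ2": hex_vertex(cd2, sign * 4),
    }
    make("TRP", {"CB": CB, **pent_w, **trp_extra})
    return t


TEMPLATES = _build_templates()

#: atoms of each template whose element is not carbon
_ELEMENT_OVERRIDES = {"N": "N", "O": "O", "S": "S"}


def atom_element(name: str) -> str:
    """Element of a standard-residue heavy atom from its PDB name."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element for atom name {name!r}")


#: template side-chain axis (local +x) and the CA origin are used by the
#: fixture generator to orient residues toward a target point.
TEMPLATE_AXIS = _U.copy()
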