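"""Idealized residue geometry: side-chain templates and nucleotide templates.

Side chains are built from a per-residue bonded topology with generic
bond lengths on a deterministic outward zigzag from the Cbeta direction
defined by the local N/CA/C frame.  These are idealized stick rotamers:
atom connectivity and rough geometry are right, but rings are only
approximately closed and no rotamer library is used.  Nucleotides are
built from planar Watson-Crick base-pair templates (hexagon/pentagon
ring geometry with 1.4 A bonds, N1-N3 separation 2.9 A) plus a
procedural sugar-phosphate arm.

Used by the naive mutant builder and the synthetic complex generator.
"""

from __future__ import annotations

import numpy as np

#: bonded side-chain topology: residue -> ((atom, parent), ...)
SIDECHAIN_TOPOLOGY: dict[str, tuple[tuple[str, str], ...]] = {
    "ALA": (),
    "ARG": (("CG", "CB"), ("CD", "CG"), ("NE", "CD"), ("CZ", "NE"),
            ("NH1", "CZ"), ("NH2", "CZ")),
    "ASN": (("CG", "CB"), ("OD1", "CG"), ("ND2", "CG")),
    "ASP": (("CG", "CB"), ("OD1", "CG"), ("OD2", "CG")),
    "CYS": (("SG", "CB"),),
    "GLN": (("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("NE2", "CD")),
    "GLU": (("CG", "CB"), ("CD", "CG"), ("OE1", "CD"), ("OE2", "CD")),
    "GLY": (),
    "HIS": (("CG", "CB"), ("ND1", "CG"), ("CD2", "CG"), ("CE1", "ND1"),
            ("NE2", "CE1")),
    "ILE": (("CG1", "CB"), ("CG2", "CB"), ("CD1", "CG1")),
    "LEU": (("CG", "CB"), ("CD1", "CG"), ("CD2", "CG")),
    "LYS": (("CG", "CB"), ("CD", "CG"), ("CE", "CD"), ("NZ", "CE")),
    "MET": (("CG", "CB"), ("SD", "CG"), ("CE", "SD")),
    "PHE": (("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"), ("CE1", "CD1"),
            ("CE2", "CD2"), ("CZ", "CE1")),
    "PRO": (("CG", "CB"), ("CD", "CG")),
    "SER": (("OG", "CB"),),
    "THR": (("OG1", "CB"), ("CG2", "CB")),
    "TRP": (("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"), ("NE1", "CD1"),
            ("CE2", "CD2"), ("CE3", "CD2"), ("CZ2", "CE2"), ("CZ3", "CE3"),
            ("CH2", "CZ2")),
    "TYR": (("CG", "CB"), ("CD1", "CG"), ("CD2", "CG"), ("CE1", "CD1"),
            ("CE2", "CD2"), ("CZ", "CE1"), ("OH", "CZ")),
    "VAL": (("CG1", "CB"), ("CG2", "CB")),
}


def element_of(atom_name: str) -> str:
    """Element inferred from a standard protein/NA atom name."""
    name = atom_name.strip()
    if name[:1].isdigit():
        name = name[1:]
    for two in ("CL", "BR", "MG", "ZN", "FE", "MN", "NA", "SE"):
        if name.upper() == two:
            return two
    return name[0].upper()


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def cbeta_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                   length: float = 1.53) -> np.ndarray:
    """Idealized Cbeta from the backbone frame (tetrahedral geometry)."""
    d1 = _unit(n - ca)
    d2 = _unit(c - ca)
    bisector = _unit(-(d1 + d2))
    perp = _unit(np.cross(d1, d2))
    direction = _unit(bisector * np.cos(0.9) + perp * np.sin(0.9))
    return ca + length * direction


def build_sidechain(resname: str, n: np.ndarray, ca: np.ndarray,
                    c: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Side-chain heavy atoms (CB onwards) as (name, element, position).

    Deterministic pure function of the backbone frame; Gly returns [].
    """
    if resname == "GLY":
        return []
    cb = cbeta_position(n, ca, c)
    out = [("CB", "C", cb)]
    topo = SIDECHAIN_TOPOLOGY[resname]
    if not topo:
        return out
    u = _unit(cb - ca)                       # outward growth axis
    ref = _unit(n - ca)
    v = _unit(ref - np.dot(ref, u) * u)      # in-plane perpendicular
    w = np.cross(u, v)
    pos = {"CB": cb}
    level = {"CB": 0}
    children: dict[str, list[str]] = {}
    for atom, parent in topo:
        children.setdefault(parent, []).append(atom)
    for atom, parent in topo:
        sibs = children[parent]
        k = sibs.index(atom)
        lvl = level[parent] + 1
        level[atom] = lvl
        zig = 0.45 if lvl % 2 else -0.45
        lateral = (k - (len(sibs) - 1) / 2.0) * 1.15
        p = pos[parent] + 1.32 * u + lateral * v + zig * w
        pos[atom] = p
        out.append((atom, element_of(atom), p))
    return out


# ---------------------------------------------------------------------------
# nucleotide templates

def _pentagon_from_edge(p_a: np.ndarray, p_b: np.ndarray,
                        outward: np.ndarray) -> list[np.ndarray]:
    """Remaining 3 vertices of a regular pentagon sharing edge a->b."""
    side = np.linalg.norm(p_b - p_a)
    r5 = side / (2 * np.sin(np.pi / 5))
    apothem = r5 * np.cos(np.pi / 5)
    mid = (p_a + p_b) / 2
    center = mid + apothem * _unit(outward)
    ang_a = np.arctan2(p_a[1] - center[1], p_a[0] - center[0])
    ang_b = np.arctan2(p_b[1] - center[1], p_b[0] - center[0])
    step = np.angle(np.exp(1j * (ang_b - ang_a)))  # signed step a -> b
    verts = []
    ang = ang_b
    for _ in range(3):
        ang += step
        verts.append(center + r5 * np.array([np.cos(ang), np.sin(ang), 0.0]))
    return verts


def _hexagon(center: np.ndarray, angles_deg: dict[str, float],
             radius: float = 1.40) -> dict[str, np.ndarray]:
    out = {}
    for name, deg in angles_deg.items():
        th = np.radians(deg)
        out[name] = center + radius * np.array([np.cos(th), np.sin(th), 0.0])
    return out


def purine_base(resname: str) -> dict[str, np.ndarray]:
    """Planar purine base in the pair frame (WC edge toward +x)."""
    center = np.array([-2.85, 0.0, 0.0])
    ring = _hexagon(center, {"N1": 0, "C2": -60, "N3": -120, "C4": 180,
                             "C5": 120, "C6": 60})
    outward = (ring["C4"] + ring["C5"]) / 2 - center
    n7, c8, n9 = _pentagon_from_edge(ring["C5"], ring["C4"], outward)
    ring.update({"N7": n7, "C8": c8, "N9": n9})
    if resname in ("DA", "A"):
        ring["N6"] = ring["C6"] + 1.35 * _unit(ring["C6"] - center)
    else:  # guanine
        ring["O6"] = ring["C6"] + 1.24 * _unit(ring["C6"] - center)
        ring["N2"] = ring["C2"] + 1.35 * _unit(ring["C2"] - center)
    return ring


def pyrimidine_base(resname: str) -> dict[str, np.ndarray]:
    """Planar pyrimidine base in the pair frame (WC edge toward -x)."""
    center = np.array([2.85, 0.0, 0.0])
    ring = _hexagon(center, {"N3": 180, "C2": 240, "N1": 300, "C6": 0,
                             "C5": 60, "C4": 120})
    ring["O2"] = ring["C2"] + 1.24 * _unit(ring["C2"] - center)
    if resname in ("DC", "C"):
        ring["N4"] = ring["C4"] + 1.35 * _unit(ring["C4"] - center)
    else:  # thymine / uracil
        ring["O4"] = ring["C4"] + 1.24 * _unit(ring["C4"] - center)
        if resname == "DT":
            ring["C7"] = ring["C5"] + 1.50 * _unit(ring["C5"] - center)
    return ring


#: sugar-phosphate arm offsets in the (outward, axis, cross) local frame
_SUGAR_ARM: tuple[tuple[str, str, tuple[float, float, float]], ...] = (
    ("C2'", "C1'", (0.5, -1.2, 0.7)),
    ("C3'", "C2'", (0.9, 0.0, -1.2)),
    ("C4'", "C3'", (0.5, 1.2, 0.7)),
    ("O4'", "C1'", (1.1, 0.6, -0.6)),
    ("O3'", "C3'", (0.9, -1.1, -0.3)),
    ("C5'", "C4'", (1.0, 1.0, 0.4)),
    ("O5'", "C5'", (0.9, 0.6, -1.0)),
    ("P", "O5'", (1.1, 0.9, 0.6)),
    ("OP1", "P", (1.2, 0.4, 0.8)),
    ("OP2", "P", (0.8, 0.4, -1.2)),
)


def nucleotide_template(resname: str, ribo: bool) -> dict[str, np.ndarray]:
    """Full nucleotide (base + sugar + phosphate) in the pair frame."""
    purine = resname in ("DA", "DG", "A", "G")
    base = purine_base(resname) if purine else pyrimidine_base(resname)
    glyc = "N9" if purine else "N1"
    center = np.array([-2.85, 0.0, 0.0]) if purine else np.array([2.85, 0.0, 0.0])
    outward = _unit(base[glyc] - center)
    c1p = base[glyc] + 1.47 * outward
    atoms = dict(base)
    atoms["C1'"] = c1p
    axis = np.array([0.0, 0.0, 1.0])
    cross = np.cross(outward, axis)
    frame = np.stack([outward, axis, cross])
    for name, parent, off in _SUGAR_ARM:
        atoms[name] = atoms[parent] + np.asarray(off) @ frame
    if ribo:
        atoms["O2'"] = atoms["C2'"] + np.array([0.0, -0.9, 1.1]) @ frame
    return atoms


#: fixed emission order for nucleotide atoms in PDB output
NUCLEOTIDE_ATOM_ORDER = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'",
    "C1'", "N9", "C8", "N7", "C5", "C6", "N6", "O6", "N1", "C2", "N2", "O2",
    "N3", "C4", "N4", "O4", "C7",
)

WC_PARTNER = {"DA": "DT", "DT": "DA", "DG": "DC", "DC": "DG",
              "A": "U", "U": "A", "G": "C", "C": "G"}
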