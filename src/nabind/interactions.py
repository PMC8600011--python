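"""Geometric typing of inter-atomic contacts (13 interaction types).

A self-contained re-implementation of the Arpeggio-style contact
classifier: every heavy-atom pair within a candidate distance is assigned
all matching interaction types out of clash, covalent, van der Waals,
van der Waals clash, hydrogen bond, weak hydrogen bond, proximal, halogen
bond, aromatic, ionic, carbonyl, hydrophobic and metal.  All geometric
thresholds live in one :class:`InteractionConfig` block.  Because
structures are hydrogen-free, angle criteria are applied only where a
donor antecedent (covalently bonded heavy neighbour) exists; otherwise
distance-only criteria are used.

Protein donor/acceptor/charge/hydrophobic/aromatic capabilities come from
the pharmacophore table; nucleic-acid N and O atoms are treated as both
donor- and acceptor-capable and the non-bridging phosphate oxygens as
negatively charged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ContractError
from .pharmacophore import assign_pharmacophores
from .structure_io import (NUCLEIC_RESIDUES, PURINE_RESIDUES, AtomRecord,
                           ComplexStructure)

INTERACTION_TYPES = (
    "clash", "covalent", "vdw", "vdw_clash", "hbond", "weak_hbond",
    "proximal", "halogen_bond", "aromatic", "ionic", "carbonyl",
    "hydrophobic", "metal",
)

VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "F": 1.47,
    "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "MG": 1.73, "ZN": 1.39, "CA": 2.31, "NA": 2.27, "K": 2.75,
    "MN": 1.97, "FE": 1.94, "CU": 1.40, "NI": 1.63, "CO": 1.95, "CD": 1.58,
}
COVALENT_RADII = {
    "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07, "F": 0.57,
    "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
    "MG": 1.41, "ZN": 1.22, "CA": 1.76, "NA": 1.66, "K": 2.03,
    "MN": 1.39, "FE": 1.32, "CU": 1.32, "NI": 1.24, "CO": 1.26, "CD": 1.44,
}
METALS = {"MG", "ZN", "CA", "NA", "K", "MN", "FE", "CU", "NI", "CO", "CD"}

PROTEIN_RINGS = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
}
PURINE_RINGS = (("N9", "C8", "N7", "C5", "C4"),
                ("N1", "C2", "N3", "C4", "C5", "C6"))
PYRIMIDINE_RINGS = (("N1", "C2", "N3", "C4", "C5", "C6"),)

#: carbonyl-group atom names: oxygen -> its carbon, per context
CARBONYL_OXYGENS = {"O", "OXT", "OD1", "OE1", "O2", "O4", "O6"}
CARBONYL_CARBONS = {"C", "CG", "CD", "C2", "C4", "C6"}

HALOGENS = {"CL", "BR", "I"}


@dataclass(frozen=True)
class InteractionConfig:
    """Distance/angle thresholds of the contact classifier (Angstrom, degrees)."""

    max_pair_distance: float = 5.5
    covalent_tolerance: float = 0.4
    clash_gap: float = 0.5     # clash iff d < vdw_sum - clash_gap
    vdw_gap: float = 0.5       # vdw contact iff vdw_sum <= d <= vdw_sum + vdw_gap
    hbond_max: float = 3.5
    hbond_min_angle: float = 90.0
    weak_hbond_max: float = 3.8
    ionic_max: float = 4.0
    aromatic_max: float = 5.0  # ring-centroid separation
    hydrophobic_max: float = 4.5
    carbonyl_max: float = 3.6
    halogen_max: float = 3.5
    metal_max: float = 2.8
    proximal_max: float = 5.0


@dataclass
class InteractionRecord:
    atom_a: AtomRecord
    atom_b: AtomRecord
    type: str
    distance: float


def _vdw(el: str) -> float:
    return VDW_RADII.get(el.upper(), 1.80)


def _cov(el: str) -> float:
    return COVALENT_RADII.get(el.upper(), 1.00)


class _AtomProps:
    """Per-atom capabilities derived once per structure."""

    __slots__ = ("donor", "acceptor", "positive", "negative", "hydrophobic",
                 "is_carbon", "is_metal", "is_halogen", "element")

    def __init__(self, atom: AtomRecord, labels: frozenset[str],
                 is_nucleic: bool) -> None:
        el = atom.element.upper()
        self.element = el
        self.is_carbon = el == "C"
        self.is_metal = el in METALS
        self.is_halogen = el in HALOGENS
        if is_nucleic:
            self.donor = el in ("N", "O")
            self.acceptor = el in ("N", "O")
            self.negative = atom.name in ("OP1", "OP2", "OP3", "O1P", "O2P", "O3P")
            self.positive = False
            self.hydrophobic = False
        else:
            self.donor = "donor" in labels
            self.acceptor = "acceptor" in labels
            self.positive = "positive" in labels
            self.negative = "negative" in labels
            self.hydrophobic = "hydrophobic" in labels and self.is_carbon


def _antecedents(structure: ComplexStructure,
                 config: InteractionConfig) -> dict[int, list[int]]:
    """Covalently bonded heavy neighbours (within-residue, by radii sum)."""
    out: dict[int, list[int]] = {i: [] for i in range(len(structure.atoms))}
    index: dict[tuple, list[int]] = {}
    for i, a in enumerate(structure.atoms):
        index.setdefault(a.residue_key, []).append(i)
    for idxs in index.values():
        for ii, i in enumerate(idxs):
            ai = structure.atoms[i]
            for j in idxs[ii + 1:]:
                aj = structure.atoms[j]
                d = float(np.linalg.norm(ai.position - aj.position))
                if d <= _cov(ai.element) + _cov(aj.element) + config.covalent_tolerance:
                    out[i].append(j)
                    out[j].append(i)
    return out


def _rings(structure: ComplexStructure) -> list[tuple[str, np.ndarray, int]]:
    """(chain_class, centroid, representative atom index) per aromatic ring."""
    rings = []
    pos_of: dict[tuple, dict[str, int]] = {}
    for i, a in enumerate(structure.atoms):
        pos_of.setdefault(a.residue_key, {})[a.name] = i
    for key, atom_map in pos_of.items():
        some = structure.atoms[next(iter(atom_map.values()))]
        resname = some.residue_name
        if resname in PROTEIN_RINGS:
            defs, cls = PROTEIN_RINGS[resname], "protein"
        elif resname in NUCLEIC_RESIDUES:
            defs = PURINE_RINGS if resname in PURINE_RESIDUES else PYRIMIDINE_RINGS
            cls = "nucleic"
        else:
            continue
        for names in defs:
            idxs = [atom_map[n] for n in names if n in atom_map]
            if len(idxs) < len(names):
                continue
            centroid = np.mean([structure.atoms[i].position for i in idxs], axis=0)
            rings.append((cls, centroid, idxs[0]))
    return rings


def _angle(p1: np.ndarray, vertex: np.ndarray, p2: np.ndarray) -> float:
    v1, v2 = p1 - vertex, p2 - vertex
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _donor_angle_ok(structure, ante, i_donor, j_acceptor,
                    config: InteractionConfig) -> bool:
    """Antecedent-donor-acceptor angle >= threshold; vacuous without antecedent."""
    neighbours = ante.get(i_donor, [])
    if not neighbours:
        return True
    d_pos = structure.atoms[i_donor].position
    a_pos = structure.atoms[j_acceptor].position
    return any(
        _angle(structure.atoms[n].position, d_pos, a_pos) >= config.hbond_min_angle
        for n in neighbours)


def compute_interactions(structure: ComplexStructure, scope: str = "inter",
                         config: InteractionConfig = InteractionConfig(),
                         labels: list[frozenset[str]] | None = None,
                         ) -> list[InteractionRecord]:
    """Classify heavy-atom contacts of the complex.

    ``scope='inter'`` restricts pairs to one protein atom against one
    nucleic-acid atom; ``scope='all'`` classifies every atom pair
    (different residues).  Each pair may yield several records, one per
    matching type; pairs within the proximal distance matching nothing
    else yield a single ``proximal`` record.
    """
    if scope not in ("inter", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    if labels is None:
        labels = assign_pharmacophores(structure)
    atoms = structure.atoms
    nchains = set(structure.nucleic_chains())
    pchains = set(structure.protein_chains())
    props = [_AtomProps(a, labels[i], a.chain_id in nchains)
             for i, a in enumerate(atoms)]
    ante = _antecedents(structure, config)

    tree = cKDTree(structure.coords)
    candidate = tree.query_pairs(r=config.max_pair_distance, output_type="ndarray")
    records: list[InteractionRecord] = []
    for i, j in candidate:
        ai, aj = atoms[i], atoms[j]
        if ai.residue_key == aj.residue_key:
            continue
        if scope == "inter":
            if not ((ai.chain_id in pchains and aj.chain_id in nchains)
                    or (aj.chain_id in pchains and ai.chain_id in nchains)):
                continue
        pi, pj = props[i], props[j]
        d = float(np.linalg.norm(ai.position - aj.position))
        vdw_sum = _vdw(ai.element) + _vdw(aj.element)
        types: list[str] = []
        if d <= _cov(ai.element) + _cov(aj.element) + config.covalent_tolerance:
            types.append("covalent")
        if d < vdw_sum - config.clash_gap:
            types.append("clash")
        elif d < vdw_sum:
            types.append("vdw_clash")
        elif d <= vdw_sum + config.vdw_gap:
            types.append("vdw")
        if d <= config.hbond_max and (
                (pi.donor and pj.acceptor
                 and _donor_angle_ok(structure, ante, i, j, config))
                or (pj.donor and pi.acceptor
                    and _donor_angle_ok(structure, ante, j, i, config))):
            types.append("hbond")
        if d <= config.weak_hbond_max and (
                (pi.is_carbon and pj.acceptor) or (pj.is_carbon and pi.acceptor)):
            types.append("weak_hbond")
        if d <= config.ionic_max and (
                (pi.positive and pj.negative) or (pj.positive and pi.negative)):
            types.append("ionic")
        if d <= config.hydrophobic_max and pi.hydrophobic and pj.hydrophobic:
            types.append("hydrophobic")
        if d <= config.carbonyl_max and (
                (ai.name in CARBONYL_OXYGENS and aj.name in CARBONYL_CARBONS
                 and aj.element.upper() == "C")
                or (aj.name in CARBONYL_OXYGENS and ai.name in CARBONYL_CARBONS
                    and ai.element.upper() == "C")):
            types.append("carbonyl")
        if d <= config.halogen_max and (
                (pi.is_halogen and pj.acceptor) or (pj.is_halogen and pi.acceptor)):
            types.append("halogen_bond")
        if d <= config.metal_max and (
                (pi.is_metal and pj.element in ("O", "N", "S"))
                or (pj.is_metal and pi.element in ("O", "N", "S"))):
            types.append("metal")
        if not types and d <= config.proximal_max:
            types.append("proximal")
        for t in types:
            records.append(InteractionRecord(ai, aj, t, d))

    # aromatic ring-centroid contacts
    rings = _rings(structure)
    for a_idx in range(len(rings)):
        for b_idx in range(a_idx + 1, len(rings)):
            cls_a, cen_a, rep_a = rings[a_idx]
            cls_b, cen_b, rep_b = rings[b_idx]
            ra, rb = atoms[rep_a], atoms[rep_b]
            if ra.residue_key == rb.residue_key:
                continue
            if scope == "inter" and {cls_a, cls_b} != {"protein", "nucleic"}:
                continue
            d = float(np.linalg.norm(cen_a - cen_b))
            if d <= config.aromatic_max:
                records.append(InteractionRecord(ra, rb, "aromatic", d))
    return records


def interaction_counts(structure: ComplexStructure, scope: str = "inter",
                       config: InteractionConfig = InteractionConfig(),
                       ) -> dict[str, int]:
    """Per-type contact counts (all 13 types present, zero-filled)."""
    counts = Counter(r.type for r in compute_interactions(structure, scope, config))
    return {t: counts.get(t, 0) for t in INTERACTION_TYPES}


@dataclass
class InteractionSummary:
    wild: dict[str, int]
    mutant: dict[str, int]

    @property
    def delta(self) -> dict[str, int]:
        return {t: self.mutant[t] - self.wild[t] for t in INTERACTION_TYPES}


def interaction_delta(wild: ComplexStructure, mutant: ComplexStructure,
                      scope: str = "inter",
                      config: InteractionConfig = InteractionConfig(),
                      ) -> InteractionSummary:
    """Per-type contact counts in wild-type and mutant, and their change."""
    if set(wild.nucleic_chains()) != set(mutant.nucleic_chains()):
        raise ContractError("wild-type and mutant must share nucleic chains")
    return InteractionSummary(
        wild=interaction_counts(wild, scope, config),
        mutant=interaction_counts(mutant, scope, config),
    )
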