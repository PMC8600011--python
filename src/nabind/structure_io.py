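"""Parsing, writing and basic geometry of protein-nucleic acid complexes.

Complexes are held in a light-weight :class:`ComplexStructure` container: a
flat, ordered list of heavy atoms plus a per-chain polymer classification
(protein / nucleic / other).  PDB reading and writing go through ``gemmi``;
only the first model is used and alternate locations are resolved to the
highest-occupancy conformer (ties broken by alphabetically first altloc).
All geometric criteria in this package are defined on heavy atoms, so
hydrogens (and waters) are dropped on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import NoNucleicAcidError, PDBParseError, ResidueNotFoundError

logger = logging.getLogger(__name__)

#: Three-letter codes of the 20 standard amino acids.
AMINO_ACIDS_3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Deoxyribonucleotide residue codes.
DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DU", "DI"}
#: Ribonucleotide residue codes.
RNA_RESIDUES = {"A", "C", "G", "U", "I"}
NUCLEIC_RESIDUES = DNA_RESIDUES | RNA_RESIDUES

PURINE_RESIDUES = {"DA", "DG", "DI", "A", "G", "I"}
PYRIMIDINE_RESIDUES = {"DC", "DT", "DU", "C", "U", "T"}

WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}


@dataclass
class AtomRecord:
    """One heavy atom of a complex."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class NucleicAcidType:
    """Nucleic-acid class of the partner: RNA/DNA x single/double stranded."""

    kind: str  # one of ssDNA, dsDNA, ssRNA, dsRNA

    def __post_init__(self) -> None:
        if self.kind not in {"ssDNA", "dsDNA", "ssRNA", "dsRNA"}:
            raise ValueError(f"unknown nucleic-acid kind {self.kind!r}")

    @property
    def is_rna(self) -> int:
        return int(self.kind in {"ssRNA", "dsRNA"})

    @property
    def is_double(self) -> int:
        return int(self.kind in {"dsDNA", "dsRNA"})


@dataclass
class ComplexStructure:
    """A parsed protein-nucleic acid complex."""

    atoms: list[AtomRecord]
    chains: dict[str, str] = field(default_factory=dict)  # chain_id -> class
    id: str = ""

    def __post_init__(self) -> None:
        self._invalidate()

    def _invalidate(self) -> None:
        self._coords = None
        self._residue_index = None

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None or len(self._coords) != len(self.atoms):
            self._coords = np.array([a.position for a in self.atoms], dtype=float)
        return self._coords

    def protein_chains(self) -> list[str]:
        return [c for c, k in self.chains.items() if k == "protein"]

    def nucleic_chains(self) -> list[str]:
        return [c for c, k in self.chains.items() if k == "nucleic"]

    def protein_atoms(self) -> list[AtomRecord]:
        prot = set(self.protein_chains())
        return [a for a in self.atoms if a.chain_id in prot]

    def nucleic_atoms(self) -> list[AtomRecord]:
        na = set(self.nucleic_chains())
        return [a for a in self.atoms if a.chain_id in na]

    def residue_atoms(self, chain_id: str, residue_number: int,
                      insertion_code: str = "") -> list[AtomRecord]:
        key = (chain_id, residue_number, insertion_code)
        if self._residue_index is None:
            self._residue_index = {}
            for a in self.atoms:
                self._residue_index.setdefault(a.residue_key, []).append(a)
        try:
            return self._residue_index[key]
        except KeyError:
            raise ResidueNotFoundError(
                f"residue {residue_number}{insertion_code} in chain {chain_id!r} "
                f"not found in complex {self.id!r}"
            ) from None

    def residues(self) -> list[tuple[tuple[str, int, str], list[AtomRecord]]]:
        """Residues in atom order as (key, atoms) pairs."""
        seen: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, []).append(a)
        return list(seen.items())

    def copy(self) -> "ComplexStructure":
        atoms = [
            AtomRecord(a.serial, a.name, a.element, a.residue_name, a.chain_id,
                       a.residue_number, a.insertion_code,
                       np.array(a.position, dtype=float), a.occupancy, a.altloc)
            for a in self.atoms
        ]
        return ComplexStructure(atoms=atoms, chains=dict(self.chains), id=self.id)


def classify_chain(residue_names: list[str]) -> str:
    """Classify a chain by majority residue-name vocabulary."""
    n_prot = sum(1 for r in residue_names if r in AMINO_ACIDS_3)
    n_nuc = sum(1 for r in residue_names if r in NUCLEIC_RESIDUES)
    if n_prot == 0 and n_nuc == 0:
        return "other"
    return "protein" if n_prot >= n_nuc else "nucleic"


def parse_structure(pdb_text: str, keep_hetero: bool = False,
                    structure_id: str = "") -> ComplexStructure:
    """Parse PDB text into a :class:`ComplexStructure`.

    First model only; hydrogens and waters are dropped; altloc groups are
    resolved to the highest-occupancy conformer (ties to the alphabetically
    first altloc).  HETATM records other than waters are kept only with
    ``keep_hetero`` (metal ions are always kept: they take part in the
    metal-coordination interaction type).
    """
    if not pdb_text or not pdb_text.strip():
        raise PDBParseError("empty PDB input")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"cannot parse PDB text: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError("PDB text contains no model")
    st.setup_entities()
    model = st[0]

    atoms: list[AtomRecord] = []
    chain_resnames: dict[str, list[str]] = {}
    serial = 0
    for chain in model:
        for res in chain:
            resname = res.name.strip()
            if resname in WATER_RESIDUES:
                continue
            het = res.het_flag == "H" and resname not in NUCLEIC_RESIDUES \
                and resname not in AMINO_ACIDS_3
            is_metal = len(res) == 1 and res[0].element.is_metal
            if het and not keep_hetero and not is_metal:
                continue
            # altloc resolution: per atom name keep max occupancy, tie -> first altloc
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                if at.element.name in ("H", "D"):
                    continue
                by_name.setdefault(at.name, []).append(at)
            chain_resnames.setdefault(chain.name, []).append(resname)
            for name, group in by_name.items():
                best = min(group, key=lambda a: (-a.occ, a.altloc or "~"))
                serial += 1
                atoms.append(AtomRecord(
                    serial=serial,
                    name=name,
                    element=best.element.name,
                    residue_name=resname,
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    position=np.array([best.pos.x, best.pos.y, best.pos.z]),
                    occupancy=best.occ,
                    altloc=(best.altloc or "").strip(),
                ))
    if not atoms:
        raise PDBParseError("PDB text contains no usable ATOM records")
    chains = {c: classify_chain(names) for c, names in chain_resnames.items()}
    return ComplexStructure(atoms=atoms, chains=chains, id=structure_id or st.name or "")


def write_pdb(structure: ComplexStructure) -> str:
    """Serialize a complex back to PDB text (via gemmi)."""
    st = gemmi.Structure()
    st.name = structure.id or "complex"
    model = gemmi.Model("1")
    cur_chain = None
    cur_res = None
    cur_res_key = None
    for a in structure.atoms:
        if cur_chain is None or cur_chain.name != a.chain_id:
            cur_chain = gemmi.Chain(a.chain_id)
            model.add_chain(cur_chain)
            cur_chain = model[len(model) - 1]
            cur_res_key = None
        key = a.residue_key + (a.residue_name,)
        if key != cur_res_key:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            cur_chain.add_residue(res)
            cur_res = cur_chain[len(cur_chain) - 1]
            cur_res_key = key
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*a.position)
        at.occ = a.occupancy
        at.altloc = a.altloc or "\0"
        cur_res.add_atom(at)
    st.add_model(model)
    return st.make_pdb_string(gemmi.PdbWriteOptions(ter_records=True, end_record=True))


def _base_pair_count(structure: ComplexStructure) -> int:
    """Number of Watson-Crick-geometry contacts (purine N1 - pyrimidine N3 <= 3.5 A)."""
    pur = [a for a in structure.nucleic_atoms()
           if a.residue_name in PURINE_RESIDUES and a.name == "N1"]
    pyr = [a for a in structure.nucleic_atoms()
           if a.residue_name in PYRIMIDINE_RESIDUES and a.name == "N3"]
    count = 0
    for p in pur:
        for q in pyr:
            if p.residue_key == q.residue_key:
                continue
            if np.linalg.norm(p.position - q.position) <= 3.5:
                count += 1
    return count


def detect_na_type(structure: ComplexStructure,
                   override: str | None = None) -> NucleicAcidType:
    """Determine the nucleic-acid type of the complex.

    RNA iff any nucleotide carries an O2' atom or a ribonucleotide residue
    code; double-stranded iff at least three Watson-Crick-geometry base
    pairs exist (purine N1 to pyrimidine N3 within 3.5 A).  A user-supplied
    override wins over detection.  Complexes containing both DNA and RNA
    chains are typed by the majority nucleic chain (a warning is logged).
    """
    if override is not None:
        return NucleicAcidType(kind=override)
    na_atoms = structure.nucleic_atoms()
    if not na_atoms:
        raise NoNucleicAcidError(
            f"complex {structure.id!r} contains no nucleic-acid chain")
    # per-chain RNA vote
    chain_is_rna: dict[str, bool] = {}
    for c in structure.nucleic_chains():
        catoms = [a for a in na_atoms if a.chain_id == c]
        has_o2p = any(a.name == "O2'" for a in catoms)
        ribo = any(a.residue_name in RNA_RESIDUES for a in catoms)
        chain_is_rna[c] = has_o2p or ribo
    votes = list(chain_is_rna.values())
    if any(votes) and not all(votes):
        logger.warning(
            "complex %s has both DNA and RNA chains; typing by majority",
            structure.id)
    rna = sum(votes) * 2 > len(votes)
    double = _base_pair_count(structure) >= 3
    kind = ("ds" if double else "ss") + ("RNA" if rna else "DNA")
    return NucleicAcidType(kind=kind)


def min_distance_to_na(structure: ComplexStructure, chain_id: str,
                       residue_number: int, insertion_code: str = "",
                       cutoff: float = 8.0) -> tuple[float, str]:
    """Minimum heavy-atom distance from a protein residue to the nucleic acid.

    Returns ``(distance, label)`` with label ``proximal`` iff the distance is
    within ``cutoff`` (boundary inclusive, default 8 A).
    """
    res_atoms = structure.residue_atoms(chain_id, residue_number, insertion_code)
    na_atoms = structure.nucleic_atoms()
    if not na_atoms:
        raise NoNucleicAcidError(
            f"complex {structure.id!r} contains no nucleic-acid chain")
    na_xyz = np.array([a.position for a in na_atoms])
    res_xyz = np.array([a.position for a in res_atoms])
    tree = cKDTree(na_xyz)
    d, _ = tree.query(res_xyz, k=1)
    dist = float(np.min(d))
    return dist, ("proximal" if dist <= cutoff else "distal")


def interface_residues(structure: ComplexStructure,
                       cutoff: float = 8.0) -> list[tuple[str, int, str]]:
    """Protein residues with any heavy atom within ``cutoff`` of the nucleic acid."""
    na_atoms = structure.nucleic_atoms()
    if not na_atoms:
        raise NoNucleicAcidError(
            f"complex {structure.id!r} contains no nucleic-acid chain")
    tree = cKDTree(np.array([a.position for a in na_atoms]))
    out = []
    for key, atoms in structure.residues():
        if structure.chains.get(key[0]) != "protein":
            continue
        if atoms[0].residue_name not in AMINO_ACIDS_3:
            continue
        d, _ = tree.query(np.array([a.position for a in atoms]), k=1)
        if np.min(d) <= cutoff:
            out.append(key)
    return out
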