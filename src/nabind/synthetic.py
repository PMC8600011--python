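"""Deterministic toy protein-nucleic acid complexes and synthetic ddG data.

Fixtures are generated, never downloaded: an ideal alpha-helical peptide
(phi = -57, psi = -47, built by internal-coordinate chain extension) is
placed a configurable gap away from an idealized B-form (DNA) or A-form
(RNA) strand or duplex assembled from planar Watson-Crick base-pair
templates.  Synthetic affinity datasets draw random mutation constructs
on interface residues and set ddG to a known linear function of computed
features plus Gaussian noise, so that model validation can check
parameter recovery against a ground truth.

The generative model has no physical energetics: it exists to exercise
every pipeline stage reproducibly (same spec and seed give bit-identical
output).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import (AffinityDataset, AffinityRecord, MutationConstruct,
                      MutationSpec)
from .errors import NabindError
from .features import ComplexFeaturizer, FeatureConfig
from .structure_io import (AA_3TO1, AtomRecord, ComplexStructure,
                           classify_chain, interface_residues, write_pdb)
from .templates import (NUCLEOTIDE_ATOM_ORDER, WC_PARTNER, build_sidechain,
                        element_of, nucleotide_template)

#: residues the toy peptide draws from (Gly/Pro excluded: special backbone)
PEPTIDE_ALPHABET = ("LYS", "ARG", "ASP", "GLU", "SER", "TYR", "ASN", "LEU",
                    "PHE", "THR", "GLN", "HIS", "VAL", "ILE", "TRP", "MET",
                    "ALA", "CYS")


@dataclass(frozen=True)
class ToySpec:
    """Parameters of one toy complex; same spec -> bit-identical PDB text."""

    n_peptide_residues: int = 10
    na_kind: str = "dsDNA"
    n_nucleotides: int = 6
    interface_gap: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptide_residues < 3 or self.n_nucleotides < 2:
            raise ValueError("need >= 3 peptide residues and >= 2 nucleotides")
        if self.na_kind not in ("ssDNA", "dsDNA", "ssRNA", "dsRNA"):
            raise ValueError(f"unknown nucleic-acid kind {self.na_kind!r}")


# ---------------------------------------------------------------------------
# internal-coordinate (NeRF) chain extension

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
                angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position D from A-B-C with |CD|, angle BCD and dihedral ABCD."""
    angle = np.radians(angle_deg)
    dihedral = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_helical_peptide(sequence: list[str], chain_id: str = "A",
                          phi: float = -57.0, psi: float = -47.0,
                          omega: float = 180.0) -> list[AtomRecord]:
    """Ideal alpha-helix with template side chains."""
    n_res = len(sequence)
    bb: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    th = np.radians(180.0 - 111.2)
    c0 = ca0 + 1.524 * np.array([np.cos(th), np.sin(th), 0.0])
    bb.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_res):
        prev = bb[-1]
        n_next = _place_atom(prev["N"], prev["CA"], prev["C"],
                             1.329, 116.2, psi)
        ca_next = _place_atom(prev["CA"], prev["C"], n_next,
                              1.458, 121.7, omega)
        c_next = _place_atom(prev["C"], n_next, ca_next, 1.524, 111.2, phi)
        bb.append({"N": n_next, "CA": ca_next, "C": c_next})
    atoms: list[AtomRecord] = []
    for i, resname in enumerate(sequence):
        f = bb[i]
        o = _place_atom(f["N"], f["CA"], f["C"], 1.231, 120.5, psi + 180.0)
        res_atoms = [("N", "N", f["N"]), ("CA", "C", f["CA"]),
                     ("C", "C", f["C"]), ("O", "O", o)]
        res_atoms += build_sidechain(resname, f["N"], f["CA"], f["C"])
        for name, element, pos in res_atoms:
            atoms.append(AtomRecord(
                serial=0, name=name, element=element, residue_name=resname,
                chain_id=chain_id, residue_number=i + 1, insertion_code="",
                position=np.asarray(pos, dtype=float)))
    return atoms


# ---------------------------------------------------------------------------
# nucleic-acid builder

def _rot_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_DYAD = np.diag([1.0, -1.0, -1.0])  # two-fold about x: swaps the strands


def build_na(kinds: list[str], double: bool, ribo: bool,
             chain_a: str = "B", chain_b: str = "C",
             ) -> list[AtomRecord]:
    """Idealized helical strand/duplex from base-pair templates.

    ``kinds`` lists the strand-A residue codes 5'->3'; strand B (if
    ``double``) carries the Watson-Crick complement via the pair dyad.
    B-form rise/twist for DNA (3.4 A / 36 deg), A-form for RNA
    (2.8 A / 32.7 deg).
    """
    rise, twist = (2.8, np.radians(32.7)) if ribo else (3.4, np.radians(36.0))
    atoms_a: list[AtomRecord] = []
    atoms_b: list[AtomRecord] = []
    purines = {"DA", "DG", "A", "G"}
    for k, resname in enumerate(kinds):
        rot = _rot_z(twist * k)
        shift = np.array([0.0, 0.0, rise * k])
        partner = WC_PARTNER[resname]
        if resname in purines:
            tmpl_a = nucleotide_template(resname, ribo)
            tmpl_b = {n: _DYAD @ p for n, p in
                      nucleotide_template(partner, ribo).items()}
        else:
            tmpl_a = {n: _DYAD @ p for n, p in
                      nucleotide_template(resname, ribo).items()}
            tmpl_b = nucleotide_template(partner, ribo)
        for name in NUCLEOTIDE_ATOM_ORDER:
            if name in tmpl_a:
                atoms_a.append(AtomRecord(
                    serial=0, name=name, element=element_of(name),
                    residue_name=resname, chain_id=chain_a,
                    residue_number=k + 1, insertion_code="",
                    position=rot @ tmpl_a[name] + shift))
            if double and name in tmpl_b:
                atoms_b.append(AtomRecord(
                    serial=0, name=name, element=element_of(name),
                    residue_name=partner, chain_id=chain_b,
                    residue_number=len(kinds) - k, insertion_code="",
                    position=rot @ tmpl_b[name] + shift))
    return atoms_a + atoms_b


def _min_dist(xyz_a: np.ndarray, xyz_b: np.ndarray) -> tuple[float, np.ndarray]:
    from scipy.spatial import cKDTree

    tree = cKDTree(xyz_b)
    d, j = tree.query(xyz_a, k=1)
    i = int(np.argmin(d))
    return float(d[i]), xyz_a[i] - xyz_b[j[i]]


def generate_toy_complex(spec: ToySpec) -> tuple[ComplexStructure, str]:
    """Build the toy complex and its PDB text."""
    rng = np.random.default_rng(spec.seed)
    sequence = [PEPTIDE_ALPHABET[i] for i in
                rng.integers(0, len(PEPTIDE_ALPHABET),
                             spec.n_peptide_residues)]
    peptide = build_helical_peptide(sequence)
    ribo = spec.na_kind.endswith("RNA")
    double = spec.na_kind.startswith("ds")
    alphabet = ("A", "G", "C", "U") if ribo else ("DA", "DG", "DC", "DT")
    kinds = [alphabet[i] for i in rng.integers(0, 4, spec.n_nucleotides)]
    na = build_na(kinds, double, ribo)

    # align the helix principal axis with the nucleic-acid axis (z) so that
    # several residues face the interface, then place at the requested gap
    pep_xyz = np.array([a.position for a in peptide])
    ca = np.array([a.position for a in peptide if a.name == "CA"])
    centered = ca - ca.mean(axis=0)
    axis = np.linalg.svd(centered, full_matrices=False)[2][0]
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(axis @ z)
    if s > 1e-8:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
        pep_xyz = (pep_xyz - ca.mean(axis=0)) @ rot.T
    na_xyz = np.array([a.position for a in na])
    offset = np.array([
        float(np.max(na_xyz[:, 0]) - np.min(pep_xyz[:, 0])
              + spec.interface_gap + 2.0),
        float(np.mean(na_xyz[:, 1]) - np.mean(pep_xyz[:, 1])),
        float(np.mean(na_xyz[:, 2]) - np.mean(pep_xyz[:, 2])),
    ])
    for _ in range(50):
        d, dvec = _min_dist(pep_xyz + offset, na_xyz)
        err = d - spec.interface_gap
        if abs(err) < 0.05:
            break
        # adjust in the plane perpendicular to both helix axes so the
        # peptide stays registered along the nucleic acid
        dvec = dvec * np.array([1.0, 1.0, 0.0])
        norm = np.linalg.norm(dvec)
        if norm < 1e-9:
            break
        offset -= 0.8 * err * dvec / norm
    for a, p in zip(peptide, pep_xyz):
        a.position = p + offset

    atoms = peptide + na
    for i, a in enumerate(atoms, start=1):
        a.serial = i
    chain_names: dict[str, list[str]] = {}
    for a in atoms:
        chain_names.setdefault(a.chain_id, []).append(a.residue_name)
    chains = {c: classify_chain(v) for c, v in chain_names.items()}
    structure = ComplexStructure(
        atoms=atoms, chains=chains,
        id=f"toy-{spec.na_kind}-{spec.n_peptide_residues}x"
           f"{spec.n_nucleotides}-s{spec.seed}")
    return structure, write_pdb(structure)


# ---------------------------------------------------------------------------
# synthetic affinity datasets

DEFAULT_EFFECT_SPEC = {
    "sub:blosum62": 0.5,
    "sub:contact_potential": 0.6,
    "geo:min_dist_na": -0.2,
}


@dataclass
class SyntheticDataset:
    """Synthetic records, their features and the generative ground truth."""

    dataset: AffinityDataset
    features: "object"            # pandas DataFrame aligned with records
    coefficients: dict[str, float]
    noise_sigma: float
    intercept: float = 0.0
    seed: int = 0


def generate_synthetic_dataset(complexes: list[ComplexStructure],
                               effect_spec: dict[str, float] | None = None,
                               noise_sigma: float = 0.2,
                               n_records: int = 500,
                               seed: int = 0,
                               multi_fraction: float = 0.1,
                               feature_config: FeatureConfig = FeatureConfig(),
                               ) -> SyntheticDataset:
    """Random mutation constructs with ddG linear in computed features.

    Sites are drawn from interface residues (within 8 A of the nucleic
    acid); ~``multi_fraction`` of the records are two-point constructs.
    ddG = sum(coeff * feature) + N(0, noise_sigma); group ids follow the
    complex, so group-aware CV can be exercised.
    """
    import pandas as pd

    effect = dict(effect_spec or DEFAULT_EFFECT_SPEC)
    rng = np.random.default_rng(seed)
    feats = [ComplexFeaturizer(s, config=feature_config) for s in complexes]
    sites_per = [interface_residues(s, 8.0) for s in complexes]
    for s, sites in zip(complexes, sites_per):
        if not sites:
            raise NabindError(f"complex {s.id!r} has no interface residues")
    letters = sorted(AA_3TO1.values())
    records: list[AffinityRecord] = []
    rows: list = []
    for i in range(n_records):
        ci = int(rng.integers(0, len(complexes)))
        structure, featurizer = complexes[ci], feats[ci]
        n_sites = 2 if (rng.random() < multi_fraction
                        and len(sites_per[ci]) >= 2) else 1
        picked = rng.choice(len(sites_per[ci]), size=n_sites, replace=False)
        specs = []
        for si in sorted(picked):
            chain, num, icode = sites_per[ci][si]
            wt3 = structure.residue_atoms(chain, num, icode)[0].residue_name
            wt = AA_3TO1[wt3]
            mut = letters[int(rng.integers(0, 20))]
            while mut == wt:
                mut = letters[int(rng.integers(0, 20))]
            specs.append(MutationSpec(chain_id=chain, wt=wt,
                                      residue_number=num, mut=mut,
                                      insertion_code=icode))
        construct = MutationConstruct(specs=tuple(specs))
        vec = featurizer.featurize_construct(construct)
        missing = [k for k in effect if k not in vec.index]
        if missing:
            raise NabindError(f"effect features not computed: {missing}")
        ddg = float(sum(c * vec[k] for k, c in effect.items())
                    + rng.normal(0.0, noise_sigma))
        records.append(AffinityRecord(
            complex_id=structure.id, construct=construct, ddg=ddg,
            na_type=featurizer.na_type, group_id=structure.id))
        rows.append(vec)
    features = pd.DataFrame([r.values for r in rows],
                            columns=rows[0].index)
    return SyntheticDataset(dataset=AffinityDataset(records=records),
                            features=features, coefficients=effect,
                            noise_sigma=noise_sigma, seed=seed)


def augment_synthetic(complexes: list[ComplexStructure],
                      syn: SyntheticDataset,
                      feature_config: FeatureConfig = FeatureConfig(),
                      ) -> tuple[AffinityDataset, "object"]:
    """Reverse-augment a synthetic dataset and featurize the reverse records.

    A reverse record's wild-type structure is the modelled mutant of its
    forward partner; its feature vector is computed on that structure
    with the reversed mutation.  Returns the augmented dataset and the
    row-aligned feature table.
    """
    import pandas as pd

    from .dataset import augment_with_reverse
    from .features import apply_construct

    by_id = {s.id: s for s in complexes}
    aug = augment_with_reverse(syn.dataset)
    rows = []
    n_fwd = len(syn.dataset)
    for i, rec in enumerate(aug.records):
        if i < n_fwd:
            rows.append(syn.features.iloc[i])
            continue
        wild = by_id[rec.complex_id]
        spec = rec.construct.specs[0]
        forward = MutationConstruct(specs=(spec.reversed(),))
        mutant = apply_construct(wild, forward)
        featurizer = ComplexFeaturizer(mutant, config=feature_config)
        rows.append(featurizer.featurize(spec))
    features = pd.DataFrame([r.values for r in rows], columns=rows[0].index)
    return aug, features


def default_toy_suite(seed: int = 0) -> list[ComplexStructure]:
    """Five toy complexes covering all four nucleic-acid kinds."""
    specs = [
        ToySpec(12, "dsDNA", 10, 4.0, seed + 1),
        ToySpec(12, "ssDNA", 10, 4.0, seed + 2),
        ToySpec(10, "dsRNA", 8, 4.0, seed + 3),
        ToySpec(11, "ssRNA", 9, 4.0, seed + 4),
        ToySpec(14, "dsDNA", 10, 4.0, seed + 5),
    ]
    return [generate_toy_complex(s)[0] for s in specs]
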