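"""Pharmacophore (physicochemical atom-class) labelling.

Protein atoms are labelled with one or more of seven classes — aromatic,
hydrophobic, negative, positive, hydrogen-bond donor, hydrogen-bond
acceptor, neutral — from a packaged residue/atom-name lookup table that
follows standard pharmacophore conventions (Arg/Lys/His positive, Asp/Glu
negative, Phe/Tyr/Trp/His ring atoms aromatic, aliphatic carbons
hydrophobic, backbone N donor / O acceptor).  Nucleic-acid atoms carry
exactly one component class: phosphate, sugar, or a base class split by
ring system (purine vs pyrimidine).

Label assignment is a pure function of (residue name, atom name); a user
table in the same CSV format can be substituted for the packaged one.
"""

from __future__ import annotations

import csv
import logging
from importlib import resources

from .errors import ContractError
from .structure_io import (AMINO_ACIDS_3, NUCLEIC_RESIDUES, PURINE_RESIDUES,
                           AtomRecord, ComplexStructure)

logger = logging.getLogger(__name__)

PROTEIN_CLASSES = ("aromatic", "hydrophobic", "negative", "positive",
                   "donor", "acceptor", "neutral")
NA_CLASSES = ("phosphate", "sugar", "base_purine", "base_pyrimidine")

#: Canonical class ordering used by signature vectors.
ALL_CLASSES = PROTEIN_CLASSES + NA_CLASSES

PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "OP3", "O5'", "O3'", "O1P", "O2P", "O3P"}


def load_pharmacophore_table(path: str | None = None) -> dict[tuple[str, str], frozenset[str]]:
    """Load the (residue, atom) -> classes table.

    ``path`` substitutes a user CSV (columns residue, atom, classes with
    ';'-separated class names) for the packaged default.
    """
    if path is None:
        source = resources.files("nabind.data").joinpath("pharmacophore.csv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[tuple[str, str], frozenset[str]] = {}
    for row in csv.DictReader(text.splitlines()):
        classes = frozenset(row["classes"].split(";"))
        bad = classes - set(PROTEIN_CLASSES)
        if bad:
            raise ValueError(f"unknown pharmacophore classes {sorted(bad)}")
        table[(row["residue"].strip(), row["atom"].strip())] = classes
    return table


_DEFAULT_TABLE: dict[tuple[str, str], frozenset[str]] | None = None


def _default_table() -> dict[tuple[str, str], frozenset[str]]:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_pharmacophore_table()
    return _DEFAULT_TABLE


def label_na_atom(atom: AtomRecord) -> frozenset[str]:
    """Component class of a nucleic-acid atom from atom-name convention."""
    name = atom.name
    if name in PHOSPHATE_ATOMS:
        return frozenset({"phosphate"})
    if "'" in name or "*" in name:  # primed atoms: the (deoxy)ribose
        return frozenset({"sugar"})
    if atom.residue_name in PURINE_RESIDUES:
        return frozenset({"base_purine"})
    return frozenset({"base_pyrimidine"})


def label_atom(atom: AtomRecord, chain_class: str,
               table: dict[tuple[str, str], frozenset[str]] | None = None,
               ) -> frozenset[str]:
    """Pharmacophore classes of one atom (pure in residue and atom name)."""
    if chain_class == "nucleic" or atom.residue_name in NUCLEIC_RESIDUES:
        return label_na_atom(atom)
    tab = table if table is not None else _default_table()
    try:
        return tab[(atom.residue_name, atom.name)]
    except KeyError:
        if atom.residue_name not in AMINO_ACIDS_3:
            logger.debug("non-standard residue %s: atom %s labelled neutral",
                         atom.residue_name, atom.name)
        return frozenset({"neutral"})


def assign_pharmacophores(structure: ComplexStructure,
                          table: dict[tuple[str, str], frozenset[str]] | None = None,
                          ) -> list[frozenset[str]]:
    """Labels for every atom of the complex, in atom order."""
    if not structure.chains:
        raise ContractError("chains must be classified before labelling")
    return [label_atom(a, structure.chains.get(a.chain_id, "other"), table)
            for a in structure.atoms]
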