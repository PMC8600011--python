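"""Per-construct feature assembly.

For one point mutation the feature vector concatenates:

* ``sig:*``   wild-type environment signature counts (cutoff scanning);
* ``dsig:*``  mutant-minus-wild signature differences;
* ``sub:*``   substitution-matrix scores of the amino-acid exchange
              (BLOSUM62 and PAM250, plus a packaged synthetic
              quasi-chemical-style contact-potential score);
* ``nma:delta_s_vib``  elastic-network vibrational-entropy change;
* ``int:<type>:wt`` / ``int:<type>:delta``  interaction-network counts
              for the 13 contact types and their change upon mutation;
* ``na:is_rna``, ``na:is_double``  nucleic-acid type binaries;
* ``geo:min_dist_na``  minimum heavy-atom distance from the site to the
              nucleic acid;
* ``opt:stability_ddg``  optional user-supplied protein-stability change
              (imputed as 0 when absent).

Multiple-point constructs are featurized from their single-point parts
and aggregated per feature (counts and deltas accumulate, scores and
distances average).

Mutant structures come from a naive template-rotamer builder aligned on
the local backbone frame; an externally built mutant PDB can be supplied
to short-circuit it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .dataset import MutationConstruct, MutationSpec
from .dynamics import vibrational_entropy_change
from .errors import MutationValidationError, SchemaMismatchError
from .interactions import (INTERACTION_TYPES, InteractionConfig,
                           interaction_counts)
from .pharmacophore import assign_pharmacophores
from .signatures import SignatureConfig, signature_feature_names, site_signature
from .structure_io import (AA_1TO3, AA_3TO1, AtomRecord, ComplexStructure,
                           NucleicAcidType, detect_na_type, min_distance_to_na)
from .templates import build_sidechain

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


def naive_mutant(structure: ComplexStructure,
                 mutation: MutationSpec) -> ComplexStructure:
    """Replace the side chain of the mutated residue by an idealized template.

    The backbone (N/CA/C/O) is untouched; the template rotamer is placed
    in the local N/CA/C frame.  Self-mutations return an unchanged copy.
    A wild-type letter mismatch raises, quoting the residue found.
    """
    site_atoms = structure.residue_atoms(mutation.chain_id,
                                         mutation.residue_number,
                                         mutation.insertion_code)
    found = site_atoms[0].residue_name
    expected = AA_1TO3[mutation.wt]
    if found != expected:
        raise MutationValidationError(
            f"wild-type mismatch at {mutation.chain_id} "
            f"{mutation.residue_number}{mutation.insertion_code}: "
            f"found {found}, mutation says {expected}")
    mutant = structure.copy()
    if mutation.wt == mutation.mut:
        return mutant
    target = AA_1TO3[mutation.mut]
    site_key = (mutation.chain_id, mutation.residue_number,
                mutation.insertion_code)
    backbone = {a.name: a for a in mutant.atoms
                if a.residue_key == site_key and a.name in BACKBONE_ATOMS}
    for name in ("N", "CA", "C"):
        if name not in backbone:
            raise MutationValidationError(
                f"site {site_key} lacks backbone atom {name}")
    new_atoms: list[AtomRecord] = []
    inserted = False
    for a in mutant.atoms:
        if a.residue_key != site_key:
            new_atoms.append(a)
            continue
        if a.name in BACKBONE_ATOMS:
            a.residue_name = target
            new_atoms.append(a)
            if a.name == "C" and not inserted:
                inserted = True
                side = build_sidechain(target, backbone["N"].position,
                                       backbone["CA"].position,
                                       backbone["C"].position)
                for at_name, element, pos in side:
                    new_atoms.append(AtomRecord(
                        serial=0, name=at_name, element=element,
                        residue_name=target, chain_id=a.chain_id,
                        residue_number=a.residue_number,
                        insertion_code=a.insertion_code,
                        position=np.asarray(pos, dtype=float)))
        # non-backbone atoms of the site are dropped (side chain replaced)
    for i, a in enumerate(new_atoms, start=1):
        a.serial = i
    out = ComplexStructure(atoms=new_atoms, chains=dict(mutant.chains),
                           id=mutant.id)
    return out


def apply_construct(structure: ComplexStructure,
                    construct: MutationConstruct) -> ComplexStructure:
    """Apply every point mutation of a construct with the naive builder."""
    out = structure
    for spec in construct:
        out = naive_mutant(out, spec)
    return out


# ---------------------------------------------------------------------------
# substitution matrices

def _load_contact_potential() -> pd.DataFrame:
    text = resources.files("nabind.data").joinpath(
        "contact_potential_synthetic.tsv").read_text()
    rows = [ln.split() for ln in text.splitlines()
            if ln.strip() and not ln.startswith("#")]
    header = rows[0]
    data = {r[0]: [float(x) for x in r[1:]] for r in rows[1:]}
    return pd.DataFrame(data, index=header).T[header]


def load_substitution_matrices(names: tuple[str, ...] = (
        "blosum62", "pam250", "contact_potential")) -> dict[str, pd.DataFrame]:
    """Named 20x20 substitution-score tables over the standard amino acids."""
    from Bio.Align import substitution_matrices

    aas = sorted(AA_3TO1.values())
    out: dict[str, pd.DataFrame] = {}
    for name in names:
        if name == "contact_potential":
            mat = _load_contact_potential()
            out[name] = mat.loc[aas, aas].astype(float)
        else:
            raw = substitution_matrices.load(name.upper())
            frame = pd.DataFrame(
                [[float(raw[a][b]) for b in aas] for a in aas],
                index=aas, columns=aas)
            out[name] = frame
    return out


_MATRICES: dict[str, pd.DataFrame] | None = None


def default_matrices() -> dict[str, pd.DataFrame]:
    global _MATRICES
    if _MATRICES is None:
        _MATRICES = load_substitution_matrices()
    return _MATRICES


def substitution_features(wt: str, mut: str,
                          matrices: dict[str, pd.DataFrame] | None = None,
                          ) -> dict[str, float]:
    """One ``sub:<name>`` score per matrix, looked up as scores[wt][mut]."""
    if wt not in AA_1TO3 or mut not in AA_1TO3:
        raise MutationValidationError(f"non-standard amino acid {wt!r}/{mut!r}")
    mats = matrices if matrices is not None else default_matrices()
    return {f"sub:{name}": float(m.loc[wt, mut]) for name, m in mats.items()}


# ---------------------------------------------------------------------------
# schema and assembly

@dataclass(frozen=True)
class FeatureConfig:
    """Knobs of the featurization pipeline."""

    signature: SignatureConfig = SignatureConfig()
    interaction: InteractionConfig = InteractionConfig()
    interaction_scope: str = "inter"
    enm_cutoff: float = 10.0
    enm_mode: str = "calpha_p"
    matrix_names: tuple[str, ...] = ("blosum62", "pam250", "contact_potential")
    #: feature-name prefixes aggregated by summation for multi-point constructs
    sum_prefixes: tuple[str, ...] = ("sig", "dsig", "int", "nma")


def feature_schema(config: FeatureConfig = FeatureConfig()) -> list[str]:
    names = signature_feature_names(config.signature, "sig")
    names += signature_feature_names(config.signature, "dsig")
    names += [f"sub:{m}" for m in config.matrix_names]
    names.append("nma:delta_s_vib")
    names += [f"int:{t}:wt" for t in INTERACTION_TYPES]
    names += [f"int:{t}:delta" for t in INTERACTION_TYPES]
    names += ["na:is_rna", "na:is_double", "geo:min_dist_na",
              "opt:stability_ddg"]
    return names


class ComplexFeaturizer:
    """Featurizes mutations of one complex, caching wild-type quantities."""

    def __init__(self, structure: ComplexStructure,
                 na_type: NucleicAcidType | None = None,
                 config: FeatureConfig = FeatureConfig()) -> None:
        self.structure = structure
        self.config = config
        self.na_type = na_type or detect_na_type(structure)
        self.matrices = load_substitution_matrices(config.matrix_names)
        self._labels = assign_pharmacophores(structure)
        self._wild_int: dict[str, int] | None = None
        self._site_cache: dict[tuple, tuple[np.ndarray, float]] = {}

    @property
    def schema(self) -> list[str]:
        return feature_schema(self.config)

    def _wild_interactions(self) -> dict[str, int]:
        if self._wild_int is None:
            self._wild_int = interaction_counts(
                self.structure, self.config.interaction_scope,
                self.config.interaction)
        return self._wild_int

    def _wild_site(self, spec: MutationSpec) -> tuple[np.ndarray, float]:
        key = spec.site
        if key not in self._site_cache:
            sig = site_signature(self.structure, spec.chain_id,
                                 spec.residue_number, spec.insertion_code,
                                 self.config.signature, self._labels)
            dist, _ = min_distance_to_na(self.structure, spec.chain_id,
                                         spec.residue_number,
                                         spec.insertion_code)
            self._site_cache[key] = (sig, dist)
        return self._site_cache[key]

    def featurize(self, spec: MutationSpec,
                  mutant_structure: ComplexStructure | None = None,
                  stability_ddg: float | None = None) -> pd.Series:
        """Feature vector of one point mutation."""
        cfg = self.config
        mutant = mutant_structure or naive_mutant(self.structure, spec)
        sig_wt, dist = self._wild_site(spec)
        sig_mut = site_signature(mutant, spec.chain_id, spec.residue_number,
                                 spec.insertion_code, cfg.signature)
        values: dict[str, float] = {}
        for name, v in zip(signature_feature_names(cfg.signature, "sig"),
                           sig_wt):
            values[name] = float(v)
        for name, wt_v, mut_v in zip(
                signature_feature_names(cfg.signature, "dsig"),
                sig_wt, sig_mut):
            values[name] = float(mut_v - wt_v)
        values.update(substitution_features(spec.wt, spec.mut, self.matrices))
        values["nma:delta_s_vib"] = vibrational_entropy_change(
            self.structure, mutant, cfg.enm_cutoff, cfg.enm_mode)
        wt_counts = self._wild_interactions()
        mut_counts = interaction_counts(mutant, cfg.interaction_scope,
                                        cfg.interaction)
        for t in INTERACTION_TYPES:
            values[f"int:{t}:wt"] = float(wt_counts[t])
            values[f"int:{t}:delta"] = float(mut_counts[t] - wt_counts[t])
        values["na:is_rna"] = float(self.na_type.is_rna)
        values["na:is_double"] = float(self.na_type.is_double)
        values["geo:min_dist_na"] = dist
        if stability_ddg is None:
            logger.debug("opt:stability_ddg absent for %s; imputing 0", spec)
            stability_ddg = 0.0
        values["opt:stability_ddg"] = float(stability_ddg)
        return pd.Series(values, index=self.schema, dtype=float)

    def featurize_construct(self, construct: MutationConstruct,
                            mode: str = "mixed",
                            stability_ddg: float | None = None) -> pd.Series:
        singles = [self.featurize(spec, stability_ddg=stability_ddg)
                   for spec in construct]
        return aggregate_multi(singles, mode=mode,
                               sum_prefixes=self.config.sum_prefixes)


def assemble_features(structure: ComplexStructure,
                      mutant_structure: ComplexStructure | None,
                      mutation: MutationSpec,
                      na_type: NucleicAcidType | None = None,
                      config: FeatureConfig = FeatureConfig(),
                      stability_ddg: float | None = None) -> pd.Series:
    """One-shot feature vector for a single point mutation."""
    feat = ComplexFeaturizer(structure, na_type, config)
    return feat.featurize(mutation, mutant_structure, stability_ddg)


def aggregate_multi(singles: list[pd.Series], mode: str = "mixed",
                    sum_prefixes: tuple[str, ...] = ("sig", "dsig", "int",
                                                     "nma")) -> pd.Series:
    """Combine single-point feature vectors into a construct vector.

    ``mode='sum'`` or ``'mean'`` applies uniformly; ``'mixed'`` (default)
    accumulates count-like features (prefixes in ``sum_prefixes``) and
    averages scores, distances and binaries.
    """
    if not singles:
        raise ValueError("need at least one feature vector")
    idx = singles[0].index
    for s in singles[1:]:
        if not s.index.equals(idx):
            raise SchemaMismatchError("feature vectors differ in schema")
    frame = pd.DataFrame([s.values for s in singles], columns=idx)
    if mode == "sum":
        return frame.sum(axis=0)
    if mode == "mean":
        return frame.mean(axis=0)
    if mode != "mixed":
        raise ValueError(f"unknown aggregation mode {mode!r}")
    out = frame.mean(axis=0)
    sum_cols = [c for c in frame.columns
                if c.split(":", 1)[0] in sum_prefixes]
    out[sum_cols] = frame[sum_cols].sum(axis=0)
    return out
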