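"""Graph-based structural signatures (cutoff scanning of atom-pair distances).

The mutation-site environment is modelled as a graph whose nodes are heavy
atoms labelled with pharmacophore classes and whose edges are distance
thresholds: for every unordered pair of the 11 classes and every cutoff of
an increasing distance grid, the signature records how many atom pairs of
those classes lie within the cutoff.  This yields, per class pair, a
cumulative distance distribution.

Defaults (environment radius 10 A, cutoffs 2..10 A in 2 A steps) follow
the cutoff-scanning convention of this signature family and are fully
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .errors import ContractError
from .pharmacophore import ALL_CLASSES
from .structure_io import AtomRecord, ComplexStructure


@dataclass(frozen=True)
class SignatureConfig:
    """Geometry of the cutoff scan."""

    environment_radius: float = 10.0  # A, around any atom of the site residue
    d_min: float = 0.0
    d_max: float = 10.0
    d_step: float = 2.0

    def __post_init__(self) -> None:
        if not (0 <= self.d_min < self.d_max and self.d_step > 0
                and self.environment_radius > 0):
            raise ValueError("invalid signature configuration")

    @property
    def cutoffs(self) -> tuple[float, ...]:
        n = int(round((self.d_max - self.d_min) / self.d_step))
        return tuple(self.d_min + self.d_step * k for k in range(1, n + 1))


def class_pairs() -> list[tuple[str, str]]:
    """Fixed ordering of unordered class pairs: (i, j) with i <= j in canon order."""
    out = []
    for i, a in enumerate(ALL_CLASSES):
        for b in ALL_CLASSES[i:]:
            out.append((a, b))
    return out


def signature_feature_names(config: SignatureConfig,
                            prefix: str = "sig") -> list[str]:
    return [f"{prefix}:{a}:{b}:<={d:g}"
            for a, b in class_pairs() for d in config.cutoffs]


def residue_environment(structure: ComplexStructure, chain_id: str,
                        residue_number: int, insertion_code: str = "",
                        radius: float = 10.0) -> list[AtomRecord]:
    """All heavy atoms within ``radius`` of any atom of the site residue.

    The site residue's own atoms are always part of the environment.
    """
    site = structure.residue_atoms(chain_id, residue_number, insertion_code)
    site_xyz = np.array([a.position for a in site])
    tree = cKDTree(structure.coords)
    hit: set[int] = set()
    for idxs in tree.query_ball_point(site_xyz, r=radius):
        hit.update(idxs)
    return [structure.atoms[i] for i in sorted(hit)]


def compute_signature(atoms: list[AtomRecord],
                      labels: list[frozenset[str]],
                      config: SignatureConfig = SignatureConfig(),
                      ) -> np.ndarray:
    """Cumulative pairwise-distance counts per pharmacophore class pair.

    Entry ((i, j), d) counts unordered atom pairs (a, b), a != b, with
    |a - b| <= d and a carrying class i while b carries class j (or vice
    versa).  An atom pair contributes at most once per class pair, however
    many of its label combinations match.  Returned as a flat integer
    vector ordered as :func:`signature_feature_names`.
    """
    if len(atoms) != len(labels):
        raise ContractError("atoms and labels differ in length")
    if any(not lab for lab in labels):
        raise ContractError("unlabelled atom in environment")
    pairs = class_pairs()
    cutoffs = config.cutoffs
    n = len(atoms)
    out = np.zeros(len(pairs) * len(cutoffs), dtype=int)
    if n < 2:
        return out
    xyz = np.array([a.position for a in atoms])
    dmat = squareform(pdist(xyz))
    iu = np.triu_indices(n, k=1)
    d_flat = dmat[iu]
    # class membership matrix
    member = {c: np.array([c in lab for lab in labels]) for c in ALL_CLASSES}
    pos = 0
    for a, b in pairs:
        ma, mb = member[a], member[b]
        if a == b:
            match = (ma[iu[0]] & mb[iu[1]])
        else:
            match = (ma[iu[0]] & mb[iu[1]]) | (mb[iu[0]] & ma[iu[1]])
        if match.any():
            dm = d_flat[match]
            for k, d in enumerate(cutoffs):
                out[pos + k] = int(np.count_nonzero(dm <= d))
        pos += len(cutoffs)
    return out


def site_signature(structure: ComplexStructure, chain_id: str,
                   residue_number: int, insertion_code: str = "",
                   config: SignatureConfig = SignatureConfig(),
                   labels: list[frozenset[str]] | None = None) -> np.ndarray:
    """Signature of the environment of one protein residue."""
    from .pharmacophore import assign_pharmacophores

    if labels is None:
        labels = assign_pharmacophores(structure)
    env = residue_environment(structure, chain_id, residue_number,
                              insertion_code, config.environment_radius)
    index = {id(a): i for i, a in enumerate(structure.atoms)}
    env_labels = [labels[index[id(a)]] for a in env]
    return compute_signature(env, env_labels, config)
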