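"""Elastic-network normal mode analysis and vibrational entropy changes.

The complex is coarse-grained to one node per residue (Calpha for protein,
P for nucleotides; an all-heavy-atom mode exists for side-chain
sensitivity) and modelled as an anisotropic network: unit-strength
Hookean springs connect node pairs within a distance cutoff.  The 3N x 3N
Hessian is diagonalised and the vibrational entropy taken, up to model
constants, as

    S_vib = -1/2 * sum_i ln(lambda_i)

over the non-zero modes.  Only entropy *differences* between wild-type
and mutant are meaningful and exported as a feature; units are
model-relative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ContractError
from .structure_io import ComplexStructure

logger = logging.getLogger(__name__)

#: relative threshold under which an eigenvalue counts as a rigid-body mode
ZERO_MODE_RTOL = 1e-8


@dataclass
class ElasticNetwork:
    """Anisotropic network model over coarse-grained nodes."""

    positions: np.ndarray         # (N, 3)
    cutoff: float
    spring_constant: float = 1.0
    hessian: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.positions)
        if n < 2:
            raise ContractError("elastic network needs at least 2 nodes")
        self.hessian = _anm_hessian(self.positions, self.cutoff,
                                    self.spring_constant)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def eigenvalues(self) -> np.ndarray:
        """All 3N eigenvalues, ascending (clipped at zero)."""
        vals = np.linalg.eigvalsh(self.hessian)
        return np.clip(vals, 0.0, None)

    def vibrational_entropy(self) -> float:
        """-1/2 sum ln(lambda) over non-zero modes (model units)."""
        vals = self.eigenvalues()
        top = vals[-1] if len(vals) else 0.0
        if top <= 0:
            return 0.0
        nonzero = vals[vals > ZERO_MODE_RTOL * top]
        return float(-0.5 * np.sum(np.log(nonzero)))


def _anm_hessian(xyz: np.ndarray, cutoff: float, gamma: float) -> np.ndarray:
    n = len(xyz)
    hess = np.zeros((3 * n, 3 * n))
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    for i, j in pairs:
        dvec = xyz[j] - xyz[i]
        d2 = float(dvec @ dvec)
        if d2 == 0.0:
            continue
        block = -gamma * np.outer(dvec, dvec) / d2
        hess[3*i:3*i+3, 3*j:3*j+3] += block
        hess[3*j:3*j+3, 3*i:3*i+3] += block
        hess[3*i:3*i+3, 3*i:3*i+3] -= block
        hess[3*j:3*j+3, 3*j:3*j+3] -= block
    if len(pairs) < n - 1:
        logger.warning("elastic network may be disconnected "
                       "(%d springs for %d nodes)", len(pairs), n)
    return hess


def coarse_grain_nodes(structure: ComplexStructure,
                       mode: str = "calpha_p") -> np.ndarray:
    """Node coordinates: Calpha + P (default) or every heavy atom."""
    if mode == "heavy":
        return structure.coords.copy()
    if mode != "calpha_p":
        raise ValueError(f"unknown coarse-grain mode {mode!r}")
    prot = set(structure.protein_chains())
    nuc = set(structure.nucleic_chains())
    pts = [a.position for a in structure.atoms
           if (a.chain_id in prot and a.name == "CA")
           or (a.chain_id in nuc and a.name == "P")]
    return np.array(pts, dtype=float)


def build_enm(structure: ComplexStructure, cutoff: float = 10.0,
              mode: str = "calpha_p",
              spring_constant: float = 1.0) -> ElasticNetwork:
    """Elastic network of the complex at the given node selection."""
    nodes = coarse_grain_nodes(structure, mode)
    return ElasticNetwork(positions=nodes, cutoff=cutoff,
                          spring_constant=spring_constant)


def vibrational_entropy_change(wild: ComplexStructure,
                               mutant: ComplexStructure,
                               cutoff: float = 10.0,
                               mode: str = "calpha_p") -> float:
    """S_vib(mutant) - S_vib(wild) on identical node selections."""
    enm_wt = build_enm(wild, cutoff, mode)
    enm_mut = build_enm(mutant, cutoff, mode)
    if mode == "calpha_p" and enm_wt.n_nodes != enm_mut.n_nodes:
        raise ContractError(
            f"node count changed upon mutation ({enm_wt.n_nodes} -> "
            f"{enm_mut.n_nodes}); networks are not comparable")
    return enm_mut.vibrational_entropy() - enm_wt.vibrational_entropy()
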