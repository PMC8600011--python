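import numpy as np
import pandas as pd
import pytest

from nabind.dataset import MutationSpec, parse_mutation_string
from nabind.errors import MutationValidationError, SchemaMismatchError
from nabind.features import (ComplexFeaturizer, aggregate_multi,
                             assemble_features, feature_schema,
                             load_substitution_matrices, naive_mutant,
                             substitution_features)
from nabind.structure_io import AA_3TO1


def _first_protein_site(structure):
    key, atoms = next((k, a) for k, a in structure.residues() if k[0] == "A")
    return key, AA_3TO1[atoms[0].residue_name]


class TestNaiveMutant:
    def test_self_mutation_identity(self, toy_dsdna):
        structure, _ = toy_dsdna
        (chain, num, icode), wt = _first_protein_site(structure)
        mutant = naive_mutant(structure, MutationSpec(chain, wt, num, wt))
        assert len(mutant.atoms) == len(structure.atoms)
        assert np.allclose(mutant.coords, structure.coords)

    def test_mutation_to_alanine_has_five_heavy_atoms(self, toy_dsdna):
        structure, _ = toy_dsdna
        (chain, num, icode), wt = _first_protein_site(structure)
        target = "A" if wt != "A" else "G"
        mutant = naive_mutant(structure, MutationSpec(chain, wt, num, target))
        site = mutant.residue_atoms(chain, num, icode)
        names = sorted(a.name for a in site)
        if target == "A":
            assert names == ["C", "CA", "CB", "N", "O"]
        else:
            assert names == ["C", "CA", "N", "O"]

    def test_backbone_untouched_to_1e6(self, toy_dsdna):
        structure, _ = toy_dsdna
        (chain, num, icode), wt = _first_protein_site(structure)
        mutant = naive_mutant(structure, MutationSpec(chain, wt, num, "W"))
        for name in ("N", "CA", "C", "O"):
            before = next(a.position for a in
                          structure.residue_atoms(chain, num, icode)
                          if a.name == name)
            after = next(a.position for a in
                         mutant.residue_atoms(chain, num, icode)
                         if a.name == name)
            assert np.allclose(before, after, atol=1e-6)

    def test_wildtype_mismatch_quotes_found_residue(self, toy_dsdna):
        structure, _ = toy_dsdna
        (chain, num, icode), wt = _first_protein_site(structure)
        wrong = "W" if wt != "W" else "F"
        with pytest.raises(MutationValidationError, match=AA_3TO1[wt]
                           if False else "found"):
            naive_mutant(structure, MutationSpec(chain, wrong, num, "A"))

    def test_other_residues_untouched(self, toy_dsdna):
        structure, _ = toy_dsdna
        (chain, num, icode), wt = _first_protein_site(structure)
        mutant = naive_mutant(structure, MutationSpec(chain, wt, num, "A"))
        before = {(a.residue_key, a.name): a.position for a in structure.atoms
                  if a.residue_key != (chain, num, icode)}
        after = {(a.residue_key, a.name): a.position for a in mutant.atoms
                 if a.residue_key != (chain, num, icode)}
        assert before.keys() == after.keys()
        for k in before:
            assert np.allclose(before[k], after[k])


class TestSubstitutionFeatures:
    def test_known_blosum_pam_entries(self):
        # frozen values read off the published BLOSUM62 / PAM250 tables
        scores = substitution_features("R", "A")
        assert scores["sub:blosum62"] == -1.0
        assert scores["sub:pam250"] == -2.0

    def test_identity_returns_diagonal(self):
        mats = load_substitution_matrices()
        scores = substitution_features("W", "W", mats)
        assert scores["sub:blosum62"] == float(mats["blosum62"].loc["W", "W"])
        assert scores["sub:contact_potential"] == 0.0

    def test_symmetry_of_shipped_matrices(self):
        for wt, mut in [("R", "A"), ("D", "K"), ("F", "S")]:
            fwd = substitution_features(wt, mut)
            rev = substitution_features(mut, wt)
            assert fwd == {k: pytest.approx(v) for k, v in rev.items()}

    def test_contact_potential_matches_packaged_file(self):
        # independent re-read of the packaged table
        from importlib import resources

        text = resources.files("nabind.data").joinpath(
            "contact_potential_synthetic.tsv").read_text()
        rows = [ln.split() for ln in text.splitlines()
                if ln.strip() and not ln.startswith("#")]
        header = rows[0]
        table = {r[0]: dict(zip(header, map(float, r[1:]))) for r in rows[1:]}
        scores = substitution_features("R", "A")
        assert scores["sub:contact_potential"] == table["R"]["A"]

    def test_nonstandard_letter_rejected(self):
        with pytest.raises(MutationValidationError):
            substitution_features("X", "A")


@pytest.fixture(scope="module")
def featurizer(toy_dsdna):
    return ComplexFeaturizer(toy_dsdna[0])


class TestAssembleFeatures:
    def test_self_mutation_all_deltas_zero(self, toy_dsdna, featurizer):
        structure, _ = toy_dsdna
        (chain, num, icode), wt = _first_protein_site(structure)
        vec = featurizer.featurize(MutationSpec(chain, wt, num, wt))
        deltas = [c for c in vec.index
                  if c.startswith(("dsig:", "nma:")) or c.endswith(":delta")]
        assert (vec[deltas] == 0).all()

    def test_na_binaries_for_dsdna(self, toy_dsdna, featurizer):
        structure, _ = toy_dsdna
        (chain, num, icode), wt = _first_protein_site(structure)
        vec = featurizer.featurize(MutationSpec(chain, wt, num, "A"))
        assert vec["na:is_rna"] == 0.0
        assert vec["na:is_double"] == 1.0

    def test_interaction_delta_consistent_with_module(self, toy_dsdna,
                                                      featurizer):
        from nabind.interactions import interaction_delta

        structure, _ = toy_dsdna
        (chain, num, icode), wt = _first_protein_site(structure)
        spec = MutationSpec(chain, wt, num, "G")
        mutant = naive_mutant(structure, spec)
        vec = featurizer.featurize(spec)
        summary = interaction_delta(structure, mutant)
        for t, d in summary.delta.items():
            assert vec[f"int:{t}:delta"] == d

    def test_deterministic_bit_identical(self, toy_dsdna, featurizer):
        structure, _ = toy_dsdna
        (chain, num, icode), wt = _first_protein_site(structure)
        spec = MutationSpec(chain, wt, num, "N")
        v1 = featurizer.featurize(spec)
        v2 = featurizer.featurize(spec)
        assert (v1 == v2).all()

    def test_schema_fixed_and_complete(self, toy_dsdna, featurizer):
        structure, _ = toy_dsdna
        (chain, num, icode), wt = _first_protein_site(structure)
        vec = featurizer.featurize(MutationSpec(chain, wt, num, "A"))
        assert list(vec.index) == feature_schema()
        assert vec.notna().all()

    def test_one_shot_wrapper_matches_featurizer(self, toy_dsdna, featurizer):
        structure, _ = toy_dsdna
        (chain, num, icode), wt = _first_protein_site(structure)
        spec = MutationSpec(chain, wt, num, "S")
        assert (assemble_features(structure, None, spec)
                == featurizer.featurize(spec)).all()


class TestAggregation:
    def _vec(self, value):
        return pd.Series({"sig:a:a:<=2": value, "sub:blosum62": value},
                         dtype=float)

    def test_single_vector_identity(self):
        v = self._vec(3.0)
        for mode in ("mean", "sum", "mixed"):
            assert (aggregate_multi([v], mode=mode) == v).all()

    def test_mean_and_sum(self):
        vecs = [self._vec(1.0), self._vec(3.0)]
        assert (aggregate_multi(vecs, "mean") == 2.0).all()
        assert (aggregate_multi(vecs, "sum") == 4.0).all()

    def test_sum_equals_n_times_mean(self):
        vecs = [self._vec(v) for v in (0.5, 2.5, -1.0)]
        mean = aggregate_multi(vecs, "mean")
        total = aggregate_multi(vecs, "sum")
        assert np.allclose(total.values, 3 * mean.values)

    def test_mixed_mode_splits_by_prefix(self):
        vecs = [self._vec(1.0), self._vec(3.0)]
        mixed = aggregate_multi(vecs, "mixed")
        assert mixed["sig:a:a:<=2"] == 4.0     # count-like: accumulated
        assert mixed["sub:blosum62"] == 2.0    # score-like: averaged

    def test_permutation_invariance(self):
        vecs = [self._vec(v) for v in (1.0, 2.0, 5.0)]
        a = aggregate_multi(vecs, "mixed")
        b = aggregate_multi(vecs[::-1], "mixed")
        assert (a == b).all()

    def test_schema_mismatch_rejected(self):
        v1 = self._vec(1.0)
        v2 = pd.Series({"sig:a:a:<=2": 1.0, "other": 2.0})
        with pytest.raises(SchemaMismatchError):
            aggregate_multi([v1, v2])


def test_multi_point_construct_aggregates_singles(toy_dsdna):
    structure, _ = toy_dsdna
    feat = ComplexFeaturizer(structure)
    sites = [(k, AA_3TO1[a[0].residue_name]) for k, a in structure.residues()
             if k[0] == "A"][:2]
    construct = parse_mutation_string(";".join(
        f"{c} {wt}{num}A" if wt != "A" else f"{c} {wt}{num}G"
        for (c, num, icode), wt in sites))
    combined = feat.featurize_construct(construct)
    singles = [feat.featurize(s) for s in construct]
    expected = aggregate_multi(singles, "mixed")
    assert np.allclose(combined.values, expected.values)
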