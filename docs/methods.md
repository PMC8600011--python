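# Methods

## Problem and conventions

`nabind` predicts the change in Gibbs free energy of protein–nucleic-acid
binding caused by missense mutations, ddG = dG_wt − dG_mut in kcal/mol.
Negative values destabilize (reduce affinity). Experimental dissociation
constants convert via dG = RT ln K_D with R = 1.98720425 × 10⁻³
kcal/(mol·K) and T defaulting to 298.15 K, so
ddG = RT ln(K_D,wt / K_D,mut). Mutations are written
`chain WTresnumMUT` (e.g. `A R45G`); the sites of a multiple-point
construct are joined with `;`. Residue identity is (chain, author residue
number, insertion code).

## Structure model

Complexes are held as a flat list of heavy atoms with a per-chain polymer
class. Parsing keeps the first model only; alternate locations resolve to
the highest-occupancy conformer (ties to the alphabetically first
altloc); hydrogens and waters are dropped, so every geometric criterion
below is defined on heavy atoms. Chains are classified by majority
residue-name vocabulary (20 standard amino acids vs.
DA/DC/DG/DT/DU/A/C/G/U).

Nucleic-acid typing: RNA iff any nucleotide carries an O2′ atom or a
ribonucleotide code; double-stranded iff at least three Watson–Crick-
geometry base pairs exist, a pair being a purine N1 within 3.5 Å of a
pyrimidine N3. The ≥3-pair rule is a minimal geometric operationalization
of "strands that form a pair"; a user override always wins. Complexes
mixing DNA and RNA chains are typed by the majority nucleic chain with a
logged warning.

Interface geometry uses the minimum heavy-atom distance between a protein
residue and any nucleic-acid atom; a residue is *proximal* iff that
distance is ≤ 8.0 Å (boundary inclusive). Design mode enumerates exactly
these residues.

## Feature classes

**Pharmacophore labels.** Protein atoms take one or more of seven classes
from a packaged (residue, atom name) table following standard
pharmacophore conventions: Arg/Lys and the His ring nitrogens positive;
Asp/Glu carboxylate oxygens negative; Phe/Tyr/Trp/His ring atoms
aromatic; aliphatic carbons hydrophobic; backbone N donor and backbone O
acceptor; side-chain O/N donors and acceptors per canonical chemistry;
anything unlisted is neutral. The table is data (CSV resource) and can be
substituted via `load_pharmacophore_table(path)`. Nucleic-acid atoms take
exactly one component class by atom-name convention — P/OP*/O5′/O3′
phosphate, primed atoms sugar, ring atoms base, split purine vs
pyrimidine; no donor/acceptor sub-labels are added to nucleic-acid nodes.
Labelling is a pure function of (residue name, atom name).

**Cutoff-scanning signatures.** The environment of the mutated residue is
every heavy atom (protein and nucleic) within `environment_radius` of any
atom of the site residue. For each unordered pair of the 11 classes and
each cutoff of the grid d_min+step … d_max, the signature counts atom
pairs of those classes within the cutoff; counts are cumulative across
the grid. An atom pair contributes at most once per class pair no matter
how many of its label combinations match. Defaults: radius 10 Å, grid
2–10 Å in 2 Å steps (the family convention for this signature style);
all configurable through `SignatureConfig`. The exported features are the
wild-type signature (`sig:*`) and the mutant-minus-wild difference
(`dsig:*`), the difference form carrying the direction of the change.

**Substitution scores.** Three 20×20 symmetric tables: BLOSUM62 and
PAM250 (loaded from Biopython), and a synthetic quasi-chemical-style
contact-potential score shipped as
`data/contact_potential_synthetic.tsv` — a constructed symmetric penalty,
−(0.25·|Δhydropathy| + 1.2·|Δcharge| + 0.008·|Δvolume|), standing in for
a published contact-potential scale that is not redistributable here. All
three are swappable.

**Elastic-network dynamics.** An anisotropic network model over Cα
(protein) and P (nucleotide) nodes with unit springs inside a 10 Å
cutoff. The 3N×3N Hessian is diagonalised; vibrational entropy is taken
as S_vib = −½ Σ ln λᵢ over non-zero modes (eigenvalues ≤ 10⁻⁸ × λ_max
count as rigid-body modes; a connected 3-D network has ≥ 6 of them).
Units are model-relative: only the mutant-minus-wild difference enters
the feature vector. Known limitation: with the default Cα/P
coarse-graining, the naive mutant builder changes no node positions, so
`nma:delta_s_vib` is exactly 0 unless the mutant structure was built
externally (backbone relaxation) or the all-heavy-atom mode is selected;
the heavy mode is exact but cubic in atom count.

**Interaction network.** A self-contained geometric re-implementation of
contact typing over heavy-atom pairs within 5.5 Å (one protein and one
nucleic atom in the default inter-molecular scope). All thresholds live
in `InteractionConfig`: covalent ≤ r_cov sum + 0.4 Å; clash < r_vdw sum
− 0.5; vdW-clash inside the vdW sum; vdW contact up to +0.5 beyond it;
H-bond donor–acceptor ≤ 3.5 Å with an antecedent–donor–acceptor angle
≥ 90° whenever a bonded antecedent exists (hydrogens are absent, so the
criterion is distance-only otherwise); weak H-bond carbon-to-acceptor
≤ 3.8 Å; ionic positive↔negative ≤ 4.0 Å (non-bridging phosphate oxygens
count as negative); aromatic ring-centroid separation ≤ 5.0 Å; hydrophobic
carbon pairs ≤ 4.5 Å; carbonyl O to carbonyl C ≤ 3.6 Å; halogen bond
Cl/Br/I to acceptor ≤ 3.5 Å; metal to O/N/S ≤ 2.8 Å; pairs within 5.0 Å
matching nothing else are *proximal*. Features are the 13 wild-type
counts and the 13 mutant-minus-wild deltas. Nucleic-acid N/O atoms are
treated as both donor- and acceptor-capable.

**Schema.** One fixed, documented header:
`sig:*`, `dsig:*`, `sub:<matrix>`, `nma:delta_s_vib`, `int:<type>:wt`,
`int:<type>:delta`, `na:is_rna`, `na:is_double`, `geo:min_dist_na`,
`opt:stability_ddg` (an optional user-supplied protein-stability change,
imputed as 0 with a logged flag when absent). Multi-point constructs
aggregate their single-point vectors: count-like features (`sig`, `dsig`,
`int`, `nma` prefixes) accumulate, scores/distances/binaries average;
uniform mean or sum modes are also available. Which features the original
protocol averaged versus accumulated is not determinable, so the split is
a documented default.

## Mutant structures

Mutants come from a naive builder: the side chain is replaced by an
idealized template rotamer placed in the local N/CA/C backbone frame;
the backbone is untouched; mutation to Gly removes the side chain.
Templates are stick rotamers grown by a deterministic outward zigzag with
generic 1.3–1.5 Å bonds — connectivity and rough shape are right, rings
close only approximately, and no rotamer library or refinement is used.
A user-supplied mutant PDB short-circuits the builder, which is the
intended path when higher-fidelity mutants (energy-minimised, MD-refined)
are available. This is the largest fidelity gap relative to a
production pipeline built on refined mutants.

## Dataset protocol

*Reverse augmentation.* Because binding free energy is a state function,
every forward record implies a reverse record with negated ddG. Reverse
records are generated only for single-point forwards with
ddG ≥ −2 kcal/mol (inclusive): stronger destabilizations imply structural
changes a modelled mutant cannot capture. Reverse records keep the
forward record's group id and reference it, so cross-validation can never
separate the pair.

*Labels.* Direction: neutral iff −0.5 ≤ ddG ≤ 0.5 (both boundaries
neutral — the inclusive reading of the printed band), otherwise
increasing/decreasing by sign. Hot-spots: only single mutations to Ala
participate (the alanine-scanning convention); hot-spot iff
ddG ≤ cutoff, with −2 and −1 kcal/mol the conventional cutoffs.
Additivity of a multi-point construct against the sum of its singles:
additive iff |ddG_multi − Σ singles| < 0.2 kcal/mol (absolute criterion)
or < 10% of |Σ singles| (relative criterion; the denominator choice is
ours — the source rule states only "within 10%").

## Model and validation

Default regressor: `ExtraTreesRegressor` with 300 trees, unlimited depth,
fixed seed (42); gradient boosting, random forest, k-NN, SVR, Gaussian
process and MLP are available behind the same config. Greedy bottom-up
feature selection adds, per round, the feature that maximizes pooled
group-CV Pearson, stopping below a 10⁻³ improvement or at a 13-feature
cap. Ties break by schema order; trimming ties break by record
order — all determinism choices are explicit.

Validation is group-based k-fold (k ∈ {5, 10, 20}) or
leave-one-complex-out; groups are complexes (plus reverse partners), and
no group ever spans folds. Reported metrics: Pearson/Spearman/Kendall
(tau-b)/RMSE; direction classification-by-regression after removing
experimentally neutral records (predicted class = sign of the prediction,
AUC from the raw prediction oriented so that higher = increasing);
outlier-trimmed variants dropping the ⌈10%⌉ worst-predicted records; and
SEN/SPE/PRE/ACC/F1/MCC for hot-spot detection with both vectors binarized
at the cutoff.

## Synthetic data

The generator builds an ideal α-helical peptide (φ = −57°, ψ = −47°,
NeRF internal-coordinate chain extension, template side chains) placed a
configurable gap from an idealized B-form DNA (3.4 Å rise / 36° twist) or
A-form RNA (2.8 Å / 32.7°) strand or duplex assembled from planar
Watson–Crick base-pair templates (hexagon/pentagon rings, N1–N3 2.9 Å).
Same spec and seed give bit-identical PDB text. The default five-complex
suite covers all four nucleic-acid kinds with 8–10 nt partners, sized so
each complex presents at least two interface residues (a 10–14-residue
helix realistically faces the groove with only a handful of residues).

Synthetic ddG datasets draw random constructs on interface residues
(≈10% two-point) and set
ddG = 0.5·BLOSUM62 + 0.6·contact-potential − 0.2·min-distance + N(0, σ),
σ = 0.2 kcal/mol by default. These coefficients make destabilizing
records dominate, mirroring the imbalance of curated experimental sets.
What passing tests show: the featurization is exact (oracle-verified),
the protocol bookkeeping is correct, and the model recovers a known
feature→ddG map across complexes. What they do not show: accuracy on real
experimental complexes — the toys have no physical energetics, no
conformational change upon mutation, and no experimental noise structure.
Because the generative effect uses symmetric substitution scores, reverse-
augmented records are predictable only through the direction-sensitive
`dsig`/`int:*:delta` features, which is why pooled metrics on the
augmented set sit below the raw-recovery numbers.

## Numerical choices and degenerate inputs

Correlations raise on zero-variance inputs rather than returning NaN;
confusion-derived metrics return 0 where a denominator vanishes.
Direction classification raises if only one class survives neutral-band
filtering. The trimmed-metrics sort is stable so ties resolve by record
order. Eigenvalues are clipped at zero before the entropy log. Empty
interaction results are valid (distant partners); an empty design-mode
scan writes an empty CSV with a warning rather than failing.

## Problem sizes

Default study conditions used by the acceptance script: five toy
complexes, 400 synthetic records (~10% multi-point), reverse
augmentation, 300-tree forests, group-5-fold CV — the full run completes
in about a minute on one core, and the test suite in well under five.
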