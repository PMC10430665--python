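# Methods

`gpcrscreen` implements a decision pipeline for structure-based virtual
screening of GPCR ligands, specialized to the problem of finding
*antagonists* with novel chemotypes: candidates that dock well, that two
random-forest classifiers call antagonist rather than agonist, that bind
tightly enough to matter, that span diverse chemistry, and whose
predicted cAMP dose-response looks potent. This note records the models,
parameters, numerical choices, and limitations.

## Protein-ligand interaction fingerprints

Each docked pose is reduced to one 8-bit block per binding-site residue:
hydrophobic contact, aromatic face-to-face, aromatic edge-to-face,
residue-as-H-bond-acceptor, residue-as-H-bond-donor, salt bridge with
the protein positive, salt bridge with the protein negative, and
coordination of a ligand metal ion. Bits are binary presence flags, not
counts. A residue enters a pose's fingerprint when any heavy atom lies
within the largest cutoff + 1 Å of any ligand heavy atom; all other
residues are implicitly zero.

Default geometric criteria (`plif.InteractionCriteria`, all
configurable):

| interaction | criterion |
|---|---|
| hydrophobic | apolar C/S pair ≤ 4.0 Å, hydrophobic residue |
| H-bond | heavy-atom D–A ≤ 3.5 Å; D–H…A ≥ 120° only when explicit H present |
| salt bridge | charged-group centers ≤ 4.0 Å |
| ring stacking | centroids ≤ 5.0 Å; face-face normals ≤ 30°, edge-face 60–90° |
| metal | residue N/O to metal ≤ 2.8 Å |

These values follow common interaction-fingerprint practice. Protein
donor/acceptor/charge typing comes from a residue template table
(poses routinely lack hydrogens); ligand typing falls back to
element+charge rules, with the H-bond angle term activated only when the
pose carries explicit hydrogens. Ligand aromatic rings are grouped from
aromatic-flagged atoms by covalent proximity (< 1.75 Å) because poses
carry no bond table; ring planes are SVD fits. Metal atoms participate
only in the metal bit, never in the organic salt-bridge bits. Water
molecules are excluded from the residue list entirely (HETATM records
are dropped at parse time).

The pose × feature matrix has 8 columns per residue in a deterministic
residue order (sorted union of contacted residues) plus an optional
trailing docking-score column. The detector is verified three ways in
the test suite: against self-validating fixture manifests, against an
independent brute-force O(atoms²) predicate oracle, and for invariance
under rigid motions and for monotonicity under cutoff shrinkage.

## Classifiers

Two random forests with identical machinery: one on pose-level
interaction-fingerprint rows (plus the docking score as the final
feature), one on molecule-level hashed circular fingerprints (Morgan
radius 2, 4096 bits — ECFP4). Hyperparameters are library defaults with
500 trees and a mandatory seed; no tuning is performed, deliberately,
because the labeled libraries are small and tuning would overfit.

Samples are poses but labels belong to molecules, so cross-validation
uses **grouped stratified 5-fold splits**: every pose of a molecule
stays on one side of each split. Group leakage is re-asserted on every
run. Metrics are precision, recall, F1, accuracy from the confusion
matrix and trapezoidal ROC AUC; zero-denominator metrics report 0 with a
warning so CV tables stay numeric.

A molecule's **antagonist probability** is the arithmetic mean of its
per-pose antagonist probabilities (soft forest voting). The probability
filter keeps candidates at or above 0.84, boundary inclusive. The mean
(rather than median or best-pose) is a design choice; the aggregator is
a single function and easy to swap.

## Shapley attributions

Feature attributions use an in-package implementation of the
path-dependent polynomial-time Tree SHAP recursion for sklearn trees and
forests. The coalition value function is the tree's expected output with
out-of-coalition features marginalized along the tree by training cover.
The implementation is exact: local accuracy (base value + attributions =
predicted probability) holds to machine precision and is asserted at
1e-6 on every explained sample; tests additionally verify exact
agreement with exhaustive 2^M coalition enumeration on small trees. The
attribution summary reports mean |attribution| and sign consistency per
feature.

## Diversity clustering

Candidates are clustered on the 1 − Tanimoto distance matrix of their
ECFP4 fingerprints with average-linkage agglomerative clustering
(average linkage is robust for Tanimoto distances; complete linkage is a
flag away). The cluster count is chosen by maximizing the silhouette
score computed on the precomputed distance matrix — not on any
embedding — with ties broken toward smaller k. Each cluster is
represented by its **medoid** (minimal summed intra-cluster distance,
ties by molecule id), an automated stand-in for the manual
visual-inspection step such pipelines traditionally use; the exported
table carries cluster ids and 2-D coordinates so a human can still
override.

The 2-D map for inspection is t-SNE (perplexity 30, learning rate 200,
5000 iterations, seeded) on a PCA reduction of the distance matrix to 50
components. PCA signs are fixed by forcing the largest-magnitude loading
positive so the embedding is deterministic. t-SNE output is
visualization only and never feeds a clustering decision.

**Novelty**: a candidate's maximum Tanimoto similarity against a
user-supplied reference set; `novel` means strictly below 0.4.

## Signal-transduction cascade

Predicted affinity pKd (= −log10 Kd/M) converts to equilibrium receptor
occupancy L/(L+Kd); two-ligand competition uses the standard
(X/KdX)/(1 + L/KdL + A/KdA) expressions. Binding is treated at
quasi-equilibrium — no binding kinetics.

Occupancy drives a minimal 4-species mass-action Gs cascade (active
G protein, inactive G protein, ATP, cAMP; see `cascade` module
docstring for the equations), with basal cAMP synthesis balanced so zero
occupancy is a fixed point at the basal level. Defaults: receptor 2 μM,
G protein 10 μM, ATP 1000 μM, basal cAMP 0.1 μM, PDE 1 μM,
k_G_act 0.1 /(μM·s), k_G_hyd 0.5 /s, k_AC_cat 2·10⁻⁴ /(μM·s),
k_PDE 1.0 /(μM·s). The rate constants are plausible-magnitude
placeholders, not fits to receptor-specific kinetic data; the simulation
is used for *qualitative potency ranking* (curve positions, shapes,
limits), and its acceptance surface is structural: monotonicity by mode,
conservation laws, agreement with the closed-form solution of the
linearized system, and step-refinement stability — never absolute cAMP
values.

Dose-response curves run a simulation per concentration on a log-spaced
grid (10⁻³–10³ μM, 24 points). The "1000 integration steps" convention
is interpreted as 1000 reporting points; an adaptive LSODA integrator
runs underneath, and halving the reporting step changes end-point cAMP
by far less than 0.1 %, making the interpretation immaterial. Agonist
mode: the candidate activates, response = cAMP change vs zero dose,
non-decreasing. Antagonist mode: a reference agonist tone (default: the
tone agonist at its occupancy EC80 = 4·Kd) elevates the baseline and the
candidate competes it off; the response is non-increasing and approaches
full suppression. A four-parameter Hill fit (bottom + (top−bottom)/(1 +
(x50/L)^n), least squares, bounded n ∈ [0.05, 10]) condenses each curve
to (top, bottom, x50, slope); flat curves get a degenerate flag and no
x50, and x50 outside the dose grid is flagged unreliable.

The affinity gate keeps candidates with pKd ≥ 5.5, boundary inclusive.
pKd 5.5 corresponds to Kd = 10⁻⁵·⁵ M ≈ 3.16 μM by exact conversion (a
common shorthand rounds this to "10 μM"; the exact form is used here and
the cutoff is configuration).

## Screening funnel

Stages in order: top docking-score fraction (ceil(fraction·n), default
1 %, most-negative-first, ties by id) → probability filter (≥ 0.84) →
affinity gate (≥ 5.5) → diversity clustering with medoid
representatives → dose-response simulation, novelty annotation, and
ranking by (antagonist probability, then potency x50). Every molecule
records the terminal stage it reached; the funnel counts are monotone by
construction and re-derivable by running the modules manually. All
stochastic steps are seeded, so a re-run with the same configuration
reproduces the report bit-exactly. A stage that empties the candidate
set terminates the funnel with a warning report and a distinct exit
status in the CLI (0 success, 2 empty funnel, 1 error).

## Synthetic data: what it emulates and what it does not

The generators exist so every stage is testable without docking runs or
database downloads.

* **Pocket fixtures** place idealized residue side chains (hard-coded
  template geometries, no rotamers) and ligand probe atoms at controlled
  distances/angles, 30 Å apart to prevent cross-talk. Each fixture
  carries a manifest of the exact 8-bit vector per residue, derived from
  the constructed geometry; construction refuses geometries ambiguously
  close (± 0.1 Å, ± 2°) to any cutoff. Fixtures exercise detector
  *predicates*, not realistic pocket shapes.
* **Two-class libraries** (default: 50 molecules/class, 5 poses per
  molecule per 3 receptor states, seed-fixed) give each molecule a
  latent bit pattern enriched in class-signature bits (12 signature
  bits, 30 % shared between classes, on-probability 0.9 vs background
  0.05), pose-level flip noise of 5 %, and per-(class, state) Gaussian
  docking scores in which agonists score best against the active-state
  receptor and antagonists against the inactive state. The score
  separations are deliberately weak — the score column alone supports
  only ≈ 0.7 pose-level accuracy — so a well-performing classifier must
  exploit the interaction bits too. With both signal sources the default
  library is learnable to ≥ 0.9 grouped-CV accuracy, and
  label-permutation collapses accuracy to chance, which is what the
  classifier acceptance checks assert. Predicted pKd values are
  N(6.5, 1) clipped to [3.5, 10], class-independent.
* **Fingerprint blobs** plant k archetype bit vectors (shared core plus
  exclusive bits sized to a target between-archetype Tanimoto, default
  0.15) and flip member bits at 2 %. They exercise clustering recovery,
  not real chemotype structure.

Passing tests on these generators demonstrates algorithmic correctness
under controlled signal, not performance on real docking data: real
PLIFs are sparser and correlated, real score distributions are not
Gaussian, and real chemotype clusters are not isotropic. The small
bundled SMILES set (xanthines and adenosine-like nucleosides) covers
fingerprint code paths with real chemical graphs.

## Numerical choices and degenerate inputs

* Distance matrices are validated (symmetry, zero diagonal, [0, 1]) and
  clipped against floating-point drift; Tanimoto of two empty bit sets
  is defined as 1 (identical vectors).
* Ties: medoids and top-fraction cuts break by molecule id; silhouette
  ties toward smaller k; altloc ties by conformer letter.
* The cascade integrator is LSODA with rtol 1e-8/atol 1e-10; species are
  clamped non-negative at output.
* Hill fitting seeds from curve endpoints and the half-amplitude
  crossing; optimizer failure returns the degenerate flag rather than
  raising.
* t-SNE perplexity is auto-reduced with a warning when n ≤ 3·perplexity;
  n < 5 is an error.

## Problem sizes

Test-suite and acceptance-script problem sizes are chosen for a
single-CPU desk run: the default library (100 molecules, 1500 pose
rows), 100 pocket fixtures, 20 clustering instances, 50 random cascade
parameter draws, forests of 50–200 trees where retraining happens inside
loops. All scale linearly if larger runs are wanted.

## Known limitations

* The cascade omits β-arrestin, GRK, receptor desensitization and Ca²⁺
  branches, and its constants are not fitted to receptor-specific
  experimental kinetics; rankings are qualitative.
* Docking itself, structure preparation, protonation enumeration, and
  affinity prediction are out of scope; docked poses, scores and pKd
  values are inputs.
* Donor/acceptor typing without hydrogens is element-based and can
  overcount; supplying poses with explicit hydrogens activates the
  angle criterion.
* The whole-library ~1.0 CV accuracy on the synthetic default reflects
  the generator's clean signal, not an expectation for real libraries.
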