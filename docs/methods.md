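# Methods

This note records the models, parameter choices and numerical conventions
behind `colchigen`, and what the test suite does and does not demonstrate.

## Activity scale

All modelling happens on the pIC50 scale, pIC50 = −log10(IC50·10⁻⁹) =
9 − log10(IC50/nM), which compresses the right-skewed nM scale into a
roughly symmetric one. `to_pic50`/`from_pic50` are exact inverses; IC50
values must be strictly positive, and table cells of the form
`54.9 ± 22.0` are reduced to their mean — the spread is not used anywhere
downstream. Missing cell-line entries are allowed and excluded per target
rather than dropping the compound.

## Randomized-SMILES augmentation

A small library is expanded by rendering each molecule as many distinct
SMILES strings (random atom orderings, seeded). The default is 1,200
attempts per molecule with string-level deduplication, which for
colchicine-sized structures yields on the order of a thousand distinct
renderings each — the regime in which a 120-compound library becomes a
corpus of ~10⁵ sequences. All renderings of a molecule canonicalize
identically; this invariant is tested across the fixture library.

## Molecular sequences and the generative model

Sequences are atom-level SMILES token lists (bracket atoms, two-letter
elements, ring-closure labels and bond symbols are single tokens), so
joining the tokens reproduces the exact string and encoding is trivially
invertible. Sampled strings are filtered through RDKit parsing, so every
returned structure is chemically valid; invalid draws simply reduce the
yield below `n_attempts`. This tokenize-and-filter design was chosen as
the smallest self-contained sequence representation: it keeps the whole
encoder/decoder inside the package and makes validity a post-condition of
sampling rather than of the grammar.

The reconstruction model is a single-layer GRU (default 64 hidden units)
with a per-position softmax head, trained autoregressively with teacher
forcing under categorical cross-entropy, implemented directly in NumPy.
Training uses the adaptive-moment optimizer (lr 5·10⁻³, β = 0.9/0.999,
global gradient-norm clip 5), batch size 128, and a deterministic
train/validation split with |validation| = round(val_fraction · N)
(a 118,070-sequence corpus at 0.1 splits 106,263/11,807). Early stopping
on a validation plateau is available (`patience`) but off by default so
the loss history always has one entry per epoch. The analytic BPTT
gradients are verified against numerical differentiation in the test
suite, and fixed (corpus, seed, epochs) reproduce the history and weights
bit for bit at a fixed thread count.

Sampling is autoregressive multinomial with temperature (default 1.0),
advanced batch-parallel with a single inverse-CDF RNG stream per call so
results are reproducible under a seed. Outputs are deduplicated by
canonical SMILES and exact training molecules are removed, so novelty and
distinctness hold by construction.

## Descriptors

The catalog combines the standard RDKit descriptor list with named
descriptors implemented here from their literature definitions:

- **AMID_O** — Randic path-weight identifier restricted to oxygens: every
  simple path contributes ∏ 1/√(deg·deg) over its edges; contributions of
  paths starting at O atoms (plus 1 per O) are averaged over the
  heavy-atom count.
- **MDEO-12** — distance-edge descriptor n/d̄² between primary (degree-1)
  and secondary (degree-2) oxygens, d̄ the geometric-mean topological
  distance; 0 when no such pair exists.
- **GATS2c / MATS2c** — Geary and Moran autocorrelations at lag 2 with
  Gasteiger charges as weights. Charges are computed on the H-explicit
  molecule and hydrogen charges are folded onto their heavy atom, so the
  weight is the group charge. Undefined (NaN) when no atom pair sits at
  distance 2 or the weights are constant.
- **RNCG** — largest negative group charge divided by the total negative
  charge (a value in (0, 1] when any negative charge exists, else 0).
- **SaasC / NdssC** — sum of E-state indices over `aasC`-typed aromatic
  carbons, and the count of `dssC` carbons, via RDKit's E-state typing.
- **EState_VSA5/6, VSA_EState5** — RDKit's hybrid E-state/VSA bins;
  **TopoPSA(NO)** — RDKit TPSA, which by default counts only N and O
  contributions.

All values are computed from the canonical form, so descriptor rows are
invariant to the SMILES rendering. Columns containing any non-finite value
across a set are dropped and logged; molecules that fail outright are
excluded and reported, never silently zeroed. The hand-checkable cases
(ethanol/dimethyl ether for AMID_O, `COCCO` for MDEO-12, a weighted path
graph for Moran/Geary) are frozen in the tests, alongside brute-force
re-enumerations on library molecules.

## QSAR tournament

Feature screening keeps descriptor columns with |Pearson r| against pIC50
at or above a threshold, ordered by descending |r|; constant columns are
skipped. Screening uses the full dataset before splitting — the protocol
is deliberately simple and mirrors small-library practice; its optimism is
bounded by the held-out metrics that drive selection. The tournament
fits MLR, decision tree, random forest, k-nearest neighbors and SVR at
random states 15, 28 and 42 with an 80/20 train/test split (the split
fraction is configurable; 80/20 is the conventional default for a
~120-point dataset). Hyperparameters beyond the random state are the
scikit-learn defaults, frozen in `QsarConfig`. Reports carry Pearson R on
train/test/whole data and MSE/MAE/RMSE both on the test split and on the
whole dataset (the "overall" convention used for final model tables).
Selection maximizes test R with ties broken by lower test RMSE, fewer
features, then RF > DT > others — encoding the preference for the forest
when a training-perfect tree is merely memorizing. Predictions for new
candidates are back-transformed to nM and are therefore strictly positive;
candidates whose selected descriptors cannot be computed are excluded and
listed.

The published final configurations (RF at states 15/15/42/28/15 with
thresholds 0.51/0.51/0.63/0.54/0.51 and the corresponding feature sets per
cell line) are shipped as constants (`PUBLISHED_FINAL_CONFIGS`,
`PUBLISHED_FEATURE_SETS`) for users who work with the original activity table;
their numeric metrics depend on that table and are not asserted here.

## Triage cascade

The fingerprint dialect was calibrated once against the printed similarity
pairs of the reference table — the 2048-bit topological path fingerprint at
RDKit defaults (maximum path length 7) reproduces the printed values
(0.844, 0.983, 0.978 and both 0.931 pairs) to three decimals — and is frozen as the
default `FingerprintSpec`; a circular (Morgan) dialect is available as the
documented alternative. Cascade thresholds are the training-set minima of
similarity-to-core and fragment score ("keep anything at least as good as
the worst training compound") and are applied inclusively. The colchicine
core is the canonical colchicine structure. Stage order is fixed:
similarity, synthesizability, stereochemistry, then (optionally) RI/SI.

The C7 stereocenter is located structurally — the sp3 carbon of a
seven-membered carbocycle fused to an aromatic ring that bears an
exocyclic nitrogen — because generated SMILES have arbitrary atom
numbering; its CIP label comes from RDKit's CIP implementation.

The synthesizability score is additive over circular fragments (atom
environments of radius 0–2), with a pluggable score table: tests use a toy
table generated to cover the fixture library, and the published SYBA score
file can be loaded for production use. Retraining the SYBA classifier is
out of scope.

Resistance bands follow the closed-left/open-right convention: RI ≤ 2
sensitive, 2 < RI ≤ 10 moderate, RI > 10 strong. SI > 1 counts as
tumor-selective. The default RI/SI stage keeps candidates whose RI class
is not "strong" and that are selective for at least one cancer line; both
rules are configurable, since no universal numeric cut-off exists for
"satisfying the prerequisites".

The chemical-space map embeds Jaccard (1 − Tanimoto) distances between
fingerprints with t-SNE (seeded, random initialization on a precomputed
distance matrix), which keeps duplicated molecules at distance zero in the
input space and makes runs reproducible.

## Docking adapter

The adapter never implements scoring: ligands are embedded with a seeded
ETKDG conformer generation plus MMFF relaxation and written as PDB blocks
(PDBQT-convertible); the search box defaults to the tubulin colchicine
site used for receptor 1SA0 (center 119.743/92.779/10.765, size 44/44/60
Å); result logs in the mode/affinity/RMSD dialect are parsed to
(best affinity, pose count). Affinity summaries partition results against
the colchicine (−8.2) and native-ligand (−8.6 kcal/mol) references with
equality judged at the engine's print resolution of 0.1 kcal/mol; both the
"stronger" (more negative) and "weaker" counts are reported so either
reading of "greater affinity" is visible. Tests run entirely against
synthesized logs, so the suite requires neither the engine binary nor any
structure download.

## Synthetic fixtures

The fixture generator emulates the training library's chemistry: a
trimethoxy-aromatic A ring, seven-membered B ring with the C7 amine, and a
tropolone-like C ring, decorated from substituent pools that mirror the
edits seen among real analogs (thio/amino/alkoxy methyl swaps on the C
ring; short alkyl, haloalkyl and amino chains on N). Stereo fractions are
configurable so the stereochemistry filter has something to reject.

Synthetic activities are linear in named descriptors on the pIC50 scale
with Gaussian noise — hence lognormal on the nM scale — centered on the
library so the intercept (7.5, ≈30 nM) pins the potency window regardless
of the weights. The default weights put comparable variance on TopoPSA(NO)
and GATS2c, two weakly coupled descriptors, so correlation screening has a
recoverable two-descriptor truth. Per-line offsets place LoVo/DX ~0.8 log
units less potent than LoVo, giving realistic resistance indices. The
ground-truth parameters (and the exact descriptor values and centering
means) are returned for recovery tests.

What passing tests show: the pipeline's arithmetic, invariants,
determinism, and its ability to recover a known linear signal at 10%
relative noise. What they do not show: predictive validity on measured
activities — real IC50 tables are noisier, non-linear in descriptors, and
assay-correlated across cell lines, none of which the generator emulates
beyond range and noise shape.

## Problem sizes and tolerances

Tests run the generator on a 20-molecule, ~2,000-rendering corpus for 4–6
epochs at 48–64 hidden units, and the QSAR suite on the 120-analog fixture
library — sizes chosen so the full suite completes in well under a minute
per module on one CPU while still exercising every code path at realistic
dimensionality. Numerical comparisons use exact equality for deterministic
bookkeeping (splits, counts, thresholds), 10⁻⁹ relative tolerance for the
pIC50 round-trip, and 10⁻⁴ absolute for hand-computed metric vectors.
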