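# Methods

## The prediction problem

The package models a drug-screening experiment: a panel of cancer cell
lines, each characterised by its somatic mutations, is exposed to a library
of small molecules, and the response of each (cell line, drug) pair is
summarised by ln(IC50) — the natural log of the concentration (µM) at which
viability is halved. Lower values mean a more sensitive cell line. The
learning task is regression of ln(IC50) from the pair's two binary feature
blocks.

## Input encodings

**Genomic fingerprint.** The feature space is the set of distinct
(gene symbol, genomic position) keys observed in the mutation corpus,
restricted to a whitelist of cancer-associated genes and ordered
lexicographically (gene, then numeric position) so encodings are
reproducible. A cell line's fingerprint sets bit *k* to 1 iff it carries any
mutation at key *k*. Three deliberate coarsenings apply: the alternate
allele is ignored (a different substitution at the same position is the
same feature), insertions/deletions are not distinguished from
substitutions, and multi-base events are keyed by their start position.
Coordinates are treated as 1-based inclusive, as in COSMIC-style exports.
On the real corpus this vocabulary has 28,328 positions over 567 genes;
the encoders work for any vocabulary size.

**Molecular fingerprint.** Each drug's SMILES is canonicalised and hashed
into three 1,024-bit substructure fingerprints, concatenated in fixed block
order (3,072 bits): (1) a path-based fingerprint respecting bond orders,
(2) an "extended" circular fingerprint built on pharmacophoric atom
invariants (donor/acceptor/aromatic/ring features), (3) the path-based
fingerprint with bond orders ignored ("graph only"). The exact generator is
RDKit; any trio of deterministic, mutually distinct hashed fingerprints
with these class semantics would serve, since the models never interpret
individual bits. Salts and multi-fragment SMILES are rejected upstream by
curation rather than stripped.

## Curation filters

* Cancer types keep ≥ 10 cell lines (count ≥ 10 retained).
* Screening-library drugs need a registered compound identifier and SMILES;
  molecular weight strictly above 1000 g/mol excludes. Identical structures
  assayed as separate series remain separate drugs.
* Approved-drug libraries for repurposing apply four ordered exclusions:
  missing SMILES/weight; weight < 200 or > 650 g/mol (strict); disconnected
  structures ('.' in SMILES); inorganic molecules, operationalised as
  "contains no carbon atom" — the literature definition being unstated,
  this is the package's documented choice.
* Instance assembly joins assay rows against the retained entities; rows
  referencing filtered-out entities are dropped, rows referencing unknown
  ids and duplicate (cell line, drug) pairs are integrity errors.

All filters return exact partitions (retained + excluded = input) and are
idempotent.

## Models

Five convolutional regressors are trained and their predictions averaged;
the member mean in ln(IC50) space is the reported output. The registry
(`configs/models.yaml`) mirrors the published family: *master*,
*fully_connected* (2× the epochs, an extra dense stage), *shallow* (one
wide convolution per branch), *tanh* (tanh hidden dense activation), and
*unified*. The published per-model layer totals (28/31/24/31/17) are kept
as informational metadata; per-layer hyperparameters are this package's
own, chosen for CPU-scale training, and parameter-count equality with the
original implementation is explicitly not a conformance goal.

Four members use the dual-convergence layout: each input block is convolved
in its own branch (Conv1D+ReLU, max-pooling, dropout), the flattened branch
outputs are concatenated — the "virtual docking" step — then mixed by a
dense layer and convolved further before the scalar linear output. The
dense mixing stage after concatenation is a deliberate architectural
choice: with purely local convolutions a genomic bit and a drug bit never
share a receptive field, so cross-block interactions (the chemistry–genetics
coupling the model exists to capture) would be unrepresentable; one dense
layer gives every subsequent ReLU convolution a global receptive field. The
*unified* member convolves the whole concatenated input as a single entity
and applies the same dense-then-convolve closing pattern; lacking the
branch separation it consistently trails the dual-convergence members on
the synthetic benchmark, which reproduces the original architecture
comparison qualitatively.

Design conventions:

* "Dense activation" (linear or tanh) applies to hidden dense layers; the
  regression output is always linear — a bounded output could not span the
  ln(IC50) range.
* Binary inputs are fed as 0/1 without normalisation; the target is
  standardised internally for optimiser conditioning and rescaled at
  prediction.
* Dropout rates are fixed per model within [0.10, 0.20]; every branch/body
  contains at least one convolution, one max-pooling and one dropout layer.
* Adam uses its standard defaults (β₁ = 0.9, β₂ = 0.999, ε = 1e-8);
  learning rate (default 2e-3) and batch size (default 256) are estimator
  parameters, and the learning rate drops to 0.3× for the final third of
  the epochs to settle into a finer minimum.
* Dropout masks are per element in minibatch training; in full-batch
  reference mode they are drawn per feature and shared across the batch,
  which is what makes the full-batch fit order-invariant.
* One integer seed drives weight initialisation, dropout masks and
  minibatch shuffling; identical seeds reproduce identical weights.
  Full-batch mode (`batch_size=None`) makes the fit invariant to instance
  order (up to float32 summation order); minibatch training is
  order-sensitive through the shuffle.

Two profiles ship: **scaled** (default; narrow channels, 25 epochs — 50 for
*fully_connected* — learning rate 2e-3) sized so the full five-member
ensemble trains on the default synthetic benchmark in a few minutes on one
CPU, and **full** (wider channels, the published 250/500 epochs) for larger
corpora. The engine underneath is a small self-contained numpy
reverse-mode implementation (1-D convolution via strided windows, max
pooling, inverted dropout, dense layers, Adam) kept in float32; its
gradients are validated against finite differences in the test suite.

## Evaluation

R² is computed exactly as the residual sum of squares over the total sum
about the observed mean — it can be negative for predictors worse than the
mean. RMSE is in ln units. AUROC uses the fixed sensitivity definition
ln(IC50) < −2 (≈ 0.135 µM, strict) with score −f, i.e. lower predicted
ln(IC50) ranks as more sensitive; it is computed rank-based with ties
counted half, the orientation being the package's documented resolution of
an ambiguity. Pearson p-values use the two-sided t approximation.

The train/test split is stratified by cancer type: each stratum contributes
round(test_fraction × size) held-out instances (round-half-to-even; too-small
strata contribute none, with a warning). k-fold CV partitions into folds
differing by at most one instance. Centric reports group instances by
cancer type, cell line or drug and skip groups with fewer than `min_n = 3`
instances — generalising the exclusion of cell lines assayed against only
one or two compounds. Random-forest and SVR baselines (scikit-learn) train
on the identical concatenated fingerprints and report the same metrics.

## Repurposing screen

A cell line is *sensitive* when predicted ln(IC50) < −2 (strict). A cancer
type is sensitive to a drug when at least 10 % of its lines are sensitive —
the source material words this rule both as "at least" and "more than"
10 %; the package uses ≥ and exposes the threshold as an option. A drug
sensitive in more than 90 % of types is flagged pan-cancer (read as
nonspecific cytotoxicity) and never called repurposable. Otherwise a
non-oncology drug is repurposable with ≥ 1 sensitive type, an oncology drug
only with a sensitive type outside its approved indications. Verdicts are
invariant to cell-line order, and lowering all predictions can only grow a
drug's sensitive-type set.

## Synthetic benchmark

The generator emulates the *shape* of a CCLP/GDSC-style corpus, not its
pharmacology. Defaults (the study conditions for all shipped benchmarks):
5 cancer types × 40 cell lines, a 2,000-key vocabulary over synthetic
genes, background mutation rate 0.01 per key (≈ 20 mutations per line,
sparse like census-restricted exomes), 30 drugs derived from drug-like
template SMILES, 10 driver keys each enriched (carrier rate 0.35) in a
random subset of types, drug baselines ~ N(1.0, 2.0²) so drug identity
dominates variance as in real screens, sensitising driver×substructure
interaction effects −U(1.5, 3.0) ln units, observation noise σ = 0.5.

The planted response is additive: y = baseline(drug) + Σ effects over
(driver carried by the cell) × (target fingerprint bit carried by the
drug) + N(0, σ²). Because the signal is an explicit function of the same
fingerprints the models see, an oracle achieves R² = 1 at σ = 0 and the
best achievable R² at noise σ is Var(signal)/(Var(signal)+σ²) — the
analytic ceiling the recovery tests compare against. A label-shuffled
control destroys the linkage and bounds leakage: trained ensembles score
R² ≈ 0 (typically negative) there.

What passing these tests does **not** show: the generator has independent
mutations (no mutational signatures or linkage), additive effects (a
nonlinearity hook exists but is off by default), Gaussian noise, and a
dense assay matrix; real corpora violate all four, so benchmark recovery
demonstrates correctness of the pipeline and learnability of planted
structure, not expected accuracy on biological data.

## Numerical and operational choices

* Degenerate inputs raise typed errors: zero-variance targets
  (undefined R²), single-class labels (undefined AUROC), non-finite
  losses (divergence, with epoch index), unknown ids (integrity).
* Max-pooling drops trailing remainder positions; convolution kernels,
  strides and pool sizes are clamped to the current length so toy widths
  (down to a handful of bits) still build valid networks.
* Fingerprint matrices are kept as uint8 end to end; the engine densifies
  per batch.
* Checkpoints are `.npz` arrays plus a JSON header (config names, seeds,
  target scaling, widths); a saved ensemble restores to identical
  predictions.
* Problem sizes in the shipped tests and the acceptance protocol are the
  benchmark defaults above (6,000 instances, ~1,750 observed genomic keys +
  3,072 drug bits); the scaled profile was sized so that protocol completes
  in minutes on a single CPU.

## Known limitations

* The numpy engine is CPU-only and minibatch-sequential; it is meant for
  the scaled profile and method study, not full-corpus training.
* PaDEL/CDK bit-exact fingerprints are out of scope by design; models
  trained on one fingerprint implementation do not transfer to another.
* The per-cancer-type mutation-position counts published for the real
  corpus do not sum to the published 28,328 subtotal; the package defines
  vocabulary size as the distinct-key count and leaves the discrepancy to
  the data provider.
* The published 1,001 → 787 cell-line reduction is not fully reconcilable
  from the stated exclusions; the pipeline simply applies the stated
  filters to whatever input it receives.
* Five-fold CV fold sizes follow the equal-size ± 1 rule; the original
  report prints two inconsistent fold sizes, neither reproducible exactly.
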