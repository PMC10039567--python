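# Methods

## The prediction problem

A record is one observation of a solvated luminogen: a molecular graph
(SMILES), a solvent (name from a packaged 24-solvent vocabulary, or its
own SMILES), and one or both peak wavelengths — the absorption peak
λ_abs and the emission peak λ_em, both in nm.  Where a compound shows
several peaks, curation keeps the longest-wavelength absorption peak and
the highest-intensity emission peak (intensity ties break toward the
longer, red-shifted wavelength, consistent with imaging use).  No
ordering between λ_em and λ_abs is enforced: apparent anti-Stokes
entries are kept, since peak-picking conventions in source spectra can
legitimately produce them.  Wavelengths stay in nm throughout; no eV
conversion is performed anywhere.

Two regression targets are treated separately — one model for
absorption, one for emission — because their physics (ground-state vs
excited-state, solvent stabilization of charge-transfer states) differ
and their errors are reported separately.

## Featurization

Each record becomes one fixed-length vector of named blocks, molecule
blocks first, solvent blocks second.  The layout (block name, offset,
length) is hashed into the model contract: a trained model refuses
feature matrices with a different layout.

**Quantitative descriptors.** A pinned, versioned list of exactly 196
RDKit descriptors (106 classed one-dimensional: composition, property
and fragment counts; 90 two-dimensional: topological indices,
VSA/EState families, ring descriptors), shipped as
`data/quantitative_descriptors.csv`.  Pinning matters because toolkit
default lists drift across versions.  Fourteen RDKit descriptors are
excluded as numerically undefined or unstable for some valid molecules
(the information-content indices that overflow on large graphs, the
BCUT2D eigenvalue descriptors and partial-charge extrema that are NaN
whenever Gasteiger charges fail).  Any non-finite value is replaced by 0
with a warning.

**Fingerprints.** Four families, all folded to binary vectors (default
2048 bits, a power of two; one bit per hashed feature, no count
simulation):

- *morgan* — circular atom environments to radius 2 (ECFP4-equivalent),
  the radius suited to activity/property prediction rather than
  similarity search;
- *daylight* — linear heavy-atom bond paths of 1–7 bonds.  Paths are
  bond-distinct walks; a walk containing a cycle contributes only at the
  maximum path length (the toolkit's enumeration rule, reproduced by the
  test oracle);
- *atompair* — (typed atom, typed atom, topological distance) triples,
  encoded with the classic injective Carhart-style codes and folded by
  modulo.  The generator-based pair hash was measured to be
  non-injective (two different element pairs can share a sparse bit),
  which would break the enumeration oracle, so the classic codes are
  used deliberately;
- *torsion* — typed linear 4-heavy-atom paths.

All fingerprint operations canonicalize their input first, so bit
patterns are invariant to SMILES spelling; dense folding keeps every
family the same length, which makes fusion layouts uniform.

**Fusion.** A "multi-modal" descriptor concatenates blocks in order.
The three shipped presets fuse a second family onto the daylight paths
(`morgan-daylight`, `atompair-daylight`, `toptorsion-daylight`), applied
to molecule and solvent alike (8192 bits total).  Fusion helps for two
reasons: families differ in which substructural distinctions they
resolve (torsions see local branching that path invariants ignore;
pairs see long-range co-occurrence beyond the 7-bond path horizon), and
a dedicated block gives a family's features collision-free bits that
hashing into a shared space would dilute.

**Solvent encoding.** Default: the solvent structure is featurized with
the same block recipes as the molecule (`same_as_molecule`).
Alternatives: `quantitative_only` (196 descriptors of the solvent) and
`one_hot` over a configured vocabulary.  Which encoding best reflects
laboratory practice is genuinely open; the choice is a config field, not
a code path.

**Scaling.** Quantitative blocks are z-scored with statistics computed
on training rows only (per fold during cross-validation) — fingerprint
bits are never scaled.  This is the only stateful transform, and keeping
it fold-local prevents information leaking from held-out records.

## Models

Seven regressors behind one contract (`fit(spec, X, y) -> TrainedModel`,
deterministic given the seed; `predict` returns finite nm values and
enforces the layout hash):

| name | backend | defaults |
|---|---|---|
| svm  | linear-kernel SVM regression (LinearSVR) | C = 1 |
| knn  | k-nearest neighbours, Euclidean | k = 5, searched in [1, 20] |
| rf   | random forest | 300 trees |
| gbrt | gradient boosted regression trees | 300 stages, depth 3, lr 0.1 |
| xgb  | XGBoost (hist) | 300 stages, depth 6, lr 0.1, λ = 1 |
| mlp  | multilayer perceptron | hidden (256, 64), ReLU |
| cnn  | NumPy 1-D CNN (below) | conv 32/64, kernel 7, stride 2 |

Boosted ensembles expose truncated-stage predictions so the
forward-stagewise additivity (prediction with m stages = prediction with
m−1 stages + the m-th tree's contribution) is directly assertable.
Random forests average training targets and therefore cannot predict
outside the training range — a documented limitation, asserted in the
tests rather than hidden.  The CART Gini impurity `1 − Σ p_i²` is
exposed as a utility for class-probability vectors; the regression trees
here split on squared error, because Gini is undefined for continuous
targets.

**The 1-D CNN.** Fingerprints are fed as a one-channel signal through
two strided convolutions (32 then 64 filters, kernel 7, stride 2, ReLU),
then the feature map is *flattened* into a dense layer (128, ReLU) and a
linear output.  An earlier design used global average pooling before the
dense head; it was abandoned after measurement, for a structural reason:
pooling makes the network translation-invariant, while hashed
fingerprint bits are position-coded — two isolated set bits at different
positions are indistinguishable to any translation-invariant readout,
which degenerates to popcount statistics (observed: training MAE stuck
near the target's spread).  The flatten head preserves position; the
convolutions still see local bit phase patterns.  Training: Adam on
mean-squared error over z-scored targets, mini-batches, early stopping
on a 10% validation split, all float32 with convolutions as BLAS
matmuls.  Widths, depths and epochs are declared defaults, not derived:
nothing in the problem fixes them.

**Hyperparameter search.** `tune` minimizes mean k-fold CV MAE by
sequential model-based search: 20% of the budget as random
initialization, then a Gaussian-process surrogate (Matern 5/2 + white
noise, fixed kernel hyperparameters for reproducibility) with
expected-improvement acquisition over a unit-cube encoding (log scale
for scale-free parameters).  The trace records every trial; the result
is the argmin over the trace, so a seeded known-good point can never be
lost.

## Evaluation

10-fold cross-validation: records are randomly assigned to ten mutually
exclusive folds with sizes differing by at most one; each fold is
predicted by a model trained on the other nine; the headline score is
the mean of the ten fold scores (R² is also reported pooled over all
out-of-fold residuals, since fold-averaged and pooled R² answer slightly
different questions).  Folds split at the record level by default; a
`group_by_molecule` option keeps all solvent observations of one
molecule in one fold — the stricter protocol when molecules repeat
across solvents, trading optimism for variance.  Error distributions
bin |residual| at 10 and 20 nm — the thresholds at which a wavelength
error starts to matter for filter selection.  The learning-curve study
(`scalability_study`) reports mean test MAE ± s.e. over repeated random
splits at each train fraction.  `benchmark_grid` cross-validates every
model × descriptor × target cell and names the winner per target.

## The synthetic benchmark

The generator exists so that every pipeline property is testable from a
cold start.  It emulates the statistical shape of curated AIEgen
databases — hundreds of distinct π-conjugated rotor molecules, a small
solvent panel, most wavelengths in the visible 400–700 nm window, the
same molecule observed in several solvents, red shifts with solvent
polarity — without claiming photophysical fidelity.

Molecules: combinatorial decoration of seven scaffold templates
(tetraphenylethylene, triphenylamine, stilbene, biphenyl, a
triphenylamine–thiophene–vinylene push-pull chain, tetraaryl pyrazine,
phenylthiophene) with twelve substituents (H, F, Br, OH, Me, OMe, NMe2,
CN, NO2, CF3, vinyl, thienyl) at 1–3 aryl positions; ~700 unique
canonical structures.  Ground truth is additive:

    λ_abs = 412 + Σ effect(fragment) × count + shift(solvent)
    λ_em  = λ_abs + 72 + Stokes-increment(solvent)

with donor/acceptor effects of 4–50 nm per occurrence (NMe2 45, NO2 50,
CN 28, …), solvent shifts of 2–24 nm and Stokes increments of 3–30 nm
ordered by polarity (ethyl acetate → DMSO), echoing the
charge-transfer-type solvent dependence of real AIEgens.  Observation
noise is independent Gaussian per target, default sd 5 nm — a realistic
literature-digitization error.  These constants were chosen once so the
default fixture (600 molecules × 5 solvents) lands mostly inside
400–700 nm; they are study conditions, not tuning knobs.  Because
effects act on substructure occurrence counts, the relationship is
exactly representable from fingerprint features: recovery failures
indict the pipeline, not the chemistry.  What passing does *not* show:
real spectra have conformer, aggregation and excited-state effects that
no occurrence-count model captures; results on this fixture bound
pipeline correctness, not chemical accuracy.

A split-signal variant plants half the effects on short branched motifs
(within one torsion window) and half on long linear motifs spanning 5–8
bonds (visible to path/pair features only), making descriptor fusion
genuinely informative; it backs the fused-beats-single check.

## Numerical choices and edge cases

- Multi-fragment SMILES (salts): the largest fragment by heavy-atom
  count is kept, logged.
- Duplicate (molecule, solvent) pairs are kept by default (repeated
  measurements are real data); `dedupe` averages targets per pair.
- Invalid rows are rejected with a logged reason, never silently
  dropped; a file yielding zero valid rows is an error.
- Constant training targets warn but fit (the model predicts the
  constant); NaN features are an error.
- Fold counts: n < k is an error; remainder records go to the first
  n mod k folds.
- Screening windows are inclusive on both bounds; the shortlist sorts by
  predicted emission descending.  No applicability-domain gate is
  imposed, but a warning fires when a candidate shares < 5% of its set
  fingerprint bits with every training molecule.
- All randomness flows from one user seed through
  `numpy.random.SeedSequence` stream splitting (derived seeds kept below
  2^31).

## Problem sizes in the standard runs

The test suite and `scripts/acceptance.py` run the benchmark grid and
learning curve on the default fixture (3000 records, 8192-bit features;
XGBoost at 300 and 150 stages respectively), the fusion comparison on
80-molecule × 3-solvent split-signal fixtures across several seeds at
120 stages, the CNN demonstration on the 180-record fixture with reduced
channels (16/32) and 30 epochs, and screening on a noiseless 180-record
fixture with exact 1-NN models.  These sizes were chosen as the smallest
at which the measured quantities stabilize; all of them are plain
package calls, so larger studies are a parameter change.

## Known limitations

- The quantitative-descriptor list pins *a* defensible 196-descriptor
  set; other choices of the same size are equally defensible.
- LinearSVR optimizes the linear-SVM objective in its primal form;
  coefficients can differ in the last digits from a kernelized solver.
- The CNN is a compact NumPy implementation: correct (gradient-checked)
  and practical to a few thousand records, but not a GPU deep-learning
  stack; at the full 8192-bit width its cross-validation is the most
  expensive operation in the package.
- Fingerprint folding at 2048 bits can merge features of large
  molecules; the enumeration oracle therefore certifies feature
  extraction at a wide fold, and the derived degenerate cases at the
  default width.
- No uncertainty quantification, no applicability-domain enforcement,
  no 3-D/conformer descriptors.
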