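# aiegen

Machine-learning prediction and screening of the absorption and emission
peak wavelengths (λ<sub>abs</sub>, λ<sub>em</sub>, in nm) of luminogens
with aggregation-induced emission (AIEgens), directly from the molecule's
SMILES and the solvent it is measured in.

## Who this is for

Designing an AIEgen for fluorescence imaging means hitting a wavelength
window — long enough for tissue penetration, matched to filters and
excitation sources — before committing to synthesis.  Quantum-chemical
routes (TD-DFT) cost days per molecule and drift systematically on many
chromophore skeletons; this package instead learns the
structure–property relationship from curated spectra of solvated
luminogens and screens large candidate lists in seconds.  It is a
library first (the functions below are the interface), with a thin
`aiegen` command-line wrapper and runnable scripts under `examples/`.

## What is inside

- **dataset** — validated spectral records `(molecule SMILES, solvent,
  λ_abs, λ_em)`; curation of multi-peak entries keeps the
  longest-wavelength absorption peak and the highest-intensity emission
  peak; canonical SMILES identity throughout.
- **featurize** — 196 pinned quantitative descriptors (molecular weight,
  lipophilicity, H-bond counts, topological indices, …) and four
  fingerprint families: Morgan circular environments, daylight-type
  linear bond paths (≤ 7 bonds, 2048 bits), atom pairs and topological
  torsions.  "Multi-modal" descriptors stitch families together —
  `toptorsion-daylight`, `atompair-daylight`, `morgan-daylight` — for the
  molecule and the solvent (8192 bits total).
- **models** — seven regressors behind one fit/predict contract:
  linear-kernel SVM, k-NN (Euclidean, k ≤ 20), random forest, gradient
  boosted trees, XGBoost, an MLP (256/64, ReLU) and a 1-D CNN that reads
  the fingerprint bit vector as a one-channel signal.  Gaussian-process
  Bayesian hyperparameter search (`aiegen.tune`).
- **evaluate** — 10-fold cross-validation (MAE/RMSE/R², per fold and
  aggregated), error distribution at the 10/20 nm thresholds, learning
  curves, and a models × descriptors benchmark grid.
- **screen** — wavelength-window screening of candidate SMILES lists;
  the default pairing is XGBoost on `toptorsion-daylight` for absorption
  and the CNN on `atompair-daylight` for emission.
- **fixtures** — a synthetic data generator that decorates AIE-typical
  rotor scaffolds (tetraphenylethylene, triphenylamine, stilbene, …)
  with donor/acceptor substituents and plants an additive ground truth
  `λ_abs = intercept + Σ fragment effects + solvent shift`,
  `λ_em = λ_abs + Stokes term`, plus Gaussian observation noise — so the
  whole pipeline is testable without any external data.

## Worked example

`examples/03_benchmark_models_and_descriptors.py` builds the small
synthetic benchmark (60 molecules × 3 solvents, 5 nm noise) and ranks
model/descriptor pairs by 10-fold cross-validation:

```
fixture: 180 records, noise sd 5.0 nm
    target model          descriptor       mae      rmse       r2  pooled_r2
absorption   xgb toptorsion-daylight  4.967426  6.180048 0.957077   0.960212
absorption   xgb            daylight  7.032723  9.022160 0.907499   0.914833
absorption   knn toptorsion-daylight 12.250788 15.859683 0.713555   0.720394
absorption   knn            daylight 12.290940 15.980364 0.710474   0.718841

winner: xgb on toptorsion-daylight
MAE 4.97 nm, RMSE 6.18 nm, R2 0.957
|error| <= 10 nm: 87%, 10-20 nm: 13%, > 20 nm: 0%
```

Reading the numbers: the observation noise floor for MAE under 5 nm
Gaussian noise is σ√(2/π) ≈ 4 nm, so XGBoost on the fused
toptorsion-daylight fingerprint (4.97 nm) has essentially recovered the
planted structure–solvent relationship, and fusing torsions onto the
daylight paths buys ~2 nm over daylight alone.  87% of held-out
predictions land within 10 nm of the truth.

The other examples cover curation (`01`), featurization layouts (`02`),
Bayesian tuning (`04`) and end-to-end screening (`05`); each prints and
explains its own output.  The same operations are available from the
shell, e.g.

```bash
aiegen fixtures make --preset small --seed 7 --out fix.csv
aiegen evaluate --in fix.csv --model xgb --preset toptorsion-daylight --target absorption
aiegen screen candidates.smi --abs-model A/ --em-model E/ --solvent THF --em-window 650 900
```

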