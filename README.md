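# nmrlogd

Predicting chromatographic lipophilicity (logD) from **computer-generated
¹H NMR spectra** — a fully computational pipeline with no experimental
input required.

## The problem

logD, the pH-dependent octanol/water distribution coefficient, governs
absorption, distribution, metabolism and toxicity of drug candidates.
Its chromatographic surrogates — **CHI logD** and **Chrom logD**,
measured by HPLC retention at pH 2.6, 7.4 and 10.5 — are routine assay
endpoints that QSPR models try to predict from structure. A ¹H NMR
spectrum is a rich molecular fingerprint for this task: resonance
positions encode each hydrogen's electronic environment, and relative
integrals encode composition. But measured spectra are expensive, noisy
(solvent signals, impurities, instrument variability) and slow to
collect at library scale. This package implements the alternative:
*generate* the spectra computationally and train on those.

## The pipeline

1. **Shift prediction** (`hose_shift`) — a built-in HOSE-code
   (Hierarchically Ordered Spherical Environment) nearest-environment
   predictor. Each hydrogen's anchor heavy atom is encoded as a canonical
   shell-by-shell string; a training table maps codes to mean observed
   shifts δ (ppm), with sphere-by-sphere fallback for unseen deep
   environments. Chemically equivalent protons receive identical shifts
   by construction.
2. **Featurization** (`spectra`) — *bucket integration*: the ppm axis
   [−1, 14) is split into 500 equal bins and each shift increments its
   bin, so a methyl gives one bucket of intensity 3 and a methylene one
   of intensity 2. Dense experimental-style traces are instead resampled
   to 16,384 points over [−1, 12] ppm, reduced to the same 500 bins by
   intensity summation, and min–max normalized to [0, 1000].
3. **Regression** (`mlmodel`) — Gradient Boosting under seeded 10-fold
   cross-validation (10CV). The headline error is the pooled
   out-of-fold RMSE (Σ over compounds of (ŷᵢ − yᵢ)², averaged, square
   root), with normalized variants

   NRMSE = RMSE / ȳ, RMSE / (y_max − y_min), RMSE / σ

   so that models trained on differently scaled label sets (e.g. CHI vs
   Chrom logD) stay comparable. A **hashed-label negative control** —
   features replaced by deterministic id-hash noise — verifies the model
   reads chemistry, not leakage.
4. **Study designs** (`experiments`, `speccompare`) — assignment-free
   spectrum comparison (rank-paired RMSE between sorted shift lists,
   paired t-tests for method ranking), dataset mixing (swap an
   increasing fraction of feature vectors from a second spectrum source),
   applicability-domain profiling (|error| vs label value), and
   ECFP4/Tanimoto similarity of external compounds to the training set.
5. **Synthetic data** (`synthgen`) — a seeded generator of compounds as
   proton-environment multisets with tabulated class shifts, Lorentzian
   traces, and logD labels with a planted linear dependence on the
   bucketized features, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from nmrlogd import (SynthConfig, generate_library, bucketize, label_slice,
                     Dataset, cross_validate_10cv, hashed_label_control)

cfg = SynthConfig(n_compounds=300, seed=1)
_, shift_lists, labels = generate_library(cfg)
X = np.vstack([bucketize(sl).counts for sl in shift_lists]).astype(float)
y = label_slice(labels, "CHI", 7.4)
ds = Dataset(X=X, y=y.to_numpy(),
             compound_ids=[sl.compound_id for sl in shift_lists])

report = cross_validate_10cv(ds, params={"max_features": "sqrt"}, seed=1)
control = cross_validate_10cv(hashed_label_control(ds, seed=1),
                              params={"max_features": "sqrt"}, seed=1)
print(f"RMSE {report.rmse:.3f}  NRMSE(sd) {report.nrmse_sd:.3f}  "
      f"control {control.rmse:.3f}")
```

prints

```
RMSE 0.511  NRMSE(sd) 0.461  control 1.142
```

meaning: on a 300-compound synthetic library with planted spectral
signal and noise, the spectrum-based model recovers CHI logD at pH 7.4
to about 0.51 log units (less than half the label standard deviation),
while the information-free control collapses to the label SD (≈ 1.1) —
the predictive skill comes from the spectra.

The same flow is available from the shell:

```bash
nmrlogd simulate --seed 1 --n-compounds 300 --out-dir sim
nmrlogd featurize --in sim/shifts.csv --out features.csv
nmrlogd evaluate --features features.csv --labels sim/labels.csv --seed 1
```

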