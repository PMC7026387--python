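# deepsol

Aqueous-solubility (logS) prediction from 881-bit substructure fingerprints
with deep 1D residual convolutional networks, plus the full supporting
pipeline: data curation, fully connected baselines, evaluation protocols and
a synthetic-data generator with a planted, recoverable mechanism.

logS is the base-10 logarithm of aqueous solubility in mol/L. Models map a
binary 881-bit substructure fingerprint (PubChem key set, PaDEL descriptor
CSV dialect) to a scalar logS.

## Quick start

```python
import numpy as np
from deepsol import ResNetRegressor, SyntheticGroundTruth, generate_dataset
from deepsol.training import split_train_test
from deepsol.metrics import evaluate

truth = SyntheticGroundTruth.random(k_active=40, seed=1, noise_sd=0.3)
features, dataset = generate_dataset(5000, truth)
train, test = split_train_test(features.n, 0.1, seed=1)

model = ResNetRegressor(n_layers=14, max_epochs=60, batch_size=128,
                        learning_rate=3e-3, random_state=1)
model.fit(features.X[train], features.y[train])

report = evaluate(features.y[test], model.predict(features.X[test]),
                  molecular_weight=features.molecular_weight[test])
print(report.r2, report.rmse, report.pct_within_10fold)
```

## Estimators

Both estimators follow the scikit-learn contract (`get_params`/`set_params`,
`fit`/`predict`/`score`, trailing-underscore fitted attributes) and compose
with sklearn pipelines and model selection.

- **`ResNetRegressor(n_layers=20, ...)`** — the "deeper-net": an N-layer
  residual 1D CNN treating the 881 bits as a one-channel sequence. N counts
  parameter layers: N−1 convolutions plus 1 fully connected output layer;
  valid depths with the default three channel stages (9→18→36) are 8, 14,
  20, 26, ... After fitting, `layer_audit_` lists every parameter layer with
  shapes and parameter counts so depth claims are checkable.
- **`DNNRegressor(hidden_sizes=(512, 1024, 2048, 4096), ...)`** — the
  fully connected "shallow-net" baseline with ReLU, dropout 0.5 and
  L2 0.001.

Training minimizes the batchwise negative coefficient of determination
(−R²) by default (`loss="mse"` is available), with Adam, early stopping on
an inner validation split, and best-state restoration. All randomness
descends from `random_state`.

## Command-line interface

Installed as `deepsol`:

```bash
deepsol curate compounds.csv -o curated.csv        # units -> logS, canonicalize, dedup
deepsol simulate --n 5000 --seed 1 --outdir syn/   # synthetic data + ground truth
deepsol train curated.csv fingerprints.csv -o model.npz --n-layers 14
deepsol crossval curated.csv fingerprints.csv -k 10 -o cv.json
deepsol predict model.npz fingerprints.csv -o predictions.csv
deepsol evaluate predictions.csv curated.csv -o evaluation.json --bootstrap 10000
```

Every model-producing command writes a manifest (config, seed, SHA-256 of
inputs) next to its outputs. Exit codes: 0 success, 2 configuration error,
3 data error, 4 numeric failure.

## Data curation

`deepsol.curation` converts heterogeneous solubility reports (mol/L, g/L,
mg/L, µg/mL, mg/mL, ...) to logS — mass units require a molecular weight,
which is computed from the structure — canonicalizes SMILES and assigns
InChIKeys via RDKit, and deduplicates by InChIKey (first record kept;
conflicting logS values replaced by the duplicate group's median). Censored
entries (`<value`) are retained and flagged but excluded from modeling.
Every rejection, conversion and merge is recorded in a provenance log
(JSONL), so record counts are conserved and auditable.

## Evaluation

`deepsol.metrics` implements R² (coefficient of determination), RMSE,
PCT-10-fold (percent of predictions within one log unit, i.e. within
10-fold of the true solubility; the boundary |Δ|=1 counts as inside), and
4-way solubility-category accuracy using lower-inclusive edges at 0.1, 10
and 100 g/L (g/L = 10^logS × MW). Bootstrap resampling
(`bootstrap_metrics`, default B=10,000) gives percentile 95% CIs.

Protocols: a single seeded 90/10 split (`split_train_test`) and k-fold CV
(`cross_validate`) with near-equal fold sizes (first n mod k folds get the
extra record) and per-fold reseeded trainings.

## Synthetic data

`SyntheticGroundTruth` plants a sparse additive mechanism over fingerprint
bits (optional pairwise terms, block-correlated bits, Gaussian noise). The
generator is fully seed-deterministic, the planted truth is exportable, and
recovery is checkable: with zero noise OLS reproduces the weights exactly,
and held-out R² has the analytic ceiling Var(signal)/(Var(signal)+σ²).
`generate_fixture_tables` writes a fixed 20-row table (mixed units, one
duplicate, one censored row, one malformed SMILES) that curates to exactly
18 records — used by the test suite end to end.

## Testing

```bash
pytest -q               # full suite incl. acceptance tests (one trains a model)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion;
`scripts/acceptance.py` computes the same quantities and writes them as a
JSON report. See `docs/methods.md` for design and numerical details.
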