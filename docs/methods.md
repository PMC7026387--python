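# Methods

Design and numerical notes for the deepsol package. The package predicts
logS — the base-10 logarithm of aqueous solubility in mol/L — from 881-bit
binary substructure fingerprints.

## 1. Data curation

### Unit normalization

Reported solubilities arrive in molar (mol/L, mmol/L, µmol/L) or mass
(g/L, mg/L, µg/L, mg/mL, µg/mL) units. Molar units convert directly:
logS = log10(value × unit factor). Mass units first convert to g/L
(mg/mL ≡ g/L, µg/mL ≡ mg/L) and then divide by the molecular weight,
which is computed from the parsed structure — a mass unit without a
resolvable structure is a hard error, never a silent guess.

Censored values (`<0.01` style) are parsed, flagged `censored=True`,
retained in the curated table for transparency, and excluded from model
fitting, because a bound is not a measurement.

### Canonicalization and deduplication

RDKit parses each SMILES; unparseable structures are rejected (logged, not
silently dropped). Canonical SMILES and InChIKeys are computed; the key
(14 + 10 + 1 uppercase letters, hyphen-separated, 27 characters) is the
deduplication identity. Within a duplicate group the first record is kept;
if the group's logS values conflict, the kept record's logS is replaced by
the group median. Every rejection, conversion and merge appends a JSONL
provenance entry, so for any input of n rows:

    valid records + rejected rows + removed duplicates = n.

## 2. Fingerprints

Fingerprints are fixed-length 881-bit binary vectors in the PaDEL
descriptor-CSV dialect (`Name,PubchemFP0,...,PubchemFP880`). The
`FingerprintVector` type enforces length and binarity at construction.
`align_features` joins fingerprints to curated records by compound id,
sorts by id (making the feature matrix invariant to input row order), and
reports missing ids exhaustively.

## 3. Architectures

### Residual 1D CNN ("deeper-net")

The 881-bit vector is treated as a one-channel sequence. The layout for a
declared depth of N parameter layers:

1. **Stem**: one convolution (kernel 7, stride 1) to the first channel
   stage, + batch norm + ReLU.
2. **Three stages** of two-convolution residual blocks (kernel 3), with
   channels 9 → 18 → 36 and the sequence length halved (stride-2 first
   convolution) at each stage transition. Each block computes
   `y = F(x) + shortcut(x)` with **no activation after the addition**;
   the shortcut is the identity when shapes match, else a 1×1 strided
   projection convolution.
3. **Head**: flatten + one fully connected layer to the scalar output.

Counting: N = 1 stem conv + (N−2) block convs + 1 fully connected layer,
so (N−2)/2 residual blocks are split equally over the three stages — N ∈
{8, 14, 20, 26} gives 1, 2, 3, 4 blocks per stage. Projection shortcuts
carry parameters but are not counted toward N (they are bookkept and
flagged in the layer audit). Every built network carries a `layer_audit`
listing each parameter layer's kind, shapes and parameter count; total
parameters stay well under 2M (17k–49k for N = 8–26).

**Why a flatten head rather than global average pooling.** With GAP, the
composition of shared-weight convolutions and a channel-mean is (nearly)
invariant to translations along the bit axis — but fingerprint bits are
positional: *which* substructure key is set is the entire signal. On
synthetic data with a planted linear bit-weight mechanism (ordinary least
squares reaches the R² noise ceiling ≈ 0.94), a GAP-headed 14-layer net
plateaued at held-out R² ≈ 0.01: the function class cannot express a
position-weighted sum of bits. A flatten head keeps position information
and costs only `36 × L_final` extra weights. `ResNetSpec(head="gap")`
remains available.

**Why no activation after the residual addition.** With `y = F(x) +
shortcut(x)`, zeroing a branch's parameters makes the block exactly its
shortcut (identity or projection) for inputs of any sign — an exact,
testable property (acceptance criterion: max deviation ≤ 1e-6). A
post-addition ReLU would destroy this for negative values.

### Fully connected baseline ("shallow-net")

Dense layers with ReLU, inverted dropout (rate 0.5) and L2 weight decay
0.001; the reference configuration is hidden sizes 512/1024/2048/4096
(≈ 11.6M parameters — the parameter bound above applies to the ResNet
family).

## 4. Numerical implementation

No autodiff framework is used; forward and backward passes are explicit
NumPy (`deepsol.nn`), verified layer-by-layer and end-to-end with central
finite differences in float64.

- **Conv1d**: tap-wise batched matmul — the output is accumulated over the
  k kernel taps as `W[:,:,t] @ x_padded[:,:,t::stride]`, avoiding im2col
  materialization; the input gradient is accumulated the same way. This
  was several times faster than im2col at these channel widths.
- **BatchNorm1d**: per-channel over (batch, length); the backward pass is
  fused into `dx = A·dout + B·x + C` with three per-channel coefficient
  vectors computed from two einsum reductions.
- **Initialization**: fan-in-scaled uniform, U(−a, a) with
  a = scale·√(3/fan_in) (weight variance 1/fan_in at scale 1). The scale is
  an exposed hyperparameter (`init_scale`) because it controls the bias
  toward the network's near-linear regime: on the planted linear synthetic
  benchmark, scale 1.0 lets the net fit training noise past the
  R² noise ceiling while held-out R² plateaus near 0.55, whereas scale 0.3
  generalizes to held-out R² ≈ 0.86 — the setting used by the acceptance
  recovery run (with L2 10⁻³, Adam 3·10⁻³, batch 128).
- **Optimizers**: Adam (bias-corrected) and SGD; L2 weight decay applies
  to weight matrices only, not biases or batch-norm affine parameters.
- **Precision**: training runs in float32; gradient tests use float64.
  A note on testing: the true gradient of a convolution bias feeding batch
  norm is ~0 (the normalization subtracts it back out), so gradient checks
  use mixed absolute/relative tolerance.

### Training loss

The default objective is the batchwise negative coefficient of
determination,

    loss = SSE / SStot − 1   (= −R² of the mini-batch),

whose gradient is `2(pred − y)/SStot`. For a fixed batch it is a rescaled
squared error; the rescaling adapts the step size to the batch's target
spread. A zero-variance batch falls back to SSE/n with a logged warning;
singleton batches are skipped. `loss="mse"` is available.

### Output calibration

At fit time the network's output is wrapped in a fixed affine
`pred = raw·scale + loc` with loc/scale set to the training targets' mean
and standard deviation. Without it, the output bias must crawl from 0 to
the target mean (≈ −3 for logS) at roughly one learning-rate unit per
step before any structure can be learned. The constants are serialized in
checkpoints; gradients flow through the affine and were verified
numerically.

### Early stopping

An inner validation slice (default 10% of the training rows, seeded) is
scored by R² each epoch; training stops after `early_stop_patience` epochs
without improvement and the best-validation weights are restored.

## 5. Evaluation

- **R²** — 1 − SSE/SStot; raises on zero-variance targets rather than
  returning a convention. Values < 0.2 are displayed as "<0.2" by the
  report formatter, but stored at full precision.
- **RMSE** — √(SSE/n), in log units.
- **PCT-10-fold** — percent of predictions within one log unit of the
  observation (within 10-fold solubility); the boundary |Δ| = 1 is inside.
- **Category accuracy** — predictions and observations are mapped to g/L
  (10^logS × MW) and binned with lower-inclusive edges 0.1, 10, 100 g/L
  into practically insoluble / slightly soluble / soluble / freely
  soluble; accuracy is exact category agreement.
- **Bootstrap** — B (default 10,000) resamples of the prediction pairs;
  percentile 2.5/97.5 intervals. Resamples with zero target variance are
  skipped for R². A perfect fit gives zero-width intervals; two seeds
  agree within Monte-Carlo error (≤ 3·sd/√B).

**Protocols**: single 90/10 split — |test| = round(n/10), so 9,943 records
give 994 test / 8,949 train — and 10-fold CV with fold sizes differing by
at most one (9,943 → seven folds of 994, three of 995), rows sorted by
compound id before folding so results are row-order invariant. Per-fold
trainings are independently seeded; a failing fold is recorded without
aborting the others. CV results report per-fold metrics and min–max
ranges.

## 6. Synthetic data with a planted mechanism

`SyntheticGroundTruth` draws k active bits with uniform weights and plants

    logS = intercept + Σ w_j·b_j + Σ w_jk·b_j·b_k + ε,  ε ~ N(0, σ²),

over Bernoulli(0.15) bits with optional block correlation: with
probability ρ a bit copies its 4-bit block's shared draw, which correlates
neighbors while keeping the marginal density exact. Outputs are clipped to
[−10, 1] by default (disable with `clip_range=None` for exact linearity).
Recovery is checkable: at σ = 0 OLS on the active bits returns the planted
weights to machine precision, and held-out R² is bounded by
Var(signal)/(Var(signal) + σ²) — about 0.94 under the acceptance settings
(n = 5,000, k = 40, σ = 0.3).

The fixed 20-row fixture (`generate_fixture_tables`) contains 17 distinct
valid compounds across five unit notations, one censored entry, one
duplicate structure under a different SMILES spelling, and one malformed
SMILES; curation must yield exactly 18 valid records (17 modeling + 1
censored) with both removals in the provenance log. Regeneration is
byte-identical.

## 7. Reproducibility

All stochastic components draw from `numpy.random.SeedSequence` trees
rooted at user-supplied seeds: the synthetic truth at [seed, 881], dataset
sampling at [seed, 17, n], model building at [seed, 7], per-fold trainings
at [seed, 11, fold]. CLI commands write manifests with the full config,
seed, package version and SHA-256 digests of inputs. Checkpoints (.npz)
serialize the architecture spec, all weights, batch-norm running statistics
and the output calibration, and reproduce predictions bit-exactly.
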