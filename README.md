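# daebls

A broad (wide, not deep) learning system for tabular clinical classification,
with denoising-autoencoder feature extraction and incremental enhancement-node
growth. Intended for disease-prediction style tasks — readmission,
heart-failure outcome, abnormal-beat classification — where tables are
imbalanced, carry missing cells, and models must be enlarged cheaply as data
accumulates, without retraining from scratch.

## The model

The hidden state is a single wide layer built from two blocks:

- **Mapping layer `Tⁿ`** — the concatenated encodings of `n` independently
  trained denoising autoencoders (DAEs). Each DAE corrupts the standardized
  input `M` into `M̃` (additive Gaussian noise by default), encodes
  `P = f(θM̃ + β)`, and is trained by mini-batch gradient descent to
  reconstruct the clean `M` through a linear decoder. At inference, encoding
  is deterministic — corruption is a training-only device.
- **Enhancement layer `Hᵐ`** — `m` groups of fixed random projections
  `H_j = ξ_j(Tⁿ W_hj + β_hj)` with weights drawn once from uniform[−1, 1]
  (shrink-scaled to keep `ξ = tanh` out of saturation) and never updated.

With `A = [Tⁿ | Hᵐ]` and one-hot targets `Y`, the only learned parameters are
the output weights, solved in closed form by ridge regression:

    W = (AᵀA + λI)⁻¹ AᵀY,     λ = 1e-10 by default

and predictions are `argmax` over the rows of `AW`.

**Incremental growth.** When a fitted model needs more capacity, a new group
of enhancement nodes `H_new` is appended and the cached pseudoinverse `A⁺` and
weights `W` are updated by a Greville-style block formula:

    D = A⁺H_new,  C = H_new − AD
    Bᵀ = C⁺                       if C ≠ 0
    Bᵀ = (I + DᵀD)⁻¹ Dᵀ A⁺        if C = 0
    A_new⁺ = [A⁺ − DBᵀ ; Bᵀ],   W_new = [W − DBᵀY ; BᵀY]

This costs a pseudoinverse of the *new* columns only, and reproduces the
from-scratch ridge solution on `[A | H_new]` to ~1e-7 relative error.

The preprocessing pipeline follows the standard clinical-table recipe, in
fixed order and fitted on training rows only: k-nearest-neighbour missing
value imputation, Z-score standardization `x* = (x − µ)/σ`, and SMOTE minority
oversampling (training split only; synthetic rows are convex combinations of
minority neighbours).

## Worked example

```
$ daebls synth --n 2000 --d 20 --minority 0.3 --missing 0.05 --noise 0.5 \
      --seed 1 --out data.csv
wrote 2000 x 20 table to data.csv
$ daebls preprocess --in data.csv --seed 1 --out-dir prep
wrote processed tables and scaler to prep
$ daebls train --train prep/train_processed.csv --nodes 200 --seed 1 \
      --model-out model.npz
trained on 2800 rows; training accuracy 98.04%; model -> model.npz
$ daebls increment --model model.npz --add-nodes 200 --model-out model2.npz
200 -> 400 enhancement nodes; model -> model2.npz
```

The synthetic table has 30% minority labels, 5% missing cells and unit-scale
noise; preprocessing imputes and standardizes it and SMOTE brings the classes
to parity (2800 = 2 × 1400 rows), after which the 200-node model separates
the training classes at 98% accuracy. `increment` doubles the enhancement
layer by the block update — no retraining — and the result matches a model
trained with 400 nodes from the start (same seeds) to within ~1e-7 in the
output weights.

The same flow is available in Python (`daebls.run_experiment`) or as one
command from a YAML config (`daebls run --config cfg.yaml`), which performs a
stratified 80/20 split, leakage-safe preprocessing, fitting, and writes a
JSON report of train/test accuracy, per-class confusion counts and timings.
`daebls bench-increment` reproduces the increment-vs-retrain comparison on
any pair of tables.

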