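# Methods

## Model

`daebls` implements a broad learning system (BLS) whose mapped-feature block
is produced by trained denoising autoencoders rather than the random linear
maps of the original BLS. The pipeline is:

1. **Preprocessing** (fit on training rows, apply to test rows):
   KNN imputation → Z-score standardization → SMOTE (training rows only).
2. **Mapping layer** `Tⁿ`: `n_groups` DAEs, each trained on the standardized
   features with an independent seed and corruption stream; their encodings
   are concatenated column-wise.
3. **Enhancement layer** `Hᵐ`: fixed random tanh projections of `Tⁿ`.
4. **Output**: one-hot ridge regression `W = (AᵀA + λI)⁻¹AᵀY` on
   `A = [Tⁿ | Hᵐ]`; prediction by per-row argmax with ties resolved toward
   the first class in sorted order.
5. **Increment**: appending an enhancement group updates `A⁺` and `W` by the
   block formulas (`D = A⁺H`, `C = H − AD`, `Bᵀ = C⁺` or
   `(I + DᵀD)⁻¹DᵀA⁺`, stack). `A`, `A⁺`, `Tⁿ` and `Y` are cached inside the
   model (and its saved file) precisely so increments work later without the
   training data; the memory cost — O(n·cols) doubles — is accepted and
   documented.

## Parameters that matter

| parameter | default | units / range | why |
|---|---|---|---|
| `n_mapping_groups × mapping_hidden` | 10 × 10 | nodes | moderate mapped width; enough capacity for 10–20 input features without dominating the enhancement layer |
| `enhancement_groups` | (1000,) | nodes | the common single-group starting point for increment experiments |
| `ridge_lambda` λ | 1e-10 | – | near-pure pseudoinverse; see numerics below |
| DAE corruption | gaussian, SD 0.1 | standardized units | canonical DAE corruption for real-valued standardized inputs; masking available |
| DAE training | 100 epochs, lr 0.01, batch 32, sigmoid encoder, linear decoder, MSE | – | plain mini-batch gradient descent; the best-by-reconstruction-error snapshot is returned, so the final error never exceeds the initial one |
| imputation `k` | 5 | neighbours | conventional; distance is Euclidean over co-observed features normalized by their count |
| SMOTE | k = 5, target ratio 1.0 | – | canonical SMOTE, full balance |
| split | stratified 80/20 | – | keeps minority classes represented in both halves |

All stage seeds derive from one global seed via `SeedSequence(seed,
spawn_key=...)`, so a single integer reproduces synthesis, split,
preprocessing, DAE training and every enhancement draw bit-for-bit.
Enhancement-group seeds are indexed by group position, which makes an
incremented model and a model fitted from scratch with the larger
architecture use *identical* random matrices — the increment-vs-retrain
comparison then isolates the algebra, not the draws.

## Numerical design choices

- **Enhancement shrink scale.** Weights and biases are drawn uniform[−1, 1]
  as usual, but the projection is scaled by `1/√(n_inputs)` before the bias
  (`H = ξ(s·TⁿW + β)`), the standard BLS shrink. Without it, ~100 sigmoid
  mapped features drive tanh deep into saturation (40%+ of cells beyond
  |0.99|), the enhancement block's spectrum collapses, and cond(A) reaches
  ~5e5; with it cond(A) stays ~3e4 and the block update tracks the direct
  ridge solution to ~1e-7. Directly constructed groups default to scale 1.
- **λ = 1e-10.** The block update is exact for the true Moore-Penrose
  pseudoinverse; using λ-ridge pseudoinverses introduces a bias that scales
  linearly in λ (measured: ~7e-4 at λ=1e-6 down to ~7e-8 at λ=1e-10 on the
  documented benchmark). λ=1e-10 keeps that bias far below the 1e-6
  equivalence the increment guarantees, while remaining ~six orders of
  magnitude above machine-level perturbations of `AᵀA` for the conditioning
  this model produces. The `C = 0` branch is detected at
  `‖C‖_F < 1e-10·max(1, ‖H_new‖_F)`.
- **Solves.** `(AᵀA + λI)X = B` is solved as a symmetric positive-definite
  system (no explicit inversion). The retrain oracle used in tests goes
  through SVD (`numpy.linalg.pinv`) and shares no code with the update path.
- **Population SD** (divide by n) in the Z-score, so the fitting set comes
  out exactly mean 0 / SD 1; σ = 0 features map to 0 with a logged warning
  (real EHR extracts contain constant columns).
- **Degenerate inputs.** Rows with every feature missing are rejected by
  name; imputation falls back to the feature's global training mean (logged)
  when fewer than k reference rows observe the feature; single-class training
  tables and zero-node increments are rejected; non-finite training losses
  raise with a suggestion to lower the learning rate.

## What the synthetic generator emulates — and what it does not

`generate_table` draws class-conditional Gaussian blobs (centroids
`class_sep` apart), adds isotropic noise, allocates the minority class
deterministically (`round(minority_fraction·n)` rows), and knocks out feature
cells completely at random at `missing_rate`. This reproduces the three
pathologies the pipeline targets — imbalance, missingness, noise — but none
of the structure of real EHR extracts: no mixed categorical/ordinal coding,
no informative (non-random) missingness, no correlated features or temporal
structure. Passing tests therefore demonstrate the *algorithmic* contracts
(equivalence, optimality, leakage-safety, reproducibility) and sane behaviour
under those pathologies; they do not certify accuracy figures on any real
clinical dataset. `generate_separable` builds a two-class table whose
supports on one feature are disjoint with a margin ≥ 4× the within-class
spread — a construction on which any consistent learner must reach 100%
training accuracy, used as the end-to-end oracle.

Default study sizes used in the tests and the acceptance script — e.g.
n = 2000 × 20 features for the increment benchmark, 1500 × 15 for the SMOTE
recall comparison, matrices up to 300 × 200 for pseudoinverse checks — were
chosen so every property is measured at a scale where its failure modes
(conditioning, concentration) are visible while a full run stays in the
seconds range on a single CPU.

## Known limitations

- Increments add enhancement nodes only; adding mapping features or new
  training rows (also closed-form in the BLS literature) is out of scope.
- The DAE is single-layer with untied weights and a fixed learning rate; no
  stacking, no adaptive optimizers.
- Caching `A` and `A⁺` inside the model file makes saved models large for
  big training sets.
- Multi-class SMOTE oversamples every non-majority class toward the majority
  count; more nuanced per-class targets are not provided.
- Timing numbers in reports are hardware-bound and intentionally never
  asserted.
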