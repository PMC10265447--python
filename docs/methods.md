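# Methods

## Model

An ER graph couples entities (drugs, proteins, domains) through sparsely
observed relation matrices. Each entity owns one embedding table
e ∈ R^(n×d) (d = 30 proteins, 20 drugs, 10 domains) and one entity module
f — a stack of 3 dense layers (20 neurons for proteins, 10 for drugs), each
layer normalization followed by tanh, i.e. pre-activation norm on every
layer. A relation between entities i and j is scored per cell by
M(u, v) with u = f_i(e_i[row]), v = f_j(e_j[col]):

1. an affine bilinear stage h_k = uᵀW_k v + A_k·u + B_k·v + b_k (k = 1..10);
2. a feed-forward head of 2 layers × 10 neurons (layer-norm + tanh);
3. a final affine map to one raw score.

Binary relations treat the score as a logit (sigmoid applied inside the
loss and at prediction time); regressions use it directly. The training
objective is Σ ω_ij L_ij over relations, ω_ij = 1 by default, L = class-
balanced BCE (positive-class weight N_neg/N_pos computed on the relation's
training cells; the literal N_pos/N_neg reading is available via
`balance_direction`) or MSE. The balanced BCE divides by the sum of the
per-term weights, so a weight of 1 recovers plain mean BCE.

The affine bilinear stage deserves a note: a pure product uᵀWv cannot
represent a function of one side alone, but entity-level ("generally
active/inactive") effects are exactly what dominates curated DTI data and
what an entity-stratified evaluation probes. The linear terms give the
module that capacity; setting `pure_bilinear=True` (with identity
activations and depth-0 entity modules) removes them and reduces the model
to classical matrix factorization Y ≈ UV, which `mf_oracle` solves by
alternating ridge regression as an independent reference. In that
configuration the trainer's converged sum of squared residuals matches the
ALS objective to well under 1%.

Entities appearing in several relations share one embedding table and one
entity module; this sharing is the fusion mechanism. Side-information
features are mixed in additively, latent = f(e) + B(e, x), where B is a
bilinear mixer with no bias term (zero features contribute exactly
nothing); sparse feature matrices stay sparse throughout the forward and
backward pass.

## Optimization

Adam, learning rate 0.001, weight decay 0.001 applied L2-coupled (added to
the gradient before the moment update, the torch `Adam(weight_decay=...)`
semantics). The coupling matters: through Adam's normalizer the decay
gradient of an embedding row that receives no data gradient becomes a
constant-rate shrink of about lr per step, so instances held out of
training collapse toward a common latent. That collapse is what makes
cold-start (pair-stratified) predictions degenerate to near-ties instead of
amplifying random initialization — the behavior an honest cold-start null
requires. An AdamW-style decoupled mode is available
(`decoupled_weight_decay=True`) but is roughly 1000× weaker for
small-gradient parameters and leaves random structure in unseen embeddings.

Embeddings initialize from N(0, 1) per coordinate; dense-layer weights use
fan-in-scaled uniform init. The unit variance is deliberately large: when an
auxiliary similarity self-relation has to split entities into activity
clusters, small initializations leave the optimizer in the symmetric
saddle where the relation predicts its mean (observed as a ~0.17 MSE floor
and no fusion benefit); unit-scale embeddings break the symmetry reliably.

Each epoch makes one full pass over every relation's training cells in
minibatches of 512, with the batches of all relations shuffled together.
Dense self-relations are subsampled to at most `per_relation_cap = 20000`
cells per epoch; the cap bounds the cost of dense auxiliary matrices, and
its value is chosen large enough that a 300×300 similarity relation still
receives sufficient gradient per epoch to escape the symmetric saddle
(starving it at a few thousand cells per epoch reproducibly trapped some
seeds). Default 200 epochs with early stopping when the global training
loss fails to improve by 1e-5 for 20 consecutive epochs. All randomness
(init, shuffling, subsampling) flows from one integer seed; two fits with
the same seed give bit-identical loss histories on one thread. Non-finite
loss aborts with the offending relation's name.

## Synthetic data generator

`generate_dti` draws true latents U (drugs), V (proteins) with i.i.d.
standard-normal coordinates, entity activity biases a_d, b_p ~ N(0,
bias_scale²), and labels

  P(y=1 | d,p) = sigmoid(a_d + b_p + γ·U_d·V_p + intercept).

Observed cells are sampled *assortatively*: a fraction `assortativity` of
cells is drawn from sign-concordant pairs (both entities active, with
probability `pos_fraction`, or both inactive), the rest uniformly. This
emulates how curated benchmarks arise — a positive set from interaction
databases paired with a separately sampled negative set — and it is the
mechanism that produces *polarization*: entities whose observed labels are
all identical. With the defaults (300 drugs × 250 proteins, 2000 cells,
bias_scale 12, assortativity 1.0) the measured combined polarization is
0.94 ± 0.02, the regime of curated human DTI data. Polarization is
monotone in bias_scale (≈0.04 at 0, ≈0.6 at 3, ≈0.83 at 6, ≈0.94 at 12 at
these densities; it also depends on cells-per-entity, so sparser matrices
polarize at smaller biases). The intercept is calibrated by bisection to
the target positive fraction (tolerance 0.005); because the sampler is
balanced by construction the intercept stays near zero and does not wash
out the polarization, which a large intercept otherwise would in the
saturated regime.

`generate_affinity` emits y = a_d + b_p + γ·U_d·V_p + N(0, noise_sd²) for a
regression task. `derive_similarity` builds a dense [0,1] similarity from
latent rows (rescaled cosine, symmetric noise, clipped); for drugs the
default latent representation appends the activity bias to U — chemically
similar drugs share both binding preferences and overall activity, and
with a large bias scale the similarity approaches a two-cluster activity
indicator, which is the clean analog of what fingerprint similarity
contributes on real data. `derive_annotations` clusters latents (k-means)
into term groups plus Bernoulli(0.1) extra terms.

What the generator does **not** emulate: real chemistry (no synthetic
SMILES), sequence-derived similarity beyond the latent proxy, heavy-tailed
per-entity cell counts, or dataset-specific artifacts. Passing tests
therefore demonstrate the *mechanisms* — leakage under polarization,
fusion through shared embeddings — not performance on any real benchmark.

## Study conditions used by the slow tests and the acceptance script

- Cold-start null: 200×150, 8000 cells, bias_scale 6, balanced; pair-
  stratified 5-fold CV, averaged over 5 fold/train seeds (dataset seed
  fixed). Mean AUC ≈ 0.5: with both endpoints unseen a single-relation
  factorization has no usable information. Per-seed means vary by ±0.04
  because held-out entities retain a little random structure after finite
  training.
- Leakage reproduction: generator defaults (polarization ≈ 0.94):
  drug-stratified AUC ≥ 0.8 (the non-stratified protein side gives the
  answer away) while pair-stratified AUC stays at chance; at bias_scale 0
  the drug-stratified AUC collapses too.
- Fusion benefit: adding the latent-derived drug–drug similarity as an MSE
  self-relation lifts pair-stratified AUC by ≥ 0.1 (observed: +0.3 to
  +0.6), paired seeds, 5 replicates of 3 folds each.
- Linear limit: masked 30×20 exact-rank-3 matrix, rank-2 fits. Rank 2 keeps
  the optimum strictly positive so a relative comparison between the
  trainer and the ALS oracle is meaningful (at rank 3 both converge to ~0
  and the ratio is ill-conditioned); λ and weight decay are both 0.
- Held-out recovery: 200×150 at 10% observed density, generator defaults,
  random 80/20 split, test AUC ≥ 0.85 within 200 epochs. At this density
  the identifiable structure is predominantly entity-level: recovering the
  rank-5 interaction alone from 3000 binary cells is undersampled
  (one-bit completion needs on the order of rank·n·log n ≈ 10k cells), and
  the linear-MF oracle at the true rank also fails there — verified, not
  assumed.

## Numerical choices and degenerate inputs

- Tanimoto of two empty fingerprints is 0 (no shared evidence), so the
  similarity diagonal is 1 only for non-empty fingerprints.
- Row normalization keeps zero rows at zero and is idempotent; it breaks
  symmetry and the matrix is used as produced (no re-symmetrization by
  default).
- pKd transform: −log10(Kd/10⁹) for Kd in nM; non-positive Kd is an error.
  Pre-combined bioactivity scores are passed through unchanged.
- no_strat folds: repair swaps guarantee the contract for every entity
  with ≥ 2 cells; an entity with a single observed cell cannot appear in
  both train and test, is left in place, and is exempted by the verifier.
- Entity instances observed in no training cell keep their (decayed)
  random embedding and are flagged `untrained` in predictions.
- Classification threshold for precision/recall is probability 0.5,
  configurable; precision of an empty positive set is 0 by convention.
- CI uses the pairwise definition with ½ credit for prediction ties; it
  equals the midrank ROC AUC when the true values are binary.

## Known limitations

- No GPU or multi-thread path; determinism is guaranteed only single-
  threaded. Dense self-relations larger than ~10⁶ cells need the
  per-relation cap.
- The trainer has no validation-based model selection (by design: plateau
  rule only), so on noisy interaction-dominated data it can memorize; see
  the recovery note above.
- Multiclass relations, GCN/sequence encoders, and hyperparameter search
  are out of scope.
- `run_experiment` rebuilds the graph per fold, which is wasteful for very
  large auxiliary matrices but keeps folds fully independent.
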