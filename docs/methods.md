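# Methods

## Problem setting

The package predicts microbe–disease associations (MDAs) from a binary
incidence matrix `X ∈ {0,1}^{n_d × n_m}`: `X[i,j] = 1` when disease `d_i` has
an experimentally reported association with microbe `m_j`.  Entries equal to
zero are *unlabeled*, not verified absences; the classifier nevertheless
treats them as negatives, which is the standard positive–unlabeled
simplification in this literature.  The working assumption throughout is that
similar diseases associate (or disassociate) with similar microbes, so the
prediction signal lives in the similarity structure of the rows and columns
of `X`.

## Pipeline

1. **Similarities.**
   - *Disease functional similarity* `D_f`: each disease carries a gene set;
     gene–gene functional linkage comes from a HumanNet-style network of
     log-likelihood scores (LLS), min–max normalised to [0, 1].  For gene
     sets `G_i` (size `a`) and `G_j` (size `b`),

         D_f(d_i, d_j) = [ Σ_{g∈G_i} max_{t∈G_j} FS(g,t)
                         + Σ_{g∈G_j} max_{t∈G_i} FS(g,t) ] / (a + b),

     with `FS(g,g) = 1`, `FS(g,g') = LLS'(g,g')`, and 0 for pairs absent from
     the network (absence of evidence scores zero — the network is sparse).
     A disease with an empty gene set has `D_f = 0` against everything.
   - *Gaussian interaction profile kernel (GIPK)* similarity `D_G`, `M_G`:
     an RBF kernel on the binary profiles (rows of `X` for diseases, columns
     for microbes), `exp(−γ ||IP_i − IP_j||²)`, with
     `γ = γ' / mean_i ||IP_i||²` and raw bandwidth `γ' = 1`.  Normalising by
     the mean squared profile norm makes the kernel scale with overall
     network density.
   - *Fusion*: `S = (F + G)/2` where the functional entry `F` is non-zero,
     and the kernel value otherwise (`gipk_fallback`).  The strictly literal
     variant, which returns 0 whenever `F = 0`, is kept behind
     `mode='paper_literal'`; it zeroes every row of a gene-less disease and
     contradicts the motivation for fusing in the first place.  Microbe
     functional similarity `M_f` (a genome-context method) is accepted as an
     optional precomputed input; absent, it is treated as all-zeros so
     `S_M = M_G`.

2. **Pair features.**  Record `k = j·n_d + i` (microbe-major) represents the
   pair `(m_j, d_i)` as the concatenation of microbe similarity row `S_M[j]`
   (length `n_m`) and disease similarity row `S_D[i]` (length `n_d`).  At the
   39 × 292 scale this gives 11,388 records of width 331.

3. **Sparse autoencoder.**  A symmetric encoder–decoder
   (331→256→128→96→64→96→128→256→331 by default; ReLU hidden, tanh output)
   minimises

       E = MSE + λ·Ω_sparsity + β·Ω_weights,

   where MSE is the mean over samples of the squared reconstruction residual
   (summed over features — the formula as printed carries no division by the
   feature dimension, and with the stated λ this balance is what keeps the
   reconstruction term in charge); Ω_sparsity is the KL divergence between
   Bernoulli variables with mean ρ and the batch-average activation of each
   penalised hidden unit; Ω_weights is half the sum of squared weights over
   all layers.  Defaults λ = 0.1, β = 5e-4, ρ = 0.05, batch 32, Adam at 1e-3.
   The KL penalty applies to the bottleneck layer by default — the penalty is
   written as a sum over the units of a single hidden layer, and penalising
   every hidden layer at the stated λ empirically collapses the encodings to
   near-constant vectors; `sparsity_all_hidden=True` restores the spread
   variant.  Batch-average activations are clamped to [1e-7, 1−1e-7] before
   the KL term, which is undefined at 0 and 1.  The implementation is plain
   NumPy with explicit backpropagation; analytic gradients are verified
   against central finite differences to 1e-4 relative in the test suite.
   Epochs default to 30: on pair-feature tables at the scales this package
   targets the training cost plateaus well before that, and the autoencoder
   is refit inside every cross-validation fold.  Inputs already lie in
   [0, 1] and are used as-is (tanh can reach them); an optional
   `rescale_inputs` flag maps them to [−1, 1] instead.

4. **Classifier.**  LightGBM with num_leaves 31, learning rate 0.1,
   unlimited depth, feature/bagging fraction 0.9, min_data_in_leaf 20 and
   100 boosting rounds (the last two are library defaults; the sources for
   the others state no round count).  Single-threaded deterministic mode.  A
   pair is called positive when its predicted probability strictly exceeds
   0.5.  Class imbalance is left unweighted by default (`scale_pos_weight`
   is available): reported accuracies in this literature track class
   prevalence, implying no rebalancing.

## Cross-validation and leakage control

Three five-fold regimes: CV1 holds out diseases (whole rows), CV2 microbes
(whole columns), CV3 individual pairs (entries).  Test records are all pairs
involving held-out entities (CV1/CV2) or the held-out entries (CV3); their
labels are masked to zero in the training copy of `X` before any kernel
similarity is computed.

Masking the test entries alone is not sufficient.  Each *training* pair's own
entry still sits inside the GIPK profiles from which its feature vector is
built, and a flexible classifier learns to read the label straight off the
feature; on test pairs — whose entries are masked — that shortcut inverts,
and measured test AUC lands at or below chance.  The masked scope therefore
cross-fits the training features: training records are split into 5 chunks,
and each chunk's features are computed from a matrix in which the test set
*and that chunk* are masked, so no record's features ever contain its own
entry.  `crossfit_chunks=0` disables this (the naive protocol, kept for
comparison), and `similarity_scope='full'` computes similarities once from
the unmasked matrix — the protocol that published AUCs near 0.98 under
entry-level CV are consistent with.  The report records which scope was used.

Under the default (honest) protocol the autoencoder is refit per fold on
training-record features only (`sae_scope='train'`; `'full'` fits on all
rows).  Folds whose test records contain a single class have undefined
AUC/AUPR; they are recorded as missing, excluded from aggregation, and
counted in the report.

Metrics: accuracy and the Matthews correlation coefficient from the 2×2
confusion table at the 0.5 threshold; AUC as the rank statistic with ties
shared; AUPR by step-wise precision–recall integration *without* the
precision envelope (the average-precision convention — AUPR conventions
differ, so this is stated explicitly).

## Synthetic data generator

The generator emulates the scale of a small curated MDA database and the
block structure the similarity assumption implies.  Diseases and microbes
are partitioned into co-association blocks; within-block pairs associate
with probability `within_block_density`, others with `background_density`.
Disease gene sets share a per-block core (the overlap fraction of each
disease's genes) plus disease-private genes; within-block gene-pool pairs
receive high-mean LLS scores, cross-block pairs low-mean.  Everything is
driven by one seed and is bitwise reproducible.

Defaults: 39 diseases × 292 microbes, 13 blocks, within-density 0.48,
background 0.003 — expected positives ≈ 452, matching the ~450/~4% density
of the emulated database, with a block-membership-oracle AUC of ≈ 0.94.  The
defaults were fixed from this closed-form arithmetic: the joint requirements
of realistic density *and* a recoverable planted signal force a few small
dense blocks rather than many diffuse ones.

What the generator does **not** emulate: heavy-tailed microbe degree
distributions, ontology-structured disease relationships, study-level
reporting biases, or any real taxonomy.  Passing tests demonstrate that the
pipeline recovers planted co-association structure under honest evaluation —
not that it attains any particular performance on real curated databases.

## What the honest protocol can and cannot recover

With ~450 positives over 292 microbes, a microbe averages 1.5 known
associations, so the microbe-side kernel rows are extremely noisy.  A
plug-in estimator that knows the true disease blocks and estimates each
microbe's block from its surviving training entries reaches AUC ≈ 0.89 on
held-out entries — the practical information ceiling of the masked protocol
(the block oracle's 0.94 is unattainable without the masked entries).  The
full pipeline recovers ≈ 0.78–0.81 of it, far above the raw-feature
logistic-regression reference (≈ 0.5, which cannot represent the
block-matching interaction).  Under `similarity_scope='full'` the same
pipeline scores ≈ 0.99 — that gap is the leakage, and it is the reason the
laxer protocol is not the default.

## Numerical and design notes

- Identifier registries are deduplicated and sorted lexicographically;
  matrix coordinates are reproducible across runs and never leak into files.
- Duplicate gene-network edges: last occurrence wins, with a warning.
- Ranking ties break lexicographically by identifier; a pair's global rank
  is 1 + the number of strictly higher scores, so exact ties share a rank.
- One global seed derives per-component seeds by hashing seed + component
  name (all below 2^31), so components never share RNG streams.
- The autoencoder's duplication-sensitive counterparts in LightGBM
  (min_data_in_leaf, min_data_in_bin, the hessian floor) are count-based;
  exact train-set duplication invariance holds only when all of them are
  scaled with the data, which the test suite does explicitly.

## Known limitations

- Microbe functional similarity is consumed, never computed; without it the
  microbe axis rests on the interaction-profile kernel alone.
- Dedup is exact-string; no ontology mapping or name canonicalisation.
- The positive–unlabeled simplification biases probability estimates
  downward; scores are useful for ranking, not calibrated risk.
- Entry-level cross-validation on association matrices is easy to
  over-score; results produced with `similarity_scope='full'` should be
  read as upper bounds, not generalisation estimates.
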