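# Methods

## Problem and model

Drug–target interaction (DTI) prediction is treated as binary link
prediction on a bipartite graph, with side information entering through
multiple similarity networks per entity type. The pipeline has four stages.

**1. Similarity views.** Binary association profiles (drug–drug,
drug–disease, drug–side-effect, drug–target for drugs; protein–protein,
protein–disease, protein–drug for targets) are compared row-wise with the
Jaccard index. Entities with empty profiles get similarity 0 to everything
and 1 to themselves, which keeps the unit-diagonal invariant and avoids
0/0. Chemical-structure and sequence similarities are consumed as
precomputed matrices; the loader repairs them (symmetrisation as (M+Mᵀ)/2,
clipping to [0,1], unit diagonal) and logs every repair. Whether
distributed similarity matrices should be re-normalised before fusion is a
convention; ours is the repair above and nothing else.

**2. Fusion.** Each of the V views is encoded by one graph-convolution
layer over one-hot features (so the propagation collapses to A_norm W_v);
a learned scoring vector gives each node a logit per view, a softmax over
views gives per-node weights, and the weighted combination is the fused
feature matrix X. A dot-product decoder Â = σ(XXᵀ) is trained against the
mean over views of the mean-squared reconstruction error. The integrated
network A_homo is the repaired Â — the reconstruction, not the average of
the inputs. Closed-form baselines are available: the entrywise arithmetic
mean ("ave") and the noisy-OR 1 − Π(1 − S_v) ("pro"). The literal product
form 1 − Π S_v is kept behind a flag but is degenerate (views agreeing at
1 fuse to 0), hence the noisy-OR reading is the default.

Two fusion-specific choices matter:

* *Encoder nonlinearity is tanh, not a rectifier.* With nonnegative
  embeddings, XXᵀ ≥ 0 entrywise and σ(XXᵀ) ≥ 0.5, so the decoder could
  never reconstruct the (majority) similarity values below 0.5 and training
  collapses X to zero. A sign-symmetric nonlinearity removes the floor.
* *All per-view encoders share one initial weight draw.* Views are
  exchangeable a priori; symmetric initialisation means duplicated views
  behave exactly like a single view (they differentiate only through their
  gradients), which makes fusion results invariant to trivially replicated
  inputs.

**3. Multi-network GCN embedding.** Three networks are propagated with the
renormalised rule X⁽ˡ⁺¹⁾ = ReLU(D̃^{-1/2}(A+I)D̃^{-1/2} X⁽ˡ⁾ W⁽ˡ⁾): the
integrated homogeneous networks (initial features: the fusion outputs
X_d, X_t), the bipartite network of training interactions (zero diagonal
blocks), and the heterogeneous network (homogeneous blocks on the diagonal,
bipartite block off it). For the joint networks the initial features are
the vertical stack [X_d; X_t], with each side first projected linearly to
the embedding width when the two feature widths differ. Every intermediate
layer is retained and a node's embeddings are stacked into a (3·l) × F_m
matrix, homo rows first, then bipartite, then heterogeneous; ablating a
network removes its l rows. All layer widths equal F_m so the stack is
rectangular, which the attention stage requires.

**4. Interactive attention and scoring.** Attention is standard multi-head
scaled dot product: per-head projections of width F_m/heads,
softmax(QKᵀ/√d)V, head concatenation, output projection. One interactive
layer applies self-attention to each side and feeds the two cross-attention
blocks (drug queries with target keys/values and vice versa) from the same
two self-attention outputs. The sublayer wrapper follows
x = LayerNorm(x_mha + Dropout(FF(x_mha))): the residual and normalisation
wrap only the feed-forward path. The conventional post-norm placement
(residual around both sublayers) is available via `attn_wrap="standard"`.
The feed-forward sublayer is two linear maps with a rectifier between and
inner width 4·F_m. A cascade of n layers concatenates the raw inputs plus
every layer output ((n+1)·F_m wide) and projects back to F_m; in the
cascade the first concatenated term is the layer-0 input on both the drug
and the target side (the drug-side equation makes this explicit and the
target side is implemented symmetrically). Mean pooling over the stack
rows gives 1 × F_m vectors; their concatenation (drug first, width 2·F_m)
is scored by an MLP with Tanh hidden layers, halving widths, and a logistic
output squash so the score lies in (0,1) and cross-entropy is well defined.
A Tanh output alone spans (−1,1), which cross-entropy cannot consume; a
`literal_tanh` mode rescales (tanh+1)/2 for that variant.

## Evaluation protocol

All 1-cells of the interaction matrix are positives; negatives are drawn
uniformly without replacement from the 0-cells at a stated ratio (1:1
default; 1:5, 1:10 supported). Positives and negatives are folded into 5
folds independently so each fold preserves the global ratio; fold sizes
differ by at most one per class. For every fold the held-out positives are
removed from the bipartite and heterogeneous adjacencies before training
and an exhaustive assertion verifies the removal; an unmasked mode exists
behind `mask_test_edges=False` for comparison, since leaving evaluation
edges in the training networks leaks labels. Note the similarity views are
built once from the full association data (including the drug–target
profile view), which is the usual transductive convention for this model
family; masking applies to the networks the supervised stage trains on.
Reported metrics (ACC, AUC, AUPR, F1, MCC; threshold 0.5) are arithmetic
means over folds. AUC/AUPR come from the score ranking with ties counted
one half; they are computed by scikit-learn and cross-checked in the tests
against brute-force pair-ordering and confusion-matrix oracles.

## Optimisation and numerics

The stack runs on a small reverse-mode autodiff engine over float64 numpy
arrays (broadcast arithmetic, flat-GEMM batched matrix products, fused
softmax, row gathering with scatter-add backward). Training uses
adaptive-moment gradient descent. The published learning rate 0.1 is the
default config value with a 10× decay on plateau (patience 25), since 0.1
is aggressive for adaptive optimisers; the synthetic benchmark uses 0.01
without decay, because its loss surface has an early plateau that the decay
heuristic would freeze into. Parameters are Glorot-uniform initialised from
a seeded generator; dropout (rate 0.1) applies only in training mode, so
evaluation is deterministic and two runs with the same config and seed
produce byte-identical reports. A non-finite loss aborts with diagnostics
and the last finite parameter state. Degenerate configurations (no network
types enabled, width not divisible by heads, unknown config keys) are hard
errors.

## Synthetic benchmark

The generator plants balanced communities over drugs (k_d=3) and targets
(k_t=4). Every association view assigns its columns to communities and
draws Bernoulli edges at rate 0.5 within the community against a 0.05
background; interactions follow a 3×4 community affinity matrix (0.9 for
each drug community's matched target community, 0.02 elsewhere) with 1%
label-flip noise. Chemical/sequence similarity surrogates are Jaccard
similarities of independent association draws — only the matrix contract
matters to the method, not real chemistry. The default instance is
50 drugs × 80 targets (≈980 positives) with a reduced operating point
(F_m=32, 4 heads, 2 GCN and 2 attention layers, 200 epochs at lr 0.01) so
fusion plus one training fold takes a few minutes on one CPU; the
acceptance script's full 5-fold run takes 15–20 minutes.

What the benchmark does and does not show: interactions are conditionally
independent given community membership, so block identity is the only
learnable signal and the Bayes-optimal AUC is about 0.95 at these rates —
recovery scores must be read against that ceiling, not against 1.0. Real
pharmacological data have heavy-tailed degree distributions, correlated
views, within-community structure and far lower interaction density; a
passing benchmark demonstrates that the pipeline recovers planted structure
end-to-end and that its bookkeeping (masking, folding, determinism) is
sound, not that it attains published real-data performance.

## Known limitations

Dense matrix algebra throughout (adequate to a few thousand nodes; no
sparse path). Fusion is trained unsupervised and then frozen; joint
fine-tuning is not implemented. Full-batch training only. Chemical
fingerprints and sequence alignments are out of scope — similarity matrices
arrive precomputed. Baseline DTI methods and case-study verification
against external databases are out of scope.
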