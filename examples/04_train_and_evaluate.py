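"""Train the full model on one cross-validation fold and evaluate it.

Pipeline: fused networks -> GCN layer stacks over the homogeneous,
bipartite and heterogeneous networks -> cascaded self-/cross-attention ->
MLP pair scorer, trained with cross-entropy on 1:1 negative-sampled pairs.
Held-out interactions are removed from the training networks (leakage
masking).  Reduced epochs here so the example runs in about a minute; the
benchmark setting in scripts/acceptance.py trains longer.
"""

from midti import build_dataset, easy_fixture, train_fold
from midti.training import fuse_problem, problem_from_synthetic

data, config = easy_fixture(seed=1)
config = config.replace(epochs=60)

problem = problem_from_synthetic(data)
fused_d, fused_t = fuse_problem(problem, config)
dataset = build_dataset(problem.dti, ratio=config.ratio, seed=config.seed)

model, metrics, history = train_fold(dataset, 0, fused_d, fused_t, config)

print(f"training loss: {history[0]:.4f} -> {history[-1]:.4f}")
print("held-out fold metrics:")
for key, value in metrics.items():
    print(f"  {key}: {value:.4f}")
print("AUC is the probability a held-out true interaction outranks a "
      "sampled non-interaction; 0.5 is chance. Short training gives a "
      "partially converged model — expect AUC well above chance but below "
      "the converged benchmark value.")
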