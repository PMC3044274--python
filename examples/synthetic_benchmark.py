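"""Measure the AUC gain of regularization on a synthetic search result.

Generates a target-decoy dataset (20 target proteins, half present;
20 decoys; 400 PSMs with correct scores ~ N(3,1) and incorrect ~
N(1,1)), re-ranks at lambda = 0.5 and compares target-decoy ROC AUC
before and after.
"""

from psmreg import SyntheticConfig, benchmark_improvement

config = SyntheticConfig(seed=7)
result = benchmark_improvement(config, lambdas=[0.5])

print(f"n_psms          : {result.n_psms}")
print(f"AUC (initial)   : {result.auc_initial:.4f}")
print(f"AUC (lambda=0.5): {result.auc_regularized[0.5]:.4f}")
print(
    "\nThe regularized scores separate target from decoy PSMs better "
    "because correct identifications cluster in present proteins and "
    "reinforce each other, while scattered incorrect matches are pulled "
    "down by their low-scoring neighbors."
)
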