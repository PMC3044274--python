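# Methods

## Model

`psmreg` treats PSM re-ranking as regularization on a peptide
co-occurrence graph. The working hypothesis is that peptides belonging
to the same protein should receive similar ranking scores: a truly
present protein tends to contribute several well-scoring peptides,
while a random match sits among low-scoring neighbors. The hypothesis
is knowingly imperfect — fragmentation propensity and physicochemistry
make real per-peptide scores of one protein vary widely — but pulling
inconsistent scores toward their group mean still helps on balance:
a lone low-scoring peptide of a well-supported protein is promoted,
and a lone high-scoring match in an otherwise silent protein is
demoted.

Given scores `X` and membership sets `U_i`, the graph weight is the
Jaccard index `w_ij = |U_i ∩ U_j| / |U_i ∪ U_j|`, a probability that
the two peptides co-occur in a protein: 1 for identical membership
(including two spectra matching the same peptide — legitimate distinct
nodes), 0 for disjoint membership (no edge). Two alternative kernels,
`|∩|/(|U_i||U_j|)` (`product`) and `|∩|/min(|U_i|,|U_j|)` (`min`), are
selectable; all three agree on which pairs are connected, and the edge
*count* of any example depends only on that support. The objective

    Q(Y) = (1-λ) Yᵀ(I-S)Y + λ ||Y-X||²

uses the normalized Laplacian `I - S`, `S = D^(-1/2) W D^(-1/2)`,
rather than the unnormalized `D - W`, so that highly connected peptides
are not penalized merely for having many neighbors. The pairwise form
`Σ_{i<j} w_ij (y_i/√d_ii - y_j/√d_jj)²` equals `Yᵀ(I-S)Y` exactly (each
unordered pair counted once); a sympy test differentiates this exact
`Q` and confirms the minimizer is `Y* = λ(I-(1-λ)S)^(-1)X` with no
hidden constant factors.

## Solvers and numerics

* **Closed form** (default up to 5000 nodes): sparse LU solve of
  `(I-(1-λ)S) Y = λX`. Invertibility holds for every λ ∈ (0,1) because
  the eigenvalues of `S` lie in [-1,1] (verified numerically on random
  graphs up to n=200, together with positive semi-definiteness of
  `I±S`).
* **Diffusion iteration** (auto above 5000 nodes, or on request):
  `Y(t+1) = λX + (1-λ)SY(t)`, started from `Y(0) = X` (the fixed point
  is unique, so the start only affects iteration count). Stops when the
  max-norm update drops below `tol = 1e-9`; `max_iter = 10000` is a
  safety net that should be unreachable since the contraction factor is
  at most `(1-λ)`. Both solvers are required by tests to agree to 1e-7
  and to satisfy the stationarity residual `|(I-(1-λ)S)Y - λX|_∞ ≤
  1e-8` on the full (dummy-padded) system; the result object exposes
  `Y_full` so that check can be repeated externally.
* λ is strictly inside (0,1). λ → 1 returns the initial scores (tested
  at λ = 0.999: within 1% of `X`); small λ smooths aggressively. The
  default 0.5 is a robust middle of the sweep. `Y*` is linear in `X`,
  so scores are scale-equivariant but **not** translation-invariant —
  the log-base chosen for E-value transformation (base 10) therefore
  matters and is recorded in the run summary.

## Isolated PSMs and dummy nodes

A PSM sharing no protein with any other PSM would have degree zero.
Each such node gets a private dummy neighbor with raw weight 1e-8 and
initial score 0; dummy entries are stripped from all outputs. One
consequence deserves emphasis: symmetric normalization cancels the
magnitude of a node's only edge (`S`-entry `w/√(w·w) = 1`), so the
isolated node's closed-form score is `x/(2-λ)` — a *uniform* rescaling
of all isolated PSMs, not a negligible perturbation. Relative order
among isolated PSMs is preserved, but their scores shift relative to
connected ones. Users comparing mostly-isolated datasets should treat
regularized scores as a ranking, not a calibrated quantity.

## Evaluation protocol

Target-decoy labeling at the PSM level: a peptide-spectrum pair is a
false positive when its peptide belongs to any decoy protein (a
peptide appearing in both a target and a decoy protein counts as decoy
under this literal rule; a target-wins variant is available via
`mixed_policy`). TPR and FPR at threshold δ use `score ≥ δ` inclusive
semantics; the ROC curve runs over the descending unique scores (ties
share a threshold), is augmented to (0,0) and (1,1), and AUC is the
trapezoidal area — tested to agree with the quadratic-time
pairwise-comparison estimator (ties counted ½) to 1e-12 and with
scikit-learn's implementation. Min-max normalization is provided for
plotting score distributions on a common [0,1] axis; a constant vector
maps to 0.5 (degenerate-range policy; never reached on real data).

## Synthetic data generator

The generator emulates the statistical structure the method exploits,
not mass spectrometry itself. It builds `n_target_proteins` targets (a
fraction `fraction_present` of them present in the sample) and
`n_decoy_proteins` decoys (`DECOY_`-prefixed). Each protein holds
`1 + Poisson(peptides_per_protein - 1)` random length-10 peptides
(collisions negligible over 20^10), each shared into a second protein
of the same class with probability `sharing_prob`; sequences are the
peptides joined by random 5-residue linkers, so substring mapping
recovers membership exactly. Each of `n_psms` PSMs is correct with
probability `frac_correct`: correct PSMs draw a peptide from a present
protein and a score from `N(mu_correct, sigma_correct²)`; incorrect
ones draw from absent targets and decoys in equal proportion — so the
decoy rate estimates the incorrect rate, mirroring target-decoy logic —
and score `N(mu_incorrect, sigma_incorrect²)`. E-values are emitted as
`10^(-score)` for format completeness. A single integer seed drives one
`numpy` Generator; identical configs give byte-identical files.

Defaults (20/20 proteins, half present, mean 8 peptides, 10% sharing,
400 PSMs, N(3,1) vs N(1,1)) give roughly two pooled standard deviations
of score separation — a mid-quality search. What passing the
benchmark shows: when correct matches concentrate in present proteins,
smoothing raises target-decoy AUC (in ≥90% of 50 replicates at λ=0.5).
What it does not show: performance on real data, where scores are
neither Gaussian nor independent of peptide identity, membership comes
from much larger databases with homology structure, and the
present/absent dichotomy is soft.

## Design choices where the design was open

* **Similarity kernel.** Jaccard is the default because it is a
  probability, symmetric, 1 exactly for co-located-everywhere peptides
  and 0 for unrelated ones; the alternatives are kept selectable since
  any kernel positive on shared membership yields the same graph
  support.
* **Objective weighting.** `(1-λ)` on smoothing and `λ` on fitting is
  the unique convention whose minimizer is `λ(I-(1-λ)S)^(-1)X` and
  whose iteration is `λX + (1-λ)SY`; adopting it makes the three forms
  consistent without correction factors.
* **E-value transform.** `-log10`; any base is equivalent up to the
  scale equivariance noted above, and base 10 matches how E-values are
  displayed.
* **Peptide identity.** Nodes are (spectrum, peptide) pairs; membership
  keys on the modification-stripped residue string, since modifications
  do not change which proteins contain a peptide. Leucine/isoleucine
  are not equated in substring mapping.
* **Problem sizes in tests.** Property suites use random graphs up to
  n=200 (dense eigendecomposition oracles), solver-equivalence
  instances up to n=500, and 50 simulation replicates of 400 PSMs —
  sizes at which every claim can be cross-checked against dense linear
  algebra or brute-force counting.

## Known limitations

* Protein inference is out of scope; the output is a re-ranked PSM
  list, not protein probabilities.
* The affinity graph uses protein co-membership only; spectral or
  sequence-composition similarity between PSMs is not modeled.
* λ is not selected automatically; use the sweep to inspect
  sensitivity.
* Isolated-PSM scores are uniformly rescaled (see above).
* Native search-engine formats (pepXML, mzIdentML) are not parsed; the
  canonical TSV is the input contract.
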