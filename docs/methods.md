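# Methods

## Model

`srbmrank` stacks two restricted Boltzmann machines over a genes x samples
expression matrix whose rows have been standardized to mean 0, variance 1
(population variance, divisor n, so "variance 1" is exact on the training
samples; constant genes are mapped to all-zero rows with a warning and are
inert everywhere downstream).

The bottom layer is a Gaussian-Bernoulli RBM: real visible units (one per
gene) with unit Gaussian noise — fixed sigma_i = 1, which the
standardization makes exact, with no per-unit variance learning — and
binary hidden units. Its energy is

    E(V,H) = sum_i (v_i - b_i)^2/2 - sum_j c_j h_j - sum_ij v_i h_j w_ji.

The top layer is a fully binary Bernoulli RBM on the first hidden layer's
outputs. In both layers the hidden conditional is sigmoid(c + W v). During
Gibbs sampling the visible reconstructions are *binary* draws even in the
Gaussian layer — a denoising convention for noisy expression data. Under
the Gaussian energy restricted to v in {0,1} the exact conditional is
sigmoid(-0.5 + b + sum_j h_j w_j); the -0.5 offset comes from the
quadratic term and is verified analytically in the tests against the
two-state Boltzmann ratio.

## Training

Parameters are learned by mini-batch gradient ascent on the log-likelihood
with the CD-k estimator (k = 1 by default): k alternating Gibbs steps from
each data vector; positive phase at the data (the Gaussian layer keeps the
real-valued v^(0) there), negative phase at the chain end. Weights start
at Normal(0, sd = 0.01) — "N(0, 0.01)" is read as a standard deviation, the
conventional small-weight initialization; `init_weight_sd` exposes the
variance reading (sd 0.1) as a one-flag change — and biases start at 0.
Batches are formed by shuffling the sample order once per epoch with the
run seed; the per-batch gradient is the *sum* over the batch, with
`mean_gradient=True` switching to the batch mean. "Iteration counts"
(50 for the Gaussian layer, 400 for the binary layer) are full passes over
the training set. Everything is deterministic given the config seed.

Defaults follow the standard recipe for this architecture: eta = 0.5,
k = 1, batch size 4 (half of an 8-sample period), 400 and 20 hidden units
(about a tenth of the visible layer, then a further compression), 50/400
epochs. One caveat matters in practice: **eta = 0.5 is not a stable rate
for the Gaussian layer.** Binary {0,1} reconstructions can never match the
zero-mean real data, so the visible-bias gradient has a persistent
negative component; at large steps the biases and weights grow without
bound and the data-energy trace rises instead of falling. The benchmark
protocol (`synthetic_data.benchmark_protocol`) therefore trains the
Gaussian layer with batch-mean gradients at eta = 0.02 — with which the
mean data energy decreases monotonically on every tested seed — and keeps
eta = 0.5 for the binary layer, where bounded gradients make it safe. The
package-level defaults remain the standard values; the stable recipe is a
documented choice of the benchmark protocol.

Per-epoch diagnostics record the mean data energy (hidden states set by
deterministic 0.5-thresholding for reproducibility; a sampled mode exists
behind a flag) and the root-mean-square gradient norm.

For tiny Bernoulli machines (n_visible + n_hidden <= 20) the module
provides brute-force enumeration oracles — partition function, state
probabilities, exact mean log-likelihood and exact likelihood gradient —
used by the tests to verify the sigmoid conditionals exactly, the CD-50
gradient within Monte-Carlo error (20,000 draws, 3 standard errors per
component), and that CD-1 training raises the exact likelihood.

## Stacking and activation statistics

The stack trains greedily: the Gaussian layer first, then the binary layer
on the thresholded layer-1 representations of the training samples. A
hidden unit counts as *activated* on a sample when its conditional
probability is >= 0.5; the tie at exactly 0.5 activates (one documented
rule rather than platform-dependent rounding). A unit's activation
frequency over a sample set is the number of activating samples, and the
integer frequency-difference table between two periods mirrors the usual
diagnostic tabulation (how many units per layer changed frequency by d,
for each d >= 0).

Two training regimes exist. The default *pooled* regime trains one model
on all samples from both periods and computes per-period activation
profiles on it; unit identities then correspond across periods by
construction. A *per-period* regime (one model per period, shared
initialization seed) is available behind a flag; how unit i of one
period's model corresponds to unit i of the other's is inherently
heuristic there, which is why pooled is the default.

## Gene ranking

Step 1 selects the differentially activated units: |frequency difference|
strictly greater than 1 (layer 1) and 5 (layer 2) by default; non-selected
units are clamped to 0 everywhere in the energy. Step 2 evaluates each
gene's circuit energy per sample,

    E_g = (v_g - b1_g)^2/2 - sum_j h1_j w1_jg v_g
          - sum_i b2_i v2_i - sum_ij h2_j w2_ji v2_i,

with h-values the deterministic thresholded activations, v_g the real
standardized expression (matching the positive-phase convention), and the
layer-1 hidden-bias term omitted as it is identical for all genes. Genes
are ranked by the absolute cross-period change of their mean energy
(stable descending sort, ties by input order).

The last two energy terms carry no gene index: within a sample they add
the same offset D_s to every gene. Their cross-period difference D does
not cancel in C_g = |delta_g + D|; whenever |D| exceeds the per-gene
spread, the absolute value makes the ranking follow the *sign* of delta_g
rather than its magnitude, and which sign wins is an artifact of the run
(on the planted-signal benchmark this collapses recovery to near chance,
AUC ~0.55). The package therefore extends the same-for-all-genes omission
principle to every gene-independent contribution by centering E_g across
genes within each sample before taking the change (`center=True`, the
default); the literal uncentered formula remains available via
`center=False`. Centered, recovery is stable at AUC 0.71-0.79 across
learning rates and widths. A consequence worth knowing: after centering,
the layer-2 terms vanish from C_g entirely, so the II-variants coincide
numerically with their single-layer RBM counterparts in the pooled regime;
layer 2 still matters for the activation diagnostics and the per-period
regime.

Variants: SRBM-II (unit selection, the default), SRBM-I (all units kept,
the weakest third of each unit's outgoing connections — by |w|, per
fan-out, floor(fraction x fan-out) per unit, ties pruned at the lower
target index — set to 0), and RBM-I/II, which train and score with the
Gaussian layer only.

## Baselines and evaluation

The Welch two-sample t-test (unequal variances — the defensible default at
8 samples per group) ranks genes by |t|; genes with zero variance in both
groups rank last with a warning. FC-RP is reconstructed as the classic
pairwise rank product: for every cross-period sample pair genes are ranked
by absolute expression difference (standardized data carry no meaningful
fold ratio), and a gene's score is the geometric mean of its ranks.
Evaluation restricts the universe to the labeled genes, sweeps the rank
cutoff, and reports TPR/FPR/precision/recall with AUC and AUPR by
trapezoidal integration; on tie-free rankings the trapezoidal AUC equals
the Mann-Whitney pair-counting statistic exactly (cross-checked against
scikit-learn in the tests). Top-k overlap (default k = 500) and the rank
positions of the best-ranked disease genes complete the battery. Ties are
broken by input order everywhere, so all outputs are reproducible.

## Synthetic data

The generator draws a sparse genes x factors loading matrix (nonzero
entries standard normal at density `loading_density`, default 0.02 — about
10 genes per factor regulon in a 500-gene panel), per-sample factor
activities (standard normal; the first `n_shifted_factors` factors gain
mean `effect_size` in period 2), and i.i.d. Gaussian noise. Genes with any
nonzero loading on a shifted factor are labeled 1. This emulates exactly
the structure the model assumes — real-valued standardized expression,
two periods, ~8 samples each, latent factors of which a few shift — and
deliberately nothing else: no count-level (negative-binomial) noise, no
library-size or batch effects, no gene-gene correlation beyond the factor
structure, no real gene names. Passing tests therefore show that the
implementation recovers the planted latent-factor shifts it targets, not
that it handles the full messiness of RNA-seq.

Benchmark scenarios: *easy* (500 genes, 8+8 samples, 20 factors, 3
shifted, effect 2.0, noise sd 0.5; ~6% of genes planted), *null*
(effect 0) and *full-scale* (4,433 genes, for feasibility runs with the
400/20 architecture). Problem sizes were chosen so the full test suite and
the acceptance script run in minutes on one CPU. Under the easy scenario
the t-test reference reaches mean AUC ~0.87: about a quarter of the
planted genes have loadings too small for any 8-vs-8 test to detect
(expected |t| below the t_14 95% quantile), which bounds every method's
recovery on this benchmark.

## Degenerate inputs and numerical choices

Constant genes standardize to zero rows; empty unit selections are allowed
(with a warning) and reduce the gene energy to its quadratic term; a batch
size larger than the sample count, mismatched gene sets/orders, non-binary
states passed to Bernoulli energies, NaN energy changes and out-of-range
selection indices all raise explicit errors. Enumeration oracles refuse
models above 20 total units. All sorts are stable; all randomness flows
from explicit seeds (one master seed fans out to per-stage streams, so
adding a stage never perturbs earlier ones).

## Limitations

The method is evaluated here only on synthetic factor-model data; the
divergence of the Gaussian layer at large learning rates means reported
defaults should not be applied blindly to new data without checking the
energy trace; cross-period unit correspondence in the per-period regime is
heuristic; and the energy-change score has no significance calibration
(no permutation p-values) — it is a ranking, not a test.
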