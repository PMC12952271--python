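# Methods

`cdrgen` generates candidate mutants of an antibody heavy-chain CDR region by
sampling from an energy-based target distribution that trades off predicted
binding affinity, predicted solubility and humanness, then selects a budgeted
candidate set near the empirical Pareto front. This note records the models,
the numerical choices, and what the synthetic validation does and does not
establish.

## Design space

The mutable region is the concatenation of CDRH1, CDRH2 and CDRH3 of the
Ab-14 heavy chain, a 33-residue window
(`GFTLNSYGISIYSDGRRTFYGDSVGRAAGTFDS`). Candidates are restricted to the
Hamming ball of radius `d_lim = 6` around this wild type. Counting variants
as a choice of six positions times any of the 20 letters at each chosen
position, the space holds C(33,6) * 20^6 ~ 7.09e13 sequences — far too many
to enumerate, which motivates sampling. Positions are 0-based internally and
1-based only in rendered reports.

## Objectives

**Affinity.** Affinity is expressed as f_aff = log10(1 nM / Kd), so 1 nM
maps to 0 and stronger binders are positive. A Gaussian process over
sequence embeddings supplies predictions: constant prior mean C, RBF kernel
k(u,v) = delta * exp(-||u-v||^2 / (2 lambda^2)), i.i.d. observation noise
sigma_n^2. The default embedding is the position-major one-hot layout, under
which squared Euclidean distance is exactly twice Hamming distance; external
protein-language-model embeddings can be served from TSV files through the
same encoder contract (no model weights are shipped or executed). The
generation-time score is the acquisition f_aff(x; beta) = mu(x) + beta *
sigma(x): beta > 0 is the optimistic upper confidence bound, beta < 0 the
pessimistic lower bound. The latent (noise-free) sigma is used by default; a
flag switches to the noisy predictive variance.

Hyperparameters (delta, lambda, sigma_n — on the log scale — plus C) are
fitted by gradient ascent on the per-datapoint log marginal likelihood of
the mean-centered targets, with a fixed budget of 600 steps at learning rate
1e-3 and no early stopping. Adam is the default update rule: with generic
initializations, plain gradient ascent at this budget moves the length scale
too little to recover known hyperparameters in simulation, while Adam does;
plain gradient ascent remains available as configuration. Initial values are
data-driven (median pairwise embedding distance for lambda, target variance
for delta, target mean for C). Factorizations use Cholesky with escalating
jitter (0, 1e-8, 1e-6, 1e-4); failure after escalation is an error, never a
silent fallback. The posterior variance is the standard Gaussian conditional
k(z,z) - k(z,X)^T (K + sigma_n^2 I)^-1 k(z,X), which is non-negative and
never exceeds delta.

**Solubility.** f_sol(x) = -sum_j SASA(j, x_j) * HW(x_j) + const. SASA
values are per-residue relative exposures (normalized to Ala-X-Ala maxima)
from a pluggable provider: constant 1.0 (the HW-only ablation), a fixed
per-amino-acid table, or precomputed per-residue vectors loaded from CSV.
The structure-trained SASA predictor that originally fills this role is out
of scope; the provider contract is its interface. The hydrophobicity weight
table is configuration; the shipped default is the Kyte-Doolittle hydropathy
scale, a documented literature placeholder that is *not* the privately
fitted weight set the score was calibrated with — absolute score magnitudes
are therefore configuration-dependent, and only rankings under a fixed table
are meaningful. `const` defaults to 0; it shifts all scores equally and
cancels in Pareto comparisons.

**Humanness.** The prior p_HUM(x) = prod_i p(x_i | x_<i) is an
autoregressive sequence likelihood (natural log throughout; the conventional
screening cutoff ln p >= -120 is inclusive). Transformer repertoire models
are not shipped. The package provides a trainable desk-scale stand-in — a
position-specific categorical prior with additive smoothing (default, since
the design region is fixed-length), plus a k-mer autoregressive mode for
variable-length extensions — and a file-backed adapter serving externally
computed log-likelihoods under the same contract. With a uniform prior the
Boltzmann target reduces to the maximum-entropy form.

## Energy model and samplers

The target is p(x) ∝ p_HUM(x) * exp(-E(x)/T) with E(x) = sum_i w_i f_i(x),
w_i >= 0, sum w_i = 1, and the f_i the negated objectives; the canonical
two-property form is E = -w * f_aff(x; beta) - (1-w) * f_sol(x). The
normalization Z is never computed — samplers use density ratios only.
Property values are memoized by sequence because the GP posterior dominates
cost and MCMC revisits states. The user-facing knob is the inverse
temperature T^-1 (published settings 10-30; the synthetic task uses 10).

**Metropolis-Hastings.** Proposals are uniform over the single-substitution
neighborhood intersected with the d_lim ball. On the ball boundary only
already-mutated positions may change, so the neighborhood shrinks from 19L
to 19*d_lim moves; the acceptance ratio includes the Hastings factor
|N(x)|/|N(x')| by default, which makes the stationary distribution exactly
the Boltzmann target (verified against exhaustive enumeration on a 27-state
toy space, total variation < 0.02). A plain-ratio mode replicates the
uncorrected recipe. Default run shape: 8 chains from the wild type, 20,000
steps each, per-chain RNG streams spawned from the master seed. Burn-in is
the earliest cut on a 5%-grid at which the Gelman-Rubin potential scale
reduction of the per-chain log unnormalized density drops below 1.1; if no
cut converges, chains are extended (default by another run length) and the
scan repeats. When convergence is still not reached the driver pools the
second halves of the chains and reports `converged: false` rather than
returning nothing. All-constant identical traces report exactly 1.0 with a
degenerate-trace warning.

**GFlowNet.** An amortized alternative: an autoregressive policy trained so
its sampling probability becomes proportional to the reward R(x) =
p_HUM(x) * exp(-E(x)/T). The loss is trajectory balance,
(log Z_theta + log P_F(x) - log R(x))^2, with a learned scalar log Z_theta
whose learning rate is 10x the policy's (1e-2 vs 1e-3 by default), 8,000
SGD steps with both rates halved at 4,000, mixed batches of 16 fresh and 16
replayed sequences, and a FIFO replay buffer of capacity 20,000 seeded with
the training library. Gradients are clipped to global norm 10 — the squared
residual is unbounded early in training. The policy is a single-hidden-layer
tanh MLP over the one-hot prefix, the position index and the running
mutation count, with analytic gradients; layer sizes are configuration. The
mutation budget is enforced by hard masking (once the prefix carries d_lim
mutations, only the wild-type letter is allowed), which guarantees zero mass
outside the ball — stricter than letting the network learn the constraint
from its distance feature. Convergence is monitored by the Spearman rank
correlation between held-out log rewards and policy log-probabilities; on an
enumerable toy target the trained policy reaches total variation < 0.1
against exact enumeration, agreeing with the MCMC sampler.

## Synthetic epistatic landscape

Ground truth for validation is f_aff(x) = f_wt + sum_i h_i(x_i) +
sum_{i<j} J_ij(x_i, x_j) with h and J zero at wild-type letters.
"Simple" mode draws fields from N(-0.5, 0.5) and couplings from N(0, 0.5);
"hard" mode draws fields from N(0, 0.5) and couplings from N(-0.5, 0.5), so
deleterious effects come mainly from pairwise interactions that single
mutants cannot reveal. f_wt defaults to 0 (only differences matter for
ranking). Tables are materialized densely (3.5 MB at L=33). The training
table emulates a saturation-plus-random library: all 660 enumerated
(position, letter) single records — including the 33 identity substitutions,
kept as wild-type-affinity rows so the printed count is 33*20 — plus 2,100
distinct random doubles and 11,900 distinct random triples, 14,660 rows
total, each observed with N(0,1) noise. Negative examples are fully
scrambled CDRs assigned the affinity implied by Ka = 1e7 /M (Kd = 100 nM,
f_aff = -2).

What this emulates: the composition and noise scale of a real deep
mutational scan around a single lead. What it does not: measurement
censoring, batch effects, higher-order epistasis, or any structural
realism. Passing the synthetic benchmark shows the machinery optimizes what
its predictive models believe; it says nothing about how well those models
would predict real binding or chromatography data.

## Selection and evaluation

Candidates are scored as (acquisition, predicted solubility) points, both
maximized. The Pareto front is the maximal non-dominated subset; the
distance of a point to the front is the minimum variance-normalized
Euclidean distance to a front member, with variances computed over the full
generated pool before any filtering (this makes the distance invariant to
separate affine rescaling of either objective). The square root is taken so
distances carry the units of normalized objective space; the squared form is
available by flag. Top-B selection keeps the B smallest distances with
lexicographic sequence tie-breaking. The acquisition coordinate (not the
posterior mean) enters both the front and the distance, matching the
generation-time energy.

The threshold-count protocol mimics a budgeted wet-lab round: filter by
predicted solubility strictly above f_sol_min (-inf disables the filter;
4.0 is the published contrast setting), rank by acquisition, keep the top
B = 500, evaluate ground truth on the survivors and count those above each
affinity threshold. Shortfalls (< B survivors) are flagged, not fatal.

Auxiliary developability metrics: the charge score (+1 for R/K, +0.1 for H,
-1 for D/E; acceptable band [-2, 2] — the wild type scores exactly 0 with
its 3 R and 3 D) and the dipeptide-weight instability index
(10/L * sum of published dipeptide weights over consecutive pairs; the
conventional reading — scores above 40 suggest instability — is adopted,
and the default weight table is taken from Biopython's published DIWV data
with a CSV override). Set-level metrics are the mean within-set pairwise
Hamming distance (diversity; at most 12 when all members sit within 6
mutations of a common reference), the mean minimum distance to the training
set (novelty), and |A∩B| / min(|A|,|B|) for the overlap of two candidate
sets — chosen because it reduces to the reported convention when the sets
have equal size.

## Baselines

The comparison generator is constrained hill-climbing: independent runs from
the wild type (published shape: 800 runs x 200 steps), each step taking the
best strict improvement of the acquisition over a sampled subset of the
single-substitution neighborhood, rejecting any proposal that violates a
hard constraint (Hamming ball; ln p_HUM >= -120; optional solubility floor).
Equal-value moves are rejected to prevent cycles. The negative control
scatters k = 3 substitutions at previously unmutated positions of the best
training variant, letters uniform over the 19 alternatives.

## Problem sizes used in the shipped tests

The test suite and benchmark runs use scaled-down study conditions chosen to
keep the full validation loop at desk scale: toy enumerable spaces (27-256
states) for exactness checks; GP training subsets of ~1,000 records drawn
from the 30% split of the full 14,660-row synthetic table; 4-6 MCMC chains
of 2,500-4,000 steps; and GFlowNet training at the published 8,000-step
schedule on a 256-state space. These sizes are the package's own defaults
for its validation suite; the full published run shapes (8 x 20,000 MCMC
steps, 800 x 200 local-search runs) remain the library defaults for real
use.

## Known limitations

- The shipped hydrophobicity table is a literature stand-in; absolute
  solubility scores are not comparable to those computed with the original
  privately fitted weights.
- The humanness stand-in is a smoothed categorical model, not a repertoire
  transformer; its log-likelihood scale differs from a transformer's, so
  thresholds such as -120 should be re-derived when the stand-in is used.
- The GFlowNet policy is a small MLP; the masked-convolution architecture
  the published dimensions describe (4 blocks, kernel 17, H = 16) is not
  implemented, and on hard multi-modal targets the MLP policy may need
  hyperparameter tuning to match MCMC.
- GP cost is cubic in training-set size at fit time and quadratic at
  prediction; the package subsamples rather than approximating (no inducing
  points).
- Only two objectives are scalarized in the shipped workflows; the sweep
  machinery generalizes, but front coverage in higher dimensions is untested.
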