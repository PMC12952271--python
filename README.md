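# cdrgen

Energy-based generative optimization of antibody CDR sequences.

`cdrgen` is for antibody engineers and method developers doing **lead
optimization**: you have a functional heavy-chain antibody, a mutagenesis
library with measured affinities around it, and a budget of B sequences you
can validate in the lab. The package generates candidate mutants of the
concatenated CDRH1/H2/H3 window (at most `d_lim` mutations from the wild
type) that jointly trade off predicted affinity, predicted solubility and
humanness, and hands back the B candidates closest to the empirical Pareto
front.

## The model

Candidates are sampled from a Boltzmann distribution over sequence space,

    p(x) ∝ p_HUM(x) · exp(−E(x)/T),
    E(x) = −w·f̂_aff(x; β) − (1−w)·f̂_sol(x),

where

- **f̂_aff(x; β) = μ(x) + β·σ(x)** is a Gaussian-process acquisition:
  an exact GP with RBF kernel `k(u,v) = δ·exp(−‖u−v‖²/2λ²)` over sequence
  embeddings (one-hot by default), fitted by marginal likelihood, with
  β > 0 the optimistic UCB and β < 0 the pessimistic LCB. Affinities are on
  the scale f_aff = log10(1 nM / Kd).
- **f̂_sol(x) = −Σ_j SASA(j, x_j)·HW(x_j) + const** scores solubility as
  hydrophobicity-weighted residue exposure (pluggable SASA providers,
  configurable weight table).
- **p_HUM** is an autoregressive humanness prior (trainable categorical
  stand-in, or external log-likelihoods via a file adapter).
- **T** balances optimality against diversity; **w** sweeps the
  affinity/solubility trade-off to trace the Pareto front.

Two samplers target the same distribution: Metropolis–Hastings over the
constrained mutation neighborhood (with multi-chain Gelman–Rubin burn-in
selection and an exactness-preserving boundary correction) and an amortized
GFlowNet-style policy trained with trajectory balance. A fully synthetic
epistatic landscape — pairwise fields-and-couplings ground truth plus a
14,660-variant noisy training library — validates the whole loop end to end.
See `docs/methods.md` for the complete account.

## Worked example

Generate candidates on a simple-mode synthetic landscape (w = 0.85,
β = 0, T⁻¹ = 10, four chains of 2,500 steps):

```python
import numpy as np
from cdrgen import (
    AB14_CDR_WT, WildType, LandscapeSpec, sample_landscape, build_dataset,
    split_dataset, fit_gp_on_sequences, affinity_solubility_energy,
    MCMCConfig, sample_posterior_sequences, CandidateSet,
)
from cdrgen.solubility import make_solubility_fn

wt = WildType(AB14_CDR_WT)
ls = sample_landscape(LandscapeSpec.simple(), wt, seed=11)
data = build_dataset(ls, seed=12)                    # 14,660 noisy records
train, _ = split_dataset(data, [0.3, 0.7], seed=13)
train = train.head(800)

model, enc = fit_gp_on_sequences(train["sequence"], train["observed_faff"], steps=150)
aff = lambda s: float(model.acquisition(enc.encode_many([s]), 0.0)[0])
sol = make_solubility_fn()
target = affinity_solubility_energy(aff, sol, w=0.85, inv_temperature=10.0)

cfg = MCMCConfig(n_chains=4, n_steps=2500, d_lim=6, seed=14,
                 extension_steps=2500, max_extensions=1)
pooled, report = sample_posterior_sequences(cfg, target, wt)
uniq = sorted(set(pooled))
cs = CandidateSet.from_arrays(uniq, [aff(s) for s in uniq], [sol(s) for s in uniq])
print(cs.select_top(3))
```

Output from this exact run:

```
kernel: KernelParams(delta=2.84, lam=2.76, sigma_n=0.54, C=-1.50)
n unique: 616   front size: 10
diversity: 7.75   novelty vs training set: 5.34
GFTKNSYGRSEYSDGRRTFYGDNQGRAAGTFDN  muts 6  acq 1.42  sol 48.70
GFTKNSYGRSHYSDGRRTFYGDNQGRAAGTFDN  muts 6  acq 1.45  sol 48.40
GFTKNSYGRSRYSDGRRTFYGDNQGRAAGTFDN  muts 6  acq 1.27  sol 49.70
```

Reading it: the fitted kernel found a length scale of ~2.8 in one-hot space
(≈ 4 mutations of correlation, since one-hot squared distance is twice
Hamming) and a noise level near the σ = 1 injected into the observations
(after the δ/σ_n split). The sampler visited 616 distinct candidates whose
mean pairwise Hamming distance is 7.75 (maximum possible 12 inside the
6-mutation ball) and which sit on average 5.3 mutations from anything in
the training library. The top candidates carry the full 6-mutation budget,
an acquisition ≈ 1.4 (predicted Kd ≈ 0.04 nM on the f_aff scale), and high
solubility scores — absolute solubility magnitudes depend on the configured
hydrophobicity table, so compare them only within a run. At this
solubility-leaning weight the sampler spends mutations on hydrophilic
substitutions (E, N, Q at variable sites), the expected trade-off.

A command-line interface wraps the same machinery:

```sh
cdrgen count-space -L 33 -d 6        # 70884352000000 (7.088e+13)
cdrgen sweep                         # the 20 (w, β) run conditions
cdrgen run --config cfg.yaml --out rundir --seed 1
```

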