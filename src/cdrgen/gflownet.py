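"""Amortized sampler: autoregressive policy trained with trajectory balance.

A small autoregressive network builds sequences left to right and is trained
so that its sampling probability becomes proportional to the Boltzmann
reward R(x) = p_HUM(x) * exp(-E(x)/T). The concrete objective is trajectory
balance with a learned log-partition parameter:

    L(x) = (log Z_theta + log P_F(x) - log R(x))^2,

averaged over a mixed batch of freshly sampled sequences and replayed
(sequence, reward) records from a FIFO buffer. At the fixed point the policy
samples exactly proportionally to the reward, matching the target the MCMC
module samples by accept/reject.

The mutation budget is enforced by hard masking: while generating position
i, if the prefix already carries d_lim mutations relative to the wild-type
prefix, only the wild-type letter is allowed, so no sampled sequence can
leave the d_lim ball. The policy network here is a small MLP over the
one-hot prefix plus the position index and running mutation count, with
analytic gradients; layer sizes are configuration.

Because training is a convergence-free stochastic optimization, the module
carries the rank-correlation diagnostic: the Spearman correlation between
held-out log rewards and the policy's log-probabilities, which approaches 1
as the policy becomes proportional to the reward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .ebm import EnergyModel
from .seqspace import SearchConstraints, WildType

_A = 20  # alphabet size for the default amino-acid policy


@dataclass(frozen=True)
class PolicyConfig:
    hidden_dim: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim <= 0:
            raise ValueError("hidden_dim must be positive")


@dataclass(frozen=True)
class TrainConfig:
    steps: int = 8_000
    batch_new: int = 16
    batch_replay: int = 16
    lr: float = 1e-3
    lr_logZ: float = 1e-2
    lr_halving_step: int = 4_000
    grad_clip: float = 10.0
    buffer_capacity: int = 20_000
    spearman_every: int = 500
    seed: int = 0


class ReplayBuffer:
    """FIFO store of (sequence, log_reward) pairs with bounded capacity."""

    def __init__(self, capacity: int = 20_000):
        if capacity <= 0:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self.seqs: list[str] = []
        self.log_rewards: list[float] = []

    def __len__(self) -> int:
        return len(self.seqs)

    def add(self, seq: str, log_reward: float) -> None:
        self.seqs.append(seq)
        self.log_rewards.append(float(log_reward))
        if len(self.seqs) > self.capacity:
            drop = len(self.seqs) - self.capacity
            del self.seqs[:drop]
            del self.log_rewards[:drop]

    def sample(self, n: int, rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
        idx = rng.integers(0, len(self.seqs), size=min(n, len(self.seqs)))
        return [self.seqs[i] for i in idx], np.array(
            [self.log_rewards[i] for i in idx]
        )


class AutoregressivePolicy:
    """Masked autoregressive MLP policy over a fixed-length alphabet space.

    Feature vector at step i: flattened one-hot of the generated prefix
    (zero-padded to L), a one-hot of the position i, and the running
    mutation count n scaled by d_lim. Logits for the 20 letters come from a
    single-hidden-layer tanh MLP; positions where n == d_lim are masked to
    the wild-type letter.
    """

    def __init__(
        self,
        wt: WildType,
        constraints: SearchConstraints,
        cfg: PolicyConfig = PolicyConfig(),
    ):
        self.wt = wt
        self.constraints = constraints
        self.alphabet = constraints.alphabet
        self.aa_index = {a: i for i, a in enumerate(self.alphabet)}
        self.L = len(wt)
        self.A = len(self.alphabet)
        self.in_dim = self.L * self.A + self.L + 1
        H = cfg.hidden_dim
        rng = np.random.default_rng(cfg.seed)
        self.W1 = rng.normal(0, 1 / math.sqrt(self.in_dim), (H, self.in_dim))
        self.b1 = np.zeros(H)
        # zero output layer: the untrained policy is exactly uniform (masked)
        self.W2 = np.zeros((self.A, H))
        self.b2 = np.zeros(self.A)
        self.logZ = 0.0

    # -- forward machinery -------------------------------------------------

    def _features(self, prefix_idx: list[int], i: int, n: int) -> np.ndarray:
        x = np.zeros(self.in_dim)
        for j, a in enumerate(prefix_idx):
            x[j * self.A + a] = 1.0
        x[self.L * self.A + i] = 1.0
        x[-1] = n / max(self.constraints.d_lim, 1)
        return x

    def _mask(self, i: int, n: int) -> np.ndarray:
        if n >= self.constraints.d_lim:
            allowed = np.zeros(self.A, dtype=bool)
            allowed[self.aa_index[self.wt.sequence[i]]] = True
            return allowed
        return np.ones(self.A, dtype=bool)

    def _step_logprobs(self, prefix_idx: list[int], i: int, n: int):
        x = self._features(prefix_idx, i, n)
        h = np.tanh(self.W1 @ x + self.b1)
        logits = self.W2 @ h + self.b2
        allowed = self._mask(i, n)
        masked = np.where(allowed, logits, -np.inf)
        masked = masked - masked.max()
        logp = masked - math.log(np.exp(masked).sum())
        return logp, (x, h, allowed)

    # -- public API --------------------------------------------------------

    def sample(self, n_seqs: int, rng: np.random.Generator):
        """Sample sequences left-to-right; returns (sequences, log_probs)."""
        seqs, logps = [], []
        for _ in range(n_seqs):
            prefix: list[int] = []
            n_mut = 0
            total = 0.0
            for i in range(self.L):
                logp, _ = self._step_logprobs(prefix, i, n_mut)
                a = int(rng.choice(self.A, p=np.exp(logp)))
                total += logp[a]
                prefix.append(a)
                if self.alphabet[a] != self.wt.sequence[i]:
                    n_mut += 1
            seqs.append("".join(self.alphabet[a] for a in prefix))
            logps.append(total)
        return seqs, np.array(logps)

    def log_prob(self, seq: str) -> float:
        """Policy log-probability of generating ``seq`` (chain rule)."""
        if len(seq) != self.L:
            raise ValueError("sequence length differs from policy length")
        total = 0.0
        prefix: list[int] = []
        n_mut = 0
        for i, letter in enumerate(seq):
            a = self.aa_index[letter]
            logp, _ = self._step_logprobs(prefix, i, n_mut)
            total += logp[a]
            prefix.append(a)
            if letter != self.wt.sequence[i]:
                n_mut += 1
        return float(total)

    def per_token_log_probs(self, seq: str) -> np.ndarray:
        out = np.empty(self.L)
        prefix: list[int] = []
        n_mut = 0
        for i, letter in enumerate(seq):
            a = self.aa_index[letter]
            logp, _ = self._step_logprobs(prefix, i, n_mut)
            out[i] = logp[a]
            prefix.append(a)
            if letter != self.wt.sequence[i]:
                n_mut += 1
        return out

    # -- gradients ---------------------------------------------------------

    def _logprob_with_grads(self, seq: str):
        """log P_F(seq) and its gradient wrt (W1, b1, W2, b2)."""
        gW1 = np.zeros_like(self.W1)
        gb1 = np.zeros_like(self.b1)
        gW2 = np.zeros_like(self.W2)
        gb2 = np.zeros_like(self.b2)
        total = 0.0
        prefix: list[int] = []
        n_mut = 0
        for i, letter in enumerate(seq):
            a = self.aa_index[letter]
            logp, (x, h, allowed) = self._step_logprobs(prefix, i, n_mut)
            total += logp[a]
            p = np.exp(logp)
            dlogits = -p
            dlogits[a] += 1.0
            dlogits[~allowed] = 0.0
            gW2 += np.outer(dlogits, h)
            gb2 += dlogits
            dh = self.W2.T @ dlogits
            dz = dh * (1.0 - h * h)
            gW1 += np.outer(dz, x)
            gb1 += dz
            prefix.append(a)
            if letter != self.wt.sequence[i]:
                n_mut += 1
        return total, (gW1, gb1, gW2, gb2)


def tb_loss(
    batch: list[tuple[str, float]], policy: AutoregressivePolicy, logZ: float
) -> float:
    """Trajectory-balance loss, mean over a (sequence, reward) batch."""
    resids = []
    for seq, reward in batch:
        if reward <= 0:
            raise ValueError(f"non-positive reward {reward!r} for {seq!r}")
        resids.append(logZ + policy.log_prob(seq) - math.log(reward))
    return float(np.mean(np.square(resids)))


def _tb_update(
    policy: AutoregressivePolicy,
    seqs: list[str],
    log_rewards: np.ndarray,
    lr: float,
    lr_logZ: float,
    grad_clip: float = 10.0,
) -> float:
    """One SGD step on the TB loss (log-reward form); returns the batch loss.

    Gradients are clipped to a global norm of ``grad_clip`` — the squared
    residual makes raw gradients unbounded early in training.
    """
    n = len(seqs)
    gW1 = np.zeros_like(policy.W1)
    gb1 = np.zeros_like(policy.b1)
    gW2 = np.zeros_like(policy.W2)
    gb2 = np.zeros_like(policy.b2)
    g_logZ = 0.0
    loss = 0.0
    for seq, logR in zip(seqs, log_rewards):
        logp, grads = policy._logprob_with_grads(seq)
        r = policy.logZ + logp - logR
        loss += r * r
        scale = 2.0 * r / n
        gW1 += scale * grads[0]
        gb1 += scale * grads[1]
        gW2 += scale * grads[2]
        gb2 += scale * grads[3]
        g_logZ += scale
    norm = math.sqrt(
        float(np.sum(gW1**2) + np.sum(gb1**2) + np.sum(gW2**2) + np.sum(gb2**2))
    )
    if norm > grad_clip:
        shrink = grad_clip / norm
        gW1 *= shrink
        gb1 *= shrink
        gW2 *= shrink
        gb2 *= shrink
    g_logZ = float(np.clip(g_logZ, -grad_clip, grad_clip))
    policy.W1 -= lr * gW1
    policy.b1 -= lr * gb1
    policy.W2 -= lr * gW2
    policy.b2 -= lr * gb2
    policy.logZ -= lr_logZ * g_logZ
    return loss / n


def convergence_spearman(
    policy: AutoregressivePolicy, heldout_seqs: list[str], heldout_log_rewards
) -> float | None:
    """Spearman rank correlation of held-out log rewards vs policy log-probs.

    Returns None when either input is constant (correlation undefined).
    """
    logps = [policy.log_prob(s) for s in heldout_seqs]
    if len(set(logps)) < 2 or len(set(np.round(heldout_log_rewards, 12))) < 2:
        return None
    rho = spearmanr(heldout_log_rewards, logps).statistic
    return None if np.isnan(rho) else float(rho)


@dataclass
class TrainResult:
    policy: AutoregressivePolicy
    losses: list[float] = field(default_factory=list)
    spearman_trace: list[tuple[int, float | None]] = field(default_factory=list)
    buffer: ReplayBuffer | None = None


def train_gflownet(
    cfg: TrainConfig,
    target: EnergyModel,
    init_data: list[str],
    wt: WildType,
    constraints: SearchConstraints | None = None,
    policy_cfg: PolicyConfig | None = None,
    heldout: list[str] | None = None,
) -> TrainResult:
    """Train the policy toward the Boltzmann target of ``target``.

    The replay buffer is seeded with ``init_data`` (the training library).
    Each step samples ``batch_new`` sequences from the policy, scores their
    log rewards under the target, mixes in ``batch_replay`` replayed
    records, takes one SGD trajectory-balance step, then inserts the new
    sequences. The learning rates are halved once at ``lr_halving_step``.
    ``heldout`` sequences (disjoint from the buffer seed) drive the periodic
    Spearman convergence diagnostic.
    """
    if not init_data:
        raise ValueError("init_data must be non-empty to seed the replay buffer")
    constraints = constraints or SearchConstraints()
    policy = AutoregressivePolicy(wt, constraints, policy_cfg or PolicyConfig(seed=cfg.seed))
    buffer = ReplayBuffer(cfg.buffer_capacity)
    for seq in init_data:
        buffer.add(seq, target.log_unnorm_density(seq))
    heldout_logR = (
        np.array([target.log_unnorm_density(s) for s in heldout]) if heldout else None
    )
    rng = np.random.default_rng(cfg.seed)
    result = TrainResult(policy=policy, buffer=buffer)
    for step in range(1, cfg.steps + 1):
        halve = 0.5 if step > cfg.lr_halving_step else 1.0
        new_seqs, _ = policy.sample(cfg.batch_new, rng)
        new_logR = np.array([target.log_unnorm_density(s) for s in new_seqs])
        rep_seqs, rep_logR = buffer.sample(cfg.batch_replay, rng)
        seqs = new_seqs + rep_seqs
        logR = np.concatenate([new_logR, rep_logR])
        loss = _tb_update(
            policy, seqs, logR, cfg.lr * halve, cfg.lr_logZ * halve, cfg.grad_clip
        )
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite trajectory-balance loss at step {step}; batch {seqs!r}"
            )
        result.losses.append(loss)
        for seq, lr_ in zip(new_seqs, new_logR):
            buffer.add(seq, lr_)
        if heldout is not None and step % cfg.spearman_every == 0:
            result.spearman_trace.append(
                (step, convergence_spearman(policy, heldout, heldout_logR))
            )
    return result
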