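"""Recurrent augmentation-policy controller trained by policy gradients.

The controller is a single-layer LSTM (100 hidden units) that emits an
augmentation strategy as a sequence of 30 categorical decisions: for each
of 5 sub-strategies x 2 operations it predicts, in order, an operation
type (16-way), a magnitude level (10-way) and a probability level
(11-way).  Each step's sampled token is embedded (together with a
step-type embedding, so the three vocabularies do not collide) and fed
back as the next input.  Prediction heads are two fully connected layers
per vocabulary, softmax outputs.

Updates use the PPO clipped-surrogate objective on the joint 30-step
log-probability with an entropy bonus, advantages taken against an
exponential-moving-average reward baseline.  A plain REINFORCE mode (one
epoch, no clipping) is kept as the analytically checkable limit.  The
reward for a sampled strategy is the negative validation loss of the child
segmentation model trained under it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .augment.ops import (NUM_MAGNITUDE_LEVELS, NUM_OPS,
                          NUM_PROBABILITY_LEVELS, OP_NAMES)
from .augment.strategy import OpInstance, Strategy, SubStrategy

__all__ = ["ControllerConfig", "Controller", "StrategySample",
           "sample_strategy", "update_policy", "reward_from_validation"]

_STEP_KINDS = ("op", "magnitude", "probability")
_VOCABS = {"op": NUM_OPS, "magnitude": NUM_MAGNITUDE_LEVELS,
           "probability": NUM_PROBABILITY_LEVELS}


@dataclass(frozen=True)
class ControllerConfig:
    hidden_units: int = 100
    num_substrategies: int = 5
    ops_per_substrategy: int = 2
    embed_dim: int = 16
    learning_rate: float = 4e-4
    entropy_weight: float = 1e-5
    init_range: float = 0.1
    ppo_clip: float = 0.2
    ppo_epochs: int = 3
    baseline_decay: float = 0.95
    normalize_advantages: bool = True
    algorithm: str = "ppo"  # "ppo" | "reinforce"

    @property
    def num_decisions(self) -> int:
        return self.num_substrategies * self.ops_per_substrategy * len(_STEP_KINDS)

    @staticmethod
    def desk() -> "ControllerConfig":
        """Preset for short searches: the learning rate is scaled up by the
        horizon ratio (~1000/30) so a 30-iteration search makes comparable
        total policy movement to the full-scale run."""
        return ControllerConfig(learning_rate=1e-2)


@dataclass
class StrategySample:
    strategy: Strategy
    decisions: np.ndarray          # int vector, one entry per step
    log_prob: float                # joint log-probability at sampling time
    step_log_probs: np.ndarray = field(default=None)


class _Head(nn.Module):
    """Two fully connected prediction layers for one vocabulary."""

    def __init__(self, hidden: int, vocab: int, rng, init_range: float):
        super().__init__()
        self.fc1 = nn.Linear(hidden, hidden, rng, init_range=init_range)
        self.fc2 = nn.Linear(hidden, vocab, rng, init_range=init_range)

    def forward(self, h: Tensor) -> Tensor:
        return self.fc2(self.fc1(h).tanh())


class Controller(nn.Module):
    def __init__(self, config: ControllerConfig, seed: int):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        ir = config.init_range
        self.token_embed = {k: nn.Embedding(v, config.embed_dim, rng, init_range=ir)
                            for k, v in _VOCABS.items()}
        self._embeds = nn.ModuleList(list(self.token_embed.values()))
        self.kind_embed = nn.Embedding(len(_STEP_KINDS), config.embed_dim, rng,
                                       init_range=ir)
        self.start = Tensor(rng.uniform(-ir, ir, (1, config.embed_dim)),
                            requires_grad=True)
        self.cell = nn.LSTMCell(config.embed_dim, config.hidden_units, rng,
                                init_range=ir)
        self.heads = {k: _Head(config.hidden_units, v, rng, ir)
                      for k, v in _VOCABS.items()}
        self._heads = nn.ModuleList(list(self.heads.values()))
        # moving-average reward baseline (not a learned parameter)
        self.baseline = 0.0
        self.baseline_initialized = False

    def step_kind(self, t: int) -> str:
        return _STEP_KINDS[t % len(_STEP_KINDS)]

    def _rollout(self, decisions: np.ndarray | None, rng=None):
        """Run the LSTM over all steps.

        With ``decisions`` given, evaluates their log-probabilities (graph
        mode, for updates).  With ``rng`` given, samples new decisions.
        Returns (decisions, per-step log-prob Tensors, per-step entropies).
        """
        cfg = self.config
        n = cfg.num_decisions
        h = Tensor(np.zeros((1, cfg.hidden_units)))
        c = Tensor(np.zeros((1, cfg.hidden_units)))
        inp = self.start
        out_decisions = np.zeros(n, dtype=np.int64)
        logps, entropies = [], []
        for t in range(n):
            kind = self.step_kind(t)
            h, c = self.cell(inp, (h, c))
            logits = self.heads[kind](h)
            logp = logits.log_softmax(axis=1)
            probs = np.exp(logp.data[0])
            if decisions is None:
                a = int(rng.choice(len(probs), p=probs / probs.sum()))
            else:
                a = int(decisions[t])
            out_decisions[t] = a
            logps.append(logp[0, a])
            entropies.append(-(logp.exp() * logp).sum())
            inp = (self.token_embed[kind](np.array([a]))
                   + self.kind_embed(np.array([_STEP_KINDS.index(kind)])))
        return out_decisions, logps, entropies

    def decode(self, decisions: np.ndarray) -> Strategy:
        """Turn the flat decision vector into a Strategy."""
        cfg = self.config
        per_op = len(_STEP_KINDS)
        ops = []
        for i in range(cfg.num_substrategies * cfg.ops_per_substrategy):
            op_idx, mag, prob = decisions[i * per_op:(i + 1) * per_op]
            ops.append(OpInstance(OP_NAMES[int(op_idx)], int(mag), int(prob)))
        subs = [SubStrategy(ops[2 * i], ops[2 * i + 1])
                for i in range(cfg.num_substrategies)]
        return Strategy(subs)

    def log_prob_and_entropy(self, decisions: np.ndarray):
        """Joint log-prob and mean step entropy of given decisions, as graph
        nodes for the policy update."""
        logps, entropies = self.step_log_probs_and_entropies(decisions)
        joint = logps[0]
        for lp in logps[1:]:
            joint = joint + lp
        ent = entropies[0]
        for e in entropies[1:]:
            ent = ent + e
        return joint, ent * (1.0 / len(entropies))

    def step_log_probs_and_entropies(self, decisions: np.ndarray):
        _, logps, entropies = self._rollout(decisions)
        return logps, entropies


def sample_strategy(controller: Controller, rng: np.random.Generator
                    ) -> StrategySample:
    """Autoregressively sample a 5-sub-strategy augmentation strategy."""
    decisions, logps, _ = controller._rollout(None, rng=rng)
    step_logps = np.array([lp.item() for lp in logps])
    return StrategySample(strategy=controller.decode(decisions),
                          decisions=decisions,
                          log_prob=float(step_logps.sum()),
                          step_log_probs=step_logps)


def reward_from_validation(loss: float) -> float:
    """Reward of a strategy is the negative child validation loss."""
    loss = float(loss)
    if not math.isfinite(loss):
        raise ValueError("validation loss must be finite")
    return -loss


def update_policy(controller: Controller,
                  batch: list[tuple[StrategySample, float]],
                  optimizer: nn.Adam | None = None) -> dict:
    """One policy update from (sample, reward) pairs; returns diagnostics."""
    if not batch:
        raise ValueError("empty update batch")
    rewards = np.array([r for _, r in batch], dtype=np.float64)
    if not np.isfinite(rewards).all():
        raise ValueError("non-finite reward in update batch")
    cfg = controller.config
    if optimizer is None:
        optimizer = controller_optimizer(controller)

    if not controller.baseline_initialized:
        controller.baseline = float(rewards.mean())
        controller.baseline_initialized = True
    advantages = rewards - controller.baseline
    controller.baseline = (cfg.baseline_decay * controller.baseline
                           + (1 - cfg.baseline_decay) * float(rewards.mean()))
    if cfg.normalize_advantages and len(batch) > 1:
        spread = advantages.std()
        if spread > 1e-8:
            advantages = (advantages - advantages.mean()) / spread

    n_epochs = 1 if cfg.algorithm == "reinforce" else cfg.ppo_epochs
    clip_count = 0
    total_terms = 0
    last_entropy = 0.0
    lo, hi = 1 - cfg.ppo_clip, 1 + cfg.ppo_clip
    for _ in range(n_epochs):
        controller.zero_grad()
        loss = None
        for (sample, _), adv in zip(batch, advantages):
            adv = float(adv)
            if cfg.algorithm == "reinforce":
                logp, ent = controller.log_prob_and_entropy(sample.decisions)
                term = logp * adv
            else:
                # PPO-clip with per-step probability ratios (the joint ratio
                # over 30 decisions saturates the clip range immediately)
                logps, entropies = controller.step_log_probs_and_entropies(
                    sample.decisions)
                term = None
                for t, lp in enumerate(logps):
                    ratio = (lp - float(sample.step_log_probs[t])).exp()
                    r = float(ratio.item())
                    total_terms += 1
                    if r * adv > min(max(r, lo), hi) * adv:
                        # clipped branch is active: constant, no gradient
                        clip_count += 1
                        piece = Tensor(np.array(min(max(r, lo), hi) * adv))
                    else:
                        piece = ratio * adv
                    term = piece if term is None else term + piece
                term = term * (1.0 / len(logps))
                ent = entropies[0]
                for e in entropies[1:]:
                    ent = ent + e
                ent = ent * (1.0 / len(entropies))
            obj = term + ent * cfg.entropy_weight
            loss = obj if loss is None else loss + obj
            last_entropy = ent.item()
        (loss * (-1.0 / len(batch))).backward()
        optimizer.step()

    return {
        "mean_advantage": float(advantages.mean()),
        "clip_fraction": clip_count / max(total_terms, 1),
        "entropy": last_entropy,
        "baseline": controller.baseline,
    }


def controller_optimizer(controller: Controller) -> nn.Adam:
    opt = getattr(controller, "_optimizer", None)
    if opt is None:
        opt = nn.Adam(controller.parameters(), lr=controller.config.learning_rate)
        controller._optimizer = opt
    return opt
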