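"""Reinforcement-learning loop with evolutionary sampling.

Three generators with shared architecture take part: the *agent* (being
trained), the *crover* (a frozen-between-syncs copy providing crossover
material) and the *prior* (the pretrained model, never updated,
providing mutation material). At every generation step a mutation draw
below the mutation threshold hands the step distribution to the prior;
otherwise a crossover draw above the crossover threshold hands it to
the crover, else the agent. All three models consume the chosen token
so their hidden states stay aligned.

Each cycle: sample a batch -> score it against the objectives -> map to
final rewards via the weighted or Pareto scheme -> roulette-select the
top fraction -> REINFORCE update of the agent. The best-mean-reward
checkpoint is kept, and the agent and crover re-synchronize to it at a
fixed interval.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from rdkit import Chem

from .generator import SampleBatch, SmilesGenerator, clone_generator
from .moo import (ObjectiveSpec, morgan_fingerprints, pareto_scheme,
                  score_molecules, weighted_reward)

logger = logging.getLogger(__name__)


@dataclass
class EvolutionConfig:
    """Knobs of the evolutionary sampling and RL loop."""

    crossover_threshold: float = 0.5
    mutation_threshold: float = 0.01
    crover_sync_interval: int = 250
    selection_fraction: float = 0.2
    epochs: int = 1000
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossover_threshold <= 1.0:
            raise ValueError("crossover_threshold must be in [0, 1]")
        if not 0.0 <= self.mutation_threshold <= 1.0:
            raise ValueError("mutation_threshold must be in [0, 1]")
        if not 0.0 < self.selection_fraction <= 1.0:
            raise ValueError("selection_fraction must be in (0, 1]")


@dataclass
class EpochMetrics:
    """Per-cycle batch quality ratios, each in [0, 1]."""

    validity: float
    desirability: float
    uniqueness: float
    mean_reward: float


def evolutionary_sample(agent: SmilesGenerator,
                        crover: SmilesGenerator | None,
                        prior: SmilesGenerator | None,
                        n: int,
                        config: EvolutionConfig,
                        rng: np.random.Generator | None = None
                        ) -> SampleBatch:
    """Sample n sequences mixing agent, crover and prior step distributions.

    Per sequence and step: a mutation draw u < mutation_threshold takes
    the token distribution from the prior; otherwise a crossover draw
    theta > crossover_threshold takes it from the crover, else from the
    agent. The agent's log-probabilities of the chosen tokens are
    recorded for the policy update. With crover/prior set to None (or
    thresholds at their limits) this degrades gracefully to plain agent
    sampling.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    models = [agent]
    for other in (crover, prior):
        if other is not None:
            if other.vocab.tokens != agent.vocab.tokens:
                raise ValueError("all models must share one vocabulary")
            models.append(other)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    go, eos = agent.vocab.go_index, agent.vocab.eos_index
    states = [m.init_state(n) for m in models]
    tokens = np.full(n, go, dtype=np.int64)
    finished = np.zeros(n, dtype=bool)
    sequences: list[list[int]] = [[] for _ in range(n)]
    log_probs = np.zeros(n)
    for _ in range(agent.config.max_len):
        probs_list = []
        new_states = []
        for m, st in zip(models, states):
            p, st2 = m.step(tokens, st)
            probs_list.append(p)
            new_states.append(st2)
        states = new_states
        agent_probs = probs_list[0]
        # choose the source distribution per sequence; the mutation and
        # crossover variables are drawn unconditionally so the sampling
        # path is rng-identical across threshold limit cases
        probs = agent_probs.copy()
        mut = rng.random(n)
        theta = rng.random(n)
        use_prior = (mut < config.mutation_threshold) & (prior is not None)
        use_crover = (~use_prior & (theta > config.crossover_threshold)
                      & (crover is not None))
        if crover is not None:
            probs[use_crover] = probs_list[1][use_crover]
        if prior is not None:
            probs[use_prior] = probs_list[-1][use_prior]
        cum = probs.cumsum(axis=-1)
        u = rng.random((n, 1))
        chosen = (u < cum).argmax(axis=-1)
        chosen = np.where(finished, eos, chosen)
        step_logp = np.log(np.maximum(agent_probs[np.arange(n), chosen],
                                      1e-300))
        log_probs += np.where(finished, 0.0, step_logp)
        for i in np.nonzero(~finished)[0]:
            sequences[int(i)].append(int(chosen[i]))
        finished |= chosen == eos
        if finished.all():
            break
        tokens = chosen
    for i in range(n):
        if len(sequences[i]) < agent.config.max_len and (
                not sequences[i] or sequences[i][-1] != eos):
            sequences[i].append(eos)
    from .corpus import decode
    smiles = [decode(seq, agent.vocab) for seq in sequences]
    return SampleBatch(sequences, smiles, log_probs)


def roulette_select(scores: np.ndarray, fraction: float = 0.2,
                    rng: np.random.Generator | None = None,
                    seed: int = 0) -> np.ndarray:
    """Fitness-proportional selection of ceil(fraction * N) distinct indices.

    Sequential draws without replacement, probabilities renormalized
    after each draw. All-zero scores fall back to uniform selection.
    """
    scores = np.asarray(scores, dtype=float)
    if (scores < 0).any():
        raise ValueError("scores must be non-negative")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(scores)
    k = int(np.ceil(fraction * n))
    p = scores.copy()
    if p.sum() == 0:
        p[:] = 1.0
    selected = np.empty(k, dtype=int)
    available = p.copy()
    for draw in range(k):
        total = available.sum()
        if total == 0:  # remaining scores all zero: uniform over what's left
            remaining = np.ones(n)
            remaining[selected[:draw]] = 0.0
            available = remaining
            total = available.sum()
        probs = available / total
        choice = rng.choice(n, p=probs)
        selected[draw] = choice
        available[choice] = 0.0
    return selected


def policy_gradient_update(agent: SmilesGenerator,
                           sequences: Sequence[Sequence[int]],
                           rewards: np.ndarray) -> float:
    """One REINFORCE step: maximize sum_b R*_b sum_t log G(y_t | y_<t).

    The sampled sequences are re-run teacher-forced and each sequence's
    token log-likelihood gradient is weighted by its final reward. An
    all-zero reward batch contributes a zero gradient and the step is
    skipped entirely, leaving the parameters untouched.
    Returns the (reward-weighted) loss value.
    """
    rewards = np.asarray(rewards, dtype=float)
    if len(rewards) != len(sequences):
        raise ValueError("rewards and sequences must align")
    if not np.any(rewards):
        return 0.0
    inputs, targets, mask = agent._batch_arrays([list(s) for s in sequences])
    agent.optimizer.zero_grad()
    loss = agent.nll_loss(inputs, targets, mask, seq_weights=rewards)
    agent.optimizer.step()
    return loss


def compute_metrics(smiles: Sequence[str], valid: np.ndarray,
                    desirable: np.ndarray, final_rewards: np.ndarray,
                    seen: set[str] | None = None) -> EpochMetrics:
    """Validity / desirability / uniqueness ratios for one cycle.

    Uniqueness counts molecules whose canonical SMILES is distinct both
    within the batch and from the accumulated ``seen`` set (which is
    updated in place when provided).
    """
    n = len(smiles)
    if n == 0:
        raise ValueError("empty batch")
    canon = []
    for smi, ok in zip(smiles, valid):
        if ok:
            mol = Chem.MolFromSmiles(smi)
            canon.append(Chem.MolToSmiles(mol))
        else:
            canon.append(None)
    batch_seen: set[str] = set()
    unique = 0
    for c in canon:
        if c is None:
            continue
        if c not in batch_seen and (seen is None or c not in seen):
            unique += 1
        batch_seen.add(c)
    if seen is not None:
        seen.update(batch_seen)
    return EpochMetrics(
        validity=float(np.mean(valid)),
        desirability=float(np.mean(desirable)),
        uniqueness=unique / n,
        mean_reward=float(np.mean(final_rewards)),
    )


@dataclass
class TrainerState:
    """Handles and bookkeeping of one RL run."""

    agent: SmilesGenerator
    crover: SmilesGenerator | None
    prior: SmilesGenerator | None
    best_weights: list[np.ndarray]
    best_reward: float
    epoch: int


def train_rl(agent: SmilesGenerator,
             objectives: Sequence[ObjectiveSpec],
             scheme: Literal["weighted", "pareto"],
             config: EvolutionConfig,
             prior: SmilesGenerator | None = None,
             crover: SmilesGenerator | None = None,
             metrics_path: str | Path | None = None,
             checkpoint_path: str | Path | None = None
             ) -> tuple[TrainerState, list[EpochMetrics]]:
    """Run the full reinforcement-learning cycle.

    Per epoch: evolutionary sampling -> objective scoring -> reward
    scheme -> metrics -> roulette selection -> policy-gradient update.
    The agent checkpoint with the highest epoch mean reward is retained
    and restored into both the agent and the crover every
    ``crover_sync_interval`` epochs. The prior is never modified.
    """
    if scheme not in ("weighted", "pareto"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if crover is None and prior is not None:
        crover = clone_generator(agent)
    rng = np.random.default_rng(config.seed)
    thresholds = [spec.threshold for spec in objectives]
    seen: set[str] = set()
    metrics_log: list[EpochMetrics] = []
    best_weights = agent.get_weights()
    best_reward = -np.inf
    for epoch in range(config.epochs):
        batch = evolutionary_sample(agent, crover, prior,
                                    config.batch_size, config, rng)
        rewards, valid, desirable = score_molecules(batch.smiles, objectives)
        if scheme == "weighted":
            _, final = weighted_reward(rewards, thresholds)
            final = np.where(valid, final, 0.0)
        else:
            # only valid molecules are solutions: invalid ones would
            # otherwise occupy rank slots (their empty fingerprints are
            # maximally distant) and earn reward the policy update
            # would then reinforce; they get exactly 0 instead
            final = np.zeros(len(batch.smiles))
            if valid.any():
                fps = morgan_fingerprints(
                    [s for s, ok in zip(batch.smiles, valid) if ok])
                sub, _ = pareto_scheme(rewards[valid], desirable[valid],
                                       fps, thresholds)
                final[valid] = sub
        m = compute_metrics(batch.smiles, valid, desirable, final, seen)
        metrics_log.append(m)
        if m.mean_reward > best_reward:
            best_reward = m.mean_reward
            best_weights = agent.get_weights()
        idx = roulette_select(final, config.selection_fraction, rng)
        policy_gradient_update(agent,
                               [batch.sequences[i] for i in idx],
                               final[idx])
        if (epoch + 1) % config.crover_sync_interval == 0:
            agent.set_weights(best_weights)
            if crover is not None:
                crover.set_weights(best_weights)
            logger.info("epoch %d: synced agent and crover to best "
                        "checkpoint (mean reward %.3f)", epoch, best_reward)
    state = TrainerState(agent=agent, crover=crover, prior=prior,
                         best_weights=best_weights, best_reward=best_reward,
                         epoch=config.epochs)
    if checkpoint_path is not None:
        saved = clone_generator(agent)
        saved.set_weights(best_weights)
        saved.save(checkpoint_path)
    if metrics_path is not None:
        with open(metrics_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "validity", "desirability",
                             "uniqueness", "mean_reward"])
            for e, m in enumerate(metrics_log):
                writer.writerow([e, f"{m.validity:.6f}",
                                 f"{m.desirability:.6f}",
                                 f"{m.uniqueness:.6f}",
                                 f"{m.mean_reward:.6f}"])
    return state, metrics_log


def composite_rank(smiles: Sequence[str], desirable: np.ndarray,
                   final_rewards: np.ndarray, top_n: int = 10
                   ) -> list[tuple[str, float]]:
    """Rank molecules by the composite score and return the top N.

    composite = 0.4 * desirability + 0.4 * reward + 0.2 * uniqueness,
    where uniqueness is a per-molecule 0/1 indicator: 1 for the first
    occurrence of a canonical structure, 0 for repeats (and for invalid
    molecules). Descending, stable.
    """
    desirable = np.asarray(desirable, dtype=float)
    final_rewards = np.asarray(final_rewards, dtype=float)
    seen: set[str] = set()
    uniq = np.zeros(len(smiles))
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi) if smi else None
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon not in seen:
            uniq[i] = 1.0
            seen.add(canon)
    composite = 0.4 * desirable + 0.4 * final_rewards + 0.2 * uniq
    order = np.argsort(-composite, kind="stable")[:top_n]
    return [(smiles[i], float(composite[i])) for i in order]
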