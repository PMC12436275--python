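"""Multi-objective reward engine.

Per-objective rewards map predicted pX onto [0, 1] (high-affinity
objectives reward potency, low-affinity objectives such as hERG reward
its absence; invalid molecules score 0 everywhere). Two aggregation
schemes convert the reward vector into the scalar reinforcement-learning
reward R*:

* weighted scheme — objective weights set each cycle from the ratio of
  below- to above-threshold molecules, so lagging objectives gain
  weight; R* is the weighted sum.
* Pareto scheme — rewards are clipped relative to each objective's
  threshold, the batch is split into non-dominated fronts, molecules are
  ordered within fronts by mean Tanimoto distance (structural outliers
  rank higher), and the global rank is mapped to R* with desirable
  molecules placed in [0.5, 1) and undesirable ones in [0, 0.5).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

#: Fixed pX normalization range: 4 (inactive floor) to 9 (high potency).
#: Chosen so the bioactivity threshold pX = 6.5 maps exactly to 0.5.
PX_RANGE = (4.0, 9.0)
DEFAULT_THRESHOLD = 0.5


def normalize_px(px: float | np.ndarray,
                 px_range: tuple[float, float] = PX_RANGE,
                 batch: np.ndarray | None = None) -> float | np.ndarray:
    """Map pX affinely onto [0, 1], clipping outside the range.

    With the default fixed range [4, 9]: (px - 4)/5, so pX 6.5 -> 0.5.
    Passing ``batch`` switches to batch-relative scaling (min/max of the
    finite batch values) — available for experimentation, but it cannot
    anchor the activity threshold at 0.5, so the fixed range is default.
    """
    if batch is not None:
        finite = batch[np.isfinite(batch)]
        lo, hi = (float(finite.min()), float(finite.max())) if len(finite) else px_range
        if hi <= lo:
            lo, hi = px_range
    else:
        lo, hi = px_range
    return np.clip((px - lo) / (hi - lo), 0.0, 1.0)


@dataclass
class ObjectiveSpec:
    """One optimization objective: a predictor plus affinity direction.

    ``predictor`` maps a list of SMILES to predicted pX values (NaN for
    invalid molecules) — typically a trained QSAR model's predict, but
    any callable with that signature works.
    """

    target_id: str
    direction: Literal["high_affinity", "low_affinity"]
    predictor: Callable[[list[str]], np.ndarray]
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.direction not in ("high_affinity", "low_affinity"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly inside (0, 1)")


def objective_reward(px: float | np.ndarray, spec: ObjectiveSpec,
                     valid: bool | np.ndarray = True) -> float | np.ndarray:
    """Reward of one objective: 0 if invalid; normalized pX if high
    affinity is required; its complement if low affinity is required."""
    r = normalize_px(px)
    if spec.direction == "low_affinity":
        r = 1.0 - r
    return np.where(valid, np.nan_to_num(r, nan=0.0), 0.0)


@dataclass
class ScoredMolecule:
    """A generated molecule with its per-objective and final rewards."""

    smiles: str
    rewards: np.ndarray  # (n_objectives,), each in [0, 1]
    valid: bool
    desirable: bool
    final_reward: float = 0.0


def score_molecules(smiles: Sequence[str],
                    objectives: Sequence[ObjectiveSpec]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate all objectives on a batch.

    Returns (rewards (n, k), valid (n,), desirable (n,)). A molecule is
    desirable when it is valid and every objective reward reaches that
    objective's threshold.
    """
    smiles = list(smiles)
    valid = np.array([Chem.MolFromSmiles(s) is not None if s else False
                      for s in smiles])
    rewards = np.zeros((len(smiles), len(objectives)))
    for j, spec in enumerate(objectives):
        px = np.asarray(spec.predictor(smiles), dtype=float)
        rewards[:, j] = objective_reward(px, spec, valid)
    thresholds = np.array([spec.threshold for spec in objectives])
    desirable = valid & (rewards >= thresholds).all(axis=1)
    return rewards, valid, desirable


# ---------------------------------------------------------------- weighted
@dataclass
class WeightAllocation:
    """Objective weights derived from below/above-threshold counts."""

    n_below: np.ndarray
    n_above: np.ndarray
    ratios: np.ndarray
    weights: np.ndarray  # sum to 1


def weighted_reward(rewards: np.ndarray,
                    thresholds: Sequence[float] | None = None
                    ) -> tuple[WeightAllocation, np.ndarray]:
    """Weighted-sum aggregation.

    Per objective i, r_i = N_below / max(N_above, 1) counted against its
    threshold; w_i = r_i / sum(r) (uniform when every r_i is 0); the
    final reward of each molecule is sum_i w_i R_i.
    """
    rewards = np.atleast_2d(np.asarray(rewards, dtype=float))
    if rewards.size == 0:
        raise ValueError("empty batch")
    k = rewards.shape[1]
    t = np.full(k, DEFAULT_THRESHOLD) if thresholds is None else np.asarray(thresholds)
    n_below = (rewards < t).sum(axis=0)
    n_above = (rewards >= t).sum(axis=0)
    ratios = n_below / np.maximum(n_above, 1)
    total = ratios.sum()
    weights = np.full(k, 1.0 / k) if total == 0 else ratios / total
    final = rewards @ weights
    return WeightAllocation(n_below, n_above, ratios, weights), final


# ------------------------------------------------------------------ pareto
def clip_score(reward: float | np.ndarray,
               threshold: float = DEFAULT_THRESHOLD) -> float | np.ndarray:
    """Threshold-clipped score: 1 above the threshold, else reward/threshold."""
    reward = np.asarray(reward, dtype=float)
    return np.where(reward > threshold, 1.0, reward / threshold)


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Pareto dominance: a >= b everywhere and a > b somewhere."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    return bool((a >= b).all() and (a > b).any())


def nondominated_sort(scores: np.ndarray) -> list[list[int]]:
    """Partition a batch into Pareto fronts (best front first).

    Standard fast non-dominated sort: front 1 holds molecules dominated
    by none; front m those dominated only by members of earlier fronts.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n = len(scores)
    if n == 0:
        raise ValueError("empty batch")
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = np.zeros(n, dtype=int)
    for i in range(n):
        ge = (scores[i] >= scores).all(axis=1)
        gt = (scores[i] > scores).any(axis=1)
        dom_i = ge & gt  # i dominates j
        dominated_by[i] = [int(j) for j in np.nonzero(dom_i)[0]]
        n_dominating += dom_i
    fronts: list[list[int]] = []
    current = [i for i in range(n) if n_dominating[i] == 0]
    while current:
        fronts.append(current)
        nxt: list[int] = []
        for i in current:
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        current = sorted(nxt)
    return fronts


def tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto distances between binary fingerprint rows."""
    fps = np.asarray(fps, dtype=float)
    inter = fps @ fps.T
    counts = fps.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return 1.0 - sim


def front_distance_rank(fronts: list[list[int]],
                        fingerprints: np.ndarray) -> np.ndarray:
    """Global Pareto order k per molecule (0 = worst, N-1 = best).

    Fronts are laid out worst-first; within a front molecules are
    ordered by ascending mean Tanimoto distance to the other front
    members, so structurally more distant molecules take later
    positions (higher rank). Singleton fronts use distance 0. Ties keep
    input order (stable sort).
    """
    n = sum(len(f) for f in fronts)
    dist = tanimoto_distance_matrix(fingerprints)
    order = np.empty(n, dtype=int)
    k = 0
    for front in reversed(fronts):  # worst front first
        if len(front) == 1:
            ranked = front
        else:
            idx = np.array(front)
            sub = dist[np.ix_(idx, idx)]
            mean_dist = sub.sum(axis=1) / (len(front) - 1)
            ranked = [front[i] for i in np.argsort(mean_dist, kind="stable")]
        for mol in ranked:
            order[mol] = k
            k += 1
    return order


@dataclass
class ParetoRanking:
    """Outcome of the Pareto scheme on one batch."""

    fronts: list[list[int]]
    order: np.ndarray  # final global rank k per molecule
    n_desired: int
    n_undesired: int


def pareto_reward(order: np.ndarray, desirable: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Map Pareto ranks to final rewards, separating the two classes.

    Desirability is re-imposed as the primary sort key so undesired
    molecules occupy ranks 0..N_undesired-1 and desired molecules the
    remainder; then

        desired:   R* = 0.5 + (k - N_undesired) / (2 N_desired)
        undesired: R* = k / (2 N_undesired)

    giving desired rewards in [0.5, 1) and undesired in [0, 0.5). When
    one class is empty the occupied class uses its own block formula.
    Returns (final rewards, re-sorted ranks k).
    """
    order = np.asarray(order)
    desirable = np.asarray(desirable, dtype=bool)
    n = len(order)
    n_desired = int(desirable.sum())
    n_undesired = n - n_desired
    # stable re-sort with desirability as primary key, Pareto rank second
    perm = sorted(range(n), key=lambda i: (desirable[i], order[i]))
    k = np.empty(n, dtype=int)
    for rank, i in enumerate(perm):
        k[i] = rank
    final = np.empty(n)
    if n_undesired:
        und = ~desirable
        final[und] = k[und] / (2 * n_undesired)
    if n_desired:
        des = desirable
        final[des] = 0.5 + (k[des] - n_undesired) / (2 * n_desired)
    return final, k


def pareto_scheme(rewards: np.ndarray, desirable: np.ndarray,
                  fingerprints: np.ndarray,
                  thresholds: Sequence[float] | None = None
                  ) -> tuple[np.ndarray, ParetoRanking]:
    """Full Pareto reward pipeline for one batch.

    Clips rewards against their objective thresholds, sorts the batch
    into non-dominated fronts, ranks within fronts by structural
    distance, and maps ranks to final rewards.
    """
    rewards = np.atleast_2d(np.asarray(rewards, dtype=float))
    k_obj = rewards.shape[1]
    t = np.full(k_obj, DEFAULT_THRESHOLD) if thresholds is None else np.asarray(thresholds)
    clipped = np.column_stack([clip_score(rewards[:, j], t[j])
                               for j in range(k_obj)])
    fronts = nondominated_sort(clipped)
    order = front_distance_rank(fronts, fingerprints)
    final, k = pareto_reward(order, desirable)
    ranking = ParetoRanking(fronts=fronts, order=k,
                            n_desired=int(np.sum(desirable)),
                            n_undesired=int(len(order) - np.sum(desirable)))
    return final, ranking


def morgan_fingerprints(smiles: Sequence[str], n_bits: int = 2048
                        ) -> np.ndarray:
    """Binary Morgan (radius 3) fingerprints; zero rows for invalid SMILES."""
    fps = np.zeros((len(smiles), n_bits), dtype=np.uint8)
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi) if smi else None
        if mol is None:
            continue
        fp = rdMolDescriptors.GetMorganFingerprintAsBitVect(
            mol, radius=3, nBits=n_bits)
        fps[i] = np.frombuffer(fp.ToBitString().encode(),
                               dtype=np.uint8) - ord("0")
    return fps


def write_reward_table(path: str | Path, smiles: Sequence[str],
                       rewards: np.ndarray, valid: np.ndarray,
                       desirable: np.ndarray, order: np.ndarray,
                       final: np.ndarray) -> None:
    """Export the scored batch as CSV: smiles, valid, R_1..R_n,
    desirable, k, R_star."""
    k_obj = rewards.shape[1]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles", "valid"]
                        + [f"R_{j + 1}" for j in range(k_obj)]
                        + ["desirable", "k", "R_star"])
        for i, smi in enumerate(smiles):
            writer.writerow([smi, int(valid[i])]
                            + [f"{rewards[i, j]:.6f}" for j in range(k_obj)]
                            + [int(desirable[i]), int(order[i]),
                               f"{final[i]:.6f}"])
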