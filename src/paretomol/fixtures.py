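"""Deterministic synthetic data generators.

Every stage of the pipeline can be exercised without any database
download: a fragment-grammar corpus of valid drug-like SMILES, a toy
structure-activity table whose pX is a known function of substructure
content, and random reward batches for the multi-objective machinery.

These are not realistic bioactivity simulators — the toy SAR encodes a
single additive substructure effect — but they have the statistical
shape the pipeline assumes: valid bounded-length SMILES, pX driven by
structure plus noise, and a mix of labeled and unlabeled records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from . import corpus as corpus_mod

#: Chain-extendable SMILES fragments: each starts with an atom and leaves
#: an open valence, so any concatenation is a valid molecule. Rings are
#: attached as branches so their closure digits stay local.
FRAGMENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)", "CO", "CN", "O", "N",
    "C(=O)", "C(=O)N", "C(=O)O", "C(F)",
    "C(c1ccccc1)",      # phenyl branch
    "C(c1ccncc1)",      # pyridyl branch
    "C(c1ccco1)",       # furyl branch
    "C(C1CCCC1)",       # cyclopentyl branch
)

_FRAGMENT_HEAVY = tuple(
    Chem.MolFromSmiles(f + "C").GetNumHeavyAtoms() - 1 for f in FRAGMENTS
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic dataset."""

    n: int
    seed: int = 0
    max_heavy_atoms: int = 40
    noise_sd: float = 0.2  # pX units

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_toy_corpus(spec: FixtureSpec) -> list[str]:
    """Generate ``spec.n`` valid SMILES from the fragment grammar.

    Each molecule is a concatenation of 2-8 fragments kept under the
    heavy-atom budget, with at least 5 heavy atoms so every entry
    survives standardization. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[str] = []
    n_frag = len(FRAGMENTS)
    while len(out) < spec.n:
        k = int(rng.integers(2, 9))
        parts: list[str] = []
        heavy = 0
        for _ in range(k):
            j = int(rng.integers(n_frag))
            if heavy + _FRAGMENT_HEAVY[j] > spec.max_heavy_atoms:
                break
            parts.append(FRAGMENTS[j])
            heavy += _FRAGMENT_HEAVY[j]
        if heavy < 5:
            continue
        out.append("".join(parts))
    return out


def make_toy_sar(spec: FixtureSpec, marker: str = "c1ccco1",
                 target_id: str = "TOY1",
                 missing_fraction: float = 0.1,
                 count_cap: int = 2) -> pd.DataFrame:
    """A synthetic ligand activity table with a known structure-activity rule.

    pX = 4 + 5 * min(#marker occurrences, cap)/cap + N(0, noise_sd),
    clamped to [3, 10]. About ``missing_fraction`` of the rows carry no
    pX value, exercising the unlabeled-record handling downstream.

    Returns a DataFrame with the standard ligand-table columns
    (compound_id, smiles, target_id, px, comment, standard_type,
    standard_relation).
    """
    patt = Chem.MolFromSmarts(marker)
    if patt is None:
        raise ValueError(f"invalid marker pattern {marker!r}")
    smiles = make_toy_corpus(spec)
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        count = min(len(mol.GetSubstructMatches(patt)), count_cap)
        px: float | None
        comment = ""
        if rng.random() < missing_fraction:
            px = np.nan
            comment = "Not Active"
        else:
            px = 4.0 + 5.0 * count / count_cap + rng.normal(0.0, spec.noise_sd)
            px = float(np.clip(px, 3.0, 10.0))
        rows.append({
            "compound_id": f"TOY{i:06d}",
            "smiles": smi,
            "target_id": target_id,
            "px": px,
            "comment": comment,
            "standard_type": "Ki",
            "standard_relation": "=",
        })
    return pd.DataFrame(rows)


def toy_px_predictor(marker: str = "c1ccco1", count_cap: int = 2):
    """A noise-free oracle predictor with the toy SAR's activity rule.

    Returns a callable mapping a list of SMILES to predicted pX values
    (NaN for unparseable SMILES) — a drop-in stand-in for a trained QSAR
    model in fast reinforcement-learning runs.
    """
    patt = Chem.MolFromSmarts(marker)
    if patt is None:
        raise ValueError(f"invalid marker pattern {marker!r}")

    def predict(smiles_list: list[str]) -> np.ndarray:
        out = np.empty(len(smiles_list))
        for i, smi in enumerate(smiles_list):
            mol = Chem.MolFromSmiles(smi) if smi else None
            if mol is None:
                out[i] = np.nan
            else:
                count = min(len(mol.GetSubstructMatches(patt)), count_cap)
                out[i] = 4.0 + 5.0 * count / count_cap
        return out

    return predict


def make_scored_batch(n: int, n_objectives: int, seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random reward vectors with paired random fingerprints.

    Returns (rewards (n, k) in [0,1], fingerprints (n, 2048) binary).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = np.random.default_rng(seed)
    rewards = rng.random((n, n_objectives))
    fps = (rng.random((n, 2048)) < 0.1).astype(np.uint8)
    return rewards, fps
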