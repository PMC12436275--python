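"""SMILES preprocessing, tokenization and vocabulary handling.

This module prepares a corpus of drug-like molecules for sequence
modelling: each molecule is charge-standardized and reduced to its
largest organic fragment, filtered by element content and size, split
into atom-level tokens, and mapped to integer indices via a
:class:`Vocabulary` whose first two entries are the ``GO`` (start) and
``EOS`` (end) control tokens.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

GO = "GO"
EOS = "EOS"

#: Elements allowed in an "organic" molecule; anything else counts as a metal
#: (or otherwise undesirable element) and is rejected during standardization.
ORGANIC_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

DEFAULT_MIN_HEAVY_ATOMS = 5
DEFAULT_MAX_HEAVY_ATOMS = 100


@dataclass(frozen=True)
class RawCompound:
    """One compound as read from an input file, before standardization."""

    source_id: str
    smiles: str

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("smiles must be non-empty")


@dataclass(frozen=True)
class Rejection:
    """Why a compound was dropped during preprocessing."""

    source_id: str
    smiles: str
    reason: str  # unparseable | metal | too_small | too_large | duplicate


_UNCHARGER = rdMolStandardize.Uncharger()
_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser()


def standardize_molecule(
    smiles: str,
    min_heavy_atoms: int = DEFAULT_MIN_HEAVY_ATOMS,
    max_heavy_atoms: int = DEFAULT_MAX_HEAVY_ATOMS,
) -> tuple[str | None, str | None]:
    """Standardize one SMILES string.

    Keeps the largest organic fragment (stripping counter-ions),
    neutralizes charges, and canonicalizes. Molecules containing
    elements outside the organic subset, or falling outside the heavy
    atom bounds, are rejected.

    Returns
    -------
    (canonical_smiles, None) on success, (None, reason) on rejection.
    Reasons: ``unparseable``, ``metal``, ``too_small``, ``too_large``.
    """
    if not smiles or not isinstance(smiles, str):
        return None, "unparseable"
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None, "unparseable"
    try:
        mol = _FRAGMENT_CHOOSER.choose(mol)
        mol = _UNCHARGER.uncharge(mol)
    except Exception:
        return None, "unparseable"
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ORGANIC_ELEMENTS:
            return None, "metal"
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy < min_heavy_atoms:
        return None, "too_small"
    if n_heavy > max_heavy_atoms:
        return None, "too_large"
    return Chem.MolToSmiles(mol), None


def filter_dataset(
    compounds: Iterable[RawCompound],
    min_heavy_atoms: int = DEFAULT_MIN_HEAVY_ATOMS,
    max_heavy_atoms: int = DEFAULT_MAX_HEAVY_ATOMS,
) -> tuple[list[RawCompound], list[Rejection]]:
    """Standardize and deduplicate a collection of compounds.

    Returns the retained compounds (with canonical SMILES) in input
    order, and a rejection log. Duplicates (identical canonical SMILES)
    keep the first occurrence. Idempotent: filtering the output again
    changes nothing.
    """
    seen: set[str] = set()
    kept: list[RawCompound] = []
    rejected: list[Rejection] = []
    for comp in compounds:
        canonical, reason = standardize_molecule(
            comp.smiles, min_heavy_atoms, max_heavy_atoms
        )
        if canonical is None:
            rejected.append(Rejection(comp.source_id, comp.smiles, reason or "unknown"))
            continue
        if canonical in seen:
            rejected.append(Rejection(comp.source_id, comp.smiles, "duplicate"))
            continue
        seen.add(canonical)
        kept.append(RawCompound(comp.source_id, canonical))
    return kept, rejected


def write_rejection_log(rejections: Sequence[Rejection], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "smiles", "reason"])
        for rej in rejections:
            writer.writerow([rej.source_id, rej.smiles, rej.reason])


# Atom-level SMILES tokenization: bracket atoms, %nn ring closures and
# two-letter elements are atomic so that join(tokenize(s)) == s always.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]"  # bracket atom, e.g. [nH], [C@@H]
    r"|%\d{2}"  # two-digit ring closure
    r"|Cl|Br|Si|Se"  # two-letter organic-subset elements
    r"|.)"  # any single character
)


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into atom-level tokens.

    Raises
    ------
    ValueError
        If a ``[`` bracket is left unmatched, with the offending position.
    """
    pos = smiles.find("[")
    while pos != -1:
        close = smiles.find("]", pos)
        if close == -1:
            raise ValueError(f"unmatched '[' at position {pos} in {smiles!r}")
        pos = smiles.find("[", close)
    tokens = _TOKEN_RE.findall(smiles)
    assert "".join(tokens) == smiles
    return tokens


@dataclass
class Vocabulary:
    """Ordered token set with GO/EOS control tokens at indices 0 and 1."""

    tokens: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        if self.tokens[:2] != [GO, EOS]:
            raise ValueError("vocabulary must start with GO, EOS")
        self._index = {tok: i for i, tok in enumerate(self.tokens)}

    @property
    def go_index(self) -> int:
        return 0

    @property
    def eos_index(self) -> int:
        return 1

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary") from None

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        tokens = Path(path).read_text().splitlines()
        return cls([t for t in tokens if t])


def build_vocabulary(corpus: Iterable[Sequence[str]]) -> Vocabulary:
    """Collect every token observed in the corpus into a Vocabulary.

    Ordering is deterministic: GO, EOS first, then lexicographic, so
    the same corpus always yields the same vocabulary file regardless
    of input order.
    """
    observed: set[str] = set()
    for token_list in corpus:
        observed.update(token_list)
    if not observed:
        raise ValueError("empty corpus")
    return Vocabulary([GO, EOS] + sorted(observed))


def encode(smiles: str, vocab: Vocabulary, max_len: int | None = None) -> list[int]:
    """Encode a SMILES string into vocabulary indices, EOS appended."""
    indices = [vocab.index(tok) for tok in tokenize(smiles)]
    indices.append(vocab.eos_index)
    if max_len is not None and len(indices) > max_len:
        raise ValueError(f"sequence length {len(indices)} exceeds max_len {max_len}")
    return indices


def decode(indices: Sequence[int], vocab: Vocabulary) -> str:
    """Decode indices back to a SMILES string, stopping at the first EOS."""
    out: list[str] = []
    for idx in indices:
        if idx == vocab.eos_index:
            break
        if idx == vocab.go_index:
            continue
        out.append(vocab.tokens[idx])
    return "".join(out)


def read_smiles_file(path: str | Path) -> list[str]:
    """Read a .smi file: one SMILES per line, blank lines skipped."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_smiles_file(smiles: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(smiles) + "\n")
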