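"""The SMILES language model.

Architecture: token embedding -> stacked LSTM blocks (each block is
several LSTM layers at the recurrent width; between blocks the output is
passed through a ReLU and a learned projection back to the embedding
width) -> causal multi-head self-attention over the final block's output
-> linear projection to vocabulary logits. Trained by teacher-forced
negative log-likelihood with Adam; sampling is autoregressive from the
GO token until EOS or the length cap.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Vocabulary, decode, encode
from .nn import (Adam, CausalSelfAttention, Embedding, Linear, LSTM, Param,
                 ReLU, softmax_cross_entropy)


@dataclass
class GeneratorConfig:
    """Hyperparameters of the SMILES generator.

    Defaults reproduce the full-scale architecture: embedding 128,
    three 3-layer LSTM blocks of width 512 (nine recurrent layers in
    total) and 4-head attention with 128-dimensional keys. Scaled-down
    configurations simply shrink these numbers.
    """

    vocab_size: int
    embed_dim: int = 128
    hidden_size: int = 512
    block_layers: int = 3
    num_blocks: int = 3
    attention_heads: int = 4
    key_dim: int | None = None  # default: hidden_size // attention_heads
    max_len: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.key_dim is None:
            self.key_dim = self.hidden_size // self.attention_heads
        if self.attention_heads * self.key_dim != self.hidden_size:
            raise ValueError(
                f"attention width {self.attention_heads}x{self.key_dim} "
                f"must equal hidden_size {self.hidden_size}")
        for name in ("vocab_size", "embed_dim", "hidden_size", "block_layers",
                     "num_blocks", "attention_heads", "key_dim", "max_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SampleBatch:
    """A batch of sampled sequences with their summed log-probabilities."""

    sequences: list[list[int]]
    smiles: list[str]
    log_probs: np.ndarray  # (n,), each <= 0

    def __len__(self) -> int:
        return len(self.sequences)


class SmilesGenerator:
    """Autoregressive SMILES generator over a fixed vocabulary."""

    def __init__(self, config: GeneratorConfig, vocab: Vocabulary):
        if config.vocab_size != len(vocab):
            raise ValueError("config.vocab_size must equal |vocab|")
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed)
        cfg = config
        self.embedding = Embedding(rng, cfg.vocab_size, cfg.embed_dim)
        self.blocks: list[list[LSTM]] = []
        self.inter: list[tuple[ReLU, Linear]] = []
        for b in range(cfg.num_blocks):
            layers = []
            for l in range(cfg.block_layers):
                d_in = cfg.embed_dim if l == 0 else cfg.hidden_size
                layers.append(LSTM(rng, d_in, cfg.hidden_size))
            self.blocks.append(layers)
            if b < cfg.num_blocks - 1:
                self.inter.append((ReLU(), Linear(rng, cfg.hidden_size,
                                                  cfg.embed_dim)))
        self.attention = CausalSelfAttention(rng, cfg.attention_heads,
                                             cfg.key_dim)
        self.out = Linear(rng, cfg.hidden_size, cfg.vocab_size)
        self.optimizer = Adam(self.params, lr=cfg.learning_rate)

    # ------------------------------------------------------------------
    @property
    def params(self) -> list[Param]:
        ps = list(self.embedding.params)
        for block in self.blocks:
            for layer in block:
                ps.extend(layer.params)
        for _, proj in self.inter:
            ps.extend(proj.params)
        ps.extend(self.attention.params)
        ps.extend(self.out.params)
        return ps

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p.value[...] = w

    # ------------------------------------------------------------------
    def forward(self, inputs: np.ndarray) -> np.ndarray:
        """Teacher-forced forward pass. inputs (B, T) ints -> logits (B, T, V)."""
        x = self.embedding.forward(inputs)
        for b, block in enumerate(self.blocks):
            for layer in block:
                x = layer.forward(x)
            if b < len(self.blocks) - 1:
                relu, proj = self.inter[b]
                x = proj.forward(relu.forward(x))
        x = self.attention.forward(x)
        return self.out.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.out.backward(dlogits)
        dx = self.attention.backward(dx)
        for b in range(len(self.blocks) - 1, -1, -1):
            if b < len(self.blocks) - 1:
                relu, proj = self.inter[b]
                dx = relu.backward(proj.backward(dx))
            for layer in reversed(self.blocks[b]):
                dx = layer.backward(dx)
        self.embedding.backward(dx)

    def nll_loss(self, inputs: np.ndarray, targets: np.ndarray,
                 mask: np.ndarray,
                 seq_weights: np.ndarray | None = None,
                 compute_grad: bool = True) -> float:
        """Teacher-forced NLL, averaged over the batch; optionally backprop."""
        if inputs.shape != targets.shape:
            raise ValueError("inputs and targets must have the same shape")
        logits = self.forward(inputs)
        loss, dlogits = softmax_cross_entropy(logits, targets, mask, seq_weights)
        if compute_grad:
            self.backward(dlogits)
        return loss

    # ------------------------------------------------------------------
    def _batch_arrays(self, encoded: list[list[int]]
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Pack encoded sequences (token indices ending in EOS) into padded
        teacher-forcing arrays: inputs start with GO, targets end with EOS,
        padding positions (after the first EOS target) are masked out."""
        go, eos = self.vocab.go_index, self.vocab.eos_index
        T = max(len(seq) for seq in encoded)
        B = len(encoded)
        inputs = np.full((B, T), eos, dtype=np.int64)
        targets = np.full((B, T), eos, dtype=np.int64)
        mask = np.zeros((B, T))
        for i, seq in enumerate(encoded):
            L = len(seq)  # includes EOS
            inputs[i, 0] = go
            inputs[i, 1:L] = seq[:-1]
            targets[i, :L] = seq
            mask[i, :L] = 1.0
        return inputs, targets, mask

    def train_corpus(self, smiles: Sequence[str], epochs: int,
                     seed: int | None = None,
                     log_path: str | Path | None = None,
                     checkpoint_path: str | Path | None = None,
                     validity_sample: int = 0) -> list[float]:
        """Teacher-forced NLL training over a SMILES corpus.

        Used for both pretraining (large general corpus) and fine-tuning
        (target-ligand corpus): the procedure is identical, only the data
        differ. Sequences longer than ``max_len`` are dropped with a count.
        Returns per-epoch mean losses; the best-loss weights are restored
        at the end (and saved to ``checkpoint_path`` if given).
        """
        if not smiles:
            raise ValueError("empty corpus")
        cfg = self.config
        encoded: list[list[int]] = []
        dropped = 0
        for s in smiles:
            seq = encode(s, self.vocab)
            if len(seq) + 1 > cfg.max_len:
                dropped += 1
                continue
            encoded.append(seq)
        if not encoded:
            raise ValueError("no sequences within max_len")
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        # bucket sequences by length so batches carry little padding
        encoded.sort(key=len)
        batches = [
            self._batch_arrays(encoded[start:start + cfg.batch_size])
            for start in range(0, len(encoded), cfg.batch_size)
        ]
        losses: list[float] = []
        best_loss = np.inf
        best_weights = self.get_weights()
        log_rows = []
        for epoch in range(epochs):
            total = 0.0
            nb = 0
            for bi in rng.permutation(len(batches)):
                inputs, targets, mask = batches[bi]
                self.optimizer.zero_grad()
                loss = self.nll_loss(inputs, targets, mask)
                self.optimizer.step()
                total += loss
                nb += 1
            epoch_loss = total / nb
            losses.append(epoch_loss)
            if epoch_loss < best_loss:
                best_loss = epoch_loss
                best_weights = self.get_weights()
            row = {"epoch": epoch, "loss": epoch_loss, "validity_sample": ""}
            if validity_sample:
                batch = self.sample(validity_sample,
                                    rng=np.random.default_rng(rng.integers(2**31)))
                from rdkit import Chem
                valid = sum(Chem.MolFromSmiles(s) is not None
                            for s in batch.smiles)
                row["validity_sample"] = valid / validity_sample
            log_rows.append(row)
        self.set_weights(best_weights)
        if checkpoint_path is not None:
            self.save(checkpoint_path)
        if log_path is not None:
            with open(log_path, "w", newline="") as fh:
                writer = csv.DictWriter(
                    fh, fieldnames=["epoch", "loss", "validity_sample"])
                writer.writeheader()
                writer.writerows(log_rows)
        if dropped:
            import logging
            logging.getLogger(__name__).info(
                "dropped %d sequences longer than max_len", dropped)
        return losses

    pretrain = train_corpus
    finetune = train_corpus

    # ------------------------------------------------------------------
    def init_state(self, batch: int) -> dict:
        return {
            "lstm": [[layer.init_state(batch) for layer in block]
                     for block in self.blocks],
            "attn": self.attention.init_state(batch),
        }

    def step(self, tokens: np.ndarray, state: dict
             ) -> tuple[np.ndarray, dict]:
        """Advance one step on the given tokens (B,). Returns token
        probabilities (B, V) for the next position and the new state."""
        x = self.embedding.step(tokens)
        new_lstm = []
        for b, block in enumerate(self.blocks):
            block_states = []
            for l, layer in enumerate(block):
                x, st = layer.step(x, state["lstm"][b][l])
                block_states.append(st)
            new_lstm.append(block_states)
            if b < len(self.blocks) - 1:
                relu, proj = self.inter[b]
                x = proj.step(relu.step(x))
        x, attn_state = self.attention.step(x, state["attn"])
        logits = self.out.step(x)
        logits -= logits.max(axis=-1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=-1, keepdims=True)
        return p, {"lstm": new_lstm, "attn": attn_state}

    def sample(self, n: int, temperature: float = 1.0,
               rng: np.random.Generator | None = None,
               seed: int | None = None) -> SampleBatch:
        """Sample n sequences autoregressively.

        ``temperature`` rescales the step distribution (0 = greedy
        argmax decoding). Each sequence starts from GO and stops at EOS
        or at ``max_len`` tokens. log_probs are the summed log
        probabilities of the chosen tokens (under temperature 1).
        """
        if n <= 0:
            raise ValueError("n must be positive")
        if rng is None:
            rng = np.random.default_rng(self.config.seed if seed is None else seed)
        go, eos = self.vocab.go_index, self.vocab.eos_index
        state = self.init_state(n)
        tokens = np.full(n, go, dtype=np.int64)
        finished = np.zeros(n, dtype=bool)
        sequences: list[list[int]] = [[] for _ in range(n)]
        log_probs = np.zeros(n)
        for _ in range(self.config.max_len):
            probs, state = self.step(tokens, state)
            if temperature == 0.0:
                chosen = probs.argmax(axis=-1)
            elif temperature == 1.0:
                cum = probs.cumsum(axis=-1)
                u = rng.random((n, 1))
                chosen = (u < cum).argmax(axis=-1)
            else:
                logp = np.log(np.maximum(probs, 1e-300)) / temperature
                logp -= logp.max(axis=-1, keepdims=True)
                p = np.exp(logp)
                p /= p.sum(axis=-1, keepdims=True)
                cum = p.cumsum(axis=-1)
                u = rng.random((n, 1))
                chosen = (u < cum).argmax(axis=-1)
            chosen = np.where(finished, eos, chosen)
            step_logp = np.log(np.maximum(
                probs[np.arange(n), chosen], 1e-300))
            log_probs += np.where(finished, 0.0, step_logp)
            for i in np.nonzero(~finished)[0]:
                sequences[int(i)].append(int(chosen[i]))
            finished |= chosen == eos
            if finished.all():
                break
            tokens = chosen
        for i in range(n):
            # sequences cut off at max_len keep their length; shorter ones
            # are guaranteed to end in EOS already
            if len(sequences[i]) < self.config.max_len and (
                    not sequences[i] or sequences[i][-1] != eos):
                sequences[i].append(eos)
        smiles = [decode(seq, self.vocab) for seq in sequences]
        return SampleBatch(sequences, smiles, log_probs)

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Save weights + config + vocabulary to a single .npz file."""
        meta = json.dumps({"config": asdict(self.config),
                           "tokens": self.vocab.tokens})
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params)}
        np.savez(path, meta=np.array(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SmilesGenerator":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        vocab = Vocabulary(meta["tokens"])
        model = cls(GeneratorConfig(**meta["config"]), vocab)
        model.set_weights([data[f"p{i}"] for i in range(len(model.params))])
        return model


def clone_generator(model: SmilesGenerator) -> SmilesGenerator:
    """A new generator with the same config, vocabulary and weights."""
    clone = SmilesGenerator(model.config, model.vocab)
    clone.set_weights(model.get_weights())
    return clone
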