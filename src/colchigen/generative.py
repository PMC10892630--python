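"""Sequence-reconstruction generative model for colchicine-like structures.

The training library is expanded by randomized-SMILES augmentation
(:mod:`colchigen.corpus`), each rendering is tokenized into a molecular
sequence, one-hot vectorized, and fed to a small recurrent network trained to
reconstruct the sequences autoregressively.  Sampling from the trained model
proposes novel structures; sampled strings are validity-filtered through the
chemistry toolkit, deduplicated by canonical SMILES, and training molecules
are excluded, so every returned record is a valid, novel structure.

Molecular sequences here are atom-level SMILES token lists: bracket atoms,
two-letter elements, ring-closure digits and bond symbols are each one token.
Joining the tokens reproduces the exact SMILES string, so encoding is
trivially invertible.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import RDLogger

from . import _rnn
from .corpus import InvalidSmilesError, MoleculeRecord, canonicalize

PAD, BOS, EOS = "<pad>", "<bos>", "<eos>"

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOSPFIbcnosp]|[=#$/\\\-+().@]|\d)"
)


class EncodingError(ValueError):
    """Raised when a string cannot be tokenized into a molecular sequence."""


class VocabularyError(KeyError):
    """Raised when a token is absent from the vocabulary."""


def encode_molecular_sequence(smiles: str) -> list[str]:
    """Tokenize a SMILES string into its molecular sequence.

    The token list joins back to the identical string, so decoding yields a
    molecule canonically equal to the input.  Raises :class:`EncodingError`
    for empty or untokenizable input and :class:`InvalidSmilesError` for
    strings that are not valid molecules.
    """
    if not smiles:
        raise EncodingError("empty string")
    canonicalize(smiles)  # raises InvalidSmilesError on bad input
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise EncodingError(f"untokenizable characters in {smiles!r}")
    return tokens


def decode_molecular_sequence(tokens: list[str]) -> str:
    return "".join(tokens)


@dataclass(frozen=True)
class TokenVocabulary:
    """Bijective token <-> index map with padding fixed at index 0."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tokens[0] != PAD or self.tokens[1] != BOS or self.tokens[2] != EOS:
            raise ValueError("vocabulary must start with PAD, BOS, EOS")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    @classmethod
    def from_corpus(cls, corpus: list[list[str]]) -> "TokenVocabulary":
        seen = sorted({tok for seq in corpus for tok in seq})
        return cls(tokens=(PAD, BOS, EOS, *seen))

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def encode(self, tokens: list[str]) -> list[int]:
        idx = self.index
        try:
            return [idx[t] for t in tokens]
        except KeyError as exc:
            raise VocabularyError(f"token {exc.args[0]!r} not in vocabulary") from exc

    def decode(self, indices: list[int]) -> list[str]:
        return [self.tokens[i] for i in indices if i > 2]


@dataclass
class SequenceTensor:
    """One-hot (max_len, vocab_size) matrix for one molecular sequence."""

    matrix: np.ndarray
    length: int


def vectorize(tokens: list[str], vocab: TokenVocabulary, max_len: int) -> SequenceTensor:
    """One-hot encode a token list, padding out to ``max_len`` rows."""
    if len(tokens) > max_len:
        raise ValueError(f"sequence of length {len(tokens)} exceeds max_len={max_len}")
    indices = vocab.encode(tokens)
    matrix = np.zeros((max_len, len(vocab)))
    matrix[np.arange(len(indices)), indices] = 1.0
    matrix[len(indices):, 0] = 1.0  # padding rows
    return SequenceTensor(matrix=matrix, length=len(indices))


def devectorize(tensor: SequenceTensor, vocab: TokenVocabulary) -> list[str]:
    indices = tensor.matrix[: tensor.length].argmax(axis=1)
    return [vocab.tokens[i] for i in indices]


@dataclass
class GeneratorModel:
    """A trained sequence model plus everything needed to sample from it."""

    vocabulary: TokenVocabulary
    max_len: int
    weights: dict[str, np.ndarray] | None = None
    history: list[tuple[int, float, float]] = field(default_factory=list)
    training_canonical: frozenset[str] = frozenset()

    @property
    def is_trained(self) -> bool:
        return self.weights is not None and bool(self.history)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "tokens": list(self.vocabulary.tokens),
            "max_len": self.max_len,
            "history": self.history,
            "training_canonical": sorted(self.training_canonical),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        np.savez(directory / "weights.npz", **(self.weights or {}))

    @classmethod
    def load(cls, directory: str | Path) -> "GeneratorModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        with np.load(directory / "weights.npz") as npz:
            weights = {k: npz[k] for k in npz.files}
        return cls(
            vocabulary=TokenVocabulary(tuple(meta["tokens"])),
            max_len=meta["max_len"],
            weights=weights,
            history=[tuple(h) for h in meta["history"]],
            training_canonical=frozenset(meta["training_canonical"]),
        )


def split_corpus(n: int, val_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic train/validation index split.

    The validation side holds ``round(val_fraction * n)`` items (a 118,070-
    rendering corpus at 0.1 splits 106,263 / 11,807).
    """
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must lie strictly between 0 and 1")
    n_val = int(round(val_fraction * n))
    if n_val == 0 or n_val == n:
        raise ValueError(f"degenerate split: {n} items at val_fraction={val_fraction}")
    order = np.random.default_rng(seed).permutation(n)
    return order[n_val:], order[:n_val]


def _to_index_matrix(
    corpus: list[list[str]], vocab: TokenVocabulary, max_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Build (inputs, targets) integer matrices: BOS-prefixed vs EOS-suffixed."""
    idx = vocab.index
    bos, eos = idx[BOS], idx[EOS]
    n = len(corpus)
    inputs = np.zeros((n, max_len), dtype=np.int64)
    targets = np.zeros((n, max_len), dtype=np.int64)
    for i, seq in enumerate(corpus):
        enc = vocab.encode(seq)
        inputs[i, 0] = bos
        inputs[i, 1 : len(enc) + 1] = enc
        targets[i, : len(enc)] = enc
        targets[i, len(enc)] = eos
    return inputs, targets


def train_generator(
    corpus: list[list[str]],
    val_fraction: float = 0.1,
    epochs: int = 10,
    seed: int = 15,
    hidden: int = 64,
    batch_size: int = 128,
    learning_rate: float = 5e-3,
    patience: int | None = None,
    training_smiles: list[str] | None = None,
) -> GeneratorModel:
    """Train the reconstruction model on a tokenized corpus.

    The corpus is split deterministically (``seed``) into training and
    validation parts; loss is categorical cross-entropy per token.  History
    records ``(epoch, train_loss, val_loss)`` once per epoch (unless
    ``patience`` triggers early stopping on a validation plateau).  Fixed
    ``(corpus, seed, epochs)`` reproduce the history bit-for-bit.

    ``training_smiles`` optionally records the canonical training molecules
    so sampling can exclude them.
    """
    if not corpus:
        raise ValueError("empty corpus")
    vocab = TokenVocabulary.from_corpus(corpus)
    max_len = max(len(seq) for seq in corpus) + 2  # EOS + safety margin
    inputs, targets = _to_index_matrix(corpus, vocab, max_len)
    train_idx, val_idx = split_corpus(len(corpus), val_fraction, seed)

    rng = np.random.default_rng(seed + 1)
    params = _rnn.init_params(len(vocab), hidden, rng)
    adam = _rnn.init_adam(params)
    history: list[tuple[int, float, float]] = []
    best_val, since_best = np.inf, 0
    for epoch in range(1, epochs + 1):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), batch_size):
            batch = order[start : start + batch_size]
            loss, grads = _rnn.loss_and_grads(params, inputs[batch], targets[batch])
            _rnn.adam_step(params, grads, adam, lr=learning_rate)
            losses.append(loss)
        val_losses = [
            _rnn.loss_and_grads(
                params, inputs[val_idx[s : s + batch_size]],
                targets[val_idx[s : s + batch_size]], compute_grads=False,
            )[0]
            for s in range(0, len(val_idx), batch_size)
        ]
        train_loss = float(np.mean(losses))
        val_loss = float(np.mean(val_losses))
        history.append((epoch, train_loss, val_loss))
        if patience is not None:
            if val_loss < best_val - 1e-4:
                best_val, since_best = val_loss, 0
            else:
                since_best += 1
                if since_best >= patience:
                    break

    canonical = frozenset(canonicalize(s) for s in training_smiles or [])
    return GeneratorModel(
        vocabulary=vocab,
        max_len=max_len,
        weights=params,
        history=history,
        training_canonical=canonical,
    )


def sample_structures(
    model: GeneratorModel,
    n_attempts: int,
    temperature: float = 1.0,
    seed: int = 42,
) -> list[MoleculeRecord]:
    """Sample novel structures from a trained model.

    Draws ``n_attempts`` token sequences, decodes them, keeps only strings
    the chemistry toolkit parses, deduplicates by canonical SMILES and drops
    exact training molecules.  Deterministic given ``seed``; the output size
    is at most ``n_attempts``.
    """
    if not model.is_trained:
        raise RuntimeError("model has not been trained")
    if n_attempts < 1:
        raise ValueError("n_attempts must be >= 1")
    idx = model.vocabulary.index
    rng = np.random.default_rng(seed)
    sequences = _rnn.sample_tokens(
        model.weights, n_attempts, model.max_len,
        bos_index=idx[BOS], eos_index=idx[EOS], pad_index=idx[PAD],
        temperature=temperature, rng=rng,
    )
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    RDLogger.DisableLog("rdApp.error")  # most raw samples are not legal SMILES
    try:
        for k, seq in enumerate(sequences):
            smiles = decode_molecular_sequence(model.vocabulary.decode(seq))
            try:
                canonical = canonicalize(smiles)
            except (InvalidSmilesError, EncodingError):
                continue
            if canonical in seen or canonical in model.training_canonical:
                continue
            seen.add(canonical)
            records.append(
                MoleculeRecord(id=f"gen{k}", smiles=smiles, canonical_smiles=canonical)
            )
    finally:
        RDLogger.EnableLog("rdApp.error")
    return records


def write_samples(records: list[MoleculeRecord], path: str | Path) -> None:
    """One canonical SMILES per line."""
    Path(path).write_text("".join(f"{r.canonical_smiles}\n" for r in records))
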