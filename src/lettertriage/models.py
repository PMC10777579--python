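"""The hybrid two-branch classifier and its single-branch / sequential kin.

Architecture overview
---------------------

* **Attention branch** — a contextual transformer encoder reads the subword
  sequence; the final hidden state at the first position (the start special)
  summarises the text and a linear head maps it to logits over the four
  disease classes.
* **CNN branch** — the same text, tokenized at word level and looked up in a
  *static* (frozen) embedding table, passes through three 1-D convolutions
  (kernel widths 2, 3 and 4, two filters each), per-filter max pooling over
  time, dropout, and a linear head to the four logits.
* **Fusion** — each branch has its own cross-entropy loss; training minimises
  the convex combination ``alpha * loss_cnn + (1 - alpha) * loss_attn``.
  ``alpha`` is *not* a network parameter: after each optimisation step it is
  moved by the rule-based recurrence

      alpha <- alpha - (loss_cnn - loss_attn) * lr_alpha * alpha

  so the branch that is currently easier to optimise gradually receives more
  weight. At inference the class probabilities are combined with the same
  convex weight.
* **Sequential model** — the contrast case: the encoder's per-token hidden
  states *are* the CNN's embedding layer, one chained network with a single
  cross-entropy loss and no alpha.

The two hybrid branches share no parameters and no tokenizer; their only
coupling is the scalar alpha, which receives no gradient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .autograd import Tensor
from .encoding import (DEFAULT_MAX_LENGTH, EmbeddingTable, TokenSequence,
                       WordPieceTokenizer, whitespace_tokenize)
from .corpus import LABELS

logger = logging.getLogger(__name__)

N_CLASSES = len(LABELS)


# -- probability / loss containers -------------------------------------------

@dataclass(frozen=True)
class ClassProbabilities:
    probs: np.ndarray   # (4,) nonnegative, sums to 1
    logits: np.ndarray  # (4,) pre-softmax scores

    def __post_init__(self):
        if self.probs.shape[-1] != N_CLASSES:
            raise ValueError("expected scores over exactly 4 classes")
        if not math.isclose(float(self.probs.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("probabilities must sum to 1")

    @property
    def top_class(self) -> int:
        return int(np.argmax(self.probs))


@dataclass(frozen=True)
class StepLosses:
    loss_cnn: float
    loss_attn: float
    loss_fused: float


@dataclass(frozen=True)
class FusionState:
    """The fusion weight alpha, its learning rate and update counter."""

    alpha: float = 0.3
    alpha_lr: float = 1e-5
    step: int = 0
    clamp_bounds: tuple[float, float] = (0.01, 0.99)

    def __post_init__(self):
        lo, hi = self.clamp_bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("clamp_bounds must satisfy 0 <= lo < hi <= 1")
        if not lo <= self.alpha <= hi:
            raise ValueError(f"alpha {self.alpha} outside clamp bounds {self.clamp_bounds}")


def fuse_losses(losses: StepLosses | tuple[float, float], fs: FusionState) -> float:
    """Convex combination ``alpha * loss_cnn + (1 - alpha) * loss_attn``."""
    if isinstance(losses, StepLosses):
        lc, la = losses.loss_cnn, losses.loss_attn
    else:
        lc, la = losses
    return fs.alpha * lc + (1.0 - fs.alpha) * la


def update_alpha(fs: FusionState, losses: StepLosses | tuple[float, float]) -> FusionState:
    """One application of the multiplicative alpha recurrence, then clamping.

    alpha receives no gradient; this is the only coupling between branches.
    Non-finite losses leave the state unchanged (with a warning).
    """
    if isinstance(losses, StepLosses):
        lc, la = losses.loss_cnn, losses.loss_attn
    else:
        lc, la = losses
    if not (math.isfinite(lc) and math.isfinite(la)):
        logger.warning("non-finite losses (%s, %s); alpha left unchanged", lc, la)
        return fs
    new_alpha = fs.alpha - (lc - la) * fs.alpha_lr * fs.alpha
    lo, hi = fs.clamp_bounds
    clamped = min(max(new_alpha, lo), hi)
    if clamped != new_alpha:
        logger.info("alpha clamped from %.6g to %.6g at step %d", new_alpha, clamped, fs.step + 1)
    return replace(fs, alpha=clamped, step=fs.step + 1)


def cross_entropy(probs: ClassProbabilities, label_index: int) -> float:
    """-log p[label], computed stably from the logits."""
    z = probs.logits - probs.logits.max()
    logp = z - np.log(np.exp(z).sum())
    return float(-logp[label_index])


def _probs_from_logits(logits: np.ndarray) -> ClassProbabilities:
    z = logits - logits.max()
    e = np.exp(z)
    return ClassProbabilities(probs=e / e.sum(), logits=logits)


# -- branches -----------------------------------------------------------------

class AttentionBranch(nn.Module):
    """Contextual encoder + dropout on H + linear head over 4 classes."""

    def __init__(self, encoder: nn.TinyTransformerEncoder, dropout: float = 0.5,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.encoder = encoder
        self.drop = nn.Dropout(dropout, rng)
        self.head = nn.Linear(encoder.hidden, N_CLASSES, rng)

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        hidden = self.encoder(ids, mask)          # (B, T, H)
        pooled = hidden[:, 0, :]                  # first-position state H
        return self.head(self.drop(pooled))       # (B, 4)


class CnnBranch(nn.Module):
    """Static word embeddings + 1-D convolution head.

    The embedding table is frozen data, not a parameter: its vectors enter
    the graph as constants, exactly as a fixed pre-trained table would.
    """

    def __init__(self, table: EmbeddingTable, dropout: float = 0.5,
                 kernel_sizes: tuple[int, ...] = (2, 3, 4),
                 filters_per_kernel: int = 2, seed: int = 0):
        super().__init__()
        self.table = table
        self.conv = nn.TextConvHead(
            in_channels=table.dim, n_classes=N_CLASSES,
            kernel_sizes=kernel_sizes, filters_per_kernel=filters_per_kernel,
            dropout=dropout, rng=np.random.default_rng(seed))

    def embed_batch(self, ids: np.ndarray) -> Tensor:
        return Tensor(self.table.matrix[ids])  # constant: frozen vectors

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        x = self.embed_batch(ids)
        if x.shape[1] < max(self.conv.kernel_sizes):
            pad_n = max(self.conv.kernel_sizes) - x.shape[1]
            logger.warning("padding sequence of length %d up by %d for the largest kernel",
                           x.shape[1], pad_n)
            x = Tensor(np.pad(x.data, ((0, 0), (0, pad_n), (0, 0))))
            mask = np.pad(mask, ((0, 0), (0, pad_n)))
        return self.conv(x, attention_mask=mask)


# -- assembled models ---------------------------------------------------------

@dataclass
class HybridEncodings:
    """Both branches' encodings of one text (each via its own tokenizer)."""

    attn_ids: np.ndarray
    attn_mask: np.ndarray
    cnn_ids: np.ndarray
    cnn_mask: np.ndarray


class HybridModel(nn.Module):
    """Two parallel branches over the same text, coupled only through alpha."""

    def __init__(self, subword_tokenizer: WordPieceTokenizer, table: EmbeddingTable,
                 encoder_hidden: int = 32, encoder_layers: int = 2,
                 encoder_heads: int = 2, encoder_ff: int = 64,
                 max_length: int = DEFAULT_MAX_LENGTH, dropout: float = 0.5,
                 fusion: FusionState | None = None, seed: int = 0):
        super().__init__()
        self.tokenizer = subword_tokenizer
        self.table = table
        self.max_length = max_length
        encoder = nn.TinyTransformerEncoder(
            n_vocab=subword_tokenizer.vocab_size, hidden=encoder_hidden,
            n_heads=encoder_heads, n_layers=encoder_layers, ff=encoder_ff,
            max_len=max_length, dropout=0.1, seed=seed)
        self.attn_branch = AttentionBranch(encoder, dropout=dropout, seed=seed + 1)
        self.cnn_branch = CnnBranch(table, dropout=dropout, seed=seed + 2)
        self.fusion = fusion if fusion is not None else FusionState()

    # encoding --------------------------------------------------------------

    def encode(self, text: str) -> HybridEncodings:
        sub = self.tokenizer.encode(text, max_length=self.max_length)
        word = whitespace_tokenize(text, max_length=self.max_length)
        return HybridEncodings(
            attn_ids=sub.ids[None, :], attn_mask=sub.attention_mask[None, :],
            cnn_ids=self.table.ids_for(word.tokens)[None, :],
            cnn_mask=word.attention_mask[None, :])

    # forward ---------------------------------------------------------------

    def forward_logits(self, enc: HybridEncodings) -> tuple[Tensor, Tensor]:
        attn_logits = self.attn_branch(enc.attn_ids, enc.attn_mask)
        cnn_logits = self.cnn_branch(enc.cnn_ids, enc.cnn_mask)
        return attn_logits, cnn_logits

    def hybrid_forward(self, text: str) -> tuple[ClassProbabilities,
                                                 ClassProbabilities,
                                                 ClassProbabilities]:
        """Run both branches on one text; combine with the current alpha."""
        self.eval()
        enc = self.encode(text)
        attn_logits, cnn_logits = self.forward_logits(enc)
        attn = _probs_from_logits(attn_logits.data[0])
        cnn = _probs_from_logits(cnn_logits.data[0])
        combined = combine_probabilities(attn, cnn, self.fusion.alpha)
        return attn, cnn, combined


def combine_probabilities(attn: ClassProbabilities, cnn: ClassProbabilities,
                          alpha: float) -> ClassProbabilities:
    """Inference rule: alpha weights the CNN branch, (1-alpha) the attention
    branch, mirroring the training-loss weights."""
    probs = alpha * cnn.probs + (1.0 - alpha) * attn.probs
    logits = np.log(np.maximum(probs, 1e-300))
    return ClassProbabilities(probs=probs, logits=logits)


class SequentialModel(nn.Module):
    """Encoder-as-embedding chained into the CNN head; one loss, no alpha."""

    def __init__(self, subword_tokenizer: WordPieceTokenizer,
                 encoder_hidden: int = 32, encoder_layers: int = 2,
                 encoder_heads: int = 2, encoder_ff: int = 64,
                 max_length: int = DEFAULT_MAX_LENGTH, dropout: float = 0.5,
                 seed: int = 0):
        super().__init__()
        self.tokenizer = subword_tokenizer
        self.max_length = max_length
        self.encoder = nn.TinyTransformerEncoder(
            n_vocab=subword_tokenizer.vocab_size, hidden=encoder_hidden,
            n_heads=encoder_heads, n_layers=encoder_layers, ff=encoder_ff,
            max_len=max_length, dropout=0.1, seed=seed)
        self.conv = nn.TextConvHead(
            in_channels=encoder_hidden, n_classes=N_CLASSES,
            dropout=dropout, rng=np.random.default_rng(seed + 1))

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        hidden = self.encoder(ids, mask)  # (B, T, H): the CNN's embedding
        return self.conv(hidden, attention_mask=mask)

    def sequential_forward(self, text: str) -> ClassProbabilities:
        self.eval()
        seq = self.tokenizer.encode(text, max_length=self.max_length)
        logits = self(seq.ids[None, :], seq.attention_mask[None, :])
        return _probs_from_logits(logits.data[0])


class SingleBranchModel(nn.Module):
    """Baseline wrapper: just the attention branch or just the CNN branch."""

    def __init__(self, which: str, subword_tokenizer: WordPieceTokenizer | None = None,
                 table: EmbeddingTable | None = None, max_length: int = DEFAULT_MAX_LENGTH,
                 dropout: float = 0.5, seed: int = 0, **encoder_kw):
        super().__init__()
        if which not in ("attn", "cnn"):
            raise ValueError("which must be 'attn' or 'cnn'")
        self.which = which
        self.max_length = max_length
        self.tokenizer = subword_tokenizer
        self.table = table
        if which == "attn":
            encoder = nn.TinyTransformerEncoder(
                n_vocab=subword_tokenizer.vocab_size,
                max_len=max_length, seed=seed,
                **encoder_kw)
            self.branch = AttentionBranch(encoder, dropout=dropout, seed=seed + 1)
        else:
            self.branch = CnnBranch(table, dropout=dropout, seed=seed + 2)

    def encode(self, text: str) -> tuple[np.ndarray, np.ndarray]:
        if self.which == "attn":
            seq = self.tokenizer.encode(text, max_length=self.max_length)
            return seq.ids[None, :], seq.attention_mask[None, :]
        word = whitespace_tokenize(text, max_length=self.max_length)
        return self.table.ids_for(word.tokens)[None, :], word.attention_mask[None, :]

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        return self.branch(ids, mask)
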