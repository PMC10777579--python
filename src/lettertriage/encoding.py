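"""Text encodings for the two classifier branches.

The convolutional branch consumes word-level tokens looked up in a *static*
(frozen) embedding table — either vectors loaded from a word2vec-format text
file such as fastText's crawl-300d-2M.vec, or a seeded random table for
self-contained runs. The attention branch consumes subword ids from its own
tokenizer; a tiny greedy WordPiece tokenizer is built in, and any object with
the same ``encode`` contract can be registered in its place. The two
tokenizations are fully independent: changing one cannot affect the other.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

PAD_TOKEN = "[PAD]"
OOV_TOKEN = "[OOV]"
SPECIAL_LITERALS = ("[SEP]", "[NOSYM]")

DEFAULT_MAX_LENGTH = 256


@dataclass
class TokenSequence:
    """Tokens (and optionally ids) after padding/truncation, with a validity mask."""

    tokens: list[str]
    m: int                       # number of real (non-pad) tokens
    attention_mask: np.ndarray   # 1.0 valid / 0.0 pad, length == len(tokens)
    ids: np.ndarray | None = None

    def __post_init__(self):
        if len(self.attention_mask) != len(self.tokens):
            raise ValueError("mask length must equal padded token count")


_WORD_RE = re.compile(r"\[SEP\]|\[NOSYM\]|[^\s.]+|\.")


def whitespace_tokenize(text: str, max_length: int = DEFAULT_MAX_LENGTH,
                        pad: bool = True) -> TokenSequence:
    """Lower-cased whitespace/punctuation word tokens for the CNN branch.

    "[SEP]" and "." are kept as standalone tokens; output is truncated to
    ``max_length`` and right-padded with the pad token.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    raw = _WORD_RE.findall(text)
    toks = [t if t in SPECIAL_LITERALS else t.lower() for t in raw]
    if len(toks) > max_length:
        logger.debug("truncating %d tokens to %d", len(toks), max_length)
        toks = toks[:max_length]
    m = len(toks)
    width = max_length if pad else m
    mask = np.zeros(width)
    mask[:m] = 1.0
    return TokenSequence(tokens=toks + [PAD_TOKEN] * (width - m), m=m,
                         attention_mask=mask)


# -- static embedding tables --------------------------------------------------

@dataclass
class EmbeddingTable:
    """Token -> row lookup over a |V| x d matrix with pad and OOV rows.

    ``oov_policy`` is "random" (a seeded random vector per unseen token type,
    cached so every later lookup of that type agrees) or "zero".
    """

    vocabulary: dict[str, int]
    matrix: np.ndarray
    oov_policy: str = "random"
    frozen: bool = True
    _oov_rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    def __post_init__(self):
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix must be finite")
        if self.oov_policy not in ("random", "zero"):
            raise ValueError(f"unknown oov_policy {self.oov_policy!r}")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def row_for(self, token: str) -> int:
        idx = self.vocabulary.get(token)
        if idx is not None:
            return idx
        if token == PAD_TOKEN:
            return self.vocabulary[PAD_TOKEN]
        if self.oov_policy == "zero":
            return self.vocabulary[OOV_TOKEN]
        # cache a fresh seeded vector for this OOV type
        idx = self.matrix.shape[0]
        vec = self._oov_rng.normal(0.0, 1.0 / np.sqrt(self.dim), (1, self.dim))
        self.matrix = np.vstack([self.matrix, vec])
        self.vocabulary[token] = idx
        return idx

    def ids_for(self, tokens: list[str]) -> np.ndarray:
        return np.array([self.row_for(t) for t in tokens], dtype=np.int64)


def _new_table(tokens: list[str], matrix_rows: list[np.ndarray], d: int,
               oov_policy: str, oov_seed: int) -> EmbeddingTable:
    vocab = {PAD_TOKEN: 0, OOV_TOKEN: 1}
    rows = [np.zeros(d), np.zeros(d)]
    for tok, row in zip(tokens, matrix_rows):
        if tok in vocab:
            continue
        vocab[tok] = len(rows)
        rows.append(row)
    return EmbeddingTable(vocabulary=vocab, matrix=np.array(rows),
                          oov_policy=oov_policy)


def load_vectors(path: str | Path, oov_policy: str = "random") -> EmbeddingTable:
    """Read a word2vec text-format vector file (header "count dim")."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path} line 1: expected header 'count dim'")
        count, d = int(header[0]), int(header[1])
        tokens, rows = [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if not parts or parts == [""]:
                continue
            vals = parts[1:]
            if len(vals) != d:
                raise ValueError(
                    f"{path} line {ln}: expected {d} floats, got {len(vals)}")
            tokens.append(parts[0])
            rows.append(np.array(vals, dtype=np.float64))
    if len(tokens) != count:
        logger.warning("%s: header declared %d vectors, found %d", path, count, len(tokens))
    return _new_table(tokens, rows, d, oov_policy, oov_seed=0)


def random_table(vocab: list[str], d: int = 300, seed: int = 0,
                 oov_policy: str = "random") -> EmbeddingTable:
    """Deterministic N(0, 1/sqrt(d)) table over `vocab`, frozen like a loaded one."""
    rng = np.random.default_rng(seed)
    uniq = list(dict.fromkeys(t for t in vocab if t not in (PAD_TOKEN, OOV_TOKEN)))
    rows = [rng.normal(0.0, 1.0 / np.sqrt(d), d) for _ in uniq]
    table = _new_table(uniq, rows, d, oov_policy, oov_seed=seed)
    table._oov_rng = np.random.default_rng(seed + 1)
    return table


@dataclass(frozen=True)
class EmbeddedSequence:
    vectors: np.ndarray  # (len(tokens), d)

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


def embed(seq: TokenSequence, table: EmbeddingTable) -> EmbeddedSequence:
    """Pure lookup: same table and sequence always give the same vectors."""
    ids = table.ids_for(seq.tokens)
    return EmbeddedSequence(vectors=table.matrix[ids])


# -- subword tokenizer for the attention branch -------------------------------

class WordPieceTokenizer:
    """Greedy longest-prefix WordPiece with learned whole words and ##-pieces.

    Sequences are wrapped as [CLS] ... [EOS]; the literal "[SEP]" in the text
    maps to the separator id, so integration inputs contain exactly one
    separator strictly inside the sequence.
    """

    SPECIALS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[EOS]")
    PAD_ID, UNK_ID, CLS_ID, SEP_ID, EOS_ID = range(5)

    def __init__(self, vocab: dict[str, int]):
        for i, sp in enumerate(self.SPECIALS):
            if vocab.get(sp) != i:
                raise ValueError("vocabulary must start with the special tokens")
        self.vocab = vocab

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    @classmethod
    def train(cls, texts: list[str], vocab_size: int = 2000) -> "WordPieceTokenizer":
        """Build a vocabulary of frequent whole words plus character pieces.

        Character-level pieces guarantee any ASCII word is encodable; frequent
        words get whole-word entries so clinical terms stay intact.
        """
        from collections import Counter
        counts: Counter[str] = Counter()
        chars: set[str] = set()
        for text in texts:
            for w in _WORD_RE.findall(text):
                if w in SPECIAL_LITERALS:
                    continue
                w = w.lower()
                counts[w] += 1
                chars.update(w)
        vocab = {sp: i for i, sp in enumerate(cls.SPECIALS)}
        vocab["[NOSYM]"] = len(vocab)
        for ch in sorted(chars):
            vocab[ch] = len(vocab)
            vocab["##" + ch] = len(vocab)
        for w, _ in counts.most_common():
            if len(vocab) >= vocab_size:
                break
            if w not in vocab:
                vocab[w] = len(vocab)
        return cls(vocab)

    def _encode_word(self, word: str) -> list[int]:
        ids = []
        start = 0
        while start < len(word):
            end = len(word)
            piece = None
            while end > start:
                cand = word[start:end] if start == 0 else "##" + word[start:end]
                if cand in self.vocab:
                    piece = cand
                    break
                end -= 1
            if piece is None:
                return [self.UNK_ID]
            ids.append(self.vocab[piece])
            start = end
        return ids

    def encode(self, text: str, max_length: int = DEFAULT_MAX_LENGTH) -> TokenSequence:
        ids = [self.CLS_ID]
        toks = ["[CLS]"]
        for w in _WORD_RE.findall(text):
            if w == "[SEP]":
                ids.append(self.SEP_ID)
                toks.append("[SEP]")
                continue
            w = w if w in SPECIAL_LITERALS else w.lower()
            if w in self.vocab:
                ids.append(self.vocab[w])
                toks.append(w)
            else:
                for pid in self._encode_word(w):
                    ids.append(pid)
                    toks.append("<piece>")
        ids = ids[:max_length - 1] + [self.EOS_ID]
        toks = toks[:max_length - 1] + ["[EOS]"]
        m = len(ids)
        pad_n = max_length - m
        mask = np.zeros(max_length)
        mask[:m] = 1.0
        return TokenSequence(
            tokens=toks + ["[PAD]"] * pad_n, m=m, attention_mask=mask,
            ids=np.array(ids + [self.PAD_ID] * pad_n, dtype=np.int64))

    def to_dict(self) -> dict:
        return {"kind": "wordpiece", "vocab": self.vocab}

    @classmethod
    def from_dict(cls, d: dict) -> "WordPieceTokenizer":
        return cls({k: int(v) for k, v in d["vocab"].items()})


_REGISTRY: dict[str, WordPieceTokenizer] = {}


def register_tokenizer(name: str, tokenizer: WordPieceTokenizer) -> None:
    _REGISTRY[name] = tokenizer


def subword_encode(text: str, encoder_spec, max_length: int = DEFAULT_MAX_LENGTH
                   ) -> TokenSequence:
    """Encode for the attention branch. ``encoder_spec`` is a registered
    tokenizer name or a tokenizer object with an ``encode`` method."""
    if isinstance(encoder_spec, str):
        if encoder_spec not in _REGISTRY:
            raise ValueError(
                f"unknown encoder_spec {encoder_spec!r}; registered: {sorted(_REGISTRY)}")
        encoder_spec = _REGISTRY[encoder_spec]
    return encoder_spec.encode(text, max_length=max_length)
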