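"""Training protocol: stratified 7:2:1 split, mini-batch Adam, accuracy, and
the (architecture x dataset-variant) experiment grid.

Two named configuration profiles ship with the package:

* ``paper_profile`` — batch size 8, Adam learning rate 1e-6, 200 epochs,
  dropout 0.5, embedding dimension 300, alpha starting at 0.3 with alpha
  learning rate 1e-5. These are the settings of the method as published.
* ``desk_profile`` — the same architecture scaled for a single CPU: a tiny
  encoder (hidden 32, 2 layers, 2 heads), learning rate 1e-3, 50 epochs,
  truncation at 128 tokens (long enough that integration inputs are never
  cut). Used by the test suite and the examples.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .autograd import Tensor
from .corpus import LABELS, ReferralLetter
from .encoding import WordPieceTokenizer, random_table, whitespace_tokenize
from .models import (FusionState, HybridModel, SequentialModel,
                     SingleBranchModel, StepLosses, combine_probabilities,
                     _probs_from_logits, update_alpha)
from .preprocess import DatasetVariant, build_variants

logger = logging.getLogger(__name__)

ARCHITECTURES = ("hybrid", "sequential", "attn", "cnn")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 8
    learning_rate: float = 1e-6
    epochs: int = 200
    dropout: float = 0.5
    seed: int = 0
    split_ratio: tuple[int, int, int] = (7, 2, 1)
    max_length: int = 256
    embedding_dim: int = 300
    encoder_hidden: int = 32
    encoder_layers: int = 2
    encoder_heads: int = 2
    encoder_ff: int = 64
    kernel_sizes: tuple[int, ...] = (2, 3, 4)
    filters_per_kernel: int = 2
    alpha0: float = 0.3
    alpha_lr: float = 1e-5
    alpha_update: str = "step"      # or "epoch"
    inference_rule: str = "convex"  # or "attn", "cnn"
    wordpiece_vocab: int = 2000

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if any(r <= 0 for r in self.split_ratio):
            raise ValueError("split ratios must be positive")
        if self.alpha_update not in ("step", "epoch"):
            raise ValueError("alpha_update must be 'step' or 'epoch'")


def paper_profile(**overrides) -> TrainConfig:
    """The published hyperparameters, verbatim."""
    return replace(TrainConfig(), **overrides)


def desk_profile(**overrides) -> TrainConfig:
    """Single-CPU profile: tiny encoder, faster optimiser, shorter sequences."""
    base = TrainConfig(learning_rate=1e-3, epochs=50, max_length=128)
    return replace(base, **overrides)


# -- splitting ----------------------------------------------------------------

def split_dataset(records, ratio: tuple[int, int, int] = (7, 2, 1), seed: int = 0,
                  label_of=None):
    """Stratified largest-remainder split into (train, val, test).

    Within each class the counts are the largest-remainder apportionment of
    the ratio; remainder ties go to the smaller-share part first, so the test
    part is never starved when a whole extra record is up for grabs.
    Deterministic in the seed.
    """
    if label_of is None:
        label_of = lambda r: r[1] if isinstance(r, tuple) else r.label
    if len(records) < 10:
        raise ValueError("need at least 10 records to split 7:2:1")
    by_class: dict[str, list] = defaultdict(list)
    for r in records:
        lab = label_of(r)
        by_class[getattr(lab, "code", lab)].append(r)
    for code, items in by_class.items():
        if len(items) < 3:
            raise ValueError(
                f"class {code} has only {len(items)} records; generate a larger corpus")
    rng = np.random.default_rng(seed)
    total = sum(ratio)
    parts: tuple[list, list, list] = ([], [], [])
    # tie-break priority: test (2) first, then val (1), then train (0)
    priority = {0: 2, 1: 1, 2: 0}
    for code in sorted(by_class):
        items = list(by_class[code])
        order = rng.permutation(len(items))
        items = [items[i] for i in order]
        n = len(items)
        shares = [n * r / total for r in ratio]
        counts = [int(np.floor(s)) for s in shares]
        rema = [(s - c, priority[i], i) for i, (s, c) in enumerate(zip(shares, counts))]
        for _, _, i in sorted(rema, key=lambda t: (-t[0], t[1])):
            if sum(counts) >= n:
                break
            counts[i] += 1
        lo = 0
        for part, c in zip(parts, counts):
            part.extend(items[lo:lo + c])
            lo += c
    return parts


# -- metrics ------------------------------------------------------------------

def accuracy(predictions, labels) -> float:
    """Fraction of argmax predictions matching the integer labels.

    ``predictions`` is an (N, 4) array of probabilities or logits; argmax
    ties resolve to the lowest class index.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape[0] != labels.shape[0] or labels.shape[0] == 0:
        raise ValueError("predictions and labels must have equal nonzero length")
    pred = np.argmax(predictions, axis=-1)
    n_ties = int(np.sum(np.sum(predictions == predictions.max(axis=-1, keepdims=True),
                               axis=-1) > 1))
    if n_ties:
        logger.debug("%d argmax ties broken toward the lowest class index", n_ties)
    return float(np.mean(pred == labels))


# -- encodings ----------------------------------------------------------------

@dataclass
class EncodedSet:
    """A dataset variant encoded once for a given model."""

    attn_ids: np.ndarray | None
    attn_mask: np.ndarray | None
    cnn_ids: np.ndarray | None
    cnn_mask: np.ndarray | None
    labels: np.ndarray

    def __len__(self):
        return len(self.labels)


def _encode_set(model, data: list[tuple[str, int]], max_length: int) -> EncodedSet:
    needs_attn = not (isinstance(model, SingleBranchModel) and model.which == "cnn")
    needs_cnn = isinstance(model, (HybridModel,)) or (
        isinstance(model, SingleBranchModel) and model.which == "cnn")
    attn_ids = attn_mask = cnn_ids = cnn_mask = None
    if needs_attn:
        seqs = [model.tokenizer.encode(t, max_length=max_length) for t, _ in data]
        attn_ids = np.stack([s.ids for s in seqs])
        attn_mask = np.stack([s.attention_mask for s in seqs])
    if needs_cnn:
        seqs = [whitespace_tokenize(t, max_length=max_length) for t, _ in data]
        cnn_ids = np.stack([model.table.ids_for(s.tokens) for s in seqs])
        cnn_mask = np.stack([s.attention_mask for s in seqs])
    return EncodedSet(attn_ids, attn_mask, cnn_ids, cnn_mask,
                      labels=np.array([y for _, y in data], dtype=np.int64))


def _trim(ids: np.ndarray, mask: np.ndarray, floor: int = 4
          ) -> tuple[np.ndarray, np.ndarray]:
    """Drop all-pad columns beyond the batch's longest real sequence.

    Pad positions are masked out of attention and pooling, so trimming does
    not change any output; it only avoids convolving and attending over
    padding. The floor keeps the largest CNN kernel applicable.
    """
    width = max(int(mask.sum(axis=1).max()), floor)
    return ids[:, :width], mask[:, :width]


def _forward_logits(model, enc: EncodedSet, idx: np.ndarray):
    """Model-appropriate logits for the rows `idx`; hybrid returns a pair."""
    if isinstance(model, HybridModel):
        a = model.attn_branch(*_trim(enc.attn_ids[idx], enc.attn_mask[idx]))
        c = model.cnn_branch(*_trim(enc.cnn_ids[idx], enc.cnn_mask[idx]))
        return a, c
    if isinstance(model, SequentialModel):
        return model(*_trim(enc.attn_ids[idx], enc.attn_mask[idx]))
    if model.which == "attn":
        return model(*_trim(enc.attn_ids[idx], enc.attn_mask[idx]))
    return model(*_trim(enc.cnn_ids[idx], enc.cnn_mask[idx]))


def predict_probs(model, enc: EncodedSet, batch_size: int = 32,
                  inference_rule: str = "convex") -> np.ndarray:
    """Class probabilities for a whole encoded set, in eval mode."""
    model.eval()
    out = []
    for lo in range(0, len(enc), batch_size):
        idx = np.arange(lo, min(lo + batch_size, len(enc)))
        logits = _forward_logits(model, enc, idx)
        if isinstance(model, HybridModel):
            a_logits, c_logits = logits
            alpha = model.fusion.alpha
            for i in range(len(idx)):
                a = _probs_from_logits(a_logits.data[i])
                c = _probs_from_logits(c_logits.data[i])
                if inference_rule == "attn":
                    out.append(a.probs)
                elif inference_rule == "cnn":
                    out.append(c.probs)
                else:
                    out.append(combine_probabilities(a, c, alpha).probs)
        else:
            for i in range(len(idx)):
                out.append(_probs_from_logits(logits.data[i]).probs)
    model.train()
    return np.array(out)


# -- training loop ------------------------------------------------------------

@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    alpha_trace: list[float] = field(default_factory=list)       # per alpha update
    step_losses: list[tuple[float, float]] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        import csv
        with Path(path).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_loss", "train_acc", "val_loss", "val_acc"])
            for i in range(len(self.train_loss)):
                w.writerow([i + 1, self.train_loss[i], self.train_acc[i],
                            self.val_loss[i] if self.val_loss else "",
                            self.val_acc[i] if self.val_acc else ""])


def train(model, train_data: list[tuple[str, int]], cfg: TrainConfig,
          val_data: list[tuple[str, int]] | None = None
          ) -> tuple[object, TrainHistory]:
    """Mini-batch Adam on the model's loss.

    For the hybrid model the loss is the alpha-fused pair of branch
    cross-entropies and alpha follows its recurrence (per step or per epoch
    per ``cfg.alpha_update``); all other models train on a single
    cross-entropy. Fixed seed and data order give a bit-reproducible history
    on one platform.
    """
    if not train_data:
        raise ValueError("train_data must be nonempty")
    history = TrainHistory()
    if cfg.epochs == 0:
        return model, history
    enc = _encode_set(model, train_data, cfg.max_length)
    enc_val = _encode_set(model, val_data, cfg.max_length) if val_data else None
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    is_hybrid = isinstance(model, HybridModel)
    n = len(enc)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        ep_loss, ep_correct = 0.0, 0
        epoch_gaps = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            y = enc.labels[idx]
            opt.zero_grad()
            if is_hybrid:
                a_logits, c_logits = _forward_logits(model, enc, idx)
                loss_a = nn.cross_entropy(a_logits, y)
                loss_c = nn.cross_entropy(c_logits, y)
                alpha = model.fusion.alpha
                loss = loss_c * alpha + loss_a * (1.0 - alpha)
                step = StepLosses(loss_cnn=float(loss_c.data),
                                  loss_attn=float(loss_a.data),
                                  loss_fused=float(loss.data))
                history.step_losses.append((step.loss_cnn, step.loss_attn))
                probs_for_acc = (alpha * _softmax_rows(c_logits.data)
                                 + (1 - alpha) * _softmax_rows(a_logits.data))
            else:
                logits = _forward_logits(model, enc, idx)
                loss = nn.cross_entropy(logits, y)
                probs_for_acc = _softmax_rows(logits.data)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch + 1}, batch ids {idx.tolist()}")
            loss.backward()
            opt.step()
            if is_hybrid and cfg.alpha_update == "step":
                model.fusion = update_alpha(model.fusion, step)
                history.alpha_trace.append(model.fusion.alpha)
            elif is_hybrid:
                epoch_gaps.append((step.loss_cnn, step.loss_attn))
            ep_loss += float(loss.data) * len(idx)
            ep_correct += int(np.sum(np.argmax(probs_for_acc, axis=-1) == y))
        if is_hybrid and cfg.alpha_update == "epoch" and epoch_gaps:
            mean = StepLosses(*np.mean(epoch_gaps, axis=0), loss_fused=0.0)
            model.fusion = update_alpha(model.fusion, mean)
            history.alpha_trace.append(model.fusion.alpha)
        history.train_loss.append(ep_loss / n)
        history.train_acc.append(ep_correct / n)
        if enc_val is not None:
            probs = predict_probs(model, enc_val, inference_rule=cfg.inference_rule)
            history.val_acc.append(accuracy(probs, enc_val.labels))
            eps = 1e-12
            history.val_loss.append(float(np.mean(
                -np.log(probs[np.arange(len(enc_val)), enc_val.labels] + eps))))
    return model, history


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def evaluate(model, data: list[tuple[str, int]], cfg: TrainConfig) -> float:
    enc = _encode_set(model, data, cfg.max_length)
    probs = predict_probs(model, enc, inference_rule=cfg.inference_rule)
    return accuracy(probs, enc.labels)


# -- model factory ------------------------------------------------------------

def build_model(arch: str, train_texts: list[str], cfg: TrainConfig, seed: int):
    """Construct a freshly initialised model whose tokenizer/embedding
    vocabularies come from the training texts only."""
    if arch not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {arch!r}; choose from {ARCHITECTURES}")
    tok = WordPieceTokenizer.train(train_texts, vocab_size=cfg.wordpiece_vocab)
    vocab = sorted({t for text in train_texts
                    for t in whitespace_tokenize(text, cfg.max_length, pad=False).tokens})
    table = random_table(vocab, d=cfg.embedding_dim, seed=seed)
    enc_kw = dict(encoder_hidden=cfg.encoder_hidden, encoder_layers=cfg.encoder_layers,
                  encoder_heads=cfg.encoder_heads, encoder_ff=cfg.encoder_ff)
    if arch == "hybrid":
        return HybridModel(tok, table, max_length=cfg.max_length, dropout=cfg.dropout,
                           fusion=FusionState(alpha=cfg.alpha0, alpha_lr=cfg.alpha_lr),
                           seed=seed, **enc_kw)
    if arch == "sequential":
        return SequentialModel(tok, max_length=cfg.max_length, dropout=cfg.dropout,
                               seed=seed, **enc_kw)
    if arch == "attn":
        return SingleBranchModel("attn", subword_tokenizer=tok,
                                 max_length=cfg.max_length, dropout=cfg.dropout,
                                 seed=seed,
                                 hidden=cfg.encoder_hidden, n_layers=cfg.encoder_layers,
                                 n_heads=cfg.encoder_heads, ff=cfg.encoder_ff)
    return SingleBranchModel("cnn", table=table, max_length=cfg.max_length,
                             dropout=cfg.dropout, seed=seed)


# -- experiment grid ----------------------------------------------------------

@dataclass
class ExperimentReport:
    entries: list[dict] = field(default_factory=list)

    def mean_accuracy(self, arch: str, variant: str) -> float:
        vals = [e["accuracy"] for e in self.entries
                if e["architecture"] == arch and e["variant"] == variant
                and "error" not in e]
        if not vals:
            raise ValueError(f"no successful runs for ({arch}, {variant})")
        return float(np.mean(vals))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.entries, indent=2))


def run_single(letters: list[ReferralLetter], arch: str, variant_name: str,
               cfg: TrainConfig, seed: int) -> dict:
    """Preprocess, split, train and test one (architecture, variant) cell."""
    _, variants = build_variants(letters)
    variant = variants[variant_name]
    data = [(text, _label_index(lab)) for text, lab in variant.records]
    tr, va, te = split_dataset(data, cfg.split_ratio, seed=seed,
                               label_of=lambda r: r[1])
    run_cfg = replace(cfg, seed=seed)
    model = build_model(arch, [t for t, _ in tr], run_cfg, seed=seed)
    model, history = train(model, tr, run_cfg, val_data=None)
    acc = evaluate(model, te, run_cfg)
    per_class = _per_class_accuracy(model, te, run_cfg)
    return {"architecture": arch, "variant": variant_name, "seed": seed,
            "accuracy": acc, "per_class_accuracy": per_class,
            "final_alpha": getattr(model, "fusion", None).alpha
            if hasattr(model, "fusion") else None,
            "n_train": len(tr), "n_test": len(te)}


def _label_index(lab) -> int:
    from .corpus import CODE_TO_INDEX
    return CODE_TO_INDEX[lab.code]


def _per_class_accuracy(model, data, cfg) -> dict[str, float]:
    enc = _encode_set(model, data, cfg.max_length)
    probs = predict_probs(model, enc, inference_rule=cfg.inference_rule)
    pred = np.argmax(probs, axis=-1)
    out = {}
    for i, lab in enumerate(LABELS):
        mask = enc.labels == i
        if mask.any():
            out[lab.code] = float(np.mean(pred[mask] == i))
    return out


def run_grid(letters: list[ReferralLetter], architectures: list[str],
             variants: list[str], cfg: TrainConfig, n_seeds: int = 1
             ) -> ExperimentReport:
    """Train every (architecture, variant) cell for each seed; a failed run is
    recorded and the grid continues."""
    report = ExperimentReport()
    for s in range(n_seeds):
        seed = cfg.seed + s
        for arch in architectures:
            for vname in variants:
                try:
                    report.entries.append(run_single(letters, arch, vname, cfg, seed))
                except Exception as exc:  # noqa: BLE001 — grid must survive
                    logger.error("run (%s, %s, seed=%d) failed: %s", arch, vname, seed, exc)
                    report.entries.append({"architecture": arch, "variant": vname,
                                           "seed": seed, "error": str(exc)})
    return report
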