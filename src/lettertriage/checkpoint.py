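"""Single-file model checkpoints.

A checkpoint is one ``.npz`` archive holding every parameter array, the
frozen embedding matrix, and a JSON metadata blob (architecture, training
config, fusion state, tokenizer vocabulary, config hash). Save and load
round-trip exactly: float64 arrays are stored losslessly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .encoding import EmbeddingTable, WordPieceTokenizer
from .models import FusionState, HybridModel, SequentialModel, SingleBranchModel
from .training import TrainConfig


def config_hash(resolved: dict) -> str:
    """Digest of a fully materialised config (all defaults explicit)."""
    blob = json.dumps(resolved, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _arch_of(model) -> str:
    if isinstance(model, HybridModel):
        return "hybrid"
    if isinstance(model, SequentialModel):
        return "sequential"
    if isinstance(model, SingleBranchModel):
        return model.which
    raise TypeError(f"unknown model type {type(model).__name__}")


def save_checkpoint(model, cfg: TrainConfig, path: str | Path) -> None:
    arch = _arch_of(model)
    meta: dict = {"arch": arch, "config": asdict(cfg),
                  "config_hash": config_hash(asdict(cfg))}
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"param_{i}"] = p.data
    tokenizer = getattr(model, "tokenizer", None)
    if tokenizer is not None:
        meta["tokenizer"] = tokenizer.to_dict()
    table = getattr(model, "table", None)
    if table is not None:
        meta["table_vocab"] = list(table.vocabulary)
        meta["table_oov_policy"] = table.oov_policy
        arrays["table_matrix"] = table.matrix
    if hasattr(model, "fusion"):
        meta["fusion"] = asdict(model.fusion)
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    np.savez_compressed(Path(path), **arrays)


def load_checkpoint(path: str | Path):
    """Rebuild the model; returns ``(model, cfg)``. Exact round trip."""
    with np.load(Path(path)) as npz:
        meta = json.loads(bytes(npz["meta"]).decode("utf-8"))
        arrays = {k: npz[k] for k in npz.files if k != "meta"}
    cfg_d = meta["config"]
    for key in ("split_ratio", "kernel_sizes"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = TrainConfig(**cfg_d)
    arch = meta["arch"]
    tokenizer = (WordPieceTokenizer.from_dict(meta["tokenizer"])
                 if "tokenizer" in meta else None)
    table = None
    if "table_vocab" in meta:
        table = EmbeddingTable(
            vocabulary={t: i for i, t in enumerate(meta["table_vocab"])},
            matrix=arrays.pop("table_matrix"),
            oov_policy=meta["table_oov_policy"])
    enc_kw = dict(encoder_hidden=cfg.encoder_hidden, encoder_layers=cfg.encoder_layers,
                  encoder_heads=cfg.encoder_heads, encoder_ff=cfg.encoder_ff)
    if arch == "hybrid":
        model = HybridModel(tokenizer, table, max_length=cfg.max_length,
                            dropout=cfg.dropout,
                            fusion=FusionState(**{**meta["fusion"],
                                                  "clamp_bounds": tuple(
                                                      meta["fusion"]["clamp_bounds"])}),
                            seed=cfg.seed, **enc_kw)
    elif arch == "sequential":
        model = SequentialModel(tokenizer, max_length=cfg.max_length,
                                dropout=cfg.dropout, seed=cfg.seed, **enc_kw)
    elif arch == "attn":
        model = SingleBranchModel("attn", subword_tokenizer=tokenizer,
                                  max_length=cfg.max_length, dropout=cfg.dropout,
                                  seed=cfg.seed,
                                  hidden=cfg.encoder_hidden, n_layers=cfg.encoder_layers,
                                  n_heads=cfg.encoder_heads, ff=cfg.encoder_ff)
    elif arch == "cnn":
        model = SingleBranchModel("cnn", table=table, max_length=cfg.max_length,
                                  dropout=cfg.dropout, seed=cfg.seed)
    else:
        raise ValueError(f"checkpoint names unknown architecture {arch!r}")
    params = [arrays[f"param_{i}"] for i in range(len(model.parameters()))]
    model.load_arrays(params)
    return model, cfg
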