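"""Split protocol, accuracy metric, training loop behaviour, grid, checkpoints."""

import numpy as np
import pytest

import lettertriage as lt
from lettertriage.corpus import CODE_TO_INDEX, LABELS
from lettertriage.training import (build_model, desk_profile, run_grid,
                                   run_single, train)
from conftest import zero_noise_config


def _variant_data(letters, name="Integration"):
    _, variants = lt.build_variants(list(letters))
    return [(t, CODE_TO_INDEX[lab.code]) for t, lab in variants[name].records]


class TestSplit:
    def test_exact_ratio_single_class(self):
        recs = [("t%d" % i, LABELS[0]) for i in range(10)]
        tr, va, te = lt.split_dataset(recs, (7, 2, 1), seed=0)
        assert (len(tr), len(va), len(te)) == (7, 2, 1)

    def test_largest_remainder_five_per_class(self):
        recs = [(f"{lab.code}-{i}", lab) for lab in LABELS for i in range(5)]
        tr, va, te = lt.split_dataset(recs, (7, 2, 1), seed=0)
        # per class 5 * (0.7, 0.2, 0.1) -> floors (3,1,0), spare record to test
        assert (len(tr), len(va), len(te)) == (12, 4, 4)

    def test_partition_and_stratification(self, noisy_letters):
        tr, va, te = lt.split_dataset(list(noisy_letters), seed=1)
        all_ids = sorted(l.id for l in tr + va + te)
        assert all_ids == sorted(l.id for l in noisy_letters)
        assert not ({l.id for l in tr} & {l.id for l in te})
        for lab in LABELS:
            n = sum(1 for l in noisy_letters if l.label == lab)
            for part, share in zip((tr, va, te), (0.7, 0.2, 0.1)):
                k = sum(1 for l in part if l.label == lab)
                assert abs(k - n * share) <= 1

    def test_deterministic_in_seed(self, noisy_letters):
        a = lt.split_dataset(list(noisy_letters), seed=5)
        b = lt.split_dataset(list(noisy_letters), seed=5)
        assert [[l.id for l in p] for p in a] == [[l.id for l in p] for p in b]

    def test_small_class_rejected(self):
        recs = [("a", LABELS[0])] * 8 + [("b", LABELS[1])] * 2
        with pytest.raises(ValueError, match="larger corpus"):
            lt.split_dataset(recs, seed=0)


class TestAccuracy:
    def test_fraction_correct(self):
        probs = np.zeros((27, 4))
        labels = np.zeros(27, dtype=int)
        probs[:24, 0] = 1.0
        probs[24:, 1] = 1.0
        assert lt.accuracy(probs, labels) == pytest.approx(24 / 27)

    def test_all_correct(self):
        probs = np.eye(4)
        assert lt.accuracy(probs, np.arange(4)) == 1.0

    def test_uniform_random_predictor_near_chance(self):
        rng = np.random.default_rng(0)
        probs = rng.random((4000, 4))
        labels = rng.integers(0, 4, 4000)
        assert lt.accuracy(probs, labels) == pytest.approx(0.25, abs=0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lt.accuracy(np.zeros((3, 4)), np.zeros(2))


class TestTrainLoop:
    def test_memorises_eight_separable_letters(self):
        letters = lt.generate_corpus(zero_noise_config(n_per_class=2, seed=11))
        data = _variant_data(letters)
        cfg = desk_profile(seed=11, epochs=120, max_length=64)
        model = build_model("hybrid", [t for t, _ in data], cfg, seed=11)
        model, hist = train(model, data, cfg)
        assert hist.train_acc[-1] == 1.0

    def test_zero_epochs_returns_untrained_with_empty_history(self, noisy_letters):
        data = _variant_data(noisy_letters)
        cfg = desk_profile(seed=0, epochs=0)
        model = build_model("cnn", [t for t, _ in data], cfg, seed=0)
        before = [p.data.copy() for p in model.parameters()]
        model, hist = train(model, data, cfg)
        assert hist.train_loss == []
        assert all(np.array_equal(a, p.data)
                   for a, p in zip(before, model.parameters()))

    def test_alpha_trace_replays_from_logged_losses(self, separable_letters):
        data = _variant_data(separable_letters)
        cfg = desk_profile(seed=2, epochs=3, max_length=64)
        model = build_model("hybrid", [t for t, _ in data], cfg, seed=2)
        model, hist = train(model, data, cfg)
        fs = lt.FusionState(alpha=cfg.alpha0, alpha_lr=cfg.alpha_lr)
        replay = []
        for lc, la in hist.step_losses:
            fs = lt.update_alpha(fs, (lc, la))
            replay.append(fs.alpha)
        assert replay == hist.alpha_trace
        assert hist.alpha_trace[0] != cfg.alpha0 or hist.step_losses[0][0] == \
            hist.step_losses[0][1]

    def test_history_is_bit_reproducible(self, separable_letters):
        data = _variant_data(separable_letters)
        cfg = desk_profile(seed=9, epochs=2, max_length=64)
        runs = []
        for _ in range(2):
            model = build_model("hybrid", [t for t, _ in data], cfg, seed=9)
            _, hist = train(model, data, cfg)
            runs.append((hist.train_loss, hist.alpha_trace))
        assert runs[0] == runs[1]

    def test_frozen_embedding_table_untouched_by_training(self, separable_letters):
        data = _variant_data(separable_letters)
        cfg = desk_profile(seed=4, epochs=2, max_length=64)
        model = build_model("hybrid", [t for t, _ in data], cfg, seed=4)
        before = model.table.matrix.copy()
        train(model, data, cfg)
        assert np.array_equal(model.table.matrix, before)

    def test_train_loss_trends_down_on_learnable_corpus(self, separable_letters):
        data = _variant_data(separable_letters)
        cfg = desk_profile(seed=3, epochs=12, max_length=64)
        model = build_model("hybrid", [t for t, _ in data], cfg, seed=3)
        _, hist = train(model, data, cfg)
        first, last = np.mean(hist.train_loss[:3]), np.mean(hist.train_loss[-3:])
        assert last < first


class TestGrid:
    def test_entry_count_and_range(self, noisy_letters):
        cfg = desk_profile(seed=0, epochs=1, max_length=64)
        rep = run_grid(list(noisy_letters), ["cnn", "attn"],
                       ["Symptoms", "Complaints"], cfg, n_seeds=1)
        assert len(rep.entries) == 4
        for e in rep.entries:
            assert 0.0 <= e["accuracy"] <= 1.0

    def test_dot_ablation_variant_available(self, noisy_letters):
        cfg = desk_profile(seed=0, epochs=1, max_length=64)
        entry = run_single(list(noisy_letters), "cnn", "SymptomsNoDot", cfg, seed=0)
        assert 0.0 <= entry["accuracy"] <= 1.0

    def test_failed_cell_recorded_and_grid_continues(self, noisy_letters):
        cfg = desk_profile(seed=0, epochs=1, max_length=64)
        rep = run_grid(list(noisy_letters), ["cnn", "no-such-arch"], ["Symptoms"],
                       cfg, n_seeds=1)
        assert any("error" in e for e in rep.entries)
        assert any("accuracy" in e for e in rep.entries)


class TestCheckpoint:
    def test_round_trip_exact(self, tmp_path, separable_letters):
        from lettertriage.checkpoint import load_checkpoint, save_checkpoint
        data = _variant_data(separable_letters)
        cfg = desk_profile(seed=6, epochs=1, max_length=64)
        model = build_model("hybrid", [t for t, _ in data], cfg, seed=6)
        train(model, data, cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(model, cfg, path)
        clone, cfg2 = load_checkpoint(path)
        assert cfg2 == cfg
        assert clone.fusion == model.fusion
        for a, b in zip(model.parameters(), clone.parameters()):
            assert np.array_equal(a.data, b.data)
        p1 = model.hybrid_forward("sudden onset headache")[2].probs
        p2 = clone.hybrid_forward("sudden onset headache")[2].probs
        assert np.array_equal(p1, p2)
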