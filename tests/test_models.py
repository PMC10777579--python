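"""Branch forward passes, loss fusion, the alpha recurrence, and the
structural contracts that distinguish hybrid from sequential."""

import math

import numpy as np
import pytest

import lettertriage as lt
from lettertriage import nn
from lettertriage.autograd import Tensor
from lettertriage.encoding import WordPieceTokenizer
from lettertriage.models import (ClassProbabilities, _probs_from_logits,
                                 cross_entropy)


@pytest.fixture(scope="module")
def tiny_hybrid(separable_letters):
    texts = [l.complaint for l in separable_letters]
    tok = WordPieceTokenizer.train(texts, vocab_size=400)
    vocab = sorted({t for text in texts
                    for t in lt.whitespace_tokenize(text, 128, pad=False).tokens})
    table = lt.random_table(vocab, d=16, seed=0)
    return lt.HybridModel(tok, table, encoder_hidden=16, encoder_ff=32,
                          max_length=64, seed=0).eval()


class TestClassProbabilities:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ClassProbabilities(probs=np.array([0.5, 0.5, 0.5, 0.5]),
                               logits=np.zeros(4))

    def test_uniform_under_equal_logits(self):
        cp = _probs_from_logits(np.zeros(4))
        assert np.allclose(cp.probs, 0.25)


class TestCnnBranch:
    def test_conv_map_lengths_and_pooled_dim(self):
        head = nn.TextConvHead(in_channels=300, n_classes=4,
                               rng=np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).normal(size=(1, 10, 300)))
        maps = head.conv_maps(x)
        assert [m.shape[1] for m in maps] == [9, 8, 7]
        assert head.pooled_dim == 6

    def test_zero_head_gives_uniform_probs(self):
        head = nn.TextConvHead(in_channels=8, n_classes=4,
                               rng=np.random.default_rng(0), dropout=0.0)
        head.head.weight.data[:] = 0.0
        head.head.bias.data[:] = 0.0
        logits = head(Tensor(np.random.default_rng(2).normal(size=(1, 10, 8))),
                      attention_mask=np.ones((1, 10)))
        assert np.allclose(_probs_from_logits(logits.data[0]).probs, 0.25)

    def test_padding_cannot_win_the_maxpool(self):
        rng = np.random.default_rng(3)
        head = nn.TextConvHead(in_channels=4, n_classes=4, rng=rng, dropout=0.0)
        x = rng.normal(size=(1, 6, 4))
        mask = np.ones((1, 6))
        base = head(Tensor(x), attention_mask=mask).data
        x_padded = np.concatenate([x, np.zeros((1, 4, 4))], axis=1)
        mask_padded = np.concatenate([mask, np.zeros((1, 4))], axis=1)
        padded = head(Tensor(x_padded), attention_mask=mask_padded).data
        assert np.allclose(base, padded)

    def test_short_sequence_padded_up_with_warning(self, tiny_hybrid, caplog):
        import logging
        ids = np.array([[1, 2]])
        mask = np.ones((1, 2))
        with caplog.at_level(logging.WARNING):
            out = tiny_hybrid.cnn_branch(ids, mask)
        assert out.data.shape == (1, 4)
        assert any("padding" in r.message for r in caplog.records)


class TestCrossEntropy:
    def test_uniform_is_ln4(self):
        cp = _probs_from_logits(np.zeros(4))
        assert cross_entropy(cp, 2) == pytest.approx(math.log(4), abs=1e-12)

    def test_certain_prediction_is_zero(self):
        cp = ClassProbabilities(probs=np.array([0.0, 1.0, 0.0, 0.0]),
                                logits=np.array([-1e9, 0.0, -1e9, -1e9]))
        assert cross_entropy(cp, 1) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation(self):
        logits = np.array([2.0, 0.0, 0.0, 0.0])
        cp = _probs_from_logits(logits)
        direct = -math.log(math.exp(2.0) / sum(math.exp(v) for v in logits))
        assert cross_entropy(cp, 0) == pytest.approx(direct, abs=1e-12)

    def test_batch_reduction_is_mean(self):
        logits = Tensor(np.array([[2.0, 0, 0, 0], [0, 3.0, 0, 0]]))
        y = np.array([0, 1])
        per = [cross_entropy(_probs_from_logits(logits.data[i]), y[i])
               for i in range(2)]
        assert float(nn.cross_entropy(logits, y).data) == \
            pytest.approx(np.mean(per), abs=1e-12)


class TestFusion:
    def test_fused_value(self):
        fs = lt.FusionState(alpha=0.3)
        assert lt.fuse_losses((1.0, 2.0), fs) == pytest.approx(1.7, abs=1e-12)

    @pytest.mark.parametrize("alpha,expected", [(0.0, 2.0), (1.0, 1.0)])
    def test_endpoints_return_single_branch(self, alpha, expected):
        fs = lt.FusionState(alpha=alpha, clamp_bounds=(0.0, 1.0))
        assert lt.fuse_losses((1.0, 2.0), fs) == expected

    def test_affine_in_alpha_with_slope_loss_gap(self):
        lc, la = 0.9, 0.5
        f = lambda a: lt.fuse_losses((lc, la),
                                     lt.FusionState(alpha=a, clamp_bounds=(0, 1)))
        slope = (f(0.6) - f(0.4)) / 0.2
        assert slope == pytest.approx(lc - la, abs=1e-12)


class TestAlphaUpdate:
    def test_single_step_value(self):
        fs = lt.FusionState(alpha=0.3, alpha_lr=1e-5)
        out = lt.update_alpha(fs, (0.9, 0.5))
        assert out.alpha == pytest.approx(0.2999988, abs=1e-12)
        assert out.step == 1

    def test_equal_losses_fixed_point(self):
        fs = lt.FusionState(alpha=0.3)
        assert lt.update_alpha(fs, (1.3, 1.3)).alpha == 0.3

    def test_matches_geometric_closed_form(self):
        gap, lr, a0 = 0.4, 1e-5, 0.3
        fs = lt.FusionState(alpha=a0, alpha_lr=lr)
        for _ in range(1000):
            fs = lt.update_alpha(fs, (1.0, 1.0 - gap))
        closed = a0 * (1.0 - gap * lr) ** 1000
        assert fs.alpha == pytest.approx(closed, abs=1e-10)
        assert fs.step == 1000

    def test_non_finite_losses_leave_state_unchanged(self):
        fs = lt.FusionState(alpha=0.3)
        assert lt.update_alpha(fs, (float("nan"), 1.0)) is fs

    def test_clamping(self):
        fs = lt.FusionState(alpha=0.02, alpha_lr=0.5, clamp_bounds=(0.01, 0.99))
        out = lt.update_alpha(fs, (5.0, 0.0))  # large gap pushes alpha down
        assert out.alpha == 0.01

    def test_alpha_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            lt.FusionState(alpha=0.0)


class TestHybridForward:
    def test_probabilities_are_valid_and_convex(self, tiny_hybrid):
        attn, cnn, combined = tiny_hybrid.hybrid_forward("sudden onset headache")
        for cp in (attn, cnn, combined):
            assert cp.probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(cp.probs >= 0)
        a = tiny_hybrid.fusion.alpha
        assert np.allclose(combined.probs, a * cnn.probs + (1 - a) * attn.probs)

    def test_alpha_zero_returns_attention_probs(self):
        attn = _probs_from_logits(np.array([3.0, 0, 0, 0]))
        cnn = _probs_from_logits(np.array([0, 3.0, 0, 0]))
        out = lt.combine_probabilities(attn, cnn, alpha=0.0)
        assert np.allclose(out.probs, attn.probs)

    def test_convex_combination_example(self):
        cnn = ClassProbabilities(np.array([1.0, 0, 0, 0]),
                                 np.array([0.0, -1e9, -1e9, -1e9]))
        attn = ClassProbabilities(np.array([0, 1.0, 0, 0]),
                                  np.array([-1e9, 0.0, -1e9, -1e9]))
        out = lt.combine_probabilities(attn, cnn, alpha=0.3)
        assert np.allclose(out.probs, [0.3, 0.7, 0.0, 0.0])

    def test_forward_is_deterministic_in_eval(self, tiny_hybrid):
        a1 = tiny_hybrid.hybrid_forward("dizziness and diplopia")
        a2 = tiny_hybrid.hybrid_forward("dizziness and diplopia")
        assert np.array_equal(a1[2].probs, a2[2].probs)


class TestGradientIsolation:
    def test_branch_losses_do_not_cross(self, tiny_hybrid):
        model = tiny_hybrid
        model.eval()  # disable dropout for exact replay
        enc = model.encode("headache and dizziness but never diplopia")
        y = np.array([1])
        attn_params = model.attn_branch.parameters()
        cnn_params = model.cnn_branch.parameters()

        model.zero_grad()
        a_logits, c_logits = model.forward_logits(enc)
        nn.cross_entropy(c_logits, y).backward()
        assert all(p.grad is None for p in attn_params)
        assert any(p.grad is not None and np.any(p.grad != 0) for p in cnn_params)

        model.zero_grad()
        a_logits, c_logits = model.forward_logits(enc)
        nn.cross_entropy(a_logits, y).backward()
        assert all(p.grad is None for p in cnn_params)
        assert any(p.grad is not None and np.any(p.grad != 0) for p in attn_params)


@pytest.fixture(scope="module")
def seq_model(separable_letters):
    texts = [l.complaint for l in separable_letters]
    tok = WordPieceTokenizer.train(texts, vocab_size=300)
    return lt.SequentialModel(tok, encoder_hidden=32, encoder_ff=32,
                              max_length=32, seed=0).eval()


class TestSequentialModel:
    def test_conv_over_encoder_states_keeps_shape_rule(self, seq_model):
        x = Tensor(np.random.default_rng(0).normal(size=(1, 10, 32)))
        maps = seq_model.conv.conv_maps(x)
        assert [m.shape[1] for m in maps] == [9, 8, 7]
        assert seq_model.conv.pooled_dim == 6

    def test_probabilities_valid(self, seq_model):
        cp = seq_model.sequential_forward("headache after falling down")
        assert cp.probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_fusion_state(self, seq_model):
        assert not hasattr(seq_model, "fusion")
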