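"""The adaptive loss-fusion weight alpha and its rule-based recurrence.

The hybrid trains on  alpha * loss_cnn + (1 - alpha) * loss_attn,  and after
each step moves alpha by  alpha <- alpha - (loss_cnn - loss_attn) * lr * alpha.
Under a constant loss gap this is a geometric recurrence with the closed form
alpha_m = alpha_0 * (1 - gap * lr)^m, which the iteration reproduces exactly.
"""

import lettertriage as lt

fs = lt.FusionState(alpha=0.3, alpha_lr=1e-5)
print(f"fused loss at alpha=0.3 with (loss_cnn, loss_attn)=(1.0, 2.0): "
      f"{lt.fuse_losses((1.0, 2.0), fs)}")

stepped = lt.update_alpha(fs, (0.9, 0.5))
print(f"alpha after one update with losses (0.9, 0.5): {stepped.alpha}")
print("  (the CNN branch is doing worse, so its weight shrinks)")

gap, steps = 0.4, 1000
state = lt.FusionState(alpha=0.3, alpha_lr=1e-5)
for _ in range(steps):
    state = lt.update_alpha(state, (1.0, 1.0 - gap))
closed = 0.3 * (1.0 - gap * state.alpha_lr) ** steps
print(f"\nafter {steps} steps with a constant gap of {gap}:")
print(f"  iterated alpha   = {state.alpha:.12f}")
print(f"  closed-form alpha = {closed:.12f}")
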