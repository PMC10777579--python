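# Methods

## Task and model

The task is single-label classification of a GP referral letter's free-text
complaint into one of four neurological ICD codes (G40, R51, M54, I63).
The classifier is a two-branch hybrid:

- **Attention branch.** A transformer encoder over subword ids. The final
  hidden state at the first position (the start special `[CLS]`) is the
  text summary `H`; logits are `Linear(H)` to 4 outputs and probabilities
  are a standard 4-way softmax. A "sigmoid in the softmax layer" reading is
  deliberately not used: the task is single-label multi-class and the
  cross-entropy loss requires a normalised distribution.
- **CNN branch.** Whitespace/word tokens looked up in a *frozen* embedding
  table (static vectors), then three 1-D convolutions over time with kernel
  widths 2, 3, 4 and two filters each. For input length `m` and kernel `k`
  the valid feature map has length `m − k + 1`; ReLU is applied, each
  filter is max-pooled over time (pad-covering windows are masked to a
  large negative value first, so padding can never win the max), the six
  pooled values are concatenated, passed through dropout and one linear
  layer to 4 logits. No hidden layer sits between pooling and logits.

Both branches compute a cross-entropy loss on the same label. Training
minimises the convex fusion

    L = α · L_cnn + (1 − α) · L_attn

and after each optimisation step α follows the rule-based recurrence

    α ← clamp( α − (L_cnn − L_attn) · lr_α · α ).

α receives no gradient and is the branches' only coupling; gradients of
either branch loss with respect to the other branch's parameters are
exactly zero (asserted numerically in the tests). Under a constant loss gap
`d` the recurrence has the closed form `α_m = α₀ (1 − d·lr_α)^m`, which the
implementation reproduces to 1e-10 over 1000 steps.

Design choices where the construction was genuinely open:

- **α update granularity**: once per mini-batch step using that batch's
  mean losses (a per-epoch mode is available). A step counter indexes the
  updates; it is distinct from the text-length symbol.
- **Clamping**: α is clamped to [0.01, 0.99]. The raw recurrence can leave
  [0, 1] under a large persistent gap, which would break the convexity of
  both the fused loss and the inference rule. Bounds are configurable and
  clamping events are logged.
- **Inference rule**: class probabilities are combined as
  `α · p_cnn + (1 − α) · p_attn`, mirroring the loss weights; attention-only
  and CNN-only rules are selectable for ablation.
- **Dropout placement** (p = 0.5): on the pooled CNN feature and on `H`,
  immediately before each linear head.
- **One optimiser** (Adam, standard moment defaults) over all trainable
  parameters of both branches.
- **H** is the raw first-position hidden state; no pooler transform.

The **sequential baseline** chains the encoder's full per-token hidden-state
matrix into the same conv/pool/linear head (conv input channels = encoder
hidden size) and trains end-to-end with a single cross-entropy — no α
anywhere. It contrasts one representation space against the hybrid's two.

## Numerical substrate

All networks run on a small reverse-mode automatic-differentiation engine
over numpy float64 arrays written for this package (`autograd.py`), with
the transformer, convolution head, Adam and losses built on it (`nn.py`).
Cross-entropy is computed through a log-sum-exp with a constant shift, so
zero probabilities never reach a bare `log`. Max-pool routes gradient to
the first argmax. Every layer's gradients are validated against central
finite differences in the test suite. Batches are trimmed to their longest
real sequence before the forward pass; padding is masked out of attention
and pooling, so trimming changes no output, only cost.

## Preprocessing

1. **Cleaning** removes the junk tokens `$$ ** Å ?? XXX` and a configurable
   greeting list (shipped defaults include "dear dr", "yours sincerely", …)
   case-insensitively by character matching, collapses whitespace, and
   strips punctuation orphaned at the very start of the text. Because a
   junk token can split a greeting phrase, the pass iterates to a fixpoint;
   cleaning is therefore idempotent.
2. **Extraction** is a deterministic longest-match, case-insensitive,
   non-overlapping lexicon matcher with a NegEx-style rule: a mention is
   negated iff one of `no, not, denies, without, never` (with `did not`
   covered by `not`) occurs within the five tokens before the match, not
   crossing `.` `;` `?` `!`. The extractor sits behind a plain
   list-of-entries interface (TSV: surface, canonical, class hint) so a
   service-backed annotator could replace it.
3. **Dot separating** emits lower-cased canonical headwords joined by
   `". "` with a trailing `"."`; an empty positive set yields the
   placeholder `[NOSYM]`. Canonical forms are emitted (not surface forms)
   so that splitting on the dot exactly recovers the positive phrase
   sequence; lexicon headwords must therefore contain no dots.
4. **Integration** is `cleaned + " [SEP] " + symptoms`, complaint first.

## Synthetic corpus

Real referral letters cannot be shipped, so the generator emulates their
statistical skeleton. Each letter is greeting + demographics + shuffled
clinical middle + closing. The middle contains, per letter:

- 3 class-indicative symptom phrases from the letter's own class lexicon
  (disjoint across classes; ≥ 6 phrases per class, drawn from published
  example letters);
- each such phrase is independently *paraphrased* with probability 0.3
  into class-indicative wording the lexicon cannot match ("tunnel vision" →
  "constricted peripheral fields"). This emulates imperfect extractor
  recall (clinical annotators miss reworded symptoms; recall around 0.7 is
  typical), which is precisely why integrating the complaint adds value
  over symptoms alone;
- one *context-cue* sentence (medication/investigation, e.g. Carbamazepine
  for the epilepsy class) carrying class signal no symptom lexicon lists;
- 1 negated off-class phrase inside a trigger template ("She denies …") —
  triggers match the extractor's set so every planted negation is
  detectable;
- shared distractor phrases (MRI scan, blood test, …) each with
  probability 0.3; junk tokens inserted as standalone tokens at rate 0.05.

Defaults: 64 letters per class, balanced. All draws come from one seeded
generator; identical configs give byte-identical corpora. With every noise
source off (junk, distractors, negations, paraphrases) a brute-force
lexicon-overlap oracle recovers 100 % of labels — the separability anchor
the learnability test builds on.

What the synthetic corpus does **not** emulate: real clinical grammar and
vocabulary breadth, class imbalance (the clinical setting had 79/65/59/58
letters per class), inter-annotator label noise, and symptoms shared
between diseases. Passing tests therefore demonstrate that the machinery
is correct and that the integration signal behaves as designed — not
clinical-grade accuracy.

## Training protocol

Stratified 7:2:1 train/validation/test split by largest-remainder
apportionment per class (remainder ties go to the smaller-share part, so
the test part is never starved); deterministic in the seed. The metric is
classification accuracy; argmax ties break to the lowest class index. The
final-epoch model is evaluated (no early stopping); best-validation
checkpointing exists but is off by default.

Two shipped profiles:

| parameter | paper-scale | desk-scale |
|---|---|---|
| batch size | 8 | 8 |
| Adam lr | 1e-6 | 1e-3 |
| epochs | 200 | 50 |
| dropout | 0.5 | 0.5 |
| embedding dim (CNN) | 300 | 300 |
| α₀ / lr_α | 0.3 / 1e-5 | 0.3 / 1e-5 |
| max tokens | 256 | 128 |
| encoder | pluggable pretrained-scale (hidden 768) | tiny (hidden 32, 2 layers, 2 heads, ff 64) |

The desk profile is the package's own working scale for a single CPU: the
tiny word-piece encoder is trained on the corpus at hand, the CNN table is
a seeded random N(0, 1/√d) table (a word2vec-format loader is provided for
full-scale static vectors), and 128 tokens covers the longest synthetic
integration text so nothing is truncated. The experiment grid and the
acceptance script run 400-letter (learnability) and 256-letter (variant
comparison) corpora — sizes chosen so a full grid completes in minutes.

## Known limitations

- The attention encoder is desk-scale; nothing here speaks to the behaviour
  of full pretrained encoders beyond the shared interface.
- The negation rule is window-based; scope phenomena ("no change in his
  headaches") and coordination are out of scope, as are UMLS normalisation,
  spelling correction and non-English text.
- OOV handling at prediction time draws cached random vectors; two fresh
  processes agree only if they meet OOV types in the same order (tables
  serialised in checkpoints are exact).
- Accuracies measured on the synthetic corpus have test sets of a few dozen
  letters; single-seed differences of one letter (~4 points) are noise, and
  the variant comparison is therefore averaged over seeds.
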