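# Methods

## Model

The model maps an (image, question) pair to a distribution over a closed
answer vocabulary through five stages.

**Question representation.**  Text is lowercased, stripped of
punctuation, whitespace-tokenized, truncated and padded to a 14-position
buffer, embedded with a word table (GloVe text files are supported; the
toy configuration uses a seeded random table of width 16, trainable), and
passed through a single-layer LSTM whose hidden states form the word-level
feature set.  States at padded positions are zeroed; padding sits at the
end of the buffer, so widening the buffer never changes any downstream
value bit-for-bit (verified end to end).

**Image representation.**  Images are resized bilinearly to a square
canvas (448 px at full scale, 64 px in the toy configuration) and passed
to a pluggable extractor.  The bundled extractor is a deterministic grid
pooler: per-patch channel statistics (mean, min, max) over a g×g grid,
projected to d_v by a fixed seeded matrix.  The min/max statistics exist
so that a small high-contrast lesion remains visible in its patch's
feature vector even when it covers a minority of pixels; without them a
linear probe cannot recover spot color from the toy scenes at all, i.e.
no visual solution would exist for any model.  Any backbone emitting an
(n_v, d_v) array plugs in through the same interface; region-annotated
(prior-knowledge) records are pooled per bounding box instead.

**Co-attention.**  Standard scaled dot-product multi-head attention with
additive masking; "sparse" attention in the source architecture is
treated as dense attention with exact-zero masked weights, since no
sparsification rule is specified (open question).  Sublayers are wrapped
post-norm (residual add, then layer normalization), the arrangement of
the cited attention architecture; a pre-norm switch exists.  The encoder
is an L-deep SA stack over the visual set; the decoder alternates SA over
the question stream with GA guided by the encoder output X^(L)
(`wiring="encoder_decoder"`); a `stacked` wiring guides layer l by X^(l)
for ablations.  Defaults at full scale are L=6 (the depth at which
accuracy peaks in the source experiments), h=8, d_model=512, d_ff=2048;
the toy configuration uses L=2, h=4, d_model=32, d_ff=64.  Dropout
(default 0.1 full-scale, 0 in the deterministic toy) follows attention
and feed-forward sublayers.

Each attended set is reduced to a vector by mask-aware attentive pooling
(linear score, softmax over valid rows, weighted sum) — the reduction the
fusion stage needs but the source architecture leaves unstated.

**Fusion.**  Tucker-factored bilinear interaction with tanh-activated
factor projections (best-performing activation in the source ablation);
ranks default to 160 at full scale and 16 in the toy configuration, both
config-overridable — the exact ranks of the source experiments are not
published.  `concat`, `add`, `multiply`, and low-rank `mlb` baselines are
provided; the source's self-contradictory "concatenation, which refers to
a simple addition" is resolved by implementing both and naming them
honestly.

**Bias balancing.**  The branch applies a two-layer perceptron to the
mask-aware mean of the (detached) LSTM word features, giving r ∈ R^{|A|};
the mask is σ(r)², clipped into the open unit interval against float
saturation; the branch classifier is a linear |A|→|A| map.  The mask
multiplies the main logits during training (`mask_on="logits"`;
multiplying post-sigmoid probabilities is implemented behind the flag —
the source's "prediction" is ambiguous).  The joint loss is the
unweighted sum of the masked main binary cross-entropy (soft targets) and
the branch's softmax cross-entropy (hard target).  The gradient barrier
(a graph detach) guarantees exactly-zero branch-loss gradients on every
question-encoder parameter; the branch classifier receives gradient only
from the branch loss.  Both facts are asserted by
`gradient_partition_check` at runtime.  Inference uses the raw main
logits; `strip-branch` exports an inference-only checkpoint without the
branch parameters.

Soft answer targets score each in-vocabulary candidate answer by the
maximum of its confidence values, "yes" → 1.0 and "maybe" → 0.5 — the
confidence-to-score map is a convention adapted from the large VQA
benchmarks, config-overridable.

## Training

No deep-learning framework is a dependency; `cropvqa.autodiff` is a
compact reverse-mode engine over float64 numpy arrays with fused
masked-softmax and layer-norm primitives, verified against finite
differences.  Training uses AdamW (lr 1e-3, weight decay 0 by default;
the reference experiments use 1e-2, which at this scale curbs the logit
drift that masked BCE otherwise induces where mask entries are small).
Because the visual stream is question-independent and questions are
templated, batches carry unique image features and unique token rows with
inverse maps; the gathered result is bit-identical to row-by-row
encoding and roughly 3× faster.  A fixed seed yields bit-identical runs
on one thread.

## Evaluation

Plain accuracy per category (yes/no, number, other), with yes/no counted
as a binary confusion matrix and other categories as TP/FP; overall
accuracy is the question-weighted mean.  A prediction is correct iff its
normalized string equals one of the record's confident ("yes") answers;
`include_maybe=True` widens the gold set to all ten candidates.  The
answer-type "color" is folded into the "other" evaluation category.

## Augmentation protocol

Gaussian noise at σ² ∈ {0.1, 0.01} (the raw field is exactly N(0, σ²);
the displayed image is clipped to [0, 1], truncating tails); multiscale
Retinex with scales {15, 80, 250} and equal weights — MSRCR with the
α=125 / β=0.35 color-restoration factor and a mean±2σ output stretch,
MSRCP on the intensity channel with a per-pixel scalar rescale that
preserves R:G:B ratios exactly; rotation uniform in [60°, 120°] with
reflection padding; text lowercasing, punctuation removal, and
table-driven keyword substitution/deletion.  All operations are
label-preserving, derive fresh record ids, log provenance, and are
deterministic given the plan seed.  The unspecified "sampling method" for
question generation is implemented as stratified oversampling with
replacement (an interpretation).

## Synthetic corpus

Scenes are 64×64 renders of one fruit (circle or ellipse; red, green or
yellow) carrying 0–5 non-overlapping disease spots (brown, purple, blue,
yellow or red; small or large).  Spot radii (4/6 px) are sized so a spot
dominates at least one 8×8 extractor patch, and placement draws without
replacement from a seeded lattice of admissible centers, so rendering is
deterministic and non-overlap is guaranteed by construction.  Six
question templates cover the three evaluation categories: disease status
(yes/no), spot count (number), fruit shape, fruit color, spot color and
spot size (other).  Ground truth is read from the scene specification, so
model accuracy is exact.  Each question carries ten confidence-labeled
candidates: the truth repeated with "yes" plus two same-domain
distractors with "maybe" (more distractors inject additional 0.5-target
noise that measurably slows answer discrimination at this scale).

The bias control: with strength β (default 0.9, matching the documented
nine-to-one skew of real spot-color questions), training scenes draw the
spot color "brown" with probability β; test scenes draw from the
normalized complementary prior, so the training shortcut actively
misleads at test time.  A question-only classifier scores ≈β on biased
training questions and ≈(1−β)/(k−1) on the anti-biased test — the
signature the corpus must exhibit, and does (verified by binomial-bound
tests and by the trained branch itself).

What the toy corpus does not emulate: photographic texture, illumination
variation, the 19 real disease classes, label noise, and open-ended
answer vocabularies.  Passing tests show the pipeline's mechanics and the
bias structure are correct; they do not predict field accuracy.

## The bias-recovery experiment, and a negative finding

`run_bias_recovery` trains matched models (L=2, d_model=32, ~1000
training triples, 30 epochs, batch 64, AdamW lr 1e-3 / decay 1e-2 — sizes
chosen so three seeded replicates of both arms complete in minutes) with
and without the branch and scores both on the anti-biased test split.

Two results are robust across seeds and configurations.  First, the
question-only branch captures the bias exactly as designed: ≈0.9 accuracy
on biased training templates, near chance on the anti-biased test.
Second — a negative finding this package reports rather than hides — the
mask-trained model does *not* surpass the identical plain model on
anti-biased test accuracy at this scale.  The reason is visible in the
loss: multiplying per-answer BCE logits by a mask in (0,1) scales every
answer's gradient by m² and makes hard 0/1 targets unreachable wherever
the mask is small, so masked training converges uniformly more slowly;
and because per-answer BCE decouples answers, the language shortcut never
blocks visual learning in the plain model — there is no shortcut basin to
escape, which is the regime where multiplicative debiasing earns its
advantage at benchmark scale.  The desk-scale experiment therefore
demonstrates the bias signature and the branch's capture of it, but not
the end-to-end accuracy gain documented at full scale; both arms'
accuracies are reported as measured.

## Numerical choices

Float64 throughout; −∞ masking realized as a −1e30 additive offset plus
an exact-zero multiplicative mask after the exponential; softmax and BCE
use max-subtraction / softplus stable forms; σ(r)² is clipped to the open
unit interval at the float boundary; attention over an all-masked key set
and pooling over an all-invalid set are rejected as degenerate inputs;
ties in argmax resolve to the lowest vocabulary index (numpy convention).
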