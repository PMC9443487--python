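# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the
numerical decisions a user should know before trusting or extending the
package.

## Dynamics and training graph

Neurons are discrete-time leaky integrate-and-fire with hard reset:
`h[k+1] = h[k]·λ·(1−o[k]) + I[k+1]`, `o[k] = H(h[k] − V_th)`. The
multiplicative reset implies a reset potential of zero, which is how the
continuous-time reset parameter is fixed; membrane resistance is absorbed
into the synaptic weights. `H(0) = 1` by convention — immaterial in
floating point, fixed for determinism. The spike derivative is replaced by
a rectangular window `(1/2a)·1[|h−V_th| < a]`, half-width `a = 0.5`
(configurable). λ is stored as an unconstrained scalar through a logistic
squash so it stays in (0,1); V_th is stored directly with a positivity
floor of 1e−3. Both are per-layer, learnable by default, frozen at
λ = 0.5, V_th = 0.5 when the `learnable` ablation switch is off.

The whole K-step closed loop — gating, encoding, extraction,
classification, map generation — is one differentiable graph; no gradient
is stopped at the map boundary, so the attack and the trainer both see the
feedback path. The package ships its own reverse-mode tape on NumPy
(`htda.autodiff`): the op set (broadcast arithmetic, matmul, im2col
convolution and transposed convolution, average pooling, replicate
padding, the surrogate spike) is exactly what the model needs, in float64
throughout.

A hard step makes the true loss piecewise constant in any weight upstream
of a spike, so finite differences cannot validate surrogate gradients
directly. For verification the LIF cell offers a `ramp` spike mode — the
integrated surrogate `clip((x+a)/(2a), 0, 1)`, whose exact derivative is
the rectangular window. The gradient-integrity test runs the full unrolled
objective in ramp mode and matches the tape against central differences to
1e−5 relative error, away from the ramp kinks.

## Architecture defaults

Extractor: six 3×3 convolution stages, channel widths (x, x, 2x, 2x, 4x,
4x), 2×2 average pooling after stages 2, 4, 6. Classifier: flatten → 256
spiking hidden units → one spiking unit per class; the decoder acts on the
concatenated binary per-step outputs. Only the encoder consumes real
values; deeper layers consume (pooled) spikes. The classifier's output
layer spikes — its binary outputs are what the decoder concatenates.

Generator: taps the output of stage 5 (penultimate convolutional stage),
three transposed-convolution layers with channel taper c → c/2 → c/4 → 1
and ReLU between layers; stride-2 layers (kernel 4, padding 1) double the
resolution until input size is reached, stride-1 layers (kernel 3) refine.
Layer normalization over all elements of each map, ε = 1e−5, no learned
affine terms. The output layer's weights are initialized non-negative:
the feedback loop self-amplifies whichever orientation the first maps
favor, and a symmetric init makes "highlight the object" vs "highlight the
background" a coin flip per seed — starting the raw map positively
correlated with feature activity selects the intended basin. ε makes the
squash only approximately invariant to rescaling of the raw map (residual
~(T_e/4)·z·ε/(2·var)); tests use the ε-limited tolerance.

Map cadence (window w = T_f/T_d steps, default T_f = 2 T_d): static inputs
use the all-ones M_0 for steps 1..w, then a single generated M_1 shared by
all later steps (generated once, for efficiency); dynamic inputs use M_n
during window n+1, regenerated every window. The loss averages over the
maps actually generated; for static inputs that is one map, numerically
identical to counting the shared map once per window in the ⌊K·T_d/T_f⌋
formula.

## Objective

`L = α·L_C + (1−α)·L_M`, cross-entropy on the decoded Y only. The
attention penalty uses the post-sigmoid gates (the values that actually
modulate the encoder). High-pass kernel: the 4-neighbor Laplacian
[[0,1,0],[1,−4,1],[0,1,0]] with replicate boundary and same-size output —
chosen so any constant map is exactly smooth, keeping the all-ones
(= γ) and all-zeros (= 0) cases analytic. β = 0.40 and γ = 0.51
throughout. α is a per-dataset weight; the synthetic study uses α = 0.5
(see below).

## Training

Mini-batch SGD with momentum 0.9; learning rate ramps linearly from 10% of
its base value over the warm-up epochs (default 5), flat afterwards (a
cosine option exists, off by default). Weights are Kaiming-uniform
initialized; membrane states are zeroed for every inference, so runs are
bit-reproducible given a seed (which governs init, shuffling and data
generation). Temperature anneals linearly from 1 to 6 over 80% of the
epochs by default. Divergence (non-finite loss) aborts with the loss-term
breakdown. Defaults of batch 200 / lr 0.1 suit dataset-scale training;
the tiny synthetic study uses batch 100 / lr 0.01 / 3 warm-up epochs,
chosen by a small grid exactly as α was (lr ≥ 0.02 destabilizes the tiny
model mid-run; α ≤ 0.1 lets the map objective dominate before features
form, α = 0.9 trains accurately but leaves the maps underconstrained).

## Adversarial evaluation

PGD in L∞: uniform start in the ε-ball, 10 sign-gradient iterations, step
η = ε/4 for synthetic data, projection after *every* iteration onto the
ε-ball intersected with the valid input range — only per-iteration
projection makes the stated budget bound hold unconditionally. The
attacked loss is the classification term; gradients pass through map
generation and gating. Event data is attacked on the real-valued
accumulated frames (never re-binarized), with the valid interval set to
the frame range.

## Efficiency accounting

Firing rate = spikes / neurons, per layer per step, and pooled over all
layers and steps for the mean. MACs are event-driven: each active unit
entering a layer contributes its fan-out (kernel support truncated at
borders × downstream channels); after average pooling, a pooled position
counts as active if any contributing spike was. The dense convolution
count is defined border-aware (connected input/output position pairs), so
the activity-density-1 limit of the sparse estimate equals it exactly.
The encoder pass (real-valued input), one generator pass per generated
map, and the decoder are counted densely; an optional mode skips
exactly-zero encoder inputs. Accumulate-only operations are reported in
MAC units (single-unit tables), with the per-layer breakdown available.

## Synthetic data

Static scenes: a smooth textured background (Gaussian-filtered noise,
0.05–0.45) with one object whose mask covers 10–25% of pixels. In
`shape` mode the class is the silhouette (disk / cross / bar) with a bright
unstructured interior — mean object/background contrast ≥ 0.25. In
`texture` mode every class uses a disk silhouette and the class is the
orientation of a period-2 square-wave grating (0.15/0.95) filling the
object. The study uses texture labels because a silhouette label survives
zero-gating (a black cut-out is itself the class signature), which makes
an inverted map — suppress the object, keep the background — a legitimate
optimum of the weakly-supervised objective; texture labels restore the
premise that only the object's interior is informative. Softer gratings
(sinusoidal, periods 3–4) and thin silhouettes are below what the tiny
backbone learns in the study's epoch budget.

Event streams: a shape translating at constant velocity; pixels newly
covered emit ON events, newly uncovered OFF events, thinned by a Bernoulli
keep-probability, timestamps jittered within the rendering step and
sorted. Accumulation bins events into half-open [s·bin, (s+1)·bin)
windows as (steps, 2, H, W) counts, clipped to {0,1} by default.
Coordinates are 0-based, row-major, origin top-left.

What the generator does *not* emulate: natural image statistics (object
texture/background correlations, scale and clutter variation), sensor
noise physics, or dataset-scale class diversity. Passing the scaled-down
study shows the mechanism works end to end — that the weakly-supervised
objective recovers object-localized maps and that gating reduces firing —
not that the quantitative gains transfer to natural benchmarks.

## The scaled-down study

`htda.experiment.tiny_study_config()` freezes the conditions: x = 8
backbone on 16×16 grayscale scenes, 2 texture classes, K = 4, T_f = 2 T_d,
1500 training / 300 held-out scenes, 15 epochs, seeds {0, 1, 2}, PGD at
ε = 32/255. The acceptance tests train the attention model and the matched
attention-off baseline per seed and check: ≥95% training accuracy within
the epoch budget; object/background gate ratio ≥ 2 on held-out scenes;
strictly lower mean firing rate than the baseline; and robust accuracy at
the largest ε at least matching the baseline in ≥2 of 3 seeds. The full
six-run study takes roughly ten minutes on one CPU core.

## Known limitations

- float64 NumPy compute: fine at study scale, not meant for
  dataset-scale (VGG-128c) training.
- The generator tap point and architecture, pooling placement, classifier
  shape, warm-up length and epoch counts are documented defaults, not
  uniquely determined by the model statement.
- Middle-layer attention targets, soft reset, refractory periods,
  per-neuron thresholds and non-gradient attacks are out of scope.
- Batch statistics are not used anywhere (no batch norm); training
  stability therefore depends on the learning-rate choice, as the grid
  above reflects.
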