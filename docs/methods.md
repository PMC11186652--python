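# Methods

## The diagnostic problem

The corpus-predominant gastritis index (CGI) flags patients at elevated
gastric-cancer risk early enough for preventive *H. pylori* eradication.
Conventionally it requires biopsies of three gastric sections — antrum, body
(corpus) and cardia (high corpus) — graded under the updated Sydney system:
each section receives an acute inflammation score (AIS) and a chronic
inflammation score (CIS), both in {0, 1, 2, 3}.  The two grades are combined
into a per-section inflammation score IS, and the diagnosis compares the
antrum against the corpus sections:

```
CGI = 1   if IS_A < IS_B
CGI = 1   if IS_A <= IS_C and IS_C != 1
CGI = 0   otherwise
```

This package implements (i) that decision rule, (ii) GSCNet, a convolutional
network that predicts CGI directly from the three endoscopic images, and
(iii) a synthetic cohort simulator so the whole method can be trained and
verified without private clinical data.

### Decision-rule details

* **AIS/CIS combination.** The combination operator behind IS is not fixed by
  the clinical definition beyond "combine the two indexes".  The default is
  the arithmetic sum (IS in 0..6) — the simplest operator that reflects
  overall inflammation; `combine_is` also accepts a `max` strategy.
* **The all-zero profile.** Read literally, the rule labels a patient with no
  inflammation anywhere (IS_A = IS_B = IS_C = 0) CGI-positive, because
  0 <= 0 and 0 != 1.  The implementation is deliberately literal; the opt-in
  flag `require_corpus_inflammation=True` additionally requires
  max(IS_B, IS_C) > 0 for a positive call.  The flag is off by default so the
  printed rule and the code never silently diverge.
* Grades are validated strictly (no clamping): an out-of-range grade is an
  error naming the offending field, because silent repair would hide upstream
  data problems.

## GSCNet

### Scaling feature fusion (SFF)

Endoscopy images arrive at uncontrolled camera-to-mucosa distances and
viewing angles, so the effective field of view varies widely.  The SFF
module runs every section image through three *shared-weight* sub-networks
that trade spatial resolution for field of view at different depths:

| branch | stem | residual stages (stride) | total stride |
|--------|------|--------------------------|--------------|
| N_L | 7x7 conv s2 + 3x3 max-pool s2 | (1, 2, 2) | 16 |
| N_M | one pooling block (3x3 conv + max-pool, s2) | (2, 2, 2) | 16 |
| N_S | two pooling blocks (s4) | (2, 2) | 16 |

Each residual stage holds two basic blocks (3x3 conv, batch-norm, ReLU,
identity or 1x1-projected shortcut) at widths 64 -> 128 -> 256 under the
default `branch_channels=256` — the truncated 18-layer residual backbone with
its final stage removed so a 224x224 input yields 14x14 maps.  A
squeeze-and-excitation block (reduction 16, the block's customary default)
caps each branch.  All three branches end at stride 16 with equal width, so
their outputs concatenate per section; a shared 1x1 convolution projects the
3x256 concatenation back to 256 channels.  The published geometry — each
scaling fusion feature is 14x14 with 256 channels — holds by construction;
pure concatenation alone would give 768 channels, so the projection is this
implementation's resolution of that tension, applied identically to all
sections.

Weight sharing is structural, not a copy: the same parameter arrays process
all three sections (the implementation stacks the section batches and runs
each branch once).  A consequence worth noting: batch-norm statistics pool
over sections as well as patients, which is exactly what a shared backbone
implies.

Stage-count reading: "3 residual blocks" is implemented as three two-block
*stages* (and two stages for N_S); the single-unit reading cannot reach
stride 16 and 14x14 maps simultaneously with the stated stems.

### Section correlation (SC)

The clinical rule only ever compares the antrum against a corpus section, so
the SC module gives the antrum an anchor role rather than treating the three
sections symmetrically.  Three heads operate on channel concatenations of the
fused features — f^AB = {f^A, f^B}, f^AC = {f^A, f^C}, f^ABC = {f^A, f^B,
f^C} — each head being two 3x3 convolutions (widths 256 -> 128 by default),
global average pooling, two fully connected layers (128 -> 64) and a 2-way
softmax.  A fusion classifier c^F takes the concatenation of the three
64-wide penultimate activations (the only head tensors that are both compact
and pre-softmax) and produces the final prediction.  Head widths are free
parameters in the published design; the defaults keep head capacity below
backbone capacity.

### Losses

Training minimises the sum of four base-2 cross-entropies, one per head:
l = l_AB + l_AC + l_ABC + l_F.  Each component is the negative log2
probability of the *true* class: for y = 0 the term is -log2(1 - p) under
the 2-way softmax.  The positive-only form (a term only when y = 1) has a
degenerate all-positive minimiser and cannot express specificity, so the
two-sided form is used.  Probabilities are clamped at 1e-7 before the log;
the gradient is zero outside the clamp range, so degenerate outputs are
finite and stable.  Batch reduction defaults to the mean (a sum over the
full training set does not transfer to minibatches); `reduction="sum"` gives
the literal per-patient sum.  Dropping l_ABC (the `-labc` ablation variant)
leaves the other three intact.

### Training regime

Reference hyper-parameters: Adam, batch size 68, learning rate 1e-5, 1000
epochs, 224x224 inputs, with stochastic augmentation — random crop
(pad-resize to 1.14x then crop), colour jitter, random grayscale,
horizontal/vertical flips, right-angle rotations.  Augmentation draws are
independent per section image: the three views come from separate camera
positions, so coupling them has no physical motivation.  No schedule, weight
decay or class weighting.  Augmentation is seeded per (epoch, patient,
section), so training is bit-reproducible from the config seed.

`init_mode="pretrained-backbone"` loads branch weights from a user-supplied
`.npz` state file; the default is seeded random (He-normal) initialisation,
and all experiments in this repository use it.

## The numerical engine

The network runs on a compact NumPy reverse-mode autodiff engine
(`gscnet.nn`): tensors wrap `ndarray`s, each op installs an analytic
backward closure, and a topological sweep accumulates gradients.
Convolution is im2col + BLAS matmul; the memory-bound inner loops (column
gather/scatter, max-pool selection, batch-norm normalisation) are
numba-compiled.  Every layer's backward pass is validated against central
finite differences in float64 (`tests/test_nn.py`).  Parameters default to
float32 for throughput.  Max-pool ties resolve to the first (row-major)
maximum; Adam uses (0.9, 0.999, 1e-8).

## Synthetic cohorts

The simulator fabricates what the network must exploit, without pretending
photorealism:

* **Scores.** AIS/CIS grades are drawn from a categorical distribution
  (uniform by default).  `patient_correlation` couples a patient's six grades
  through a Gaussian copula with a shared latent propensity; 0 means
  independent.  Labels are *derived* from the sampled scores through the
  decision rule — never stored independently — so label/score inconsistency
  is impossible by construction.
* **Appearance.** Each section has a distinct base hue; severity raises the
  red channel by `severity_gain` (default 0.08) per IS unit, lowers green by
  half of that, and adds Poisson lesion speckles (`lesion_rate`, default 1.5
  per IS unit).  The opposed red/green shift keeps the severity signal in
  the red-green contrast, which survives the global illumination offset.
* **Nuisance.** Centre zoom-crop-resize with a factor uniform in [0.7, 1.3]
  (camera distance), rotation jitter of +/-15 degrees (viewing angle), a
  global illumination offset (sigma 0.05) and pixel noise (sigma 0.02),
  applied after the appearance stage.
* **Determinism.** Per-image seeds derive from (cohort seed, patient index,
  section) via `numpy.random.SeedSequence`, so cohorts are reproducible
  independent of generation order, and regeneration is byte-identical.

What this does *not* model: specular highlights, bubbles, biopsy artifacts,
peristalsis blur, inter-patient anatomy.  Passing tests therefore show the
architecture can learn cross-section severity comparisons under scale,
angle and illumination nuisance — not clinical performance on real
endoscopy.

## Experiment presets and problem sizes

All training defaults above describe the reference regime; the repository's
own experiments run a CPU-sized preset (`gscnet.presets`), chosen once as
the package's benchmark conditions:

* **Learning preset** — 240 training / 80 test patients, uniform grades,
  independent sections, severity gain 0.08, full nuisance, 64x64 images,
  width-reduced model (stages 16/32/64, fusion 64), Adam at 5e-4, batch 32,
  20 epochs with the full augmentation set.  Augmentation matters beyond
  fidelity to the training recipe: without it the model can memorise a
  cohort this small and held-out AUC decays as training proceeds; with it
  the held-out plateau is flat and seed-robust.  A trained run is expected
  to exceed 0.90 held-out accuracy and 0.95 AUC; at this gain the Bayes
  rate is near 1, and as `severity_gain -> 0` any classifier degrades to
  the majority-class rate.
* **Ablation preset** — 96 / 48 patients with section-correlated labels
  (`patient_correlation=0.8`), 20 epochs at the same rate, a further
  width-reduced model (stages 8/16/32), used for paired variant-vs-variant
  runs (median over seeds 0/1/2).

The learning rate is far above the clinical regime's 1e-5 because the models
and images are an order of magnitude smaller (1e-5 would not converge within
the preset's schedule), and 5e-4 rather than 1e-3 because the hotter rate
makes late training oscillate (held-out accuracy swinging 0.85-0.95 between
adjacent epochs) while 5e-4 settles into a stable plateau.  The same rate is
used for the ablation preset deliberately: paired comparisons at an unstable
or under-converged operating point measure optimisation speed, not
architecture — the single-head `-SC` variant optimises faster than the
four-loss network early on, so short or hot runs systematically favour it.

## Ablation semantics

* `-SFF`: only the large-field-of-view branch N_L remains (single scale).
* `-CA`: squeeze-and-excitation replaced by identity.
* `-SC`: a single head on f^ABC with one loss; no pairwise heads, no fusion
  classifier.
* `-labc`: full architecture, third correlation loss dropped.

Undefined metrics (zero denominators, single-class truth for AUC) propagate
as explicit `None` markers so ablation tables cannot silently absorb them as
zeros.

## Known limitations

* The advantage of the pairwise correlation heads over a single
  three-section head is small at these cohort sizes, and depends on the
  sections being correlated: with independent section severities the AB/AC
  heads are supervised toward a label that depends on a section they cannot
  see, so their losses carry irreducible error and can act as gradient
  noise on the shared backbone.  Clinically, gastric inflammation is
  strongly stomach-wide, which is the regime the design targets.
* The synthetic severity signal is low-frequency and colour-dominated;
  texture-dominated pathology would stress the multi-scale design
  differently.
* Training at the published scale (224px, 1000 epochs) is supported by the
  code but not exercised by the test suite; the presets above are the tested
  envelope.
* The engine is single-device and keeps whole batches of activations in
  memory; batch size is the only memory lever.
* Reproducibility is bit-exact on a fixed BLAS/numba stack; across different
  BLAS builds, reductions may reorder and results can differ in the last few
  ulps.
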