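# Methods

## Problem and model

A nodule found on a baseline screening LDCT is often indeterminate; its
behaviour over the next year (growth vs stability) carries most of the
malignancy signal. The package's core is a growth-predictive Wasserstein GAN
(GP-WGAN): a predictor network G maps the baseline ROI patch X (64×64
pixels, 32 mm at 0.5 mm/pixel, intensities in [0, 1]) to a predicted
follow-up patch GX, trained against the real follow-up XF about 12 months
later; a critic D scores patches with an unbounded real value.

Generator objective (weighted sum of four terms, each also reported
unweighted):

    LG = λ1·L1(GX, XF) + λ2·(1 − SSIM(GX, XF)) + λ3·L_LP(GX, XF) + λ4·(−E[D(GX)])

* **L1** — mean absolute pixel error, the workhorse of image-to-image
  translation.
* **SSIM loss** — windowed structural similarity (11×11 Gaussian window,
  σ = 1.5, K1 = 0.01, K2 = 0.03, dynamic range 1.0), implemented
  differentiably on the package's autodiff engine and cross-checked against
  `skimage.metrics.structural_similarity` to machine precision.
* **Learned perceptual loss** — mean squared distance between
  channel-normalized feature maps of a frozen two-stage ResNet-style
  extractor, summed over stages. The extractor is randomly initialized from
  a fixed seed and never trained: no pretrained weights are shipped or
  downloaded, runs are fully reproducible offline, and fixed random
  extractors are a known-serviceable basis for perceptual distances. The
  extractor seed is recorded in the run manifest.
* **Adversarial term** — the generator maximizes the critic's score on its
  outputs.

Critic objective, Wasserstein distance with gradient penalty on interpolated
images x̂ = t·XF + (1 − t)·GX, t ~ Unif(0, 1), one t per pair:

    LD = E[D(GX)] − E[D(XF)] + λD · E[(‖∇x̂ D(x̂)‖₂ − 1)²]

`discriminator_loss` also exposes the mirrored sign convention
(`sign_convention="printed"`, LD = −E[D(GX)] + E[D(XF)] + penalty). Under
that convention the critic and the generator both push D(GX) upward — they
cooperate instead of compete — so the trainer defaults to the standard form
above; the switch exists for inspecting both conventions.

Defaults: λ1 = 100, λ2 = 10, λ3 = 1, λ4 = 1 (L1-dominant weighting, the
usual image-translation choice), λD = 10, n_critic = 5, Adam with learning
rate 2·10⁻⁴ and momentum parameters (0, 0.9), batch size 8. The learning
rate follows common image-to-image translation practice so that the
200-step smoke profile trains to a useful model on one CPU.

## Architectures

**Predictor** — encoder–decoder with skip connections at three resolution
levels (64→32→16 px), base width 16 channels doubling per level, instance
normalization, leaky-ReLU encoder / ReLU decoder, nearest-neighbour
upsampling + convolution in the decoder. The output is residual in logit
space: out = sigmoid(logit(X) + Δ) with the final convolution
zero-initialized, so the untrained model is exactly the identity map and
training only has to learn the baseline→follow-up change. This matches the
problem structure (the benign majority is stable) and keeps the output in
(0, 1). A `residual=False` switch restores a plain sigmoid decoder. The
model size is a deliberate CPU-scale choice; widths and depth are
configurable.

**Critic** — five stride-2 convolutions (16→256 channels), leaky ReLU, no
normalization layers (batch-type normalization interacts badly with the
per-sample gradient penalty), and a final linear head giving one unbounded
score per patch.

**Gradient penalty without second-order autodiff.** The engine
(`nodulegp.tensor`) is first-order only. Because the critic is piecewise
linear (convolutions, leaky ReLU, linear head), ∇x̂ D(x̂) can be written as
an explicit transpose pass — transposed convolutions of the critic's own
weights with the forward activation masks held constant. That pass is built
as a differentiable graph, so backpropagating the penalty yields its
parameter gradients exactly (almost everywhere; the mask-derivative terms
vanish a.e.). Tests verify (a) the transpose-pass input gradient equals the
ordinary backprop input gradient bitwise, and (b) dLD/dθ including the
penalty matches central finite differences.

**Training schedule.** Each iteration draws one minibatch, takes `n_critic`
critic steps against the current detached predictions, then one generator
step; per-term losses are recorded every iteration. One master seed fans out
via a splitmix64-style hash to independent streams (parameter init, batch
order, t samples), making runs bit-reproducible on a fixed platform. At
deployment only the frozen predictor is used; `predict_followup` refuses
unfrozen models.

## Synthetic data generator

The simulator emulates the longitudinal structure the model is meant to
learn, at the cohort proportions of an NLST-style screening population.

* **Growth law.** Malignant nodules grow as d(t) = d₀·2^(t_days/(3·VDT)),
  the diameter form of exponential volume doubling; VDT is log-uniform on
  [180, 1460] days ("six months to several years"). Benign nodules are
  exactly stable by default (a config switch adds ±10% follow-up jitter).
  Months convert to days at 365.25/12. Diameters beyond 30 mm are clipped
  and flagged.
* **Baseline size.** Truncated lognormal on [4, 30] mm, median 6 mm (log-sd
  0.45) for benign and 13 mm (log-sd 0.40) for malignant. Size is the
  dominant single-scan malignancy correlate in screening cohorts; making the
  classes size-separable is what renders growth *learnable from the baseline
  image*, which is the premise of the whole approach. (With identical size
  distributions the optimal predictor is nearly the identity map, and no
  training objective can beat input-copying on follow-up similarity.)
* **Morphology.** Spiculated margins with probability 0.27 (malignant) /
  0.08 (benign), 4–9 Gaussian angular spikes scaled to the radius;
  attenuation classes solid/ground-glass/mixed at 0.71/0.20/0.09
  (malignant) and 0.81/0.13/0.06 (benign); these follow screening-cohort
  frequencies. Rendering is a radially symmetric sigmoid-edge disk
  (softness 0.6 mm), so the full width at half maximum of the profile equals
  the design diameter for solid and ground-glass nodules. Mixed nodules are
  a ground-glass halo plus a solid core at half the radius whose edge
  softness scales with the radius — every length in the profile is then
  proportional to the diameter and growth *ratios* are preserved; the
  profile-scan diameter of a mixed nodule tracks its dense core.
* **Background and noise.** A smoothed Gaussian random field (sd 0.03 around
  a parenchyma level of 0.11 under the (−1000, 400) HU window) is fixed per
  nodule across timepoints (it is anatomy); white acquisition noise
  (sd 0.02) is redrawn per timepoint. Intensity levels for solid
  (0.70–0.85) and ground-glass (0.30–0.45) tissue correspond to ≈ 0 HU and
  ≈ −500 HU under the same window.
* **Measurement oracle.** `measure_diameter_mm` is independent of the
  renderer: it centres on the half-maximum mask centroid, takes a median
  radial profile (the median suppresses spicules and noise), and
  interpolates the half-maximum crossing. Its error is about one pixel for
  low-contrast ground-glass nodules — the tolerance used by the growth-law
  checks.

**What the simulator does not emulate:** real parenchymal texture, vessels
and pleural attachments; part-solid evolution, cavitation or shrinkage;
scanner/protocol variation; multi-nodule subjects; registration error
between timepoints. Passing synthetic tests therefore demonstrates the
machinery (losses, training dynamics, statistics) and the growth-learning
behaviour under clean conditions — not clinical performance.

## Real-CT preparation path

`patchprep` resamples scans to 0.5 mm isotropic voxels with cubic B-spline
interpolation (SimpleITK), clamping interpolation overshoot to the input
range, extracts the 32 mm ROI on the radiologist-selected axial slice
centred on the marked nodule (nearest-voxel rounding; the ROI spans the
half-open range [c−32, c+32) so the mark lands on pixel (32, 32); ROIs that
leave the volume raise an error rather than pad), and windows HU to [0, 1]
with a fixed (−1000, 400) lung window. Per-patch normalization is a
plausible alternative; the fixed window is the package's choice and is
configurable.

## Evaluation statistics

* **AUC** is the Mann–Whitney concordance probability (ties counted ½);
  standard errors and paired AUC comparisons use DeLong's structural
  components (verified against the R `pROC` implementation). Hochberg's
  step-up adjustment (via statsmodels) handles the three pairwise
  comparisons of baseline / GP-nodule / real-follow-up scoring.
* **Risk stratification** uses the published three-level threshold rules
  (Brock < 0.0117 / [0.0117, 0.10] / > 0.10; risk-model scores < 0.45 /
  [0.45, 0.81] / > 0.81, a closed middle interval; Lung-RADS categories
  consumed directly as <3 / =3 / >3). `match_subgroup_thresholds` places
  thresholds at order statistics so two scorers stratify identical subgroup
  sizes; tied blocks are absorbed into the lower group and the achieved
  sizes are reported.
* **NRI.** From the 3×3 outcome-split migration tables: event NRI =
  (events up − events down)/n_event, nonevent NRI = (nonevents down −
  nonevents up)/n_nonevent, overall = their sum; any move to a strictly
  higher of the three ordered groups counts once as an escalation.
  Components are kept as exact rationals; reported values round half-up to
  2 dp. Significance uses the Pencina-style Z with component variance
  (p_up + p_down − (p_up − p_down)²)/n; a component with no movement has an
  undefined Z, reported as NaN. The asymptotic p-values agree with an exact
  multinomial null simulation to ≈ 0.01–0.02 at a few hundred subjects.
  Published p-values for the packaged blocks were computed with different
  (unpublished) variance details, so small differences there are expected;
  NRI point values are exact.
* **Toy risk scorer.** A seeded logistic regression over simple patch
  features (profile-scan diameter, mean/max intensity, above-half-max area
  and its ratio to the equivalent disk) stands in for a full lung-cancer
  risk prediction model as the downstream reader of baseline, GP-nodule and
  follow-up patches. It is intentionally minimal: the evaluation design,
  not the scorer, is the point.

## Packaged reclassification counts

`nodulegp/data/reclassification_counts.json` ships the published 3×3
migration counts of a 450-subject NLST screening test cohort (53
biopsy-proven cancers, 397 negatives) whose risk groups were re-assigned by
a risk model reading GP-nodules, against four initial stratifications
(Lung-RADS, Brock, and the same risk model on real baseline or follow-up
nodules). Feeding these counts through `nri` reproduces the published
event/nonevent NRI values at 2 dp for every block, and the overall values
for three of the four. In the Lung-RADS block the exact overall NRI is
8/53 + 94/397 = 0.3877, which rounds to 0.39, while the published summary
prints 0.38 — inconsistent with the published counts and the stated
overall = event + nonevent identity under any single rounding convention.
The package reports the exact arithmetic.

## Problem sizes and numerical choices

The default experiment profile is smoke-scale: 64 training pairs
(14 malignant / 50 benign, the cohort's ≈ 21% prevalence), 200 generator
steps, 32 held-out pairs; `ExperimentConfig.full_scale()` mirrors the
776/450-subject reference split. Training runs in float32; gradient checks
run in float64. The penalty's norm is stabilized with a 1e-12 epsilon inside
the square root (a constant critic therefore scores a penalty of 1 to within
2·10⁻⁶). Degenerate inputs fail loudly: empty datasets, single-class score
sets, out-of-bounds ROIs, infeasible stratification targets and non-finite
losses all raise with context (the trainer attaches its diagnostic state).

## Known limitations

* The simulator's class-conditional geometry makes growth predictable by
  design; real nodules carry weaker, noisier cues, and no claim about
  clinical accuracy follows from these experiments.
* The critic is unconditional (it scores single patches, not
  (baseline, follow-up) pairs), faithful to the defining objective; a
  conditional critic is a natural extension.
* One 12-month interval only; multi-year horizons and irregular intervals
  are out of scope.
* The autodiff engine implements exactly the operations these networks
  need; it is not a general-purpose framework (no second-order gradients —
  the gradient penalty relies on the critic's piecewise linearity).
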