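# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices made where the design was genuinely open, and what
the tests do and do not demonstrate.

## Phase-contrast phantoms

A synthetic exam contains one paired magnitude/phase cine per vessel
(LPA, RPA, SVC, IVC, Ao). Each vessel is a circular lumen on a static
tissue background (tissue signal 0.4, lumen 1.0, additive Gaussian noise,
default SD 3% of lumen signal). Through-plane velocity follows a
Poiseuille (parabolic) profile by default — centerline velocity times
`1 - (r/R)^2` — with a plug profile available because it makes the flow
integral trivially analytic (`v0 * pi R^2 * RR`). Velocity profiles are
evaluated on a 4x supersampled grid and block-averaged, so edge pixels
carry partial-volume velocities as in real PCMR; without this, the
pixel-count area of small disks deviates from `pi R^2` by up to ~8% and
the 2% flow-conservation contract is unattainable. The binary truth mask
is the set of pixels with at least 50% lumen coverage.

Phase is stored in radians with `phi = pi * v / VENC`; specs whose peak
velocity reaches VENC are rejected rather than wrapped, so ground truth is
alias-free. Waveforms are class-typical: early-systolic arterial pulses
for Ao/LPA/RPA, low-pulsatility biphasic venous flow for SVC/IVC, plus a
diastolic-dominant shape used by the cohort generator. Default venous
peak velocities are set so that caval return is below aortic output,
giving a positive aortopulmonary collateral fraction. No MR physics
beyond this is emulated: no coil profiles, eddy currents or background
phase offsets (background phase correction is deliberately out of scope),
so passing tests say nothing about robustness to those artifacts.

Flow-curve cohorts are drawn from parametric archetypes (total indexed
flow, channel split fraction, diastolic dominance, pulsatility). The
defaults mirror the five pulmonary-artery and four caval phenotypes
reported for Fontan patients — e.g. "normal distribution, high flow"
(2.91 L/min/m^2, 42% LPA) or "diastolic-dominant, normal flow"; the
printed cluster-level flow summaries fix total flow and split, while the
waveform shapes themselves are free choices since no quantitative
per-cluster waveform is published. Noise is temporally smooth
(Gaussian-filtered white noise, SD 0.15 L/min/m^2), giving a minimum
archetype separation of ~25x the per-frame noise SD (>5x by a wide
margin). BSA is lognormal (median 1.5 m^2, log-SD 0.18). Event times are
exponential with cluster-specific hazards (piecewise-exponential when
cluster membership changes across scans), with independent exponential
censoring plus administrative censoring.

## The segmentation network (DCS)

The architecture follows the five-scale UNet3+ pattern: filters
(16, 32, 64, 128, 255), two 3x3x3 convolutions per encoder scale (one at
the bottleneck), spatial-only 2x max-pooling (the time axis is never
pooled), full-scale skip connections in the decoder (each stage fuses
projections of all encoder and decoder scales; projection and fusion
channel counts derive from the configuration rather than being
hard-coded), deep supervision with one softmax head at the bottleneck and
each decoder stage (weights 0.25/0.25/0.25/0.25/1.00), and a CGM branch
(global max-pool, dropout 0.3, dense softmax over 6 classes). The series
description is matched against an editable token dictionary into a
six-slot one-hot vector (ambiguous or empty text maps to the other/empty
slot), passed through a two-layer MLP to one bottleneck plane (64 values
for the default geometry), tiled across frames and concatenated, giving
the 256-channel bottleneck. At inference the CGM probabilities gate
(multiply) the vessel channels of the final head and the mask is the
voxel argmax restricted to the predicted class; the gating realization is
a package choice, as is the 6-class per-voxel softmax (background
explicit).

Losses: focal Tversky per class over all voxels of the batch
(`TI = TP / (TP + 0.7 FN + 0.3 FP)`, loss `sum_c (1 - TI_c)^(4/3)`;
alpha/beta/gamma are configurable package defaults, as the loss constants
are not published) plus categorical cross-entropy on the CGM, combined
1.00 : 0.25 at every deep-supervision head. Two numerical choices proved
load-bearing on CPU-scale training: (i) instance normalization after
every convolution — without batch statistics the five-scale network
reliably collapses to the background class; and (ii) global gradient-norm
clipping at 5.0 in Adam, because the focal Tversky gradient
`d(1-TI)^gamma/dTI` is unbounded as TI -> 1 for gamma < 2 and caused
mid-training blow-ups. Neither changes the loss value reported.

Augmentation: shared per-sample affine (rotation +-10 deg, translation
+-5%, scale 0.9-1.1), brightness/contrast jitter on the magnitude
channel, description scrambled to a random one-hot in 5% of draws, and
the imaginary-channel sign inverted on alternating samples so the model
is invariant to the flow-encoding direction.

Two configurations exist. The default reproduces the published geometry
exactly (128x128 at 2 mm, 32 frames, 400 epochs, batch 8, Adam 1e-3 —
the learning rate itself being unpublished). The test profile used by the
training experiments is reduced to fit a single CPU: 32x32 at 2 mm,
8 frames, filters (4, 8, 16, 32, 63) (bottleneck 63 + 1 = 64), projection
width 4, decoder width 8, geometric augmentation off, 60 epochs on
20 phantom exams (100 series). Under that profile the model reaches
median held-out foreground Dice >= 0.98 and 25/25 classification in the
training experiments; this demonstrates that the joint architecture and
losses learn the task, not that the full profile reproduces any
registry-level accuracy.

## Flow quantification

Flow per frame is `sum_mask VENC * phi / pi * pixel_area` (mL/s); the
net forward volume integrates the periodic curve over one RR interval
(wrap-around trapezoid, equal to the frame mean times RR); the indexed
flow rate is net volume x HR / BSA (L/min/m^2). Connected components are
labelled in 2D+time with 26-connectivity, so a vessel persists across
frames rather than fragmenting per frame. Dice between two empty masks is
defined as 1 (a correct empty prediction is perfect agreement). The
collateral fraction is declared as `100 * (Ao - (SVC + IVC)) / Ao`; the
registry's exact definition is not public, so this aortic-minus-caval
convention is flagged as a package choice.

## Deep temporal clustering

Inputs are per-sample BSA-indexed curves, cubic-spline resampled to
30 frames, z-scored with a single mean/SD over the whole dataset (so
amplitude differences between samples survive), channels concatenated.
Exams are excluded before clustering when the aortic curve peaks in the
second half of the cycle (pulse-gated acquisition), its net volume is
below 10 mL (non-physiological), or RR/BSA are missing.

Encoder: 1D convolution (50 filters, kernel 10, same padding so pooling
by 3 yields a 10-step latent sequence), BiLSTM(50) then BiLSTM(1), both
tanh-bounded; the latent vector is the flattened bidirectional output
sequence (10 x 2 = 20 dimensions — the flattening is a package choice).
Decoder: time-distributed dense(50), 3x upsampling, 1D deconvolution
(kernel 10) back to 30 x 2. Pretraining minimizes reconstruction MSE for
100 epochs (Adam 1e-3, batch 64). Centroids are initialized by k-means
(10 restarts) on the latent vectors; joint training minimizes
MSE + KL(P || Q) with equal weights over autoencoder weights and
centroids.

Assignment bookkeeping: the target distribution P, hard labels and the
fraction-changed statistic are recomputed every 100 epochs. The k-means
initialization is not counted as an update step, so the first convergence
comparison happens between the first and second self-training updates
(a minimum of 200 joint epochs). This matters: on well-separated
synthetic cohorts the hard labels are already stable at initialization,
and declaring convergence before any self-training would leave the latent
space no sharper than the baseline (latent silhouette 0.52 after zero
effective self-training intervals vs 0.71 after one and 0.97 after
three), defeating the purpose of the KL step. Training stops at
convergence (< 0.1% changed) or a 3000-epoch cap, in which case a
non-convergence flag is returned with the partial state (large k on tight
cohorts exercises this path). Hard-label ties break to the lowest cluster
index. The silhouette is computed in latent space by default (input space
available), with Euclidean distance.

The PCA + k-means baseline concatenates the two 30-frame channels into
60-dimensional vectors, mean-centers over the dataset, keeps enough
components for 95% variance (the published component count is unstated),
and clusters the PC weights with k-means (50 restarts); its silhouette is
computed in PC-weight space.

## Outcome analysis

Cluster membership is assigned per exam, so exposure is time-varying.
Counting-process intervals carry the cluster and covariates (age at
interval start, sex, BSA, indexed aortic flow, EF) from each exam forward
to the next exam or the event/censor time; events sit only on final
intervals; exams dated after the outcome are rejected with a report. The
Cox model is lifelines' time-varying fitter with reference-coded cluster
indicators, each cluster usable as the reference; tie handling follows
lifelines (ties are measure-zero in the synthetic cohorts). The
Simon-Makuch estimator re-evaluates each group's at-risk set at every
event time from the intervals covering it and truncates a group's curve
once fewer than ten individuals remain at risk; with no membership
changes it reduces exactly to Kaplan-Meier (verified against lifelines to
1e-12). Group comparison utilities (Kruskal-Wallis with hand-implemented
Dunn post-hoc tests under Benjamini-Hochberg correction, chi-square for
categoricals) are provided for synthetic cohorts.

## Neural-network substrate

No deep-learning framework is used; `fontanflow.nn` is a small
reverse-mode autodiff engine on numpy. 3D convolutions are computed by
scatter-GEMM over kernel offsets (one batched GEMM per offset accumulated
into a shifted padded output) with pooled, reused work buffers —
materialized patch matrices and fresh 100 MB allocations each proved to
dominate run time. Gradients of every operation are verified against
central finite differences in the test suite. Float32 is used for network
weights and activations; equation-level utilities (soft assignment,
target distribution, silhouette, flow integrals) are float64.

## Problem sizes

The shipped experiments use 20 training + 5 held-out phantom exams
(125 series) for segmentation, cohorts of n=200-600 with k_true = 4 for
clustering, and 20 replicates of n=600-1000 subjects for the survival
checks. These sizes are the package's test conditions; they demonstrate
correctness of the algorithms and recovery under known ground truth, not
performance on registry-scale clinical data.

## Known limitations

* Phantoms are geometrically simple (one circular vessel per series);
  classification difficulty is far below real anatomical variation
  (bilateral vessels, heterotaxy), so classification accuracy on phantoms
  does not transfer.
* The vessel-token dictionary ships with obvious tokens only and is meant
  to be edited per site.
* Background phase offsets are neither simulated nor corrected.
* The full-profile network is buildable and its geometry is verified, but
  training it at 128x128x32 on numpy/CPU is impractical; all learning
  experiments use the test profile.
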