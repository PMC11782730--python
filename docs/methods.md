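# Methods

`b1net` implements a deep-learning calibration chain for parallel-transmit
(pTx) MRI at ultra-high field: complex-valued encoder–decoder networks that
estimate channel-wise transmit-field (B1+) maps from multi-channel
localizer images, the map-quality metrics used to judge them, and the
downstream pulse-design consumers (static phase-only shimming, kt-point
pulses, Bloch-simulated flip-angle maps). Because acquired in-vivo
libraries are not redistributable, the package ships a synthetic
transceiver-coil phantom simulator that poses the same learning problem at
desk scale; everything below describes both the model and what the
synthetic study does and does not demonstrate.

## The estimation problem

At 7T the transmit RF field B1+ of each coil element is a complex-valued,
spatially inhomogeneous map that varies between subjects. Subject-specific
pTx pulse design needs these maps at the start of every session, and
measuring them channel-by-channel costs minutes. The network sidesteps the
measurement: a fast CP+-mode localizer (acquired anyway) is mapped directly
to the 8 channel-wise complex B1+ maps,

    (8 Rx-channel complex localizer slices + combined magnitude; 9 channels)
        -> (8 Tx-channel complex B1+ maps),

slice-wise on a 128 x 96 grid (full profile) or 64 x 48 (scaled profile).
The mapping is learnable because in a transceiver array the receive
profiles that weight the localizer resemble the transmit profiles being
estimated.

## Network

The architecture is a U-Net-style encoder–decoder built from
complex-valued primitives:

* **Complex convolution** — 3x3 kernels, "same" padding; the complex
  product is executed as one real convolution on stacked [Re | Im]
  channels with the block kernel [[Wr, Wi], [-Wi, Wr]].
* **ModReLU** — ReLU(|z| + b) e^{i angle(z)} with a learnable real bias b
  per channel (initialised to 0); magnitude gating that preserves phase.
  The output at z = 0 is defined as 0 (continuous limit).
* **Resampling by stride-2 convolutions** (down) and their exact adjoint,
  stride-2 transposed convolutions (up) — no pooling.
* Four encoder and four decoder stages, two convolutions per stage,
  feature maps 16/32/64/128 (base 16, doubling per stage), concatenating
  skip connections and dropout (rate 0.1, configurable) at stage ends,
  and an 8 x 6 bottleneck for the 128 x 96 input.
* After the shared decoder trunk, one **head per Tx channel**: four
  convolutions with decreasing feature maps (16 -> 8 -> 4 -> 1), the last
  one linear. A `full_split_decoder` switch duplicates the whole decoder
  per channel instead; the heads-only split is the default because it is
  8x lighter and the two readings were otherwise indistinguishable.
* **Complex Glorot initialisation**: real and imaginary parts drawn
  independently with half the Glorot-uniform variance each, so
  E|w|^2 = 2/(fan_in + fan_out).

A real-valued baseline of identical topology (`variant="real_split"`)
consumes the complex data as 17 real channels (8 Re + 8 Im + magnitude)
and emits 16 (Re/Im per Tx channel), with a feature-width multiplier to
realise different parameter counts.

All layers run on a small reverse-mode automatic-differentiation engine
over real numpy arrays written for this package; complex tensors are
carried as (Re, Im) pairs so the real chain rule produces the correct
complex gradients. Gradient correctness is enforced by finite-difference
tests on every primitive and through a full network.

## Loss

Training minimises a perpendicular + L2 loss. The prediction P is
decomposed against the target phasor u = T/|T| into a perpendicular
residual Im(u* P) and an in-line residual Re(u* P) − |T|:

    L = mean[ (Im(u* P))^2 + lambda (Re(u* P) - |T|)^2 ].

The perpendicular term penalises the error component orthogonal to the
target's direction in the complex plane (a pure phase-direction error);
the in-line term the magnitude-direction error; lambda (default 1)
balances the two, and at lambda = 1 the loss is exactly the complex mean
squared error. Where T = 0 the phasor is taken as 1, reducing to a plain
squared pull toward zero. Two rejected alternatives are worth recording:
penalising |perpendicular component| without squaring gives a
constant-magnitude subgradient that leaves batch-1 Adam with a permanent
error floor, and pairing the perpendicular term with a plain
magnitude-matching term (|T| − |P|)^2 creates a spurious zero at
anti-parallel predictions (P = −T). Both were observed to stall training
outright.

## Training

Adam, batch size 1, learning rate lr0 (1 - decay)^epoch. The full profile
uses lr0 = 1e-4 decaying 0.19% per epoch for 1000 epochs; the scaled
profile (below) uses lr0 = 5e-4 decaying 4% per epoch for 30 epochs
(single-orientation model) / 6 epochs (all-orientation model) — a
proportionally larger step, with a comparable total start-to-end decay
factor compressed into the ~30x shorter schedule. Before training, inputs and targets are multiplied by an
internal conditioning gain (1/mean|T|, clipped to [1, 100], divided out at
prediction time): under the per-subject normalisation the field
magnitudes are ~0.08, and without the gain Adam's ~lr-sized parameter
steps exceed the feature scale, driving ModReLU biases negative and
killing the gates. Training supervises the whole image grid — the
simulator's ground-truth fields are defined everywhere — which matches the
whole-image SSIM used for evaluation; the error metrics are brain-masked.

Cross-validation is subject-wise: the 15 subjects are randomly divided
into 5 folds of 3; each fold's subjects never appear in its training set,
and the same partition (fixed seed) is reused across network variants.
Models are trained per orientation (transversal / sagittal / coronal) or
on all orientations pooled, to probe orientation transfer.

Per-subject normalisation: B1+ maps are divided by the 99th percentile of
the CP+-combined magnitude (so the combined map peaks near 1), localizers
by their maximum combined magnitude; scales are recorded and invertible.

## Synthetic phantom library

The simulator emulates the structure of an acquired multi-subject library:

* **Subjects** — ellipsoidal heads, semi-axes (7.5, 9, 8) cm jittered
  ±10% per subject, small centre offsets, a smooth random proton-density
  field (zero outside the head).
* **Coil** — 8 loop elements on a 14 cm-radius cylinder, equally spaced
  azimuths with ±2° jitter and ±10% gain jitter per session.
* **Transmit fields** — analytic: magnitude is a loop falloff
  (d0/(d0+d))^1.2 (d0 = 8 cm) plus a central-brightening Gaussian
  (amplitude 0.25, width 6 cm) mimicking constructive interference at 7T;
  phase is the element-relative azimuth plus a linear wave-phase term
  (20 rad/m) mimicking the short in-tissue RF wavelength. These constants
  were set so the CP+-mode flip-angle CV over the head lands in the
  25–30% range reported for real 7T head coils, and so a phase-only shim
  at 60% efficiency is attainable.
* **Receive fields** — azimuth-mirrored copies of the transmit fields with
  conjugated wave phase: the transceive property ("B1− resembles B1+")
  that makes the inverse problem well-posed.
* **Localizers** — per Rx channel j: PD · sin(FA_nom |CP+ combined|/ref) ·
  B1−_j plus complex Gaussian noise at a requested image SNR (default 50,
  nominal FA 25°); the 9th channel is the root-sum-of-squares magnitude.
* **Orientations** — transversal, sagittal, coronal stacks per subject;
  per-channel patterns differ systematically between orientations (mean
  complex SSIM between a channel's transversal and coronal pattern is
  ~0.2), reproducing the orientation-transfer failure mode.

What the synthetic study demonstrates: that the implementation learns the
localizer-to-B1+ mapping from receive-weighted images, generalises across
held-out subjects, fails across orientations when trained on one, and
supports the downstream pulse-design chain. What it does not demonstrate:
performance on real anatomy (no tissue heterogeneity, motion, B0 effects,
or coil-model error), absolute-unit mapping, or Maxwell-faithful fields.

## Scaled study profile

The reproduction study (tests and `scripts/acceptance.py`) runs at:
15 subjects, 6 slices per orientation, 64 x 48 grid at 4 mm, SNR 50, base
8 features (~750k parameters), 30 epochs for the transversal model
(~72 training slices) and 6 epochs for the all-orientation model
(~216 slices), evaluated on the 3 held-out subjects of fold 0. These sizes
are the package's chosen desk-scale conditions; all of them are plain
keyword arguments for larger runs.

## Pulse design

* **Channel combination** — MOS/POS maps are magnitude and phase of
  sum_k b_k B1+_k.
* **Phase-only shimming** — minimise the coefficient of variation (CV,
  population std/mean) of the combined magnitude over the mask, subject to
  the shim efficiency mean(MOS)/mean(sum_k |B1+_k|) lying within ±1% of a
  target (default 60%, evaluated on the centre slice; a volumetric mode
  exists). Solved by multi-start SLSQP over 7 relative phases with the
  CP+ phases always among the starts; infeasible targets are returned
  flagged rather than silently relaxed.
* **kt-points** — greedy selection of n_points locations from a symmetric
  3x3x3 low-frequency k-space candidate grid (±30 rad/m per axis, k = 0
  first); for each candidate set, RF weights from magnitude-least-squares
  variable exchange (Tikhonov-regularised normal equations, phase target
  initialised with the CP+ combined phase, 30 exchanges). Subpulse 100 µs,
  blip 50 µs, target 10°, all configurable. Increasing the Tikhonov weight
  never increases RF power (tested).
* **STA forward model** — theta(r) = gamma tau sum_n sum_c w_nc B1+_c(r)
  e^{i r·k_n}, with one normalised B1 unit = 1 µT.
* **Bloch simulator** — hard-pulse model: each subpulse rotates the
  magnetisation about its instantaneous transverse effective field; the
  gradient blips enter as the position-dependent phase r·k_n of each
  subpulse's rotation axis (the hard-pulse equivalent of interleaved
  z-precession, exact up to the final z-rotation, which does not affect
  the flip angle arccos(Mz)). Relaxation is neglected. Agreement with the
  STA prediction is within 2% per voxel for designed pulses at ≤5°
  targets.

## Metrics

Relative magnitude error is normalised by the mask-mean ground-truth
magnitude (a per-voxel denominator variant exists but explodes near field
nulls); phase error is the circular mean |angle(P conj(T))| in degrees;
RMSE comes in magnitude and complex flavours; SSIM (7x7 uniform window,
k1 = 0.01, k2 = 0.03, data range = joint max) is computed on magnitudes,
on unwrapped phase maps (2D phase unwrapping, deterministic), and as the
mean of real-part and imaginary-part SSIM ("complex"); Pearson
correlations are mask-restricted, with phases unwrapped first. The brain
mask recipe is Otsu on the log-compressed combined magnitude + largest
connected component + hole fill — log compression because the strong
receive shading otherwise cuts dim tissue.

## Numerical choices and edge cases

* float32 throughout the network; float64 in pulse design and metrics.
* ModReLU magnitude uses a 1e-12 guard inside the square root during
  training; the functional form returns exactly 0 at z = 0.
* Empty masks, all-zero images, zero-mean flip angles, channel or grid
  mismatches and rate-1 dropout raise ValueError with the offending
  dimension named; slices not intersecting the phantom warn and return an
  empty-mask stack.
* All stochastic components (init, folds, dropout, noise, multi-start
  optimisers) take explicit seeds; library generation funnels every
  random draw through one seeded generator, and generated files record
  seed and config hash.

## Known limitations

* The analytic field model is not an electromagnetic solution; SAR and
  power limits are out of scope.
* Training at the full 128 x 96 / 1000-epoch profile on CPU is possible
  but slow (~hours); the shipped study uses the scaled profile.
* The real-valued baseline trains with a plain complex-MSE objective on
  split channels, matching its original formulation, so loss values are
  not directly comparable between variants.
* Checkpoints store raw weights + config JSON in .npz form; they are not
  portable to other frameworks.
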