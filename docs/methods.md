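# Methods

## Velocity decoding and standardization

Per-pixel color-flow data enter as quadrature components (rxx, rxy) of the
normalized lag-1 Doppler autocorrelation plus signal power in dB. The
decoder inverts the dB encoding (R(0,0) = 10^(P/10), base-10 since the power
is in decibels), rescales the quadrature pair to R(0,1), and applies the
Kasai phase estimator v = arg(R(0,1))/π · f_Nyquist with the phase taken in
(−π, π], so a phase of exactly π maps to +f_Nyquist (a single-valued
convention at the aliasing boundary). Pixels with zero signal have no
defined phase; they are assigned velocity 0 and excluded from the flow mask
(no signal ⇒ no flow).

Flow/background segmentation applies Otsu's threshold to the **dB-scale**
power raster with a 256-bin histogram. The choice of scale and bin count are
assumptions: dB because that is the scale on which scanner power maps are
exported and displayed, 256 bins as the standard default for 8-bit-style
histograms. Thresholding linear power instead changes the
threshold but, for well-separated lumen/background power levels (default
25 vs 5 dB), not the mask.

ROI standardization crops to the bounding box of the largest 8-connected
flow component (8-connectivity avoids splitting vessel segments that touch
diagonally), zero-pads the short axis symmetrically to a square (odd
remainder to the trailing side), resizes bilinearly to 64×64, and divides by
f_Nyquist, clipping to [−1, 1]. Bounding-box centering (not centroid) was
chosen so content never leaves the canvas. Normalization is the fixed
physical map v/f_Nyquist rather than per-image min-max: per-image scaling
would erase cross-image velocity-magnitude differences, which are part of
the anomaly signal.

## Synthetic flow phantom

The phantom emulates the data the detector consumes — post-Kasai velocity
fields re-encoded as quadrature frames — not ultrasound physics. Normal
frames contain a vessel band (default 20 px wide in a 96×96 frame, mild
sinusoidal curvature) carrying a parabolic Poiseuille profile with peak
velocity 0.6·f_Nyquist, modulated by 1 + 0.3·sin(2π·phase) across the
cardiac cycle, plus Gaussian velocity noise (sd 0.03·f_Nyquist) and ~1 dB
power noise. Hemorrhage frames add a jet: a disk (default 16 px) straddling
the vessel wall in which each pixel draws a velocity magnitude in
[0.5, 1]·f_Nyquist and flips sign with probability `jet_alias_prob`
(default 0.5), reproducing the alternating-sign red-blue-check appearance of
turbulent extravasation after Kasai processing. Velocities are capped at
f_Nyquist: post-Kasai aliasing manifests exactly as sign flips, so no wrap
modelling beyond the flip is needed. The jet carries lumen-level power
(extravasated blood is flow, not background), which keeps it inside the
Otsu mask.

What the phantom does **not** model: speckle, spectral broadening, wall
filters, beam geometry, clutter, anatomy other than one vessel, or
hemodynamic realism of the jet. Passing tests therefore demonstrate that the
pipeline recovers programmed velocity structure and separates the two
programmed flow classes; they do not certify performance on clinical
Doppler data, where normal variability is far richer.

All phantom outputs are pure functions of (config, arguments): per-frame
randomness comes from a seed sequence keyed by (config seed, frame seed).

## Networks and training

Both networks are built on an in-package numpy layer stack (im2col-based
strided convolution, its exact adjoint as the fractionally-strided
deconvolution, batch normalization with running statistics, explicit
backward passes), verified against central-difference gradients in the test
suite. Working precision is float32.

Generator: dense projection of the latent vector (length 100, prior
U[−1,1]^100) to 4×4×(8w), then four deconvolution blocks (kernel 4, stride
2, padding 1) doubling resolution to 64×64; blocks 1–3 use batch
normalization + ReLU, block 4 is a bare deconvolution with tanh output.
Discriminator: four convolution blocks (LeakyReLU 0.2, batch-normalized
from block 2 on), flatten, dense to a scalar logit. Base width w = 16 by
default — a deliberately desk-scale network; widths are configurable.
Images are single-channel signed velocity rasters: scanner velocity data
are 16-bit scalar fields, and the RGB color-flow display is only a
rendering of them, so one channel is the faithful sample space.

Training: Adam (lr 2·10⁻⁴, β = (0.5, 0.999)), batch size 64, 25 epochs,
weights initialized N(0, 0.02²), all seeded. The generator uses the
non-saturating objective (maximize log D(G(z))) by default — the standard
remedy for vanishing early-training gradients, equivalent at equilibrium to
minimizing log(1 − D(G(z))), which remains available via
`TrainConfig(non_saturating=False)`. The trainer refuses any image whose
label is not `normal`: training contamination would undermine the anomaly
premise. The adversarial objective value V(G, D) is logged per epoch.

## Latent inversion and scoring

Inversion freezes all network weights (asserted bit-identical afterwards)
and descends on z alone. Each of φ steps evaluates the residual loss
L_R = Σ|x − G(z)| normalized by (pixel count × 2) and the discrimination
loss L_D = softplus(−logit(G(z))) (sigmoid cross-entropy against target
α = 1), combines them as L = (1−γ)L_R + γL_D, and updates z by gradient
descent (step size 0.05 with momentum 0.9; chosen once as the smallest
setting that reliably converged within 200 steps on the phantom). The
anomaly score A is the total loss at the final evaluated step, clamped to
[0, 1].

Two interpretive choices deserve note. The raw residual sum is not bounded
by 1, but the score is defined to lie in [0, 1]; the normalization by
(pixels × dynamic range) reconciles the two, and the raw sum is kept on the
result object for diagnostics. Second, the loop evaluates losses and then
updates z, so the reported score belongs to the last evaluated iterate
(G at iteration φ), matching the literal loop structure of the procedure;
the fixed-point test (x = G(z*), start at z*, φ = 1 ⇒ residual ≈ 0) pins
this reading down.

Batch normalization uses running statistics during inversion, making the
result independent of batching and deterministic. `n_restarts` (default 1,
matching the single-start procedure the score definition assumes; restarts
run together as one batch) reruns the descent from fresh prior samples and
keeps the lowest final loss; single-start inversion is known to be
initialization-sensitive.

Residual binarization pools all residual pixels and takes a single global
Otsu threshold (a fixed-percentile rule is available); "determined from the
histogram of all residual images" admits several readings, and an explicit
rule is required for reproducibility. The rule used is recorded in the
detection output metadata. A sequence-level call declares hemorrhage when at
least `persistence_fraction` (default 0.8) of frames have non-empty
binarized residuals.

## Evaluation

ROC curves sweep all distinct score thresholds (scikit-learn backend); AUC
is the trapezoidal integral, equal to the tie-aware pairwise probability
P(pos > neg) + ½P(pos = neg), which the tests verify against brute-force
enumeration to 10⁻¹². The operating point for sensitivity/specificity is
the Youden-J maximizer by default (the single-point choice is otherwise
underdetermined). Score distributions per timepoint are compared to
baseline with the Mann-Whitney U test (rank-based, robust to the skewed
score distributions), Bonferroni-multiplied across comparisons; frame-level
ground truth labels every frame of an injured timepoint positive.

## Benchmark sizing

The end-to-end benchmark (`hemoflow.benchmark.run_benchmark`, also driven by
`scripts/acceptance.py`) trains on 500 synthetic normal images for 25 epochs
(lr 2·10⁻⁴, latent 100, width 16) and inverts 50 + 50 held-out queries with
φ = 200, γ = 0.1, `jet_alias_prob` 0.5 — the full experiment in miniature,
sized to desk-scale CPU hardware (≈10 minutes on one core). φ = 200 rather
than 2000 suffices here because the phantom's normal manifold is far simpler
than clinical flow. The miniature trains at batch size 16 rather than the
full-protocol default of 64: what matters for convergence is the number of
optimizer updates, and 500 images at batch 64 over 25 epochs yield only
~175 updates against ~1300 in a thousands-of-images run — measurably
underfitting the generator (best-of-32 random-sample reconstruction error
of held-out normals improves ~6× at batch 16). Training and query phantoms
use distinct seeds, so no query is ever seen during training.

## Known limitations

- The phantom's normal class is much narrower than real normotensive flow
  across animals and probes; synthetic AUCs are upper bounds on what the
  same pipeline achieves on clinical data.
- Binarized-residual localization is coarse: reconstruction error spreads
  along the vessel, not only over the jet, so residual maps localize the
  anomaly region only approximately (score-level detection is much stronger
  than pixel-level localization; see the benchmark's localization-overlap
  metric).
- Plain gradient descent in latent space can stall in poor local minima for
  individual queries; only median-level descent progress is guaranteed (and
  tested). Restarts mitigate this at linear cost.
- The numpy networks are CPU-bound and intentionally small; the
  architecture is not meant for GPU-scale image sizes.
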