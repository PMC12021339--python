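# Methods

This note documents the models implemented in `mpragelike`, the parameter
choices that matter, what the digital phantom does and does not emulate,
and the numerical conventions a user re-deriving our outputs needs.

## Contrast synthesis

The MPRAGE-like image is the voxelwise regularized ratio

    S(λ) = (T1w − λ) / (D + λ),   D ∈ { 0.5·(PDw + MTw), MTw, PDw }

over first-echo magnitude MPM volumes on a common grid (inputs are assumed
rigidly coregistered upstream; no resampling is performed here). The three
denominator choices are exposed as variants `all`, `MT`, `PD`. Two
properties drive the design:

1. **Receive-bias cancellation.** A multiplicative coil-sensitivity field
   common to all contrasts cancels exactly in the ratio at λ = 0. For
   λ > 0 the cancellation is only approximate — λ trades background-noise
   suppression against reintroduced spatial inhomogeneity.
2. **Closed-form T1 weighting.** In the small-flip-angle spoiled-GRE
   regime, S_X ≈ PD·α_X·TR_X·R1 / (α_X²/2 + δ_X + TR_X·R1), so each
   variant's λ=0 ratio equals a closed-form function of R1app and δapp.
   The implementation's closed-form oracle keeps the TR ratio between the
   numerator and denominator contrasts; when the T1w and PDw TRs are equal
   (as in the default protocol) the prefactor reduces to the familiar
   α-only form.

**Clipping.** After the ratio, voxels outside (clip_low, clip_high) are set
to 0; defaults (0, 500) assume raw-scanner-scale inputs (hundreds to
thousands of a.u.) and must be rescaled along with any intensity
normalization. Clipping is applied once, on the final image. The ratio is
evaluated with IEEE semantics and 0/0 voxels (empty background) map to 0.

**Δs/s.** The percent change map 100·(S(λ) − S(0))/S(0) is NaN where
S(0) = 0; the NaN count is returned rather than epsilon-padded, so
downstream statistics stay honest.

**SSIM.** The three-factor form

    SSIM = (2μxμy+C1)/(μx²+μy²+C1) · (2σxσy+C2)/(σx²+σy²+C2) · (cov+C3)/(σxσy+C3)

is computed from whole-volume statistics by default (`global` mode); a
cubic sliding-window mode is provided for sensitivity analysis. Constants
default to the conventional C1 = (0.01·L)², C2 = (0.03·L)², C3 = C2/2 with
L the reference's data range. Sample statistics use the unbiased (n−1)
estimator throughout the package. SSIM(x, x) is returned as exactly 1.

**λ selection.** For each subject and each λ in
{0, 50, 100, 200, 300, 400, 500}, the synthesized image's SSIM against the
subject's reference anatomical is computed; the selected λ maximizes the
subject-mean SSIM, with ties broken toward the smaller λ (less
reintroduced inhomogeneity). On the phantom cohort the selected λ depends
on the simulated noise level and reference; it is reported, not assumed.

## Quantitative maps and synMPRAGE

The dual-flip-angle rational approximations

    R1app = (S_T1·α_T1/TR_T1 − S_PD·α_PD/TR_PD) / (2·(S_PD/α_PD − S_T1/α_T1))
    A     = S_PD·S_T1·(TR_PD·α_T1/α_PD − TR_T1·α_PD/α_T1) / (S_T1·TR_PD·α_T1 − S_PD·TR_T1·α_PD)
    δapp  = (A·α_MT/S_MT − 1)·TR_MT·R1app − α_MT²/2

exactly invert the small-angle forward model (verified to machine
precision in the tests). Against exact-SPGR (Ernst-equation) data at the
default protocol (25°/5°/6°, TR 34/34/50.5 ms) the measured bias is ≲ 2%
for R1 over 0.5–2.0 s⁻¹ and ≲ 4% for δ over brain-tissue R1; the bias
grows with flip angle, so transmit-field scaling toward 1.25× nominal
raises it to ≈ 4% — the acceptance script reports the measured values.
When a relative-B1 map is supplied, local flip angles B1 × nominal are
used. R1 outside the physical plausibility window [0, 10] s⁻¹ (or
non-finite) is flagged NaN before synthesis.

**MPRAGE signal models.** The published synMPRAGE recipe evaluates a
sequence equation that is not reproduced in full anywhere we can cite a
closed form from, so two monotone T1-weighting maps are exposed:

- `ir_closed_form` (default): S = M0·sin α·(1 − 2e^(−TI·R1) + e^(−TR·R1)),
  with M0 = RP = B1 = 1, TI = 1.1 s, TR = 2.7 s, α = 5°.
- `readout_steady_state`: the periodic steady state of
  {perfect inversion → relaxation → readout train (α pulses, echo spacing
  τ) → relaxation to TR}, evaluated at the k-space-center pulse (midpoint
  of the train). Echo spacing (6 ms) and line count (192) are documented
  placeholders, configurable, since no readout parameters are printed in
  a protocol we replicate.

Both models are strictly increasing in R1 over the brain-tissue range
(≈ 0.15–3 s⁻¹) at this timing — that is what makes the output purely
T1-weighted. Neither is monotone arbitrarily close to R1 = 0: the closed
form's derivative at R1→0+ is sin α·(2·TI − TR) < 0 for TI = 1.1 s,
TR = 2.7 s, producing a shallow dip (≈ 0.03·sin α deep) below
≈ 0.13 s⁻¹. No brain tissue, including CSF (R1 ≈ 0.23 s⁻¹), falls in that
interval; the test suite asserts the brain-range property and documents
the full-interval caveat.

**Background masking.** Negative PD values (fit outliers) are excluded,
Otsu's threshold is computed on the remaining values, and the binary mask
is dilated then closed with ball structuring elements (default radius 2,
6-connectivity). Inside an empty inter-mode histogram gap the
between-class-variance objective is flat, so the threshold's exact
position in the gap is arbitrary; correctness is defined (and tested) by
the induced partition, which matches an exhaustive-search oracle.

## Evaluation metrics

- **SNR/CNR** use the unbiased SD; constant ROIs yield +inf with a
  warning. The estimator choice is recorded in the CLI manifests.
- **Dice** implements the intersection numerator 2|G∩P|/(|G|+|P|).
- **ASSD** extracts boundary voxels (foreground with a background
  neighbor under configurable connectivity, default 6; the array edge
  counts as background) and averages bidirectional nearest-neighbor
  distances between boundary-voxel centers, anisotropy-aware, in mm.
  Mesh-based surfaces are out of scope; the voxel-center convention makes
  the metric exactly reproducible and oracle-checkable.
- **Aggregation** iterates nonzero reference regions (minus an exclusion
  list); regions empty in the test map get Dice 0 and ASSD NaN
  (missing-region rule). Summaries report median, 25th/75th and 5th/95th
  percentiles over finite values plus NaN counts, mirroring box-plot
  reporting with 5th/95th whiskers.
- **Wilcoxon signed-rank** (two-sided) drops zero differences, uses the
  exact permutation null for n ≤ 20 tie-free samples and the
  tie-corrected normal approximation with continuity correction
  otherwise; scipy provides the distribution machinery and the tests
  cross-check against full 2ⁿ sign enumeration. The Bonferroni threshold
  is α/n_tests (0.05/20 = 0.0025 for the five-region × four-method volume
  family).

## The digital phantom

Geometry is a nest of seeded-jittered ellipsoids: CSF envelope ⊃ cortical
GM shell ⊃ WM core, with two small ellipsoidal nuclei (thalamus, putamen)
embedded in the WM. The simplicity is deliberate: region volumes and
surfaces are exactly countable for metric tests, while seeded jitter
varies the geometry across subjects.

Per-tissue parameters live in `data/tissue_defaults.json` (R1 1.0 / 0.65 /
0.23 s⁻¹ for WM / cortical GM / CSF, nuclei between GM and WM; δ 0.025 /
0.012 / 0 with nuclei intermediate; PD ordered CSF > GM > WM and scaled so
raw contrast intensities land in the 500–2500 a.u. range that the default
clip window assumes). These are plausible ultra-high-field configuration
values chosen once for the simulator, not measured constants; tests read
them from the config so alternates can be swapped in.

Simulation: local flip angle = transmit field × nominal; signal from the
small-angle or exact-SPGR model (δ applied only to the MTw contrast; in
the exact model δ is a per-TR fractional reduction of longitudinal
magnetization, so the small-angle/exact discrepancy is a measured
quantity, not a hidden approximation); one shared receive field multiplies
all three contrasts; Gaussian or Rician (magnitude) noise is added last.
Transmit defaults to ×[0.75, 1.25] of nominal — realized flip angles
between 75% and 125% of nominal are typical at 7T — receive to
×[0.8, 1.2], noise to Rician SD 20 a.u. (≈ 1.4% of the WM T1w signal,
SNR ≈ 70 per contrast). Both fields are seeded low-frequency cosine
mixtures rescaled into their ranges. Everything derives from the integer
seed; equal specs give bit-identical datasets.

**What the phantom does not emulate:** realistic anatomical geometry and
partial-volume mixing at tissue interfaces, T2*/multi-echo decay (R2* is
carried as metadata only), flow/vessel signal, motion, k-space sampling
artifacts, and the spatial noise correlations of accelerated
reconstructions. Passing phantom tests therefore demonstrates correctness
of the signal equations, the bias-cancellation algebra, and the metric
implementations — not segmentation quality on real brains, which in the
target application also depends on an external segmentation network.

## Problem sizes and numerics

Pipeline-level checks use 48³ phantoms (and 24³–32³ for the multi-subject
λ sweep cohort of three seeds); these sizes make every property —
bias-cancellation to < 1e-10 relative, closed-form agreement to < 1e-9
relative — measurable in seconds while leaving all voxel-level algebra
identical to full-resolution use. Grid compatibility is enforced at 1e-4
relative tolerance on shape/spacing/affine. Flip angles are degrees at
every user interface and radians internally; times are ms on the CLI and
seconds internally. Voxel indexing is 0-based; reported distances are mm.

## Known limitations

- No registration or resampling: inputs must share a grid.
- The synMPRAGE sequence models are idealized (perfect inversion, no
  readout blurring); they are monotone R1 maps, not scanner simulations.
- PD amplitude is receive-weighted and uncalibrated.
- The λ grid and clip window are intensity-scale-dependent; normalized
  inputs require rescaled settings.
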