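# Methods

## Signal model

The physics-based synthetic FLAIR evaluates the inversion-recovery
spin-echo equation voxelwise from co-registered quantitative maps
(T1, T2 in milliseconds, proton density in arbitrary units):

    S_P = PD · (1 − 2e^(−TI/T1) + e^(−TR/T1)) / (1 + e^(−TR/T1) cos θ) · e^(−TE/T2)

Default timing is the reference 3 T FLAIR TSE protocol: TR 10 000 ms,
TI 2800 ms, TE 120 ms, θ = 90°. The model's output is *signed*: tissue
with T1 beyond the inversion null point (≈ 4.9 s under these timings;
`ir_null_t1` computes it by bracketed root finding) produces negative
values, which is precisely how fluid attenuation operates. A
`magnitude=True` switch mimics scanner magnitude display; the fusion
stage is consistent either way, so the signed model is the default and
nothing is clipped before the Fourier transform. Voxels with zero proton
density return exactly zero; positive proton density with non-positive
relaxation times is rejected rather than silently zeroed, to surface bad
masks early. All times are milliseconds; a TR below 50 ms triggers a
units warning (values entered in seconds), not a rescale.

The model deliberately omits B1 inhomogeneity, echo-train effects,
magnetization transfer, diffusion and susceptibility. Those un-modeled
effects are the reason the hybrid stage exists.

## Hybrid k-space fusion

Conventions, fixed package-wide: arrays are `(slice, phase-encode,
readout)`; transforms are per-slice 2-D, orthonormal and DC-centered (DC
at `(n_y//2, n_x//2)`), so Parseval bookkeeping for the normalization is
exact. The keyhole is the contiguous band of `ceil(n_y/R)` phase-encode
lines starting at `n_y//2 − n_keep//2`; the DC line is always acquired.
For the protocol matrix (224 lines, R = 8) that is 28 lines, indices
98–125, 12.5% of the data.

The Tukey taper lives on the acquired band only, in the band's
normalized coordinate (first acquired line → 0, last → 1); outside the
band the weight is zero, since weighting unacquired conventional lines
would be meaningless. Ratio r = 0.25 by default: r = 0 is the boxcar
(truncation ringing), r = 1 the Hann window (heavy blurring); the
intermediate taper is the compromise. A degenerate single-line band is
clamped to weight 1 with a warning instead of being annihilated by the
taper's zero endpoints.

The normalization factor `N = RMS(|F(S_C,R)·w|) / RMS(|F(S_P)·w|)` is
computed over *all complex samples on lines with w > 0* (both axes,
modulus before squaring). This index set makes N invariant to readout
length and to how unacquired lines are stored (zero-filled or absent),
and it makes the hybrid image exactly invariant to a positive rescaling
of the synthetic input. N is computed per slice by default (multi-2D
acquisition; per-volume optional), and the combination

    H = F⁻¹( F(S_C,R)·w + N·F(S_P)·(1 − w) )

takes the real part by default (`final_magnitude` mimics scanner
output). Brain masking is applied to both images *before* the
transforms — extracranial fat is bright on FLAIR and would otherwise
dominate N — and voxels outside the mask are copied bit-identically from
the synthetic volume afterwards (skull reinsertion). With fully
consistent inputs (conventional = synthetic) the whole chain is an
identity to FFT round-off; this is tested at 1e−9 relative RMS.

Two entry points cover the two acquisition routes. The retrospective
route (`hybrid_reconstruct`) takes a fully sampled conventional image and
masks its spectrum; the prospective route (`hybrid_reconstruct_kspace`)
takes acquired k-space lines, zero-fill reconstructs the magnitude image
a scanner would hand over, and proceeds identically. Because the
simulator draws noise from one RNG substream per (slice, line),
retrospectively masking a full acquisition is bit-identical to the
prospective acquisition of the same lines, and the two routes produce
bit-identical hybrid images for a shared seed — the simulation analogue
of a prospective/retrospective equivalence experiment, strengthened from
"negligible difference" to exact.

## Preprocessing surrogates

Clinical pipelines use external tools for rigid registration and brain
extraction. This package ships deterministic, dependency-free surrogates
with the same interfaces so production tools can be slotted in:

* **Registration** — in-plane rigid pose (dy, dx, θ) of the conventional
  volume relative to the synthetic one. Translation by phase correlation
  with upsampled-DFT subvoxel refinement on the central slice; rotation
  by a coarse scan plus golden-section search over ±10° (same-session
  head-motion scale) maximizing normalized cross-correlation.
  Candidates are scored with cubic interpolation: linear-interpolation
  blur otherwise biases the score toward zero rotation for sub-degree
  angles. Final resampling is linear. Accuracy on phantoms: ≤ 0.1 voxel,
  ≤ 0.25° (noiseless shifts recover exactly; 4° rotation recovers within
  0.02° at SNR 20). Already-aligned inputs (< 0.01 voxel, < 0.05°)
  return an exact identity and an untouched copy.
* **Brain extraction** — threshold at `frac × 99th percentile` (frac
  0.5), per-slice radius-2 closing, largest 3-D connected component,
  then per-slice hole filling. Selecting the component *before* filling
  matters: filling first would flood the ring-shaped scalp component's
  interior across the dark skull gap and fuse scalp with brain. On
  phantoms the mask reaches Dice 1.0 against the ground-truth brain;
  ≥ 0.95 is the tested bound.

The registration similarity metric (intensity cross-correlation) is a
design choice; contrast between the two FLAIR variants is similar enough
on brain-masked images that a cross-modal metric (mutual information) is
not needed here.

## Phantom generator

The phantom is the study's data substitute: a multi-slice head of nested
ellipsoids (scalp, signal-void skull gap, GM shell, WM core, CSF
ventricles, one WM lesion) rasterized innermost-wins onto a
`(slices, 224, 224)` grid, with per-tissue properties

| tissue | T1 (ms) | T2 (ms) | PD |
|---|---|---|---|
| WM | 850 | 70 | 0.65 |
| GM | 1300 | 100 | 0.80 |
| CSF | 4300 | 2000 | 1.00 |
| lesion | 1100 | 95 | 0.85 |
| scalp | 380 | 60 | 0.90 |

The scalp/skull ellipsoids extend beyond the imaged slab in z (a head
continues past the slice stack), which keeps the dark skull gap present
on every slice — without it, near-polar slices would fuse scalp and
brain in the extraction step. Structure nesting is validated at
rasterization.

The simulated *conventional* acquisition departs from the signal model
in exactly the ways real TSE FLAIR does:

* **Lesion mismatch** λ (default 1.8): the lesion's conventional
  intensity is multiplied by λ, the stand-in for un-modeled lesion
  contrast. In the noiseless case the conventional lesion-to-WM ratio
  exceeds the physics-based one by exactly λ (tested).
* **Tissue attenuation** (default WM × 0.88, GM × 0.94): TSE echo trains
  saturate bound-pool magnetization, suppressing WM most and GM
  somewhat, while fluids and edematous lesions are barely affected. This
  makes the mismatch global, as it is in practice; with a purely
  lesion-local mismatch the synthetic image would be trivially
  near-identical to the conventional one everywhere else and
  whole-image similarity could not discriminate the arms.
* **Map texture** (2% multiplicative heterogeneity on T1/T2/PD): real
  quantitative maps are never piecewise constant, and the CNR
  denominator (within-tissue standard deviation) would be zero without
  it.
* **k-space noise**: circular complex Gaussian, per-sample modulus std
  = `noise_sigma × RMS(image)` (default 2%), drawn from one RNG
  substream per (slice, phase-encode line) keyed on the seed — the
  mechanism behind the retrospective/prospective bit-equality contract.
  Noisy volumes are magnitude-reconstructed.
* **Rigid offset** (optional): in-plane misalignment of the conventional
  scan, recovered by the registration stage.

Cohorts use `jittered_phantom_spec`: one shared head shift/scale per
subject (preserving nesting and the skull gap) plus independent lesion
position/size/orientation jitter.

What the phantom does **not** emulate: realistic cortical folding and
anatomical texture, coil sensitivities, partial-Fourier or non-Cartesian
sampling, echo-train point-spread blurring, B0/B1 inhomogeneity, and
multiple or non-solid lesions. Passing tests therefore demonstrate the
correctness and direction-of-effect of the *reconstruction machinery*,
not clinical image quality.

## Evaluation

Per arm (physics / hybrid / conventional) and subject: lesion-to-GM and
lesion-to-WM mean-signal ratios, and CNRs `(mean_lesion − mean_tissue)/σ`
with σ the median of the lesion/GM/WM sample standard deviations (n − 1;
CSF excluded — the noise definition enumerates exactly those three
regions). Voxels are pooled across slices, one value per subject. All
four metrics are invariant to global positive rescaling, so arms on
different intensity scales compare directly. SSIM uses the canonical
constants (11×11 Gaussian window, σ 1.5, K1 0.01, K2 0.03, dynamic range
from the reference) and averages per-slice scores for volumes.

Arm comparisons use the two-sided Wilcoxon signed-rank test: zeros
discarded (classic convention, count reported), midranks for ties, exact
p from the full 2ⁿ sign-assignment null distribution for n ≤ 25
(dynamic programming over doubled midranks), normal approximation with
continuity and tie corrections beyond. Cohort exclusion flags are user
input only — lesion-polarity judgments are radiological, never computed.

## Problem sizes and determinism

Tests and the acceptance script run phantoms at the protocol's in-plane
matrix (224 × 224, so the R = 8 keyhole geometry is exactly the
protocol's 28-line band) with the slab shortened to 4–7 slices, and a
10-subject cohort; these sizes were chosen as the smallest at which every
tested property is non-trivial. The full 30-slice slab runs identically
via `RunConfig(shape=(30, 224, 224))`. Every random draw (phantom
texture, noise, jitter) descends from explicit integer seeds; no OS
entropy is consulted, and identical configurations yield byte-identical
outputs including the metrics JSON.
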