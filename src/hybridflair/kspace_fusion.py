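"""Keyhole k-space fusion of conventional and physics-based FLAIR.

The hybrid reconstruction replaces the central (contrast-carrying) band of
the physics-based FLAIR k-space with the acquired lines of an
ultra-undersampled conventional FLAIR, blended by a Tukey taper w(y) and an
RMS normalization factor N:

    H = F^{-1}( F(S_C,R) . w  +  N . F(S_P) . (1 - w) )

    N = RMS(|F(S_C,R)| . w) / RMS(|F(S_P)| . w)   over lines with w > 0

where S_C,R is the (brain-masked, registered) undersampled conventional
image and S_P the physics-based synthetic image.  The taper suppresses the
ringing a hard keyhole edge would cause while keeping more of the acquired
band at full weight than a Hann window would.

Conventions (fixed throughout the package):

* arrays are ``(slice, phase-encode, readout)``; k-space is per-slice 2-D;
* Fourier transforms are orthonormal and DC-centered: the DC sample of an
  ``(n_y, n_x)`` spectrum sits at ``(n_y // 2, n_x // 2)``;
* the keyhole is a contiguous band of ``ceil(n_y / R)`` phase-encode lines
  starting at ``n_y//2 - ceil(n_y/R)//2`` (DC always included);
* the Tukey taper lives on the acquired band only (w = 0 outside), in the
  band's normalized coordinate (first acquired line -> 0, last -> 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateInputError, InputError

__all__ = [
    "SamplingSpec",
    "image_to_kspace",
    "kspace_to_image",
    "make_keyhole_spec",
    "tukey_window",
    "retrospective_undersample",
    "normalization_factor",
    "combine_kspace",
    "hybrid_reconstruct",
    "hybrid_reconstruct_kspace",
]


# ---------------------------------------------------------------------------
# Fourier transform pair

def image_to_kspace(img: np.ndarray) -> np.ndarray:
    """Orthonormal, DC-centered 2-D DFT of one image slice."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise InputError(f"expected a 2-D slice, got ndim={img.ndim}")
    if not np.all(np.isfinite(img)):
        raise InputError("non-finite values in image slice")
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img), norm="ortho"))


def kspace_to_image(k: np.ndarray, *, magnitude: bool = False) -> np.ndarray:
    """Inverse of :func:`image_to_kspace`.

    Returns the real part by default (the imaginary residue of a hybrid
    combination of real images is reported separately by the caller when it
    matters); ``magnitude=True`` mimics scanner magnitude output.
    """
    k = np.asarray(k)
    if k.ndim != 2:
        raise InputError(f"expected a 2-D k-space slice, got ndim={k.ndim}")
    x = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k), norm="ortho"))
    return np.abs(x) if magnitude else x.real


# ---------------------------------------------------------------------------
# Sampling geometry

@dataclass(frozen=True)
class SamplingSpec:
    """Keyhole Cartesian undersampling scheme along the phase-encode axis.

    ``acquired_lines`` is the contiguous, centered band of
    ``ceil(n_y / r_accel)`` line indices; ``taper_ratio`` is the Tukey
    ratio r (0 = boxcar, 1 = Hann).
    """

    r_accel: int
    n_y: int
    acquired_lines: np.ndarray = field(repr=False)
    taper_ratio: float = 0.25

    def __post_init__(self) -> None:
        lines = np.asarray(self.acquired_lines, dtype=int)
        object.__setattr__(self, "acquired_lines", lines)
        if self.r_accel < 1:
            raise InputError(f"acceleration factor must be >= 1, got {self.r_accel}")
        if not (0.0 <= self.taper_ratio <= 1.0):
            raise InputError(f"taper_ratio must be in [0, 1], got {self.taper_ratio}")
        n_keep = math.ceil(self.n_y / self.r_accel)
        if len(lines) != n_keep or np.any(np.diff(lines) != 1):
            raise InputError("acquired_lines must be the contiguous centered band")
        if lines[0] < 0 or lines[-1] >= self.n_y:
            raise InputError("acquired_lines out of range")

    @property
    def n_keep(self) -> int:
        return len(self.acquired_lines)

    @property
    def fraction(self) -> float:
        """Fraction of phase-encode lines acquired (1/R up to rounding)."""
        return self.n_keep / self.n_y


def make_keyhole_spec(n_y: int, r_accel: int, taper_ratio: float = 0.25) -> SamplingSpec:
    """Centered keyhole band for acceleration factor R.

    The band holds ``ceil(n_y / R)`` lines and starts at
    ``n_y//2 - n_keep//2`` so the DC line ``n_y//2`` is always acquired.
    """
    if r_accel < 1:
        raise InputError(f"acceleration factor must be >= 1, got {r_accel}")
    if r_accel > n_y:
        raise InputError(f"acceleration factor {r_accel} exceeds n_y={n_y}")
    n_keep = math.ceil(n_y / r_accel)
    start = n_y // 2 - n_keep // 2
    lines = np.arange(start, start + n_keep)
    return SamplingSpec(r_accel=r_accel, n_y=n_y, acquired_lines=lines,
                        taper_ratio=taper_ratio)


def tukey_window(spec: SamplingSpec) -> np.ndarray:
    """Tukey (cosine-tapered) weights over the keyhole band, zero elsewhere.

    On the band's normalized coordinate y in [0, 1]:

        w = 1/2 {1 + cos(2 pi / r (y - r/2))}        0     <= y <= r/2
        w = 1                                        r/2   <= y <= 1 - r/2
        w = 1/2 {1 + cos(2 pi / r (y - 1 + r/2))}    1-r/2 <= y <= 1

    r = 0 degenerates to the all-ones boxcar, r = 1 to the Hann window
    sin^2(pi y).  A single-line band is clamped to weight 1 (the formula's
    endpoints would annihilate the only acquired line) with a warning.
    """
    r = spec.taper_ratio
    n = spec.n_keep
    w = np.zeros(spec.n_y, dtype=float)
    if n == 1:
        warnings.warn(
            "single-line keyhole: clamping taper weight to 1 on the DC line",
            UserWarning,
            stacklevel=2,
        )
        w[spec.acquired_lines] = 1.0
        return w
    y = np.arange(n) / (n - 1)
    band = np.ones(n, dtype=float)
    if r > 0:
        lo = y < r / 2
        hi = y > 1 - r / 2
        band[lo] = 0.5 * (1.0 + np.cos(2.0 * np.pi / r * (y[lo] - r / 2)))
        band[hi] = 0.5 * (1.0 + np.cos(2.0 * np.pi / r * (y[hi] - 1 + r / 2)))
    w[spec.acquired_lines] = band
    return w


def retrospective_undersample(k: np.ndarray, spec: SamplingSpec) -> np.ndarray:
    """Zero every phase-encode line outside the keyhole band.

    Acquired lines are copied bit-identically, so masking a simulated full
    acquisition reproduces a prospective acquisition of the same lines
    exactly.
    """
    k = np.asarray(k)
    if k.ndim != 2 or k.shape[0] != spec.n_y:
        raise InputError(
            f"k-space shape {k.shape} does not match n_y={spec.n_y}"
        )
    out = np.zeros_like(k)
    out[spec.acquired_lines, :] = k[spec.acquired_lines, :]
    return out


# ---------------------------------------------------------------------------
# Normalization and combination

def normalization_factor(k_conv: np.ndarray, k_phys: np.ndarray,
                         w: np.ndarray) -> float:
    """RMS intensity-scale factor between the two windowed k-spaces.

    ``N = RMS(|k_conv . w|) / RMS(|k_phys . w|)`` with the RMS taken over
    every complex sample (both axes) on lines with w > 0.  Restricting the
    index set to the window support makes N invariant to readout length
    and to zero-filled unacquired lines.
    """
    k_conv = np.asarray(k_conv)
    k_phys = np.asarray(k_phys)
    if k_conv.shape != k_phys.shape:
        raise InputError(
            f"k-space shapes differ: {k_conv.shape} vs {k_phys.shape}"
        )
    w = np.asarray(w, dtype=float)
    sel = w > 0
    wc = w[sel, None]
    num = np.sqrt(np.mean(np.abs(k_conv[sel, :] * wc) ** 2))
    den = np.sqrt(np.mean(np.abs(k_phys[sel, :] * wc) ** 2))
    if den == 0.0:
        raise DegenerateInputError(
            "physics-based k-space has zero energy inside the window support"
        )
    if num == 0.0:
        raise DegenerateInputError(
            "conventional k-space has zero energy inside the window support"
        )
    return float(num / den)


def combine_kspace(k_conv: np.ndarray, k_phys: np.ndarray, w: np.ndarray,
                   n_factor: float) -> np.ndarray:
    """Tapered keyhole substitution ``k_conv.w + N.k_phys.(1 - w)``.

    The taper is broadcast along the readout axis.  Where w = 1 the output
    is exactly the conventional data; where w = 0 it is exactly
    ``N . k_phys``.
    """
    k_conv = np.asarray(k_conv)
    k_phys = np.asarray(k_phys)
    if k_conv.shape != k_phys.shape:
        raise InputError(
            f"k-space shapes differ: {k_conv.shape} vs {k_phys.shape}"
        )
    if not n_factor > 0:
        raise InputError(f"n_factor must be positive, got {n_factor}")
    wc = np.asarray(w, dtype=float)[:, None]
    return k_conv * wc + n_factor * k_phys * (1.0 - wc)


# ---------------------------------------------------------------------------
# Full hybrid reconstruction

def _validate_hybrid_inputs(conv_like, phys, spec, brain_mask):
    phys = np.asarray(phys, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    if phys.ndim != 3:
        raise InputError(f"expected 3-D volumes, got phys ndim={phys.ndim}")
    if conv_like.shape != phys.shape or mask.shape != phys.shape:
        raise InputError(
            "inputs are not on one grid: "
            f"conv {conv_like.shape}, phys {phys.shape}, mask {mask.shape}"
        )
    if phys.shape[1] != spec.n_y:
        raise InputError(
            f"sampling spec n_y={spec.n_y} does not match phase-encode "
            f"dimension {phys.shape[1]}"
        )
    if not mask.any():
        raise DegenerateInputError("brain mask is empty")
    return phys, mask


def _fuse_slices(k_conv_slices, phys, spec, mask, *, per_slice_norm,
                 final_magnitude):
    """Shared Eq-by-Eq core: taper, normalize, combine, invert, reinsert."""
    w = tukey_window(spec)
    k_phys_slices = [image_to_kspace(phys[s] * mask[s])
                     for s in range(phys.shape[0])]
    nonempty = [s for s in range(phys.shape[0]) if mask[s].any()]
    if not per_slice_norm:
        sel = w > 0
        wc = w[sel, None]
        num = np.sqrt(np.mean([np.abs(k_conv_slices[s][sel, :] * wc) ** 2
                               for s in nonempty]))
        den = np.sqrt(np.mean([np.abs(k_phys_slices[s][sel, :] * wc) ** 2
                               for s in nonempty]))
        if den == 0.0 or num == 0.0:
            raise DegenerateInputError("zero windowed k-space energy")
        n_global = float(num / den)

    out = np.array(phys, dtype=float, copy=True)
    for s in nonempty:
        kc, kp = k_conv_slices[s], k_phys_slices[s]
        n = normalization_factor(kc, kp, w) if per_slice_norm else n_global
        h = kspace_to_image(combine_kspace(kc, kp, w, n),
                            magnitude=final_magnitude)
        out[s] = np.where(mask[s], h, phys[s])
    return out


def hybrid_reconstruct(
    conv: np.ndarray,
    phys: np.ndarray,
    spec: SamplingSpec,
    brain_mask: np.ndarray,
    *,
    per_slice_norm: bool = True,
    final_magnitude: bool = False,
) -> np.ndarray:
    """Hybrid FLAIR from a fully sampled conventional image (retrospective).

    Per slice: brain-mask both images, transform to k-space, keep only the
    keyhole band of the conventional spectrum, normalize, combine under the
    Tukey taper, invert, and reinsert the skull region (voxels outside the
    mask are copied bit-identically from ``phys``).

    With fully consistent inputs (``conv == phys``) the chain is an exact
    identity up to FFT round-off: the band carries the same data, N = 1,
    and ``w + (1 - w) = 1``.
    """
    conv = np.asarray(conv, dtype=float)
    phys, mask = _validate_hybrid_inputs(conv, phys, spec, brain_mask)
    k_conv = [
        retrospective_undersample(image_to_kspace(conv[s] * mask[s]), spec)
        if mask[s].any() else None
        for s in range(phys.shape[0])
    ]
    return _fuse_slices(k_conv, phys, spec, mask,
                        per_slice_norm=per_slice_norm,
                        final_magnitude=final_magnitude)


def hybrid_reconstruct_kspace(
    k_conv: np.ndarray,
    phys: np.ndarray,
    spec: SamplingSpec,
    brain_mask: np.ndarray,
    *,
    per_slice_norm: bool = True,
    final_magnitude: bool = False,
) -> np.ndarray:
    """Hybrid FLAIR from acquired conventional k-space (prospective route).

    ``k_conv`` is a full-grid complex volume whose unacquired lines are
    ignored (they are masked to the keyhole band).  Each slice is
    zero-fill reconstructed to a magnitude image — the image a scanner
    would hand over — then brain-masked and fused exactly like the
    retrospective route.  Because a retrospectively masked full
    acquisition is bit-identical to a prospective acquisition on the
    acquired lines, the two routes give bit-identical hybrids for the same
    noise realization.
    """
    k_conv = np.asarray(k_conv)
    phys, mask = _validate_hybrid_inputs(k_conv, phys, spec, brain_mask)
    k_slices = []
    for s in range(phys.shape[0]):
        if not mask[s].any():
            k_slices.append(None)
            continue
        ku = retrospective_undersample(k_conv[s], spec)
        s_cr = kspace_to_image(ku, magnitude=True)  # zero-filled recon
        k_slices.append(image_to_kspace(s_cr * mask[s]))
    return _fuse_slices(k_slices, phys, spec, mask,
                        per_slice_norm=per_slice_norm,
                        final_magnitude=final_magnitude)
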