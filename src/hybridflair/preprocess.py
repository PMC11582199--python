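"""Rigid registration, brain extraction and skull bookkeeping.

The conventional FLAIR acquisition may be slightly misaligned with respect
to the synthetic volume (same-session head motion), and extracranial fat is
bright enough to dominate the k-space normalization, so before fusion the
conventional image is rigidly aligned to the physics-based image and both
are restricted to a brain-only mask.  The skull/scalp region is reinserted
from the physics-based image after fusion.

These are deliberately self-contained surrogates for the clinical tools
normally used for these steps (intensity-based rigid registration, BET
brain extraction): phase correlation with subvoxel refinement plus a
golden-section in-plane rotation search, and threshold-plus-morphology
masking.  They share the interfaces a production tool would use, so either
can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize_scalar
from skimage.measure import label as cc_label
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .exceptions import DegenerateInputError, InputError

__all__ = [
    "RigidTransform",
    "apply_rigid",
    "register_rigid",
    "extract_brain_mask",
    "reinsert_skull",
]

#: rotation search half-range (degrees); same-session head motion scale
ROTATION_BOUND_DEG = 10.0


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid pose ``(dy, dx, theta_deg)`` of a volume.

    Forward convention: a volume with this pose relative to a reference is
    ``shift(rotate(reference, theta_deg), (dy, dx))`` — rotation about the
    slice center first, then translation, linear interpolation.
    """

    dy: float = 0.0
    dx: float = 0.0
    theta_deg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dy", "dx", "theta_deg"):
            if not np.isfinite(getattr(self, name)):
                raise InputError(f"{name} must be finite")
        if abs(self.theta_deg) > 45:
            raise InputError(
                f"|theta_deg| <= 45 expected for same-session scans, "
                f"got {self.theta_deg}"
            )

    @property
    def is_identity(self) -> bool:
        return self.dy == self.dx == self.theta_deg == 0.0


def _rotate(vol: np.ndarray, theta_deg: float, order: int = 1) -> np.ndarray:
    if theta_deg == 0.0:
        return vol.copy()
    return ndi.rotate(vol, theta_deg, axes=(-2, -1), reshape=False,
                      order=order, mode="constant", cval=0.0)


def _shift(vol: np.ndarray, dy: float, dx: float, order: int = 1) -> np.ndarray:
    if dy == 0.0 and dx == 0.0:
        return vol.copy()
    sh = (dy, dx) if vol.ndim == 2 else (0.0, dy, dx)
    return ndi.shift(vol, sh, order=order, mode="constant", cval=0.0)


def apply_rigid(vol: np.ndarray, t: RigidTransform) -> np.ndarray:
    """Apply the forward pose: rotate in-plane about the center, then shift."""
    vol = np.asarray(vol, dtype=float)
    return _shift(_rotate(vol, t.theta_deg), t.dy, t.dx)


def apply_rigid_inverse(vol: np.ndarray, t: RigidTransform) -> np.ndarray:
    """Undo the forward pose: shift back, then rotate back."""
    vol = np.asarray(vol, dtype=float)
    return _rotate(_shift(vol, -t.dy, -t.dx), -t.theta_deg)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    return float((a * b).sum() / den) if den > 0 else 0.0


def _estimate_shift(fixed: np.ndarray, moving: np.ndarray,
                    upsample: int) -> tuple[float, float]:
    """Forward shift (dy, dx) of ``moving`` relative to ``fixed``."""
    shift, _, _ = phase_cross_correlation(fixed, moving,
                                          upsample_factor=upsample,
                                          normalization=None)
    # phase_cross_correlation returns the shift that registers moving onto
    # fixed; the forward pose is its negation
    return float(-shift[0]), float(-shift[1])


def register_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    *,
    rotation_bound: float = ROTATION_BOUND_DEG,
) -> tuple[RigidTransform, np.ndarray]:
    """Estimate the in-plane rigid pose of ``moving`` relative to ``fixed``.

    Translation by phase correlation with subvoxel (upsampled-DFT)
    refinement on the central slice; rotation by a coarse scan plus
    golden-section search over ``+-rotation_bound`` degrees maximizing the
    normalized cross-correlation after shift compensation.

    Returns the estimated forward :class:`RigidTransform` (a phantom that
    was shifted by ``(3, -2)`` yields ``dy, dx = (3, -2)``) and ``moving``
    resampled into the grid of ``fixed``.  Inputs that are already aligned
    (shift estimate below 0.01 voxel, rotation below 0.05 degrees) return
    an exact identity transform and an untouched copy.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise InputError(
            f"moving {moving.shape} and fixed {fixed.shape} grids differ"
        )
    for name, a in (("moving", moving), ("fixed", fixed)):
        if a.std() == 0:
            raise DegenerateInputError(f"{name} image is constant")

    m2 = moving if moving.ndim == 2 else moving[moving.shape[0] // 2]
    f2 = fixed if fixed.ndim == 2 else fixed[fixed.shape[0] // 2]

    def score(theta: float) -> float:
        # cubic interpolation here: linear blurs a rotated candidate enough
        # to bias the score toward theta = 0 for sub-degree rotations
        mr = _rotate(m2, -theta, order=3)
        dy, dx = _estimate_shift(f2, mr, upsample=20)
        return -_ncc(_shift(mr, -dy, -dx, order=3), f2)

    thetas = np.linspace(-rotation_bound, rotation_bound, 21)
    scores = [score(t) for t in thetas]
    i = int(np.argmin(scores))
    lo = thetas[max(i - 1, 0)]
    hi = thetas[min(i + 1, len(thetas) - 1)]
    res = minimize_scalar(score, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-3})
    theta = float(res.x)

    mr = _rotate(m2, -theta, order=3)
    dy_r, dx_r = _estimate_shift(f2, mr, upsample=100)
    # fall back to pure translation if the rotated fit is no better
    dy0, dx0 = _estimate_shift(f2, m2, upsample=100)
    if -_ncc(_shift(m2, -dy0, -dx0, order=3), f2) <= score(theta):
        theta, dy_r, dx_r = 0.0, dy0, dx0

    # compose: aligned = shift(rotate(m, -theta), -(dy_r, dx_r));
    # forward translation is the residual shift rotated back into the
    # fixed frame: d = R(theta) . (dy_r, dx_r)
    c, s = np.cos(np.radians(theta)), np.sin(np.radians(theta))
    dy = c * dy_r - s * dx_r
    dx = s * dy_r + c * dx_r

    if abs(dy) < 0.01 and abs(dx) < 0.01 and abs(theta) < 0.05:
        return RigidTransform(), moving.copy()
    t = RigidTransform(dy=dy, dx=dx, theta_deg=theta)
    return t, apply_rigid_inverse(moving, t)


def extract_brain_mask(img: np.ndarray, frac_threshold: float = 0.5) -> np.ndarray:
    """Threshold-and-morphology brain mask.

    Threshold at ``frac_threshold`` times a robust maximum (the 99th
    intensity percentile), close with a radius-2 disk per slice, fill
    holes (ventricles), and keep the largest connected component —
    discarding the bright but disconnected scalp ring.  Deterministic.
    """
    img = np.asarray(img, dtype=float)
    if not (0.0 <= frac_threshold <= 1.0):
        raise InputError(f"frac_threshold must be in [0, 1], got {frac_threshold}")
    if not np.any(img > 0):
        raise DegenerateInputError("image has no positive intensities")
    thr = frac_threshold * np.percentile(img, 99)
    raw = img > thr if thr > 0 else img > 0
    if not raw.any():
        raise DegenerateInputError("empty foreground after thresholding")

    vol = raw if raw.ndim == 3 else raw[None]
    foot = disk(2)
    closed = np.stack([
        ndi.binary_closing(sl, structure=foot) if sl.any() else sl
        for sl in vol
    ])
    lab = cc_label(closed, connectivity=1)
    if lab.max() == 0:
        raise DegenerateInputError("empty foreground after morphology")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    # largest component first, THEN fill holes: filling a ring-shaped
    # scalp component before selection would flood the skull gap and fuse
    # scalp with brain
    comp = lab == int(np.argmax(sizes))
    mask = np.stack([ndi.binary_fill_holes(sl) for sl in comp])
    return mask if raw.ndim == 3 else mask[0]


def reinsert_skull(hybrid: np.ndarray, phys: np.ndarray,
                   mask: np.ndarray) -> np.ndarray:
    """Compose the final volume: ``hybrid`` inside the brain mask,
    ``phys`` (which retains the skull/scalp signal) outside.

    Each voxel is a bit-exact copy from exactly one source.
    """
    hybrid = np.asarray(hybrid)
    phys = np.asarray(phys)
    mask = np.asarray(mask, dtype=bool)
    if not (hybrid.shape == phys.shape == mask.shape):
        raise InputError(
            f"shapes differ: hybrid {hybrid.shape}, phys {phys.shape}, "
            f"mask {mask.shape}"
        )
    return np.where(mask, hybrid, phys)
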