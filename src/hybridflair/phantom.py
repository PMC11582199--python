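"""Seeded digital brain phantom and acquisition simulator.

No public dataset accompanies the hybrid-FLAIR problem, so this module
provides a fully deterministic stand-in: a multi-slice ellipsoidal head
phantom with quantitative T1/T2/PD maps and a tissue label map, plus a
simulator for the conventional FLAIR acquisition including

* a *lesion contrast mismatch*: the lesion's conventional-FLAIR intensity
  is multiplied by a factor ``lambda >= 1`` that the analytic signal model
  does not know about — a stand-in for magnetization transfer, partial
  volume, diffusion and susceptibility effects that make real lesions
  brighter on acquired FLAIR than on physics-based synthetic FLAIR;
* optional rigid in-plane misalignment of the conventional scan;
* circular complex Gaussian noise added in k-space, with one RNG
  substream per (slice, phase-encode line) so that a prospectively
  acquired keyhole and a retrospectively masked full acquisition are
  bit-identical on the acquired lines for the same seed.

Everything is a pure function of the :class:`PhantomSpec` (geometry,
tissue table, seed); no OS entropy is ever consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .kspace_fusion import SamplingSpec, image_to_kspace, kspace_to_image
from .metrics import LABELS
from .physics_synth import QuantitativeMapSet, SequenceParams, synthesize_flair
from .preprocess import RigidTransform, apply_rigid

__all__ = [
    "Ellipsoid",
    "PhantomSpec",
    "default_phantom_spec",
    "jittered_phantom_spec",
    "make_phantom",
    "simulate_conventional_flair",
    "simulate_full_kspace",
    "simulate_prospective_acquisition",
    "DEFAULT_TISSUE_PROPS",
]

#: label -> (T1 ms, T2 ms, PD); representative 3 T brain values
DEFAULT_TISSUE_PROPS: dict[int, tuple[float, float, float]] = {
    LABELS["wm"]: (850.0, 70.0, 0.65),
    LABELS["gm"]: (1300.0, 100.0, 0.80),
    LABELS["csf"]: (4300.0, 2000.0, 1.00),
    LABELS["lesion"]: (1100.0, 95.0, 0.85),
    # short-T1 fat-dominated scalp/skull compartment: bright on FLAIR,
    # which is exactly why brain extraction precedes the k-space fusion
    LABELS["skull"]: (380.0, 60.0, 0.90),
}


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned-in-z ellipsoid with optional in-plane rotation."""

    center: tuple[float, float, float]  # (z, y, x), voxels
    axes: tuple[float, float, float]    # semi-axes (az, ay, ax), voxels
    rot_deg: float = 0.0

    def contains(self, zz: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
        cz, cy, cx = self.center
        az, ay, ax = self.axes
        dz, dy, dx = zz - cz, yy - cy, xx - cx
        if self.rot_deg:
            th = np.radians(self.rot_deg)
            dy, dx = np.cos(th) * dy + np.sin(th) * dx, -np.sin(th) * dy + np.cos(th) * dx
        return (dz / az) ** 2 + (dy / ay) ** 2 + (dx / ax) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one synthetic head and its acquisition.

    ``structures`` must be nested scalp > skull-inner > brain > WM, with
    ventricles and lesions inside the WM core; violation raises at
    rasterization.  ``lesion_mismatch`` is the multiplicative
    hyperintensity lambda applied to lesion voxels of the *conventional*
    simulation only.  ``noise_sigma`` is the per-sample complex k-space
    noise std relative to the image RMS.
    """

    shape: tuple[int, int, int] = (30, 224, 224)
    structures: dict[str, Ellipsoid | tuple[Ellipsoid, ...]] = field(default_factory=dict)
    tissue_props: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_PROPS))
    lesion_mismatch: float = 1.8
    #: multiplicative un-modeled attenuation of the *conventional* signal per
    #: tissue label: magnetization transfer in a TSE echo train saturates
    #: WM most and GM somewhat, while fluids and lesions are barely affected
    unmodeled_tissue_factors: dict[int, float] = field(
        default_factory=lambda: {LABELS["wm"]: 0.88, LABELS["gm"]: 0.94})
    noise_sigma: float = 0.02
    texture_sigma: float = 0.02
    rigid_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (dy, dx, theta)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_mismatch < 1.0:
            raise InputError(
                f"lesion_mismatch must be >= 1, got {self.lesion_mismatch}"
            )
        if self.noise_sigma < 0:
            raise InputError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if not (0.0 <= self.texture_sigma < 0.5):
            raise InputError(
                f"texture_sigma must be in [0, 0.5), got {self.texture_sigma}")
        if not self.structures:
            object.__setattr__(
                self, "structures", _default_structures(self.shape))


def _default_structures(shape: tuple[int, int, int]) -> dict[str, "Ellipsoid | tuple"]:
    """Head geometry scaled to the grid (fractions of the half-extents)."""
    nz, ny, nx = shape
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    hz, hy, hx = nz / 2, ny / 2, nx / 2

    def ell(fz, fy, fx, dz=0.0, dy=0.0, dx=0.0, rot=0.0):
        return Ellipsoid(center=(cz + dz * hz, cy + dy * hy, cx + dx * hx),
                         axes=(fz * hz, fy * hy, fx * hx), rot_deg=rot)

    return {
        # scalp/skull z-axes exceed the slab: the head continues beyond the
        # imaged slices, so their in-plane radius varies slowly and the dark
        # skull gap separates scalp from brain on every slice
        "scalp": ell(1.70, 0.94, 0.82),
        "skull": ell(1.60, 0.88, 0.74),
        "brain": ell(0.90, 0.78, 0.62),
        "wm": ell(0.80, 0.64, 0.48),
        "ventricles": (
            ell(0.45, 0.18, 0.06, dy=-0.04, dx=-0.10),
            ell(0.45, 0.18, 0.06, dy=-0.04, dx=+0.10),
        ),
        "lesion": ell(0.35, 0.085, 0.075, dy=0.22, dx=0.16, rot=20.0),
    }


def default_phantom_spec(shape: tuple[int, int, int] = (30, 224, 224),
                         seed: int = 0, **overrides) -> PhantomSpec:
    """The reference phantom on the given grid (default 30 x 224 x 224)."""
    return PhantomSpec(shape=shape, seed=seed, **overrides)


def jittered_phantom_spec(seed: int,
                          shape: tuple[int, int, int] = (30, 224, 224),
                          **overrides) -> PhantomSpec:
    """A per-subject variant: geometry perturbed by a seeded RNG.

    Centers move by up to ~1.5% of the grid and semi-axes scale by up to
    ~4%, emulating anatomical variability across a cohort while keeping
    structure nesting intact.
    """
    rng = np.random.default_rng(seed)
    base = _default_structures(shape)
    g = np.array(shape, dtype=float)
    # the head varies as a whole (shared in-plane shift and size factor),
    # which preserves structure nesting and the dark skull gap; the lesion
    # additionally moves and rescales on its own
    head_dc = rng.uniform(-0.01, 0.01, size=3) * g
    head_dc[0] = 0.0
    head_f = rng.uniform(0.97, 1.03)
    lesion_dc = rng.uniform(-0.012, 0.012, size=3) * g
    lesion_dc[0] = 0.0
    lesion_f = rng.uniform(0.9, 1.1, size=3)
    lesion_rot = rng.uniform(-30, 30)
    center = (np.array(shape, dtype=float) - 1) / 2

    def scale_about_center(e: Ellipsoid) -> Ellipsoid:
        c = center + (np.array(e.center) - center) * head_f + head_dc
        return Ellipsoid(center=tuple(c),
                         axes=tuple(np.array(e.axes) * head_f),
                         rot_deg=e.rot_deg)

    structures: dict[str, Ellipsoid | tuple[Ellipsoid, ...]] = {}
    for name, v in base.items():
        if isinstance(v, tuple):
            structures[name] = tuple(scale_about_center(e) for e in v)
        else:
            structures[name] = scale_about_center(v)
    les = structures["lesion"]
    structures["lesion"] = Ellipsoid(
        center=tuple(np.array(les.center) + lesion_dc),
        axes=tuple(np.array(les.axes) * lesion_f),
        rot_deg=les.rot_deg + lesion_rot)
    return PhantomSpec(shape=shape, structures=structures, seed=seed,
                       **overrides)


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, QuantitativeMapSet]:
    """Rasterize the label map and fill the quantitative maps.

    A voxel takes the innermost structure's label (painting order scalp,
    skull, brain/GM, WM core, ventricles/CSF, lesion).  Nesting of the
    structures is verified and violations raise ``InputError``.
    """
    nz, ny, nx = spec.shape
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    s = spec.structures
    masks = {name: (np.any([e.contains(zz, yy, xx) for e in v], axis=0)
                    if isinstance(v, tuple) else v.contains(zz, yy, xx))
             for name, v in s.items()}

    for inner, outer in (("skull", "scalp"), ("brain", "skull"), ("wm", "brain"),
                         ("ventricles", "wm"), ("lesion", "wm")):
        if np.any(masks[inner] & ~masks[outer]):
            raise InputError(f"structure '{inner}' is not nested inside '{outer}'")
    if np.any(masks["lesion"] & masks["ventricles"]):
        raise InputError("lesion overlaps the ventricles")

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[masks["scalp"]] = LABELS["skull"]
    labels[masks["skull"]] = LABELS["skull"]
    labels[masks["brain"]] = LABELS["gm"]
    labels[masks["wm"]] = LABELS["wm"]
    labels[masks["ventricles"]] = LABELS["csf"]
    labels[masks["lesion"]] = LABELS["lesion"]
    # the bony skull itself is signal-poor: carve a dark gap between scalp
    # and brain so extraction can separate them
    gap = masks["skull"] & ~masks["brain"]

    t1 = np.zeros(spec.shape)
    t2 = np.zeros(spec.shape)
    pd = np.zeros(spec.shape)
    for lab, (v1, v2, vp) in spec.tissue_props.items():
        m = labels == lab
        t1[m], t2[m], pd[m] = v1, v2, vp
    pd[gap] = 0.0
    t1[gap] = 0.0
    t2[gap] = 0.0
    if spec.texture_sigma > 0:
        # within-tissue microstructural heterogeneity: real quantitative
        # maps are never piecewise constant, and tissue noise levels (the
        # CNR denominator) would be zero without it
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(101,)))
        fg = pd > 0
        for arr in (t1, t2, pd):
            factor = 1.0 + spec.texture_sigma * rng.standard_normal(spec.shape)
            arr[fg] *= np.clip(factor, 0.5, 1.5)[fg]
    return labels, QuantitativeMapSet(t1=t1, t2=t2, pd=pd)


# ---------------------------------------------------------------------------
# Acquisition simulation

def _line_noise(seed: int, s: int, y: int, n_x: int) -> np.ndarray:
    """Unit-modulus-variance complex noise for one k-space line.

    One RNG substream per (slice, line): the same line always draws the
    same noise for a given seed, whether or not other lines are acquired.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(s, y)))
    v = rng.standard_normal(2 * n_x)
    return (v[0::2] + 1j * v[1::2]) / np.sqrt(2.0)


def simulate_full_kspace(img: np.ndarray, noise_sigma: float,
                         seed: int) -> np.ndarray:
    """Fully sampled noisy k-space of a volume, line-keyed noise streams.

    Noise std per complex sample is ``noise_sigma * RMS(img)`` (the
    orthonormal FFT preserves RMS, so this is an image-relative SNR
    control).
    """
    img = np.asarray(img, dtype=float)
    k = np.stack([image_to_kspace(sl) for sl in img]).astype(complex)
    if noise_sigma > 0:
        sigma = noise_sigma * float(np.sqrt(np.mean(img**2)))
        for s in range(img.shape[0]):
            for y in range(img.shape[1]):
                k[s, y, :] += sigma * _line_noise(seed, s, y, img.shape[2])
    return k


def simulate_prospective_acquisition(img: np.ndarray, samp: SamplingSpec,
                                     noise_sigma: float, seed: int) -> np.ndarray:
    """Keyhole acquisition: noisy k-space on the acquired lines only.

    Draws noise from the same per-(slice, line) substreams as
    :func:`simulate_full_kspace`, so retrospectively masking the full
    acquisition reproduces this output bit-exactly.  Unacquired lines are
    zero in the returned full-grid array.
    """
    img = np.asarray(img, dtype=float)
    if img.shape[1] != samp.n_y:
        raise InputError(
            f"sampling spec n_y={samp.n_y} does not match image {img.shape}"
        )
    k = np.zeros(img.shape, dtype=complex)
    sigma = noise_sigma * float(np.sqrt(np.mean(img**2))) if noise_sigma > 0 else 0.0
    for s in range(img.shape[0]):
        ks = image_to_kspace(img[s])
        for y in samp.acquired_lines:
            k[s, y, :] = ks[y, :]
            if sigma > 0:
                k[s, y, :] += sigma * _line_noise(seed, s, int(y), img.shape[2])
    return k


def conventional_clean_image(maps: QuantitativeMapSet, labels: np.ndarray,
                             seq: SequenceParams, spec: PhantomSpec) -> np.ndarray:
    """Noiseless conventional FLAIR: the signal model warped by the
    un-modeled effects (lesion hyperintensity, per-tissue MT attenuation),
    rigidly offset if requested."""
    img = synthesize_flair(maps, seq)
    img = img.copy()
    labels = np.asarray(labels)
    img[labels == LABELS["lesion"]] *= spec.lesion_mismatch
    for lab, factor in spec.unmodeled_tissue_factors.items():
        img[labels == lab] *= factor
    dy, dx, theta = spec.rigid_offset
    if (dy, dx, theta) != (0.0, 0.0, 0.0):
        img = apply_rigid(img, RigidTransform(dy=dy, dx=dx, theta_deg=theta))
    return img


def simulate_conventional_flair(maps: QuantitativeMapSet, labels: np.ndarray,
                                seq: SequenceParams,
                                spec: PhantomSpec) -> np.ndarray:
    """Simulated conventional (fully sampled) FLAIR image.

    With ``noise_sigma == 0`` this is the clean image itself (degenerating
    to ``synthesize_flair`` when lambda = 1 and no offset); otherwise the
    magnitude reconstruction of the noisy k-space.
    """
    img = conventional_clean_image(maps, labels, seq, spec)
    if spec.noise_sigma == 0:
        return img
    k = simulate_full_kspace(img, spec.noise_sigma, spec.seed)
    return np.stack([kspace_to_image(ks, magnitude=True) for ks in k])
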