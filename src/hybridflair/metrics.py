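"""Lesion-conspicuity metrics and the paired signed-rank test.

An image arm (physics-based, hybrid, or conventional) is scored against a
tissue segmentation by:

* lesion-to-GM and lesion-to-WM signal ratios (mean lesion intensity over
  mean tissue intensity);
* lesion-to-GM and lesion-to-WM contrast-to-noise ratios, where the noise
  level is the median of the per-tissue intensity standard deviations of
  {lesion, GM, WM};
* SSIM against a reference image (structural similarity, canonical
  constants);
* a paired exact Wilcoxon signed-rank test across subjects for arm
  comparisons.

All ratio/CNR metrics are invariant to a global positive rescaling of the
image, so arms on different intensity scales are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skimage.metrics import structural_similarity

from .exceptions import DegenerateInputError, InputError

__all__ = [
    "LABELS",
    "TissueStats",
    "ContrastMetrics",
    "tissue_stats",
    "contrast_metrics",
    "ssim",
    "wilcoxon_signed_rank",
    "WilcoxonResult",
    "cohort_report",
    "METRIC_COLUMNS",
]

#: label codes of the tissue segmentation
LABELS = {
    "background": 0,
    "wm": 1,
    "gm": 2,
    "csf": 3,
    "lesion": 4,
    "skull": 5,
}

METRIC_COLUMNS = ("lesion_gm_ratio", "lesion_wm_ratio", "cnr_gm", "cnr_wm")


@dataclass(frozen=True)
class TissueStats:
    mean: float
    std: float  # sample std, n - 1 denominator
    n: int


@dataclass(frozen=True)
class ContrastMetrics:
    lesion_gm_ratio: float
    lesion_wm_ratio: float
    cnr_gm: float
    cnr_wm: float
    noise_sigma: float

    def as_dict(self) -> dict[str, float]:
        return {
            "lesion_gm_ratio": self.lesion_gm_ratio,
            "lesion_wm_ratio": self.lesion_wm_ratio,
            "cnr_gm": self.cnr_gm,
            "cnr_wm": self.cnr_wm,
            "noise_sigma": self.noise_sigma,
        }


def tissue_stats(
    img: np.ndarray,
    labels: np.ndarray,
    which: tuple[str, ...] = ("lesion", "gm", "wm"),
) -> dict[str, TissueStats]:
    """Mean, sample standard deviation and voxel count per tissue.

    Voxels are pooled over all slices (one value per subject).  Each
    requested tissue must hold at least two voxels, otherwise the sample
    standard deviation is undefined.
    """
    img = np.asarray(img, dtype=float)
    labels = np.asarray(labels)
    if img.shape != labels.shape:
        raise InputError(
            f"image {img.shape} and label map {labels.shape} grids differ"
        )
    unknown = set(np.unique(labels)) - set(LABELS.values())
    if unknown:
        raise InputError(f"unknown label codes {sorted(unknown)}")
    out: dict[str, TissueStats] = {}
    for name in which:
        vals = img[labels == LABELS[name]]
        if vals.size < 2:
            raise InputError(
                f"tissue '{name}' has {vals.size} voxel(s); need >= 2"
            )
        out[name] = TissueStats(mean=float(vals.mean()),
                                std=float(vals.std(ddof=1)),
                                n=int(vals.size))
    return out


def contrast_metrics(stats: dict[str, TissueStats]) -> ContrastMetrics:
    """Lesion-to-tissue ratios and CNRs from per-tissue statistics.

    ``ratio_X = mean_lesion / mean_X`` and
    ``CNR_X = (mean_lesion - mean_X) / sigma`` with sigma the median of
    the lesion/GM/WM sample standard deviations.
    """
    for name in ("lesion", "gm", "wm"):
        if name not in stats:
            raise InputError(f"missing statistics for tissue '{name}'")
    les, gm, wm = stats["lesion"], stats["gm"], stats["wm"]
    sigma = float(np.median([les.std, gm.std, wm.std]))
    if sigma == 0.0:
        raise DegenerateInputError("median tissue standard deviation is zero")
    if gm.mean <= 0 or wm.mean <= 0:
        raise InputError("tissue means must be positive for signal ratios")
    return ContrastMetrics(
        lesion_gm_ratio=les.mean / gm.mean,
        lesion_wm_ratio=les.mean / wm.mean,
        cnr_gm=(les.mean - gm.mean) / sigma,
        cnr_wm=(les.mean - wm.mean) / sigma,
        noise_sigma=sigma,
    )


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean structural similarity of ``a`` against reference ``b``.

    11x11 Gaussian weights (sigma 1.5), K1 = 0.01, K2 = 0.03, dynamic
    range taken from the reference.  3-D volumes are scored per slice and
    averaged (multi-2D acquisition).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError(f"shapes differ: {a.shape} vs {b.shape}")
    rng = float(b.max() - b.min())
    if rng == 0.0:
        raise DegenerateInputError("constant reference image")
    kw = dict(win_size=11, gaussian_weights=True, sigma=1.5,
              use_sample_covariance=False, K1=0.01, K2=0.03, data_range=rng)
    if a.ndim == 2:
        return float(structural_similarity(a, b, **kw))
    if a.ndim == 3:
        return float(np.mean([structural_similarity(a[s], b[s], **kw)
                              for s in range(a.shape[0])]))
    raise InputError(f"expected 2-D or 3-D arrays, got ndim={a.ndim}")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test

@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    p_value: float
    n_used: int
    n_zero: int  #: zero differences discarded (classic Wilcoxon convention)
    exact: bool


#: largest sample for which the exact null distribution is enumerated
_EXACT_N_MAX = 25


def wilcoxon_signed_rank(diffs: np.ndarray) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded; ties in |d| receive midranks.  For
    n <= 25 the two-sided p-value is exact, from the full null
    distribution of W+ over all 2^n sign assignments (computed by dynamic
    programming over the doubled, hence integer, midranks); beyond that a
    normal approximation with continuity and tie corrections is used.
    """
    d = np.asarray(diffs, dtype=float).ravel()
    if not np.all(np.isfinite(d)):
        raise InputError("non-finite differences")
    nz = d[d != 0]
    n_zero = int(d.size - nz.size)
    if nz.size == 0:
        raise DegenerateInputError("all paired differences are zero")
    n = int(nz.size)
    if n < 5:
        raise InputError(f"need >= 5 nonzero differences, got {n}")

    ranks = rankdata(np.abs(nz))  # midranks
    w_plus = float(ranks[nz > 0].sum())

    if n <= _EXACT_N_MAX:
        r2 = np.rint(2 * ranks).astype(np.int64)  # doubled midranks: integers
        total = int(r2.sum())
        # counts[w] = number of sign assignments with doubled W+ == w
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[:total + 1 - r]
            counts = counts + shifted
        w2 = int(round(2 * w_plus))
        n_conf = counts.sum()  # == 2**n
        cdf = counts[: w2 + 1].sum() / n_conf
        sf = counts[w2:].sum() / n_conf
        p = min(1.0, 2.0 * min(cdf, sf))
        return WilcoxonResult(w_plus=w_plus, p_value=float(p), n_used=n,
                              n_zero=n_zero, exact=True)

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
    from scipy.stats import norm

    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return WilcoxonResult(w_plus=w_plus, p_value=float(p), n_used=n,
                          n_zero=n_zero, exact=False)


# ---------------------------------------------------------------------------
# Cohort aggregation

def cohort_report(
    physics: pd.DataFrame,
    hybrid: pd.DataFrame,
    conventional: pd.DataFrame | None = None,
    exclude: "pd.Series | np.ndarray | list | None" = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-metric cohort summary and paired hybrid-vs-physics tests.

    Each arm is a DataFrame indexed by subject with the four contrast
    metric columns.  ``exclude`` flags subjects to drop (a boolean vector
    aligned with the index, or a list of subject ids) — e.g. subjects
    whose lesion polarity makes the ratio metrics meaningless; this is a
    user-supplied judgment, never computed here.

    Returns ``(summary, tests)``: arm means per metric over the included
    subjects, and the exact Wilcoxon signed-rank p-value of hybrid versus
    physics per metric.
    """
    arms = {"physics": physics, "hybrid": hybrid}
    if conventional is not None:
        arms["conventional"] = conventional
    idx = physics.index
    for name, df in arms.items():
        if not df.index.equals(idx):
            raise InputError(f"subject index of arm '{name}' does not match")
        missing = [c for c in METRIC_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"arm '{name}' lacks metric columns {missing}")

    if exclude is None:
        keep = np.ones(len(idx), dtype=bool)
    else:
        ex = np.asarray(exclude)
        if ex.dtype == bool:
            if ex.size != len(idx):
                raise InputError("boolean exclude flags must match subjects")
            keep = ~ex
        else:
            keep = ~idx.isin(list(ex))
    n_inc = int(keep.sum())
    if n_inc < 5:
        raise InputError(f"need >= 5 included subjects, got {n_inc}")

    summary = pd.DataFrame(
        {name: df.loc[keep, list(METRIC_COLUMNS)].mean()
         for name, df in arms.items()}
    ).T
    summary.insert(0, "n", n_inc)

    rows = {}
    for col in METRIC_COLUMNS:
        d = (hybrid.loc[keep, col] - physics.loc[keep, col]).to_numpy()
        res = wilcoxon_signed_rank(d)
        rows[col] = {"w_plus": res.w_plus, "p_value": res.p_value,
                     "n_used": res.n_used, "n_zero": res.n_zero,
                     "exact": res.exact}
    tests = pd.DataFrame(rows).T
    return summary, tests
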