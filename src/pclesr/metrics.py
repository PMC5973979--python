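"""Image-quality assessment: SSIM, Global Contrast Factor, composite score.

Evaluation of super-resolved bundle images uses two complementary
metrics: the structural similarity index (SSIM) against the HR reference,
and the Global Contrast Factor (GCF), a reference-free multi-resolution
contrast measure.  Per method, six aggregate scores are produced (mean
and std of SSIM(SR, HR), of dGCF(SR, LR) and of dGCF(SR, HR)), and a
composite score averages the min-max-normalised SSIM with the normalised
dGCF(SR, LR) across the compared methods (the LR identity mapping is
always included as the baseline of that normalisation cohort).

GCF expects display intensities in [0, 1]; evaluation therefore runs on
per-frame [0, 1]-rescaled images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import stats as sps

from .errors import DegenerateInputError, InvalidArgumentError
from .image import CartesianImage
from .data import rescale_unit

__all__ = [
    "SSIMParams",
    "QualityReport",
    "ssim",
    "gcf",
    "delta_gcf",
    "composite_score",
    "paired_ttest",
    "evaluate_method",
    "evaluate_methods",
]

#: Superpixel edge lengths of the GCF resolution pyramid.
GCF_LEVELS = (1, 2, 4, 8, 16, 25, 50, 100, 200)


def _gcf_weight(i: int) -> float:
    # empirical resolution weighting of the GCF, i is the 1-based level
    x = i / 7.0
    return (-0.406385 * x + 0.334573) * x + 0.0877526


@dataclass(frozen=True)
class SSIMParams:
    """SSIM internals: 11-pixel Gaussian window (sigma 1.5), k1/k2 defaults."""

    window: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise InvalidArgumentError("window must be odd and >= 3")
        if self.k1 <= 0 or self.k2 <= 0 or self.data_range <= 0:
            raise InvalidArgumentError("SSIM constants must be positive")


def ssim_map(a: np.ndarray, b: np.ndarray, params: SSIMParams = SSIMParams()) -> np.ndarray:
    """Local SSIM map with a Gaussian window (population covariances)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidArgumentError("image shapes must match")
    radius = (params.window - 1) // 2
    truncate = radius / params.sigma

    def F(x):
        return ndi.gaussian_filter(x, params.sigma, truncate=truncate, mode="constant")

    ua, ub = F(a), F(b)
    va = F(a * a) - ua * ua
    vb = F(b * b) - ub * ub
    vab = F(a * b) - ua * ub
    c1 = (params.k1 * params.data_range) ** 2
    c2 = (params.k2 * params.data_range) ** 2
    return ((2 * ua * ub + c1) * (2 * vab + c2)) / ((ua**2 + ub**2 + c1) * (va + vb + c2))


def ssim(
    a: np.ndarray | CartesianImage,
    b: np.ndarray | CartesianImage,
    params: SSIMParams = SSIMParams(),
    mask: np.ndarray | None = None,
) -> float:
    """Mean structural similarity between two images.

    With ``mask=None`` the mean is taken over window centres whose support
    lies fully inside the frame (the convention of the standard SSIM
    implementations).  With a FoV mask, the mean runs over in-mask window
    centres; windows crossing the FoV rim see zeros outside, which is the
    rim convention of the reconstruction itself.
    """
    if isinstance(a, CartesianImage):
        if mask is None:
            mask = a.fov_mask
        a = a.pixels
    if isinstance(b, CartesianImage):
        b = b.pixels
    S = ssim_map(a, b, params)
    radius = (params.window - 1) // 2
    if mask is None:
        return float(S[radius:-radius, radius:-radius].mean())
    if mask.shape != S.shape:
        raise InvalidArgumentError("mask shape must match image shape")
    if not mask.any():
        raise InvalidArgumentError("mask is empty")
    return float(S[mask].mean())


def _block_stats(x: np.ndarray, valid: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Block-average ``x`` over w-by-w superpixels, counting only valid pixels."""
    rows, cols = x.shape
    pr, pc = (-rows) % w, (-cols) % w
    xs = np.pad(np.where(valid, x, 0.0), ((0, pr), (0, pc)))
    vs = np.pad(valid.astype(np.float64), ((0, pr), (0, pc)))
    R, C = xs.shape[0] // w, xs.shape[1] // w
    sums = xs.reshape(R, w, C, w).sum(axis=(1, 3))
    cnts = vs.reshape(R, w, C, w).sum(axis=(1, 3))
    ok = cnts > 0
    means = np.zeros_like(sums)
    means[ok] = sums[ok] / cnts[ok]
    return means, ok


def gcf(image: np.ndarray | CartesianImage, mask: np.ndarray | None = None) -> float:
    """Global Contrast Factor of a display-range [0, 1] image.

    Pixel values are gamma-linearised (``l = v**2.2``) and converted to a
    perceptual lightness ``L = 100*sqrt(l)``.  At each resolution level
    the *linear* luminance is block-averaged into superpixels of edge
    1, 2, 4, 8, 16, 25, 50, 100 and 200 pixels; the level contrast is the
    mean over superpixels of the mean absolute lightness difference to
    the 4-neighbours, and the GCF is the weighted sum of level contrasts.
    Levels whose superpixel grid is smaller than 2x2 are skipped.  With a
    FoV mask, only in-FoV pixels enter the block averages and only
    neighbour pairs of valid superpixels enter the contrasts.
    """
    if isinstance(image, CartesianImage):
        if mask is None:
            mask = image.fov_mask
        image = image.pixels
    v = np.asarray(image, dtype=np.float64)
    if mask is None:
        mask = np.ones_like(v, dtype=bool)
    vals = v[mask]
    if vals.size and (vals.min() < -1e-6 or vals.max() > 1.0 + 1e-6):
        raise InvalidArgumentError("gcf expects display intensities in [0, 1]; rescale first")
    lin = np.clip(v, 0.0, 1.0) ** 2.2

    total = 0.0
    for i, w in enumerate(GCF_LEVELS, start=1):
        lw, ok = _block_stats(lin, mask, w)
        if lw.shape[0] < 2 or lw.shape[1] < 2:
            continue
        L = 100.0 * np.sqrt(lw)
        diff_sum = np.zeros_like(L)
        diff_cnt = np.zeros_like(L)
        for axis in (0, 1):
            d = np.abs(np.diff(L, axis=axis))
            pair_ok = ok & np.roll(ok, -1, axis=axis)
            pair_ok = np.delete(pair_ok, -1, axis=axis)
            d = np.where(pair_ok, d, 0.0)
            lo = [slice(None)] * 2
            hi = [slice(None)] * 2
            lo[axis] = slice(0, -1)
            hi[axis] = slice(1, None)
            diff_sum[tuple(lo)] += d
            diff_cnt[tuple(lo)] += pair_ok
            diff_sum[tuple(hi)] += d
            diff_cnt[tuple(hi)] += pair_ok
        use = ok & (diff_cnt > 0)
        if not use.any():
            continue
        local_contrast = diff_sum[use] / diff_cnt[use]
        total += _gcf_weight(i) * float(local_contrast.mean())
    return total


def delta_gcf(
    a: np.ndarray | CartesianImage,
    b: np.ndarray | CartesianImage,
    mask: np.ndarray | None = None,
) -> float:
    """Contrast difference ``gcf(a) - gcf(b)``."""
    return gcf(a, mask) - gcf(b, mask)


def composite_score(
    ssim_means: dict[str, float], dgcf_lr_means: dict[str, float]
) -> dict[str, float]:
    """Composite quality score per method.

    Each factor (mean SSIM to HR, mean dGCF to LR) is min-max normalised
    across the compared methods, then the two normalised factors are
    averaged.  A factor that is constant across methods carries no ranking
    information and is set to the neutral value 0.5 for every method.
    """
    methods = list(ssim_means)
    if set(methods) != set(dgcf_lr_means):
        raise InvalidArgumentError("factor dictionaries must share the same methods")
    if len(methods) < 2:
        raise InvalidArgumentError("composite score needs at least 2 methods")

    def norm(factor: dict[str, float]) -> dict[str, float]:
        vals = np.asarray([factor[m] for m in methods], dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi <= lo:
            return {m: 0.5 for m in methods}
        return {m: (factor[m] - lo) / (hi - lo) for m in methods}

    ns, ng = norm(ssim_means), norm(dgcf_lr_means)
    return {m: 0.5 * (ns[m] + ng[m]) for m in methods}


def paired_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on per-image score lists (textbook formula)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InvalidArgumentError("inputs must be equal-length 1-D arrays of size >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return 0.0, 1.0
        raise DegenerateInputError("differences have zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


@dataclass
class QualityReport:
    """Aggregate quality scores of one SR method over a set of frames."""

    method: str
    ssim_mean: float
    ssim_std: float
    dgcf_lr_mean: float
    dgcf_lr_std: float
    dgcf_hr_mean: float
    dgcf_hr_std: float
    n_images: int
    tot_cs: float | None = None
    per_image: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "ssim_mean": self.ssim_mean,
            "ssim_std": self.ssim_std,
            "dgcf_lr_mean": self.dgcf_lr_mean,
            "dgcf_lr_std": self.dgcf_lr_std,
            "dgcf_hr_mean": self.dgcf_hr_mean,
            "dgcf_hr_std": self.dgcf_hr_std,
            "n_images": self.n_images,
            "tot_cs": self.tot_cs,
        }


def _prep(img: CartesianImage) -> CartesianImage:
    """Rescale to [0, 1] for metric evaluation; constant frames pass through."""
    try:
        return rescale_unit(img)
    except DegenerateInputError:
        return img


def evaluate_method(
    sr_images: list[CartesianImage],
    lr_images: list[CartesianImage],
    hr_images: list[CartesianImage],
    method: str = "sr",
    params: SSIMParams = SSIMParams(),
) -> QualityReport:
    """Six-score quality report of one method over aligned frame lists.

    Images are individually rescaled to [0, 1] before the metrics are
    computed (the GCF gamma model is defined on display intensities).
    Metrics run over in-FoV pixels.
    """
    if not (len(sr_images) == len(lr_images) == len(hr_images)):
        raise InvalidArgumentError("image lists must have equal lengths")
    if not sr_images:
        raise InvalidArgumentError("need at least one image")
    s_list, dlr_list, dhr_list = [], [], []
    for sr, lr, hr in zip(sr_images, lr_images, hr_images):
        sr, lr, hr = _prep(sr), _prep(lr), _prep(hr)
        mask = sr.fov_mask
        s_list.append(ssim(sr.pixels, hr.pixels, params, mask))
        g_sr = gcf(sr.pixels, mask)
        dlr_list.append(g_sr - gcf(lr.pixels, mask))
        dhr_list.append(g_sr - gcf(hr.pixels, mask))
    s, dlr, dhr = map(np.asarray, (s_list, dlr_list, dhr_list))
    return QualityReport(
        method=method,
        ssim_mean=float(s.mean()),
        ssim_std=float(s.std(ddof=1)) if s.size > 1 else 0.0,
        dgcf_lr_mean=float(dlr.mean()),
        dgcf_lr_std=float(dlr.std(ddof=1)) if dlr.size > 1 else 0.0,
        dgcf_hr_mean=float(dhr.mean()),
        dgcf_hr_std=float(dhr.std(ddof=1)) if dhr.size > 1 else 0.0,
        n_images=len(sr_images),
        per_image={"ssim": s, "dgcf_lr": dlr, "dgcf_hr": dhr},
    )


def evaluate_methods(
    sr_by_method: dict[str, list[CartesianImage]],
    lr_images: list[CartesianImage],
    hr_images: list[CartesianImage],
    params: SSIMParams = SSIMParams(),
) -> dict[str, QualityReport]:
    """Evaluate several methods and attach composite scores.

    The LR identity mapping is always added as the ``lr`` baseline row,
    mirroring the use of the input LR scores as the reference of the
    normalisation cohort.
    """
    reports = {
        name: evaluate_method(srs, lr_images, hr_images, method=name, params=params)
        for name, srs in sr_by_method.items()
    }
    if "lr" not in reports:
        reports["lr"] = evaluate_method(lr_images, lr_images, hr_images, method="lr", params=params)
    tot = composite_score(
        {m: r.ssim_mean for m, r in reports.items()},
        {m: r.dgcf_lr_mean for m, r in reports.items()},
    )
    for m, r in reports.items():
        r.tot_cs = tot[m]
    return reports
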