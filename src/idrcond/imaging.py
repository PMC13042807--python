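"""Imaging scalars for condensate quantification.

Line-scan condensation index (CI) and peak-to-valley ratio (PVR),
intensity-window focus segmentation with condensed area/intensity
fractions, Pearson colocalization, FRAP double normalization with a
single-exponential recovery fit, and drift-corrected acceptor-photobleach
FRET efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from skimage import measure

from . import config

__all__ = [
    "LineScan",
    "NucleusImage",
    "FociSegmentation",
    "FretRois",
    "FrapTraces",
    "FrapResult",
    "smooth",
    "condensation_index",
    "peak_valley_ratio",
    "segment_foci",
    "condensed_fractions",
    "count_puncta",
    "pearson_colocalization",
    "frap_normalize",
    "pbfret_efficiency",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineScan:
    """An ordered intensity trace sampled along a drawn line."""

    intensities: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float)
        if x.ndim != 1 or x.size == 0:
            raise ValueError("line scan must be a nonempty 1-D array")
        if not np.all(np.isfinite(x)) or np.any(x < 0):
            raise ValueError("line scan intensities must be finite and >= 0")
        object.__setattr__(self, "intensities", x)

    def __len__(self) -> int:
        return len(self.intensities)


@dataclass(frozen=True)
class NucleusImage:
    """A single-plane intensity image with a binary nucleus mask."""

    intensity: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        img = np.asarray(self.intensity, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if img.ndim != 2 or img.shape != mask.shape:
            raise ValueError("intensity and mask must be same-shape 2-D arrays")
        if not mask.any():
            raise ValueError("nucleus mask is empty")
        object.__setattr__(self, "intensity", img)
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class FociSegmentation:
    """Labeled foci within the nucleus mask with per-focus measurements."""

    labels: np.ndarray          # 0 = background, 1..n = foci
    areas: np.ndarray           # pixels per focus
    integrated: np.ndarray      # summed intensity per focus

    @property
    def n_foci(self) -> int:
        return len(self.areas)


@dataclass(frozen=True)
class FretRois:
    """Raw donor ROI intensities for acceptor-photobleach FRET.

    ``d_*`` are bleached-ROI donor means, ``dn_*`` unbleached
    (negative-control) ROI donor means; ``bg_pre``/``bg_post`` are the
    per-image background means subtracted from all ROIs of that image.
    """

    d_pre: float
    d_post: float
    dn_pre: float
    dn_post: float
    bg_pre: float = 0.0
    bg_post: float = 0.0

    def __post_init__(self) -> None:
        for name in ("d_pre", "d_post", "dn_pre", "dn_post"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FrapTraces:
    """Bleach-ROI, background-ROI and total-area traces for one cell."""

    bleach: np.ndarray
    background: np.ndarray
    total: np.ndarray
    bleach_index: int
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.bleach, dtype=float)
        g = np.asarray(self.background, dtype=float)
        t = np.asarray(self.total, dtype=float)
        if not (b.shape == g.shape == t.shape) or b.ndim != 1:
            raise ValueError("traces must be same-length 1-D arrays")
        if self.bleach_index < 5:
            raise ValueError("need >= 5 pre-bleach frames")
        if self.bleach_index >= len(b):
            raise ValueError("bleach index beyond trace")
        object.__setattr__(self, "bleach", b)
        object.__setattr__(self, "background", g)
        object.__setattr__(self, "total", t)
        if self.times is not None:
            tm = np.asarray(self.times, dtype=float)
            if tm.shape != b.shape:
                raise ValueError("times must match trace length")
            object.__setattr__(self, "times", tm)


@dataclass(frozen=True)
class FrapResult:
    normalized: np.ndarray      # double-normalized curve (pre-bleach mean 1)
    fullscale: np.ndarray       # rescaled so first post-bleach point is 0
    mobile_fraction: float
    half_time: float
    tau: float


# ---------------------------------------------------------------------------
# Line-scan metrics
# ---------------------------------------------------------------------------

def smooth(scan: LineScan, window: int = config.SMOOTH_WINDOW) -> LineScan:
    """Centered running average; the window is clipped at the trace ends
    and each output point averages the samples actually available."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    x = scan.intensities
    if window > len(x):
        raise ValueError("window longer than trace")
    if window == 1:
        return LineScan(x.copy())
    half = window // 2
    cs = np.concatenate(([0.0], np.cumsum(x)))
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    out = (cs[hi + 1] - cs[lo]) / (hi - lo + 1)
    return LineScan(out)


def condensation_index(scan: LineScan) -> float:
    """CI = (I_peak - I_baseline) / (1.4826 * MAD).

    I_baseline is the linearly interpolated 20th percentile, MAD the
    median absolute deviation from the median.  A trace whose peak equals
    its baseline has no punctum prominence and scores 0; a positive peak
    over zero dispersion indicates a degenerate trace and raises.
    """
    x = scan.intensities
    if len(x) < 11:
        raise ValueError("condensation index needs >= 11 samples")
    peak = float(np.max(x))
    baseline = float(np.percentile(x, config.CI_BASELINE_PERCENTILE))
    if peak == baseline:
        return 0.0
    mad = float(np.median(np.abs(x - np.median(x))))
    if mad == 0.0:
        raise ValueError("degenerate trace: positive peak with zero MAD")
    return (peak - baseline) / (config.MAD_CONSISTENCY * mad)


def peak_valley_ratio(scan: LineScan) -> float:
    """PVR = (I_peak - I_valley) / (I_peak + I_valley) of the trace."""
    x = scan.intensities
    peak = float(np.max(x))
    valley = float(np.min(x))
    if peak + valley == 0.0:
        raise ValueError("all-zero trace has undefined PVR")
    return (peak - valley) / (peak + valley)


# ---------------------------------------------------------------------------
# Focus segmentation and fractions
# ---------------------------------------------------------------------------

def segment_foci(
    image: NucleusImage,
    window: tuple[float, float] = config.FOCI_WINDOW,
    min_area: int = config.FOCI_MIN_AREA,
    connectivity: int = config.FOCI_CONNECTIVITY,
) -> FociSegmentation:
    """Pixels inside the intensity window within the nucleus mask,
    8-connected components, components smaller than ``min_area`` dropped.

    The window is interpreted on the image's native intensity scale.
    """
    low, high = window
    if low > high:
        raise ValueError("intensity window low > high")
    fg = image.mask & (image.intensity >= low) & (image.intensity <= high)
    labels = measure.label(fg, connectivity=connectivity)
    areas = []
    integ = []
    keep = np.zeros_like(labels)
    next_id = 0
    for region in measure.regionprops(labels, intensity_image=image.intensity):
        if region.area < min_area:
            continue
        next_id += 1
        keep[labels == region.label] = next_id
        areas.append(region.area)
        integ.append(region.area * region.intensity_mean)
    return FociSegmentation(keep, np.asarray(areas, dtype=float),
                            np.asarray(integ, dtype=float))


def condensed_fractions(
    image: NucleusImage, foci: FociSegmentation
) -> tuple[float, float]:
    """(condensed area fraction, condensed intensity fraction).

    Area fraction = total focus area over nuclear mask area; intensity
    fraction = total focus integrated fluorescence over total nuclear
    fluorescence.
    """
    if foci.labels.shape != image.intensity.shape:
        raise ValueError("segmentation does not match image")
    mask_area = float(image.mask.sum())
    total_fluor = float(image.intensity[image.mask].sum())
    if total_fluor <= 0:
        raise ValueError("zero total nuclear fluorescence")
    return (float(foci.areas.sum()) / mask_area,
            float(foci.integrated.sum()) / total_fluor)


def count_puncta(foci: FociSegmentation) -> int:
    """Number of segmented foci."""
    return foci.n_foci


def pearson_colocalization(
    image_a: np.ndarray, image_b: np.ndarray, mask: np.ndarray
) -> float:
    """Pearson correlation of two channels over the masked pixels."""
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if a.shape != b.shape or a.shape != m.shape:
        raise ValueError("images and mask must share a shape")
    xa, xb = a[m], b[m]
    if xa.size < 2 or np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ValueError("colocalization needs >= 2 distinct values per channel")
    return float(stats.pearsonr(xa, xb).statistic)


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def frap_normalize(traces: FrapTraces) -> FrapResult:
    """Double normalization of a FRAP trace and single-exponential fit.

    The bleach-ROI and total-area traces are background-subtracted, the
    bleach trace is corrected for acquisition bleaching by the total
    trace, and the result is scaled so the pre-bleach mean equals 1.  A
    full-scale curve maps the first post-bleach point to 0; the recovery
    I(t) = M * (1 - exp(-t/tau)) is fit to it, giving the mobile
    fraction M and half-time tau * ln 2.
    """
    k = traces.bleach_index
    roi = traces.bleach - traces.background
    tot = traces.total - traces.background
    t_pre = float(np.mean(tot[:k]))
    i_pre = float(np.mean(roi[:k]))
    if t_pre <= 0 or i_pre <= 0:
        raise ValueError("non-positive pre-bleach intensity")
    if np.any(tot <= 0):
        raise ValueError("non-positive total-area intensity after subtraction")
    dn = (t_pre / tot) * (roi / i_pre)
    dn = dn / float(np.mean(dn[:k]))   # pre-bleach mean exactly 1
    f0 = float(dn[k])
    if f0 >= 1.0:
        raise ValueError("no bleach depth: first post-bleach point >= pre-bleach")
    fs = (dn - f0) / (1.0 - f0)

    if traces.times is not None:
        t = traces.times - traces.times[k]
    else:
        t = np.arange(len(dn), dtype=float) - k
    t_post = t[k:]
    y_post = fs[k:]

    if np.allclose(y_post, y_post[0], atol=1e-12):
        m = float(max(y_post[0], 0.0))
        return FrapResult(dn, fs, m, float("nan"), float("nan"))

    span = float(t_post[-1] - t_post[0]) or 1.0

    def model(tt, m, tau):
        return m * (1.0 - np.exp(-tt / tau))

    p0 = (float(np.clip(y_post[-1], 0.05, 1.0)), span / 4.0)
    popt, _ = optimize.curve_fit(
        model, t_post, y_post, p0=p0,
        bounds=([0.0, 1e-9], [1.5, span * 100.0]), maxfev=10000,
    )
    m, tau = float(popt[0]), float(popt[1])
    return FrapResult(dn, fs, m, tau * np.log(2.0), tau)


# ---------------------------------------------------------------------------
# pbFRET
# ---------------------------------------------------------------------------

def pbfret_efficiency(rois: FretRois) -> float:
    """Acceptor-photobleach FRET efficiency with drift correction.

    After per-image background subtraction, the unbleached control ROI
    gives the drift factor b = DN_post / DN_pre; the bleached-ROI donor
    is corrected as Corr_D_post = D_post / b and the efficiency is
    E = 1 - D_pre / Corr_D_post = 1 - D_pre * b / D_post.  E can be
    negative when the corrected donor dims after the bleach.
    """
    d_pre = rois.d_pre - rois.bg_pre
    dn_pre = rois.dn_pre - rois.bg_pre
    d_post = rois.d_post - rois.bg_post
    dn_post = rois.dn_post - rois.bg_post
    if dn_pre <= 0 or dn_post <= 0 or d_post <= 0:
        raise ValueError("non-positive ROI intensity after background subtraction")
    b = dn_post / dn_pre
    return 1.0 - d_pre * b / d_post
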