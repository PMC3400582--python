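"""Automated per-well worm GFP quantification.

The pipeline mirrors the high-content screen's image analysis: the four
sub-images of a well are stitched, the well boundary is found on a blurred
bright-field image by thresholding at L*F (L from Otsu's method, F = 0.9),
worms are segmented inside the well from a bottom-hat filtered bright-field
image with Otsu's method — replaced by a robust outlier rule when Otsu's
effectiveness drops below 0.7 — followed by an object-area filter that
rejects debris.  Reporter signal for the well is the median GFP intensity
over worm pixels after subtracting the median non-worm background, and
condition-level values average four to eight replicate wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

__all__ = [
    "SegmentationParams",
    "OtsuResult",
    "SegmentationResult",
    "WellMeasurement",
    "stitch_tiles",
    "split_tiles",
    "otsu_threshold",
    "detect_well_boundary",
    "outlier_threshold",
    "segment_worms",
    "measure_well_fluorescence",
    "summarize_condition",
    "quantify_well",
]


class NoWellDetectedError(ValueError):
    """Raised when the bright-field image has no thresholdable well."""


@dataclass
class SegmentationParams:
    """Tunable knobs of the well/worm segmentation.

    ``well_threshold_factor`` (F) scales the Otsu level used for well
    detection; ``effectiveness_cutoff`` gates the fallback from Otsu's method
    to the median + k*MAD outlier rule; ``size_min``/``size_max`` bound
    accepted object areas in px^2; ``outlier_k`` is the MAD multiplier.
    """

    well_threshold_factor: float = 0.9
    blur_sigma: float = 5.0
    bottomhat_radius: int = 8
    effectiveness_cutoff: float = 0.7
    size_min: float = 150.0
    size_max: float = 4000.0
    outlier_k: float = 3.0
    # per-well statistic: median over all worm pixels (default) or median of
    # per-object mean intensities
    object_statistic: str = "pixel_median"

    def __post_init__(self) -> None:
        if not (0 < self.well_threshold_factor <= 1):
            raise ValueError("well_threshold_factor must be in (0, 1]")
        if not (0 < self.effectiveness_cutoff < 1):
            raise ValueError("effectiveness_cutoff must be in (0, 1)")
        if self.size_min >= self.size_max:
            raise ValueError("size_min must be < size_max")


@dataclass
class OtsuResult:
    level: float
    effectiveness: float
    degenerate: bool = False


@dataclass
class SegmentationResult:
    well_mask: np.ndarray
    worm_labels: np.ndarray
    otsu_level: float
    effectiveness: float
    method: str  # "otsu" | "outlier"
    n_objects: int
    flags: list[str] = field(default_factory=list)


@dataclass
class WellMeasurement:
    background_estimate: float
    median_worm_fluorescence: float
    n_worm_pixels: int
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return "empty-well" not in self.flags


def stitch_tiles(tiles: list[np.ndarray], layout: tuple[int, int] = (2, 2)) -> np.ndarray:
    """Reassemble row-major tiles into the full-well image (lossless)."""
    rows, cols = layout
    if len(tiles) != rows * cols:
        raise ValueError(f"expected {rows * cols} tiles, got {len(tiles)}")
    shape = tiles[0].shape
    if any(t.shape != shape for t in tiles):
        raise ValueError("tiles must share a shape")
    return np.block([[tiles[r * cols + c] for c in range(cols)] for r in range(rows)])


def split_tiles(image: np.ndarray, layout: tuple[int, int] = (2, 2)) -> list[np.ndarray]:
    """Inverse of :func:`stitch_tiles` (row-major order)."""
    rows, cols = layout
    h, w = image.shape
    if h % rows or w % cols:
        raise ValueError("image shape not divisible by tile layout")
    th, tw = h // rows, w // cols
    return [image[r * th:(r + 1) * th, c * tw:(c + 1) * tw].copy()
            for r in range(rows) for c in range(cols)]


def otsu_threshold(pixels: np.ndarray, nbins: int = 256) -> OtsuResult:
    """Otsu level L and effectiveness eta for an intensity sample.

    L maximizes the between-class variance over candidate thresholds; the
    effectiveness eta = sigma^2_between(L) / sigma^2_total is Otsu's own
    separability measure (1 for a perfectly bimodal sample, 0 for a constant
    one).  Candidates are the midpoints between consecutive distinct values
    when there are at most ``nbins`` of them, otherwise ``nbins`` evenly
    spaced levels over the observed range.  Ties break toward the lower
    threshold.  A constant sample is degenerate: eta = 0, no exception.
    """
    x = np.asarray(pixels, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty intensity sample")
    total_var = float(x.var())
    uniq = np.unique(x)
    if uniq.size < 2 or total_var == 0:
        return OtsuResult(level=float(uniq[0]), effectiveness=0.0, degenerate=True)

    if uniq.size <= nbins:
        candidates = (uniq[:-1] + uniq[1:]) / 2.0
    else:
        edges = np.linspace(x.min(), x.max(), nbins + 1)
        candidates = edges[1:-1]

    xs = np.sort(x)
    csum = np.concatenate(([0.0], np.cumsum(xs)))
    n = xs.size
    # split index: pixels <= t go to class 0
    idx = np.searchsorted(xs, candidates, side="right")
    valid = (idx > 0) & (idx < n)
    idx = idx[valid]
    candidates = candidates[valid]
    if idx.size == 0:
        return OtsuResult(level=float(uniq[0]), effectiveness=0.0, degenerate=True)
    w0 = idx / n
    w1 = 1.0 - w0
    mu0 = csum[idx] / idx
    mu1 = (csum[n] - csum[idx]) / (n - idx)
    sb = w0 * w1 * (mu0 - mu1) ** 2
    best = int(np.argmax(sb))  # first max -> lower threshold on ties
    eta = float(sb[best] / total_var)
    return OtsuResult(level=float(candidates[best]),
                      effectiveness=min(eta, 1.0))


def detect_well_boundary(brightfield: np.ndarray,
                         params: SegmentationParams | None = None) -> np.ndarray:
    """Well mask from a blurred bright-field image thresholded at L*F.

    The blurred image is thresholded at ``otsu level * well_threshold_factor``;
    the largest connected foreground component is kept and its holes filled,
    so the mask is one connected region covering the illuminated well.
    """
    params = params or SegmentationParams()
    img = np.asarray(brightfield, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    blurred = ndi.gaussian_filter(img, sigma=params.blur_sigma)
    res = otsu_threshold(blurred)
    if res.degenerate:
        raise NoWellDetectedError("constant bright-field image: no well detected")
    mask = blurred > res.level * params.well_threshold_factor
    labels, n = ndi.label(mask)
    if n == 0:
        raise NoWellDetectedError("threshold produced no foreground")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    mask = labels == keep
    return ndi.binary_fill_holes(mask)


def outlier_threshold(pixels: np.ndarray, k: float = 3.0) -> tuple[np.ndarray, bool]:
    """Foreground = pixels above median + k * (SD-consistent) MAD.

    Returns ``(mask, flagged)`` where ``flagged`` marks the degenerate case of
    an empty foreground (e.g. a constant sample).  The rule is shift
    equivariant: adding a constant to all pixels selects the same set.
    """
    x = np.asarray(pixels, dtype=float)
    if x.size == 0:
        raise ValueError("empty intensity sample")
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826
    mask = x > med + k * mad
    return mask, bool(not mask.any())


def segment_worms(brightfield: np.ndarray, well_mask: np.ndarray,
                  params: SegmentationParams | None = None) -> SegmentationResult:
    """Bottom-hat worm segmentation inside the well with gated Otsu fallback.

    Worms are darker than the well interior in bright field; the bottom-hat
    (morphological closing minus image, disk footprint) turns them into
    bright peaks on a flat background, removing smooth illumination
    gradients.  Otsu's method thresholds the filtered pixels inside the well
    unless its effectiveness is below ``effectiveness_cutoff`` (exactly at
    the cutoff Otsu is still used), in which case the median + k*MAD outlier
    rule substitutes.  Connected components with area outside
    [size_min, size_max] are discarded as debris/clumps.
    """
    params = params or SegmentationParams()
    well_mask = np.asarray(well_mask, dtype=bool)
    if not well_mask.any():
        raise ValueError("empty well mask")
    img = np.asarray(brightfield, dtype=float)

    footprint = morphology.disk(params.bottomhat_radius)
    filtered = morphology.closing(img, footprint) - img
    # the rim of the well is itself a dark-to-bright transition; analyze only
    # pixels safely interior to the well
    interior = ndi.binary_erosion(well_mask, iterations=params.bottomhat_radius + 1)
    if not interior.any():
        interior = well_mask
    vals = filtered[interior]

    flags: list[str] = []
    res = otsu_threshold(vals)
    if res.degenerate or res.effectiveness < params.effectiveness_cutoff:
        fg_vals, flagged = outlier_threshold(vals, params.outlier_k)
        method = "outlier"
        if flagged:
            flags.append("degenerate-threshold")
        fg = np.zeros_like(interior)
        fg[interior] = fg_vals
    else:
        method = "otsu"
        fg = interior & (filtered > res.level)

    labels, n = ndi.label(fg)
    if n:
        areas = ndi.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
        bad = (areas < params.size_min) | (areas > params.size_max)
        if bad.any():
            labels[np.isin(labels, np.flatnonzero(bad) + 1)] = 0
        # relabel compactly
        labels, n = ndi.label(labels > 0)
    if n == 0:
        flags.append("empty-well")
    return SegmentationResult(well_mask=well_mask, worm_labels=labels,
                              otsu_level=res.level,
                              effectiveness=res.effectiveness,
                              method=method, n_objects=int(n), flags=flags)


def measure_well_fluorescence(gfp: np.ndarray,
                              seg: SegmentationResult,
                              object_statistic: str = "pixel_median") -> WellMeasurement:
    """Background-subtracted median worm GFP for one well.

    Background is the median GFP over well pixels that are not worm objects;
    the well value is the median over all worm-object pixels of
    (gfp - background), clipped at zero.  ``object_statistic='object_median'``
    switches to the median of per-object mean intensities.
    """
    gfp = np.asarray(gfp, dtype=float)
    if gfp.shape != seg.worm_labels.shape:
        raise ValueError("gfp shape does not match segmentation")
    worm = seg.worm_labels > 0
    bg_pixels = gfp[seg.well_mask & ~worm]
    background = float(np.median(bg_pixels)) if bg_pixels.size else 0.0
    n_pix = int(worm.sum())
    flags = list(seg.flags)
    if n_pix == 0:
        if "empty-well" not in flags:
            flags.append("empty-well")
        return WellMeasurement(background_estimate=background,
                               median_worm_fluorescence=float("nan"),
                               n_worm_pixels=0, flags=flags)
    if object_statistic == "object_median":
        means = ndi.mean(gfp, labels=seg.worm_labels,
                         index=np.arange(1, seg.n_objects + 1))
        value = float(np.median(means)) - background
    else:
        value = float(np.median(gfp[worm] - background))
    return WellMeasurement(background_estimate=background,
                           median_worm_fluorescence=max(value, 0.0),
                           n_worm_pixels=n_pix, flags=flags)


def summarize_condition(measurements: list[WellMeasurement]) -> tuple[float, float, np.ndarray]:
    """Condition value = mean of per-well medians across replicate wells.

    Returns ``(mean, sd, per_well_values)``; the per-well values feed the
    downstream one-tailed t-test.  Raises if every replicate is flagged.
    """
    values = np.array([m.median_worm_fluorescence for m in measurements if m.ok])
    if values.size == 0:
        raise ValueError("all replicate wells flagged; no usable measurement")
    return float(values.mean()), float(values.std(ddof=1)) if values.size > 1 else 0.0, values


def quantify_well(well, params: SegmentationParams | None = None) -> WellMeasurement:
    """Full per-well pipeline: well boundary -> worm segmentation -> GFP median."""
    params = params or SegmentationParams()
    mask = detect_well_boundary(well.brightfield, params)
    seg = segment_worms(well.brightfield, mask, params)
    return measure_well_fluorescence(well.gfp, seg, params.object_statistic)
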