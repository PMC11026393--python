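"""Nuclei segmentation and counting on grayscale fields.

The pipeline mirrors standard high-content practice: polynomial background
(illumination) correction, Sauvola local adaptive thresholding, 8-connected
labelling with an equivalent-diameter size filter, then per-nucleus
measurements and per-well field averaging.

Sauvola's rule marks a pixel foreground when its value exceeds
``m * (1 + k * (s / R - 1))``, with m and s the local mean and standard
deviation in a square window and R a dynamic-range constant. On fluorescence
backgrounds that are uniformly dark the rule degenerates (s ~ 0 drags the
threshold to m), so an absolute intensity floor is applied on top of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "SauvolaParams",
    "NucleusMeasurement",
    "correct_illumination",
    "sauvola_threshold",
    "label_and_filter",
    "count_nuclei",
    "median_nucleus_intensity",
    "average_fields",
    "flag_bright_fields",
]

EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class SauvolaParams:
    window: int = 31
    k: float = 0.2
    R: float = 65535.0 / 2.0
    min_intensity_floor: float = 65535.0 * 0.02

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if not (0 < self.k < 1):
            raise ValueError("k must be in (0, 1)")
        if self.R <= 0:
            raise ValueError("R must be positive")

    @classmethod
    def for_diameter(cls, expected_diameter_px: float, **kw) -> "SauvolaParams":
        """Window spanning roughly two expected object diameters (odd)."""
        w = 2 * int(round(expected_diameter_px)) + 1
        return cls(window=max(w, 3), **kw)


@dataclass(frozen=True)
class NucleusMeasurement:
    label: int
    area: int
    centroid: tuple
    median_intensity: float


def _poly_terms(order: int, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            cols.append((yy**i) * (xx**j))
    return np.stack(cols, axis=-1)


def correct_illumination(
    img, poly_order: int = 2, n_iter: int = 3, clip_sigma: float = 2.5
) -> np.ndarray:
    """Subtract a fitted 2-D polynomial background, clipping output at zero.

    The background (total degree ``poly_order``) is least-squares fitted with
    iterative upper-side sigma clipping: after each fit, pixels more than
    ``clip_sigma`` residual SDs *above* the surface — the bright foreground
    objects — are dropped and the surface refitted, so stained cells do not
    drag the background estimate upward. A constant image comes back as all
    zeros rather than an error.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) <= 16:
        raise ValueError("image must be 2-D and larger than 16x16")
    if poly_order not in (1, 2, 3, 4):
        raise ValueError("poly_order must be in 1..4")
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    # normalized coords keep the Vandermonde well-conditioned
    yn = 2.0 * yy / h - 1.0
    xn = 2.0 * xx / w - 1.0
    A_full = _poly_terms(poly_order, yn.ravel(), xn.ravel())
    stride = max(1, int(np.sqrt(h * w / 40_000)))
    sub = (slice(None, None, stride),)
    A = _poly_terms(poly_order, yn[::stride, ::stride].ravel(), xn[::stride, ::stride].ravel())
    vals = img[::stride, ::stride].ravel()
    keep = np.ones(vals.size, dtype=bool)
    coef = np.zeros(A.shape[1])
    for _ in range(n_iter):
        coef, *_ = np.linalg.lstsq(A[keep], vals[keep], rcond=None)
        res = vals - A @ coef
        sd = res[keep].std()
        if sd <= 1e-6 * max(1.0, float(np.abs(vals).max())):
            break  # surface already explains the kept pixels
        nxt = res <= clip_sigma * sd
        if nxt.sum() < 4 * A.shape[1]:
            break
        keep = nxt
    background = (A_full @ coef).reshape(h, w)
    return np.clip(img - background, 0.0, None)


def sauvola_threshold(img, params: SauvolaParams) -> np.ndarray:
    """Binary foreground mask by Sauvola's local rule plus an intensity floor.

    Local mean/SD are computed in a ``window`` x ``window`` box with
    reflective (mirror) border padding. A pixel is foreground iff
    ``value > m * (1 + k * (s/R - 1))`` and ``value > min_intensity_floor``.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if params.window > min(img.shape):
        raise ValueError("window larger than image")
    m = ndimage.uniform_filter(img, size=params.window, mode="mirror")
    m2 = ndimage.uniform_filter(img * img, size=params.window, mode="mirror")
    s = np.sqrt(np.maximum(m2 - m * m, 0.0))
    thresh = m * (1.0 + params.k * (s / params.R - 1.0))
    return (img > thresh) & (img > params.min_intensity_floor)


def label_and_filter(
    mask, min_diameter_px: float, max_diameter_px: float
) -> np.ndarray:
    """8-connected labelling with an equivalent-diameter size filter.

    Components whose equivalent diameter 2*sqrt(area/pi) falls outside
    [min, max] are removed; surviving labels are compacted to 1..n in raster
    order of each component's first pixel.
    """
    if not (0 < min_diameter_px < max_diameter_px):
        raise ValueError("require 0 < min_diameter < max_diameter")
    mask = np.asarray(mask, dtype=bool)
    raw, n = ndimage.label(mask, structure=EIGHT_CONN)
    if n == 0:
        return np.zeros(mask.shape, dtype=np.int32)
    areas = np.bincount(raw.ravel())[1:]
    eq_diam = 2.0 * np.sqrt(areas / np.pi)
    keep = (eq_diam >= min_diameter_px) & (eq_diam <= max_diameter_px)
    # raster order of first pixel
    flat = raw.ravel()
    first_seen = []
    seen = np.zeros(n + 1, dtype=bool)
    for lab in flat:
        if lab and not seen[lab]:
            seen[lab] = True
            first_seen.append(lab)
    lut = np.zeros(n + 1, dtype=np.int32)
    nxt = 1
    for lab in first_seen:
        if keep[lab - 1]:
            lut[lab] = nxt
            nxt += 1
    return lut[raw]


def count_nuclei(labels) -> int:
    """Number of distinct non-zero labels in a label mask."""
    labels = np.asarray(labels)
    u = np.unique(labels)
    return int((u != 0).sum())


def median_nucleus_intensity(labels, intensity_img) -> list[NucleusMeasurement]:
    """Per-label area, centroid and median intensity under the label."""
    labels = np.asarray(labels)
    intensity = np.asarray(intensity_img, dtype=float)
    if labels.shape != intensity.shape:
        raise ValueError("label and intensity images must share a shape")
    out = []
    present = np.unique(labels)
    present = present[present != 0]
    if present.size == 0:
        return out
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, present)
    for lab, cen in zip(present, centroids):
        sel = labels == lab
        out.append(
            NucleusMeasurement(
                label=int(lab),
                area=int(sel.sum()),
                centroid=(float(cen[0]), float(cen[1])),
                median_intensity=float(np.median(intensity[sel])),
            )
        )
    return out


def average_fields(values) -> float:
    """Arithmetic mean over a well's imaging fields, ignoring missing fields.

    Missing (NaN/None) fields are excluded and logged; if every field is
    excluded the well-level value is NaN.
    """
    arr = np.array([np.nan if v is None else v for v in values], dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one field")
    bad = int(np.isnan(arr).sum())
    if bad:
        logger.info("excluded %d missing/QC-failed field(s) of %d", bad, arr.size)
    if bad == arr.size:
        return float("nan")
    return float(np.nanmean(arr))


def flag_bright_fields(p99_intensities, ratio: float = 5.0) -> np.ndarray:
    """Automatic QC: flag fields whose background-corrected 99th-percentile
    intensity exceeds ``ratio`` times the plate median of that statistic."""
    p99 = np.asarray(p99_intensities, dtype=float)
    med = np.nanmedian(p99)
    return p99 > ratio * med
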