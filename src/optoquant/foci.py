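"""Transcription-site (MS2 focus) detection and counting.

Per-frame pipeline: a small median filter removes salt-and-pepper
pixels; a much larger median filter estimates the background, which is
subtracted; a light Gaussian blur smooths the residual; the result is
thresholded with a threshold that increases logarithmically during nc14
(nuclear background rises through the cycle); one-pixel objects,
objects touching the frame border and objects outside the embryo mask
are discarded; finally only objects containing at least one raw pixel
above a second, higher threshold survive — the low threshold finds both
real foci and noise, the high threshold removes the noise.

Counting is instantaneous (not cumulative); per-embryo series are
normalized by the starting count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import rank
from skimage.morphology import footprint_rectangle

from .stacks import ImageStack


@dataclass
class FociParams:
    median_small_px: int = 3        # salt-and-pepper removal
    median_bg_px: int = 51          # background estimation scale
    gauss_sigma_px: float = 1.0
    thr_low: float = 500.0          # a.u., on the processed image
    thr_high_raw: float = 2600.0    # a.u., on the raw image
    thr_log_coeff: float = 0.0      # user-defined logarithmic increase
    nc14_start_frame: int = 0
    min_object_px: int = 2          # one-pixel objects are removed
    embryo_min_area_px: int = 100   # sub-embryo components discarded
    embryo_blur_sigma_px: float = 8.0

    def __post_init__(self):
        if self.median_small_px < 3 or self.median_small_px % 2 == 0:
            raise ValueError("median_small_px must be odd and >= 3")
        if self.median_bg_px <= self.median_small_px or self.median_bg_px % 2 == 0:
            raise ValueError("median_bg_px must be odd and > median_small_px")
        if self.thr_low <= 0:
            raise ValueError("thr_low must be positive")
        if self.thr_high_raw < self.thr_low:
            raise ValueError("thr_high_raw must be >= thr_low")


@dataclass
class EmbryoMask:
    mask: np.ndarray
    area_px: int


@dataclass
class FociFrame:
    frame: int
    centroids: np.ndarray       # (n, 2) float (y, x)
    labels: np.ndarray          # (n,) int object ids

    def __len__(self):
        return len(self.centroids)


@dataclass
class FociCountSeries:
    time_min: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray | None
    normalization_failed: bool = False


def compute_embryo_mask(stack: ImageStack, params: FociParams) -> EmbryoMask:
    """Segment the whole embryo from the temporal projection.

    Max-projects over time, blurs, thresholds, closes morphologically,
    drops components below ``embryo_min_area_px`` and keeps the largest.
    """
    proj = np.max(np.asarray(stack.data, dtype=float), axis=0)
    blurred = ndimage.gaussian_filter(proj, params.embryo_blur_sigma_px)
    if blurred.max() <= 0:
        raise ValueError("no embryo found")
    thr = 0.5 * (blurred.max() + blurred.min())
    mask = blurred > thr
    mask = ndimage.binary_closing(mask, structure=np.ones((5, 5)))
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no embryo found")
    sizes = ndimage.sum(mask, lab, index=np.arange(1, n + 1))
    sizes[sizes < params.embryo_min_area_px] = 0
    if sizes.max() == 0:
        raise ValueError("no embryo found")
    mask = lab == (1 + int(np.argmax(sizes)))
    return EmbryoMask(mask=mask, area_px=int(mask.sum()))


def threshold_schedule(frame: int, params: FociParams,
                       n_nc14_frames: int) -> float:
    """Detection threshold for a frame.

    Constant at ``thr_low`` before nc14; from the start of nc14 it grows
    as ``thr_low * (1 + c * ln(1 + (f - f14) / n_nc14))`` — a slow
    logarithmic ramp tracking the rising nuclear background.
    """
    if n_nc14_frames < 1:
        raise ValueError("n_nc14_frames must be >= 1")
    if frame < params.nc14_start_frame:
        return float(params.thr_low)
    rel = (frame - params.nc14_start_frame) / n_nc14_frames
    return float(params.thr_low * (1.0 + params.thr_log_coeff * np.log1p(rel)))


def preprocess_frame(image: np.ndarray, params: FociParams) -> np.ndarray:
    """Median-denoise, subtract median background, Gaussian-blur."""
    img = np.asarray(image, dtype=float)
    small = ndimage.median_filter(img, size=params.median_small_px)
    # Large-kernel median via a sliding-histogram rank filter (uint16).
    as_u16 = np.clip(np.round(small), 0, 65535).astype(np.uint16)
    bg = rank.median(
        as_u16, footprint_rectangle((params.median_bg_px,) * 2)
    ).astype(float)
    resid = small - bg
    return ndimage.gaussian_filter(resid, params.gauss_sigma_px)


def detect_foci_frame(image: np.ndarray, embryo: EmbryoMask,
                      params: FociParams, frame: int = 0,
                      n_nc14_frames: int = 1,
                      processed: np.ndarray | None = None) -> FociFrame:
    """Detect transcription sites in one frame.

    ``processed`` may carry a precomputed :func:`preprocess_frame`
    output to avoid repeating the filtering.
    """
    img = np.asarray(image, dtype=float)
    if img.shape != embryo.mask.shape:
        raise ValueError("image and embryo mask shapes differ")
    if processed is None:
        processed = preprocess_frame(img, params)
    thr = threshold_schedule(frame, params, n_nc14_frames)
    binary = processed > thr
    lab, n = ndimage.label(binary)
    if n == 0:
        return FociFrame(frame=frame, centroids=np.empty((0, 2)),
                         labels=np.empty(0, dtype=int))
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum(binary, lab, index=idx)
    keep = sizes >= params.min_object_px

    # Border objects: any pixel on the outermost frame rows/columns.
    border = np.zeros_like(binary)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    on_border = ndimage.maximum(border, lab, index=idx).astype(bool)
    keep &= ~on_border

    # Embryo restriction: the object's centroid must lie in the mask.
    cents_all = np.asarray(ndimage.center_of_mass(binary, lab, index=idx))
    ri = np.clip(np.round(cents_all[:, 0]).astype(int), 0, img.shape[0] - 1)
    ci = np.clip(np.round(cents_all[:, 1]).astype(int), 0, img.shape[1] - 1)
    keep &= embryo.mask[ri, ci]

    # Second pass: at least one raw pixel above the high threshold.
    raw_max = ndimage.maximum(img, lab, index=idx)
    keep &= raw_max > params.thr_high_raw

    kept = idx[keep]
    return FociFrame(frame=frame, centroids=cents_all[keep], labels=kept)


def detect_foci_movie(stack: ImageStack, params: FociParams,
                      embryo: EmbryoMask | None = None) -> list[FociFrame]:
    """Run detection over every frame of a movie."""
    if embryo is None:
        embryo = compute_embryo_mask(stack, params)
    n14 = max(stack.n_frames - params.nc14_start_frame, 1)
    return [
        detect_foci_frame(stack.data[f], embryo, params, frame=f,
                          n_nc14_frames=n14)
        for f in range(stack.n_frames)
    ]


def count_series(foci: list[FociFrame],
                 frame_interval_s: float) -> FociCountSeries:
    """Instantaneous focus counts with start-count normalization."""
    if not foci:
        raise ValueError("need at least one frame")
    counts = np.array([len(f) for f in foci], dtype=int)
    time_min = np.array([f.frame for f in foci]) * frame_interval_s / 60.0
    if counts[0] == 0:
        return FociCountSeries(time_min=time_min, counts=counts,
                               normalized=None, normalization_failed=True)
    return FociCountSeries(time_min=time_min, counts=counts,
                           normalized=counts / counts[0])
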