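"""Nuclei segmentation, midline-band selection, intensity traces and
nearest-neighbor tracking with gap closing.

Segmentation is edge-based: a Laplacian-of-Gaussian filter (sigma 4 px
for population movies, 10 px for high-zoom FRAP fields) outlines each
nucleus, closed contours are filled, touching nuclei are split by
watershed, and a size gate removes partial or merged objects.  Frames
where nothing is detected (e.g. when blue light switches) reuse the
previous frame's segmentation.

For population movies the embryo outline is fit with an ellipse and
only nuclei within a fixed band around the major-axis midline are
quantified.  Tracking joins nearest centroids under a one-nucleus-radius
cutoff, searches up to ten frames back for lost nuclei, and discards
tracks that miss the movie's start or end or cover less than half of
the frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .geometry import EllipseParams, fit_ellipse_lsq
from .stacks import ImageStack


@dataclass
class SegParams:
    log_sigma_px: float = 4.0           # 4 population view, 10 high zoom
    min_area_px: float | None = None    # default: 0.25 x median area
    max_area_px: float | None = None    # default: 4 x median area
    carry_forward: bool = True
    embryo_blur_sigma_px: float = 1.0
    embryo_norm_threshold: float = 0.005
    midline_band_px: float = 100.0
    log_response_frac: float = 0.05     # LoG edge strength cutoff
    min_width_frac: float = 0.5         # inscribed-radius gate vs median
    min_intensity_frac: float | None = 0.5   # vs median object mean
    collapse_frac: float = 0.25         # carry forward if count collapses

    def __post_init__(self):
        if self.log_sigma_px <= 0:
            raise ValueError("log_sigma_px must be positive")
        if not (0 < self.embryo_norm_threshold < 1):
            raise ValueError("embryo_norm_threshold must be in (0,1)")
        if self.min_area_px is not None and self.max_area_px is not None \
                and self.min_area_px >= self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")


@dataclass
class NucleusObject:
    label: int
    centroid: tuple       # (y, x) px
    area: float
    mean_intensity: float


@dataclass
class SegmentationFrame:
    frame: int
    label_image: np.ndarray
    objects: list
    carried_forward: bool = False


@dataclass
class TrackSet:
    #: per track: list of (frame, (y, x), mean_intensity)
    tracks: list = field(default_factory=list)
    #: per track: list of bridged (gap_start_frame, gap_stop_frame)
    gaps: list = field(default_factory=list)
    n_input_frames: int = 0


def segment_nuclei_frame(image: np.ndarray, params: SegParams,
                         prev: SegmentationFrame | None = None,
                         frame: int = 0) -> SegmentationFrame:
    """Segment one frame by LoG edges, filling, watershed and size gate.

    Falls back to ``prev``'s labels (intensities re-measured on the
    current frame) when nothing is detected and carry-forward is on.
    """
    img = np.asarray(image, dtype=float)
    L = ndimage.gaussian_laplace(img, params.log_sigma_px)
    scale = float(np.abs(L).max())
    mask = np.zeros(img.shape, dtype=bool)
    if scale > 0:
        # Bright blobs give a negative LoG ring just inside their edge;
        # filling the ring recovers the blob.
        mask = ndimage.binary_fill_holes(L < -params.log_response_frac * scale)

    labels = np.zeros(img.shape, dtype=int)
    if mask.any():
        distance = ndimage.distance_transform_edt(mask)
        min_dist = max(int(2 * params.log_sigma_px), 3)
        peaks = peak_local_max(distance, min_distance=min_dist,
                               labels=mask, exclude_border=False)
        markers = np.zeros(img.shape, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        if len(peaks):
            labels = watershed(-distance, markers, mask=mask)
        else:
            labels, _ = ndimage.label(mask)

    objects = _measure(labels, img)
    objects, labels = _size_gate(objects, labels, params)
    objects, labels = _refine_cores(objects, labels, img)

    # Carry the previous segmentation forward when detection fails or
    # collapses (contrast inversion while illumination switches leaves
    # almost nothing nucleus-like); intensities are re-measured on the
    # current frame.
    collapsed = prev is not None and prev.objects and \
        len(objects) < params.collapse_frac * len(prev.objects)
    if not objects or (params.carry_forward and collapsed):
        if params.carry_forward and prev is not None and prev.objects:
            lab = prev.label_image
            objs = _measure(lab, img)
            return SegmentationFrame(frame=frame, label_image=lab,
                                     objects=objs, carried_forward=True)
        raise ValueError("no nuclei detected and no previous segmentation")
    return SegmentationFrame(frame=frame, label_image=labels, objects=objects)


def _measure(labels: np.ndarray, img: np.ndarray) -> list:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return []
    cents = ndimage.center_of_mass(np.ones_like(img), labels, index=ids)
    areas = ndimage.sum(labels > 0, labels, index=ids)
    # Mean intensity on a 1-px eroded mask: boundary pixels mix nucleus
    # and cytoplasm and would bias the nuclear mean.
    eroded = labels.copy()
    eroded[~ndimage.binary_erosion(labels > 0)] = 0
    means = []
    for lb in ids:
        sel = eroded == lb
        if not sel.any():
            sel = labels == lb
        means.append(float(img[sel].mean()))
    return [
        NucleusObject(label=int(lb), centroid=(float(c[0]), float(c[1])),
                      area=float(a), mean_intensity=float(m))
        for lb, c, a, m in zip(ids, cents, areas, means)
    ]


def _size_gate(objects, labels, params: SegParams):
    if not objects:
        return objects, labels
    areas = np.array([o.area for o in objects])
    med = float(np.median(areas))
    lo = params.min_area_px if params.min_area_px is not None else 0.25 * med
    hi = params.max_area_px if params.max_area_px is not None else 4.0 * med
    # Width gate: thin objects (embryo-edge fragments, partial nuclei)
    # have a small inscribed radius even when their area passes.
    dist = ndimage.distance_transform_edt(labels > 0)
    widths = np.array([float(ndimage.maximum(dist, labels, index=o.label))
                       for o in objects])
    w_med = float(np.median(widths))
    wide = {o.label for o, w in zip(objects, widths)
            if w >= params.min_width_frac * w_med}
    # Intensity gate: cytoplasm patches enclosed by edge contours have
    # nucleus-like sizes but sit well below the nuclear brightness.
    bright = {o.label for o in objects}
    if params.min_intensity_frac is not None:
        i_med = float(np.median([o.mean_intensity for o in objects]))
        bright = {o.label for o in objects
                  if o.mean_intensity >= params.min_intensity_frac * i_med}
    kept = [o for o in objects
            if lo <= o.area <= hi and o.label in wide and o.label in bright]
    if len(kept) != len(objects):
        drop = {o.label for o in objects} - {o.label for o in kept}
        labels = labels.copy()
        labels[np.isin(labels, list(drop))] = 0
    # Relabel contiguously from 1.
    out = np.zeros_like(labels)
    remap = []
    for new, o in enumerate(kept, start=1):
        out[labels == o.label] = new
        remap.append(NucleusObject(label=new, centroid=o.centroid,
                                   area=o.area,
                                   mean_intensity=o.mean_intensity))
    return remap, out


def _refine_cores(objects, labels, img):
    """Shrink objects to their bright intensity core.

    Watershed regions of nuclei abutting the embryo boundary drag in a
    tail of dimmer edge pixels that shifts the centroid; when an object
    shows strong internal contrast, keep only its upper-intensity core
    (largest connected component above the percentile midpoint).
    Homogeneous objects are left untouched.
    """
    if not objects:
        return objects, labels
    out_labels = labels.copy()
    refined = []
    for o in objects:
        sel = labels == o.label
        vals = img[sel]
        p5, p95 = np.percentile(vals, [5, 95])
        if p95 <= 0 or (p95 - p5) <= 0.3 * p95:
            refined.append(o)
            continue
        core = sel & (img > 0.5 * (p5 + p95))
        lab_c, n_c = ndimage.label(core)
        if n_c == 0 or core.sum() < 0.25 * sel.sum():
            refined.append(o)
            continue
        sizes = ndimage.sum(core, lab_c, index=np.arange(1, n_c + 1))
        core = lab_c == (1 + int(np.argmax(sizes)))
        out_labels[sel] = 0
        out_labels[core] = o.label
        cy, cx = ndimage.center_of_mass(core)
        refined.append(NucleusObject(
            label=o.label, centroid=(float(cy), float(cx)),
            area=float(core.sum()), mean_intensity=float(img[core].mean())))
    return refined, out_labels


def segment_movie(stack: ImageStack, params: SegParams) -> list:
    """Segment every frame, carrying segmentation across blank frames."""
    frames = []
    prev = None
    for f in range(stack.n_frames):
        seg = segment_nuclei_frame(stack.data[f], params, prev=prev, frame=f)
        frames.append(seg)
        prev = seg
    return frames


def fit_embryo_ellipse(stack: ImageStack, params: SegParams) -> EllipseParams:
    """Fit the embryo outline with an ellipse.

    Max-projects the movie, blurs, min-max normalizes, thresholds at the
    normalized level, opens and closes morphologically, and fits the
    boundary of the largest component by least squares.
    """
    proj = np.max(np.asarray(stack.data, dtype=float), axis=0)
    blurred = ndimage.gaussian_filter(proj, params.embryo_blur_sigma_px)
    # Reference the normalization to the modal (off-embryo) background:
    # detector pedestals sit well above zero and would otherwise pull
    # the low normalized threshold below the noise floor.
    lo, hi = float(np.median(blurred)), float(blurred.max())
    if hi <= lo:
        raise ValueError("blank stack: no embryo to fit")
    norm = np.clip((blurred - lo) / (hi - lo), 0.0, None)
    mask = norm > params.embryo_norm_threshold
    st = np.ones((5, 5))
    mask = ndimage.binary_closing(ndimage.binary_opening(mask, st), st)
    lab, n = ndimage.label(mask)
    if n == 0:
        raise ValueError("no embryo component found")
    sizes = ndimage.sum(mask, lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    from skimage import measure as skmeasure
    contours = skmeasure.find_contours(mask.astype(float), 0.5)
    boundary = max(contours, key=len)
    if len(boundary) < 5:
        raise ValueError("degenerate embryo boundary")
    return fit_ellipse_lsq(boundary)


def midline_band_filter(objects, ellipse: EllipseParams,
                        band_px: float = 100.0) -> list:
    """Keep nuclei within ``band_px`` of the embryo midline.

    The midline is the major-axis line of the fitted ellipse; distance
    is the signed perpendicular distance of the centroid (inclusive
    boundary).
    """
    cy, cx = ellipse.center
    so, co = np.sin(ellipse.orientation), np.cos(ellipse.orientation)
    kept = []
    for o in objects:
        oy, ox = o.centroid
        d = -(ox - cx) * so + (oy - cy) * co
        if abs(d) <= band_px:
            kept.append(o)
    return kept


def intensity_timeseries(stack: ImageStack, segmentations,
                         ellipse: EllipseParams | None = None,
                         band_px: float = 100.0):
    """Per-frame mean +/- s.d. of per-nucleus mean intensity.

    Restricts to the midline band when an ellipse is given.  Frames with
    no usable nuclei report NaN (missing), never zero.

    Returns
    -------
    dict with keys ``time_min``, ``mean``, ``sd``, ``n``.
    """
    n_frames = len(segmentations)
    mean = np.full(n_frames, np.nan)
    sd = np.full(n_frames, np.nan)
    n = np.zeros(n_frames, dtype=int)
    for i, seg in enumerate(segmentations):
        objs = seg.objects
        if ellipse is not None:
            objs = midline_band_filter(objs, ellipse, band_px)
        vals = np.array([o.mean_intensity for o in objs])
        n[i] = vals.size
        if vals.size:
            mean[i] = vals.mean()
            sd[i] = vals.std(ddof=1) if vals.size > 1 else 0.0
    return {"time_min": stack.times_min()[:n_frames], "mean": mean,
            "sd": sd, "n": n}


def link_tracks(segmentations, max_gap_frames: int = 10,
                end_window: int = 10, min_coverage: float = 0.5,
                radius_px: float | None = None) -> TrackSet:
    """Link per-frame nuclei into tracks by nearest-centroid matching.

    The matching cutoff is the radius of a single nucleus (median
    ``sqrt(area/pi)`` of the first frame unless given).  Matching is
    greedy by ascending distance, one-to-one; tracks unmatched in a
    frame stay alive for up to ``max_gap_frames`` frames and may be
    re-joined (gap closing, last known centroid, no extrapolation).

    Track filters: a track is removed if it misses any of the first
    ``end_window`` frames, any of the last ``end_window`` frames, or
    holds fewer than ``min_coverage`` of all frames.
    """
    if len(segmentations) < 2:
        raise ValueError("need at least 2 frames to track")
    n_frames = len(segmentations)
    first_objs = segmentations[0].objects
    if radius_px is None:
        if not first_objs:
            raise ValueError("first frame has no objects")
        radius_px = float(np.median(
            [np.sqrt(o.area / np.pi) for o in first_objs]))

    # active track: dict(points=[(f,(y,x),I)], gaps=[], last_frame, last_pos)
    active = []
    done = []
    for o in sorted(first_objs, key=lambda o: o.label):
        active.append({"points": [(0, o.centroid, o.mean_intensity)],
                       "gaps": [], "last_frame": 0, "last_pos": o.centroid})

    for f in range(1, n_frames):
        objs = sorted(segmentations[f].objects, key=lambda o: o.label)
        # Candidate pairs within the cutoff, tracks with gap <= max_gap.
        pairs = []
        for ti, tr in enumerate(active):
            if f - tr["last_frame"] > max_gap_frames:
                continue
            ty, tx = tr["last_pos"]
            for oi, o in enumerate(objs):
                d = np.hypot(o.centroid[0] - ty, o.centroid[1] - tx)
                if d <= radius_px:
                    pairs.append((d, ti, oi))
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_t, used_o = set(), set()
        for d, ti, oi in pairs:
            if ti in used_t or oi in used_o:
                continue
            used_t.add(ti)
            used_o.add(oi)
            tr = active[ti]
            o = objs[oi]
            if f - tr["last_frame"] > 1:
                tr["gaps"].append((tr["last_frame"] + 1, f))
            tr["points"].append((f, o.centroid, o.mean_intensity))
            tr["last_frame"] = f
            tr["last_pos"] = o.centroid
        # New tracks for unmatched objects.
        for oi, o in enumerate(objs):
            if oi not in used_o:
                active.append({"points": [(f, o.centroid, o.mean_intensity)],
                               "gaps": [], "last_frame": f,
                               "last_pos": o.centroid})
        # Retire tracks whose gap can no longer be closed.
        still = []
        for tr in active:
            if f - tr["last_frame"] > max_gap_frames:
                done.append(tr)
            else:
                still.append(tr)
        active = still
    done.extend(active)

    kept_tracks, kept_gaps = [], []
    head = set(range(min(end_window, n_frames)))
    tail = set(range(max(n_frames - end_window, 0), n_frames))
    for tr in done:
        frames = {p[0] for p in tr["points"]}
        if not head <= frames:
            continue
        if not tail <= frames:
            continue
        if len(frames) < min_coverage * n_frames:
            continue
        kept_tracks.append(tr["points"])
        kept_gaps.append(tr["gaps"])
    return TrackSet(tracks=kept_tracks, gaps=kept_gaps,
                    n_input_frames=n_frames)
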