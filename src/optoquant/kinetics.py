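"""Single-exponential recovery fitting for nuclear re-import and FRAP.

The model is

    I(t) = I_ss - alpha * exp(-beta * t)

with ``I_ss`` the steady-state intensity, ``alpha`` the difference between
the steady-state and initial intensity, and ``beta`` (1/min) the inverse
recovery time.  Time is measured from the first frame of the fit window
(first post-bleach frame for FRAP, first post-light-off frame for
re-import), and ``beta`` is always reported per minute.

Fitting is trust-region nonlinear least squares with an analytic Jacobian
and non-negativity bounds on all three parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .stats import TTestResult, ttest_pooled


@dataclass
class ExpFitResult:
    I_ss: float
    alpha: float
    beta: float          # 1/min
    fit_window: tuple    # (start_frame, end_frame) inclusive-exclusive
    rss: float
    converged: bool

    def predict(self, t_min):
        """Model evaluated at times (minutes from the window start)."""
        t = np.asarray(t_min, dtype=float)
        return self.I_ss - self.alpha * np.exp(-self.beta * t)


@dataclass
class FrapResult:
    nucleus_trace: np.ndarray
    bleach_frames: tuple
    fit: ExpFitResult
    track_centroids: np.ndarray | None = None


class FlatTraceError(ValueError):
    """Raised when a trace carries no recovery signal to fit."""


def fit_single_exponential(t_min, intensity, window=None) -> ExpFitResult:
    """Fit I(t) = I_ss - alpha * exp(-beta * (t - t0)) to a trace.

    Parameters
    ----------
    t_min : array-like
        Sample times in minutes.
    intensity : array-like
        Intensities (a.u.), same length as ``t_min``.
    window : (start, stop), optional
        Index range (stop exclusive) to fit; defaults to the whole trace.
        ``t0`` is the time of the first sample in the window.

    Returns
    -------
    ExpFitResult

    Raises
    ------
    FlatTraceError
        If the windowed trace has (numerically) zero variance, making
        ``beta`` unidentifiable.
    """
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if window is None:
        window = (0, t.size)
    lo, hi = int(window[0]), int(window[1])
    tw = t[lo:hi]
    yw = y[lo:hi]
    if tw.size < 4:
        raise ValueError("fit window needs at least 4 points")
    if not np.all(np.isfinite(yw)):
        raise ValueError("intensities must be finite")
    if yw.var() <= 1e-12 * max(yw.mean() ** 2, 1e-300):
        raise FlatTraceError("flat trace, beta unidentifiable")

    ts = tw - tw[0]
    duration = max(ts[-1], 1e-9)
    n_tail = max(1, int(np.ceil(0.1 * ts.size)))
    iss0 = float(np.mean(yw[-n_tail:]))
    alpha0 = max(iss0 - yw[0], 0.0)
    beta0 = 2.0 / duration
    x0 = np.array([max(iss0, 1e-9), max(alpha0, 1e-9), beta0])

    def resid(p):
        iss, a, b = p
        return (iss - a * np.exp(-b * ts)) - yw

    def jac(p):
        _, a, b = p
        e = np.exp(-b * ts)
        return np.column_stack([np.ones_like(ts), -e, a * ts * e])

    sol = least_squares(
        resid, x0, jac=jac, bounds=([0, 0, 0], [np.inf] * 3),
        xtol=1e-10, ftol=1e-12, gtol=1e-12, max_nfev=1000,
    )
    iss, a, b = sol.x
    return ExpFitResult(
        I_ss=float(iss), alpha=float(a), beta=float(b),
        fit_window=(lo, hi), rss=float(np.sum(sol.fun ** 2)),
        converged=bool(sol.success),
    )


def per_nucleus_recovery(tracks, light_off_frame: int,
                         frame_interval_s: float):
    """Fit the re-import recovery of every tracked nucleus after light-off.

    Parameters
    ----------
    tracks : TrackSet
        Filtered nucleus tracks (see :mod:`optoquant.nuclei`).
    light_off_frame : int
        First frame after illumination ends; the fit window runs from
        there to the end of each track.
    frame_interval_s : float
        Acquisition interval (seconds), used to convert frames to minutes.

    Returns
    -------
    (fits, summary)
        ``fits`` is a list of ExpFitResult (one per usable track, skipped
        tracks yield None); ``summary`` is a dict with across-nucleus
        mean and s.d. of I_ss, alpha and beta.
    """
    fits = []
    for track in tracks.tracks:
        frames = np.array([pt[0] for pt in track])
        inten = np.array([pt[2] for pt in track])
        sel = frames >= light_off_frame
        if sel.sum() < 4:
            fits.append(None)
            continue
        t_min = frames[sel] * frame_interval_s / 60.0
        try:
            fits.append(fit_single_exponential(t_min, inten[sel]))
        except FlatTraceError:
            fits.append(None)
    usable = [f for f in fits if f is not None]
    summary = {"n_nuclei": len(usable)}
    if usable:
        for name in ("I_ss", "alpha", "beta"):
            vals = np.array([getattr(f, name) for f in usable])
            summary[f"{name}_mean"] = float(vals.mean())
            summary[f"{name}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return fits, summary


def frap_analyze(stack, bleach_roi, bleach_frames, seg_params=None) -> FrapResult:
    """Track the center-most bleached nucleus and fit its recovery.

    Segments every frame (high-zoom LoG scale), selects the nucleus whose
    centroid is nearest the bleach-ROI center on the first frame, follows
    it by nearest-centroid tracking (carrying the previous segmentation
    across frames where segmentation fails), and fits the recovery model
    from the first post-bleach frame to the end.

    Parameters
    ----------
    stack : ImageStack
        FRAP movie.
    bleach_roi : (y, x, r)
        Bleach circle in pixels.
    bleach_frames : (start, stop)
        Frame range of the bleach (stop exclusive); fitting starts at
        ``stop``.
    seg_params : SegParams, optional
        Segmentation settings; defaults to the high-zoom preset
        (LoG sigma 10 px).
    """
    from .nuclei import SegParams, segment_nuclei_frame

    if seg_params is None:
        seg_params = SegParams(log_sigma_px=10.0)
    cy, cx, r = bleach_roi
    b_start, b_stop = int(bleach_frames[0]), int(bleach_frames[1])
    if not (0 <= b_start < b_stop <= stack.n_frames):
        raise ValueError("bleach_frames outside movie")

    prev = None
    trace = np.full(stack.n_frames, np.nan)
    centroids = np.full((stack.n_frames, 2), np.nan)
    target = None
    target_mask = None
    match_radius = None
    for f in range(stack.n_frames):
        try:
            seg = segment_nuclei_frame(stack.data[f], seg_params, prev=prev)
        except ValueError:
            if prev is None:
                raise
            seg = prev
        prev = seg
        objs = seg.objects
        if objs and match_radius is None:
            match_radius = float(np.median(
                [np.sqrt(o.area / np.pi) for o in objs]))
        k = None
        if objs:
            pts = np.array([o.centroid for o in objs])
            if target is None:
                d = np.hypot(pts[:, 0] - cy, pts[:, 1] - cx)
                k = int(np.argmin(d))
                if d[k] > r:
                    raise ValueError(
                        "no nucleus within the bleach ROI at frame 0")
            else:
                d = np.hypot(pts[:, 0] - target[0], pts[:, 1] - target[1])
                k = int(np.argmin(d))
                # The bleached nucleus can vanish from the segmentation
                # while dark; keep measuring its last known pixels rather
                # than jumping to a neighbor.
                if d[k] > match_radius:
                    k = None
        if k is not None:
            target = objs[k].centroid
            target_mask = seg.label_image == objs[k].label
        if target_mask is None:
            continue
        trace[f] = float(stack.data[f][target_mask].mean())
        centroids[f] = target

    t_min = stack.times_min()
    ok = np.isfinite(trace)
    fit = fit_single_exponential(
        t_min[ok], trace[ok],
        window=(int(np.searchsorted(np.flatnonzero(ok), b_stop)), int(ok.sum())),
    )
    return FrapResult(
        nucleus_trace=trace, bleach_frames=(b_start, b_stop), fit=fit,
        track_centroids=centroids,
    )


def compare_rates(betas_a, betas_b) -> TTestResult:
    """Pooled two-sample unpaired t-test on two sets of rate constants."""
    return ttest_pooled(betas_a, betas_b)
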