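"""Readers and writers: multi-page TIFF stacks with YAML sidecars,
CSV tables for foci, tracks and traces, and run configuration.

TIFF pages are 16-bit grayscale, one page per frame; acquisition
metadata (pixel size, frame interval) travels in a YAML sidecar next to
the TIFF because plain TIFF tags are unreliable across writers.  CSV is
comma-separated with a header row, UTF-8, floats at 6 significant
digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .stacks import ImageStack


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".yaml")


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as multi-page 16-bit TIFF plus metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.quantized(), photometric="minisblack")
    meta = {"pixel_size_um": float(stack.pixel_size_um),
            "frame_interval_s": float(stack.frame_interval_s)}
    sidecar_path(path).write_text(yaml.safe_dump(meta))


def read_stack(path, pixel_size_um: float | None = None,
               frame_interval_s: float | None = None) -> ImageStack:
    """Read a grayscale multi-page TIFF as an ImageStack.

    Metadata comes from the YAML sidecar when present; explicit
    arguments override it.  Missing metadata is an error naming the
    argument to supply.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected grayscale T x Y x X TIFF, got shape {data.shape}")
    meta = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = frame_interval_s if frame_interval_s is not None \
        else meta.get("frame_interval_s")
    if px is None:
        raise ValueError(f"{path}: pixel size unknown; pass pixel_size_um "
                         "or provide a YAML sidecar")
    if dt is None:
        raise ValueError(f"{path}: frame interval unknown; pass "
                         "frame_interval_s or provide a YAML sidecar")
    return ImageStack(data, pixel_size_um=float(px), frame_interval_s=float(dt))


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].map(lambda v: float(f"{v:.6g}"))
    return out


def write_foci_csv(path, foci) -> None:
    """Per-frame focus centroids: frame,label,y_px,x_px."""
    rows = [
        {"frame": f.frame, "label": int(lb), "y_px": float(y), "x_px": float(x)}
        for f in foci for lb, (y, x) in zip(f.labels, f.centroids)
    ]
    df = pd.DataFrame(rows, columns=["frame", "label", "y_px", "x_px"])
    _fmt(df).to_csv(path, index=False)


def read_foci_csv(path):
    """Inverse of :func:`write_foci_csv`, returning FociFrame objects."""
    from .foci import FociFrame
    df = pd.read_csv(path)
    frames = []
    n_frames = int(df["frame"].max()) + 1 if len(df) else 0
    for f in range(n_frames):
        sub = df[df["frame"] == f]
        frames.append(FociFrame(
            frame=f, centroids=sub[["y_px", "x_px"]].to_numpy(dtype=float),
            labels=sub["label"].to_numpy(dtype=int)))
    return frames


def write_count_series_csv(path, series) -> None:
    df = pd.DataFrame({
        "frame": np.arange(len(series.counts)),
        "time_min": series.time_min,
        "count": series.counts,
        "normalized": (series.normalized if series.normalized is not None
                       else np.full(len(series.counts), np.nan)),
    })
    _fmt(df).to_csv(path, index=False)


def write_tracks_csv(path, tracks) -> None:
    """track_id,frame,y_px,x_px,mean_intensity,gap_bridged."""
    rows = []
    for tid, (pts, gaps) in enumerate(zip(tracks.tracks, tracks.gaps)):
        bridged = {f for g0, g1 in gaps for f in range(g0, g1)}
        for frame, (y, x), inten in pts:
            rows.append({"track_id": tid, "frame": frame, "y_px": y,
                         "x_px": x, "mean_intensity": inten,
                         "gap_bridged": int(bool(bridged & {frame - 1}))})
    df = pd.DataFrame(rows, columns=["track_id", "frame", "y_px", "x_px",
                                     "mean_intensity", "gap_bridged"])
    _fmt(df).to_csv(path, index=False)


def write_trace_csv(path, trace: dict) -> None:
    df = pd.DataFrame({"frame": np.arange(len(trace["mean"])),
                       "time_min": trace["time_min"],
                       "mean": trace["mean"], "sd": trace["sd"],
                       "n": trace["n"]})
    _fmt(df).to_csv(path, index=False)


def write_fits_csv(path, fits, ids=None) -> None:
    """id,I_ss,alpha,beta_per_min,rss,converged (one row per fit)."""
    rows = []
    for i, fit in enumerate(fits):
        if fit is None:
            continue
        rows.append({"id": ids[i] if ids is not None else i,
                     "I_ss": fit.I_ss, "alpha": fit.alpha,
                     "beta_per_min": fit.beta, "rss": fit.rss,
                     "converged": int(fit.converged)})
    df = pd.DataFrame(rows, columns=["id", "I_ss", "alpha", "beta_per_min",
                                     "rss", "converged"])
    _fmt(df).to_csv(path, index=False)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_config(path) -> dict:
    """Load a YAML/JSON run configuration as a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text) or {}
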