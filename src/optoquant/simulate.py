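"""Synthetic embryo generator with full ground truth.

Renders the acquisition regimes the quantification pipeline is built
for, so every downstream stage can be tested against known truth:

* live nuclear-fluorescence movies of an elliptical embryo carrying a
  hexagonally packed nuclear field, a DV Gaussian concentration
  gradient, and optogenetic perturbations — reversible nuclear export
  (LEXY-like: nuclear drop with cytoplasmic rise under blue light,
  single-exponential re-entry after light-off) or light-induced
  degradation (BLID-like: both compartments decay, with a short
  post-light delay and no recovery);
* live transcription-reporter movies where nuclei inside a gene's
  expression domain carry one diffraction-limited spot whose on/off
  state follows the nuclear level under perturbation;
* FRAP movies with a circular bleach ROI recovering as
  ``I(t) = I_ss - alpha * exp(-beta t)``;
* fixed cross-section images: a peripheral ring of nuclei modulated by
  the DV gradient, plus expression channels painted over angular
  intervals of the periphery.

Defaults mirror typical confocal acquisition for this preparation:
512 x 512 px frames at 0.29 um/px every 25 s for population movies, and
0.100 um/px at one frame per 2 s for FRAP.  Output is quantized to
16 bit on write.  All randomness flows through one seeded generator, so
identical (config, seed) pairs give byte-identical stacks and truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erfc

from .geometry import EllipseParams, arc_fraction_of_theta, ellipse_arc_length, \
    ellipse_perimeter, theta_at_fraction
from .stacks import ChannelStack, ImageStack


class ConfigurationError(ValueError):
    """Simulation configuration cannot produce a valid scene."""


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class PerturbationSpec:
    """Optogenetic perturbation of nuclear levels.

    mode 'export': under light the nuclear level decays exponentially at
    ``export_rate_per_min`` toward ``floor_frac`` of baseline (exported
    protein accumulates in the cytoplasm); after light-off it re-enters
    with rate ``reimport_rate_per_min``.  mode 'degrade': both
    compartments decay at ``degrade_rate_per_min`` during light and for
    ``degrade_post_light_delay`` further frames, then hold — no recovery.
    """

    mode: str = "none"                      # none | export | degrade
    light_on_frame: int = 0
    light_off_frame: int = 0
    export_rate_per_min: float = 3.0
    reimport_rate_per_min: float = 0.24     # typical re-import inverse time
    degrade_rate_per_min: float = 0.15
    degrade_post_light_delay: int = 2       # frames
    floor_frac: float = 0.10                # nuclear signal never hits 0

    def __post_init__(self):
        if self.mode not in ("none", "export", "degrade"):
            raise ConfigurationError(f"unknown perturbation mode {self.mode!r}")
        if self.mode != "none" and not (self.light_on_frame < self.light_off_frame):
            raise ConfigurationError("need light_on_frame < light_off_frame")
        for r in (self.export_rate_per_min, self.reimport_rate_per_min,
                  self.degrade_rate_per_min):
            if r < 0:
                raise ConfigurationError("rates must be >= 0")


@dataclass
class GradientSpec:
    """DV Gaussian of nuclear concentration: A*exp(-d^2/2 sigma^2) + B.

    ``peak_position`` and ``sigma`` are fractions of the DV extent
    (arc-length fraction for cross-section views, image-axis fraction
    for ventral/dorsolateral movies); amplitudes in a.u.
    """

    amplitude: float = 8000.0
    peak_position: float = 0.5
    sigma: float = 0.15
    offset: float = 2000.0

    def value(self, frac):
        d = np.abs(np.asarray(frac, dtype=float) - self.peak_position)
        d = np.minimum(d, 1.0 - d)  # circular distance on the DV arc
        return self.amplitude * np.exp(-d * d / (2.0 * self.sigma ** 2)) + self.offset


@dataclass
class FociSpec:
    """Transcription-spot rendering and gating."""

    gene: str = "sna"
    spot_sigma_um: float = 0.3
    spot_amplitude: float = 3000.0
    activation_probability: float = 0.95
    #: domain as a band of the embryo minor axis, fractions in [0, 1]
    domain_band: tuple = (0.35, 0.65)
    deactivation_threshold_frac: float = 0.5   # of each nucleus's baseline
    deactivation_delay_frames: int = 2


@dataclass
class NoiseSpec:
    gaussian_sd: float = 300.0
    poisson: bool = False
    salt_pepper_fraction: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.salt_pepper_fraction <= 0.05):
            raise ConfigurationError("salt_pepper_fraction must be in [0, 0.05]")
        if self.gaussian_sd < 0:
            raise ConfigurationError("gaussian_sd must be >= 0")


@dataclass
class SimConfig:
    view: str = "ventral"                   # ventral | dorsolateral | cross-section-profile
    image_shape: tuple = (512, 512)
    pixel_size_um: float = 0.29
    frame_interval_s: float = 25.0
    n_frames: int = 100
    nucleus_radius_um: float = 2.6
    nucleus_spacing_um: float = 6.5
    baseline_from_gradient: bool = True
    gradient: GradientSpec = field(default_factory=GradientSpec)
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    foci: FociSpec = field(default_factory=FociSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    #: embryo semi-axes as fractions of the image (col, row)
    embryo_axes_frac: tuple = (0.46, 0.30)
    cytoplasm_frac: float = 0.25            # cytoplasm level / local baseline
    lattice_jitter_frac: float = 0.10       # s.d. as fraction of spacing
    edge_margin_px: float = 4.0             # nuclei keep clear of the outline
    drift_px_per_frame: tuple = (0.0, 0.0)  # (dy, dx) rigid nuclear drift
    #: list of (nucleus_index, frame_start, frame_stop): nucleus invisible
    occlusions: tuple = ()

    def __post_init__(self):
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ConfigurationError("pixel size and frame interval must be positive")
        if self.nucleus_spacing_um < 2 * self.nucleus_radius_um * 0.9:
            raise ConfigurationError("nucleus_spacing_um too small for the radius")
        if self.view not in ("ventral", "dorsolateral", "cross-section-profile"):
            raise ConfigurationError(f"unknown view {self.view!r}")
        if self.perturbation.mode != "none" and \
                self.perturbation.light_off_frame > self.n_frames:
            raise ConfigurationError("light_off_frame beyond movie end")

    @property
    def nucleus_radius_px(self) -> float:
        return self.nucleus_radius_um / self.pixel_size_um

    @property
    def nucleus_spacing_px(self) -> float:
        return self.nucleus_spacing_um / self.pixel_size_um


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    #: per nucleus: array of (frame, y, x); occluded frames omitted
    nuclei_tracks: list = field(default_factory=list)
    #: per nucleus: per-frame nuclear level (a.u.), shape (n_frames,)
    nuclear_level: list = field(default_factory=list)
    #: per frame: list of (nucleus_index, y, x) of active (spot-on) nuclei
    foci_truth: list = field(default_factory=list)
    #: per-nucleus active flag (drawn once from activation probability)
    active_nuclei: np.ndarray | None = None
    frap_params: tuple | None = None        # (I_ss, alpha, beta)
    frap_nucleus_index: int | None = None
    gradient_params: tuple | None = None    # (amplitude, mu, sigma, offset)
    embryo_mask: np.ndarray | None = None
    embryo_ellipse: EllipseParams | None = None
    mid_ellipse: EllipseParams | None = None
    true_widths: dict = field(default_factory=dict)   # gene -> list of fractions
    cytoplasm_level: np.ndarray | None = None


# --------------------------------------------------------------------------
# Nuclear level model
# --------------------------------------------------------------------------

def nuclear_level_model(t_min, spec: PerturbationSpec, baseline: float,
                        frame_interval_s: float = 25.0):
    """Nuclear intensity (a.u.) at time ``t_min`` under a perturbation.

    Piecewise single-exponential model, continuous at every segment
    boundary:

    * ``none`` — constant at ``baseline``;
    * ``export`` — baseline before light; decays toward
      ``floor_frac * baseline`` at the export rate during light;
      recovers after light-off as ``I_ss - alpha*exp(-beta t')`` with
      ``I_ss = baseline`` and ``alpha`` set by continuity;
    * ``degrade`` — decays at the degradation rate during light and for
      ``degrade_post_light_delay`` frames beyond light-off, then holds.

    Raises
    ------
    ValueError
        For negative times.
    """
    t = np.asarray(t_min, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if spec.mode == "none":
        out = np.full_like(t, float(baseline))
        return float(out[0]) if scalar else out

    dt = frame_interval_s / 60.0
    t_on = spec.light_on_frame * dt
    t_off = spec.light_off_frame * dt
    out = np.full_like(t, float(baseline))

    if spec.mode == "export":
        floor = spec.floor_frac * baseline
        during = (t >= t_on) & (t < t_off)
        out[during] = floor + (baseline - floor) * np.exp(
            -spec.export_rate_per_min * (t[during] - t_on))
        level_off = floor + (baseline - floor) * math.exp(
            -spec.export_rate_per_min * (t_off - t_on))
        after = t >= t_off
        alpha = baseline - level_off
        out[after] = baseline - alpha * np.exp(
            -spec.reimport_rate_per_min * (t[after] - t_off))
    else:  # degrade
        t_stop = t_off + spec.degrade_post_light_delay * dt
        during = (t >= t_on) & (t < t_stop)
        out[during] = baseline * np.exp(
            -spec.degrade_rate_per_min * (t[during] - t_on))
        final = baseline * math.exp(-spec.degrade_rate_per_min * (t_stop - t_on))
        out[t >= t_stop] = final
    return float(out[0]) if scalar else out


# --------------------------------------------------------------------------
# Scene construction helpers
# --------------------------------------------------------------------------

def _embryo_ellipse(config: SimConfig) -> EllipseParams:
    ny, nx = config.image_shape
    return EllipseParams(
        center=((ny - 1) / 2.0, (nx - 1) / 2.0),
        semi_major=config.embryo_axes_frac[0] * nx,
        semi_minor=config.embryo_axes_frac[1] * ny,
        orientation=0.0,
    )


def _ellipse_mask(ellipse: EllipseParams, shape) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = ellipse.center
    co, so = np.cos(ellipse.orientation), np.sin(ellipse.orientation)
    u = (xx - cx) * co + (yy - cy) * so
    v = -(xx - cx) * so + (yy - cy) * co
    return (u / ellipse.semi_major) ** 2 + (v / ellipse.semi_minor) ** 2 <= 1.0


def _soft_ellipse(ellipse: EllipseParams, shape, edge_px: float = 0.75):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = ellipse.center
    co, so = np.cos(ellipse.orientation), np.sin(ellipse.orientation)
    u = (xx - cx) * co + (yy - cy) * so
    v = -(xx - cx) * so + (yy - cy) * co
    rho = np.sqrt((u / ellipse.semi_major) ** 2 + (v / ellipse.semi_minor) ** 2)
    scale = math.sqrt(ellipse.semi_major * ellipse.semi_minor)
    return 0.5 * erfc((rho - 1.0) * scale / (edge_px * math.sqrt(2.0)))


def _hex_lattice(config: SimConfig, ellipse: EllipseParams,
                 rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal nucleus centers inside the embryo, (N, 2) (y, x)."""
    s = config.nucleus_spacing_px
    ny, nx = config.image_shape
    row_step = s * math.sqrt(3.0) / 2.0
    centers = []
    j = 0
    y = s / 2.0
    while y < ny:
        x0 = s / 2.0 + (s / 2.0 if j % 2 else 0.0)
        x = x0
        while x < nx:
            centers.append((y, x))
            x += s
        y += row_step
        j += 1
    centers = np.asarray(centers, dtype=float)
    centers += rng.normal(0.0, config.lattice_jitter_frac * s, centers.shape)
    # Keep nuclei whose disk fits inside the embryo.
    r = config.nucleus_radius_px + config.edge_margin_px
    shrunk = EllipseParams(center=ellipse.center,
                           semi_major=max(ellipse.semi_major - r - 1, 1.0),
                           semi_minor=max(ellipse.semi_minor - r - 1, 1.0),
                           orientation=ellipse.orientation)
    cy, cx = shrunk.center
    co, so = np.cos(shrunk.orientation), np.sin(shrunk.orientation)
    u = (centers[:, 1] - cx) * co + (centers[:, 0] - cy) * so
    v = -(centers[:, 1] - cx) * so + (centers[:, 0] - cy) * co
    inside = (u / shrunk.semi_major) ** 2 + (v / shrunk.semi_minor) ** 2 <= 1.0
    return centers[inside]


def _paint_disk(frame: np.ndarray, cy: float, cx: float, radius: float,
                amplitude: float, edge_px: float = 0.5) -> None:
    """Add a soft-edged disk (error-function edge) in place."""
    ny, nx = frame.shape
    m = int(math.ceil(radius + 4 * edge_px + 2))
    y0, y1 = max(int(cy) - m, 0), min(int(cy) + m + 1, ny)
    x0, x1 = max(int(cx) - m, 0), min(int(cx) + m + 1, nx)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.hypot(yy - cy, xx - cx)
    frame[y0:y1, x0:x1] += amplitude * 0.5 * erfc(
        (r - radius) / (edge_px * math.sqrt(2.0)))


def _paint_gaussian(frame: np.ndarray, cy: float, cx: float, sigma: float,
                    amplitude: float) -> None:
    ny, nx = frame.shape
    m = int(math.ceil(5 * sigma + 2))
    y0, y1 = max(int(cy) - m, 0), min(int(cy) + m + 1, ny)
    x0, x1 = max(int(cx) - m, 0), min(int(cx) + m + 1, nx)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    frame[y0:y1, x0:x1] += amplitude * np.exp(-d2 / (2.0 * sigma ** 2))


def _dv_fraction(config: SimConfig, centers: np.ndarray,
                 ellipse: EllipseParams) -> np.ndarray:
    """DV coordinate of each nucleus for movie views, as a fraction.

    For ventral/dorsolateral movies the DV axis maps onto the image row
    direction across the embryo: 0 at the top edge of the embryo, 1 at
    the bottom.
    """
    cy = ellipse.center[0]
    b = ellipse.semi_minor
    return np.clip((centers[:, 0] - (cy - b)) / (2.0 * b), 0.0, 1.0)


# --------------------------------------------------------------------------
# Movie generators
# --------------------------------------------------------------------------

def simulate_nuclei_movie(config: SimConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a nuclear-fluorescence movie with ground truth.

    Nuclei are soft-edged disks on a jittered hexagonal lattice; each
    nucleus's level follows :func:`nuclear_level_model` with a baseline
    set by the DV gradient.  The cytoplasm is rendered so that the total
    embryo signal is conserved under export and decays under
    degradation.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ellipse = _embryo_ellipse(config)
    centers0 = _hex_lattice(config, ellipse, rng)
    if len(centers0) < 4:
        raise ConfigurationError("image too small to hold at least 4 nuclei")

    dv = _dv_fraction(config, centers0, ellipse)
    baselines = config.gradient.value(dv) if config.baseline_from_gradient \
        else np.full(len(centers0), config.gradient.offset + config.gradient.amplitude)

    t_min = np.arange(config.n_frames) * config.frame_interval_s / 60.0
    levels = np.stack([
        nuclear_level_model(t_min, config.perturbation, float(b),
                            config.frame_interval_s)
        for b in baselines
    ])  # (N, T)

    mask = _ellipse_mask(ellipse, config.image_shape)
    soft = _soft_ellipse(ellipse, config.image_shape)
    r = config.nucleus_radius_px
    nuc_area = math.pi * r * r
    cyto_area = max(float(mask.sum()) - nuc_area * len(centers0), 1.0)

    # Cytoplasm level: export conserves the embryo total; degradation
    # shrinks it on the same schedule as the nuclei.
    cyto0 = config.cytoplasm_frac * float(baselines.mean())
    total0 = float(np.sum(baselines) * nuc_area + cyto0 * cyto_area)
    cyto = np.empty(config.n_frames)
    if config.perturbation.mode == "export":
        nuclear_tot = levels.sum(axis=0) * nuc_area
        cyto[:] = (total0 - nuclear_tot) / cyto_area
    elif config.perturbation.mode == "degrade":
        ref = nuclear_level_model(t_min, config.perturbation, 1.0,
                                  config.frame_interval_s)
        cyto[:] = cyto0 * ref
    else:
        cyto[:] = cyto0

    drift = np.asarray(config.drift_px_per_frame, dtype=float)
    occl = {(int(i), f) for (i, f0, f1) in config.occlusions
            for f in range(int(f0), int(f1))}

    frames = np.empty((config.n_frames,) + tuple(config.image_shape),
                      dtype=np.float64)
    tracks: list[list] = [[] for _ in centers0]
    for f in range(config.n_frames):
        frame = cyto[f] * soft
        pos = centers0 + drift * f
        for i, (cy, cx) in enumerate(pos):
            if (i, f) in occl:
                continue
            tracks[i].append((f, float(cy), float(cx)))
            _paint_disk(frame, cy, cx, r, levels[i, f] - cyto[f])
        frames[f] = frame

    stack = ImageStack(np.clip(frames, 0, None),
                       pixel_size_um=config.pixel_size_um,
                       frame_interval_s=config.frame_interval_s)
    if config.noise.gaussian_sd or config.noise.poisson or \
            config.noise.salt_pepper_fraction:
        stack = apply_noise(stack, config.noise,
                            seed=int(rng.integers(2 ** 31)))
    truth = GroundTruth(
        nuclei_tracks=[np.asarray(tr) for tr in tracks],
        nuclear_level=[levels[i] for i in range(len(centers0))],
        embryo_mask=mask, embryo_ellipse=ellipse,
        cytoplasm_level=cyto,
    )
    return stack, truth


def simulate_foci_movie(config: SimConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a transcription-reporter (MS2/MCP) movie with ground truth.

    Nuclei appear as a dim background field; every nucleus inside the
    configured gene domain is active with the configured probability and
    carries one Gaussian spot at a fixed jittered intranuclear position.
    During a perturbation, spots switch off ``deactivation_delay_frames``
    after the nucleus's simulated level falls below the activation
    threshold, and only recover when the level does (export mode).
    """
    rng = np.random.default_rng(config.seed)
    ellipse = _embryo_ellipse(config)
    centers0 = _hex_lattice(config, ellipse, rng)
    if len(centers0) < 4:
        raise ConfigurationError("image too small to hold at least 4 nuclei")

    dv = _dv_fraction(config, centers0, ellipse)
    lo, hi = config.foci.domain_band
    in_domain = (dv >= lo) & (dv <= hi)
    if not np.any(in_domain):
        raise ConfigurationError("gene domain contains no nuclei")
    active = in_domain & (rng.random(len(centers0))
                          < config.foci.activation_probability)

    baselines = config.gradient.value(dv) if config.baseline_from_gradient \
        else np.full(len(centers0), config.gradient.offset + config.gradient.amplitude)
    t_min = np.arange(config.n_frames) * config.frame_interval_s / 60.0
    levels = np.stack([
        nuclear_level_model(t_min, config.perturbation, float(b),
                            config.frame_interval_s)
        for b in baselines
    ])

    # Spot gate: below-threshold with a frame delay, symmetric for
    # reactivation.  Degradation never recovers by construction of the
    # level model (the level stays at its floor).
    thr = config.foci.deactivation_threshold_frac * baselines[:, None]
    above = levels >= thr
    delay = config.foci.deactivation_delay_frames
    gate = np.empty_like(above)
    state = np.ones(len(centers0), dtype=bool)
    pending = np.zeros(len(centers0), dtype=int)
    for f in range(config.n_frames):
        flip = above[:, f] != state
        pending = np.where(flip, pending + 1, 0)
        commit = pending > delay
        state = np.where(commit, above[:, f], state)
        pending = np.where(commit, 0, pending)
        gate[:, f] = state

    r = config.nucleus_radius_px
    spot_sigma_px = config.foci.spot_sigma_um / config.pixel_size_um
    jitter_r = 0.5 * r * np.sqrt(rng.random(len(centers0)))
    jitter_th = 2 * np.pi * rng.random(len(centers0))
    spot_off = np.column_stack([jitter_r * np.sin(jitter_th),
                                jitter_r * np.cos(jitter_th)])

    mask = _ellipse_mask(ellipse, config.image_shape)
    soft = _soft_ellipse(ellipse, config.image_shape)
    # MCP channel: uniform dim background + slightly brighter nuclei.
    bg_level = 800.0
    nuc_level = 400.0

    frames = np.empty((config.n_frames,) + tuple(config.image_shape))
    foci_truth: list[list] = []
    tracks: list[list] = [[] for _ in centers0]
    for f in range(config.n_frames):
        frame = bg_level * soft
        this_frame: list[tuple] = []
        for i, (cy, cx) in enumerate(centers0):
            tracks[i].append((f, float(cy), float(cx)))
            _paint_disk(frame, cy, cx, r, nuc_level)
            if active[i] and gate[i, f]:
                sy, sx = cy + spot_off[i, 0], cx + spot_off[i, 1]
                _paint_gaussian(frame, sy, sx, spot_sigma_px,
                                config.foci.spot_amplitude)
                this_frame.append((i, float(sy), float(sx)))
        foci_truth.append(this_frame)
        frames[f] = frame

    stack = ImageStack(np.clip(frames, 0, None),
                       pixel_size_um=config.pixel_size_um,
                       frame_interval_s=config.frame_interval_s)
    if config.noise.gaussian_sd or config.noise.poisson or \
            config.noise.salt_pepper_fraction:
        stack = apply_noise(stack, config.noise,
                            seed=int(rng.integers(2 ** 31)))
    truth = GroundTruth(
        nuclei_tracks=[np.asarray(tr) for tr in tracks],
        nuclear_level=[levels[i] for i in range(len(centers0))],
        foci_truth=foci_truth, active_nuclei=active,
        embryo_mask=mask, embryo_ellipse=ellipse,
    )
    return stack, truth


def simulate_frap_movie(config: SimConfig, bleach_roi, bleach_frames,
                        frap_params) -> tuple[ImageStack, GroundTruth]:
    """Render a FRAP movie: nuclei in the bleach ROI drop and recover.

    Parameters
    ----------
    bleach_roi : (y, x, r)
        Bleach circle, pixels.
    bleach_frames : (start, stop)
        Frames during which bleaching ramps the ROI nuclei down (stop
        exclusive); recovery starts at ``stop``.
    frap_params : (I_ss, alpha, beta)
        Recovery model parameters; the ROI nucleus sits at ``I_ss - alpha``
        at bleach end and recovers as ``I_ss - alpha*exp(-beta t)`` with
        ``t`` in minutes from bleach end.  ``beta`` in 1/min.
    """
    i_ss, alpha, beta = (float(v) for v in frap_params)
    if i_ss <= 0 or alpha <= 0 or beta <= 0:
        raise ConfigurationError("frap_params must all be positive")
    if alpha > i_ss:
        raise ConfigurationError("alpha must not exceed I_ss")
    b_start, b_stop = int(bleach_frames[0]), int(bleach_frames[1])
    if not (0 <= b_start < b_stop <= config.n_frames):
        raise ConfigurationError("bleach_frames outside the movie")

    rng = np.random.default_rng(config.seed)
    ellipse = _embryo_ellipse(config)
    centers = _hex_lattice(config, ellipse, rng)
    if len(centers) < 4:
        raise ConfigurationError("image too small to hold at least 4 nuclei")
    mask = _ellipse_mask(ellipse, config.image_shape)

    ry, rx, rr = bleach_roi
    for py, px in ((ry, rx), (ry - rr, rx), (ry + rr, rx),
                   (ry, rx - rr), (ry, rx + rr)):
        iy, ix = int(round(py)), int(round(px))
        if not (0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1]
                and mask[iy, ix]):
            raise ConfigurationError("bleach ROI lies outside the embryo")
    d_roi = np.hypot(centers[:, 0] - ry, centers[:, 1] - rx)
    bleached = d_roi <= rr
    center_idx = int(np.argmin(d_roi))

    t_min = np.arange(config.n_frames) * config.frame_interval_s / 60.0
    # Recovery clock starts at the bleach-end frame, so the first
    # post-bleach frame already sits one interval into the recovery.
    t_rec = t_min - t_min[b_stop - 1]

    levels = np.empty((len(centers), config.n_frames))
    levels[:] = i_ss
    for i in np.flatnonzero(bleached):
        ramp = np.linspace(i_ss, i_ss - alpha, b_stop - b_start + 1)[1:]
        levels[i, b_start:b_stop] = ramp
        rec = t_rec[b_stop:]
        levels[i, b_stop:] = i_ss - alpha * np.exp(-beta * np.clip(rec, 0, None))

    soft = _soft_ellipse(ellipse, config.image_shape)
    cyto = config.cytoplasm_frac * i_ss
    r = config.nucleus_radius_px
    frames = np.empty((config.n_frames,) + tuple(config.image_shape))
    tracks: list[list] = [[] for _ in centers]
    for f in range(config.n_frames):
        frame = cyto * soft
        for i, (cy, cx) in enumerate(centers):
            tracks[i].append((f, float(cy), float(cx)))
            _paint_disk(frame, cy, cx, r, levels[i, f] - cyto)
        frames[f] = frame

    stack = ImageStack(np.clip(frames, 0, None),
                       pixel_size_um=config.pixel_size_um,
                       frame_interval_s=config.frame_interval_s)
    if config.noise.gaussian_sd or config.noise.poisson or \
            config.noise.salt_pepper_fraction:
        stack = apply_noise(stack, config.noise,
                            seed=int(rng.integers(2 ** 31)))
    truth = GroundTruth(
        nuclei_tracks=[np.asarray(tr) for tr in tracks],
        nuclear_level=[levels[i] for i in range(len(centers))],
        frap_params=(i_ss, alpha, beta), frap_nucleus_index=center_idx,
        embryo_mask=mask, embryo_ellipse=ellipse,
    )
    return stack, truth


def apply_noise(stack: ImageStack, noise: NoiseSpec, seed: int) -> ImageStack:
    """Add Gaussian read noise, optional Poisson resampling, then
    salt-and-pepper pixels; clip to the 16-bit range.

    A zero-noise configuration returns the input data unchanged.
    Deterministic under ``seed``.
    """
    data = np.asarray(stack.data, dtype=float)
    if not (noise.gaussian_sd or noise.poisson or noise.salt_pepper_fraction):
        return ImageStack(data.copy(), stack.pixel_size_um,
                          stack.frame_interval_s)
    rng = np.random.default_rng(seed)
    out = data.copy()
    if noise.poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, out.shape)
    if noise.salt_pepper_fraction > 0:
        hit = rng.random(out.shape) < noise.salt_pepper_fraction
        salt = rng.random(out.shape) < 0.5
        vmax = float(data.max())
        out[hit & salt] = vmax
        out[hit & ~salt] = 0.0
    out = np.clip(out, 0, 65535)
    return ImageStack(out, stack.pixel_size_um, stack.frame_interval_s)


# --------------------------------------------------------------------------
# Fixed embryos
# --------------------------------------------------------------------------

def simulate_fixed_embryo(config: SimConfig, expression_channels=None
                          ) -> tuple[ChannelStack, GroundTruth]:
    """Render a fixed cross-section embryo: nuclear ring + expression.

    The nuclear channel is a ring of peripheral nuclei whose intensity
    follows the DV Gaussian gradient (position = arc-length fraction
    along the mid-ring ellipse, 0 at the ventral-most point).  Each
    expression channel paints the ring band over one or more angular
    intervals; the recorded true normalized width of each interval is
    its arc length over the perimeter.

    Parameters
    ----------
    expression_channels : list of (gene, [(theta1, theta2), ...]), optional
        Up to 3 channels, each a list of parametric-angle intervals.
    """
    expression_channels = expression_channels or []
    if len(expression_channels) > 3:
        raise ConfigurationError("at most 3 expression channels")
    rng = np.random.default_rng(config.seed)
    ny, nx = config.image_shape
    mid = EllipseParams(
        center=((ny - 1) / 2.0, (nx - 1) / 2.0),
        semi_major=config.embryo_axes_frac[0] * nx,
        semi_minor=config.embryo_axes_frac[1] * ny,
        orientation=0.0,
    )
    r = config.nucleus_radius_px
    perim = ellipse_perimeter(mid)
    n_nuc = max(int(perim // config.nucleus_spacing_px), 8)
    frac = np.arange(n_nuc) / n_nuc
    theta = theta_at_fraction(mid, frac)
    ys, xs = mid.point(theta)
    jit = rng.normal(0.0, config.lattice_jitter_frac * config.nucleus_spacing_px,
                     (n_nuc, 2)) * 0.3
    ys, xs = ys + jit[:, 0], xs + jit[:, 1]

    grad = config.gradient
    levels = grad.value(frac)
    nuclear = np.zeros((ny, nx))
    for cy, cx, lv in zip(ys, xs, levels):
        _paint_disk(nuclear, cy, cx, r, lv)

    channels = [nuclear]
    names = ["nuclear"]
    truth = GroundTruth(
        gradient_params=(grad.amplitude, grad.peak_position, grad.sigma,
                         grad.offset),
        mid_ellipse=mid,
        embryo_mask=_ellipse_mask(mid, (ny, nx)),
    )
    th_lookup, fr_lookup = arc_fraction_of_theta(mid)
    brush = 1.2 * r
    for gene, intervals in expression_channels:
        ch = np.zeros((ny, nx))
        widths = []
        for th1, th2 in intervals:
            if th2 <= th1:
                th2 += 2 * np.pi
            widths.append(ellipse_arc_length(mid, th1, th2) / perim)
            # Paint the ring band over the interval, trimming the path by
            # the brush radius so the round end caps land on the interval
            # boundaries rather than bulging past them.
            f1 = float(np.interp(np.mod(th1, 2 * np.pi), th_lookup, fr_lookup))
            f2 = f1 + (widths[-1] if th2 - th1 < 2 * np.pi else 1.0)
            df = brush / perim
            lo, hi = f1 + df, f2 - df
            if hi <= lo:
                lo = hi = (f1 + f2) / 2.0
            n_samp = max(int((hi - lo) * perim), 2)
            tt = theta_at_fraction(mid, np.linspace(lo, hi, n_samp))
            if th2 - th1 >= 2 * np.pi - 1e-12:
                tt = theta_at_fraction(mid, np.linspace(0, 1, int(perim),
                                                        endpoint=False))
            by, bx = mid.point(tt)
            for cy, cx in zip(by, bx):
                _paint_disk(ch, cy, cx, brush, grad.amplitude)
        channels.append(np.clip(ch, 0, grad.amplitude * 1.5))
        names.append(gene)
        truth.true_widths[gene] = widths

    if config.noise.gaussian_sd > 0:
        for i, ch in enumerate(channels):
            channels[i] = np.clip(
                ch + rng.normal(0.0, config.noise.gaussian_sd, ch.shape),
                0, 65535)
    return ChannelStack(channels=channels, pixel_size_um=config.pixel_size_um,
                        channel_names=names), truth


# --------------------------------------------------------------------------
# Presets
# --------------------------------------------------------------------------

def default_nuclei_config(mode: str = "none", seed: int = 0,
                          n_frames: int = 60, **overrides) -> SimConfig:
    """Population nuclear movie preset (export/degrade experiments)."""
    if mode != "none":
        pert = PerturbationSpec(mode=mode, light_on_frame=n_frames // 6,
                                light_off_frame=n_frames // 6 + 24)
    else:
        pert = PerturbationSpec()
    cfg = SimConfig(n_frames=n_frames, seed=seed, perturbation=pert,
                    noise=NoiseSpec(gaussian_sd=150.0))
    return replace(cfg, **overrides) if overrides else cfg


def default_foci_config(gene: str = "sna", mode: str = "none", seed: int = 0,
                        n_frames: int = 100, **overrides) -> SimConfig:
    """Transcription-reporter movie preset (~60 in-domain nuclei, SNR 10)."""
    if mode != "none":
        pert = PerturbationSpec(mode=mode, light_on_frame=n_frames // 5,
                                light_off_frame=n_frames // 5 + 30)
    else:
        pert = PerturbationSpec()
    foci = FociSpec(gene=gene, spot_amplitude=3000.0,
                    domain_band=(0.39, 0.61) if gene == "sna" else (0.15, 0.42))
    cfg = SimConfig(n_frames=n_frames, seed=seed, perturbation=pert, foci=foci,
                    noise=NoiseSpec(gaussian_sd=300.0))
    return replace(cfg, **overrides) if overrides else cfg


def default_frap_config(seed: int = 0, n_frames: int = 570,
                        **overrides) -> SimConfig:
    """FRAP preset: high zoom, 0.100 um/px, one frame per 2 s, ~19 min."""
    cfg = SimConfig(
        image_shape=(256, 256), pixel_size_um=0.100, frame_interval_s=2.0,
        n_frames=n_frames, nucleus_radius_um=2.4, nucleus_spacing_um=6.0,
        embryo_axes_frac=(0.7, 0.7), seed=seed,
        noise=NoiseSpec(gaussian_sd=100.0),
    )
    return replace(cfg, **overrides) if overrides else cfg


def default_fixed_config(seed: int = 0, **overrides) -> SimConfig:
    """Fixed cross-section preset for gradient and width quantification."""
    cfg = SimConfig(
        view="cross-section-profile", image_shape=(512, 512),
        pixel_size_um=0.5, n_frames=1, nucleus_radius_um=3.0,
        nucleus_spacing_um=7.0, seed=seed,
        gradient=GradientSpec(amplitude=100.0, peak_position=0.0,
                              sigma=0.15, offset=10.0),
        noise=NoiseSpec(gaussian_sd=0.0),
    )
    return replace(cfg, **overrides) if overrides else cfg
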