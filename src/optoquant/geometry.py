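"""Fixed-embryo geometry: DV intensity profiles, Gaussian gradient fits,
nuclear-ring segmentation, and normalized expression-domain widths.

The embryo periphery is modelled as an ellipse.  Positions along the
dorsal-ventral (DV) circumference are expressed as arc-length fractions
in [0, 1), with 0 at the parametric angle 0 (the ventral-most point by
the package's convention).  Domain widths are arc lengths between the
angles where the mid-ring ellipse crosses the segmented expression
domain, normalized by the full perimeter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.integrate import quad
from skimage import measure


# --------------------------------------------------------------------------
# Ellipse primitives
# --------------------------------------------------------------------------

@dataclass
class EllipseParams:
    """Ellipse in image coordinates: center (row, col), semi-axes, tilt.

    ``orientation`` is the angle (radians) of the major axis measured
    from the +col axis toward +row.  Invariant: a >= b > 0.
    """

    center: tuple          # (cy, cx) px
    semi_major: float      # a, px
    semi_minor: float      # b, px
    orientation: float     # rad

    def __post_init__(self):
        if self.semi_minor <= 0 or self.semi_major < self.semi_minor:
            raise ValueError("require semi_major >= semi_minor > 0")

    def point(self, theta):
        """(y, x) on the ellipse at parametric angle(s) theta."""
        th = np.asarray(theta, dtype=float)
        ca, sa = np.cos(self.orientation), np.sin(self.orientation)
        ex = self.semi_major * np.cos(th)
        ey = self.semi_minor * np.sin(th)
        x = self.center[1] + ex * ca - ey * sa
        y = self.center[0] + ex * sa + ey * ca
        return y, x


def ellipse_arc_length(ellipse: EllipseParams, theta1: float, theta2: float,
                       rtol: float = 1e-11) -> float:
    """Arc length along the ellipse between parametric angles.

    Numerical quadrature of ``integral of sqrt(a^2 sin^2 t + b^2 cos^2 t) dt``.
    Requires ``theta1 < theta2 <= theta1 + 2*pi``.
    """
    if not (theta1 < theta2 <= theta1 + 2 * np.pi + 1e-12):
        raise ValueError("require theta1 < theta2 <= theta1 + 2*pi")
    a, b = ellipse.semi_major, ellipse.semi_minor

    def integrand(t):
        return np.sqrt(a * a * np.sin(t) ** 2 + b * b * np.cos(t) ** 2)

    val, _ = quad(integrand, theta1, theta2, epsrel=rtol, epsabs=0, limit=200)
    return float(val)


def ellipse_perimeter(ellipse: EllipseParams) -> float:
    return ellipse_arc_length(ellipse, 0.0, 2 * np.pi)


def arc_fraction_of_theta(ellipse: EllipseParams, n: int = 4096):
    """Dense lookup (theta, fraction): arc-length fraction at each angle."""
    theta = np.linspace(0.0, 2 * np.pi, n + 1)
    a, b = ellipse.semi_major, ellipse.semi_minor
    sp = np.sqrt(a * a * np.sin(theta) ** 2 + b * b * np.cos(theta) ** 2)
    s = np.concatenate([[0.0], np.cumsum((sp[1:] + sp[:-1]) / 2.0
                                         * np.diff(theta))])
    return theta, s / s[-1]


def theta_at_fraction(ellipse: EllipseParams, frac):
    """Parametric angle at a given arc-length fraction (vectorized)."""
    theta, f = arc_fraction_of_theta(ellipse)
    return np.interp(np.mod(frac, 1.0), f, theta)


def fit_ellipse_lsq(points_yx: np.ndarray) -> EllipseParams:
    """Least-squares ellipse fit to boundary points ((y, x) rows)."""
    pts = np.asarray(points_yx, dtype=float)
    if pts.shape[0] < 5:
        raise ValueError("ellipse fit needs at least 5 boundary points")
    # EllipseModel works in (x, y); feed (col, row).
    model = measure.EllipseModel.from_estimate(pts[:, ::-1])
    if not model:
        raise ValueError("ellipse fit failed")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = model.theta
    if b > a:
        a, b = b, a
        theta += np.pi / 2.0
    theta = float(np.mod(theta + np.pi / 2.0, np.pi) - np.pi / 2.0)
    return EllipseParams(center=(float(yc), float(xc)), semi_major=float(a),
                         semi_minor=float(b), orientation=theta)


# --------------------------------------------------------------------------
# DV gradient
# --------------------------------------------------------------------------

@dataclass
class GradientFitResult:
    amplitude: float   # peak level above offset, a.u.
    mu: float          # peak DV position, arc fraction in [0, 1)
    sigma: float       # gradient scaling factor, arc fraction
    offset: float      # background, a.u.
    rss: float
    converged: bool
    low_amplitude: bool = False


def dv_profile(image: np.ndarray, ellipse: EllipseParams, n_bins: int = 64,
               band_px: float = 20.0, n_radial: int | None = None):
    """Mean peripheral intensity binned by DV arc-length position.

    Samples the image along the ellipse within ``+/- band_px`` of the
    periphery (along the local normal) and averages into ``n_bins``
    angular bins, returned against bin-center arc fractions in [0, 1).
    """
    if n_bins < 16:
        raise ValueError("n_bins must be >= 16")
    if n_radial is None:
        n_radial = int(np.ceil(band_px)) + 1   # ~2 px radial step
    n_samp = max(8 * n_bins, 1024)
    frac = (np.arange(n_samp) + 0.5) / n_samp
    theta = theta_at_fraction(ellipse, frac)
    y0, x0 = ellipse.point(theta)
    # Local outward normal from the gradient of the implicit form.
    ca, sa = np.cos(ellipse.orientation), np.sin(ellipse.orientation)
    dx = -ellipse.semi_major * np.sin(theta) * ca \
        - ellipse.semi_minor * np.cos(theta) * sa
    dy = -ellipse.semi_major * np.sin(theta) * sa \
        + ellipse.semi_minor * np.cos(theta) * ca
    norm = np.hypot(dx, dy)
    ny, nx = dx / norm, -dy / norm   # rotate tangent by -90 deg -> normal
    offs = np.linspace(-band_px, band_px, n_radial)
    ys = y0[None, :] + offs[:, None] * ny[None, :]
    xs = x0[None, :] + offs[:, None] * nx[None, :]
    vals = ndimage.map_coordinates(np.asarray(image, dtype=float),
                                   [ys.ravel(), xs.ravel()], order=1,
                                   mode="nearest").reshape(n_radial, n_samp)
    per_sample = vals.mean(axis=0)
    bins = np.minimum((frac * n_bins).astype(int), n_bins - 1)
    prof = np.array([per_sample[bins == b].mean() for b in range(n_bins)])
    centers = (np.arange(n_bins) + 0.5) / n_bins
    return centers, prof


def fit_gaussian_gradient(position, intensity) -> GradientFitResult:
    """Fit A*exp(-(x-mu)^2/(2 sigma^2)) + B to a circular DV profile.

    The profile is rotated so its empirical maximum sits at 0.5 before
    fitting (circular positions in [0, 1)), then ``mu`` is mapped back.
    """
    x = np.asarray(position, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if x.size < 8:
        raise ValueError("profile needs at least 8 points")
    k = int(np.argmax(y))
    shift = 0.5 - x[k]
    xr = np.mod(x + shift, 1.0)
    order = np.argsort(xr)
    xr, yr = xr[order], y[order]

    a0 = float(y.max() - y.min())
    b0 = float(y.min())
    p0 = [max(a0, 1e-12), 0.5, 0.125, b0]

    def model(x_, A, mu, sig, B):
        return A * np.exp(-(x_ - mu) ** 2 / (2.0 * sig ** 2)) + B

    try:
        popt, _ = optimize.curve_fit(
            model, xr, yr, p0=p0,
            bounds=([0, 0, 1e-6, -np.inf], [np.inf, 1, 10, np.inf]),
            maxfev=5000,
        )
        converged = True
    except RuntimeError:
        popt, converged = p0, False
    A, mu, sig, B = (float(v) for v in popt)
    rss = float(np.sum((model(xr, *popt) - yr) ** 2))
    spread = max(abs(a0), 1e-12)
    return GradientFitResult(
        amplitude=A, mu=float(np.mod(mu - shift, 1.0)), sigma=sig, offset=B,
        rss=rss, converged=converged,
        low_amplitude=A < 0.05 * spread or a0 < 1e-9 * max(abs(b0), 1.0),
    )


# --------------------------------------------------------------------------
# Nuclear-ring segmentation and domain widths
# --------------------------------------------------------------------------

def segment_nuclear_rings(image: np.ndarray, log_sigma_px: float = 20.0):
    """Locate the peripheral nuclear ring of a cross-section image.

    LoG filtering at a coarse scale responds negatively inside the bright
    ring of nuclei; filling that band yields the outer embryo outline and
    its hole the inner (yolk-facing) outline.  Ellipses are fit to both
    boundaries and averaged parameter-wise to give the mid-ring ellipse.

    Returns
    -------
    (outer, inner, mid) : EllipseParams
    """
    img = np.asarray(image, dtype=float)
    L = ndimage.gaussian_laplace(img, log_sigma_px)
    scale = np.abs(L).max()
    if scale == 0:
        raise ValueError("blank image, no ring found")
    band = L < -0.02 * scale
    band = ndimage.binary_opening(band, iterations=1)
    lab, n = ndimage.label(band)
    if n == 0:
        raise ValueError("no ring band detected")
    sizes = ndimage.sum(band, lab, index=np.arange(1, n + 1))
    band = lab == (1 + int(np.argmax(sizes)))
    filled = ndimage.binary_fill_holes(band)
    hole = filled & ~band
    lab_h, n_h = ndimage.label(hole)
    if n_h == 0:
        raise ValueError("solid object: no inner ring boundary found")
    sizes_h = ndimage.sum(hole, lab_h, index=np.arange(1, n_h + 1))
    inner_region = lab_h == (1 + int(np.argmax(sizes_h)))
    if inner_region.sum() < 25:
        raise ValueError("inner region too small to be a ring interior")
    # A solid object also yields a LoG band with a "hole", but that hole
    # is bright (the object's interior) rather than dark.
    if img[inner_region].mean() > 0.5 * img[band].mean():
        raise ValueError("solid object: no dark ring interior found")

    outer = _fit_boundary_ellipse(filled)
    inner = _fit_boundary_ellipse(inner_region)
    mid = _average_ellipses(outer, inner)
    return outer, inner, mid


def _fit_boundary_ellipse(mask: np.ndarray) -> EllipseParams:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no boundary contour")
    boundary = max(contours, key=len)
    return fit_ellipse_lsq(boundary)


def _average_ellipses(e1: EllipseParams, e2: EllipseParams) -> EllipseParams:
    # Orientation averaged on the doubled angle (axes are pi-periodic);
    # near-circular fits have arbitrary tilt, so weight by eccentricity.
    w1 = max(e1.semi_major - e1.semi_minor, 1e-9)
    w2 = max(e2.semi_major - e2.semi_minor, 1e-9)
    c = w1 * np.cos(2 * e1.orientation) + w2 * np.cos(2 * e2.orientation)
    s = w1 * np.sin(2 * e1.orientation) + w2 * np.sin(2 * e2.orientation)
    orient = 0.5 * np.arctan2(s, c)
    return EllipseParams(
        center=((e1.center[0] + e2.center[0]) / 2.0,
                (e1.center[1] + e2.center[1]) / 2.0),
        semi_major=(e1.semi_major + e2.semi_major) / 2.0,
        semi_minor=(e1.semi_minor + e2.semi_minor) / 2.0,
        orientation=float(orient),
    )


@dataclass
class DomainWidthResult:
    gene: str
    widths_normalized: list = field(default_factory=list)
    arc_lengths_px: list = field(default_factory=list)
    perimeter_px: float = 0.0
    crossing_angles: list = field(default_factory=list)   # (theta_start, theta_end)


def domain_widths(expr_image: np.ndarray, mid_ellipse: EllipseParams,
                  threshold: float | None = None, gene: str = "",
                  n_angles: int = 4096,
                  min_component_frac: float = 0.25) -> DomainWidthResult:
    """Normalized expression-domain widths along the mid-ring ellipse.

    The expression channel is thresholded (Otsu when ``threshold`` is
    None), components smaller than ``min_component_frac`` of the largest
    are dropped as noise, and the mid ellipse is sampled at ``n_angles``
    parametric angles.  Each maximal angular run inside the segmented
    mask becomes one domain; its width is the arc length between the
    crossing angles divided by the perimeter.
    """
    img = np.asarray(expr_image, dtype=float)
    if threshold is None:
        from skimage.filters import threshold_otsu
        threshold = threshold_otsu(img)
    mask = img > threshold
    lab, n = ndimage.label(mask)
    perim = ellipse_perimeter(mid_ellipse)
    result = DomainWidthResult(gene=gene, perimeter_px=perim)
    if n == 0:
        return result
    sizes = ndimage.sum(mask, lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_component_frac * sizes.max()) + 1
    mask = np.isin(lab, keep)

    theta = np.arange(n_angles) * 2 * np.pi / n_angles
    ys, xs = mid_ellipse.point(theta)
    iy = np.clip(np.round(ys).astype(int), 0, img.shape[0] - 1)
    ix = np.clip(np.round(xs).astype(int), 0, img.shape[1] - 1)
    inside = mask[iy, ix]
    if inside.all():
        result.widths_normalized = [1.0]
        result.arc_lengths_px = [perim]
        result.crossing_angles = [(0.0, 2 * np.pi)]
        return result
    if not inside.any():
        return result

    # Circular runs of consecutive inside samples.
    arr = inside.astype(int)
    d = np.diff(arr, append=arr[0])
    starts = np.flatnonzero(d == 1) + 1        # first-inside index
    ends = np.flatnonzero(d == -1) + 1         # first-outside index after run
    starts, ends = list(starts % n_angles), list(ends % n_angles)
    if inside[0]:
        # Run wrapping through zero: rotate lists so pairs align.
        starts = starts[-1:] + starts[:-1]
    step = 2 * np.pi / n_angles
    for s_idx, e_idx in zip(starts, ends):
        # Crossing angle = midpoint of last-outside and first-inside sample.
        th1 = (s_idx - 0.5) * step
        th2 = (e_idx - 0.5) * step
        if th2 <= th1:
            th2 += 2 * np.pi
        arc = ellipse_arc_length(mid_ellipse, th1, th2, rtol=1e-10)
        result.crossing_angles.append((th1, th2))
        result.arc_lengths_px.append(arc)
        result.widths_normalized.append(arc / perim)
    return result
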