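"""Iterative log-domain bias-field correction.

A smooth multiplicative intensity inhomogeneity is estimated by repeatedly
(1) sharpening the log-intensity histogram to predict the expected true image,
(2) smoothing the difference between the current log image and that prediction
with a tensor-product cubic B-spline least-squares approximator, and
(3) subtracting the smoothed residual field.  Residual fields accumulate into a
single total field across a multi-resolution schedule of control-point
spacings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "N4Config",
    "BiasFieldEstimate",
    "expected_true_image",
    "smooth_field",
    "run_n4",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class N4Config:
    """Settings for the iterative bias-correction scheme.

    Parameters
    ----------
    max_iterations : int
        Iteration cap per resolution level.
    convergence_threshold : float
        Stop a level once the coefficient of variation of ``exp(residual)``
        falls below this value.
    fitting_levels : int
        Number of multi-resolution levels; the control-point spacing is halved
        at each successive level.
    control_point_spacing : float
        B-spline control-point spacing in pixels at the coarsest level.
    histogram_bins : int
        Bin count for the log-intensity histogram.
    sharpening_fwhm : float
        Full width at half maximum (log-intensity units) of the Gaussian that
        is deconvolved from the histogram.
    wiener_noise : float
        Noise constant of the Wiener deconvolution.
    """

    max_iterations: int = 50
    convergence_threshold: float = 1e-3
    fitting_levels: int = 2
    control_point_spacing: float = 192.0
    histogram_bins: int = 200
    sharpening_fwhm: float = 0.15
    wiener_noise: float = 0.01

    def __post_init__(self) -> None:
        if self.max_iterations < 1 or self.fitting_levels < 1 or self.histogram_bins < 1:
            raise ConfigurationError("counts must be >= 1")
        for name in ("convergence_threshold", "control_point_spacing",
                     "sharpening_fwhm", "wiener_noise"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")


@dataclass
class BiasFieldEstimate:
    """Accumulated log-domain bias field and its per-iteration residuals.

    ``residual_fields[0]`` is the identically-zero initial estimate; the total
    field is the elementwise sum of all residuals.
    """

    residual_fields: list = field(default_factory=list)
    total_field: np.ndarray | None = None
    n_iterations: int = 0

    def check_sum_invariant(self, atol: float = 1e-9) -> bool:
        acc = np.zeros_like(self.total_field)
        for r in self.residual_fields:
            acc += r
        return bool(np.max(np.abs(acc - self.total_field)) < atol)


def expected_true_image(log_image: np.ndarray, config: N4Config,
                        weights_mask: np.ndarray | None = None) -> np.ndarray:
    """Estimate the expected uncorrupted log image via histogram sharpening.

    The log-intensity histogram is deconvolved with a Gaussian of FWHM
    ``config.sharpening_fwhm`` by Wiener deconvolution, and every pixel is
    mapped to the conditional expectation of the sharpened intensity given its
    observed intensity.

    Parameters
    ----------
    log_image : ndarray
        2-D log-intensity field.
    config : N4Config
    weights_mask : ndarray of bool, optional
        Restrict the histogram to these pixels (the mapping is still applied
        everywhere).

    Returns
    -------
    ndarray
        Field of the same shape whose histogram is at least as sharp as the
        input's.
    """
    log_image = np.asarray(log_image, dtype=float)
    if not np.all(np.isfinite(log_image)):
        raise InvalidInputError("log_image contains non-finite values")
    sample = log_image[weights_mask] if weights_mask is not None else log_image.ravel()
    vmin = float(sample.min())
    vmax = float(sample.max())
    if vmax - vmin < 1e-12:
        return log_image.copy()

    nb = config.histogram_bins
    edges = np.linspace(vmin, vmax, nb + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    binwidth = edges[1] - edges[0]
    hist, _ = np.histogram(sample, bins=edges)
    hist = hist.astype(float)

    sigma_bins = config.sharpening_fwhm * _FWHM_TO_SIGMA / binwidth

    # Wiener deconvolution of the histogram, zero-padded to suppress wrap-around.
    n_fft = 2 * nb
    idx = np.arange(n_fft, dtype=float)
    dist = np.minimum(idx, n_fft - idx)
    kernel = np.exp(-0.5 * (dist / sigma_bins) ** 2)
    kernel /= kernel.sum()
    f_hat = np.fft.rfft(kernel)
    v_hat = np.fft.rfft(hist, n_fft)
    u_hat = np.conj(f_hat) * v_hat / (np.abs(f_hat) ** 2 + config.wiener_noise)
    sharpened = np.fft.irfft(u_hat, n_fft)[:nb]
    sharpened = np.clip(sharpened, 0.0, None)

    # Conditional expectation E[u | v] under the sharpened density.
    num = gaussian_filter1d(sharpened * centers, sigma_bins, mode="constant")
    den = gaussian_filter1d(sharpened, sigma_bins, mode="constant")
    mapping = np.where(den > 1e-12 * den.max() + 1e-300, num / np.maximum(den, 1e-300), centers)

    out = np.interp(log_image, centers, mapping)
    return out.reshape(log_image.shape)


def _bspline_basis(n: int, spacing: float) -> np.ndarray:
    """Dense cubic B-spline design matrix on a uniform control grid over [0, n-1]."""
    if n == 1:
        return np.ones((1, 4))
    nseg = max(1, int(np.ceil((n - 1) / spacing)))
    step = (n - 1) / nseg
    grid = np.arange(nseg + 1) * step
    knots = np.concatenate([
        grid[0] - step * np.array([3.0, 2.0, 1.0]),
        grid,
        grid[-1] + step * np.array([1.0, 2.0, 3.0]),
    ])
    x = np.arange(n, dtype=float)
    return BSpline.design_matrix(x, knots, 3, extrapolate=True).toarray()


def smooth_field(field_2d: np.ndarray, spacing: float) -> np.ndarray:
    """Least-squares cubic B-spline approximation of a 2-D field.

    This is the smoothing operator applied to each residual: an orthogonal
    projection onto the tensor-product spline space, hence idempotent.

    Parameters
    ----------
    field_2d : ndarray
        2-D scalar field.
    spacing : float
        Control-point spacing in pixels, >= 2.
    """
    field_2d = np.asarray(field_2d, dtype=float)
    if field_2d.ndim != 2:
        raise InvalidInputError("field must be 2-D")
    if spacing < 2:
        raise ConfigurationError("spacing must be >= 2 pixels")
    h, w = field_2d.shape
    if spacing > h and spacing > w:
        raise ConfigurationError(
            f"control-point spacing {spacing} exceeds both image dimensions {h}x{w}")

    bx = _bspline_basis(h, spacing)
    by = _bspline_basis(w, spacing)
    gx = bx.T @ bx
    gy = by.T @ by
    # Tiny ridge keeps nearly-empty edge basis functions solvable.
    gx += 1e-12 * np.trace(gx) / gx.shape[0] * np.eye(gx.shape[0])
    gy += 1e-12 * np.trace(gy) / gy.shape[0] * np.eye(gy.shape[0])
    coef = np.linalg.solve(gx, bx.T @ field_2d @ by)
    coef = np.linalg.solve(gy, coef.T).T
    return bx @ coef @ by.T


def run_n4(image: np.ndarray, fov: np.ndarray | None = None,
           config: N4Config | None = None) -> tuple[np.ndarray, BiasFieldEstimate]:
    """Correct a multiplicative bias field on ``image``.

    Parameters
    ----------
    image : ndarray
        2-D intensity image, strictly positive inside ``fov``.
    fov : ndarray of bool, optional
        Field-of-view mask; defaults to the whole image.
    config : N4Config, optional

    Returns
    -------
    corrected : ndarray
        ``exp(log(image) - total_field)`` inside the FOV, input values outside.
    bias : BiasFieldEstimate
    """
    if config is None:
        config = N4Config()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidInputError("image must be 2-D")
    if fov is None:
        fov = np.ones(image.shape, dtype=bool)
    else:
        fov = np.asarray(fov, dtype=bool)
        if fov.shape != image.shape:
            raise InvalidInputError("fov shape does not match image")
    if not fov.any():
        raise InvalidInputError("empty field-of-view mask")
    bad = np.argwhere(fov & ~(image > 0))
    if bad.size:
        y, x = bad[0]
        raise InvalidInputError(
            f"non-positive pixel inside FOV at (row={y}, col={x}): {image[y, x]}")

    h, w = image.shape
    log_orig = np.zeros_like(image)
    log_orig[fov] = np.log(image[fov])
    u = log_orig.copy()

    residuals: list[np.ndarray] = [np.zeros(image.shape)]
    total = np.zeros_like(image)

    for level in range(config.fitting_levels):
        spacing = config.control_point_spacing / (2.0 ** level)
        spacing = float(np.clip(spacing, 2.0, max(h, w)))
        for _ in range(config.max_iterations):
            sharp = expected_true_image(u, config, weights_mask=fov)
            diff = u - sharp
            fill = float(diff[fov].mean())
            diff = np.where(fov, diff, fill)
            resid = smooth_field(diff, spacing)
            resid -= resid[fov].mean()

            u = u - resid
            total += resid
            residuals.append(resid)

            e = np.exp(resid[fov])
            cv = float(e.std() / e.mean())
            if cv < config.convergence_threshold:
                break

    corrected = image.copy()
    corrected[fov] = np.exp(log_orig[fov] - total[fov])
    bias = BiasFieldEstimate(residual_fields=residuals, total_field=total,
                             n_iterations=len(residuals) - 1)
    return corrected, bias
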