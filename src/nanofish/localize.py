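"""Sub-pixel localization of diffraction-limited spots.

Three estimators of the position of a point source are provided:

* least-squares fitting of an elliptical 2D Gaussian (the workhorse),
* background-subtracted intensity-weighted centroid (fast, noise-sensitive),
* maximum-likelihood estimation under a Poisson photon model (most accurate
  at low photon counts, slowest).

The Gaussian model of a spot is the continuous profile

    F(x, y) = z0 + A * exp(-[((x - x0)/sx)^2 + ((y - y0)/sy)^2] / 2)

with background ``z0``, peak intensity ``A``, center ``(x0, y0)`` and
per-axis standard deviations ``(sx, sy)``. Predicted pixel counts integrate
this profile over each pixel (error-function differences) rather than
point-sampling it at the pixel center, so that fits of spots whose width is
comparable to the pixel size carry no pixelation bias. Under this
convention the total signal above background is ``2*pi*A*sx*sy / a**2``
counts, ``a`` being the pixel size.

The localization precision (standard error of the fitted center per axis)
follows the standard photon-statistics formula

    sigma^2 = s^2/N + a^2/(12 N) + 8*pi*s^4*b^2 / (a^2 N^2)

where ``N`` is the number of detected signal photons, ``b`` the background
*noise* in photons per pixel (a standard deviation, not a mean level) and
``s`` the PSF standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.special import erf

from .core import ROI, UnfittableSpotError

__all__ = [
    "FitInit",
    "SpotFit",
    "theoretical_width",
    "initial_estimate",
    "fit_gaussian_lsq",
    "fit_gaussian_mle",
    "localize_centroid",
    "photons_from_counts",
    "model_photons",
    "localization_precision",
    "background_noise_estimate",
    "gaussian_model_image",
]

#: default relative tolerance on the objective between iterations ("0.01%")
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITERATIONS = 100


def theoretical_width(wavelength_nm: float, numerical_aperture: float) -> float:
    """Diffraction-limited Gaussian PSF standard deviation, s = 0.21 λ / NA.

    This is the Gaussian that best approximates the central lobe of the
    Airy pattern of a widefield microscope.
    """
    if wavelength_nm <= 0 or numerical_aperture <= 0:
        raise ValueError("wavelength and numerical aperture must be positive")
    return 0.21 * wavelength_nm / numerical_aperture


@dataclass
class FitInit:
    """Initial parameter estimates for a Gaussian spot fit."""

    z0: float
    A: float
    x0_nm: float
    y0_nm: float
    sx_nm: float
    sy_nm: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise UnfittableSpotError("initial amplitude must be positive")
        if self.sx_nm <= 0 or self.sy_nm <= 0:
            raise ValueError("initial widths must be positive")


@dataclass
class SpotFit:
    """Result of a spot localization.

    ``photons`` is the estimated number of detected signal photons N;
    ``background_noise`` the per-pixel background noise b (photons);
    ``sigma_nm`` the localization precision computed from them.
    """

    z0: float
    A: float
    x0_nm: float
    y0_nm: float
    sx_nm: float
    sy_nm: float
    theta: float
    n_iterations: int
    converged: bool
    residual_ss: float
    photons: float
    background_noise: float
    sigma_nm: float
    method: str = "lsq"
    photons_model: float = float("nan")
    flags: list[str] = field(default_factory=list)

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x0_nm, self.y0_nm])


def _axis_pixel_integrals(edges_nm: np.ndarray, mu: float, s: float) -> np.ndarray:
    """Fraction of a unit 1D Gaussian N(mu, s^2) falling in each pixel."""
    z = (edges_nm - mu) / (s * math.sqrt(2.0))
    e = erf(z)
    return 0.5 * (e[1:] - e[:-1])


def gaussian_model_image(
    roi: ROI,
    z0: float,
    A: float,
    x0_nm: float,
    y0_nm: float,
    sx_nm: float,
    sy_nm: float,
    theta: float = 0.0,
) -> np.ndarray:
    """Predicted pixel counts for the Gaussian spot model over a ROI.

    For the default axis-aligned model the Gaussian is integrated over each
    pixel. The opt-in rotated model (theta != 0) is point-sampled at pixel
    centers, an adequate approximation for the diagnostics it serves.
    """
    a = roi.pixel_size_nm
    if theta == 0.0:
        ix = _axis_pixel_integrals(roi.x_edges_nm(), x0_nm, sx_nm)
        iy = _axis_pixel_integrals(roi.y_edges_nm(), y0_nm, sy_nm)
        shape = np.outer(iy, ix) * (2.0 * math.pi * sx_nm * sy_nm / a**2)
        return z0 + A * shape
    xc, yc = np.meshgrid(roi.x_centers_nm(), roi.y_centers_nm())
    ct, st = math.cos(theta), math.sin(theta)
    u = (xc - x0_nm) * ct + (yc - y0_nm) * st
    v = -(xc - x0_nm) * st + (yc - y0_nm) * ct
    return z0 + A * np.exp(-0.5 * ((u / sx_nm) ** 2 + (v / sy_nm) ** 2))


def initial_estimate(roi: ROI, s_theory_nm: float) -> FitInit:
    """Starting parameters for the iterative fit.

    Background is the mean of the perimeter pixels, the amplitude is the
    brightest pixel minus that background, the center is the center of the
    brightest pixel (first in row-major order on ties), both widths start
    at the theoretical PSF width, and the rotation starts at zero.
    """
    z0 = float(roi.perimeter_values().mean())
    flat_idx = int(np.argmax(roi.data))  # row-major first occurrence on ties
    i, j = np.unravel_index(flat_idx, roi.data.shape)
    A = float(roi.data[i, j]) - z0
    if A <= 0:
        raise UnfittableSpotError("no signal above perimeter background")
    x0 = roi.x_centers_nm()[j]
    y0 = roi.y_centers_nm()[i]
    return FitInit(z0=z0, A=A, x0_nm=float(x0), y0_nm=float(y0),
                   sx_nm=s_theory_nm, sy_nm=s_theory_nm, theta=0.0)


def background_noise_estimate(roi: ROI, gain: Optional[float] = None) -> float:
    """Background noise b: standard deviation of perimeter pixels in photons."""
    g = roi.gain if gain is None else gain
    return float(roi.perimeter_values().std(ddof=0)) / g


def photons_from_counts(roi: ROI, fit: SpotFit, gain: Optional[float] = None) -> float:
    """Signal photons N = (total counts - fitted background) / gain, >= 0."""
    g = roi.gain if gain is None else gain
    if g <= 0:
        raise ValueError("gain must be positive")
    n = (float(roi.data.sum()) - fit.z0 * roi.data.size) / g
    return max(n, 0.0)


def model_photons(fit: SpotFit, pixel_size_nm: float, gain: float = 1.0) -> float:
    """Model-based photon estimate 2*pi*A*sx*sy / (a^2 * gain)."""
    return 2.0 * math.pi * fit.A * fit.sx_nm * fit.sy_nm / (pixel_size_nm**2 * gain)


def localization_precision(s_nm: float, n_photons: float, pixel_size_nm: float,
                           background_noise: float) -> float:
    """Per-axis precision of a fitted spot center.

    sigma = sqrt( s^2/N + a^2/(12 N) + 8 pi s^4 b^2 / (a^2 N^2) )

    ``background_noise`` is the standard deviation of the background in
    photons per pixel. For an elliptical fit pass s = sqrt(sx * sy).
    """
    if s_nm <= 0 or pixel_size_nm <= 0:
        raise ValueError("s and pixel size must be positive")
    if n_photons <= 0:
        raise ValueError("precision undefined for zero photons")
    if background_noise < 0:
        raise ValueError("background noise must be non-negative")
    s2, a2, n = s_nm**2, pixel_size_nm**2, n_photons
    var = s2 / n + a2 / (12.0 * n) + 8.0 * math.pi * s2**2 * background_noise**2 / (a2 * n**2)
    return math.sqrt(var)


def _finalize(roi: ROI, p: np.ndarray, theta: float, n_iter: int, converged: bool,
              resid_ss: float, method: str, gain: float,
              flags: Optional[list[str]] = None) -> SpotFit:
    z0, A, x0, y0, sx, sy = (float(v) for v in p)
    fit = SpotFit(z0=z0, A=A, x0_nm=x0, y0_nm=y0, sx_nm=abs(sx), sy_nm=abs(sy),
                  theta=theta, n_iterations=n_iter, converged=converged,
                  residual_ss=resid_ss, photons=0.0, background_noise=0.0,
                  sigma_nm=float("nan"), method=method, flags=list(flags or []))
    if not roi.contains_nm(fit.x0_nm, fit.y0_nm):
        fit.flags.append("center_outside_roi")
        fit.converged = False
    fit.photons = photons_from_counts(roi, fit, gain)
    fit.photons_model = model_photons(fit, roi.pixel_size_nm, gain)
    fit.background_noise = background_noise_estimate(roi, gain)
    if fit.photons > 0:
        s_eff = math.sqrt(fit.sx_nm * fit.sy_nm)
        fit.sigma_nm = localization_precision(
            s_eff, fit.photons, roi.pixel_size_nm, fit.background_noise)
    else:
        fit.flags.append("zero_photons")
    return fit


def fit_gaussian_lsq(
    roi: ROI,
    init: Optional[FitInit] = None,
    tol: float = DEFAULT_TOL,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    s_theory_nm: Optional[float] = None,
    gain: Optional[float] = None,
    convergence: str = "sse",
) -> SpotFit:
    """Least-squares elliptical Gaussian fit by Levenberg–Marquardt iteration.

    The six parameters (z0, A, x0, y0, sx, sy) are adjusted to minimize the
    sum of squared differences between the integrated-Gaussian model and the
    observed counts. Iterations stop when the relative change of the sum of
    squares between successive accepted steps falls below ``tol`` (default
    1e-4, i.e. 0.01%); pass ``convergence="step"`` to use the maximum
    relative parameter change instead. The two widths adjust independently:
    real spots are never perfectly symmetric.
    """
    if init is None:
        if s_theory_nm is None:
            if roi.optics is None:
                raise ValueError("need init, s_theory_nm, or ROI optics metadata")
            s_theory_nm = theoretical_width(roi.optics.wavelength_nm,
                                            roi.optics.numerical_aperture)
        init = initial_estimate(roi, s_theory_nm)
    if convergence not in ("sse", "step"):
        raise ValueError("convergence must be 'sse' or 'step'")
    g = roi.gain if gain is None else gain
    counts = roi.data.ravel()
    a = roi.pixel_size_nm

    def predict(p: np.ndarray) -> np.ndarray:
        return gaussian_model_image(roi, *p).ravel()

    def jacobian(p: np.ndarray, f0: np.ndarray) -> np.ndarray:
        # forward differences; steps scaled to parameter magnitudes
        steps = np.array([
            max(abs(p[0]), 1.0) * 1e-6 + 1e-9,
            max(abs(p[1]), 1.0) * 1e-6,
            a * 1e-5,
            a * 1e-5,
            max(p[4], 1.0) * 1e-6,
            max(p[5], 1.0) * 1e-6,
        ])
        J = np.empty((f0.size, 6))
        for k in range(6):
            q = p.copy()
            q[k] += steps[k]
            J[:, k] = (predict(q) - f0) / steps[k]
        return J

    p = np.array([init.z0, init.A, init.x0_nm, init.y0_nm,
                  init.sx_nm, init.sy_nm], dtype=float)
    f = predict(p)
    sse = float(((f - counts) ** 2).sum())
    lam = 1e-3
    converged = False
    n_iter = 0
    for _ in range(max_iterations):
        r = f - counts
        J = jacobian(p, f)
        jtj = J.T @ J
        jtr = J.T @ r
        accepted = False
        for _damp in range(25):
            try:
                delta = np.linalg.solve(jtj + lam * np.diag(np.diag(jtj) + 1e-12), -jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            q = p + delta
            if q[1] <= 0 or q[4] <= 0 or q[5] <= 0:
                lam *= 10.0
                continue
            fq = predict(q)
            sse_q = float(((fq - counts) ** 2).sum())
            if sse_q <= sse:
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            break
        n_iter += 1
        lam = max(lam / 10.0, 1e-12)
        if convergence == "sse":
            rel = (sse - sse_q) / sse if sse > 0 else 0.0
        else:
            scale = np.maximum(np.abs(p), np.array([1.0, 1.0, a, a, a, a]))
            rel = float(np.max(np.abs(delta) / scale))
        p, f, sse = q, fq, sse_q
        if rel < tol:
            converged = True
            break
    return _finalize(roi, p, 0.0, n_iter, converged, sse, "lsq", g)


def fit_gaussian_mle(
    roi: ROI,
    init: Optional[FitInit] = None,
    gain: Optional[float] = None,
    tol: float = DEFAULT_TOL,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    s_theory_nm: Optional[float] = None,
) -> SpotFit:
    """Maximum-likelihood Gaussian fit under Poisson photon statistics.

    Counts are converted to photons with the camera gain and the Poisson
    log-likelihood of the integrated-Gaussian-plus-background model is
    maximized (L-BFGS-B). Convergence follows the same relative-change
    criterion as the least-squares fit, applied to the negative
    log-likelihood.
    """
    g = roi.gain if gain is None else gain
    if g <= 0:
        raise ValueError("gain must be positive")
    if init is None:
        if s_theory_nm is None:
            if roi.optics is None:
                raise ValueError("need init, s_theory_nm, or ROI optics metadata")
            s_theory_nm = theoretical_width(roi.optics.wavelength_nm,
                                            roi.optics.numerical_aperture)
        init = initial_estimate(roi, s_theory_nm)
    photons_img = np.maximum(roi.data / g, 0.0).ravel()
    a = roi.pixel_size_nm
    pos = photons_img > 0
    c_log_c = np.zeros_like(photons_img)
    c_log_c[pos] = photons_img[pos] * np.log(photons_img[pos])

    def nll(p: np.ndarray) -> float:
        # Poisson deviance: 2*sum(mu - c + c*log(c/mu)); same optimum as the
        # log-likelihood but bounded below by 0, so the relative-change
        # stopping rule behaves like the least-squares one
        mu = gaussian_model_image(roi, *p).ravel()
        mu = np.maximum(mu, 1e-12)
        return float(2.0 * np.sum(mu - photons_img
                                  + c_log_c - photons_img * np.log(mu)))

    p0 = np.array([init.z0 / g, init.A / g, init.x0_nm, init.y0_nm,
                   init.sx_nm, init.sy_nm])
    xe, ye = roi.x_edges_nm(), roi.y_edges_nm()
    bounds = [(0.0, None), (1e-9, None), (xe[0], xe[-1]), (ye[0], ye[-1]),
              (a / 20.0, 20.0 * max(init.sx_nm, init.sy_nm)),
              (a / 20.0, 20.0 * max(init.sx_nm, init.sy_nm))]
    res = optimize.minimize(
        nll, p0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": tol, "maxiter": max_iterations})
    p = res.x.copy()
    p[0] *= g  # back to counts for the shared record layout
    p[1] *= g
    flags = [] if res.success else [f"optimizer:{res.message}"]
    fit = _finalize(roi, p, 0.0, int(res.nit), bool(res.success),
                    float(res.fun), "mle", g, flags)
    return fit


def localize_centroid(roi: ROI) -> tuple[float, float]:
    """Background-subtracted intensity-weighted centroid, in parent-frame nm.

    The perimeter mean is subtracted and negative residuals clipped to zero.
    Simple and fast, but degrades quickly as the signal-to-noise ratio drops.
    """
    bg = float(roi.perimeter_values().mean())
    w = np.clip(roi.data - bg, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise UnfittableSpotError("centroid undefined: no signal above background")
    x = float((w.sum(axis=0) * roi.x_centers_nm()).sum() / total)
    y = float((w.sum(axis=1) * roi.y_centers_nm()).sum() / total)
    return x, y
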