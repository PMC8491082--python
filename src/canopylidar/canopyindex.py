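"""Spectral canopy-structure measure (the 3D canopy index, 3DCI).

A plot's grayscale CHM is taken to the frequency domain with a forward 2D
DFT; the log-scaled, centre-shifted magnitude spectrogram summarizes the
spatial variation of canopy height.  Amplitudes sampled along the main
diagonal through the DC centre form the canopy structural curve once a
Gaussian is fitted to them.  The area beneath the fitted curve (trapezoidal
rule over [a, b], default [-100, 100]) accumulates spatial variance - larger
area, less uniform canopy - and the curvature at the curve apex indexes
canopy density (denser canopy, flatter curve).  Areas are min-max normalized
over a cohort of plots, with the band stretched to 59.3% of the cohort
minimum and 129.4% of the maximum so every normalized value falls strictly
inside (0, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SpectralImage",
    "CanopyCurve",
    "dft_magnitude",
    "sample_diagonal",
    "fit_gaussian_curve",
    "curve_auc",
    "parametric_curvature",
    "curve_curvature",
    "compute_3dci",
    "canopy_curve_for_image",
]


@dataclass
class SpectralImage:
    """Centred log-magnitude spectrum of a plot CHM.

    ``log_magnitude`` is log(1 + |F|) with the DC component shifted to the
    centre cell; ``image`` is the same grid linearly rescaled to 0-255 for
    display.
    """

    log_magnitude: np.ndarray
    image: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.log_magnitude.shape

    @property
    def centre(self) -> tuple[int, int]:
        m, n = self.shape
        return m // 2, n // 2


@dataclass
class CanopyCurve:
    """Canopy structural curve of one plot: frequency samples, raw and
    Gaussian-fitted amplitudes, and the scalar descriptors derived from
    them."""

    frequencies: np.ndarray
    amplitudes: np.ndarray
    amplitude: float | None = None  # Gaussian A
    centre: float | None = None  # Gaussian mu
    sigma: float | None = None  # Gaussian width
    fitted: np.ndarray | None = None
    fit_ok: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        """Fitted amplitudes when the fit succeeded, else the raw samples."""
        return self.fitted if self.fit_ok else self.amplitudes


def dft_magnitude(image: np.ndarray) -> SpectralImage:
    """Forward 2D DFT magnitude -> log(1 + |F|) -> DC centred -> 0-255."""
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    spectrum = np.fft.fft2(img)
    log_mag = np.fft.fftshift(np.log1p(np.abs(spectrum)))
    lo, hi = log_mag.min(), log_mag.max()
    if hi > lo:
        scaled = 255.0 * (log_mag - lo) / (hi - lo)
    else:
        scaled = np.zeros_like(log_mag)
    return SpectralImage(log_mag, scaled)


def sample_diagonal(
    spec: SpectralImage,
    a: int = -100,
    b: int = 100,
    both_diagonals: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitudes along the main diagonal through the spectrum centre.

    Samples sit at integer diagonal steps a..b from the DC cell (b - a + 1
    values).  When the image cannot host the requested span, the available
    diagonal profile is linearly resampled onto the same number of points so
    the frequency domain stays fixed across plot sizes.  ``both_diagonals``
    averages the main and anti-diagonal profiles.

    Amplitudes are read from the log-magnitude grid before its 0-255 display
    rescaling: the rescale maps each plot's own extremes to the full range,
    which would erase exactly the cross-plot amplitude differences the area
    under the curve accumulates.
    """
    if a >= b:
        raise ValueError("a must be < b")
    cy, cx = spec.centre
    m, n = spec.shape
    span = min(cy, cx, m - 1 - cy, n - 1 - cx)
    freqs = np.arange(a, b + 1, dtype=np.float64)

    def profile(sign: int) -> np.ndarray:
        if span >= max(-a, b):
            steps = np.arange(a, b + 1)
            return spec.log_magnitude[cy + steps, cx + sign * steps]
        if span < 1:
            raise ValueError("spectrum too small to sample a diagonal")
        steps = np.arange(-span, span + 1)
        raw = spec.log_magnitude[cy + steps, cx + sign * steps]
        scaled_pos = (steps - (-span)) / (2 * span) * (b - a) + a
        return np.interp(freqs, scaled_pos, raw)

    amps = profile(1)
    if both_diagonals:
        amps = 0.5 * (amps + profile(-1))
    return freqs, amps


def _gaussian(x: np.ndarray, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian_curve(
    frequencies: np.ndarray, amplitudes: np.ndarray
) -> CanopyCurve:
    """Least-squares Gaussian fit A exp(-(x - mu)^2 / 2 sigma^2) to the
    sampled amplitudes; a failed or degenerate fit is flagged and the raw
    curve retained."""
    x = np.asarray(frequencies, dtype=np.float64)
    yv = np.asarray(amplitudes, dtype=np.float64)
    if x.size < 5:
        raise ValueError("need at least 5 samples to fit")
    curve = CanopyCurve(x, yv)
    if np.ptp(yv) == 0:
        curve.flags.append("degenerate_fit")
        return curve
    peak = float(yv.max())
    mu0 = float(x[np.argmax(yv)])
    sigma0 = max((x.max() - x.min()) / 8.0, 1e-3)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gaussian, x, yv,
                p0=(peak, mu0, sigma0),
                bounds=((0.0, x.min(), 1e-6), (np.inf, x.max(), np.inf)),
                maxfev=10000,
            )
    except (RuntimeError, ValueError):
        curve.flags.append("fit_failed")
        return curve
    curve.amplitude, curve.centre, curve.sigma = map(float, popt)
    curve.fitted = _gaussian(x, *popt)
    curve.fit_ok = True
    return curve


def curve_auc(curve: CanopyCurve) -> float:
    """Area beneath the structural curve by the trapezoidal rule,
    sum_k (f(x_k) + f(x_{k+1})) / 2 * dx_k, over the sampled span."""
    y = curve.values
    if y is None or y.size < 2:
        raise ValueError("need at least 2 samples for the trapezoidal rule")
    return float(np.trapezoid(y, curve.frequencies))


def parametric_curvature(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Curvature kappa(t) = |x'y'' - x''y'| / (x'^2 + y'^2)^(3/2) of a
    parametric curve sampled over index t, derivatives by central
    differences."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 5:
        raise ValueError("need at least 5 samples for curvature")

    def d1(v: np.ndarray) -> np.ndarray:
        out = np.empty_like(v)
        out[1:-1] = (v[2:] - v[:-2]) / 2.0
        out[0], out[-1] = v[1] - v[0], v[-1] - v[-2]
        return out

    def d2(v: np.ndarray) -> np.ndarray:
        # single-step Laplacian: second-order accurate at unit index spacing
        out = np.empty_like(v)
        out[1:-1] = v[2:] - 2.0 * v[1:-1] + v[:-2]
        out[0], out[-1] = out[1], out[-2]
        return out

    dx, dy = d1(x), d1(y)
    ddx, ddy = d2(x), d2(y)
    denom = (dx * dx + dy * dy) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.abs(dx * ddy - ddx * dy) / denom
    return np.nan_to_num(kappa)


def curve_curvature(curve: CanopyCurve) -> float:
    """Curvature of the fitted structural curve at its apex (x = mu)."""
    if not curve.fit_ok or curve.fitted is None:
        raise ValueError("curvature needs a successful Gaussian fit")
    kappa = parametric_curvature(curve.frequencies, curve.fitted)
    apex = int(np.argmin(np.abs(curve.frequencies - curve.centre)))
    return float(kappa[apex])


def compute_3dci(auc_values: np.ndarray) -> np.ndarray:
    """Min-max normalize cohort AUC values to the open interval (0, 1).

    The band is stretched beyond the observed range: MinValue = 59.3% of the
    cohort minimum and MaxValue = 129.4% of the cohort maximum, so
    y = (x - 0.593 min) / (1.294 max - 0.593 min).  Scale-invariant: a cohort
    multiplied by any positive constant normalizes identically.
    """
    x = np.asarray(auc_values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 cohort values")
    if np.any(x <= 0):
        raise ValueError("AUC values must be positive")
    lo, hi = x.min(), x.max()
    if lo == hi:
        raise ValueError("cohort values are identical (zero range)")
    min_value = 0.593 * lo
    max_value = 1.294 * hi
    return (x - min_value) / (max_value - min_value)


def canopy_curve_for_image(
    plot_image: np.ndarray,
    a: int = -100,
    b: int = 100,
    both_diagonals: bool = False,
) -> CanopyCurve:
    """Plot CHM image -> spectrogram -> diagonal sampling -> Gaussian fit."""
    spec = dft_magnitude(plot_image)
    freqs, amps = sample_diagonal(spec, a, b, both_diagonals)
    return fit_gaussian_curve(freqs, amps)
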