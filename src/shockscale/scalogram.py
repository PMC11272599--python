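"""Continuous wavelet transform with a Morlet mother wavelet, and scalogram images.

The transform of a signal :math:`f(t)` at scale :math:`a` and shift :math:`b` is

.. math:: C(a, b) = \\frac{1}{\\sqrt{a}} \\int f(t)\\, \\overline{\\psi\\!\\left(\\frac{t-b}{a}\\right)} \\, dt

with the Morlet mother wavelet
:math:`\\psi(t) = e^{2\\pi i t} e^{-t^2 / 2\\sigma^2}` — a unit-modulus complex
carrier at one cycle per unit wavelet time under a Gaussian envelope of width
``sigma``.  The pseudo-frequency probed at scale ``a`` (seconds) is therefore
``center_frequency / a`` Hz with ``center_frequency = 1``.

The discretised transform sums over sample times with :math:`\\Delta t = 1/fs`
and truncates the wavelet where its envelope falls below :math:`10^{-8}` of
the peak.  :func:`cwt` uses an FFT-convolution path; :func:`cwt_direct` is the
literal double-loop summation kept as the reference the fast path must match.

Scalograms render coefficient magnitudes through a matplotlib colormap
(default the MATLAB-style ``jet``), min–max scaled per image, high frequency
(small scale) at the top, resized to a square 8-bit RGB image (default
227×227×3).
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
from scipy.signal import fftconvolve
from skimage.transform import resize

from shockscale.types import ECGFragment

#: Envelope truncation threshold relative to the wavelet peak.
ENVELOPE_CUTOFF = 1e-8


@dataclass(frozen=True)
class MorletConfig:
    """Morlet wavelet parameters: Gaussian width ``sigma`` (dimensionless);
    the complex carrier fixes the center frequency at 1 cycle per unit time."""

    sigma: float = 1.0
    center_frequency: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class ScaleGrid:
    """Strictly increasing positive scales, in seconds."""

    scales: tuple[float, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.scales, dtype=float)
        if a.size == 0:
            raise ValueError("scale grid must be non-empty")
        if np.any(a <= 0) or np.any(np.diff(a) <= 0):
            raise ValueError("scales must be strictly increasing and positive")

    @classmethod
    def log_spaced(cls, a_min: float, a_max: float, n_scales: int = 64) -> "ScaleGrid":
        return cls(tuple(np.geomspace(a_min, a_max, n_scales)))

    @classmethod
    def from_frequencies(
        cls,
        f_min: float = 1.0,
        f_max: float = 50.0,
        n_scales: int = 64,
        center_frequency: float = 1.0,
    ) -> "ScaleGrid":
        """Log-spaced scales whose pseudo-frequencies span [f_min, f_max] Hz."""
        return cls.log_spaced(center_frequency / f_max, center_frequency / f_min, n_scales)

    def __len__(self) -> int:
        return len(self.scales)

    def pseudo_frequencies(self, center_frequency: float = 1.0) -> np.ndarray:
        return center_frequency / np.asarray(self.scales)


@dataclass
class CWTCoefficients:
    """Complex coefficient matrix indexed (scale, shift)."""

    values: np.ndarray  # (n_scales, n_samples) complex
    scales: ScaleGrid
    shifts: np.ndarray  # sample times b in seconds
    fs: float

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class ScalogramImage:
    """Square 8-bit RGB image of coefficient magnitudes."""

    pixels: np.ndarray  # (H, W, 3) uint8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3 or self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be an (H, W, 3) uint8 array")


def morlet(t: np.ndarray | float, cfg: MorletConfig | None = None) -> np.ndarray | complex:
    """Morlet mother wavelet :math:`e^{2\\pi i t} e^{-t^2/2\\sigma^2}`."""
    cfg = cfg or MorletConfig()
    t = np.asarray(t, dtype=float)
    out = np.exp(2j * np.pi * cfg.center_frequency * t) * np.exp(-(t**2) / (2 * cfg.sigma**2))
    return complex(out) if out.ndim == 0 else out


def _support_halfwidth(a: float, cfg: MorletConfig) -> float:
    # |t/a| beyond which the envelope drops under ENVELOPE_CUTOFF of its peak
    return a * cfg.sigma * np.sqrt(-2.0 * np.log(ENVELOPE_CUTOFF))


def cwt_direct(frag: ECGFragment, grid: ScaleGrid, cfg: MorletConfig | None = None) -> CWTCoefficients:
    """Literal double-loop discretisation of the transform (reference path)."""
    cfg = cfg or MorletConfig()
    x = frag.samples
    t = frag.times
    dt = 1.0 / frag.fs
    values = np.empty((len(grid), len(x)), dtype=complex)
    for i, a in enumerate(grid.scales):
        half = _support_halfwidth(a, cfg)
        for j, b in enumerate(t):
            u = (t - b) / a
            mask = np.abs(t - b) <= half
            psi = morlet(u[mask], cfg)
            values[i, j] = np.sum(x[mask] * np.conj(psi)) * dt / np.sqrt(a)
    return CWTCoefficients(values=values, scales=grid, shifts=t.copy(), fs=frag.fs)


def cwt(frag: ECGFragment, grid: ScaleGrid, cfg: MorletConfig | None = None) -> CWTCoefficients:
    """FFT-convolution transform; matches :func:`cwt_direct` to numerical precision."""
    cfg = cfg or MorletConfig()
    x = frag.samples
    n = len(x)
    dt = 1.0 / frag.fs
    t = frag.times
    values = np.empty((len(grid), n), dtype=complex)
    for i, a in enumerate(grid.scales):
        half = _support_halfwidth(a, cfg)
        J = int(np.floor(half / dt))
        u = np.arange(-J, J + 1) * dt
        # kernel h(v) = conj(psi(-v/a)) so that (x * h)[b] = sum_t x[t] conj(psi((t-b)/a))
        kernel = np.conj(morlet(-u / a, cfg))
        conv = fftconvolve(x.astype(complex), kernel, mode="same")
        values[i] = conv * dt / np.sqrt(a)
    return CWTCoefficients(values=values, scales=grid, shifts=t.copy(), fs=frag.fs)


class CWTTransformer:
    """Batch transformer that caches per-scale kernel FFTs for a fixed
    (n_samples, fs, grid, wavelet) combination — the hot path when converting
    thousands of equal-length fragments."""

    def __init__(self, n_samples: int, fs: float, grid: ScaleGrid, cfg: MorletConfig | None = None):
        self.cfg = cfg or MorletConfig()
        self.grid = grid
        self.fs = fs
        self.n = n_samples
        dt = 1.0 / fs
        halves = [int(np.floor(_support_halfwidth(a, self.cfg) / dt)) for a in grid.scales]
        Jmax = max(halves)
        self.L = int(2 ** np.ceil(np.log2(n_samples + 2 * Jmax + 1)))
        self._kernel_ffts = []
        for a, J in zip(grid.scales, halves):
            u = np.arange(-J, J + 1) * dt
            kernel = np.conj(morlet(-u / a, self.cfg)) * dt / np.sqrt(a)
            # roll so that kernel center lands at sample 0 of the circular conv
            padded = np.zeros(self.L, dtype=complex)
            padded[: 2 * J + 1] = kernel
            padded = np.roll(padded, -J)
            self._kernel_ffts.append(np.fft.fft(padded))

    def transform(self, frag: ECGFragment) -> CWTCoefficients:
        if len(frag.samples) != self.n or frag.fs != self.fs:
            raise ValueError("fragment length/fs does not match transformer")
        xf = np.fft.fft(frag.samples, self.L)
        values = np.empty((len(self.grid), self.n), dtype=complex)
        for i, kf in enumerate(self._kernel_ffts):
            values[i] = np.fft.ifft(xf * kf)[: self.n]
        return CWTCoefficients(values=values, scales=self.grid, shifts=frag.times, fs=self.fs)


def render(
    coeffs: CWTCoefficients,
    size: int = 227,
    colormap: str = "jet",
    log_magnitude: bool = False,
) -> ScalogramImage:
    """Render coefficient magnitudes as a square 8-bit RGB scalogram.

    Magnitudes are min–max scaled to [0, 1] per image (a constant matrix maps
    to all zeros), passed through the named colormap, oriented with small
    scales (high frequencies) at the top, resized with bilinear interpolation
    and quantised to [0, 255].
    """
    mag = coeffs.magnitude()
    if not np.all(np.isfinite(mag)):
        raise ValueError("coefficients must be finite")
    if log_magnitude:
        mag = np.log1p(mag)
    lo, hi = float(mag.min()), float(mag.max())
    norm = (mag - lo) / (hi - lo) if hi > lo else np.zeros_like(mag)
    try:
        cmap = matplotlib.colormaps[colormap]
    except KeyError as exc:
        raise ValueError(f"unknown colormap {colormap!r}") from exc
    rgb = cmap(norm)[:, :, :3]  # row 0 = smallest scale = highest frequency: top
    resized = resize(rgb, (size, size, 3), order=1, mode="edge", anti_aliasing=False)
    pixels = np.clip(np.round(resized * 255.0), 0, 255).astype(np.uint8)
    return ScalogramImage(pixels=pixels)


def normalize_for_model(img: ScalogramImage) -> np.ndarray:
    """Scale 8-bit pixels to floats in [0, 1] by dividing by 255."""
    return img.pixels.astype(np.float64) / 255.0


def save_png(img: ScalogramImage, path) -> None:
    from PIL import Image

    Image.fromarray(img.pixels).save(str(path))


def load_png(path) -> ScalogramImage:
    from PIL import Image

    return ScalogramImage(pixels=np.asarray(Image.open(str(path)).convert("RGB")))
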