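"""Even-symmetric Gabor bank and triple-lobe ordinal filter.

The contour representation used throughout the pipeline is built in two linear
stages applied to a single-channel image ``I``:

1. ``F = I * G`` — convolution with a bank of even-symmetric (cosine-carrier)
   Gabor kernels

   ``G(x, y) = gamma / (2 pi sigma^2) * exp(-(x_t^2 + gamma^2 y_t^2) / (2 sigma^2))
   * cos(2 pi f x_t)``

   with ``x_t = x cos(theta) + y sin(theta)``, ``y_t = -x sin(theta) + y cos(theta)``,
   reduced across the bank by summation (a linear, isotropic zero-DC band-pass
   whose zero crossings localize contours; a signed max-magnitude reduction is
   also available).

2. ``S = F * Ordinal`` — convolution with a zero-sum "triple lobe" filter, a
   positive central Gaussian flanked by negative Gaussian lobes.  The balanced
   (zero-sum) kernel suppresses the DC component of ``F`` and produces a
   centre-surround contrast response whose zero crossings localize contours.

All convolutions are true convolutions (kernel flipped) with reflect padding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .exceptions import ParameterError

__all__ = [
    "GaborParams",
    "OrdinalParams",
    "FeatureMap",
    "make_gabor_kernel",
    "default_gabor_bank",
    "gabor_feature_map",
    "make_ordinal_kernel",
    "make_ordinal_kernel_2d",
    "ordinal_feature_map",
    "normalize_map",
]


@dataclass(frozen=True)
class GaborParams:
    """Parameters of one even-symmetric Gabor kernel.

    f : center frequency, cycles/pixel (> 0)
    theta : orientation, radians in [0, pi)
    sigma : Gaussian envelope scale, pixels (> 0)
    gamma : envelope length-to-width ratio (> 0)
    support : half-width of the square kernel, pixels (>= 1)
    """

    f: float
    theta: float
    sigma: float
    gamma: float
    support: int

    def __post_init__(self):
        if self.f <= 0:
            raise ParameterError(f"Gabor center frequency must be > 0, got {self.f}")
        if self.sigma <= 0:
            raise ParameterError(f"Gabor sigma must be > 0, got {self.sigma}")
        if self.gamma <= 0:
            raise ParameterError(f"Gabor gamma must be > 0, got {self.gamma}")
        if self.support < 1:
            raise ParameterError(f"Gabor support must be >= 1, got {self.support}")


@dataclass(frozen=True)
class OrdinalParams:
    """Lobes of the ordinal filter: signed sum of 1-D Gaussians.

    positive_lobes / negative_lobes : sequences of (omega, sigma) pairs, where
    omega is the lobe center offset (pixels) and sigma its scale (> 0).
    c_p / c_n : polarity coefficients; with the defaults the discretized kernel
    sums to zero (positive and negative lobes balance).
    """

    positive_lobes: tuple = ((0.0, 1.0),)
    negative_lobes: tuple = ((-3.0, 1.0), (3.0, 1.0))
    c_p: float = 1.0
    c_n: float = 0.5

    def __post_init__(self):
        if len(self.positive_lobes) < 1 or len(self.negative_lobes) < 1:
            raise ParameterError("ordinal filter needs >= 1 positive and >= 1 negative lobe")
        for omega, sigma in (*self.positive_lobes, *self.negative_lobes):
            if sigma <= 0:
                raise ParameterError(f"ordinal lobe sigma must be > 0, got {sigma}")


@dataclass
class FeatureMap:
    """A real 2-D response field with its generating parameters.

    kind is "gabor-F" for the Gabor stage or "ordinal-S" for the
    Gabor-ordinal stage.  values has the same shape as the source image.
    """

    values: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ParameterError("feature map must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("feature map contains non-finite values")
        if self.kind not in ("gabor-F", "ordinal-S"):
            raise ParameterError(f"unknown feature-map kind {self.kind!r}")

    @property
    def shape(self):
        return self.values.shape


def make_gabor_kernel(params: GaborParams) -> np.ndarray:
    """Sample the even-symmetric Gabor kernel on a (2*support+1)^2 grid.

    The kernel is exactly even, K(x, y) == K(-x, -y): both the Gaussian
    envelope and the cosine carrier are even functions of (x_t, y_t).
    """
    s = params.support
    y, x = np.mgrid[-s : s + 1, -s : s + 1].astype(float)
    xt = x * math.cos(params.theta) + y * math.sin(params.theta)
    yt = -x * math.sin(params.theta) + y * math.cos(params.theta)
    envelope = np.exp(-(xt**2 + params.gamma**2 * yt**2) / (2.0 * params.sigma**2))
    carrier = np.cos(2.0 * math.pi * params.f * xt)
    return params.gamma / (2.0 * math.pi * params.sigma**2) * envelope * carrier


def default_gabor_bank(
    n_orientations: int = 8,
    sigmas: tuple = (2.0, 4.0, 8.0),
    gamma: float = 0.5,
) -> list[GaborParams]:
    """Conventional bank: theta = k*pi/n, f = 1/(2*sigma), support = ceil(3*sigma)."""
    bank = []
    for sigma in sigmas:
        for k in range(n_orientations):
            bank.append(
                GaborParams(
                    f=1.0 / (2.0 * sigma),
                    theta=k * math.pi / n_orientations,
                    sigma=float(sigma),
                    gamma=gamma,
                    support=int(math.ceil(3.0 * sigma)),
                )
            )
    return bank


def _convolve_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True 2-D convolution with reflect border handling, same-size output."""
    ph = kernel.shape[0] // 2
    pw = kernel.shape[1] // 2
    padded = np.pad(image, ((ph, ph), (pw, pw)), mode="reflect")
    out = fftconvolve(padded, kernel, mode="same")
    return out[ph : ph + image.shape[0], pw : pw + image.shape[1]]


def gabor_feature_map(
    image: np.ndarray, bank: list[GaborParams], combine: str = "sum"
) -> FeatureMap:
    """Convolve with every bank kernel and reduce across the bank.

    The default reduction sums the responses over all orientations and
    scales, a linear reduction that behaves like one isotropic zero-DC
    band-pass operator: the zero crossings of the result localize contours
    stably in both modalities.  "signed_max" keeps the single response of
    largest magnitude (with its sign) instead; being nonlinear, it switches
    winners near response zero crossings and trades localization for
    orientation selectivity.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ParameterError("image must be a non-empty single-channel 2-D array")
    if not np.all(np.isfinite(image)):
        raise ParameterError("image contains non-finite values")
    if len(bank) == 0:
        raise ParameterError("Gabor bank is empty")
    if combine not in ("signed_max", "sum"):
        raise ParameterError(f"unknown reduction {combine!r}")

    responses = np.stack([_convolve_reflect(image, make_gabor_kernel(p)) for p in bank])
    if combine == "sum":
        values = responses.sum(axis=0)
    else:
        winner = np.argmax(np.abs(responses), axis=0)
        values = np.take_along_axis(responses, winner[None], axis=0)[0]
    return FeatureMap(values=values, kind="gabor-F", params={"bank": list(bank)})


def _discrete_gaussian(x: np.ndarray, omega: float, sigma: float) -> np.ndarray:
    g = np.exp(-((x - omega) ** 2) / (2.0 * sigma**2))
    return g / g.sum()


def make_ordinal_kernel(params: OrdinalParams, support: int) -> np.ndarray:
    """Sample the 1-D ordinal kernel on [-support, support].

    Each lobe is a discretely normalized Gaussian, so the kernel sum equals
    c_p * N_p - c_n * N_n exactly; with the balanced defaults that is zero.
    """
    for omega, sigma in (*params.positive_lobes, *params.negative_lobes):
        if abs(omega) + 3.0 * sigma > support:
            raise ParameterError(
                f"lobe (omega={omega}, sigma={sigma}) exceeds support {support}"
            )
    x = np.arange(-support, support + 1, dtype=float)
    kernel = np.zeros_like(x)
    for omega, sigma in params.positive_lobes:
        kernel += params.c_p * _discrete_gaussian(x, omega, sigma)
    for omega, sigma in params.negative_lobes:
        kernel -= params.c_n * _discrete_gaussian(x, omega, sigma)
    return kernel


def make_ordinal_kernel_2d(params: OrdinalParams, support: int) -> np.ndarray:
    """Isotropic 2-D realization: positive lobes are circular Gaussians at the
    origin; each negative lobe (omega, sigma) becomes four Gaussians at
    (+-omega, 0) and (0, +-omega) carrying a quarter of its weight each, so the
    lobe balance (and the zero sum, with balanced coefficients) is preserved.
    """
    for omega, sigma in (*params.positive_lobes, *params.negative_lobes):
        if abs(omega) + 3.0 * sigma > support:
            raise ParameterError(
                f"lobe (omega={omega}, sigma={sigma}) exceeds support {support}"
            )
    y, x = np.mgrid[-support : support + 1, -support : support + 1].astype(float)

    def gauss2d(cx, cy, sigma):
        g = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * sigma**2))
        return g / g.sum()

    kernel = np.zeros_like(x)
    for omega, sigma in params.positive_lobes:
        kernel += params.c_p * gauss2d(0.0, 0.0, sigma)
    for omega, sigma in params.negative_lobes:
        r = abs(omega)
        for cx, cy in ((r, 0.0), (-r, 0.0), (0.0, r), (0.0, -r)):
            kernel -= 0.25 * params.c_n * gauss2d(cx, cy, sigma)
    return kernel


def ordinal_feature_map(F: FeatureMap, params: OrdinalParams | None = None) -> FeatureMap:
    """Convolve the Gabor map F with the isotropic 2-D ordinal kernel."""
    if F.kind != "gabor-F":
        raise ParameterError(f"ordinal stage expects a gabor-F map, got {F.kind!r}")
    params = params or OrdinalParams()
    support = int(
        math.ceil(max(abs(o) + 3.0 * s for o, s in (*params.positive_lobes, *params.negative_lobes)))
    )
    kernel = make_ordinal_kernel_2d(params, support)
    values = _convolve_reflect(F.values, kernel)
    return FeatureMap(values=values, kind="ordinal-S", params={**F.params, "ordinal": params})


def normalize_map(fmap: FeatureMap) -> FeatureMap:
    """Scale values into [-1, 1] by the maximum magnitude.

    Symmetric scaling preserves the zero level of the signed response, which
    the contour stage relies on (zero crossings localize edges).  An all-zero
    map is returned unchanged.
    """
    peak = np.max(np.abs(fmap.values))
    values = fmap.values / peak if peak > 0 else fmap.values
    return FeatureMap(values=values, kind=fmap.kind, params=dict(fmap.params))
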