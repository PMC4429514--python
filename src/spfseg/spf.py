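"""Signed pressure force (SPF) construction for the two-phase model.

The SPF replaces the gradient-based edge-stopping function of a geodesic
active contour with a region statistic whose *sign* tells the contour which
way to move: positive inside the object (expand), negative outside
(shrink), with magnitude normalized into [-1, 1].

Two SPFs are combined here:

* a *global* SPF driven by the mean intensities inside/outside the contour
  (robust far from the object, blind to intensity inhomogeneity), and
* a *local* SPF driven by kernel-weighted local fitting functions
  (accurate under inhomogeneity, short-sighted far from edges).

A per-pixel adaptive weight ``omega`` in [0, 1], computed once from a 5x5
local contrast ratio of the input image, balances the two: smooth regions
get mostly the global force, high-contrast (near-boundary) regions get
mostly the local force.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .core import SmoothingKernel, gaussian_convolve, heaviside_eps

__all__ = [
    "GlobalMeans",
    "LocalFits",
    "global_region_means",
    "local_fitting_functions",
    "spf_global",
    "spf_local",
    "local_contrast",
    "adaptive_weight",
    "combined_spf",
]

logger = logging.getLogger(__name__)

#: floor applied to every normalization denominator
DENOM_FLOOR = 1e-12


class GlobalMeans(NamedTuple):
    """Mean intensity inside (``c1``) and outside (``c2``) the contour."""

    c1: float
    c2: float


class LocalFits(NamedTuple):
    """Local interior (``f1``) and exterior (``f2``) intensity fits."""

    f1: np.ndarray
    f2: np.ndarray


def _check_same_shape(*fields: np.ndarray) -> None:
    shapes = {np.asarray(f).shape for f in fields}
    if len(shapes) != 1:
        raise ValueError(f"field shapes disagree: {sorted(shapes)}")


def global_region_means(image: np.ndarray, phi: np.ndarray, eps_h: float) -> GlobalMeans:
    """Heaviside-weighted mean intensities on the two sides of ``phi``.

    ``c1`` averages over H_eps(phi), ``c2`` over 1 - H_eps(phi). A side
    whose total weight falls below the numerical floor degenerates to the
    global image mean (with a warning) rather than dividing by ~0.
    """
    image = np.asarray(image, dtype=float)
    phi = np.asarray(phi, dtype=float)
    _check_same_shape(image, phi)
    h = heaviside_eps(phi, eps_h)
    w1 = float(h.sum())
    w2 = float((1.0 - h).sum())
    fallback = float(image.mean())
    if w1 < DENOM_FLOOR:
        logger.warning("inside region degenerate (weight %.3g); using global mean", w1)
        c1 = fallback
    else:
        c1 = float((image * h).sum() / w1)
    if w2 < DENOM_FLOOR:
        logger.warning("outside region degenerate (weight %.3g); using global mean", w2)
        c2 = fallback
    else:
        c2 = float((image * (1.0 - h)).sum() / w2)
    return GlobalMeans(c1=c1, c2=c2)


def local_fitting_functions(
    image: np.ndarray,
    phi: np.ndarray,
    kernel: SmoothingKernel,
    eps_h: float,
) -> LocalFits:
    """Kernel-weighted local mean intensities on each side of the contour.

    f1 = K*(H(phi) I) / K*(H(phi)) and f2 with the complementary weight.
    Denominators are floored at ``DENOM_FLOOR``; with the arctan Heaviside
    the weights never vanish exactly, so the floor only guards pathological
    inputs.
    """
    image = np.asarray(image, dtype=float)
    phi = np.asarray(phi, dtype=float)
    _check_same_shape(image, phi)
    h = heaviside_eps(phi, eps_h)
    num1 = gaussian_convolve(h * image, kernel)
    den1 = gaussian_convolve(h, kernel)
    num2 = gaussian_convolve((1.0 - h) * image, kernel)
    den2 = gaussian_convolve(1.0 - h, kernel)
    floored = (den1 < DENOM_FLOOR).sum() + (den2 < DENOM_FLOOR).sum()
    if floored:
        logger.warning("floored %d local-fit denominators", int(floored))
    f1 = num1 / np.maximum(den1, DENOM_FLOOR)
    f2 = num2 / np.maximum(den2, DENOM_FLOOR)
    return LocalFits(f1=f1, f2=f2)


def _normalize_spf(deviation: np.ndarray) -> np.ndarray:
    """Scale a deviation field by its max absolute value into [-1, 1].

    A (numerically) zero deviation field — a constant image — yields an
    all-zero SPF: no region evidence, no force.
    """
    m = float(np.abs(deviation).max())
    if m < DENOM_FLOOR:
        return np.zeros_like(deviation)
    return deviation / m


def spf_global(image: np.ndarray, means: GlobalMeans) -> np.ndarray:
    """Global SPF: sign of I - (c1 + c2)/2, normalized to [-1, 1]."""
    image = np.asarray(image, dtype=float)
    return _normalize_spf(image - 0.5 * (means.c1 + means.c2))


def spf_local(image: np.ndarray, fits: LocalFits) -> np.ndarray:
    """Local SPF: sign of I - (f1 + f2)/2, normalized to [-1, 1]."""
    image = np.asarray(image, dtype=float)
    _check_same_shape(image, fits.f1, fits.f2)
    return _normalize_spf(image - 0.5 * (fits.f1 + fits.f2))


def local_contrast(image: np.ndarray, window: int = 5) -> np.ndarray:
    """Michelson-style local contrast ratio over an odd square window.

    C_R(x) = (max_R I - min_R I) / (max_R I + min_R I + eta) with
    eta = 1e-8, computed over the ``window``-sized neighborhood of each
    pixel with replicate padding. Zero on flat regions, large across
    intensity edges, invariant to positive rescaling of the image, and
    bounded in [0, 1) for non-negative intensities.
    """
    window = int(window)
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    image = np.asarray(image, dtype=float)
    eta = 1e-8
    mx = ndimage.maximum_filter(image, size=window, mode="nearest")
    mn = ndimage.minimum_filter(image, size=window, mode="nearest")
    return (mx - mn) / (mx + mn + eta)


def adaptive_weight(contrast: np.ndarray, beta: float) -> np.ndarray:
    """Adaptive global/local balance omega = exp(-beta * C_R / mean(C_R)).

    omega is 1 on perfectly flat images (mean contrast 0), close to 1 in
    smooth regions (global force dominates and sweeps the contour quickly),
    and decays toward 0 where contrast is far above average (near edges,
    where the local force must take over). Strictly decreasing in C_R.
    """
    if not beta > 0:
        raise ValueError(f"beta must be positive, got {beta!r}")
    contrast = np.asarray(contrast, dtype=float)
    m = float(contrast.mean())
    if m <= 0.0:
        return np.ones_like(contrast)
    return np.exp(-beta * contrast / m)


def combined_spf(
    global_spf: np.ndarray,
    local_spf: np.ndarray,
    omega: np.ndarray,
) -> np.ndarray:
    """Convex combination omega * global + (1 - omega) * local, in [-1, 1].

    The result is clipped to [-1, 1]: mathematically the convex combination
    of bounded fields is bounded, but floating-point rounding may overshoot
    by one ulp and the SPF contract is a hard bound.
    """
    global_spf = np.asarray(global_spf, dtype=float)
    local_spf = np.asarray(local_spf, dtype=float)
    omega = np.asarray(omega, dtype=float)
    _check_same_shape(global_spf, local_spf, omega)
    out = omega * global_spf + (1.0 - omega) * local_spf
    return np.clip(out, -1.0, 1.0)
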