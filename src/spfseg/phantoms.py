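"""Synthetic phantoms with known ground truth.

Generates piecewise-constant 2-D objects corrupted by a smooth
multiplicative bias field (emulating MR coil-sensitivity inhomogeneity) and
additive Gaussian noise:

    image = clip( intensities[truth] * (1 + bias) + noise, 0, 1 )

Multiplicative bias is used (rather than additive) because MR
inhomogeneity scales tissue intensity. For geometries where the object does
not span the whole field of view, the object is deliberately placed *off*
the bias-field apex: a bias concentric with the object merely rescales both
classes by the same factor at every radius and leaves them globally
separable, whereas a misaligned bias makes the dim side of the object
darker than the brightened background near the apex — the canonical regime
where purely global region statistics fail.

Every phantom call draws from one ``numpy.random.default_rng(seed)``;
identical specs produce bit-identical arrays. The solver itself is RNG-free.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

__all__ = ["PhantomSpec", "make_bias_field", "make_phantom", "save_phantom", "GEOMETRIES"]

GEOMETRIES = (
    "disk",
    "rectangle",
    "hand_like_polygon",
    "two_vessels",
    "four_quadrant",
    "brain_rings",
)

BIAS_KINDS = ("none", "linear_ramp", "gaussian_blob")

# Default region intensities per geometry (label 0 first). Two-region
# geometries use a low-contrast 0.4/0.6 pairing typical of adjacent soft
# tissues; brain_rings orders background < CSF < GM < WM as in T1-weighted MR.
DEFAULT_INTENSITIES = {
    "disk": (0.4, 0.6),
    "rectangle": (0.4, 0.6),
    "hand_like_polygon": (0.4, 0.6),
    "two_vessels": (0.4, 0.6),
    "four_quadrant": (0.1, 0.4, 0.7, 1.0),
    "brain_rings": (0.05, 0.35, 0.6, 0.85),
}


@dataclass(frozen=True)
class PhantomSpec:
    shape: Tuple[int, int] = (128, 128)
    geometry: str = "disk"
    region_intensities: Optional[Tuple[float, ...]] = None
    bias: str = "none"
    bias_strength: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}; choose from {GEOMETRIES}")
        if self.bias not in BIAS_KINDS:
            raise ValueError(f"unknown bias kind {self.bias!r}; choose from {BIAS_KINDS}")
        if not 0.0 <= self.bias_strength < 1.0:
            raise ValueError("bias_strength must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.region_intensities is not None:
            vals = tuple(float(v) for v in self.region_intensities)
            if len(set(vals)) != len(vals):
                raise ValueError("region intensities must be distinct")
            object.__setattr__(self, "region_intensities", vals)

    @property
    def intensities(self) -> Tuple[float, ...]:
        if self.region_intensities is not None:
            return self.region_intensities
        return DEFAULT_INTENSITIES[self.geometry]


def _grid(shape: Tuple[int, int]):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return rr.astype(float), cc.astype(float)


def _truth(shape: Tuple[int, int], geometry: str) -> np.ndarray:
    h, w = shape
    rr, cc = _grid(shape)
    labels = np.zeros(shape, dtype=np.int32)
    if geometry == "disk":
        # off the bias apex: center at 0.35*shape, radius 0.2*min(shape)
        r0, c0 = 0.35 * h, 0.35 * w
        radius = 0.2 * min(h, w)
        labels[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = 1
    elif geometry == "rectangle":
        labels[int(0.25 * h):int(0.75 * h), int(0.25 * w):int(0.75 * w)] = 1
    elif geometry == "hand_like_polygon":
        # palm block with four fingers and a thumb stub
        labels[int(0.55 * h):int(0.90 * h), int(0.25 * w):int(0.75 * w)] = 1
        fw = max(2, int(0.06 * w))
        for k in range(4):
            c_start = int((0.28 + 0.12 * k) * w)
            labels[int(0.15 * h):int(0.58 * h), c_start:c_start + fw] = 1
        labels[int(0.60 * h):int(0.72 * h), int(0.12 * w):int(0.28 * w)] = 1
    elif geometry == "two_vessels":
        half = max(2, int(round(0.04 * w)))
        for frac in (0.3, 0.7):
            c0 = int(round(frac * w))
            labels[:, c0 - half:c0 + half + 1] = 1
    elif geometry == "four_quadrant":
        labels[: h // 2, : w // 2] = 0
        labels[: h // 2, w // 2:] = 1
        labels[h // 2:, : w // 2] = 2
        labels[h // 2:, w // 2:] = 3
    elif geometry == "brain_rings":
        r0, c0 = (h - 1) / 2.0, (w - 1) / 2.0
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        m = min(h, w)
        for lab, frac in ((1, 0.45), (2, 0.35), (3, 0.22)):  # CSF, GM, WM
            labels[d2 <= (frac * m) ** 2] = lab
    return labels


def make_bias_field(shape: Tuple[int, int], kind: str, strength: float) -> np.ndarray:
    """Smooth bias field with values in [-strength, +strength].

    ``linear_ramp``: zero-mean left-to-right ramp with endpoints at
    -strength and +strength. ``gaussian_blob``: centered Gaussian bump
    linearly rescaled so the apex sits at +strength and the farthest corner
    at -strength (blob width 0.25 * min(shape) pixels).
    """
    if kind not in BIAS_KINDS:
        raise ValueError(f"unknown bias kind {kind!r}")
    if not 0.0 <= strength < 1.0:
        raise ValueError("strength must lie in [0, 1)")
    h, w = shape
    if kind == "none" or strength == 0.0:
        return np.zeros(shape, dtype=float)
    if kind == "linear_ramp":
        col = np.linspace(-strength, strength, w) if w > 1 else np.zeros(1)
        return np.broadcast_to(col, shape).astype(float).copy()
    rr, cc = _grid(shape)
    sig = 0.25 * min(h, w)
    g = np.exp(-(((rr - (h - 1) / 2) ** 2 + (cc - (w - 1) / 2) ** 2) / (2.0 * sig**2)))
    gmin, gmax = float(g.min()), float(g.max())
    return strength * (2.0 * (g - gmin) / (gmax - gmin) - 1.0)


def make_phantom(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Render a phantom; returns ``(image, truth)``.

    ``truth`` is the exact integer label field the image was generated
    from, so Dice-based evaluation carries zero annotation ambiguity. Note
    the final clip to [0, 1] slightly truncates the noise distribution near
    the intensity extremes.
    """
    truth = _truth(spec.shape, spec.geometry)
    intensities = spec.intensities
    n_regions = int(truth.max()) + 1
    if len(intensities) < n_regions:
        raise ValueError(
            f"{spec.geometry!r} needs {n_regions} region intensities, got {len(intensities)}"
        )
    image = np.asarray(intensities, dtype=float)[truth]
    bias = make_bias_field(spec.shape, spec.bias, spec.bias_strength)
    image = image * (1.0 + bias)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    return np.clip(image, 0.0, 1.0), truth


def save_phantom(spec: PhantomSpec, outdir) -> dict:
    """Write image (16-bit PNG), truth labels (8-bit PNG) and a JSON sidecar.

    Returns the paths written. Kept here (not in io) so a phantom directory
    is self-describing and byte-reproducible from its sidecar alone.
    """
    from . import io as _io  # deferred: phantoms stays importable without imageio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    image, truth = make_phantom(spec)
    paths = {
        "image": outdir / "image.png",
        "truth": outdir / "truth.png",
        "spec": outdir / "spec.json",
    }
    _io.save_image(paths["image"], image, bit_depth=16)
    _io.save_labels(paths["truth"], truth)
    with open(paths["spec"], "w") as fh:
        json.dump(dataclasses.asdict(spec), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
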