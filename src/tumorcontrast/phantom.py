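"""Two-compartment elliptical tumor phantom and contrast-agent effect models.

The phantom is a homogeneous elliptical tumor nested inside a homogeneous
elliptical region of normal adjacent tissue, rendered as co-registered
T1-weighted and T2-weighted signal maps.  Default baselines are 100 au in
T1w and 70 au in T2w for both compartments, so the pre-injection tumor
contrast is exactly 1 in every image variant.

Contrast agents act as multiplicative fractional signal changes per
compartment per weighting: an idealized targeted T1 agent raises tumor T1w
signal by 50% and leaves everything else untouched; a targeted T2 agent
halves tumor T2w signal; a dual T1/T2 agent does both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import ContainmentError, ScaleError, ShapeError, ValidationError
from .roi import RoiPair

logger = logging.getLogger(__name__)

WEIGHTINGS = ("t1w", "t2w", "difference", "sum")
SCALES = ("analog_au", "uint16", "uint8")


@dataclass(frozen=True)
class WeightedImage:
    """A 2-D grayscale signal map tagged with weighting and scale.

    ``scale`` distinguishes the analog arbitrary-unit representation used
    for all quantitative work from the integer working (uint16) and export
    (uint8) formats.  Negative values are only admitted for
    difference-weighted images in analog scale (signed subtraction);
    integer scales are always non-negative and range-checked.
    """

    pixels: np.ndarray
    weighting: str
    scale: str = "analog_au"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"image must be 2-D, got shape {px.shape}")
        if self.weighting not in WEIGHTINGS:
            raise ValidationError(f"unknown weighting {self.weighting!r}")
        if self.scale not in SCALES:
            raise ScaleError(f"unknown scale {self.scale!r}")
        if self.scale == "uint8":
            if px.min() < 0 or px.max() > 255:
                raise ScaleError("uint8 image has values outside [0, 255]")
            px = px.astype(np.uint8)
        elif self.scale == "uint16":
            if px.min() < 0 or px.max() > 65535:
                raise ScaleError("uint16 image has values outside [0, 65535]")
            px = px.astype(np.uint16)
        else:
            px = px.astype(float)
            if self.weighting != "difference" and px.min() < 0:
                raise ValidationError(
                    "negative analog signal only allowed in difference images"
                )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class Ellipse:
    """Axis specification of one ellipse: center, semi-axes, rotation (deg)."""

    cx: float
    cy: float
    a: float
    b: float
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValidationError("ellipse semi-axes must be positive")

    def mask(self, width: int, height: int) -> np.ndarray:
        """Rasterize with the pixel-center rule: inside iff
        (x'/a)^2 + (y'/b)^2 <= 1 in the ellipse's rotated frame,
        0-based pixel coordinates."""
        y, x = np.mgrid[0:height, 0:width]
        dx = x - self.cx
        dy = y - self.cy
        th = np.deg2rad(self.rotation)
        xr = dx * np.cos(th) + dy * np.sin(th)
        yr = -dx * np.sin(th) + dy * np.cos(th)
        return (xr / self.a) ** 2 + (yr / self.b) ** 2 <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, baseline signals and noise model of the digital phantom.

    Baselines default to equal tumor/tissue signal (100 au T1w, 70 au T2w)
    so pre-injection contrast is unity.  ``noise_sigma`` adds magnitude
    noise (Gaussian by default, Rician optionally); 0 renders the exact
    noiseless phantom.
    """

    grid_width: int = 256
    grid_height: int = 256
    tissue_ellipse: Ellipse = Ellipse(128, 128, 100, 60)
    tumor_ellipse: Ellipse = Ellipse(128, 128, 30, 20)
    s_t1w_tissue: float = 100.0
    s_t1w_tumor: float = 100.0
    s_t2w_tissue: float = 70.0
    s_t2w_tumor: float = 70.0
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"  # gaussian | rician
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_width <= 0 or self.grid_height <= 0:
            raise ValidationError("grid dimensions must be positive")
        for name in ("s_t1w_tissue", "s_t1w_tumor", "s_t2w_tissue", "s_t2w_tumor"):
            if getattr(self, name) < 0:
                raise ValidationError(f"baseline signal {name} must be >= 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")


@dataclass(frozen=True)
class AgentEffect:
    """Fractional multiplicative signal changes of a contrast agent.

    A fraction ``f`` scales the affected compartment's signal by ``1 + f``
    in the given weighting; +0.5 means a 50% increase, −0.5 a 50% drop.
    A "perfect" targeted agent has zero tissue fractions (it accumulates
    in the tumor only).
    """

    name: str
    f_t1w_tumor: float = 0.0
    f_t2w_tumor: float = 0.0
    f_t1w_tissue: float = 0.0
    f_t2w_tissue: float = 0.0

    def __post_init__(self) -> None:
        for fld in ("f_t1w_tumor", "f_t2w_tumor", "f_t1w_tissue", "f_t2w_tissue"):
            if 1.0 + getattr(self, fld) < 0:
                raise ValidationError(
                    f"{fld} = {getattr(self, fld)} gives a negative signal multiplier"
                )

    @property
    def is_targeted(self) -> bool:
        return self.f_t1w_tissue == 0.0 and self.f_t2w_tissue == 0.0

    def composed(self, other: "AgentEffect") -> "AgentEffect":
        """Sequential application of two agents: multipliers compose."""
        def comp(f, g):
            return (1 + f) * (1 + g) - 1
        return AgentEffect(
            name=f"{self.name}+{other.name}",
            f_t1w_tumor=comp(self.f_t1w_tumor, other.f_t1w_tumor),
            f_t2w_tumor=comp(self.f_t2w_tumor, other.f_t2w_tumor),
            f_t1w_tissue=comp(self.f_t1w_tissue, other.f_t1w_tissue),
            f_t2w_tissue=comp(self.f_t2w_tissue, other.f_t2w_tissue),
        )


def builtin_effects() -> list[AgentEffect]:
    """The three idealized targeted agents: T1-only, T2-only and dual.

    T1: +50% tumor signal on T1w.  T2: −50% tumor signal on T2w.
    Dual: both at once.  All tissue fractions are zero (perfect targeting).
    """
    return [
        AgentEffect("t1", f_t1w_tumor=+0.5),
        AgentEffect("t2", f_t2w_tumor=-0.5),
        AgentEffect("dual", f_t1w_tumor=+0.5, f_t2w_tumor=-0.5),
    ]


def _add_noise(signal: np.ndarray, sigma: float, model: str,
               rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return signal
    if model == "gaussian":
        return signal + rng.normal(0.0, sigma, size=signal.shape)
    # Rician magnitude noise: |signal + complex Gaussian|
    re = signal + rng.normal(0.0, sigma, size=signal.shape)
    im = rng.normal(0.0, sigma, size=signal.shape)
    return np.hypot(re, im)


def render_phantom(spec: PhantomSpec) -> tuple[WeightedImage, WeightedImage, RoiPair]:
    """Render the phantom as pre-injection T1w and T2w images plus ROI masks.

    Tumor pixels take the tumor baseline, tissue pixels (inside the tissue
    ellipse but outside the tumor) the tissue baseline, background is 0.
    The returned tissue mask is the annulus excluding tumor pixels, so the
    two ROIs are disjoint.
    """
    w, h = spec.grid_width, spec.grid_height
    tissue_region = spec.tissue_ellipse.mask(w, h)
    tumor = spec.tumor_ellipse.mask(w, h)
    if not tumor.any():
        raise ValidationError("tumor ellipse rasterizes to zero pixels")
    if (tumor & ~tissue_region).any():
        raise ContainmentError(
            "tumor ellipse is not fully contained in the tissue ellipse"
        )
    tissue = tissue_region & ~tumor
    if not tissue.any():
        raise ValidationError("tissue annulus rasterizes to zero pixels")

    rng = np.random.default_rng(spec.seed)
    images = []
    for s_tissue, s_tumor in ((spec.s_t1w_tissue, spec.s_t1w_tumor),
                              (spec.s_t2w_tissue, spec.s_t2w_tumor)):
        px = np.zeros((h, w), dtype=float)
        px[tissue] = s_tissue
        px[tumor] = s_tumor
        px = _add_noise(px, spec.noise_sigma, spec.noise_model, rng)
        if spec.noise_model == "gaussian":
            # magnitude images are non-negative; clip the rare negative tail
            px = np.clip(px, 0.0, None)
        images.append(px)
    logger.info("rendered phantom %dx%d: tumor %d px, tissue %d px",
                w, h, tumor.sum(), tissue.sum())
    return (
        WeightedImage(images[0], "t1w"),
        WeightedImage(images[1], "t2w"),
        RoiPair(tumor, tissue, provenance="phantom"),
    )


def apply_agent(
    t1w: WeightedImage,
    t2w: WeightedImage,
    rois: RoiPair,
    effect: AgentEffect,
) -> tuple[WeightedImage, WeightedImage]:
    """Apply a contrast agent's fractional changes, yielding post-injection images.

    Tumor pixels are scaled by ``1 + f_*_tumor`` and tissue pixels by
    ``1 + f_*_tissue`` in each weighting; background is unchanged.
    """
    if t1w.shape != t2w.shape or t1w.shape != rois.shape:
        raise ShapeError(
            f"grids differ: t1w {t1w.shape}, t2w {t2w.shape}, masks {rois.shape}"
        )
    out = []
    for img, f_tumor, f_tissue in (
        (t1w, effect.f_t1w_tumor, effect.f_t1w_tissue),
        (t2w, effect.f_t2w_tumor, effect.f_t2w_tissue),
    ):
        px = np.asarray(img.pixels, dtype=float).copy()
        px[rois.tumor_mask] *= 1.0 + f_tumor
        px[rois.tissue_mask] *= 1.0 + f_tissue
        out.append(replace(img, pixels=px, scale="analog_au"))
    return out[0], out[1]
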