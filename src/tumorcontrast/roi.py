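"""Region-of-interest statistics and the tumor-contrast ratio.

The central statistic is the tumor contrast

    TC = S_tu / S_ti

where ``S_tu`` is the mean signal over a tumor ROI and ``S_ti`` the mean
signal over an adjacent-tissue ROI.  TC is computed per image variant
(T1w, T2w, their difference and their sum) before and after contrast-agent
injection; all quantitative arithmetic happens on the analog (floating
point, arbitrary-unit) representation, never on 8-bit display exports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import ShapeError, UndefinedContrastError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - type-only imports
    from .imops import CombinePolicy
    from .phantom import WeightedImage

logger = logging.getLogger(__name__)

VARIANTS = ("t1w", "t2w", "difference", "sum")
PHASES = ("pre", "post")


@dataclass(frozen=True)
class RoiPair:
    """Tumor and adjacent-tissue masks on a common pixel grid.

    Masks are boolean arrays; they must be disjoint and non-empty.
    ``provenance`` records where the masks came from: rasterized from a
    phantom specification, loaded from mask files, or given as an explicit
    geometric spec.
    """

    tumor_mask: np.ndarray
    tissue_mask: np.ndarray
    provenance: str = "phantom"

    def __post_init__(self) -> None:
        tumor = np.asarray(self.tumor_mask, dtype=bool)
        tissue = np.asarray(self.tissue_mask, dtype=bool)
        object.__setattr__(self, "tumor_mask", tumor)
        object.__setattr__(self, "tissue_mask", tissue)
        if tumor.shape != tissue.shape:
            raise ShapeError(
                f"mask grids differ: tumor {tumor.shape} vs tissue {tissue.shape}"
            )
        if tumor.ndim != 2:
            raise ValidationError("masks must be 2-D")
        if not tumor.any():
            raise ValidationError("tumor mask is empty")
        if not tissue.any():
            raise ValidationError("tissue mask is empty")
        if (tumor & tissue).any():
            raise ValidationError("tumor and tissue masks overlap")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tumor_mask.shape

    def swapped(self) -> "RoiPair":
        """Masks with tumor and tissue roles exchanged."""
        return RoiPair(self.tissue_mask, self.tumor_mask, provenance=self.provenance)


@dataclass
class ContrastReport:
    """S_tu, S_ti and TC per image variant and injection phase.

    Wraps a tidy DataFrame with columns ``phase``, ``variant``, ``s_tu``,
    ``s_ti``, ``tc``; values are stored at full precision and rendered at
    two decimals only for display.
    """

    rows: list[dict] = field(default_factory=list)

    def add_row(self, phase: str, variant: str, s_tu: float, s_ti: float) -> None:
        tc = tumor_contrast(s_tu, s_ti)
        self.rows.append({"phase": phase, "variant": variant,
                          "s_tu": float(s_tu), "s_ti": float(s_ti), "tc": tc})

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["phase", "variant", "s_tu", "s_ti", "tc"])

    def tc(self, phase: str, variant: str) -> float:
        """Tumor contrast for one (phase, variant) row."""
        sel = self.frame[(self.frame.phase == phase) & (self.frame.variant == variant)]
        if sel.empty:
            raise KeyError(f"no report row for phase={phase!r} variant={variant!r}")
        return float(sel.tc.iloc[0])

    def signals(self, phase: str, variant: str) -> tuple[float, float]:
        sel = self.frame[(self.frame.phase == phase) & (self.frame.variant == variant)]
        if sel.empty:
            raise KeyError(f"no report row for phase={phase!r} variant={variant!r}")
        return float(sel.s_tu.iloc[0]), float(sel.s_ti.iloc[0])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.6f")

    def to_json(self, path) -> None:
        self.frame.to_json(path, orient="records", indent=2, double_precision=6)

    def __str__(self) -> str:  # 2-decimal display, full precision retained
        disp = self.frame.copy()
        for col in ("s_tu", "s_ti", "tc"):
            disp[col] = disp[col].map(lambda v: f"{v:.2f}")
        return disp.to_string(index=False)


def roi_means(img: "WeightedImage", rois: RoiPair) -> tuple[float, float]:
    """Mean signal over the tumor and tissue masks.

    Returns ``(s_tu, s_ti)`` as arithmetic means of the pixel values under
    each mask, computed in the image's native (analog) values.
    """
    pixels = np.asarray(img.pixels, dtype=float)
    if pixels.shape != rois.shape:
        raise ShapeError(
            f"image grid {pixels.shape} does not match mask grid {rois.shape}"
        )
    s_tu = float(pixels[rois.tumor_mask].mean())
    s_ti = float(pixels[rois.tissue_mask].mean())
    logger.info(
        "ROI means (%s): tumor n=%d mean=%.4f | tissue n=%d mean=%.4f",
        img.weighting, rois.tumor_mask.sum(), s_tu, rois.tissue_mask.sum(), s_ti,
    )
    return s_tu, s_ti


def tumor_contrast(s_tu: float, s_ti: float) -> float:
    """TC = S_tu / S_ti, the tumor-to-adjacent-tissue signal ratio."""
    if s_ti == 0:
        raise UndefinedContrastError(
            "tissue signal is zero; tumor contrast is undefined "
            "(degenerate subtraction of identical tissue signals?)"
        )
    return s_tu / s_ti


def full_report(
    t1w_pre: "WeightedImage",
    t2w_pre: "WeightedImage",
    t1w_post: "WeightedImage",
    t2w_post: "WeightedImage",
    rois: RoiPair,
    policy: "CombinePolicy | None" = None,
) -> ContrastReport:
    """S_tu, S_ti and TC for all four variants in both phases (8 rows).

    The difference and sum images are formed in analog space from the
    supplied weighted images under ``policy`` (signed subtraction by
    default), then reduced to ROI means.
    """
    from .imops import CombinePolicy, combine  # deferred: imops imports phantom

    if policy is None:
        policy = CombinePolicy()
    report = ContrastReport()
    for phase, (t1w, t2w) in (("pre", (t1w_pre, t2w_pre)),
                              ("post", (t1w_post, t2w_post))):
        diff = combine(t1w, t2w, policy.with_mode("subtract"))
        summ = combine(t1w, t2w, policy.with_mode("add"))
        for variant, img in (("t1w", t1w), ("t2w", t2w),
                             ("difference", diff), ("sum", summ)):
            s_tu, s_ti = roi_means(img, rois)
            report.add_row(phase, variant, s_tu, s_ti)
    return report
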