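"""Ground-truth root image analysis ("shovelomics").

After a trial, root crowns are excavated, washed, dried and photographed
against a high-contrast backdrop at a known pixel scale.  The amount of
root matter that could have interacted with the in-soil sensor is
approximated by counting root pixels ``S`` inside a rectangular region of
interest whose vertical extent maps to the electrode depth span
(1.9-16.1 cm below the crown) and whose horizontal extent maps to the
device diameter.  Per-genotype medians of ``S`` are then correlated with
per-genotype medians of the devices' time-averaged daily detection rate
``R`` (ordinary least squares; the reported statistic is R squared).

A synthetic root-image generator draws root-like strokes from the crown
anchor with a configurable depth distribution and reports the exact
painted-pixel count inside the ROI, giving a closed-loop oracle for the
segmentation and counting chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from skimage.draw import line as draw_line

from .device import DeviceGeometry

__all__ = [
    "RootImage",
    "ElectrodeROI",
    "segment_root_pixels",
    "electrode_roi",
    "count_root_pixels",
    "genotype_median_correlation",
    "generate_root_image",
    "otsu_threshold",
]


@dataclass
class RootImage:
    """Grayscale root-crown photograph with scale and crown anchor.

    ``crown_anchor`` is the (row, col) pixel of the root-crown reference
    point (soil line at the stem); electrode depths are measured downward
    from it.
    """

    pixels: np.ndarray  # 2-D grayscale
    pixel_scale_cm: float  # cm per pixel
    crown_anchor: tuple[int, int]
    device_id: str | None = None
    genotype: str | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("RootImage requires a 2-D grayscale array")
        if self.pixel_scale_cm <= 0:
            raise ValueError("pixel_scale_cm must be positive")
        r, c = self.crown_anchor
        h, w = self.pixels.shape
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("crown_anchor outside image bounds")


@dataclass(frozen=True)
class ElectrodeROI:
    """Pixel rectangle covering the electrode region (half-open bounds)."""

    row_top: int
    row_bottom: int
    col_left: int
    col_right: int

    @property
    def height_px(self) -> int:
        return self.row_bottom - self.row_top

    @property
    def width_px(self) -> int:
        return self.col_right - self.col_left

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_top, self.row_bottom), slice(
            self.col_left, self.col_right
        )


def segment_root_pixels(
    image: RootImage | np.ndarray,
    threshold: float,
    root_brighter: bool = True,
) -> np.ndarray:
    """Binary root mask by global intensity threshold.

    Roots photographed against a dark backdrop are brighter than
    background (the default polarity); set ``root_brighter=False`` for the
    opposite convention.  Raising the threshold never grows the mask
    (under the default polarity).
    """
    px = image.pixels if isinstance(image, RootImage) else np.asarray(image)
    if px.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if root_brighter:
        mask = px >= threshold
    else:
        mask = px <= threshold
    if mask.all() or not mask.any():
        warnings.warn(
            "threshold produced an all-or-nothing mask; check polarity "
            "and threshold value",
            stacklevel=2,
        )
    return mask


def otsu_threshold(image: RootImage | np.ndarray) -> float:
    """Optional automatic threshold helper (off by default in pipelines)."""
    from skimage.filters import threshold_otsu

    px = image.pixels if isinstance(image, RootImage) else np.asarray(image)
    return float(threshold_otsu(px))


def electrode_roi(
    image: RootImage, geometry: DeviceGeometry = DeviceGeometry()
) -> ElectrodeROI:
    """Pixel rectangle of the region electrodes could interact with.

    Vertical extent: the electrode depth span (``depth_shallow_cm`` to
    ``depth_deep_cm`` below the crown anchor); horizontal extent: the
    device diameter, centred on the anchor column.  All physical lengths
    are converted with the image's pixel scale; a rectangle extending past
    the image bounds is clipped with a warning.
    """
    ps = image.pixel_scale_cm
    r0, c0 = image.crown_anchor
    top = r0 + int(round(geometry.depth_shallow_cm / ps))
    height = int(round((geometry.depth_deep_cm - geometry.depth_shallow_cm) / ps))
    width = int(round(geometry.diameter_cm / ps))
    left = c0 - width // 2
    bottom, right = top + height, left + width
    h, w = image.pixels.shape
    if top < 0 or left < 0 or bottom > h or right > w:
        warnings.warn("electrode ROI clipped to image bounds", stacklevel=2)
    return ElectrodeROI(
        row_top=max(0, top),
        row_bottom=min(h, bottom),
        col_left=max(0, left),
        col_right=min(w, right),
    )


def count_root_pixels(
    image: RootImage,
    threshold: float,
    geometry: DeviceGeometry = DeviceGeometry(),
    root_brighter: bool = True,
) -> int:
    """Root-pixel count ``S`` inside the electrode ROI."""
    mask = segment_root_pixels(image, threshold, root_brighter)
    rs, cs = electrode_roi(image, geometry).slices()
    return int(mask[rs, cs].sum())


def genotype_median_correlation(
    rates: pd.DataFrame,
    pixel_counts: pd.DataFrame,
    rate_col: str = "R",
    count_col: str = "S",
) -> dict[str, object]:
    """R squared between genotype medians of detection rate and root pixels.

    Both inputs need ``device_id`` and ``genotype`` columns.  Per-genotype
    medians of each measure are computed over its devices, then the
    coefficient of determination of an ordinary least-squares fit of the
    median pixel count on the median rate is returned (identical to the
    squared Pearson correlation for simple OLS).
    """
    r_med = rates.groupby("genotype")[rate_col].median()
    s_med = pixel_counts.groupby("genotype")[count_col].median()
    joined = pd.concat(
        [r_med.rename("R_med"), s_med.rename("S_med")], axis=1
    ).dropna()
    if len(joined) < 3:
        raise ValueError(
            f"need at least 3 genotypes with both measures; got {len(joined)}"
        )
    if joined["R_med"].nunique() == 1 or joined["S_med"].nunique() == 1:
        return {
            "r_squared": np.nan,
            "slope": np.nan,
            "intercept": np.nan,
            "n_genotypes": len(joined),
            "valid": False,
            "reason": "zero variance in a median vector",
            "medians": joined,
        }
    fit = scipy.stats.linregress(joined["R_med"], joined["S_med"])
    return {
        "r_squared": float(fit.rvalue**2),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "n_genotypes": len(joined),
        "valid": True,
        "reason": "",
        "medians": joined,
    }


def generate_root_image(
    n_roots: int,
    pixel_scale_cm: float = 0.05,
    seed: int | np.random.Generator = 0,
    image_shape: tuple[int, int] = (480, 640),
    depth_profile: np.ndarray | None = None,
    geometry: DeviceGeometry = DeviceGeometry(),
    background: int = 20,
    root_intensity: int = 230,
    noise_sd: float = 0.0,
) -> tuple[RootImage, int]:
    """Synthetic root-crown photograph with exact ROI pixel truth.

    Draws ``n_roots`` root-like polyline strokes fanning downward from
    the crown anchor (bright roots on a dark backdrop).  Each stroke's
    target depth is drawn from ``depth_profile`` over the electrode depth
    indices (default uniform), so deeper-rooting phenotypes can be
    emulated.  Returns the image and the exact count of root pixels
    falling inside the electrode ROI — the oracle for the segmentation
    chain.  Gaussian pixel noise (``noise_sd`` in intensity units) can be
    added to exercise robustness; the truth count refers to the noise-free
    painted mask.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    h, w = image_shape
    anchor = (h // 8, w // 2)
    painted = np.zeros(image_shape, dtype=bool)
    epp = geometry.electrodes_per_paddle
    profile = (
        np.full(epp, 1.0 / epp) if depth_profile is None else np.asarray(depth_profile)
    )
    depth_span = geometry.depth_deep_cm - geometry.depth_shallow_cm
    for _ in range(n_roots):
        d_idx = rng.choice(epp, p=profile)
        depth_cm = geometry.depth_shallow_cm + (d_idx + rng.random()) * (
            depth_span / epp
        )
        # a root is a few connected segments wandering down to its depth
        r, c = anchor
        target_r = anchor[0] + depth_cm / pixel_scale_cm
        drift = rng.normal(0.0, 0.35)
        n_seg = rng.integers(2, 5)
        for s in range(n_seg):
            r_next = r + (target_r - r) / (n_seg - s)
            c_next = c + drift * (r_next - r) + rng.normal(0, 2.0)
            rr, cc = draw_line(
                int(round(r)), int(round(c)), int(round(r_next)), int(round(c_next))
            )
            ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            painted[rr[ok], cc[ok]] = True
            r, c = r_next, c_next

    pixels = np.full(image_shape, background, dtype=float)
    pixels[painted] = root_intensity
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, image_shape)
    pixels = np.clip(pixels, 0, 255)
    image = RootImage(
        pixels=pixels, pixel_scale_cm=pixel_scale_cm, crown_anchor=anchor
    )
    rs, cs = electrode_roi(image, geometry).slices()
    s_true = int(painted[rs, cs].sum())
    return image, s_true
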