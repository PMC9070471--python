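"""Stain quantification for VVG- and Picrosirius-Red-stained sections.

Percentage-area measurement of collagen and elastin from 8-bit RGB
micrographs.  The tissue footprint is segmented from the blue channel
(highest tissue/background contrast; the modal blue value is the bright
blank slide).  Collagen is scored per pixel by the weighted index

    collagen index = R/50 - G/20 + B/30

applied to raw 0-255 channel values, which places pink-through-magenta-to-
dark-red collagen hues above the nominal threshold of 1.0 while unstained
tissue scores roughly -0.75 to 1.0.  Elastin (grey-to-black under VVG) is
scored by equally weighted darkness, 1 - (R+G+B)/765, thresholded at 0.5.
All areas are pixel-count ratios against the tissue mask, so no spatial
calibration is needed.  The collagen threshold can be calibrated against
the adjacent Picrosirius-Red section, and threshold-variation errors
quantify how sensitive each area estimate is to the cut-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.morphology import remove_small_holes, remove_small_objects


@dataclass
class StainQuantification:
    """Percentage-area result with threshold-sensitivity error bars."""

    fraction: float
    err_low: float
    err_high: float
    threshold_used: float
    kind: str

    def __post_init__(self) -> None:
        if self.fraction - self.err_low < -1e-12:
            raise ValueError("err_low cannot push the fraction below 0")
        if self.fraction + self.err_high > 1 + 1e-12:
            raise ValueError("err_high cannot push the fraction above 1")


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    return image


def tissue_mask(
    image: np.ndarray,
    min_fragment_px: int = 64,
    max_hole_px: int = 256,
) -> np.ndarray:
    """Segment tissue from blank slide using the blue channel.

    Pixels whose blue value is below the modal blue value (the bright blank
    slide) are tissue.  Connected components (8-connectivity) smaller than
    ``min_fragment_px`` are removed and holes smaller than ``max_hole_px``
    filled.  A single-colour image has no tissue: empty mask plus a warning.
    """
    image = _as_rgb(image)
    blue = image[..., 2]
    counts = np.bincount(blue.ravel(), minlength=256)
    # ties between modes -> the brightest, since background is bright slide
    mode = int(np.flatnonzero(counts == counts.max()).max())
    mask = blue < mode
    if not mask.any():
        warnings.warn("no pixels below the modal blue value; empty tissue mask", stacklevel=2)
        return mask
    # "smaller than N" semantics: skimage's max_size removes <= its value
    mask = remove_small_objects(mask, max_size=min_fragment_px - 1, connectivity=2)
    mask = remove_small_holes(mask, max_size=max_hole_px - 1, connectivity=2)
    return mask


def collagen_index_map(image: np.ndarray) -> np.ndarray:
    """Per-pixel collagen index R/50 - G/20 + B/30 on raw 8-bit values."""
    image = _as_rgb(image).astype(float)
    return image[..., 0] / 50.0 - image[..., 1] / 20.0 + image[..., 2] / 30.0


def elastin_index_map(image: np.ndarray) -> np.ndarray:
    """Per-pixel elastin index: equally weighted darkness 1 - (R+G+B)/765.

    Black scores 1, white 0; the nominal elastin/non-elastin boundary is 0.5.
    """
    image = _as_rgb(image).astype(float)
    return 1.0 - image.sum(axis=2) / 765.0


def _fraction_above(index_map: np.ndarray, mask: np.ndarray, threshold: float) -> float:
    n_tissue = int(mask.sum())
    if n_tissue == 0:
        raise ValueError("tissue mask is empty")
    return float(np.count_nonzero((index_map > threshold) & mask)) / n_tissue


def quantify_stain(
    index_map: np.ndarray,
    mask: np.ndarray,
    threshold: float,
    kind: str = "collagen",
    delta: float | None = None,
) -> StainQuantification:
    """Percentage area = pixels strictly above threshold / pixels in mask.

    If ``delta`` is given, threshold-variation error bars are attached
    (see :func:`threshold_sensitivity_error`).
    """
    index_map = np.asarray(index_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if index_map.shape != mask.shape:
        raise ValueError("index map and mask shapes differ")
    frac = _fraction_above(index_map, mask, threshold)
    if delta is not None:
        err_low, err_high = threshold_sensitivity_error(index_map, mask, threshold, delta)
    else:
        err_low = err_high = 0.0
    return StainQuantification(frac, err_low, err_high, threshold, kind)


def psr_collagen_fraction(
    psr_image: np.ndarray,
    mask: np.ndarray,
    margin: int = 30,
) -> float:
    """Collagen area fraction of a Picrosirius-Red section.

    A masked pixel is collagen when red dominates both other channels by at
    least ``margin`` grey levels (R > G + margin and R > B + margin) —
    PSR collagen is a saturated red against a pale counterstain.
    """
    psr_image = _as_rgb(psr_image).astype(int)
    mask = np.asarray(mask, dtype=bool)
    n_tissue = int(mask.sum())
    if n_tissue == 0:
        raise ValueError("tissue mask is empty")
    r, g, b = psr_image[..., 0], psr_image[..., 1], psr_image[..., 2]
    red = (r > g + margin) & (r > b + margin)
    return float(np.count_nonzero(red & mask)) / n_tissue


def calibrate_collagen_threshold(
    vvg_image: np.ndarray,
    mask: np.ndarray,
    target_fraction: float,
    nominal: float = 1.0,
    span: float = 0.75,
    step: float = 0.01,
) -> float:
    """Calibrate the collagen threshold against a target (PSR) area fraction.

    Searches ``nominal +/- span`` in steps of ``step`` for the threshold
    whose VVG collagen fraction is closest to ``target_fraction``; ties are
    broken towards the nominal value (then towards the smaller threshold).
    A flat index map cannot be calibrated: the nominal threshold is returned
    with a warning.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    index_map = collagen_index_map(vvg_image)
    mask = np.asarray(mask, dtype=bool)
    vals = index_map[mask]
    if vals.size == 0:
        raise ValueError("tissue mask is empty")
    if np.ptp(vals) == 0:
        warnings.warn("flat collagen index map; calibration impossible, nominal kept", stacklevel=2)
        return float(nominal)
    grid = nominal + np.arange(-span, span + step / 2, step)
    n_tissue = vals.size
    sorted_vals = np.sort(vals)
    # fraction strictly above t = count of values > t
    fracs = 1.0 - np.searchsorted(sorted_vals, grid, side="right") / n_tissue
    errs = np.abs(fracs - target_fraction)
    best = errs.min()
    candidates = np.flatnonzero(errs <= best + 1e-12)
    dist = np.abs(grid[candidates] - nominal)
    closest = candidates[dist <= dist.min() + 1e-12]
    return float(grid[closest.min()])


def threshold_sensitivity_error(
    index_map: np.ndarray,
    mask: np.ndarray,
    threshold: float,
    delta: float,
) -> tuple[float, float]:
    """Error bars from varying the threshold either side of its optimum.

    ``err_high`` is the extra area admitted by lowering the threshold by
    ``delta``; ``err_low`` is the area lost by raising it by ``delta``.
    Both are non-negative because the area fraction is non-increasing in the
    threshold.  An index map bimodal about the threshold gives (0, 0);
    sensitive regions give large errors.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    index_map = np.asarray(index_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    at = _fraction_above(index_map, mask, threshold)
    err_high = _fraction_above(index_map, mask, threshold - delta) - at
    err_low = at - _fraction_above(index_map, mask, threshold + delta)
    return err_low, err_high


def quantify_section_pair(
    vvg_image: np.ndarray,
    psr_image: np.ndarray | None = None,
    collagen_threshold: float = 1.0,
    elastin_threshold: float = 0.5,
    delta: float = 0.05,
    calibrate: bool = True,
    min_fragment_px: int = 64,
    max_hole_px: int = 256,
) -> dict:
    """Full per-section report: mask, calibration, fractions and errors.

    When a PSR section is supplied and ``calibrate`` is true, the collagen
    threshold is calibrated so the VVG collagen area matches the PSR area.
    """
    mask = tissue_mask(vvg_image, min_fragment_px, max_hole_px)
    col_map = collagen_index_map(vvg_image)
    el_map = elastin_index_map(vvg_image)
    report: dict = {"tissue_px": int(mask.sum())}
    threshold = collagen_threshold
    if psr_image is not None:
        psr_frac = psr_collagen_fraction(psr_image, tissue_mask(psr_image, min_fragment_px, max_hole_px))
        report["psr_collagen_fraction"] = psr_frac
        if calibrate and 0.0 < psr_frac < 1.0:
            threshold = calibrate_collagen_threshold(vvg_image, mask, psr_frac, nominal=collagen_threshold)
    col = quantify_stain(col_map, mask, threshold, "collagen", delta)
    el = quantify_stain(el_map, mask, elastin_threshold, "elastin", delta)
    report["collagen"] = col.__dict__
    report["elastin"] = el.__dict__
    return report
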