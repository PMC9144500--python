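"""Quantification of fluorescein penetration in skin-section micrographs.

The read-outs per image are:

* **ART** (amount after RGB threshold) — the mean grey value per pixel
  (MGV/px) of the green channel inside the dye mask, averaged over the
  whole tissue region; a semi-quantitative surrogate for the amount of
  penetrated compound.  Zeros inside the tissue count in the
  denominator, so ART scales with both stained area and intensity.
* **Penetration depth** — the deepest dye-mask pixel below the detected
  skin surface, in µm, after despeckling.
* **SCT** — stratum corneum thickness: the bright contiguous band at
  the surface, median across columns, in µm.

The dye mask is a green-dominance rule (``G >= g_min`` and
``G - max(R, B) >= margin``): skin autofluorescence is broadband and
never strongly green-dominant, while the fluorescein emission is, so
thresholding on green dominance subtracts the autofluorescence.
Samples whose transepidermal water loss (TEWL) exceeds 15 g/cm²/h are
excluded as barrier-damaged.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import median_filter
from skimage.measure import label

from .particles import to_gray8
from .types import Micrograph

__all__ = [
    "rgb_threshold",
    "detect_surface",
    "tissue_roi",
    "compute_art",
    "compute_depth",
    "measure_sct",
    "relative_sct",
    "qc_tewl",
    "TEWL_LIMIT",
]

#: Barrier-integrity exclusion limit (g/cm²/h); strictly greater excludes.
TEWL_LIMIT = 15.0

#: Default green-dominance mask parameters (grey units).
DEFAULT_G_MIN = 50
DEFAULT_MARGIN = 20


def rgb_threshold(
    img: Micrograph, g_min: int = DEFAULT_G_MIN, margin: int = DEFAULT_MARGIN
) -> np.ndarray:
    """Dye mask: pixels with ``G >= g_min`` and ``G - max(R, B) >= margin``.

    Implements autofluorescence subtraction as a green-dominance rule;
    requires all three channels, so grey input is rejected.
    """
    if not img.is_rgb:
        raise ValueError("rgb_threshold needs an RGB image; got a grey micrograph")
    px = img.pixels.astype(np.int16)
    g = px[:, :, 1]
    rb = np.maximum(px[:, :, 0], px[:, :, 2])
    return (g >= g_min) & (g - rb >= margin)


def detect_surface(
    img: Micrograph,
    k: float = 5.0,
    smooth_window: int = 15,
    background_rows: int = 30,
) -> np.ndarray:
    """Per-column skin surface row (topmost tissue pixel), smoothed.

    The background level and noise are estimated from the top
    ``background_rows`` rows (above any tissue); per column the surface
    is the topmost row whose grey value exceeds
    ``background + k * noise``; the resulting line is median-smoothed
    across columns.  Raises if no tissue is found.
    """
    grey = to_gray8(img).pixels.astype(np.float64)
    h, w = grey.shape
    top = grey[: min(background_rows, h // 4), :]
    background = float(np.median(top))
    noise = float(np.std(top))
    thresh = background + k * max(noise, 1.0)

    above = grey >= thresh
    if not above.any():
        raise ValueError("no tissue detected: no pixel exceeds the background level")
    has_tissue = above.any(axis=0)
    first = np.argmax(above, axis=0).astype(np.float64)
    if not has_tissue.all():
        if not has_tissue.any():
            raise ValueError("no tissue detected in any column")
        # Columns without signal borrow the nearest detected column.
        cols = np.arange(w)
        first[~has_tissue] = np.interp(
            cols[~has_tissue], cols[has_tissue], first[has_tissue]
        )
    surface = median_filter(first, size=smooth_window, mode="nearest")
    return np.clip(np.rint(surface), 0, h - 1).astype(np.intp)


def tissue_roi(shape: tuple[int, int], surface: np.ndarray) -> np.ndarray:
    """Boolean ROI of all pixels at or below the surface line."""
    h, w = shape
    rows = np.arange(h)[:, None]
    return rows >= surface[None, :]


def compute_art(img: Micrograph, mask: np.ndarray, roi: np.ndarray) -> float:
    """ART in MGV/px: masked green summed over the ROI, per ROI pixel.

    ``mask`` is the dye mask from :func:`rgb_threshold`; ``roi`` the
    tissue region.  The denominator is the full ROI size so that images
    with more stained area score higher even at equal intensity.
    """
    if mask.shape != img.shape or roi.shape != img.shape:
        raise ValueError("mask and roi must match the image shape")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty tissue ROI: cannot normalise ART")
    green = img.pixels[:, :, 1] if img.is_rgb else img.pixels
    total = float(green[mask & roi].sum())
    return total / n_roi


def compute_depth(
    mask: np.ndarray,
    surface: np.ndarray,
    scale: float,
    min_blob: int = 3,
    mode: str = "max",
    percentile: float = 99.0,
) -> float:
    """Penetration depth (µm) of the dye mask below the surface line.

    Components smaller than ``min_blob`` pixels are removed (despeckle),
    then depth is the maximum over remaining mask pixels of
    ``(row − surface_row(column)) / scale``.  ``mode="percentile"``
    instead takes the given percentile of per-pixel depths, a more
    speck-robust alternative.  An empty (despeckled) mask has depth 0.
    """
    if not scale > 0:
        raise ValueError(f"scale must be positive px/µm, got {scale}")
    if min_blob > 1:
        labelled = label(mask, connectivity=2)
        if labelled.max() > 0:
            sizes = np.bincount(labelled.ravel())
            keep = sizes >= min_blob
            keep[0] = False
            mask = keep[labelled]
        else:
            mask = np.zeros_like(mask)
    if not mask.any():
        return 0.0
    rows, cols = np.nonzero(mask)
    depths = (rows - surface[cols]) / scale
    depths = depths[depths >= 0]
    if depths.size == 0:
        return 0.0
    if mode == "max":
        return float(depths.max())
    if mode == "percentile":
        return float(np.percentile(depths, percentile))
    raise ValueError(f"unknown depth mode {mode!r}; use 'max' or 'percentile'")


def measure_sct(
    img: Micrograph, surface: np.ndarray, scale: float
) -> float:
    """Stratum corneum thickness (µm): median bright-band run length.

    Per column, the SC is the contiguous run of rows starting at the
    surface whose grey value stays above a threshold placed midway
    between the SC-band median brightness (sampled just below the
    surface) and the deeper-tissue median brightness (sampled in the
    lower part of the tissue).  The image-wide SCT is the median of the
    per-column run lengths divided by ``scale``.
    """
    if not scale > 0:
        raise ValueError(f"scale must be positive px/µm, got {scale}")
    grey = to_gray8(img).pixels.astype(np.float64)
    h, w = grey.shape
    cols = np.arange(w)
    depth_below = (np.arange(h)[:, None] - surface[None, :])

    sc_sample = grey[(depth_below >= 1) & (depth_below <= 8)]
    tissue_extent = h - 1 - surface  # rows available below the surface, per column
    lo = (0.70 * tissue_extent)[None, :]
    hi = (0.90 * tissue_extent)[None, :]
    deep_sample = grey[(depth_below >= lo) & (depth_below <= hi)]
    if sc_sample.size == 0 or deep_sample.size == 0:
        raise ValueError("cannot sample the SC band / deep tissue: surface too low")
    sc_level = float(np.median(sc_sample))
    deep_level = float(np.median(deep_sample))
    if sc_level - deep_level < 10:
        raise ValueError(
            "no distinguishable stratum corneum band: surface brightness "
            f"({sc_level:.0f}) barely exceeds deep tissue ({deep_level:.0f})"
        )
    thresh = 0.5 * (sc_level + deep_level)

    bright = grey >= thresh
    below = depth_below >= 0
    # Run length: first depth at which the band is broken, per column.
    broken = below & ~bright
    any_break = broken.any(axis=0)
    first_break = np.argmax(broken, axis=0)
    run = np.where(any_break, first_break - surface, h - surface)
    run = np.clip(run, 0, None).astype(np.float64)
    sct_px = float(np.median(run[cols >= 0]))
    if sct_px <= 0:
        raise ValueError("stratum corneum band has zero thickness at the median column")
    return sct_px / scale


def relative_sct(treated: list[float], control: list[float]) -> float:
    """Relative SCT in % of control: ``100 · mean(treated)/mean(control)``."""
    if len(treated) == 0 or len(control) == 0:
        raise ValueError("relative_sct needs non-empty treated and control samples")
    control_mean = float(np.mean(control))
    if control_mean <= 0:
        raise ValueError("control mean SCT must be positive")
    return 100.0 * float(np.mean(treated)) / control_mean


def qc_tewl(tewl: float) -> str:
    """Barrier-integrity QC: ``"exclude"`` iff TEWL > 15 g/cm²/h."""
    if tewl < 0:
        raise ValueError(f"TEWL cannot be negative, got {tewl}")
    return "exclude" if tewl > TEWL_LIMIT else "include"
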