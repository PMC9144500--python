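"""Shared containers for micrographs and measurement records.

All stages of the pipeline exchange :class:`Micrograph` objects: 8-bit
images tagged with their pixel scale (px/µm) and acquisition modality.
Downstream records (per-particle, per-image penetration, per-group
statistics) are plain dataclasses or pandas frames; nothing here owns
any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Micrograph",
    "ParticleRecord",
    "ParticleSizingResult",
    "PenetrationResult",
    "SctResult",
]


@dataclass
class Micrograph:
    """An 8-bit micrograph plus the metadata every stage needs.

    Parameters
    ----------
    pixels
        ``uint8`` array, shape ``(H, W, 3)`` for RGB or ``(H, W)`` for grey.
    scale
        Pixel scale in px/µm (e.g. 2.84 for skin sections, 3.3 for
        particle dispersions at 200x magnification).
    modality
        Free-text acquisition tag, e.g. ``"epifluorescence"`` or
        ``"polarized"``.
    """

    pixels: np.ndarray
    scale: float
    modality: str = "epifluorescence"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise ValueError(
                f"Micrograph pixels must be 8-bit (uint8), got {self.pixels.dtype}"
            )
        if self.pixels.ndim not in (2, 3) or (
            self.pixels.ndim == 3 and self.pixels.shape[2] != 3
        ):
            raise ValueError(
                f"Micrograph must be (H, W) grey or (H, W, 3) RGB, got shape {self.pixels.shape}"
            )
        if not self.scale > 0:
            raise ValueError(f"scale must be positive px/µm, got {self.scale}")

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class ParticleRecord:
    """One connected component of a thresholded dispersion image."""

    label: int
    area: float  # µm²
    feret: float  # µm, maximum caliper
    centroid: tuple[float, float]  # (row, col) in px


@dataclass
class ParticleSizingResult:
    """Post-filter particle population summary.

    ``mean_feret``/``sd_feret`` are ``None`` when no particle survives the
    minimum-size filter.
    """

    records: list[ParticleRecord] = field(default_factory=list)
    mean_feret: float | None = None
    sd_feret: float | None = None
    n: int = 0
    excluded_n: int = 0


@dataclass(frozen=True)
class PenetrationResult:
    """Per-image penetration read-out: ART (MGV/px) and depth (µm)."""

    art: float
    depth: float
    group: str = ""


@dataclass(frozen=True)
class SctResult:
    """Stratum corneum thickness, absolute and relative to control."""

    sct: float  # µm
    rel_sct: float  # % of untreated control
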