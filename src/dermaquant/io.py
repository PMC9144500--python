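"""Reading and writing micrographs, ground truth, and report tables.

Images travel as 8-bit RGB TIFF (PNG accepted for reading and used for
the audit overlays); tables are plain CSV so every run is diffable.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .types import Micrograph

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import ReportBundle, RunConfig
    from .synthetic import StudyRecord, StudySet

__all__ = [
    "read_micrograph",
    "write_micrograph",
    "save_study",
    "write_report",
    "overlay",
    "particle_table",
]


def particle_table(records) -> pd.DataFrame:
    """Per-particle table: label, area_um2, feret_um, x, y (px)."""
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "area_um2": r.area,
                "feret_um": r.feret,
                "x": r.centroid[1],
                "y": r.centroid[0],
            }
            for r in records
        ]
    )


def read_micrograph(path: str | Path, scale: float, modality: str = "epifluorescence") -> Micrograph:
    """Read a TIFF/PNG micrograph; must already be 8-bit."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        pixels = tifffile.imread(path)
    else:
        pixels = iio.imread(path)
    pixels = np.asarray(pixels)
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[:, :, :3]
    return Micrograph(pixels, scale=scale, modality=modality)


def write_micrograph(img: Micrograph, path: str | Path) -> None:
    """Write a micrograph as 8-bit TIFF or PNG, by extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, img.pixels)
    else:
        iio.imwrite(path, img.pixels)


def save_study(study: "StudySet", outdir: str | Path) -> pd.DataFrame:
    """Write a study's images as TIFF plus a ground-truth CSV.

    The CSV holds one row per image: file, group, depth_true_um,
    amount_true, sct_true_um, surface_row, tewl.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(study.records):
        fname = f"{i:04d}_{rec.group}.tif"
        write_micrograph(rec.image, outdir / fname)
        rows.append(
            {
                "file": fname,
                "group": rec.group,
                "depth_true_um": rec.truth.depth_true,
                "amount_true": rec.truth.amount_true,
                "sct_true_um": rec.truth.sct_true,
                "surface_row": rec.truth.surface_row,
                "tewl": rec.tewl,
            }
        )
    truth = pd.DataFrame(rows)
    truth.to_csv(outdir / "ground_truth.csv", index=False)
    return truth


def overlay(img: Micrograph, surface: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Audit overlay: surface line in cyan, dye mask tinted magenta."""
    out = (
        np.stack([img.pixels] * 3, axis=-1)
        if not img.is_rgb
        else img.pixels.copy()
    )
    out = out.astype(np.uint8)
    out[mask, 0] = np.minimum(255, out[mask, 0].astype(int) + 120).astype(np.uint8)
    cols = np.arange(out.shape[1])
    for dr in (-1, 0, 1):
        rows = np.clip(surface + dr, 0, out.shape[0] - 1)
        out[rows, cols] = (0, 255, 255)
    return out


def write_report(
    bundle: "ReportBundle",
    outdir: str | Path,
    write_overlays: bool = False,
    records: "list[StudyRecord] | None" = None,
    config: "RunConfig | None" = None,
) -> None:
    """Write every report table as CSV (and optional PNG overlays)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.per_image.to_csv(outdir / "per_image.csv", index=False)
    bundle.per_group.to_csv(outdir / "per_group.csv", index=False)
    bundle.fold_change.to_csv(outdir / "fold_changes.csv", index=False)
    bundle.region_calls.to_csv(outdir / "region_calls.csv", index=False)

    stats_rows, cluster_rows = [], []
    for measure, report in bundle.stats.items():
        for _, row in report.pairwise.iterrows():
            stats_rows.append(
                {
                    "measure": measure,
                    "route": report.route,
                    "omnibus_p": report.omnibus_p,
                    "pair": f"{row['group_a']} vs {row['group_b']}",
                    "p_adj": row["p"],
                    "star": row["star"],
                }
            )
        for k, cluster in enumerate(report.clusters):
            cluster_rows.append(
                {
                    "measure": measure,
                    "cluster": k + 1,
                    "members": "|".join(sorted(cluster)),
                }
            )
    pd.DataFrame(stats_rows).to_csv(outdir / "stats.csv", index=False)
    pd.DataFrame(cluster_rows).to_csv(outdir / "clusters.csv", index=False)

    if write_overlays and records is not None and config is not None:
        from .penetration import detect_surface, rgb_threshold

        ovdir = outdir / "overlays"
        ovdir.mkdir(exist_ok=True)
        for i, rec in enumerate(records):
            surface = detect_surface(rec.image)
            mask = rgb_threshold(rec.image, g_min=config.g_min, margin=config.margin)
            iio.imwrite(ovdir / f"{i:04d}_{rec.group}.png",
                        overlay(rec.image, surface, mask))
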