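"""End-to-end orchestration: study → QC → quantification → statistics.

``run_pipeline`` drives a whole study — synthetic (a design of preset
arms) or real (a CSV manifest of image files) — through TEWL QC, the
penetration read-outs (ART, depth, SCT), per-group summaries, the
statistics decision tree per measure, fold changes against a reference
arm, and skin-region calls.  Results come back as a
:class:`ReportBundle` of pandas frames and are optionally written as
CSV files plus audit overlays.

TEWL-excluded images are still quantified (their rows carry
``qc_status="exclude"``) but are omitted from group summaries and
statistics.  Arms with (near-)zero variance in a measure — e.g. the
untreated arm, whose depth is identically 0 — are quantified and
summarised but left out of the omnibus statistics, where normality
tests are undefined on constant samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .penetration import (
    compute_art,
    compute_depth,
    detect_surface,
    measure_sct,
    qc_tewl,
    rgb_threshold,
    tissue_roi,
)
from .stats import GroupSample, StatsReport, run_comparison
from .synthetic import StudyRecord, StudySet, make_study
from .types import Micrograph

logger = logging.getLogger("dermaquant")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "fold_changes", "region_call"]

MEASURES = ("art", "depth", "sct")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mode="synthetic"`` generates the study from ``design`` (entries
    ``(preset, n)`` or ``(label, preset, n)``) with the mandatory
    ``seed``; ``mode="real"`` reads ``manifest``, a CSV with columns
    ``file, group, tewl, scale_px_per_um``.
    """

    mode: str = "synthetic"
    design: list[tuple] = field(default_factory=list)
    manifest: str | Path | None = None
    scale: float = 2.84  # px/µm, synthetic mode
    size: tuple[int, int] = (768, 1024)
    g_min: int = 50
    margin: int = 20
    min_blob: int = 3
    depth_mode: str = "max"
    alpha: float = 0.05
    seed: int | None = None
    reference: str | None = None  # fold-change reference arm
    epidermis_um: float = 100.0
    tewl_violation_fraction: float = 0.1
    outdir: str | Path | None = None
    write_overlays: bool = False


@dataclass
class ReportBundle:
    """Everything one run produced."""

    per_image: pd.DataFrame
    per_group: pd.DataFrame
    stats: dict[str, StatsReport]
    fold_change: pd.DataFrame
    region_calls: pd.DataFrame
    study: StudySet | None = None


def region_call(mpd: float, sct: float, epidermis: float = 100.0) -> str:
    """Skin region reached: ``mpd ≤ sct`` → stratum corneum, ``≤
    epidermis`` → epidermis, deeper → dermis."""
    if mpd < 0:
        raise ValueError("penetration depth cannot be negative")
    if mpd <= sct:
        return "stratum_corneum"
    if mpd <= epidermis:
        return "epidermis"
    return "dermis"


def fold_changes(per_group: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Per-group percentage change vs a reference arm.

    For each measure (ART, MPD, SCT): ``100 · (mean/ref_mean − 1)``.
    """
    if reference not in set(per_group["group"]):
        raise ValueError(f"reference group {reference!r} not present")
    ref = per_group.loc[per_group["group"] == reference].iloc[0]
    rows = []
    for _, row in per_group.iterrows():
        entry = {"group": row["group"]}
        for measure in MEASURES:
            ref_mean = ref[f"{measure}_mean"]
            if not ref_mean > 0:
                raise ValueError(
                    f"reference mean of {measure!r} is not positive; "
                    "fold change undefined"
                )
            entry[f"{measure}_pct_change"] = 100.0 * (
                row[f"{measure}_mean"] / ref_mean - 1.0
            )
        rows.append(entry)
    return pd.DataFrame(rows)


def quantify_image(
    img: Micrograph,
    g_min: int = 50,
    margin: int = 20,
    min_blob: int = 3,
    depth_mode: str = "max",
) -> dict[str, float]:
    """ART, depth and SCT of one skin-section micrograph."""
    surface = detect_surface(img)
    mask = rgb_threshold(img, g_min=g_min, margin=margin)
    roi = tissue_roi(img.shape, surface)
    return {
        "art": compute_art(img, mask, roi),
        "depth": compute_depth(
            mask, surface, img.scale, min_blob=min_blob, mode=depth_mode
        ),
        "sct": measure_sct(img, surface, img.scale),
    }


def _load_real_study(config: RunConfig) -> list[StudyRecord]:
    manifest = pd.read_csv(config.manifest)
    required = {"file", "group", "tewl", "scale_px_per_um"}
    if missing := required - set(manifest.columns):
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    base = Path(config.manifest).parent
    paths = [
        (p if p.is_absolute() else base / p)
        for p in (Path(f) for f in manifest["file"])
    ]
    # Fail fast, before any computation, if a file is unreadable.
    for p in paths:
        if not p.is_file():
            raise FileNotFoundError(f"manifest references unreadable file: {p}")
    from .synthetic import SkinGroundTruth

    records = []
    for p, (_, row) in zip(paths, manifest.iterrows()):
        img = dio.read_micrograph(p, scale=float(row["scale_px_per_um"]))
        records.append(
            StudyRecord(
                image=img,
                truth=SkinGroundTruth(np.nan, np.nan, np.nan, -1),
                group=str(row["group"]),
                tewl=float(row["tewl"]),
                tewl_violator=False,
                seed=-1,
            )
        )
    return records


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run a full study and return all tables; see module docstring."""
    study: StudySet | None = None
    if config.mode == "synthetic":
        if config.seed is None:
            raise ValueError("synthetic mode requires a seed")
        if not config.design:
            raise ValueError("synthetic mode requires a non-empty design")
        study = make_study(
            config.design,
            config.seed,
            size=config.size,
            scale=config.scale,
            tewl_violation_fraction=config.tewl_violation_fraction,
        )
        records = study.records
    elif config.mode == "real":
        if config.manifest is None:
            raise ValueError("real mode requires a manifest path")
        records = _load_real_study(config)
    else:
        raise ValueError(f"unknown mode {config.mode!r}; use 'synthetic' or 'real'")

    rows = []
    for i, rec in enumerate(records):
        status = qc_tewl(rec.tewl)
        measures = quantify_image(
            rec.image,
            g_min=config.g_min,
            margin=config.margin,
            min_blob=config.min_blob,
            depth_mode=config.depth_mode,
        )
        rows.append(
            {
                "index": i,
                "group": rec.group,
                "tewl": rec.tewl,
                "qc_status": status,
                "art_mgv_px": measures["art"],
                "depth_um": measures["depth"],
                "sct_um": measures["sct"],
            }
        )
        if status == "exclude":
            logger.info("image %d (%s): TEWL %.1f > 15, excluded from statistics",
                        i, rec.group, rec.tewl)
    per_image = pd.DataFrame(rows)

    included = per_image[per_image["qc_status"] == "include"]
    order = list(dict.fromkeys(per_image["group"]))
    col_of = {"art": "art_mgv_px", "depth": "depth_um", "sct": "sct_um"}
    summary_rows = []
    for group in order:
        sub = included[included["group"] == group]
        entry: dict[str, object] = {"group": group, "n": len(sub)}
        for measure, col in col_of.items():
            entry[f"{measure}_mean"] = float(sub[col].mean()) if len(sub) else np.nan
            entry[f"{measure}_sd"] = (
                float(sub[col].std(ddof=1)) if len(sub) > 1 else np.nan
            )
        summary_rows.append(entry)
    per_group = pd.DataFrame(summary_rows)

    reference = config.reference or order[0]
    if reference in set(per_group["group"]):
        sct_ref = per_group.loc[per_group["group"] == reference, "sct_mean"].iloc[0]
        per_group["rel_sct_pct"] = 100.0 * per_group["sct_mean"] / sct_ref

    stats_reports: dict[str, StatsReport] = {}
    for measure, col in col_of.items():
        samples = []
        for group in order:
            vals = included.loc[included["group"] == group, col].to_numpy()
            # Degenerate (near-constant) arms break normality tests.
            if len(vals) >= 3 and np.std(vals) > 1e-9:
                samples.append(GroupSample(group, vals))
            else:
                logger.info("measure %s: arm %r degenerate or too small, "
                            "omitted from statistics", measure, group)
        if len(samples) >= 2:
            report = run_comparison(samples, alpha=config.alpha)
            stats_reports[measure] = report
            logger.info("measure %s: route %s, omnibus p=%.3g",
                        measure, report.route, report.omnibus_p)

    fold = fold_changes(per_group, reference)
    regions = pd.DataFrame(
        {
            "group": per_group["group"],
            "region": [
                region_call(m, s, config.epidermis_um)
                for m, s in zip(per_group["depth_mean"], per_group["sct_mean"])
            ],
        }
    )

    bundle = ReportBundle(per_image, per_group, stats_reports, fold, regions, study)
    if config.outdir is not None:
        dio.write_report(bundle, config.outdir, write_overlays=config.write_overlays,
                         records=records, config=config)
    return bundle
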