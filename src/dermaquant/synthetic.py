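"""Seeded synthetic micrographs with known ground truth.

Real study material (ex vivo porcine skin sections, TiO2 dispersions)
cannot be shipped, so every downstream stage is exercised on synthetic
micrographs that emulate the relevant optics:

* **Skin sections** (epifluorescence): a dark background above a tissue
  band whose top edge is the skin surface; a brighter stratum corneum
  (SC) band of known thickness; diffuse, textured tissue
  autofluorescence rendered predominantly in red+blue with weak green;
  and a purely green fluorescein signal that ramps down linearly from
  the surface to a programmable penetration front.
* **Particle dispersions** (polarized light): bright convex blobs —
  single ellipses or fused ellipse clusters ("agglomerates") — on a
  dark field, with the true maximum-caliper (Feret) diameter of every
  rendered blob returned as ground truth.

Formulation presets encode the study arms: penetration depth, relative
dye amount (particle-free control = 1), and SC thickness as % of
untreated.  The green-channel dye amplitude is calibrated in closed
form so that, on expectation, the masked green integral measured by the
RGB-threshold pipeline is proportional to the preset's relative amount;
fold-change recovery is therefore meaningful end to end.

Every generator is bit-exactly reproducible from its ``(inputs, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .particles import feret_diameter
from .types import Micrograph

__all__ = [
    "FormulationPreset",
    "SkinGroundTruth",
    "ParticleImageSpec",
    "StudyRecord",
    "StudySet",
    "preset",
    "particle_preset",
    "make_skin_section",
    "make_particle_image",
    "make_study",
    "PRESETS",
    "PARTICLE_PRESETS",
]

# ---------------------------------------------------------------------------
# Rendering model constants
# ---------------------------------------------------------------------------

#: Stratum corneum thickness of untreated skin in this model (µm);
#: presets scale it via ``sct_factor``.
SCT_BASE_UM = 40.0

#: Background (non-tissue) grey level.
BG_LEVEL = 8.0

#: Tissue autofluorescence channel fractions of ``autofluor_level``:
#: bluish with weak green, so a green-dominance rule can separate dye
#: from autofluorescence.
AUTOFLUOR_RGB = (0.9, 0.5, 1.0)

#: Stratum corneum band: bright, with the same green deficit
#: ``G - max(R, B) = -0.5*autofluor_level`` as the deeper tissue, so the
#: dye mask threshold behaves identically inside and below the band.
SC_MAX_LEVEL = 110.0

#: Dye amplitude at the penetration front (grey units); comfortably
#: above the default green-dominance cut so the front is recoverable.
DYE_EDGE = 60.0

#: ART calibration gain: chosen so the particle-free control preset
#: (amount 1.0, depth 43 µm, SC 40 µm) renders with a surface dye
#: amplitude of 90 grey units.  See :func:`_dye_surface_amplitude`.
ART_GAIN = 6885.0

#: Default frame (rows, cols) and skin-section pixel scale.
DEFAULT_SKIN_SHAPE = (768, 1024)
DEFAULT_SKIN_SCALE = 2.84  # px/µm
DEFAULT_PARTICLE_SHAPE = (768, 1024)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FormulationPreset:
    """Ground-truth parameter set emulating one formulation arm.

    ``depth_true`` is the mean penetration front (µm), ``amount_true``
    the relative penetrated dye amount (particle-free control = 1.0),
    and ``sct_factor`` the stratum corneum thickness as % of untreated.
    The ``*_cv`` fields give the between-replicate biological
    coefficient of variation applied per generated section.
    """

    name: str
    depth_true: float  # µm
    amount_true: float  # relative, control == 1.0
    sct_factor: float  # % of untreated SCT
    autofluor_level: float = 40.0  # grey units
    noise_sigma: float = 6.0  # grey units
    front_width: float = 5.0  # µm
    depth_cv: float = 0.08
    amount_cv: float = 0.10
    sct_cv: float = 0.04

    def __post_init__(self) -> None:
        if self.depth_true < 0:
            raise ValueError("depth_true must be >= 0")
        if self.amount_true < 0:
            raise ValueError("amount_true must be >= 0")
        if not 50 <= self.sct_factor <= 200:
            raise ValueError("sct_factor must lie within 50–200 % of untreated")


@dataclass(frozen=True)
class SkinGroundTruth:
    """Per-image realized ground truth of one synthetic skin section."""

    depth_true: float  # µm, realized front of this section
    amount_true: float  # realized relative dye amount
    sct_true: float  # µm, realized SC thickness
    surface_row: int  # px row of the skin surface


@dataclass(frozen=True)
class ParticleImageSpec:
    """Parameters of one synthetic particle-dispersion image."""

    n_particles: int
    diameter_mean: float  # µm, mean target Feret
    diameter_sd: float  # µm
    agglomeration: float  # probability a blob is a fused ellipse cluster
    scale: float = 3.3  # px/µm
    brightness: float = 200.0  # grey units of blob pixels

    def __post_init__(self) -> None:
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.diameter_mean <= 0:
            raise ValueError("diameter_mean must be positive")
        if not 0 <= self.agglomeration <= 1:
            raise ValueError("agglomeration must be a probability in [0, 1]")


@dataclass(frozen=True)
class StudyRecord:
    """One generated section with its arm label and synthetic TEWL."""

    image: Micrograph
    truth: SkinGroundTruth
    group: str
    tewl: float  # g/cm²/h
    tewl_violator: bool  # generator bookkeeping for QC cross-checks
    seed: int


@dataclass
class StudySet:
    """A seeded collection of study records plus its design."""

    records: list[StudyRecord]
    design: list[tuple[str, str, int]]  # (group label, preset name, n)
    seed: int


# ---------------------------------------------------------------------------
# Preset registries
# ---------------------------------------------------------------------------

PRESETS: dict[str, FormulationPreset] = {
    p.name: p
    for p in [
        # Untreated skin: no dye at all.
        FormulationPreset("untreated", depth_true=0.0, amount_true=0.0, sct_factor=100),
        # Particle-free dye solution: dye reaches only the stratum corneum.
        FormulationPreset("control_groupI", depth_true=43.0, amount_true=1.0, sct_factor=100),
        # Low particle content (5–10 %): epidermal penetration.
        FormulationPreset("nlc_groupII", depth_true=80.0, amount_true=1.6, sct_factor=105),
        # High particle content (20–40 %): transdermal penetration.
        FormulationPreset("nlc_groupIII", depth_true=110.0, amount_true=2.0, sct_factor=105),
        # Glycerol humectant without particles: hydration only.
        FormulationPreset("glycerol_control", depth_true=43.0, amount_true=1.05, sct_factor=110),
        # Particles plus glycerol: additive hydration, particle-driven depth.
        FormulationPreset("nlc_glycerol", depth_true=80.0, amount_true=1.68, sct_factor=115),
    ]
}

PARTICLE_PRESETS: dict[str, ParticleImageSpec] = {
    # TiO2 in water: inhomogeneous, large aggregates, very broad sizes.
    "water_dispersion": ParticleImageSpec(
        n_particles=120, diameter_mean=3.84, diameter_sd=2.3, agglomeration=0.30
    ),
    # TiO2 in surfactant solution: smaller, more homogeneous blobs.
    "surfactant_dispersion": ParticleImageSpec(
        n_particles=160, diameter_mean=2.98, diameter_sd=1.3, agglomeration=0.05
    ),
}


def preset(name: str) -> FormulationPreset:
    """Look up a registered formulation preset by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; registered presets: {sorted(PRESETS)}"
        ) from None


def particle_preset(name: str) -> ParticleImageSpec:
    """Look up a registered particle-dispersion preset by name."""
    try:
        return PARTICLE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown particle preset {name!r}; registered presets: "
            f"{sorted(PARTICLE_PRESETS)}"
        ) from None


# ---------------------------------------------------------------------------
# Skin sections
# ---------------------------------------------------------------------------


def _dye_surface_amplitude(
    amount: float, depth: float, sct: float, autofluor_level: float
) -> float:
    """Surface dye amplitude making expected masked green ∝ ``amount``.

    The dye ramps linearly from amplitude ``D0`` at the surface to
    :data:`DYE_EDGE` at ``depth``.  Under the default green-dominance
    mask the whole dye column is selected, so per column the masked
    green integral (in grey·µm) is::

        depth · ((D0 + DYE_EDGE)/2 + 0.5·A) + (SC_green − 0.5·A) · sct

    with ``A = autofluor_level``.  Equating this to ``ART_GAIN · amount``
    and solving for ``D0`` makes ART fold changes between presets equal
    their programmed amount ratios on expectation.
    """
    sc_green = SC_MAX_LEVEL - 0.5 * autofluor_level
    sc_excess = sc_green - 0.5 * autofluor_level
    d0 = 2.0 * (
        (ART_GAIN * amount - sc_excess * sct) / depth - 0.5 * autofluor_level
    ) - DYE_EDGE
    if d0 < DYE_EDGE:
        raise ValueError(
            f"preset not renderable: calibrated surface amplitude {d0:.1f} falls "
            f"below the front amplitude {DYE_EDGE}; amount too low for this depth"
        )
    return d0


def _nominal_sct(p: FormulationPreset) -> float:
    """Nominal SC thickness (µm) of a preset, before per-image jitter."""
    return SCT_BASE_UM * p.sct_factor / 100.0


def _dye_profile(depth_um: np.ndarray, d0: float, depth: float, front_width: float) -> np.ndarray:
    """Dye amplitude vs depth (µm): linear ramp, then a soft front.

    The amplitude ramps from ``d0`` at the surface to :data:`DYE_EDGE`
    at the start of the front transition, which is *centred* on
    ``depth`` and decays to zero over ``front_width``.  Centring the
    transition keeps the deepest above-threshold pixel unbiased around
    the programmed front for any mask cut near half the edge amplitude;
    a transition placed entirely beyond ``depth`` would make every
    thresholded depth read structurally too deep.
    """
    prof = np.zeros_like(depth_um)
    front_start = max(depth - front_width / 2.0, 0.0)
    in_ramp = (depth_um >= 0) & (depth_um <= front_start)
    if front_start > 0:
        prof[in_ramp] = d0 - (d0 - DYE_EDGE) * depth_um[in_ramp] / front_start
    in_front = (depth_um > front_start) & (depth_um < front_start + front_width)
    prof[in_front] = DYE_EDGE * (
        1.0 - (depth_um[in_front] - front_start) / front_width
    )
    return prof


def make_skin_section(
    formulation: FormulationPreset | str,
    seed: int,
    size: tuple[int, int] = DEFAULT_SKIN_SHAPE,
    scale: float = DEFAULT_SKIN_SCALE,
    noise: bool = True,
    jitter: bool = True,
) -> tuple[Micrograph, SkinGroundTruth]:
    """Render one synthetic vertical skin section.

    Parameters
    ----------
    formulation
        A :class:`FormulationPreset` or a registered preset name.
    seed
        Integer seed; identical ``(formulation, seed, size, scale)``
        yield bit-identical images.
    size
        Frame shape ``(rows, cols)``.
    scale
        Pixel scale in px/µm.
    noise, jitter
        Disable to obtain noise-free renders / suppress the per-image
        biological variability (used by calibration checks).

    Returns
    -------
    (image, truth)
        The RGB micrograph and the realized per-image ground truth.
    """
    p = preset(formulation) if isinstance(formulation, str) else formulation
    h, w = size
    rng = np.random.default_rng(seed)

    # Per-image biological realization (fixed draw order for determinism);
    # truncated at ±3 SD — larger excursions are not biologically plausible.
    zs = np.clip(rng.standard_normal(3), -3.0, 3.0)
    if not jitter:
        zs[:] = 0.0
    depth = max(p.depth_true * (1.0 + p.depth_cv * zs[0]), 0.0)
    amount = max(p.amount_true * (1.0 + p.amount_cv * zs[1]), 0.0)
    sct = max(SCT_BASE_UM * (p.sct_factor / 100.0) * (1.0 + p.sct_cv * zs[2]), 1.0)
    surface_row = int(rng.integers(40, max(h // 4, 41)))

    needed = surface_row + int((depth + p.front_width) * scale) + 8
    if needed >= h:
        raise ValueError(
            f"penetration front ({depth:.0f} µm at {scale} px/µm, surface row "
            f"{surface_row}) does not fit a {h}-row frame; enlarge the image"
        )

    img = np.full((h, w, 3), BG_LEVEL, dtype=np.float32)

    # Textured tissue autofluorescence below the surface; the smooth
    # field is generated at quarter resolution (correlation length ~12 px
    # at full scale) and upsampled, which is visually equivalent.
    h4, w4 = -(-h // 4), -(-w // 4)
    texture = gaussian_filter(
        rng.standard_normal((h4, w4)).astype(np.float32), sigma=3
    )
    texture /= max(float(texture.std()), 1e-9)
    texture = np.repeat(np.repeat(texture, 4, axis=0), 4, axis=1)[:h, :w]
    texture = np.clip(1.0 + 0.06 * texture, 0.8, 1.2)
    tissue = slice(surface_row, h)
    for ch, frac in enumerate(AUTOFLUOR_RGB):
        img[tissue, :, ch] = p.autofluor_level * frac * texture[tissue, :]

    # Stratum corneum band: bright, same green deficit as deeper tissue.
    sct_px = max(int(round(sct * scale)), 1)
    sc = slice(surface_row, min(surface_row + sct_px, h))
    sc_rgb = (SC_MAX_LEVEL, SC_MAX_LEVEL - 0.5 * p.autofluor_level, SC_MAX_LEVEL - 20.0)
    for ch, level in enumerate(sc_rgb):
        img[sc, :, ch] = level * texture[sc, :]

    # Green dye signal: linear ramp to the front, taper over front_width.
    # The surface amplitude is calibrated from the preset's *nominal*
    # parameters; the per-image amount realization scales the whole
    # profile, so mean ART stays proportional to amount on expectation.
    if amount > 0 and depth > 0:
        d0 = _dye_surface_amplitude(
            p.amount_true, p.depth_true, _nominal_sct(p), p.autofluor_level
        )
        rows = np.arange(h, dtype=np.float64)
        depth_um = (rows - surface_row) / scale
        profile = (amount / p.amount_true) * _dye_profile(
            depth_um, d0, depth, p.front_width
        )
        img[:, :, 1] += profile.astype(np.float32)[:, None]

    if noise:
        img += p.noise_sigma * rng.standard_normal((h, w, 3), dtype=np.float32)

    np.rint(img, out=img)
    np.clip(img, 0, 255, out=img)
    pixels = img.astype(np.uint8)
    truth = SkinGroundTruth(
        depth_true=depth, amount_true=amount, sct_true=sct, surface_row=surface_row
    )
    return Micrograph(pixels, scale=scale, modality="epifluorescence"), truth


# ---------------------------------------------------------------------------
# Particle dispersions
# ---------------------------------------------------------------------------


def _sample_target_feret(rng: np.random.Generator, spec: ParticleImageSpec) -> float:
    """Draw a target blob Feret (µm) from a lognormal size distribution.

    A floor of 0.6 µm keeps every rendered blob above the 0.4 µm
    artefact cut of the sizing pipeline, so the generated truth and the
    post-filter measurement describe the same population.
    """
    sigma2 = np.log1p((spec.diameter_sd / spec.diameter_mean) ** 2)
    mu = np.log(spec.diameter_mean) - sigma2 / 2.0
    for _ in range(1000):
        d = float(rng.lognormal(mu, np.sqrt(sigma2)))
        if d >= 0.6:
            return d
    raise RuntimeError("size distribution almost entirely below the 0.6 µm floor")


#: Rasterizing a continuous ellipse by pixel centres and measuring over
#: pixel corners inflates the caliper by ~0.7 px on average; the
#: continuous geometry is shrunk by this much so the rendered blob's
#: pixel-corner Feret is centred on the requested diameter.
_CORNER_INFLATION_PX = 0.7


def _blob_pixels(
    rng: np.random.Generator, feret_px: float, agglomerate: bool
) -> np.ndarray:
    """Rasterize one blob centred at the origin; returns (n, 2) offsets.

    A blob is a single ellipse of major diameter ``feret_px`` or, for an
    agglomerate, a chain of 2–3 overlapping ellipses spanning that
    extent along a random axis.
    """
    feret_px = max(feret_px - _CORNER_INFLATION_PX, 1.0)
    theta = rng.uniform(0, np.pi)
    parts: list[tuple[float, float, float]] = []  # (offset along axis, a, b)
    if agglomerate and feret_px >= 4.0:
        k = int(rng.integers(2, 4))
        if k == 2:
            u = rng.uniform(0.55, 0.70, size=2)
            d = u * feret_px
            parts.append((-feret_px / 2 + d[0] / 2, d[0] / 2, d[0] / 2 * rng.uniform(0.6, 0.95)))
            parts.append((feret_px / 2 - d[1] / 2, d[1] / 2, d[1] / 2 * rng.uniform(0.6, 0.95)))
        else:
            u = rng.uniform(0.40, 0.55, size=2)
            d_mid = 0.5 * feret_px
            parts.append((-feret_px / 2 + u[0] * feret_px / 2, u[0] * feret_px / 2,
                          u[0] * feret_px / 2 * rng.uniform(0.6, 0.95)))
            parts.append((0.0, d_mid / 2, d_mid / 2 * rng.uniform(0.6, 0.95)))
            parts.append((feret_px / 2 - u[1] * feret_px / 2, u[1] * feret_px / 2,
                          u[1] * feret_px / 2 * rng.uniform(0.6, 0.95)))
    else:
        a = feret_px / 2
        parts.append((0.0, a, a * rng.uniform(0.6, 0.95)))

    half = int(np.ceil(feret_px / 2)) + 2
    rr, cc = np.mgrid[-half : half + 1, -half : half + 1]
    ct, st = np.cos(theta), np.sin(theta)
    inside = np.zeros(rr.shape, dtype=bool)
    for offset, a, b in parts:
        cy, cx = offset * st, offset * ct
        u = (cc - cx) * ct + (rr - cy) * st  # along-axis coordinate
        v = -(cc - cx) * st + (rr - cy) * ct
        inside |= (u / a) ** 2 + (v / max(b, 0.5)) ** 2 <= 1.0
    coords = np.argwhere(inside)
    return coords - np.array([half, half])


def make_particle_image(
    spec: ParticleImageSpec,
    seed: int,
    size: tuple[int, int] = DEFAULT_PARTICLE_SHAPE,
) -> tuple[Micrograph, list[float]]:
    """Render a dispersion image and return per-blob true Feret diameters.

    Blobs are placed so that no two touch unless fused by design; the
    truth list holds the maximum caliper diameter (µm) of each rendered
    blob, measured on its pixel-corner polygon.  Placement that fails
    after bounded retries raises instead of silently overlapping.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    canvas = np.zeros((h, w), dtype=bool)
    placed: list[tuple[float, float, float]] = []  # (row, col, radius)
    truths: list[float] = []

    for _ in range(spec.n_particles):
        feret_um = _sample_target_feret(rng, spec)
        feret_px = feret_um * spec.scale
        agglomerate = bool(rng.uniform() < spec.agglomeration)
        offsets = _blob_pixels(rng, feret_px, agglomerate)
        radius = feret_px / 2 + 3.0

        for attempt in range(300):
            r0 = float(rng.uniform(radius + 1, h - radius - 1))
            c0 = float(rng.uniform(radius + 1, w - radius - 1))
            if all(
                np.hypot(r0 - rr, c0 - cc) >= radius + pr for rr, cc, pr in placed
            ):
                break
        else:
            raise RuntimeError(
                f"could not place blob {len(placed) + 1}/{spec.n_particles} without "
                "overlap after 300 attempts; reduce n_particles or blob sizes"
            )

        coords = offsets + np.array([int(round(r0)), int(round(c0))])
        canvas[coords[:, 0], coords[:, 1]] = True
        placed.append((r0, c0, radius))
        truths.append(feret_diameter(coords) / spec.scale)

    img = np.full((h, w), 10.0) + rng.normal(0.0, 5.0, size=(h, w))
    img[canvas] = spec.brightness + rng.normal(0.0, 5.0, size=int(canvas.sum()))
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Micrograph(pixels, scale=spec.scale, modality="polarized"), truths


# ---------------------------------------------------------------------------
# Studies
# ---------------------------------------------------------------------------


def make_study(
    design: list[tuple],
    seed: int,
    size: tuple[int, int] = DEFAULT_SKIN_SHAPE,
    scale: float = DEFAULT_SKIN_SCALE,
    tewl_violation_fraction: float = 0.1,
) -> StudySet:
    """Generate a seeded multi-arm study of skin sections.

    ``design`` entries are ``(preset_name, n_replicates)`` or
    ``(group_label, preset_name, n_replicates)`` — the latter lets two
    arms share preset parameters under distinct labels (e.g. 5 % and
    10 % particle arms both following the group-II parameter set).

    Synthetic TEWL values are drawn so that ``tewl_violation_fraction``
    of all records exceeds the 15 g/cm²/h barrier-integrity limit; each
    record carries a bookkeeping flag for QC cross-checks.
    """
    if not design:
        raise ValueError("study design is empty")
    norm: list[tuple[str, str, int]] = []
    for entry in design:
        if len(entry) == 2:
            name, n = entry
            label = name
        else:
            label, name, n = entry
        if n < 1:
            raise ValueError(f"arm {label!r} needs at least one replicate, got {n}")
        preset(name)  # validate
        norm.append((str(label), str(name), int(n)))

    n_total = sum(n for _, _, n in norm)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s) for s in ss.generate_state(n_total, dtype=np.uint32)]
    rng = np.random.default_rng(ss.spawn(1)[0])

    n_viol = int(round(tewl_violation_fraction * n_total))
    viol_idx = set(rng.choice(n_total, size=n_viol, replace=False).tolist())
    tewl_ok = rng.uniform(4.0, 12.0, size=n_total)
    tewl_bad = rng.uniform(15.5, 25.0, size=n_total)

    records: list[StudyRecord] = []
    i = 0
    for label, name, n in norm:
        for _ in range(n):
            img, truth = make_skin_section(name, child_seeds[i], size=size, scale=scale)
            violator = i in viol_idx
            records.append(
                StudyRecord(
                    image=img,
                    truth=truth,
                    group=label,
                    tewl=float(tewl_bad[i] if violator else tewl_ok[i]),
                    tewl_violator=violator,
                    seed=child_seeds[i],
                )
            )
            i += 1
    return StudySet(records=records, design=norm, seed=seed)
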