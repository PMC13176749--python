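"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators:

* :func:`make_tld_study` — duplicate TLD read-outs per anatomical region around
  known true organ doses.  Measurement error is multiplicative Gaussian with a
  coefficient of variation ``noise_cv`` (TLD precision is dose-proportional);
  every chip then carries an additive background dose.  Defaults mirror the
  reference study design: two chips per region, three background chips,
  background 0.077 mSv, CV 5%.

* :func:`make_slice` — a three-entity (bone / soft tissue / air) axial slice:
  an air background, a soft-tissue head disc, a bone arch annulus, and two air
  cavities as a sinus analogue.  Pixel noise is Gaussian per entity; the
  within-VOI SD scales with sqrt(reference_mas / protocol_mas), encoding
  quantum noise proportional to 1/sqrt(mAs), so a half-rotation ("quick")
  acquisition at 14.4 mAs is noisier than the 21.6 mAs reference by sqrt(1.5).
  Each suggested VOI site additionally receives a mean offset drawn with the
  per-entity ``between_voi_sd`` (structural drift of local means, not dose
  dependent).  Generated images are quantized to integer HU so the unsigned
  16-bit DICOM round-trip is exact.

Both generators take an explicit seed (no global random state) and return a
ground-truth record from which every expected pipeline output is computable.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .dosimetry import TldReadout
from .image_quality import VoiSpec, ellipse_mask

logger = logging.getLogger(__name__)

DEFAULT_ENTITY_MEANS = {"bone": 1800.0, "soft_tissue": 0.0, "air": -1000.0}
DEFAULT_WITHIN_VOI_SD = {"bone": 180.0, "soft_tissue": 120.0, "air": 50.0}
DEFAULT_BETWEEN_VOI_SD = {"bone": 150.0, "soft_tissue": 50.0, "air": 40.0}


# ---------------------------------------------------------------------------
# TLD study generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthTldConfig:
    """Study design for a synthetic TLD experiment (doses in mSv)."""

    true_doses: Mapping[str, float]
    background_dose: float = 0.077
    noise_cv: float = 0.05
    n_per_region: int = 2
    n_background: int = 3
    protocol: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_doses:
            raise ValueError("true_doses must not be empty")
        for region, dose in self.true_doses.items():
            if dose <= 0:
                raise ValueError(f"true dose for {region!r} must be > 0, got {dose}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.background_dose < 0:
            raise ValueError("background_dose must be >= 0")
        if self.n_per_region < 1 or self.n_background < 1:
            raise ValueError("chip counts must be >= 1")


@dataclass(frozen=True)
class TldGroundTruth:
    true_doses: Mapping[str, float]
    background_dose: float
    noise_cv: float
    seed: int


def make_tld_study(
    config: SynthTldConfig, seed: int | None = None
) -> tuple[list[TldReadout], TldGroundTruth]:
    """Generate raw read-outs: true_dose x (1 + N(0, cv)) + background."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    readouts: list[TldReadout] = []
    for region, dose in config.true_doses.items():
        for i in range(1, config.n_per_region + 1):
            value = dose * (1.0 + rng.normal(0.0, config.noise_cv)) + config.background_dose
            readouts.append(
                TldReadout(
                    dosimeter_id=f"{region}-{i}",
                    region=region,
                    protocol=config.protocol,
                    value=max(value, 0.0),
                )
            )
    for i in range(1, config.n_background + 1):
        value = config.background_dose * (1.0 + rng.normal(0.0, config.noise_cv))
        readouts.append(
            TldReadout(
                dosimeter_id=f"background-{i}",
                region="background",
                protocol=config.protocol,
                value=max(value, 0.0),
            )
        )
    truth = TldGroundTruth(
        true_doses=dict(config.true_doses),
        background_dose=config.background_dose,
        noise_cv=config.noise_cv,
        seed=config.seed if seed is None else seed,
    )
    return readouts, truth


# ---------------------------------------------------------------------------
# slice generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Disc:
    entity: str
    center: tuple[float, float]  # (row, col)
    radius: float


@dataclass(frozen=True)
class Annulus:
    entity: str
    center: tuple[float, float]
    r_inner: float
    r_outer: float


@dataclass(frozen=True)
class Rect:
    entity: str
    top: int
    left: int
    height: int
    width: int


Shape = Union[Disc, Annulus, Rect]


@dataclass(frozen=True)
class SynthSliceConfig:
    """Geometry and noise model of one synthetic axial slice."""

    image_size: tuple[int, int] = (256, 256)
    background_entity: str = "air"
    shapes: tuple[Shape, ...] = ()
    voi_specs: tuple[VoiSpec, ...] = ()
    entity_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENTITY_MEANS)
    )
    within_voi_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WITHIN_VOI_SD)
    )
    between_voi_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_VOI_SD)
    )
    protocol_mas: float = 21.6
    reference_mas: float = 21.6
    protocol: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol_mas <= 0 or self.reference_mas <= 0:
            raise ValueError("mAs values must be > 0")
        for mapping, label in (
            (self.within_voi_sd, "within_voi_sd"),
            (self.between_voi_sd, "between_voi_sd"),
        ):
            for entity, sd in mapping.items():
                if sd < 0:
                    raise ValueError(f"{label}[{entity!r}] must be >= 0, got {sd}")

    @property
    def noise_factor(self) -> float:
        """Quantum-noise scaling sqrt(reference_mas / protocol_mas)."""
        return math.sqrt(self.reference_mas / self.protocol_mas)


@dataclass
class SliceGroundTruth:
    entity_means: Mapping[str, float]
    within_sd_effective: Mapping[str, float]  # within_voi_sd x noise factor
    between_voi_sd: Mapping[str, float]
    voi_offsets: Mapping[str, float]
    voi_n_pixels: Mapping[str, int]
    protocol_mas: float
    reference_mas: float
    seed: int

    def expected_voi_mean_sd(self, entity: str, n_pixels: int) -> float:
        """Predicted SD of a VOI mean: between-VOI drift + averaged pixel noise."""
        within = self.within_sd_effective.get(entity, 0.0)
        between = self.between_voi_sd.get(entity, 0.0)
        return math.sqrt(between**2 + within**2 / n_pixels)


@dataclass
class SliceResult:
    image: np.ndarray  # integer-valued HU
    masks: dict[str, np.ndarray]
    voi_specs: list[VoiSpec]
    ground_truth: SliceGroundTruth


def _shape_mask(shape: Shape, size: tuple[int, int]) -> np.ndarray:
    rows, cols = size
    y, x = np.mgrid[0:rows, 0:cols]
    if isinstance(shape, Disc):
        cy, cx = shape.center
        if cy - shape.radius < -0.5 or cy + shape.radius > rows - 0.5 \
                or cx - shape.radius < -0.5 or cx + shape.radius > cols - 0.5:
            raise ValueError(f"shape out of bounds: {shape}")
        return (y - cy) ** 2 + (x - cx) ** 2 <= shape.radius**2
    if isinstance(shape, Annulus):
        cy, cx = shape.center
        if shape.r_inner >= shape.r_outer:
            raise ValueError(f"annulus r_inner >= r_outer: {shape}")
        if cy - shape.r_outer < -0.5 or cy + shape.r_outer > rows - 0.5 \
                or cx - shape.r_outer < -0.5 or cx + shape.r_outer > cols - 0.5:
            raise ValueError(f"shape out of bounds: {shape}")
        r2 = (y - cy) ** 2 + (x - cx) ** 2
        return (r2 >= shape.r_inner**2) & (r2 <= shape.r_outer**2)
    if isinstance(shape, Rect):
        if shape.top < 0 or shape.left < 0 or shape.top + shape.height > rows \
                or shape.left + shape.width > cols:
            raise ValueError(f"shape out of bounds: {shape}")
        mask = np.zeros(size, dtype=bool)
        mask[shape.top:shape.top + shape.height, shape.left:shape.left + shape.width] = True
        return mask
    raise TypeError(f"unknown shape type {type(shape).__name__}")


def default_slice_config(
    protocol: str = "synthetic",
    protocol_mas: float = 21.6,
    reference_mas: float = 21.6,
    image_size: tuple[int, int] = (256, 256),
    voi_diameter: float = 6.0,
    seed: int = 0,
    **overrides,
) -> SynthSliceConfig:
    """Head-like default geometry scaled to ``image_size``, with 9 VOI sites.

    An air background, a soft-tissue head disc (radius 0.45 of the short image
    side), a bone arch annulus (0.30-0.40), and two air sinus cavities; three
    suggested VOIs per entity, all placed well inside their entity regions.
    """
    rows, cols = image_size
    m = min(rows, cols)
    if m < 64:
        raise ValueError("default geometry needs an image of at least 64x64")
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    shapes: tuple[Shape, ...] = (
        Disc("soft_tissue", (cy, cx), 0.45 * m),
        Annulus("bone", (cy, cx), 0.30 * m, 0.40 * m),
        Disc("air", (cy - 0.10 * m, cx - 0.13 * m), 0.08 * m),
        Disc("air", (cy - 0.10 * m, cx + 0.13 * m), 0.08 * m),
    )
    rb = 0.35 * m  # bone VOI ring radius
    sites = {
        "bone": [
            (cx, cy - rb),
            (cx - rb * math.cos(math.pi / 6), cy + rb / 2),
            (cx + rb * math.cos(math.pi / 6), cy + rb / 2),
        ],
        "soft_tissue": [
            (cx, cy + 0.15 * m),
            (cx - 0.15 * m, cy + 0.12 * m),
            (cx + 0.15 * m, cy + 0.12 * m),
        ],
        "air": [
            (cx - 0.13 * m, cy - 0.10 * m),
            (cx + 0.13 * m, cy - 0.10 * m),
            (8.0, 8.0),  # background corner
        ],
    }
    vois = []
    counter = 1
    for entity in ("bone", "soft_tissue", "air"):
        for x, y in sites[entity]:
            vois.append(
                VoiSpec(
                    voi_id=str(counter),
                    slice_region="synthetic_head",
                    protocol=protocol,
                    entity=entity,
                    center=(x, y),
                    diameter=voi_diameter,
                )
            )
            counter += 1
    return SynthSliceConfig(
        image_size=image_size,
        shapes=shapes,
        voi_specs=tuple(vois),
        protocol_mas=protocol_mas,
        reference_mas=reference_mas,
        protocol=protocol,
        seed=seed,
        **overrides,
    )


def make_slice(config: SynthSliceConfig, seed: int | None = None) -> SliceResult:
    """Render one synthetic slice; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    size = config.image_size
    labels = np.full(size, config.background_entity, dtype=object)
    covered = np.zeros(size, dtype=bool)
    for shape in config.shapes:
        mask = _shape_mask(shape, size)
        overlap = mask & covered
        if overlap.any():
            logger.info(
                "shape %r overwrites %d previously claimed pixels (later shape wins)",
                shape, int(overlap.sum()),
            )
        labels[mask] = shape.entity
        covered |= mask

    factor = config.noise_factor
    entities = sorted(set(labels.ravel().tolist()))
    image = np.empty(size, dtype=float)
    masks: dict[str, np.ndarray] = {}
    for entity in entities:
        mask = labels == entity
        masks[entity] = mask
        mean = config.entity_means.get(entity)
        if mean is None:
            raise ValueError(f"no entity mean configured for {entity!r}")
        sd = config.within_voi_sd.get(entity, 0.0) * factor
        image[mask] = mean + (rng.standard_normal(int(mask.sum())) * sd if sd > 0 else 0.0)

    voi_offsets: dict[str, float] = {}
    voi_n_pixels: dict[str, int] = {}
    for spec in config.voi_specs:
        vmask = ellipse_mask(size, spec.center, spec.diameter)
        if not vmask.any():
            raise ValueError(f"suggested VOI {spec.voi_id!r} selects zero pixels")
        if not (labels[vmask] == spec.entity).all():
            raise ValueError(
                f"suggested VOI {spec.voi_id!r} ({spec.entity}) leaves its entity region"
            )
        offset = rng.normal(0.0, config.between_voi_sd.get(spec.entity, 0.0))
        image[vmask] += offset
        voi_offsets[spec.voi_id] = float(offset)
        voi_n_pixels[spec.voi_id] = int(vmask.sum())

    # quantize to integer HU: what a 16-bit scanner export would store
    image = np.clip(np.rint(image), -1000, 64535)

    truth = SliceGroundTruth(
        entity_means=dict(config.entity_means),
        within_sd_effective={
            e: config.within_voi_sd.get(e, 0.0) * factor for e in entities
        },
        between_voi_sd=dict(config.between_voi_sd),
        voi_offsets=voi_offsets,
        voi_n_pixels=voi_n_pixels,
        protocol_mas=config.protocol_mas,
        reference_mas=config.reference_mas,
        seed=config.seed if seed is None else seed,
    )
    return SliceResult(
        image=image,
        masks=masks,
        voi_specs=list(config.voi_specs),
        ground_truth=truth,
    )
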