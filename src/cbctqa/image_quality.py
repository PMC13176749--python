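"""VOI pixel statistics and quantitative CBCT image-quality metrics.

A VOI (volume — effectively region — of interest) is the set of pixels whose
centres fall inside the ellipse inscribed in a ``diameter x diameter`` bounding
box (boundary inclusive).  Per slice region and protocol, three VOIs are placed
on each of three entities (bone, soft tissue, air); the per-entity aggregate of
the three VOI means feeds the metrics:

* ``SNR = mean_bone / sd_soft`` — signal over noise, where the noise term is the
  sample SD of the soft-tissue VOI means (between-VOI dispersion);
* ``CNR = |mean_bone - mean_soft| / sd_soft`` — the low-contrast-resolution
  measure;
* ``DIN = |P1 - P2| / Dmax`` — the DIN (Deutsches Institut fuer Normung)
  uniformity index, with contrast ``|P1 - P2|`` between the bone and soft-tissue
  aggregate means and ``Dmax`` the largest absolute deviation of a soft-tissue
  VOI mean from the soft-tissue aggregate mean.

CNR and DIN are invariant under adding a constant to all pixel values; all
three are invariant under a positive rescaling.  Air VOIs are collected and
profiled but enter no metric.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._common import round_half_up, sample_sd

logger = logging.getLogger(__name__)

ENTITIES = ("bone", "soft_tissue", "air")
METRICS = ("snr", "cnr", "din")


@dataclass(frozen=True)
class VoiSpec:
    """Placement of one elliptical VOI on a slice.

    ``center`` is (x, y) in 0-based pixel coordinates, x = column index;
    half-integer centres are allowed.  ``diameter`` is the side of the bounding
    box of the inscribed ellipse, in pixels.
    """

    voi_id: str
    slice_region: str
    protocol: str
    entity: str
    center: tuple[float, float]
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter < 2:
            raise ValueError(f"VOI {self.voi_id!r}: diameter must be >= 2 px")


@dataclass(frozen=True)
class VoiStats:
    """Pixel statistics of one VOI (``sd`` is the sample SD over its pixels)."""

    voi_id: str
    area_px2: float
    minimum: float
    maximum: float
    mean: float
    sd: float
    n_pixels: int | None = None
    area_mm2: float | None = None
    slice_region: str | None = None
    protocol: str | None = None
    entity: str | None = None

    def __post_init__(self) -> None:
        eps = 1e-9
        if not (self.minimum - eps <= self.mean <= self.maximum + eps):
            raise ValueError(
                f"VOI {self.voi_id!r}: min {self.minimum} <= mean {self.mean} "
                f"<= max {self.maximum} violated"
            )
        if self.sd < 0:
            raise ValueError(f"VOI {self.voi_id!r}: sd must be >= 0")


@dataclass(frozen=True)
class EntityAggregate:
    """Three-VOI summary for one slice_region x protocol x entity.

    ``mean``/``sd``/``minimum``/``maximum`` summarise the per-VOI means;
    ``dmax`` is the largest absolute deviation of a VOI mean from ``mean``.
    """

    slice_region: str
    protocol: str
    entity: str
    voi_means: tuple[float, ...]
    mean: float
    sd: float
    minimum: float
    maximum: float
    dmax: float


@dataclass(frozen=True)
class QualityMetrics:
    slice_region: str
    protocol: str
    snr: float
    cnr: float
    din: float


@dataclass(frozen=True)
class QualityRatios:
    """Quick/Regular per-metric ratios.

    ``ratios`` divides the unrounded metrics.  ``rounded`` follows the report
    convention: each metric is first rounded to 2 decimals, the quotient of the
    rounded metrics is then itself rounded to 2 decimals (half up).
    """

    slice_region: str
    quick_protocol: str
    regular_protocol: str
    ratios: dict[str, float]
    rounded: dict[str, float]


# ---------------------------------------------------------------------------
# VOI extraction
# ---------------------------------------------------------------------------

def ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], diameter: float
) -> np.ndarray:
    """Boolean mask of pixels whose centres lie inside the inscribed ellipse.

    With a half-integer centre a diameter-6 VOI selects 32 pixels; with an
    integer centre, 29.
    """
    rows, cols = shape
    cx, cy = center
    r = diameter / 2.0
    y, x = np.mgrid[0:rows, 0:cols]
    # boundary inclusive; tiny relative slack guards against float representation
    return ((x - cx) ** 2 + (y - cy) ** 2) <= (r * r) * (1 + 1e-12)


def extract_voi(
    image: np.ndarray,
    spec: VoiSpec,
    pixel_spacing: tuple[float, float] | None = None,
) -> VoiStats:
    """Statistics of the pixels selected by ``spec`` on a 2-D HU image."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    rows, cols = arr.shape
    cx, cy = spec.center
    r = spec.diameter / 2.0
    if cx - r < -0.5 or cx + r > cols - 0.5 or cy - r < -0.5 or cy + r > rows - 0.5:
        raise ValueError(
            f"VOI {spec.voi_id!r} (center {spec.center}, diameter {spec.diameter}) "
            f"exceeds image bounds {arr.shape}"
        )
    mask = ellipse_mask(arr.shape, spec.center, spec.diameter)
    pixels = arr[mask]
    if pixels.size == 0:
        raise ValueError(f"VOI {spec.voi_id!r} selects zero pixels")
    n = int(pixels.size)
    area_mm2 = None
    if pixel_spacing is not None:
        area_mm2 = n * float(pixel_spacing[0]) * float(pixel_spacing[1])
    return VoiStats(
        voi_id=spec.voi_id,
        n_pixels=n,
        area_px2=float(n),
        area_mm2=area_mm2,
        minimum=float(pixels.min()),
        maximum=float(pixels.max()),
        mean=float(pixels.mean()),
        sd=sample_sd(pixels),
        slice_region=spec.slice_region,
        protocol=spec.protocol,
        entity=spec.entity,
    )


# ---------------------------------------------------------------------------
# aggregation and metrics
# ---------------------------------------------------------------------------

def _unique_label(stats: Sequence[VoiStats], attr: str) -> str | None:
    labels = {getattr(s, attr) for s in stats if getattr(s, attr) is not None}
    if len(labels) > 1:
        raise ValueError(f"VOI group mixes {attr} labels: {sorted(labels)}")
    return labels.pop() if labels else None


def aggregate_entity(stats: Sequence[VoiStats]) -> EntityAggregate:
    """Aggregate the per-VOI means of one slice_region x protocol x entity."""
    if not stats:
        raise ValueError("cannot aggregate an empty VOI group")
    region = _unique_label(stats, "slice_region")
    protocol = _unique_label(stats, "protocol")
    entity = _unique_label(stats, "entity")
    means = tuple(s.mean for s in stats)
    if len(means) == 1:
        logger.warning(
            "entity aggregate for %s/%s/%s built from a single VOI; sd set to 0",
            region, protocol, entity,
        )
    mean = float(np.mean(means))
    return EntityAggregate(
        slice_region=region or "",
        protocol=protocol or "",
        entity=entity or "",
        voi_means=means,
        mean=mean,
        sd=sample_sd(means),
        minimum=min(means),
        maximum=max(means),
        dmax=float(max(abs(m - mean) for m in means)),
    )


def snr(bone: EntityAggregate, soft: EntityAggregate) -> float:
    """Signal-to-noise ratio: bone aggregate mean over soft-tissue between-VOI SD."""
    if soft.sd <= 0:
        raise ValueError("undefined SNR (zero noise): soft-tissue SD is 0")
    return bone.mean / soft.sd


def cnr(bone: EntityAggregate, soft: EntityAggregate) -> float:
    """Contrast-to-noise ratio: |bone - soft| contrast over soft-tissue SD."""
    if soft.sd <= 0:
        raise ValueError("undefined CNR (zero noise): soft-tissue SD is 0")
    return abs(bone.mean - soft.mean) / soft.sd


def din(bone: EntityAggregate, soft: EntityAggregate) -> float:
    """DIN uniformity index: contrast |P1 - P2| over the soft-tissue Dmax."""
    if soft.dmax <= 0:
        raise ValueError("undefined DIN: soft-tissue Dmax is 0")
    return abs(bone.mean - soft.mean) / soft.dmax


def compute_quality(bone: EntityAggregate, soft: EntityAggregate) -> QualityMetrics:
    """All three metrics for one slice region x protocol."""
    if bone.slice_region != soft.slice_region or bone.protocol != soft.protocol:
        raise ValueError(
            "bone and soft aggregates must share slice_region and protocol"
        )
    return QualityMetrics(
        slice_region=bone.slice_region,
        protocol=bone.protocol,
        snr=snr(bone, soft),
        cnr=cnr(bone, soft),
        din=din(bone, soft),
    )


def quality_ratio(quick: QualityMetrics, regular: QualityMetrics) -> QualityRatios:
    """Quick/Regular ratio per metric (unrounded and report-rounded)."""
    if quick.slice_region != regular.slice_region:
        raise ValueError("metrics to be ratioed must share slice_region")
    ratios: dict[str, float] = {}
    rounded: dict[str, float] = {}
    for name in METRICS:
        q = getattr(quick, name)
        r = getattr(regular, name)
        if r <= 0:
            raise ValueError(f"regular {name.upper()} must be > 0, got {r}")
        ratios[name] = q / r
        rounded[name] = round_half_up(round_half_up(q, 2) / round_half_up(r, 2), 2)
    return QualityRatios(
        slice_region=quick.slice_region,
        quick_protocol=quick.protocol,
        regular_protocol=regular.protocol,
        ratios=ratios,
        rounded=rounded,
    )


def uniformity_profile(aggregates: Sequence[EntityAggregate]) -> pd.DataFrame:
    """Per-entity mean +/- SD table, ordered by slice region then protocol.

    The ``sd`` column doubles as the noise estimate; no smoothing is applied.
    """
    if not aggregates:
        raise ValueError("no aggregates supplied")
    region_order = list(dict.fromkeys(a.slice_region for a in aggregates))
    protocol_order = list(dict.fromkeys(a.protocol for a in aggregates))
    entity_order = [e for e in ENTITIES if any(a.entity == e for a in aggregates)]
    entity_order += [a.entity for a in aggregates if a.entity not in entity_order]

    def key(a: EntityAggregate):
        return (
            region_order.index(a.slice_region),
            protocol_order.index(a.protocol),
            entity_order.index(a.entity),
        )

    rows = [
        {
            "slice_region": a.slice_region,
            "protocol": a.protocol,
            "entity": a.entity,
            "mean": a.mean,
            "sd": a.sd,
        }
        for a in sorted(aggregates, key=key)
    ]
    return pd.DataFrame(rows, columns=["slice_region", "protocol", "entity", "mean", "sd"])


def plot_uniformity_profile(profile: pd.DataFrame, path=None):
    """Optional errorbar figure of the uniformity profile (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for (entity, protocol), grp in profile.groupby(["entity", "protocol"], sort=False):
        ax.errorbar(
            grp["slice_region"],
            grp["mean"],
            yerr=grp["sd"],
            marker="o",
            capsize=3,
            linestyle="--" if "quick" in protocol else "-",
            label=f"{entity} / {protocol}",
        )
    ax.set_xlabel("slice region")
    ax.set_ylabel("mean pixel value (HU)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
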