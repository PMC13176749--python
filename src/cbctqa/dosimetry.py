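"""Thermoluminescent-dosimeter (TLD) data reduction and ICRP-103 effective dose.

The reduction chain mirrors standard phantom dosimetry practice:

1. :func:`subtract_background` — average the dedicated background dosimeters and
   subtract that mean from every field read-out (after applying each chip's
   element correction coefficient, ECC).
2. :func:`aggregate_region` — merge the corrected read-outs sharing one
   anatomical region and protocol into a mean ± sample SD absorbed dose.
3. :func:`effective_dose` — ED = Σ wT · D_T over regions with a tissue
   weighting factor; regions marked :data:`EXCLUDED` contribute nothing.

Protocol-comparison statistics (:func:`dose_reduction`, :func:`lateral_ratio`,
:func:`average_absorbed_dose`, :func:`exposure_summary`) operate on the
aggregated objects.  All doses are in mSv; for the diagnostic photon energies
involved the radiation weighting factor is 1, so absorbed dose in mGy and
equivalent dose in mSv are numerically interchangeable.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from ._common import round_half_up, sample_sd

logger = logging.getLogger(__name__)

BACKGROUND_REGION = "background"


class _Excluded:
    """Marker for a region deliberately left out of the effective-dose sum."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "EXCLUDED"


EXCLUDED = _Excluded()


@dataclass(frozen=True)
class TldReadout:
    """One dosimeter reading tied to a region and protocol.

    ``value`` is the read-out in mSv.  ``correction_coefficient`` is the
    chip-specific ECC, an abstract multiplicative calibration factor.
    ``background_corrected`` marks values that have already had the background
    mean removed (those may legitimately be negative).
    """

    dosimeter_id: str
    region: str
    protocol: str
    value: float
    correction_coefficient: float = 1.0
    background_corrected: bool = False

    def __post_init__(self) -> None:
        if self.correction_coefficient <= 0:
            raise ValueError(
                f"correction_coefficient must be > 0, got "
                f"{self.correction_coefficient} for {self.dosimeter_id!r}"
            )
        if not self.background_corrected and self.value < 0:
            raise ValueError(
                f"raw read-out must be >= 0, got {self.value} for {self.dosimeter_id!r}"
            )

    @property
    def is_background(self) -> bool:
        return self.region == BACKGROUND_REGION


@dataclass(frozen=True)
class BackgroundSummary:
    """Mean/SD of the dedicated background dosimeters, in mSv."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class RegionDose:
    """Aggregated absorbed dose for one anatomical region under one protocol."""

    region: str
    protocol: str
    values: tuple[float, ...]
    mean: float
    sd: float
    minimum: float
    maximum: float

    @classmethod
    def from_values(cls, region: str, protocol: str, values: Sequence[float]) -> "RegionDose":
        if len(values) == 0:
            raise ValueError(f"no dose values for region {region!r}")
        vals = tuple(float(v) for v in values)
        return cls(
            region=region,
            protocol=protocol,
            values=vals,
            mean=float(np.mean(vals)),
            sd=sample_sd(vals),
            minimum=min(vals),
            maximum=max(vals),
        )

    def __post_init__(self) -> None:
        eps = 1e-9
        if not (self.minimum - eps <= self.mean <= self.maximum + eps):
            raise ValueError(
                f"inconsistent RegionDose for {self.region!r}: "
                f"min {self.minimum} <= mean {self.mean} <= max {self.maximum} violated"
            )


@dataclass(frozen=True)
class TissueWeighting:
    """Mapping region -> ICRP-103 tissue weighting factor wT (or EXCLUDED).

    The factor set is never renormalised: :meth:`validate` reports a warning
    when the non-excluded factors do not sum to 1, but leaves them untouched.
    """

    entries: Mapping[str, Union[float, _Excluded]]
    name: str = "custom"

    def __post_init__(self) -> None:
        for region, w in self.entries.items():
            if w is not EXCLUDED and (not math.isfinite(float(w)) or float(w) < 0):
                raise ValueError(f"weighting factor for {region!r} must be >= 0, got {w}")

    def __contains__(self, region: str) -> bool:
        return region in self.entries

    def factor(self, region: str) -> Union[float, _Excluded]:
        try:
            return self.entries[region]
        except KeyError:
            raise KeyError(
                f"region {region!r} is absent from weighting table {self.name!r}"
            ) from None

    def weight_sum(self) -> float:
        return float(sum(w for w in self.entries.values() if w is not EXCLUDED))

    def excluded_regions(self) -> list[str]:
        return [r for r, w in self.entries.items() if w is EXCLUDED]

    def validate(self) -> list[str]:
        """Return (and log) human-readable warnings about this factor set."""
        warnings: list[str] = []
        total = self.weight_sum()
        if abs(total - 1.0) > 1e-6:
            warnings.append(
                f"tissue weighting factors of {self.name!r} sum to {total:g}, not 1.0; "
                "factors are used as-is (no renormalisation)"
            )
        for region in self.excluded_regions():
            warnings.append(
                f"region {region!r} has no weighting factor and is excluded from the "
                "effective dose"
            )
        for msg in warnings:
            logger.warning(msg)
        return warnings


#: Scanner-reported dose indices eligible for the exposure comparison.
DOSE_INDICES = (
    "exposure_time_s",
    "mas",
    "air_kerma_mgy",
    "dap_mgy_cm2",
    "dlp_mgy_cm",
    "ctdi_w_mgy",
    "ctdi_vol_mgy",
)


@dataclass(frozen=True)
class ExposureRecord:
    """Scanner output indices for one protocol (all optional except the name)."""

    protocol: str
    kv: float | None = None
    tube_current_ma: float | None = None
    exposure_time_s: float | None = None
    mas: float | None = None
    air_kerma_mgy: float | None = None
    dap_mgy_cm2: float | None = None
    dlp_mgy_cm: float | None = None
    ctdi_w_mgy: float | None = None
    ctdi_vol_mgy: float | None = None

    def __post_init__(self) -> None:
        if (
            self.tube_current_ma is not None
            and self.exposure_time_s is not None
            and self.mas is not None
        ):
            expected = self.tube_current_ma * self.exposure_time_s
            if abs(expected - self.mas) > 1e-9:
                raise ValueError(
                    f"inconsistent exposure record for {self.protocol!r}: "
                    f"mA x s = {expected!r} but mAs = {self.mas!r}"
                )


@dataclass(frozen=True)
class ExposureSummary:
    """Per-index reduction (%) between two exposure records plus the average."""

    reference_protocol: str
    comparison_protocol: str
    per_index: Mapping[str, float]
    average: float


@dataclass
class DoseReport:
    """Full dosimetry result for one protocol."""

    protocol: str
    region_doses: list[RegionDose]
    effective_dose: float
    average_absorbed_dose: float
    background_mean: float
    background_sd: float
    weighting_name: str = "custom"
    warnings: list[str] = field(default_factory=list)

    def verify(self, weights: TissueWeighting, atol: float = 1e-9) -> None:
        """Check the stored ED against a recomputation from region_doses."""
        recomputed = effective_dose(self.region_doses, weights)
        if abs(recomputed - self.effective_dose) > atol:
            raise ValueError(
                f"DoseReport for {self.protocol!r} is inconsistent: stored ED "
                f"{self.effective_dose!r} vs recomputed {recomputed!r}"
            )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def subtract_background(
    readouts: Sequence[TldReadout],
    policy: str = "allow_negative",
) -> tuple[list[TldReadout], BackgroundSummary]:
    """Apply per-chip ECC then subtract the mean background from field read-outs.

    The ECC is applied before background subtraction (calibration precedes field
    use).  ``policy`` is ``"allow_negative"`` (default: keep negative corrected
    values, warn) or ``"clamp"`` (floor them at 0, warn).  Background read-outs
    are consumed and do not appear in the output list.
    """
    if policy not in ("allow_negative", "clamp"):
        raise ValueError(f"unknown background policy {policy!r}")
    if not readouts:
        raise ValueError("no read-outs supplied")
    background = [r for r in readouts if r.is_background]
    fields = [r for r in readouts if not r.is_background]
    if not background:
        raise ValueError("missing background: no read-outs labelled 'background'")
    if not fields:
        raise ValueError("no non-background read-outs supplied")

    bg_values = [r.correction_coefficient * r.value for r in background]
    summary = BackgroundSummary(
        mean=float(np.mean(bg_values)), sd=sample_sd(bg_values), n=len(bg_values)
    )

    corrected: list[TldReadout] = []
    for r in fields:
        value = r.correction_coefficient * r.value - summary.mean
        if value < 0:
            if policy == "clamp":
                logger.warning(
                    "corrected dose for %s (%s) was %.6g mSv; clamped to 0",
                    r.dosimeter_id, r.region, value,
                )
                value = 0.0
            else:
                logger.warning(
                    "corrected dose for %s (%s) is negative (%.6g mSv); kept",
                    r.dosimeter_id, r.region, value,
                )
        corrected.append(
            replace(
                r,
                value=value,
                correction_coefficient=1.0,
                background_corrected=True,
            )
        )
    return corrected, summary


def aggregate_region(readouts: Sequence[TldReadout]) -> RegionDose:
    """Merge corrected read-outs of one region+protocol into a RegionDose."""
    if not readouts:
        raise ValueError("cannot aggregate an empty read-out group")
    regions = {r.region for r in readouts}
    protocols = {r.protocol for r in readouts}
    if len(regions) > 1 or len(protocols) > 1:
        raise ValueError(
            f"read-out group mixes regions/protocols: {sorted(regions)} / {sorted(protocols)}"
        )
    return RegionDose.from_values(
        region=readouts[0].region,
        protocol=readouts[0].protocol,
        values=[r.value for r in readouts],
    )


def effective_dose(
    region_doses: Iterable[RegionDose], weights: TissueWeighting
) -> float:
    """ED = Σ wT × mean dose over regions carrying a weighting factor (mSv)."""
    total = 0.0
    for rd in region_doses:
        w = weights.factor(rd.region)  # KeyError with region name if absent
        if w is EXCLUDED:
            logger.info(
                "region %r excluded from effective dose (no weighting factor)",
                rd.region,
            )
            continue
        total += float(w) * rd.mean
    return total


def _as_scalar(x: Union[RegionDose, DoseReport, float]) -> float:
    if isinstance(x, RegionDose):
        return x.mean
    if isinstance(x, DoseReport):
        return x.effective_dose
    return float(x)


def dose_reduction(
    reference: Union[RegionDose, DoseReport, float],
    comparison: Union[RegionDose, DoseReport, float],
) -> float:
    """Percent reduction 100·(ref − cmp)/ref; negative when cmp exceeds ref."""
    ref = _as_scalar(reference)
    cmp_ = _as_scalar(comparison)
    if ref <= 0:
        raise ValueError(f"reference dose must be > 0, got {ref}")
    return 100.0 * (ref - cmp_) / ref


@dataclass(frozen=True)
class LateralRatio:
    """Right/left mean-dose ratio for one paired structure."""

    structure: str
    protocol: str
    value: float
    rounded: float  # 1 decimal, report convention


def lateral_ratio(right: RegionDose, left: RegionDose) -> LateralRatio:
    """Right-to-left mean absorbed dose ratio (dimensionless)."""
    if left.mean <= 0:
        raise ValueError(f"left mean dose must be > 0, got {left.mean}")
    structure = right.region
    for prefix in ("right_", "left_"):
        if structure.startswith(prefix):
            structure = structure[len(prefix):]
    value = right.mean / left.mean
    return LateralRatio(
        structure=structure,
        protocol=right.protocol,
        value=value,
        rounded=round_half_up(value, 1),
    )


def average_absorbed_dose(region_doses: Sequence[RegionDose]) -> float:
    """Unweighted arithmetic mean of the region mean doses (mSv).

    Every measured region contributes, including regions excluded from the
    effective dose.
    """
    if not region_doses:
        raise ValueError("no region doses supplied")
    return float(np.mean([rd.mean for rd in region_doses]))


def exposure_summary(
    regular: ExposureRecord, quick: ExposureRecord
) -> ExposureSummary:
    """Per-index percent reduction between two exposure records + average."""
    per_index: dict[str, float] = {}
    for name in DOSE_INDICES:
        ref = getattr(regular, name)
        cmp_ = getattr(quick, name)
        if ref is None or cmp_ is None:
            continue
        if ref <= 0:
            raise ValueError(f"reference index {name!r} must be > 0, got {ref}")
        per_index[name] = 100.0 * (ref - cmp_) / ref
    if not per_index:
        raise ValueError(
            f"no shared populated dose indices between {regular.protocol!r} "
            f"and {quick.protocol!r}"
        )
    return ExposureSummary(
        reference_protocol=regular.protocol,
        comparison_protocol=quick.protocol,
        per_index=per_index,
        average=float(np.mean(list(per_index.values()))),
    )
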