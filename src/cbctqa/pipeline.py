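"""End-to-end orchestration of the two-protocol comparison.

``run_dose_stage`` executes the dosimetry chain (background subtraction ->
region aggregation -> effective dose -> comparison statistics);
``run_iq_stage`` executes the image-quality chain (VOI ingest or extraction ->
entity aggregation -> SNR/CNR/DIN -> ratios -> uniformity profile);
``run_compare`` composes both and emits CSV + JSON reports.

Report rounding convention: doses 3 decimals, percentages 2, metrics 2,
ratios 2 (1 for lateral dose ratios) — half up; unrounded values are always
retained in the JSON report.  Reports are self-checked on emission: every
derived number must be recomputable from the embedded inputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from ._common import round_half_up
from .dosimetry import (
    BackgroundSummary,
    DoseReport,
    ExposureRecord,
    ExposureSummary,
    LateralRatio,
    RegionDose,
    TissueWeighting,
    TldReadout,
    aggregate_region,
    average_absorbed_dose,
    dose_reduction,
    effective_dose,
    exposure_summary,
    lateral_ratio,
    subtract_background,
)
from .image_quality import (
    EntityAggregate,
    QualityMetrics,
    QualityRatios,
    VoiSpec,
    VoiStats,
    aggregate_entity,
    compute_quality,
    extract_voi,
    quality_ratio,
    uniformity_profile,
)

logger = logging.getLogger(__name__)


@dataclass
class DoseStageResult:
    reports: dict[str, DoseReport]
    background: BackgroundSummary
    reference_protocol: str
    #: comparison protocol -> region -> reduction %
    per_region_reduction: dict[str, dict[str, float]]
    #: comparison protocol -> effective-dose reduction %
    ed_reduction: dict[str, float]
    #: comparison protocol -> mean-absorbed-dose reduction %
    mean_dose_reduction: dict[str, float]
    #: protocol -> lateral right/left ratios
    lateral_ratios: dict[str, list[LateralRatio]]
    warnings: list[str] = field(default_factory=list)


@dataclass
class IqStageResult:
    aggregates: list[EntityAggregate]
    #: (slice_region, protocol) -> metrics
    metrics: dict[tuple[str, str], QualityMetrics]
    #: slice_region -> quick/regular ratios (only when exactly two protocols)
    ratios: dict[str, QualityRatios]
    profile: "object"  # pandas DataFrame
    reference_protocol: str
    warnings: list[str] = field(default_factory=list)


def _ordered_unique(items) -> list:
    return list(dict.fromkeys(items))


def run_dose_stage(
    readouts: list[TldReadout],
    weighting: TissueWeighting,
    policy: str = "allow_negative",
    reference_protocol: str | None = None,
    known_regions: list[str] | None = None,
) -> DoseStageResult:
    """Reduce raw TLD read-outs to per-protocol dose reports and comparisons."""
    warnings: list[str] = list(weighting.validate())
    if known_regions is not None:
        bad = sorted(
            {r.region for r in readouts}
            - set(known_regions) - {"background"}
        )
        if bad:
            raise ValueError(f"read-outs reference unknown region(s): {bad}")

    corrected, background = subtract_background(readouts, policy=policy)
    negatives = [r for r in corrected if r.value < 0]
    if negatives:
        warnings.append(
            f"{len(negatives)} corrected dose(s) are negative under "
            f"policy={policy!r}: " + ", ".join(r.dosimeter_id for r in negatives)
        )

    protocols = _ordered_unique(r.protocol for r in corrected)
    if reference_protocol is None:
        reference_protocol = protocols[0]
    elif reference_protocol not in protocols:
        raise ValueError(
            f"reference protocol {reference_protocol!r} not among {protocols}"
        )

    reports: dict[str, DoseReport] = {}
    for protocol in protocols:
        chips = [r for r in corrected if r.protocol == protocol]
        regions = _ordered_unique(r.region for r in chips)
        region_doses = [
            aggregate_region([r for r in chips if r.region == region])
            for region in regions
        ]
        ed = effective_dose(region_doses, weighting)
        reports[protocol] = DoseReport(
            protocol=protocol,
            region_doses=region_doses,
            effective_dose=ed,
            average_absorbed_dose=average_absorbed_dose(region_doses),
            background_mean=background.mean,
            background_sd=background.sd,
            weighting_name=weighting.name,
        )

    # conservation: every read-out is either background or inside a report
    accounted = background.n + sum(
        len(rd.values) for rep in reports.values() for rd in rep.region_doses
    )
    if accounted != len(readouts):
        raise RuntimeError(
            f"read-out conservation violated: {len(readouts)} in, {accounted} accounted"
        )

    per_region: dict[str, dict[str, float]] = {}
    ed_red: dict[str, float] = {}
    mean_red: dict[str, float] = {}
    ref_report = reports[reference_protocol]
    ref_by_region = {rd.region: rd for rd in ref_report.region_doses}
    for protocol in protocols:
        if protocol == reference_protocol:
            continue
        cmp_report = reports[protocol]
        per_region[protocol] = {
            rd.region: dose_reduction(ref_by_region[rd.region], rd)
            for rd in cmp_report.region_doses
            if rd.region in ref_by_region and ref_by_region[rd.region].mean > 0
        }
        ed_red[protocol] = dose_reduction(ref_report, cmp_report)
        mean_red[protocol] = dose_reduction(
            ref_report.average_absorbed_dose, cmp_report.average_absorbed_dose
        )
    if len(protocols) == 1:
        warnings.append(
            "single protocol supplied; no protocol-comparison statistics computed"
        )

    laterals: dict[str, list[LateralRatio]] = {}
    for protocol, report in reports.items():
        by_region = {rd.region: rd for rd in report.region_doses}
        pairs = []
        for region in by_region:
            if region.startswith("right_"):
                left = "left_" + region[len("right_"):]
                if left in by_region and by_region[left].mean > 0:
                    pairs.append(lateral_ratio(by_region[region], by_region[left]))
        if pairs:
            laterals[protocol] = pairs

    return DoseStageResult(
        reports=reports,
        background=background,
        reference_protocol=reference_protocol,
        per_region_reduction=per_region,
        ed_reduction=ed_red,
        mean_dose_reduction=mean_red,
        lateral_ratios=laterals,
        warnings=warnings,
    )


def extract_from_slices(
    slices: list[dict], voi_specs: list[VoiSpec]
) -> list[VoiStats]:
    """Extract VOI statistics from DICOM slices listed in a manifest.

    Each manifest entry (slice_region, protocol, path) consumes the VOI specs
    sharing its slice_region and protocol.
    """
    from .io_formats import read_dicom_slice

    stats: list[VoiStats] = []
    used = set()
    for entry in slices:
        image, meta = read_dicom_slice(entry["path"])
        matching = [
            s for s in voi_specs
            if s.slice_region == entry["slice_region"]
            and s.protocol == entry["protocol"]
        ]
        if not matching:
            logger.warning(
                "no VOI specs for slice %s/%s", entry["slice_region"], entry["protocol"]
            )
        for spec in matching:
            stats.append(extract_voi(image, spec, meta.get("pixel_spacing_mm")))
            used.add(id(spec))
    unused = [s.voi_id for s in voi_specs if id(s) not in used]
    if unused:
        raise ValueError(f"VOI spec(s) matched no slice: {unused}")
    return stats


def run_iq_stage(
    voi_stats: list[VoiStats],
    reference_protocol: str | None = None,
) -> IqStageResult:
    """Aggregate VOI statistics and compute the quality metrics and ratios."""
    if not voi_stats:
        raise ValueError("no VOI statistics supplied")
    unlabeled = [s.voi_id for s in voi_stats
                 if not (s.slice_region and s.protocol and s.entity)]
    if unlabeled:
        raise ValueError(
            f"VOI statistics without slice_region/protocol/entity labels: {unlabeled}"
        )
    warnings: list[str] = []
    groups = _ordered_unique(
        (s.slice_region, s.protocol, s.entity) for s in voi_stats
    )
    aggregates = [
        aggregate_entity(
            [s for s in voi_stats
             if (s.slice_region, s.protocol, s.entity) == key]
        )
        for key in groups
    ]
    by_key = {(a.slice_region, a.protocol, a.entity): a for a in aggregates}

    protocols = _ordered_unique(a.protocol for a in aggregates)
    if reference_protocol is None:
        reference_protocol = protocols[0]
    elif reference_protocol not in protocols:
        raise ValueError(
            f"reference protocol {reference_protocol!r} not among {protocols}"
        )

    metrics: dict[tuple[str, str], QualityMetrics] = {}
    for region in _ordered_unique(a.slice_region for a in aggregates):
        for protocol in protocols:
            bone = by_key.get((region, protocol, "bone"))
            soft = by_key.get((region, protocol, "soft_tissue"))
            if bone is None or soft is None:
                warnings.append(
                    f"{region}/{protocol}: bone or soft-tissue aggregate missing; "
                    "metrics skipped"
                )
                continue
            metrics[(region, protocol)] = compute_quality(bone, soft)

    ratios: dict[str, QualityRatios] = {}
    if len(protocols) == 2:
        other = next(p for p in protocols if p != reference_protocol)
        for region in _ordered_unique(r for r, _p in metrics):
            reg = metrics.get((region, reference_protocol))
            quick = metrics.get((region, other))
            if reg is not None and quick is not None:
                ratios[region] = quality_ratio(quick, reg)
    elif len(protocols) == 1:
        warnings.append("single protocol supplied; no quality ratios computed")

    return IqStageResult(
        aggregates=aggregates,
        metrics=metrics,
        ratios=ratios,
        profile=uniformity_profile(aggregates),
        reference_protocol=reference_protocol,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# full comparison report
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    dose: DoseStageResult
    iq: IqStageResult | None = None
    exposure: ExposureSummary | None = None

    @property
    def warnings(self) -> list[str]:
        out = list(self.dose.warnings)
        if self.iq is not None:
            out.extend(self.iq.warnings)
        return out

    def verify(self, weighting: TissueWeighting) -> None:
        """Self-consistency: every derived number recomputes from its inputs."""
        for report in self.dose.reports.values():
            report.verify(weighting)
        ref = self.dose.reports[self.dose.reference_protocol]
        for protocol, value in self.dose.ed_reduction.items():
            expected = dose_reduction(ref, self.dose.reports[protocol])
            if abs(expected - value) > 1e-9:
                raise ValueError("ED reduction inconsistent with its inputs")
        if self.iq is not None:
            for (region, protocol), m in self.iq.metrics.items():
                by_key = {
                    (a.slice_region, a.protocol, a.entity): a
                    for a in self.iq.aggregates
                }
                recomputed = compute_quality(
                    by_key[(region, protocol, "bone")],
                    by_key[(region, protocol, "soft_tissue")],
                )
                if abs(recomputed.snr - m.snr) > 1e-9:
                    raise ValueError("quality metrics inconsistent with aggregates")

    def to_dict(self) -> dict:
        dose = self.dose
        payload: dict = {
            "package": {"name": "cbctqa", "version": __version__},
            "dose": {
                "background_mSv": {
                    "mean": dose.background.mean,
                    "sd": dose.background.sd,
                    "n": dose.background.n,
                },
                "reference_protocol": dose.reference_protocol,
                "protocols": {
                    protocol: {
                        "effective_dose_mSv": report.effective_dose,
                        "average_absorbed_dose_mSv": report.average_absorbed_dose,
                        "weighting": report.weighting_name,
                        "regions": {
                            rd.region: {
                                "values_mSv": list(rd.values),
                                "mean_mSv": rd.mean,
                                "sd_mSv": rd.sd,
                                "min_mSv": rd.minimum,
                                "max_mSv": rd.maximum,
                            }
                            for rd in report.region_doses
                        },
                    }
                    for protocol, report in dose.reports.items()
                },
                "reductions_pct": {
                    "effective_dose": dose.ed_reduction,
                    "average_absorbed_dose": dose.mean_dose_reduction,
                    "per_region": dose.per_region_reduction,
                },
                "lateral_ratios": {
                    protocol: {
                        lr.structure: {"value": lr.value, "rounded": lr.rounded}
                        for lr in ratios
                    }
                    for protocol, ratios in dose.lateral_ratios.items()
                },
            },
            "warnings": self.warnings,
        }
        if self.exposure is not None:
            payload["exposure"] = {
                "reference_protocol": self.exposure.reference_protocol,
                "comparison_protocol": self.exposure.comparison_protocol,
                "per_index_reduction_pct": dict(self.exposure.per_index),
                "average_reduction_pct": self.exposure.average,
            }
        if self.iq is not None:
            iq = self.iq
            payload["image_quality"] = {
                "reference_protocol": iq.reference_protocol,
                "aggregates": [
                    {
                        "slice_region": a.slice_region,
                        "protocol": a.protocol,
                        "entity": a.entity,
                        "voi_means": list(a.voi_means),
                        "mean": a.mean,
                        "sd": a.sd,
                        "min": a.minimum,
                        "max": a.maximum,
                        "dmax": a.dmax,
                    }
                    for a in iq.aggregates
                ],
                "metrics": {
                    f"{region}/{protocol}": {
                        "snr": m.snr, "cnr": m.cnr, "din": m.din
                    }
                    for (region, protocol), m in iq.metrics.items()
                },
                "ratios": {
                    region: {
                        "unrounded": dict(r.ratios),
                        "rounded": dict(r.rounded),
                    }
                    for region, r in iq.ratios.items()
                },
                "uniformity_profile": iq.profile.to_dict(orient="records"),
            }
        return payload

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_dose_csv(self, path) -> None:
        import csv

        dose = self.dose
        protocols = list(dose.reports)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["region", "protocol", "minimum_mSv", "maximum_mSv",
                        "mean_mSv", "sd_mSv", "dose_reduction_pct"])
            ref = dose.reports[dose.reference_protocol]
            regions = [rd.region for rd in ref.region_doses]
            for region in regions:
                for protocol in protocols:
                    by_region = {
                        rd.region: rd for rd in dose.reports[protocol].region_doses
                    }
                    rd = by_region.get(region)
                    if rd is None:
                        continue
                    reduction = ""
                    if protocol != dose.reference_protocol:
                        val = dose.per_region_reduction.get(protocol, {}).get(region)
                        if val is not None:
                            reduction = f"{round_half_up(val, 2):.2f}"
                    w.writerow([
                        region, protocol,
                        f"{round_half_up(rd.minimum, 3):.3f}",
                        f"{round_half_up(rd.maximum, 3):.3f}",
                        f"{round_half_up(rd.mean, 3):.3f}",
                        f"{round_half_up(rd.sd, 3):.3f}",
                        reduction,
                    ])
            for protocol in protocols:
                report = dose.reports[protocol]
                reduction = ""
                if protocol != dose.reference_protocol and protocol in dose.ed_reduction:
                    reduction = f"{round_half_up(dose.ed_reduction[protocol], 2):.2f}"
                w.writerow([
                    "effective_dose", protocol, "", "",
                    f"{round_half_up(report.effective_dose, 3):.3f}", "", reduction,
                ])
            w.writerow([
                "background", "-", "", "",
                f"{round_half_up(dose.background.mean, 3):.3f}",
                f"{round_half_up(dose.background.sd, 3):.3f}", "",
            ])

    def write_quality_csv(self, path) -> None:
        if self.iq is None:
            raise ValueError("no image-quality stage in this report")
        write_quality_csv(self.iq, path)


def write_quality_csv(iq: IqStageResult, path) -> None:
    """Table-7-shaped CSV: region x metric with per-protocol values + ratio."""
    import csv

    protocols = _ordered_unique(p for _r, p in iq.metrics)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["slice_region", "metric"] + protocols + ["quick_regular_ratio"])
        for region in _ordered_unique(r for r, _p in iq.metrics):
            for metric in ("snr", "cnr", "din"):
                row = [region, metric]
                for protocol in protocols:
                    m = iq.metrics.get((region, protocol))
                    row.append(
                        "" if m is None
                        else f"{round_half_up(getattr(m, metric), 2):.2f}"
                    )
                ratio = iq.ratios.get(region)
                row.append("" if ratio is None else f"{ratio.rounded[metric]:.2f}")
                w.writerow(row)


def run_compare(
    readouts: list[TldReadout],
    weighting: TissueWeighting,
    voi_stats: list[VoiStats] | None = None,
    exposure: tuple[ExposureRecord, ExposureRecord] | None = None,
    policy: str = "allow_negative",
    reference_protocol: str | None = None,
) -> ComparisonReport:
    """Full pipeline: dose stage, optional image-quality stage, exposure summary."""
    dose = run_dose_stage(
        readouts, weighting, policy=policy, reference_protocol=reference_protocol
    )
    iq = None
    if voi_stats:
        iq = run_iq_stage(voi_stats)
    exp = exposure_summary(*exposure) if exposure is not None else None
    report = ComparisonReport(dose=dose, iq=iq, exposure=exp)
    report.verify(weighting)
    return report
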