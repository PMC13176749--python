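"""Readers and writers for every external format the pipeline touches.

CSV files are comma-separated UTF-8 with a mandatory header row and "." as the
decimal separator; readers accept ``decimal=","`` for locales that export with
a decimal comma.  All writers are deterministic: fixed column order, fixed
numeric formatting, LF line endings.  Readers validate the schema and raise
:class:`SchemaError` naming the offending field — no silent coercion.

DICOM support covers single-frame uncompressed grayscale slices; stored values
are mapped to HU through the standard rescale slope/intercept transform.
"""
from __future__ import annotations

import csv
import hashlib
import logging
import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid
import yaml

from .dosimetry import EXCLUDED, ExposureRecord, TissueWeighting, TldReadout
from .image_quality import VoiSpec, VoiStats

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A file violates the expected schema."""


def _read_table(path, required: tuple[str, ...], optional: tuple[str, ...] = (),
                decimal: str = ".", allow_extra: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, decimal=decimal, skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if not allow_extra:
        extra = [c for c in df.columns if c not in required + optional]
        if extra:
            raise SchemaError(f"{path}: unexpected column(s) {extra}")
    return df


def _fmt(x, ndigits: int | None = None) -> str:
    """Fixed, locale-independent numeric formatting for writers."""
    if x is None:
        return ""
    if ndigits is not None:
        return f"{x:.{ndigits}f}"
    return f"{float(x):.6g}"


def _open_write(path):
    return open(path, "w", encoding="utf-8", newline="")


# ---------------------------------------------------------------------------
# TLD read-outs
# ---------------------------------------------------------------------------

def read_tld_csv(path, decimal: str = ".") -> list[TldReadout]:
    """Columns: dosimeter_id, region, protocol, value_mSv[, ecc]."""
    df = _read_table(
        path,
        required=("dosimeter_id", "region", "protocol", "value_mSv"),
        optional=("ecc",),
        decimal=decimal,
    )
    readouts = []
    for idx, row in df.iterrows():
        if pd.isna(row["value_mSv"]):
            raise SchemaError(f"{path}: row {idx}: empty value_mSv")
        ecc = row.get("ecc", 1.0)
        readouts.append(
            TldReadout(
                dosimeter_id=str(row["dosimeter_id"]),
                region=str(row["region"]),
                protocol=str(row["protocol"]),
                value=float(row["value_mSv"]),
                correction_coefficient=1.0 if pd.isna(ecc) else float(ecc),
            )
        )
    if not readouts:
        logger.warning("%s: no TLD read-out rows", path)
    return readouts


def write_tld_csv(readouts, path) -> None:
    with _open_write(path) as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["dosimeter_id", "region", "protocol", "value_mSv", "ecc"])
        for r in readouts:
            w.writerow(
                [r.dosimeter_id, r.region, r.protocol, _fmt(r.value),
                 _fmt(r.correction_coefficient)]
            )


# ---------------------------------------------------------------------------
# tissue weighting table
# ---------------------------------------------------------------------------

def read_weighting_csv(path, decimal: str = ".", name: str | None = None) -> TissueWeighting:
    """Columns: region, wT.  An empty cell or "-" marks an excluded region."""
    df = pd.read_csv(path, decimal=decimal, skipinitialspace=True, dtype=str)
    df.columns = [str(c).strip() for c in df.columns]
    for col in ("region", "wT"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column(s) ['{col}']")
    entries: dict[str, object] = {}
    for idx, row in df.iterrows():
        region = str(row["region"]).strip()
        if region in entries:
            raise SchemaError(f"{path}: duplicate region {region!r}")
        raw = row["wT"]
        raw = "" if pd.isna(raw) else str(raw).strip()
        if raw in ("", "-"):
            entries[region] = EXCLUDED
        else:
            if decimal == ",":
                raw = raw.replace(",", ".")
            try:
                entries[region] = float(raw)
            except ValueError:
                raise SchemaError(
                    f"{path}: row {idx}: wT value {raw!r} is not a number, '-' or empty"
                ) from None
    table = TissueWeighting(entries=entries, name=name or Path(path).stem)
    table.validate()  # logs the weight-sum / exclusion warnings
    return table


def write_weighting_csv(table: TissueWeighting, path) -> None:
    with _open_write(path) as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["region", "wT"])
        for region, factor in table.entries.items():
            w.writerow([region, "-" if factor is EXCLUDED else _fmt(factor)])


# ---------------------------------------------------------------------------
# measure table (ImageJ-compatible)
# ---------------------------------------------------------------------------

_MEASURE_COLS = ("Label", "Area", "Mean", "StdDev", "Min", "Max")


def _parse_label(label: str) -> dict:
    """Labels of the form region:protocol:entity:voi_id carry VOI metadata."""
    parts = label.split(":")
    if len(parts) == 4:
        return {
            "slice_region": parts[0],
            "protocol": parts[1],
            "entity": parts[2],
            "voi_id": parts[3],
        }
    return {"slice_region": None, "protocol": None, "entity": None, "voi_id": label}


def read_measure_csv(path, decimal: str = ".") -> list[VoiStats]:
    """ImageJ-style measure table: Label, Area, Mean, StdDev, Min, Max."""
    df = _read_table(path, required=_MEASURE_COLS, decimal=decimal, allow_extra=True)
    stats = []
    for _, row in df.iterrows():
        meta = _parse_label(str(row["Label"]))
        stats.append(
            VoiStats(
                voi_id=meta["voi_id"],
                area_px2=float(row["Area"]),
                minimum=float(row["Min"]),
                maximum=float(row["Max"]),
                mean=float(row["Mean"]),
                sd=float(row["StdDev"]),
                slice_region=meta["slice_region"],
                protocol=meta["protocol"],
                entity=meta["entity"],
            )
        )
    if not stats:
        logger.warning("%s: measure table contains no rows", path)
    return stats


def write_measure_csv(stats, path) -> None:
    with _open_write(path) as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_MEASURE_COLS)
        for s in stats:
            if s.slice_region and s.protocol and s.entity:
                label = f"{s.slice_region}:{s.protocol}:{s.entity}:{s.voi_id}"
            else:
                label = s.voi_id
            w.writerow(
                [label, _fmt(s.area_px2), _fmt(s.mean), _fmt(s.sd),
                 _fmt(s.minimum), _fmt(s.maximum)]
            )


# ---------------------------------------------------------------------------
# VOI specs, exposure records, slice manifests
# ---------------------------------------------------------------------------

def read_voi_spec_csv(path, decimal: str = ".") -> list[VoiSpec]:
    """Columns: voi_id, slice_region, protocol, entity, center_x, center_y, diameter_px."""
    df = _read_table(
        path,
        required=("voi_id", "slice_region", "protocol", "entity",
                  "center_x", "center_y", "diameter_px"),
        decimal=decimal,
    )
    return [
        VoiSpec(
            voi_id=str(row["voi_id"]),
            slice_region=str(row["slice_region"]),
            protocol=str(row["protocol"]),
            entity=str(row["entity"]),
            center=(float(row["center_x"]), float(row["center_y"])),
            diameter=float(row["diameter_px"]),
        )
        for _, row in df.iterrows()
    ]


def write_voi_spec_csv(specs, path) -> None:
    with _open_write(path) as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["voi_id", "slice_region", "protocol", "entity",
                    "center_x", "center_y", "diameter_px"])
        for s in specs:
            w.writerow([s.voi_id, s.slice_region, s.protocol, s.entity,
                        _fmt(s.center[0]), _fmt(s.center[1]), _fmt(s.diameter)])


_EXPOSURE_COLS = {
    "protocol": "protocol",
    "kv": "kv",
    "ma": "tube_current_ma",
    "time_s": "exposure_time_s",
    "mas": "mas",
    "air_kerma_mGy": "air_kerma_mgy",
    "dap_mGy_cm2": "dap_mgy_cm2",
    "dlp_mGy_cm": "dlp_mgy_cm",
    "ctdi_w_mGy": "ctdi_w_mgy",
    "ctdi_vol_mGy": "ctdi_vol_mgy",
}


def read_exposure_csv(path, decimal: str = ".") -> list[ExposureRecord]:
    """One row per protocol; empty cells mean the index was not reported."""
    df = _read_table(
        path,
        required=("protocol",),
        optional=tuple(c for c in _EXPOSURE_COLS if c != "protocol"),
        decimal=decimal,
    )
    records = []
    for _, row in df.iterrows():
        kwargs = {"protocol": str(row["protocol"])}
        for col, attr in _EXPOSURE_COLS.items():
            if col == "protocol" or col not in df.columns:
                continue
            val = row[col]
            kwargs[attr] = None if pd.isna(val) else float(val)
        records.append(ExposureRecord(**kwargs))
    return records


def write_exposure_csv(records, path) -> None:
    cols = list(_EXPOSURE_COLS)
    with _open_write(path) as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(cols)
        for r in records:
            w.writerow(
                [r.protocol] + [_fmt(getattr(r, _EXPOSURE_COLS[c])) for c in cols[1:]]
            )


def read_slice_manifest(path, decimal: str = ".") -> list[dict]:
    """Columns: slice_region, protocol, path — one DICOM slice per row."""
    df = _read_table(path, required=("slice_region", "protocol", "path"), decimal=decimal)
    base = Path(path).parent
    out = []
    for _, row in df.iterrows():
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = base / p
        out.append(
            {"slice_region": str(row["slice_region"]),
             "protocol": str(row["protocol"]), "path": p}
        )
    return out


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_dicom_slice(path) -> tuple[np.ndarray, dict]:
    """Read a single-frame DICOM slice; return the HU array and metadata.

    Stored values pass through the rescale transform; when slope/intercept are
    absent, slope 1 / intercept 0 are assumed with a warning.
    """
    ds = pydicom.dcmread(path)
    if "PixelData" not in ds:
        raise SchemaError(f"{path}: DICOM file has no PixelData")
    tsuid = getattr(ds.file_meta, "TransferSyntaxUID", None)
    if tsuid is not None and tsuid.is_compressed:
        raise SchemaError(
            f"{path}: compressed transfer syntax {tsuid} is unsupported; "
            "transcode to Explicit VR Little Endian first"
        )
    if int(getattr(ds, "NumberOfFrames", 1)) != 1:
        raise SchemaError(f"{path}: multi-frame DICOM is unsupported")
    photometric = getattr(ds, "PhotometricInterpretation", "MONOCHROME2")
    if photometric not in ("MONOCHROME1", "MONOCHROME2"):
        raise SchemaError(
            f"{path}: unsupported photometric interpretation {photometric!r}"
        )
    arr = ds.pixel_array.astype(float)
    if "RescaleSlope" in ds and "RescaleIntercept" in ds:
        slope, intercept = float(ds.RescaleSlope), float(ds.RescaleIntercept)
    else:
        slope, intercept = 1.0, 0.0
        logger.warning("%s: missing rescale tags; assuming slope 1, intercept 0", path)
    hu = arr * slope + intercept

    spacing = None
    if "PixelSpacing" in ds:
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    bits = int(getattr(ds, "BitsStored", ds.BitsAllocated))
    meta = {
        "pixel_spacing_mm": spacing,
        "bits_stored": bits,
        "gray_levels": 2 ** bits - 1,
        "rows": int(ds.Rows),
        "cols": int(ds.Columns),
        "series_description": str(getattr(ds, "SeriesDescription", "")),
    }
    return hu, meta


def write_dicom_slice(
    image_hu: np.ndarray,
    path,
    pixel_spacing: tuple[float, float] = (0.127, 0.127),
    series_description: str = "cbctqa synthetic slice",
) -> None:
    """Write an integer-HU image as a secondary-capture-style DICOM slice.

    Storage is unsigned 16-bit with rescale intercept -1000 / slope 1, so HU in
    [-1000, 64535] round-trip exactly.  Output is byte-deterministic: UIDs are
    derived from the pixel content and dates are fixed.
    """
    arr = np.asarray(image_hu)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    rounded = np.rint(arr)
    if not np.allclose(arr, rounded, atol=1e-6):
        logger.warning("image contains non-integer HU values; rounding for storage")
    stored = rounded + 1000.0
    if stored.min() < 0 or stored.max() > 65535:
        raise ValueError(
            f"HU range [{arr.min()}, {arr.max()}] does not fit unsigned 16-bit "
            "storage with intercept -1000"
        )
    stored16 = stored.astype(np.uint16)

    digest = hashlib.sha256(stored16.tobytes() + series_description.encode()).hexdigest()
    sop_uid = generate_uid(entropy_srcs=[digest, "sop"])
    series_uid = generate_uid(entropy_srcs=[digest, "series"])
    study_uid = generate_uid(entropy_srcs=[digest, "study"])

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = sop_uid
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = study_uid
    ds.Modality = "OT"
    ds.SeriesDescription = series_description
    ds.PatientName = "PHANTOM^SYNTHETIC"
    ds.PatientID = "cbctqa"
    ds.ContentDate = "20200101"
    ds.ContentTime = "000000"
    ds.StudyDate = "20200101"
    ds.StudyTime = "000000"
    ds.Rows, ds.Columns = stored16.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleIntercept = -1000.0
    ds.RescaleSlope = 1.0
    ds.RescaleType = "HU"
    ds.PixelSpacing = [f"{pixel_spacing[0]:.6g}", f"{pixel_spacing[1]:.6g}"]
    ds.PixelData = stored16.tobytes()
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Structured run configuration (YAML file, unknown keys rejected)."""

    tld: str | None = None
    weighting: str | None = None
    measures: str | None = None
    exposure: str | None = None
    slices: str | None = None
    vois: str | None = None
    out_dir: str | None = None
    background_policy: str = "allow_negative"
    decimal_comma: bool = False
    reference_protocol: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.background_policy not in ("allow_negative", "clamp"):
            raise SchemaError(
                f"background_policy must be 'allow_negative' or 'clamp', "
                f"got {self.background_policy!r}"
            )


def read_config(path) -> StudyConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    known = {f.name for f in dc_fields(StudyConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s) {unknown}")
    cfg = StudyConfig(**data)
    base = Path(path).parent
    for name in ("tld", "weighting", "measures", "exposure", "slices", "vois", "out_dir"):
        val = getattr(cfg, name)
        if val is not None and not Path(val).is_absolute():
            setattr(cfg, name, str(base / val))
    return cfg


# ---------------------------------------------------------------------------
# bundled reference study
# ---------------------------------------------------------------------------

def write_reference_study(out_dir) -> dict[str, Path]:
    """Write the bundled reference phantom study as pipeline input files."""
    from . import reference

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tld": out / "tld_readouts.csv",
        "weighting": out / "tissue_weighting.csv",
        "exposure": out / "exposure_records.csv",
        "measures": out / "voi_measures.csv",
    }
    write_tld_csv(reference.reference_tld_readouts(), paths["tld"])
    write_weighting_csv(reference.reference_weighting(), paths["weighting"])
    write_exposure_csv(list(reference.reference_exposure()), paths["exposure"])
    write_measure_csv(reference.reference_voi_stats(), paths["measures"])
    return paths
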