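"""Tabular readers/writers and run configuration.

Detection tables are tab-separated UTF-8 in the shape of a
classification-platform export: one row per measured object, with at
least an object id, an area (in pixels or mm²) or ESD, a taxon, and the
id of the layer sample it came from.  Real exports carry dozens of extra
columns; unknown columns pass through untouched on read and are ignored
by the pipeline.

Numeric output is written at 6 significant digits so write-then-read
round trips are stable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import pandas as pd
import yaml

from .imaging import (
    PixelCalibration,
    area_px_to_mm2,
    biovolume_from_esd,
    esd_from_area,
)
from .population import Detection, DepthLayer, TowMetadata

__all__ = [
    "DetectionTableDialect",
    "RunConfig",
    "read_detection_table",
    "write_detection_table",
    "read_tow_metadata",
    "write_tow_metadata",
    "packaged_tow_fixture",
]

_FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class DetectionTableDialect:
    """Column mapping for a detection table export."""

    object_id: str = "object_id"
    sample_id: str = "sample_id"
    species: str = "species"
    stage: str = "stage"           # optional column
    area_px: str = "area_px"       # any one of area_px / area_mm2 / esd_mm suffices
    area_mm2: str = "area_mm2"
    esd_mm: str = "esd_mm"
    biovolume_mm3: str = "biovolume_mm3"


class ParseError(ValueError):
    """A table failed validation; the message names the row and column."""


def read_detection_table(
    path: str | Path,
    dialect: DetectionTableDialect | None = None,
    cal: PixelCalibration | None = None,
) -> list[Detection]:
    """Read a TSV detection table into validated :class:`Detection` rows.

    ESD is taken from the ESD column when present, else computed from
    mm² area, else from pixel area via ``cal``; biovolume likewise falls
    back to the sphere formula.  Missing required columns and negative
    areas raise :class:`ParseError` naming the offending row/column.
    """
    dia = dialect or DetectionTableDialect()
    df = pd.read_csv(path, sep="\t", dtype={dia.object_id: str, dia.sample_id: str})

    for col in (dia.object_id, dia.sample_id, dia.species):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    size_cols = [c for c in (dia.esd_mm, dia.area_mm2, dia.area_px) if c in df.columns]
    if not size_cols:
        raise ParseError(
            f"{path}: need one of {dia.esd_mm!r}, {dia.area_mm2!r}, {dia.area_px!r}"
        )

    out: list[Detection] = []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based, counting the header line
        try:
            if dia.esd_mm in df.columns and pd.notna(row[dia.esd_mm]):
                esd = float(row[dia.esd_mm])
                area = float(row[dia.area_mm2]) if dia.area_mm2 in df.columns and pd.notna(
                    row.get(dia.area_mm2)
                ) else None
            elif dia.area_mm2 in df.columns and pd.notna(row.get(dia.area_mm2)):
                area = float(row[dia.area_mm2])
                if area < 0:
                    raise ValueError(f"negative area in column {dia.area_mm2!r}")
                esd = esd_from_area(area)
            else:
                px = float(row[dia.area_px])
                if px < 0:
                    raise ValueError(f"negative area in column {dia.area_px!r}")
                area = area_px_to_mm2(px, cal)
                esd = esd_from_area(area)
            if dia.biovolume_mm3 in df.columns and pd.notna(row.get(dia.biovolume_mm3)):
                bv = float(row[dia.biovolume_mm3])
            else:
                bv = biovolume_from_esd(esd)
            stage = None
            if dia.stage in df.columns and pd.notna(row.get(dia.stage)):
                stage = str(row[dia.stage])
            out.append(
                Detection(
                    object_id=str(row[dia.object_id]),
                    sample_id=str(row[dia.sample_id]),
                    species=str(row[dia.species]),
                    stage=stage,
                    esd_mm=esd,
                    area_mm2=area,
                    biovolume_mm3=bv,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}: row {rowno}: {exc}") from exc
    return out


def write_detection_table(detections: list[Detection], path: str | Path) -> None:
    """Write detections as TSV (6-significant-digit floats)."""
    df = pd.DataFrame(
        {
            "object_id": [d.object_id for d in detections],
            "sample_id": [d.sample_id for d in detections],
            "species": [d.species for d in detections],
            "stage": [d.stage if d.stage is not None else "" for d in detections],
            "area_mm2": [d.area_mm2 for d in detections],
            "esd_mm": [d.esd_mm for d in detections],
            "biovolume_mm3": [d.sphere_biovolume_mm3 for d in detections],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _parse_fraction(value) -> float:
    """Aliquots may be written '1/128' or as a decimal."""
    if isinstance(value, str) and "/" in value:
        return float(Fraction(value))
    return float(value)


def read_tow_metadata(path: str | Path) -> list[TowMetadata]:
    """Read tow-layer metadata TSV into validated :class:`TowMetadata`.

    Requires columns ``sample_id, top_m, bottom_m, filtered_volume_m3,
    aliquot_fraction``; ``date``, ``day_night``, ``mesh_um`` and
    ``mouth_area_m2`` are optional.  Layers within each (date,
    day_night) tow must be non-overlapping.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "top_m", "bottom_m", "filtered_volume_m3", "aliquot_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")

    metas: list[TowMetadata] = []
    for i, row in df.iterrows():
        try:
            metas.append(
                TowMetadata(
                    sample_id=str(row.sample_id),
                    layer=DepthLayer(float(row.top_m), float(row.bottom_m)),
                    filtered_volume_m3=float(row.filtered_volume_m3),
                    aliquot_fraction=_parse_fraction(row.aliquot_fraction),
                    date=str(row.date) if "date" in df.columns else None,
                    day_night=str(row.day_night) if "day_night" in df.columns else None,
                    mesh_um=float(row.mesh_um) if "mesh_um" in df.columns else 335.0,
                    mouth_area_m2=float(row.mouth_area_m2)
                    if "mouth_area_m2" in df.columns
                    else 1.5,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from exc

    # layers must not overlap within one tow (same date + phase)
    by_tow: dict[tuple, list[TowMetadata]] = {}
    for m in metas:
        by_tow.setdefault((m.date, m.day_night), []).append(m)
    for key, group in by_tow.items():
        ordered = sorted(group, key=lambda m: m.layer.top_m)
        for a, b in zip(ordered, ordered[1:]):
            if a.layer.overlaps(b.layer):
                raise ParseError(
                    f"{path}: tow {key}: overlapping layers "
                    f"{a.sample_id} {a.layer} / {b.sample_id} {b.layer}"
                )
    return metas


def write_tow_metadata(metas: list[TowMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "date": [m.date for m in metas],
            "day_night": [m.day_night for m in metas],
            "top_m": [m.layer.top_m for m in metas],
            "bottom_m": [m.layer.bottom_m for m in metas],
            "filtered_volume_m3": [m.filtered_volume_m3 for m in metas],
            "aliquot_fraction": [m.aliquot_fraction for m in metas],
            "mesh_um": [m.mesh_um for m in metas],
            "mouth_area_m2": [m.mouth_area_m2 for m in metas],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def packaged_tow_fixture() -> list[TowMetadata]:
    """The packaged eight-tow (four seasons × day/night), eight-layer
    metadata fixture.  Depth layers, dates and day/night flags follow the
    published sampling scheme; filtered volumes are plausible synthetic
    values (the field flowmeter data are unpublished)."""
    import importlib.resources

    ref = importlib.resources.files("zoopop.data") / "tows_k2.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_tow_metadata(path)


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run, serialisable to YAML.

    Written alongside every output directory so a run can be reproduced
    exactly from its own provenance record.
    """

    pixel_pitch_um: float = 10.58
    bin_width_mm: float = 0.1
    min_area_px: int = 30
    threshold: str | float = "otsu"
    ambiguity_ratio: float = 3.0
    metridia_threshold_mm: float = 2.0
    seed: int | None = None
    inputs: dict = dataclasses.field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.pixel_pitch_um <= 0 or cfg.bin_width_mm <= 0:
            raise ParseError(f"{path}: pixel pitch and bin width must be > 0")
        return cfg
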