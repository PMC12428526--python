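"""Depth-stratified abundance and biovolume accounting.

The sampling design this module serves is a multi-net system that samples
eight discrete depth layers between the surface and 1,000 m, by day and by
night.  Each layer sample is subsampled (an *aliquot*) before scanning, so
the chain from counted individuals to population quantities is:

    concentration (per m³)  = (count / aliquot_fraction) / filtered_volume
    areal (per m²)          = concentration × layer thickness
    column total (per m²)   = Σ areal over layers
    layer fraction          = areal / column total

The same arithmetic applies when "count" is replaced by summed individual
biovolume (mm³ instead of individuals).

The weighted mean depth (WMD) of a profile — the areal-abundance-weighted
mean of layer midpoints — summarises residence depth; the day-minus-night
difference in WMD is the diel vertical migration (DVM) amplitude.  A
positive amplitude means the population sits shallower at night.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np

__all__ = [
    "STANDARD_LAYERS",
    "DepthLayer",
    "TowMetadata",
    "Detection",
    "LayerMeasure",
    "VerticalProfile",
    "concentration",
    "areal_from_concentration",
    "build_profile",
    "weighted_mean_depth",
    "dvm_amplitude",
]


@dataclass(frozen=True, order=True)
class DepthLayer:
    """One sampled depth stratum, metres below surface (positive downward)."""

    top_m: float
    bottom_m: float

    def __post_init__(self) -> None:
        if not (0 <= self.top_m < self.bottom_m):
            raise ValueError(
                f"invalid layer bounds: top={self.top_m}, bottom={self.bottom_m}"
            )

    @property
    def thickness_m(self) -> float:
        return self.bottom_m - self.top_m

    @property
    def midpoint_m(self) -> float:
        return (self.top_m + self.bottom_m) / 2.0

    def overlaps(self, other: "DepthLayer") -> bool:
        return self.top_m < other.bottom_m and other.top_m < self.bottom_m


#: The eight standard strata of the 0–1,000 m sampling scheme.
STANDARD_LAYERS: tuple[DepthLayer, ...] = tuple(
    DepthLayer(t, b)
    for t, b in [
        (0, 50), (50, 100), (100, 150), (150, 200),
        (200, 300), (300, 500), (500, 750), (750, 1000),
    ]
)


@dataclass(frozen=True)
class TowMetadata:
    """One net-tow layer sample and its scaling factors.

    ``aliquot_fraction`` is the proportion of the sample actually scanned
    (1/2 … 1/128 in practice); counts are divided by it.  ``mesh_um`` and
    ``mouth_area_m2`` are informational (335 µm, 1.5 m² for the sampler
    this emulates).
    """

    sample_id: str
    layer: DepthLayer
    filtered_volume_m3: float
    aliquot_fraction: float
    date: _date | str | None = None
    day_night: str | None = None  # "D" or "N"
    mesh_um: float = 335.0
    mouth_area_m2: float = 1.5

    def __post_init__(self) -> None:
        if not self.filtered_volume_m3 > 0:
            raise ValueError(
                f"{self.sample_id}: filtered_volume_m3 must be > 0, "
                f"got {self.filtered_volume_m3}"
            )
        if not 0 < self.aliquot_fraction <= 1:
            raise ValueError(
                f"{self.sample_id}: aliquot_fraction must be in (0, 1], "
                f"got {self.aliquot_fraction}"
            )
        if self.day_night is not None and self.day_night not in ("D", "N"):
            raise ValueError(f"{self.sample_id}: day_night must be 'D' or 'N'")


@dataclass(frozen=True)
class Detection:
    """One measured individual, linked to the layer sample it came from."""

    object_id: str
    sample_id: str
    species: str
    esd_mm: float
    area_mm2: float | None = None
    biovolume_mm3: float | None = None
    stage: str | None = None

    def __post_init__(self) -> None:
        if not self.esd_mm > 0:
            raise ValueError(f"{self.object_id}: esd_mm must be > 0")
        if self.biovolume_mm3 is not None:
            expected = (4.0 / 3.0) * math.pi * (self.esd_mm / 2.0) ** 3
            # 1e-4 accommodates tables round-tripped at 6 significant digits
            if not math.isclose(self.biovolume_mm3, expected, rel_tol=1e-4):
                raise ValueError(
                    f"{self.object_id}: biovolume {self.biovolume_mm3} inconsistent "
                    f"with ESD {self.esd_mm} (expected {expected:.6g})"
                )

    @property
    def sphere_biovolume_mm3(self) -> float:
        if self.biovolume_mm3 is not None:
            return self.biovolume_mm3
        return (4.0 / 3.0) * math.pi * (self.esd_mm / 2.0) ** 3


@dataclass(frozen=True)
class LayerMeasure:
    """Per-layer concentration, areal value and water-column fraction."""

    layer: DepthLayer
    conc: float          # per m³
    areal: float         # per m²
    fraction: float      # of the water-column total; NaN when total is 0


@dataclass(frozen=True)
class VerticalProfile:
    """A stack of :class:`LayerMeasure` with its water-column total."""

    layers: tuple[LayerMeasure, ...]
    column_total: float  # per m²
    measure: str         # "abundance" or "biovolume"

    def fraction_in(self, layer: DepthLayer) -> float:
        for lm in self.layers:
            if lm.layer == layer:
                return lm.fraction
        raise KeyError(f"layer {layer} not in profile")

    def fractions(self) -> np.ndarray:
        return np.array([lm.fraction for lm in self.layers])


def concentration(count_in_aliquot: float, meta: TowMetadata) -> float:
    """Whole-sample concentration (per m³) from an aliquot count.

    ``(count / aliquot_fraction) / filtered_volume_m3``; identical for a
    summed biovolume per aliquot (mm³ m⁻³).
    """
    if count_in_aliquot < 0:
        raise ValueError("count must be >= 0")
    return (count_in_aliquot / meta.aliquot_fraction) / meta.filtered_volume_m3


def areal_from_concentration(conc: float, layer: DepthLayer) -> float:
    """Areal value (per m²) = concentration × layer thickness.

    Multiplying a per-m³ concentration by the metres of water the net
    fished (the layer's thickness) is what makes layer values addable
    into a per-m² water-column total.
    """
    return conc * layer.thickness_m


def _check_layers(metas: list[TowMetadata]) -> None:
    ordered = sorted(metas, key=lambda m: m.layer.top_m)
    for a, b in zip(ordered, ordered[1:]):
        if a.layer.overlaps(b.layer):
            raise ValueError(
                f"overlapping layers: {a.sample_id} {a.layer} vs {b.sample_id} {b.layer}"
            )


def build_profile(
    detections: list[Detection],
    metas: list[TowMetadata],
    measure: str = "abundance",
    species: str | None = None,
    stage: str | None = None,
    expected_layers: tuple[DepthLayer, ...] | None = STANDARD_LAYERS,
    allow_partial: bool = False,
) -> VerticalProfile:
    """Aggregate detections into a depth-stratified vertical profile.

    Every detection's ``sample_id`` must appear in ``metas``; detections
    are optionally filtered to one species (and stage) first.  Layers the
    metadata does not cover are *missing*, not zero: unless
    ``allow_partial`` is set, a profile over ``expected_layers`` that
    lacks one of them is an error, because the column total would be an
    underestimate.

    Layer fractions are NaN when the column total is zero.
    """
    if measure not in ("abundance", "biovolume"):
        raise ValueError(f"unknown measure {measure!r}")
    if not metas:
        raise ValueError("no tow metadata given")
    _check_layers(metas)

    meta_by_id = {m.sample_id: m for m in metas}
    if len(meta_by_id) != len(metas):
        raise ValueError("duplicate sample_id in metadata")

    if expected_layers is not None and not allow_partial:
        covered = {m.layer for m in metas}
        missing = [l for l in expected_layers if l not in covered]
        if missing:
            raise ValueError(
                f"layers not sampled: {missing}; pass allow_partial=True to "
                "accept a partial water column"
            )

    dets = [
        d for d in detections
        if (species is None or d.species == species)
        and (stage is None or d.stage == stage)
    ]
    for d in dets:
        if d.sample_id not in meta_by_id:
            raise KeyError(
                f"detection {d.object_id} references unknown sample_id "
                f"{d.sample_id!r}"
            )

    per_sample: dict[str, float] = {m.sample_id: 0.0 for m in metas}
    for d in dets:
        per_sample[d.sample_id] += 1.0 if measure == "abundance" else d.sphere_biovolume_mm3

    areals: list[tuple[DepthLayer, float, float]] = []
    for m in sorted(metas, key=lambda m: m.layer.top_m):
        conc = concentration(per_sample[m.sample_id], m)
        areals.append((m.layer, conc, areal_from_concentration(conc, m.layer)))

    total = sum(a for _, _, a in areals)
    layer_measures = tuple(
        LayerMeasure(
            layer=layer,
            conc=conc,
            areal=areal,
            fraction=(areal / total) if total > 0 else float("nan"),
        )
        for layer, conc, areal in areals
    )
    return VerticalProfile(layers=layer_measures, column_total=total, measure=measure)


def weighted_mean_depth(profile: VerticalProfile) -> float:
    """Areal-weighted mean of layer midpoints (m).

    A resolution-limited residence-depth summary: with eight layers the
    estimate cannot resolve structure finer than the layer midpoint
    spacing.
    """
    if profile.column_total <= 0:
        raise ValueError("weighted mean depth undefined for an empty profile")
    num = sum(lm.layer.midpoint_m * lm.areal for lm in profile.layers)
    return num / profile.column_total


def dvm_amplitude(day: VerticalProfile, night: VerticalProfile) -> float:
    """Diel vertical-migration amplitude: WMD(day) − WMD(night), metres.

    Positive when the population sits shallower at night (classic DVM);
    near zero for populations with no diel change, e.g. a seasonal
    vertical migrant resident at depth both day and night.
    """
    day_scheme = tuple(lm.layer for lm in day.layers)
    night_scheme = tuple(lm.layer for lm in night.layers)
    if day_scheme != night_scheme:
        raise ValueError("day and night profiles use different layer schemes")
    return weighted_mean_depth(day) - weighted_mean_depth(night)
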