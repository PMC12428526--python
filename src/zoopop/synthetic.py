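"""Synthetic net-tow samples and scan images with known ground truth.

No per-individual field data are available for the sampling programme
this package models, so every pipeline stage is exercised against
populations generated here.  The generator reproduces the statistical
structure the analysis assumes:

* individuals belong to copepodite-stage cohorts whose ESD is Normal
  (stage mean, sd), truncated at zero by resampling, with the packaged
  stage reference as the default parameters;
* each individual occupies one of the eight standard depth layers, drawn
  from an explicit day or night probability vector (per stage where the
  behaviour is stage-specific, e.g. adult males that skip the nocturnal
  ascent);
* physical subsampling is emulated by binomial aliquot thinning — each
  individual survives the split with probability ``aliquot_fraction`` —
  rather than deterministic division, matching how a plankton splitter
  actually behaves.

Presets encode the qualitative vertical-distribution patterns of the two
study species (a diel vertical migrant and a seasonal vertical migrant)
as explicit per-layer probability vectors, so tests compare pipeline
output against the preset's own ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import draw as _draw

from .population import Detection, DepthLayer, STANDARD_LAYERS, TowMetadata
from .size_structure import load_packaged_stage_reference

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "generate_population",
    "generate_scan_image",
    "preset",
    "stage_cohort_config",
    "PRESET_NAMES",
]

#: Per-layer aliquot fractions for field scenarios: small splits where the
#: catch is dense (surface), whole or half samples at depth.
_FIELD_ALIQUOTS = (1 / 32, 1 / 16, 1 / 16, 1 / 8, 1 / 8, 1 / 8, 1 / 4, 1 / 2)
#: Filtered volume per layer: thickness x 1.5 m2 mouth x oblique path factor 2.
_FIELD_VOLUMES = tuple(l.thickness_m * 1.5 * 2.0 for l in STANDARD_LAYERS)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one synthetic sampling scenario.

    ``day_dist``/``night_dist`` are probability vectors over the eight
    standard layers; ``stage_dists`` overrides them for individual stages.
    ``n_individuals`` is the population size generated *per phase* (day
    and night each), before aliquot thinning.
    """

    name: str
    species: str
    season: str
    stage_weights: dict[str, float]
    stage_params: dict[str, tuple[float, float]]  # stage -> (mean, sd) mm
    day_dist: tuple[float, ...]
    night_dist: tuple[float, ...]
    stage_dists: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = field(
        default_factory=dict
    )  # stage -> (day, night)
    layers: tuple[DepthLayer, ...] = STANDARD_LAYERS
    filtered_volume_m3: tuple[float, ...] = _FIELD_VOLUMES
    aliquot_fraction: tuple[float, ...] = _FIELD_ALIQUOTS
    n_individuals: int = 2000
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.layers)
        for label, dist in [("day", self.day_dist), ("night", self.night_dist)] + [
            (f"{st} {ph}", d)
            for st, (dd, nd) in self.stage_dists.items()
            for ph, d in [("day", dd), ("night", nd)]
        ]:
            if len(dist) != n:
                raise ValueError(f"{label} distribution has {len(dist)} layers, expected {n}")
            if any(p < 0 for p in dist) or not math.isclose(sum(dist), 1.0, abs_tol=1e-9):
                raise ValueError(f"{label} distribution must be nonnegative and sum to 1")
        if not self.stage_weights or any(w < 0 for w in self.stage_weights.values()):
            raise ValueError("stage weights must be nonnegative and nonempty")
        if sum(self.stage_weights.values()) <= 0:
            raise ValueError("stage weights must not all be zero")
        for st, (mu, sd) in self.stage_params.items():
            if mu <= 0 or sd <= 0:
                raise ValueError(f"stage {st}: mean and sd must be > 0")
        for st in self.stage_weights:
            if st not in self.stage_params:
                raise ValueError(f"stage {st} has a weight but no (mean, sd)")
        if len(self.filtered_volume_m3) != n or len(self.aliquot_fraction) != n:
            raise ValueError("per-layer volume/aliquot vectors must match the layer scheme")
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")

    def dist_for(self, stage: str, phase: str) -> tuple[float, ...]:
        """Resolved layer distribution for a stage in phase ``"D"``/``"N"``."""
        if stage in self.stage_dists:
            day, night = self.stage_dists[stage]
            return day if phase == "D" else night
        return self.day_dist if phase == "D" else self.night_dist


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for oracle-style comparisons.

    ``individuals`` holds every generated individual (kept or thinned
    away) with its phase, true stage, ESD and layer index.  For scan
    images, ``object_areas`` records the exact rasterised pixel count of
    each placed object.
    """

    config: ScenarioConfig | None = None
    individuals: pd.DataFrame | None = None
    object_areas: tuple[int, ...] = ()

    def true_fraction(self, phase: str, layer_index: int) -> float:
        """Population-level layer probability (stage-weight mixture)."""
        cfg = self.config
        total_w = sum(cfg.stage_weights.values())
        return sum(
            w / total_w * cfg.dist_for(st, phase)[layer_index]
            for st, w in cfg.stage_weights.items()
        )


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float, n: int) -> np.ndarray:
    """Normal(mu, sd) truncated to (0, inf) by resampling."""
    out = rng.normal(mu, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mu, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def generate_population(
    config: ScenarioConfig, seed: int | None = None
) -> tuple[list[Detection], list[TowMetadata], GroundTruth]:
    """Generate detections and tow metadata for one day + night tow pair.

    For each phase, ``n_individuals`` individuals are drawn: stage from
    the abundance weights, ESD from the stage's truncated Normal, layer
    from the phase's (per-stage) vertical distribution.  Each individual
    then survives the aliquot split with its layer's
    ``aliquot_fraction``; only survivors appear in the detection table,
    but every individual is recorded in the ground truth.

    Fully reproducible: the same ``seed`` (or ``config.seed``) gives
    identical tables.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    stages = list(config.stage_weights)
    weights = np.array([config.stage_weights[s] for s in stages], dtype=float)
    weights = weights / weights.sum()

    metas: list[TowMetadata] = []
    for phase in ("D", "N"):
        for i, layer in enumerate(config.layers):
            metas.append(
                TowMetadata(
                    sample_id=f"{config.name}_{phase}_L{i + 1}",
                    layer=layer,
                    filtered_volume_m3=config.filtered_volume_m3[i],
                    aliquot_fraction=config.aliquot_fraction[i],
                    day_night=phase,
                    date=config.season,
                )
            )

    records = []
    detections: list[Detection] = []
    obj = 0
    for phase in ("D", "N"):
        n = config.n_individuals
        if n == 0:
            continue
        stage_idx = rng.choice(len(stages), size=n, p=weights)
        layer_idx = np.empty(n, dtype=int)
        esd = np.empty(n)
        for k, st in enumerate(stages):
            sel = stage_idx == k
            m = int(sel.sum())
            if m == 0:
                continue
            mu, sd = config.stage_params[st]
            esd[sel] = _truncated_normal(rng, mu, sd, m)
            dist = np.asarray(config.dist_for(st, phase), dtype=float)
            layer_idx[sel] = rng.choice(len(config.layers), size=m, p=dist / dist.sum())
        keep = rng.random(n) < np.asarray(config.aliquot_fraction)[layer_idx]

        for j in range(n):
            st = stages[stage_idx[j]]
            records.append(
                {
                    "phase": phase,
                    "stage": st,
                    "esd_mm": esd[j],
                    "layer_index": int(layer_idx[j]),
                    "kept": bool(keep[j]),
                }
            )
            if keep[j]:
                obj += 1
                d = float(esd[j])
                detections.append(
                    Detection(
                        object_id=f"{config.name}_{obj:06d}",
                        sample_id=f"{config.name}_{phase}_L{layer_idx[j] + 1}",
                        species=config.species,
                        stage=st,
                        esd_mm=d,
                        area_mm2=math.pi * (d / 2.0) ** 2,
                        biovolume_mm3=(4.0 / 3.0) * math.pi * (d / 2.0) ** 3,
                    )
                )

    truth = GroundTruth(
        config=config,
        individuals=pd.DataFrame(
            records, columns=["phase", "stage", "esd_mm", "layer_index", "kept"]
        ),
    )
    return detections, metas, truth


# ---------------------------------------------------------------------------
# scan-image fixtures


def generate_scan_image(
    n_objects: int,
    size_range_px: tuple[int, int] = (10, 30),
    shape: tuple[int, int] = (512, 512),
    noise_sd: float = 4.0,
    seed: int | None = None,
    background_level: int = 230,
    object_level: int = 60,
    max_retries: int = 200,
) -> tuple[np.ndarray, GroundTruth]:
    """Render dark filled ellipses on a light noisy background.

    Objects are placed by rejection so that their bounding circles never
    touch (at least one background pixel between any two objects); the
    ground truth records each object's exact rasterised pixel count — the
    oracle the segmentation tests measure against.

    Returns an ``uint8`` image and a :class:`GroundTruth` whose
    ``object_areas`` are the true areas in placement order.
    """
    if n_objects < 0:
        raise ValueError("n_objects must be >= 0")
    lo, hi = size_range_px
    if not (0 < lo <= hi):
        raise ValueError("size_range_px must satisfy 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full(shape, float(background_level))

    placed: list[tuple[float, float, float]] = []  # (row, col, bounding radius)
    areas: list[int] = []
    for _ in range(n_objects):
        for attempt in range(max_retries):
            a = rng.uniform(lo, hi)            # semi-major axis
            b = rng.uniform(0.6 * a, a)        # semi-minor axis
            theta = rng.uniform(0, math.pi)
            r = rng.uniform(a + 2, h - a - 2)
            c = rng.uniform(a + 2, w - a - 2)
            if all(
                math.hypot(r - pr, c - pc) > a + prad + 2 for pr, pc, prad in placed
            ):
                break
        else:
            raise RuntimeError(
                f"could not place object {len(placed) + 1} without overlap "
                f"after {max_retries} retries"
            )
        rr, cc = _draw.ellipse(r, c, a, b, shape=shape, rotation=theta)
        img[rr, cc] = object_level
        placed.append((r, c, a))
        areas.append(int(len(rr)))

    img = img + rng.normal(0.0, noise_sd, size=shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, GroundTruth(object_areas=tuple(areas))


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = (
    "mpacifica_dvm",
    "ebungii_svm_october",
    "ebungii_july_recruitment",
    "metridia_mixture",
)

_REF = None


def _packaged_params(species: str) -> dict[str, tuple[float, float]]:
    global _REF
    if _REF is None:
        _REF = load_packaged_stage_reference()
    sub = _REF.rows_for(species)
    return {
        row.stage: (float(row.mean_esd_mm), float(row.sd_esd_mm))
        for row in sub.itertuples()
    }


def preset(name: str, n_individuals: int = 2000, seed: int | None = None) -> ScenarioConfig:
    """Return a documented scenario configuration.

    ``mpacifica_dvm``
        *M. pacifica* across all stages: deep daytime modes, a strong
        0–50 m nocturnal mode, except adult males which stay deep both
        day and night.
    ``ebungii_svm_october``
        *E. bungii* in its dormant season: stages C3 and later, ~90% of
        the population at 200–500 m with identical day and night
        distributions (seasonal, not diel, migration).
    ``ebungii_july_recruitment``
        Summer recruitment: young stages (C1–C4) dominate and sit in the
        0–50 m surface layer day and night; the few later stages are
        deeper.
    ``metridia_mixture``
        *M. pacifica* stage cohorts plus a >2-mm congener component (the
        large *Metridia* species group, not resolvable to species by
        ESD), for exercising the 2-mm size split.
    """
    day_deep = (0.02, 0.08, 0.20, 0.20, 0.25, 0.15, 0.07, 0.03)
    night_surface = (0.60, 0.15, 0.08, 0.05, 0.05, 0.04, 0.02, 0.01)
    c6m_deep = (0.00, 0.02, 0.08, 0.15, 0.30, 0.30, 0.10, 0.05)

    if name == "mpacifica_dvm":
        return ScenarioConfig(
            name=name,
            species="mpacifica",
            season="Oct",
            stage_weights={
                "C1": 0.20, "C2": 0.18, "C3": 0.16, "C4F": 0.09, "C4M": 0.09,
                "C5F": 0.08, "C5M": 0.06, "C6F": 0.08, "C6M": 0.06,
            },
            stage_params=_packaged_params("mpacifica"),
            day_dist=day_deep,
            night_dist=night_surface,
            stage_dists={"C6M": (c6m_deep, c6m_deep)},  # males skip the ascent
            n_individuals=n_individuals,
            seed=seed,
        )
    if name == "ebungii_svm_october":
        at_depth = (0.00, 0.00, 0.02, 0.03, 0.45, 0.45, 0.04, 0.01)
        return ScenarioConfig(
            name=name,
            species="ebungii",
            season="Oct",
            stage_weights={
                "C3": 0.10, "C4F": 0.15, "C4M": 0.10, "C5F": 0.20,
                "C5M": 0.15, "C6F": 0.20, "C6M": 0.10,
            },
            stage_params=_packaged_params("ebungii"),
            day_dist=at_depth,
            night_dist=at_depth,  # no diel change: SVM resident at depth
            n_individuals=n_individuals,
            seed=seed,
        )
    if name == "ebungii_july_recruitment":
        surface = (0.70, 0.15, 0.05, 0.04, 0.03, 0.02, 0.007, 0.003)
        mid = (0.05, 0.10, 0.15, 0.15, 0.25, 0.20, 0.06, 0.04)
        return ScenarioConfig(
            name=name,
            species="ebungii",
            season="Jul",
            stage_weights={
                "C1": 0.30, "C2": 0.25, "C3": 0.20, "C4F": 0.08, "C4M": 0.07,
                "C5F": 0.04, "C5M": 0.03, "C6F": 0.02, "C6M": 0.01,
            },
            stage_params=_packaged_params("ebungii"),
            day_dist=surface,
            night_dist=surface,
            stage_dists={
                st: (mid, mid) for st in ("C5F", "C5M", "C6F", "C6M")
            },
            n_individuals=n_individuals,
            seed=seed,
        )
    if name == "metridia_mixture":
        params = _packaged_params("mpacifica")
        # >2-mm congener group (M. okhotensis / asymmetrica / curticauda)
        params["LARGE_C6F"] = (2.75, 0.25)
        return ScenarioConfig(
            name=name,
            species="metridia_spp",
            season="Oct",
            stage_weights={
                "C1": 0.18, "C2": 0.16, "C3": 0.14, "C4F": 0.08, "C4M": 0.08,
                "C5F": 0.08, "C5M": 0.06, "C6F": 0.07, "C6M": 0.05,
                "LARGE_C6F": 0.10,
            },
            stage_params=params,
            day_dist=day_deep,
            night_dist=night_surface,
            n_individuals=n_individuals,
            seed=seed,
        )
    raise KeyError(f"unknown preset {name!r}; known: {PRESET_NAMES}")


def stage_cohort_config(
    species: str, stage: str, n_individuals: int = 1000, seed: int | None = None
) -> ScenarioConfig:
    """Single-stage cohort with no aliquot splitting.

    Emulates the stage-reference measurement procedure: individuals of
    one sorted stage scanned in full (aliquot 1), so the recovered mean
    and sd estimate the cohort parameters directly.
    """
    params = _packaged_params(species)
    if stage not in params:
        raise KeyError(f"stage {stage!r} not in packaged reference for {species!r}")
    uniform = tuple([1.0 / len(STANDARD_LAYERS)] * len(STANDARD_LAYERS))
    return ScenarioConfig(
        name=f"{species}_{stage}_cohort",
        species=species,
        season="ref",
        stage_weights={stage: 1.0},
        stage_params={stage: params[stage]},
        day_dist=uniform,
        night_dist=uniform,
        aliquot_fraction=tuple([1.0] * len(STANDARD_LAYERS)),
        n_individuals=n_individuals,
        seed=seed,
    )
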