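"""Size-frequency structure: ESD histograms, size-by-depth matrices, and
copepodite-stage cohort assignment.

Copepods pass through six post-naupliar copepodite stages (C1–C6; C6 is
the adult, sexed F/M from C4 on), each occupying a fairly tight band of
body size.  Given a reference table of per-stage ESD mean ± sd, an
individual's stage can be assigned by Gaussian maximum posterior — with
the important caveat that late stages of some species overlap heavily in
ESD, so assignments carry posterior weights and an ambiguity flag rather
than pretending to certainty.

Histograms use 0.1-mm ESD bins by default, half-open ``[x, x + w)`` and
aligned to zero, weighted by each individual's areal-abundance
contribution so that the histogram total equals the water-column total.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .population import (
    Detection,
    DepthLayer,
    TowMetadata,
    STANDARD_LAYERS,
    areal_from_concentration,
    concentration,
)

__all__ = [
    "StageReference",
    "load_packaged_stage_reference",
    "stage_reference_from_measurements",
    "SizeHistogram",
    "esd_histogram",
    "SizeDepthMatrix",
    "size_depth_matrix",
    "StageAssignment",
    "classify_stage",
    "split_metridia",
]

#: C1 → C6 ordering used for display and the female growth-monotonicity check.
STAGE_ORDER = ("C1", "C2", "C3", "C4F", "C4M", "C5F", "C5M", "C6F", "C6M")

_BIN_EPS = 1e-9  # tolerance for half-open bin edges under float division


class StageReference:
    """Per-(species, stage) ESD mean and sd table.

    Thin wrapper over a DataFrame with columns
    ``species, stage, mean_esd_mm, sd_esd_mm``; rows with nonpositive mean
    or sd are rejected at construction.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"species", "stage", "mean_esd_mm", "sd_esd_mm"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"stage reference missing columns: {sorted(missing)}")
        bad = table[(table.mean_esd_mm <= 0) | (table.sd_esd_mm <= 0)]
        if len(bad):
            raise ValueError(
                f"stage reference rows with nonpositive mean/sd: "
                f"{bad[['species', 'stage']].to_dict('records')}"
            )
        if table.duplicated(["species", "stage"]).any():
            raise ValueError("duplicate (species, stage) rows in reference")
        self.table = table.reset_index(drop=True)

    def species(self) -> list[str]:
        return sorted(self.table.species.unique())

    def rows_for(self, species: str) -> pd.DataFrame:
        sub = self.table[self.table.species == species]
        if sub.empty:
            raise KeyError(f"species {species!r} not in stage reference")
        return sub

    def params(self, species: str, stage: str) -> tuple[float, float]:
        sub = self.rows_for(species)
        row = sub[sub.stage == stage]
        if row.empty:
            raise KeyError(f"stage {stage!r} not in reference for {species!r}")
        return float(row.mean_esd_mm.iloc[0]), float(row.sd_esd_mm.iloc[0])


def load_packaged_stage_reference() -> StageReference:
    """Load the packaged per-stage ESD reference for *Metridia pacifica*
    (``mpacifica``) and *Eucalanus bungii* (``ebungii``)."""
    ref = importlib.resources.files("zoopop.data") / "stage_reference.tsv"
    with importlib.resources.as_file(ref) as path:
        return StageReference(pd.read_csv(path, sep="\t"))


def stage_reference_from_measurements(
    measurements: dict[tuple[str, str], np.ndarray] | dict[str, np.ndarray],
    species: str | None = None,
) -> StageReference:
    """Build a stage reference from stage-sorted ESD measurements.

    ``measurements`` maps ``(species, stage)`` — or ``stage`` alone if
    ``species`` is given — to arrays of ESD values.  Mean and sd are the
    sample statistics (sd with the n−1 denominator).  Stages with fewer
    than 2 measurements are an error; a zero sample sd is rejected by the
    :class:`StageReference` invariant.
    """
    rows = []
    for key, values in measurements.items():
        if isinstance(key, tuple):
            sp, st = key
        else:
            if species is None:
                raise ValueError("species must be given for bare stage keys")
            sp, st = species, key
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(
                f"stage {sp}/{st}: need >= 2 measurements, got {arr.size}"
            )
        rows.append(
            {
                "species": sp,
                "stage": st,
                "mean_esd_mm": float(arr.mean()),
                "sd_esd_mm": float(arr.std(ddof=1)),
            }
        )
    return StageReference(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# histograms


@dataclass(frozen=True)
class SizeHistogram:
    """Abundance-weighted ESD histogram on half-open bins aligned to zero."""

    bin_width_mm: float
    edges: np.ndarray       # k+1 edges, multiples of bin_width
    values: np.ndarray      # k per-bin totals (weights summed)
    measure: str            # "areal", "count", ...

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def bin_of(self, esd_mm: float) -> int:
        """Index of the half-open bin containing ``esd_mm``."""
        return int(np.floor(esd_mm / self.bin_width_mm + _BIN_EPS))

    def modal_bin(self) -> tuple[float, float]:
        """(left edge, right edge) of the highest-valued bin."""
        i = int(np.argmax(self.values))
        return float(self.edges[i]), float(self.edges[i + 1])


def esd_histogram(
    esd_mm: np.ndarray,
    weights: np.ndarray | None = None,
    bin_width_mm: float = 0.1,
    measure: str = "count",
) -> SizeHistogram:
    """Histogram ESD values into half-open ``[x, x+w)`` bins.

    ``weights`` defaults to 1 per individual (raw counts); pass each
    individual's areal-abundance contribution to get a per-m² histogram.
    The histogram total equals the summed weights exactly (conservation).
    """
    if bin_width_mm <= 0:
        raise ValueError("bin_width_mm must be > 0")
    esd = np.asarray(esd_mm, dtype=float)
    w = np.ones_like(esd) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != esd.shape:
        raise ValueError("weights must match esd values in length")
    if (w < 0).any():
        raise ValueError("weights must be >= 0")

    if esd.size == 0:
        return SizeHistogram(
            bin_width_mm=bin_width_mm,
            edges=np.array([0.0, bin_width_mm]),
            values=np.zeros(1),
            measure=measure,
        )
    if (esd < 0).any():
        raise ValueError("ESD values must be >= 0")

    idx = np.floor(esd / bin_width_mm + _BIN_EPS).astype(int)
    n_bins = int(idx.max()) + 1
    values = np.zeros(n_bins)
    np.add.at(values, idx, w)
    edges = np.arange(n_bins + 1) * bin_width_mm
    return SizeHistogram(
        bin_width_mm=bin_width_mm, edges=edges, values=values, measure=measure
    )


# ---------------------------------------------------------------------------
# size-by-depth matrices


@dataclass(frozen=True)
class SizeDepthMatrix:
    """Percent of water-column areal abundance by (ESD bin × depth layer).

    ``cells[b, l]`` is the percentage of the water-column total found in
    ESD bin ``b`` within layer ``l``; the grand total is 100 when any
    individuals are present.
    """

    bin_edges: np.ndarray
    layers: tuple[DepthLayer, ...]
    cells: np.ndarray  # shape (n_bins, n_layers), percent

    @property
    def grand_total(self) -> float:
        return float(self.cells.sum())

    def bin_totals(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    def layer_totals(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{l.top_m:g}-{l.bottom_m:g}m" for l in self.layers]
        rows = [
            f"[{self.bin_edges[i]:.1f},{self.bin_edges[i + 1]:.1f})"
            for i in range(len(self.bin_edges) - 1)
        ]
        return pd.DataFrame(self.cells, index=rows, columns=cols)


def size_depth_matrix(
    detections: list[Detection],
    metas: list[TowMetadata],
    species: str | None = None,
    bin_width_mm: float = 0.1,
    expected_layers: tuple[DepthLayer, ...] | None = STANDARD_LAYERS,
    allow_partial: bool = False,
) -> SizeDepthMatrix:
    """Joint size × depth composition as percent of the water-column total.

    Each detection contributes its areal abundance
    (thickness / (aliquot × volume)) to the cell of its ESD bin and source
    layer; cells are then normalised to percent of the water-column total.
    """
    meta_by_id = {m.sample_id: m for m in metas}
    if expected_layers is not None and not allow_partial:
        covered = {m.layer for m in metas}
        missing = [l for l in expected_layers if l not in covered]
        if missing:
            raise ValueError(f"layers not sampled: {missing}")

    layers = tuple(sorted({m.layer for m in metas}, key=lambda l: l.top_m))
    layer_idx = {l: i for i, l in enumerate(layers)}

    dets = [d for d in detections if species is None or d.species == species]
    for d in dets:
        if d.sample_id not in meta_by_id:
            raise KeyError(f"detection {d.object_id} references unknown sample_id")

    if dets:
        max_esd = max(d.esd_mm for d in dets)
        n_bins = int(np.floor(max_esd / bin_width_mm + _BIN_EPS)) + 1
    else:
        n_bins = 1
    cells = np.zeros((n_bins, len(layers)))
    for d in dets:
        m = meta_by_id[d.sample_id]
        contrib = areal_from_concentration(concentration(1.0, m), m.layer)
        b = int(np.floor(d.esd_mm / bin_width_mm + _BIN_EPS))
        cells[b, layer_idx[m.layer]] += contrib

    total = cells.sum()
    if total > 0:
        cells = 100.0 * cells / total
    edges = np.arange(n_bins + 1) * bin_width_mm
    return SizeDepthMatrix(bin_edges=edges, layers=layers, cells=cells)


# ---------------------------------------------------------------------------
# stage assignment and the Metridia size split


@dataclass(frozen=True)
class StageAssignment:
    """Gaussian maximum-posterior stage call with its full posterior."""

    esd_mm: float
    species: str
    stage: str
    posteriors: dict[str, float]
    ambiguous: bool


def classify_stage(
    esd_mm: float,
    species: str,
    ref: StageReference,
    ambiguity_ratio: float = 3.0,
) -> StageAssignment:
    """Assign a copepodite stage from ESD by Gaussian maximum posterior.

    Posterior weight of each stage is proportional to the Normal density
    of ``esd_mm`` under that stage's (mean, sd), with equal priors.  When
    the best and second-best posteriors differ by less than
    ``ambiguity_ratio``, the call is flagged ambiguous — expected for
    late stages whose ESD bands overlap (e.g. a small adult male falling
    inside the C5 band), and deliberately never hidden.
    """
    if esd_mm <= 0:
        raise ValueError(f"esd_mm must be > 0, got {esd_mm}")
    sub = ref.rows_for(species)
    stages = list(sub.stage)
    dens = np.array(
        [
            stats.norm.pdf(esd_mm, loc=mu, scale=sd)
            for mu, sd in zip(sub.mean_esd_mm, sub.sd_esd_mm)
        ]
    )
    if dens.sum() == 0:
        # esd so far outside every band that all densities underflow:
        # fall back to nearest mean in sd units
        z = np.abs((esd_mm - sub.mean_esd_mm.to_numpy()) / sub.sd_esd_mm.to_numpy())
        post = np.zeros(len(stages))
        post[int(np.argmin(z))] = 1.0
    else:
        post = dens / dens.sum()

    order = np.argsort(post)[::-1]
    best = int(order[0])
    ambiguous = False
    if len(order) > 1 and post[order[1]] > 0:
        ambiguous = post[best] / post[order[1]] < ambiguity_ratio
    return StageAssignment(
        esd_mm=esd_mm,
        species=species,
        stage=stages[best],
        posteriors=dict(zip(stages, post.tolist())),
        ambiguous=ambiguous,
    )


def split_metridia(esd_mm: float, threshold_mm: float = 2.0) -> str:
    """Split *Metridia* detections by the 2-mm ESD boundary.

    *M. pacifica* stays below ~2 mm ESD at every stage, while its three
    larger congeners (*M. okhotensis*, *M. asymmetrica*, *M. curticauda*)
    exceed it; ESD alone cannot resolve the large group to species.
    Returns ``"pacifica"`` for ESD < threshold and ``"large_metridia"``
    otherwise (boundary assigned upward).
    """
    if esd_mm <= 0:
        raise ValueError(f"esd_mm must be > 0, got {esd_mm}")
    return "pacifica" if esd_mm < threshold_mm else "large_metridia"
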