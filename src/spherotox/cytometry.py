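"""Marker-based cell classification and per-spheroid readouts.

Cells are 3D nucleus objects, optionally paired with a calcein-positive
cytoplasm object. Viability follows the staining logic of the
live/dead assay: EthD-1 enters only membrane-compromised (dead) cells,
calcein AM marks metabolically active cytoplasm. On conflicting
evidence (both markers positive) the dead call wins — conservative
toward toxicity detection. The per-spheroid readout vector collects the
multi-parametric panel: live/dead counts, summed live-cell volume,
calcein intensities, spheroid volume/diameter, Hoechst intensity, and
mean internuclear distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from skimage import filters

from .vol3d import DEFAULT_CYTO_DISPLACEMENT_UM, Object3D, SpheroidRegion


class ScoringConfigError(ValueError):
    """Raised when a required channel/threshold is missing."""


@dataclass(frozen=True)
class ChannelRoles:
    """Which stack channel plays which biological role."""

    nuclear: str = "DAPI"
    live: str = "FITC"
    dead: str = "TexasRed"
    caspase: str | None = None
    mito: str | None = None


@dataclass(frozen=True)
class ScoreThresholds:
    """Mean-intensity cutoffs per marker channel (image intensity units)."""

    dead_mean: float
    live_mean: float | None = None
    caspase_mean: float | None = None
    mito_mean: float | None = None


@dataclass
class CellRecord:
    """One classified 3D cell."""

    nucleus: Object3D
    cytoplasm: Object3D | None = None
    viability: str = "live"  # exactly one of {"live", "dead"}
    caspase_positive: bool | None = None
    mito_intact: bool | None = None

    @property
    def is_live(self) -> bool:
        return self.viability == "live"


def estimate_threshold(values: Sequence[float], fallback: float) -> float:
    """Per-plate marker threshold: midpoint between the negative and
    positive intensity modes via Otsu, falling back to ``fallback`` when
    the pooled distribution is not usefully bimodal (e.g. an all-live
    plate, where any split would cut through noise)."""
    vals = np.asarray(values, dtype=float)
    if len(vals) < 4 or np.ptp(vals) == 0:
        return fallback
    thr = float(filters.threshold_otsu(vals))
    lo, hi = vals[vals <= thr], vals[vals > thr]
    if not len(lo) or not len(hi):
        return fallback
    spread = max(lo.std(), hi.std(), 1e-9)
    if (hi.mean() - lo.mean()) < 4.0 * spread:
        return fallback
    return thr


def match_cytoplasm(
    nuclei: Sequence[Object3D],
    cytoplasm: Sequence[Object3D],
    max_displacement_um: float = DEFAULT_CYTO_DISPLACEMENT_UM,
) -> dict[int, int]:
    """Optimal one-to-one nucleus->cytoplasm pairing by 3D centroid
    distance under the cytoplasm displacement cap. Returns a mapping of
    nucleus index to cytoplasm index."""
    if not nuclei or not cytoplasm:
        return {}
    big = 1e12
    cost = np.full((len(nuclei), len(cytoplasm)), big)
    for i, nuc in enumerate(nuclei):
        nx, ny, nz = nuc.centroid_um
        for j, cy in enumerate(cytoplasm):
            cx, cyy, cz = cy.centroid_um
            d = math.sqrt((nx - cx) ** 2 + (ny - cyy) ** 2 + (nz - cz) ** 2)
            if d <= max_displacement_um:
                cost[i, j] = d
    rows, cols = linear_sum_assignment(cost)
    return {i: j for i, j in zip(rows, cols) if cost[i, j] < big}


def score_cells(
    nuclei: Sequence[Object3D],
    cytoplasm: Sequence[Object3D] | None,
    thresholds: ScoreThresholds,
    roles: ChannelRoles | None = None,
    max_cyto_displacement_um: float = DEFAULT_CYTO_DISPLACEMENT_UM,
) -> list[CellRecord]:
    """Classify each nucleus as live or dead (plus optional marker flags).

    dead  <=>  nuclear EthD-1 mean >= threshold (EthD dominance: a cell
    both calcein+ and EthD+ is dead); live <=> not dead, i.e. EthD-1
    exclusion — whether or not a calcein cytoplasm was matched, since
    deep live cells can lose calcein signal before EthD turns positive.
    """
    if roles is None:
        roles = ChannelRoles()
    if not nuclei:
        return []
    if roles.dead not in nuclei[0].mean_intensity:
        raise ScoringConfigError(
            f"nuclei lack measurements for dead-marker channel {roles.dead!r}"
        )
    pairing = match_cytoplasm(nuclei, cytoplasm or [], max_cyto_displacement_um)
    records = []
    for i, nuc in enumerate(nuclei):
        dead = nuc.mean_intensity[roles.dead] >= thresholds.dead_mean
        rec = CellRecord(
            nucleus=nuc,
            cytoplasm=(cytoplasm[pairing[i]] if i in pairing else None),
            viability="dead" if dead else "live",
        )
        if roles.caspase is not None:
            if roles.caspase not in nuc.mean_intensity:
                raise ScoringConfigError(
                    f"nuclei lack caspase channel {roles.caspase!r}"
                )
            if thresholds.caspase_mean is None:
                raise ScoringConfigError("caspase_mean threshold not set")
            rec.caspase_positive = (
                nuc.mean_intensity[roles.caspase] >= thresholds.caspase_mean
            )
        if roles.mito is not None:
            src = rec.cytoplasm if (rec.cytoplasm is not None and
                                    roles.mito in rec.cytoplasm.mean_intensity) else nuc
            if roles.mito not in src.mean_intensity:
                raise ScoringConfigError(f"no measurements for mito channel {roles.mito!r}")
            if thresholds.mito_mean is None:
                raise ScoringConfigError("mito_mean threshold not set")
            rec.mito_intact = src.mean_intensity[roles.mito] >= thresholds.mito_mean
        records.append(rec)
    return records


def mean_internuclear_distance(cells: Sequence[CellRecord] | np.ndarray) -> float:
    """Mean over nuclei of the 3D nearest-neighbor centroid distance (μm).

    Accepts cell records or an (n, 3) array of centroids. With fewer
    than 2 nuclei the distance is undefined and NaN is returned.
    """
    if isinstance(cells, np.ndarray):
        pts = np.asarray(cells, dtype=float)
    else:
        pts = np.array([c.nucleus.centroid_um for c in cells], dtype=float)
    if len(pts) < 2:
        return float("nan")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    return float(dists[:, 1].mean())


@dataclass
class SpheroidReadout:
    """The multi-parametric per-well feature vector."""

    well_id: str
    dose_uM: float
    n_cells_total: int
    n_live: int
    n_dead: int
    sum_live_cell_volume_um3: float
    integrated_calcein_intensity: float
    mean_calcein_intensity: float
    spheroid_volume_um3: float
    spheroid_diameter_um: float
    mean_hoechst_intensity: float
    mean_internuclear_distance_um: float
    n_caspase_pos: int | None = None
    n_mito_intact: int | None = None
    compound_name: str = ""
    replicate_id: str = ""
    role: str = "treated"

    def __post_init__(self) -> None:
        if self.n_live + self.n_dead != self.n_cells_total:
            raise ValueError("n_live + n_dead must equal n_cells_total")

    def as_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


def spheroid_readouts(
    region: SpheroidRegion | None,
    cells: Sequence[CellRecord],
    well_id: str = "",
    dose_uM: float = 0.0,
    roles: ChannelRoles | None = None,
    **meta,
) -> SpheroidReadout:
    """Assemble the readout vector for one well.

    Summed live-cell volume and integrated calcein intensity come from
    the matched calcein-positive cytoplasm objects of live cells;
    whole-spheroid quantities (volume, diameter, mean channel
    intensities) come from the detected spheroid region when available.
    """
    if roles is None:
        roles = ChannelRoles()
    live = [c for c in cells if c.is_live]
    dead_n = len(cells) - len(live)
    live_cyto = [c.cytoplasm for c in live if c.cytoplasm is not None]
    sum_live_vol = float(sum(c.volume_um3 for c in live_cyto))
    integ_cal = float(sum(c.integrated_intensity.get(roles.live, 0.0)
                          for c in live_cyto))
    if region is not None:
        mean_cal = region.mean_intensity.get(roles.live, float("nan"))
        mean_hoechst = region.mean_intensity.get(roles.nuclear, float("nan"))
        sph_vol = region.volume_um3
        sph_diam = region.equivalent_diameter_um
    else:
        mean_cal = (float(np.mean([c.mean_intensity.get(roles.live, np.nan)
                                   for c in live_cyto]))
                    if live_cyto else float("nan"))
        mean_hoechst = (float(np.mean([c.nucleus.mean_intensity.get(roles.nuclear, np.nan)
                                       for c in cells]))
                        if cells else float("nan"))
        sph_vol = float("nan")
        sph_diam = float("nan")
    n_casp = None
    if cells and cells[0].caspase_positive is not None:
        n_casp = sum(bool(c.caspase_positive) for c in cells)
    n_mito = None
    if cells and cells[0].mito_intact is not None:
        n_mito = sum(bool(c.mito_intact) for c in cells)
    return SpheroidReadout(
        well_id=well_id,
        dose_uM=dose_uM,
        n_cells_total=len(cells),
        n_live=len(live),
        n_dead=dead_n,
        sum_live_cell_volume_um3=sum_live_vol,
        integrated_calcein_intensity=integ_cal,
        mean_calcein_intensity=mean_cal,
        spheroid_volume_um3=sph_vol,
        spheroid_diameter_um=sph_diam,
        mean_hoechst_intensity=mean_hoechst,
        mean_internuclear_distance_um=mean_internuclear_distance(cells),
        n_caspase_pos=n_casp,
        n_mito_intact=n_mito,
        **meta,
    )


NORMALIZED_FIELDS = (
    "n_live",
    "sum_live_cell_volume_um3",
    "integrated_calcein_intensity",
    "mean_calcein_intensity",
    "spheroid_volume_um3",
    "spheroid_diameter_um",
    "mean_hoechst_intensity",
    "mean_internuclear_distance_um",
)


def normalize_readouts(
    readouts: Sequence[SpheroidReadout],
    control_well_ids: Sequence[str],
) -> "pd.DataFrame":
    """Express readouts as % of the mean of the designated control wells.

    Every panel quantity is normalized to the control mean (control
    wells average 100% by construction); the dead-cell count is instead
    normalized to the total number of counted cells in the controls.
    """
    import pandas as pd

    controls = [r for r in readouts if r.well_id in control_well_ids]
    if not controls:
        raise ScoringConfigError("normalization requested but no control wells found")
    rows = []
    ctrl_total_cells = float(np.mean([c.n_cells_total for c in controls]))
    ctrl_means = {
        f: float(np.mean([getattr(c, f) for c in controls])) for f in NORMALIZED_FIELDS
    }
    for r in readouts:
        row = {"well_id": r.well_id, "dose_uM": r.dose_uM}
        for f in NORMALIZED_FIELDS:
            denom = ctrl_means[f]
            row[f + "_pct"] = 100.0 * getattr(r, f) / denom if denom else float("nan")
        row["n_dead_pct_of_control_cells"] = (
            100.0 * r.n_dead / ctrl_total_cells if ctrl_total_cells else float("nan")
        )
        rows.append(row)
    return pd.DataFrame(rows)
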